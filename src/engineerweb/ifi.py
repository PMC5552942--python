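"""Isotopic functional indices (IFIs) and hierarchical clustering.

Communities are point sets in the two-dimensional isotope space
(d13C, d15N).  Five indices are computed:

* SEA -- standard ellipse area (permil^2), pi * sqrt(l1 * l2) with l the
  eigenvalues of the sample covariance; a niche-width proxy.
* NR  -- d15N range (permil); a trophic-chain-length proxy.
* IDiv -- biomass-weighted isotopic divergence, in [0, 1].
* IDis -- weighted mean distance to the biomass-weighted centroid.
* IEve -- evenness of biomass along the minimum spanning tree, in (0, 1].

SEA and NR are computed in raw permil space (their values are reported in
permil units); the biomass-weighted trio is computed after min-max
scaling of each axis to [0, 1] using pooled minima/maxima across the
communities being compared, so values are comparable across habitats.
Differences between two communities are tested by a two-tailed
permutation test that reallocates species rows (point and biomass weight
together) between the communities.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform

from .datatypes import ValidationError

log = logging.getLogger("engineerweb")

#: Below this species count IFI values are considered unreliable.
ACCURACY_THRESHOLD = 20


@dataclass
class IsotopePointSet:
    """Species-level points in isotope space with optional biomass weights.

    ``points`` is (n, 2) in permil (d13C, d15N); ``weights`` are relative
    biomasses on the simplex (None for unweighted sets, e.g. when sources
    are included).  ``species`` codes give deterministic tie-breaks.
    """

    points: np.ndarray
    weights: Optional[np.ndarray] = None
    species: Optional[Sequence[str]] = None
    scope: str = "foodweb"
    label: str = ""

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] != 2:
            raise ValidationError("points must be (n, 2)")
        if self.species is None:
            self.species = [f"sp{i:03d}" for i in range(len(self.points))]
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if len(self.weights) != len(self.points):
                raise ValidationError("weights/points length mismatch")
            if (self.weights < 0).any():
                raise ValidationError("weights must be >= 0")
            tot = self.weights.sum()
            if abs(tot - 1.0) > 1e-9:
                if tot <= 0:
                    raise ValidationError("weights sum to 0")
                self.weights = self.weights / tot
        if len(self.points) < ACCURACY_THRESHOLD:
            log.warning("point set %r has n=%d < %d species; IFI values "
                        "may be inaccurate", self.label, len(self.points),
                        ACCURACY_THRESHOLD)

    @property
    def n(self) -> int:
        return len(self.points)


@dataclass
class IFIResult:
    SEA: float = np.nan
    NR: float = np.nan
    IDiv: float = np.nan
    IDis: float = np.nan
    IEve: float = np.nan
    n: int = 0
    degenerate: bool = False
    scope: str = ""


# --------------------------------------------------------------- clustering

@dataclass
class HacGrouping:
    linkage_matrix: np.ndarray
    k: int
    labels: np.ndarray
    relative_loss: dict
    degenerate: bool = False


def hac_ward(points: np.ndarray, k: Optional[int] = None,
             k_max: int = 8) -> HacGrouping:
    """Ward clustering on Euclidean distances with inertia-based cut.

    The number of groups is chosen (over k in [2, min(k_max, n-1)]) where
    the relative loss of between-partition inertia is highest: each Ward
    merge increases within-group inertia by h^2/2 (h the merge height);
    the chosen k maximises the ratio of the inertia loss incurred by
    merging k groups into k-1 to the loss incurred by the previous merge.
    Pass ``k`` to force a cut (e.g. k=3 for the energy-group sources).
    """
    x = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(x)
    if n < 2:
        raise ValidationError("clustering needs >= 2 points")
    if np.allclose(x, x[0]):
        log.warning("all points identical: single degenerate cluster")
        z = linkage(x, method="ward")
        return HacGrouping(linkage_matrix=z, k=1,
                           labels=np.zeros(n, dtype=int),
                           relative_loss={}, degenerate=True)
    z = linkage(x, method="ward")
    heights = z[:, 2]
    losses = heights ** 2 / 2.0          # within-inertia gain per merge
    rel = {}
    for k_cand in range(2, min(k_max, n - 1) + 1):
        # merge n-k_cand+1 (1-based) reduces k_cand -> k_cand-1 groups
        num = losses[n - k_cand]
        den = losses[n - k_cand - 1] if n - k_cand - 1 >= 0 else np.nan
        rel[k_cand] = float(num / den) if den and den > 0 else np.inf
    chosen = int(k) if k is not None else max(rel, key=rel.get)
    labels = cut_tree(z, n_clusters=chosen).ravel()
    return HacGrouping(linkage_matrix=z, k=chosen, labels=labels,
                       relative_loss=rel)


# ------------------------------------------------------------------ indices

def ifi_sea(points: np.ndarray, small_sample: bool = False
            ) -> tuple[float, bool]:
    """Standard ellipse area (permil^2) and a degeneracy flag.

    SEA = pi * sqrt(l1 * l2), eigenvalues of the sample covariance
    (n-1 denominator).  Collinear point sets give 0 with the flag set.
    ``small_sample`` applies the (n-1)/(n-2) small-sample correction.
    """
    x = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(x)
    if n < 3:
        raise ValidationError("SEA needs >= 3 points")
    cov = np.cov(x.T, ddof=1)
    det = float(np.linalg.det(cov))
    if det <= 1e-14:
        return 0.0, True
    sea = float(np.pi * np.sqrt(det))
    if small_sample:
        sea *= (n - 1) / (n - 2)
    return sea, False


def ifi_nr(points: np.ndarray) -> float:
    """d15N range: max - min of the nitrogen coordinate (permil)."""
    x = np.atleast_2d(np.asarray(points, dtype=float))
    return float(x[:, 1].max() - x[:, 1].min())


def scale_pooled(point_sets: Iterable[np.ndarray]) -> list[np.ndarray]:
    """Min-max scale each axis to [0, 1] using pooled extrema.

    All sets in a comparison share the same scaling so the weighted
    indices are comparable across them.  A degenerate axis (zero pooled
    range) maps to 0.
    """
    sets = [np.atleast_2d(np.asarray(p, dtype=float)) for p in point_sets]
    pooled = np.vstack(sets)
    lo = pooled.min(axis=0)
    span = pooled.max(axis=0) - lo
    span[span == 0] = 1.0
    return [(p - lo) / span for p in sets]


def _mst_edges(points: np.ndarray, species: Sequence[str]
               ) -> list[tuple[int, int, float]]:
    """Minimum spanning tree edges with deterministic tie-breaks.

    Equal-length edges are disambiguated by adding an infinitesimal rank
    perturbation in lexicographic species-code order.
    """
    n = len(points)
    d = squareform(pdist(points))
    order = np.argsort(np.argsort(species))
    eps = np.finfo(float).eps * 64
    tie = (order[:, None] * n + order[None, :]) * eps
    mst = minimum_spanning_tree(d + tie + np.eye(n))  # diag offset ignored
    coo = mst.tocoo()
    return [(int(i), int(j), float(d[i, j]))
            for i, j in zip(coo.row, coo.col)]


def ifi_weighted(points: np.ndarray, weights: np.ndarray,
                 species: Optional[Sequence[str]] = None
                 ) -> tuple[float, float, float]:
    """Biomass-weighted (IDiv, IDis, IEve) in already-scaled space.

    IDiv: with G the centroid of the convex-hull vertices and d_i the
    distance of species i to G, IDiv = (Dd + dbar)/(D|d| + dbar) where
    dbar is the unweighted mean of d_i, Dd = sum w_i (d_i - dbar) and
    D|d| = sum w_i |d_i - dbar|.

    IDis: sum w_i ||x_i - G_w|| with G_w the weighted centroid.

    IEve: each MST branch l=(i,j) gets EW_l = length_l/(w_i + w_j) and
    PEW_l = EW_l / sum EW; IEve = (sum min(PEW_l, 1/(S-1)) - 1/(S-1)) /
    (1 - 1/(S-1)).  Zero-weight species stay in the geometry but
    contribute nothing to weighted sums.
    """
    x = np.atleast_2d(np.asarray(points, dtype=float))
    w = np.asarray(weights, dtype=float)
    if species is None:
        species = [f"sp{i:03d}" for i in range(len(x))]
    if len(x) < 2:
        raise ValidationError("weighted indices need >= 2 points")
    if (w < 0).any() or w.sum() <= 0:
        raise ValidationError("weights must be >= 0 and sum > 0")
    w = w / w.sum()
    if (w == 0).any():
        log.warning("%d zero-weight species retained in geometry",
                    int((w == 0).sum()))

    # IDis
    g_w = w @ x
    idis = float(w @ np.linalg.norm(x - g_w, axis=1))

    # IDiv (needs a 2-D convex hull)
    idiv = np.nan
    if len(x) >= 3:
        try:
            hull = ConvexHull(x)
            g_hull = x[hull.vertices].mean(axis=0)
            d = np.linalg.norm(x - g_hull, axis=1)
            dbar = d.mean()
            dd = float(w @ (d - dbar))
            dabs = float(w @ np.abs(d - dbar))
            idiv = (dd + dbar) / (dabs + dbar) if (dabs + dbar) > 0 else 1.0
        except QhullError:
            log.warning("degenerate (collinear) hull: IDiv undefined")

    # IEve
    s = len(x)
    edges = _mst_edges(x, list(species))
    ew = np.array([length / (w[i] + w[j]) if (w[i] + w[j]) > 0 else np.inf
                   for i, j, length in edges])
    if not np.isfinite(ew).all() or ew.sum() <= 0:
        ieve = np.nan
    else:
        pew = ew / ew.sum()
        q = 1.0 / (s - 1)
        ieve = float((np.minimum(pew, q).sum() - q) / (1.0 - q)) \
            if s > 2 else 1.0
    return idiv, idis, ieve


def compute_ifi(point_set: IsotopePointSet,
                scaled_points: Optional[np.ndarray] = None,
                small_sample: bool = False) -> IFIResult:
    """All five indices for one community.

    SEA and NR use the raw permil coordinates; the weighted trio uses
    ``scaled_points`` (pooled min-max scaling) when provided, falling back
    to scaling by the set's own extrema.
    """
    pts = point_set.points
    res = IFIResult(n=point_set.n, scope=point_set.scope)
    if point_set.n >= 3:
        res.SEA, res.degenerate = ifi_sea(pts, small_sample=small_sample)
    res.NR = ifi_nr(pts)
    if point_set.weights is not None and point_set.n >= 2:
        sp = scaled_points if scaled_points is not None \
            else scale_pooled([pts])[0]
        res.IDiv, res.IDis, res.IEve = ifi_weighted(
            sp, point_set.weights, point_set.species)
    return res


# ------------------------------------------------------- permutation test

@dataclass
class IfiComparison:
    index: str
    value_a: float
    value_b: float
    delta_obs: float
    pseudo_p: float
    n_perm: int
    alpha_adj: float
    significant: bool
    n_redrawn: int = 0


_INDEX_NEEDS_WEIGHTS = {"IDiv", "IDis", "IEve"}


def _index_values(pts: np.ndarray, w: Optional[np.ndarray],
                  species: Sequence[str], scaled: np.ndarray,
                  indices: Sequence[str]) -> dict:
    out = {}
    if "SEA" in indices:
        out["SEA"] = ifi_sea(pts)[0]
    if "NR" in indices:
        out["NR"] = ifi_nr(pts)
    if _INDEX_NEEDS_WEIGHTS & set(indices):
        idiv, idis, ieve = ifi_weighted(scaled, w, species)
        out.update(IDiv=idiv, IDis=idis, IEve=ieve)
    return {k: out[k] for k in indices}


def compare_ifi_permutation(set_a: IsotopePointSet, set_b: IsotopePointSet,
                            indices: Sequence[str] = ("SEA", "NR", "IDiv"),
                            n_perm: int = 10_000,
                            seed: int | None = None,
                            rng: np.random.Generator | None = None,
                            alpha: float = 0.05,
                            n_tests: int = 1) -> list[IfiComparison]:
    """Two-tailed permutation test of index differences between two sets.

    Species rows (point + weight) are pooled and reallocated uniformly at
    random into groups of the original sizes; weights are renormalised
    within each permuted group.  pseudo_p = (#{|Dperm| >= |Dobs|} + 1) /
    (n_perm + 1); significance is declared at ``alpha / n_tests``
    (Bonferroni over the number of permutation tests performed).
    Permutations whose hull-based indices are degenerate are redrawn (the
    count is reported).  Axis scaling is computed once on the pooled pair,
    so it is permutation-invariant.
    """
    for name in indices:
        if name not in ("SEA", "NR", "IDiv", "IDis", "IEve"):
            raise ValueError(f"unknown index {name!r}")
    need_w = bool(_INDEX_NEEDS_WEIGHTS & set(indices))
    if need_w and (set_a.weights is None or set_b.weights is None):
        raise ValidationError("weighted indices need weights on both sets")
    if rng is None:
        rng = np.random.default_rng(seed)

    pts = np.vstack([set_a.points, set_b.points])
    species = list(set_a.species) + list(set_b.species)
    if need_w:
        w = np.concatenate([set_a.weights, set_b.weights])
    else:
        w = np.ones(len(pts))
    scaled_all = scale_pooled([pts])[0]
    n_a = set_a.n
    idx_a = np.arange(n_a)
    idx_b = np.arange(n_a, len(pts))

    def values(ia, ib):
        va = _index_values(pts[ia], w[ia] / w[ia].sum(),
                           [species[i] for i in ia], scaled_all[ia], indices)
        vb = _index_values(pts[ib], w[ib] / w[ib].sum(),
                           [species[i] for i in ib], scaled_all[ib], indices)
        return va, vb

    va_obs, vb_obs = values(idx_a, idx_b)
    delta_obs = {k: va_obs[k] - vb_obs[k] for k in indices}

    exceed = {k: 0 for k in indices}
    redrawn = 0
    done = 0
    while done < n_perm:
        perm = rng.permutation(len(pts))
        ia, ib = perm[:n_a], perm[n_a:]
        try:
            va, vb = values(ia, ib)
        except (ValidationError, QhullError):
            redrawn += 1
            if redrawn > 10 * n_perm:
                raise ValidationError("too many degenerate permutations")
            continue
        if any(not np.isfinite(va[k]) or not np.isfinite(vb[k])
               for k in indices):
            redrawn += 1
            continue
        for k in indices:
            if abs(va[k] - vb[k]) >= abs(delta_obs[k]) - 1e-12:
                exceed[k] += 1
        done += 1
    if redrawn:
        log.info("redrew %d degenerate permutations", redrawn)

    out = []
    for k in indices:
        p = (exceed[k] + 1) / (n_perm + 1)
        out.append(IfiComparison(
            index=k, value_a=va_obs[k], value_b=vb_obs[k],
            delta_obs=delta_obs[k], pseudo_p=p, n_perm=n_perm,
            alpha_adj=alpha / n_tests,
            significant=p < alpha / n_tests, n_redrawn=redrawn))
    return out
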