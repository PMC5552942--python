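"""Predator-community structure: diversity indices, PERMANOVA, CA.

PERMANOVA is the one-way permutational MANOVA on a distance matrix
(pseudo-F from among/within sums of squared distances, p-value by label
permutation with the add-one convention).  It is implemented here rather
than wrapped so that every permutation stream is driven by an explicit
seeded generator and so the calibration suites can run hundreds of
thousands of permutations quickly; a homogeneity-of-dispersion pre-check
(permutation F-test on distances to group centroids in principal
coordinates) accompanies it.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .datatypes import ValidationError

log = logging.getLogger("engineerweb")


# ------------------------------------------------------------- diversity

def diversity_indices(density: pd.DataFrame) -> pd.DataFrame:
    """Per-haul species richness, Simpson diversity and Pielou evenness.

    ``density`` is hauls x species (individuals/km^2).  Simpson is the
    complement form 1 - sum p_i^2 (0 for a monoculture); Pielou is
    (-sum p_i ln p_i)/ln SR, undefined (NaN, flagged) when SR < 2.
    """
    x = density.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValidationError("negative densities")
    totals = x.sum(axis=1)
    if (totals == 0).any():
        bad = density.index[totals == 0][0]
        raise ValidationError(f"haul {bad!r} has zero total density")
    p = x / totals[:, None]
    sr = (x > 0).sum(axis=1)
    simpson = 1.0 - (p ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        shannon = -np.where(p > 0, p * np.log(p), 0.0).sum(axis=1)
        pielou = np.where(sr >= 2, shannon / np.log(np.maximum(sr, 2)),
                          np.nan)
    out = pd.DataFrame({"SR": sr, "simpson": simpson, "pielou": pielou},
                       index=density.index)
    out["pielou_defined"] = sr >= 2
    return out


# -------------------------------------------------------------- permanova

@dataclass
class PermanovaResult:
    pseudo_F: float
    p: float
    n_perm: int
    dispersion_F: float = np.nan
    dispersion_p: float = np.nan
    pairwise: Optional[pd.DataFrame] = None


def _distance_matrix(x: np.ndarray, metric: str) -> np.ndarray:
    metric = {"euclidean": "euclidean", "bray-curtis": "braycurtis",
              "braycurtis": "braycurtis", "bray": "braycurtis"}[metric]
    d = squareform(pdist(x, metric=metric))
    if np.isnan(d).any():
        raise ValidationError("distance matrix contains NaN "
                              "(all-zero rows under Bray-Curtis?)")
    return d


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """One-way pseudo-F from a squared-distance matrix and group codes."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    ss_among = ss_total - ss_within
    if ss_within <= 0:
        return 0.0 if ss_among <= 0 else np.inf
    return (ss_among / (n_groups - 1)) / (ss_within / (n - n_groups))


def permanova(matrix, groups: Sequence, distance: str = "euclidean",
              n_perm: int = 10_000, seed: int | None = None,
              rng: np.random.Generator | None = None,
              standardize: bool = False,
              dispersion_check: bool = True) -> PermanovaResult:
    """One-way PERMANOVA of ``matrix`` rows against ``groups`` labels.

    ``matrix`` may be a samples x variables array/DataFrame (distances are
    computed with ``distance``) or a precomputed square distance matrix.
    ``standardize`` z-scores each column first (for index matrices on
    heterogeneous scales).  p = (#{F_perm >= F_obs} + 1)/(n_perm + 1).
    A degenerate design (all rows identical) returns pseudo-F 0, p 1.
    """
    x = np.asarray(matrix, dtype=float)
    labels = np.asarray(list(groups))
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValidationError("PERMANOVA needs >= 2 groups")
    if np.bincount(codes).min() < 2:
        raise ValidationError("every group needs >= 2 rows")
    if x.ndim == 2 and x.shape[0] == x.shape[1] and np.allclose(x, x.T) \
            and np.allclose(np.diag(x), 0):
        d = x.copy()
    else:
        if standardize:
            sd = x.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            x = (x - x.mean(axis=0)) / sd
        d = _distance_matrix(x, distance)
    if np.isnan(d).any():
        raise ValidationError("distance matrix contains NaN")
    d2 = d ** 2
    n = d2.shape[0]
    f_obs = _pseudo_f(d2, codes, len(uniq))
    if rng is None:
        rng = np.random.default_rng(seed)
    if f_obs == 0.0:
        # no among-group variance at all: every permutation ties
        result = PermanovaResult(pseudo_F=0.0, p=1.0, n_perm=n_perm)
    else:
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            if _pseudo_f(d2, codes[perm], len(uniq)) >= f_obs:
                count += 1
        result = PermanovaResult(pseudo_F=float(f_obs),
                                 p=(count + 1) / (n_perm + 1),
                                 n_perm=n_perm)
    if dispersion_check:
        f_disp, p_disp = permdisp(d, codes, n_perm=n_perm, rng=rng)
        result.dispersion_F = f_disp
        result.dispersion_p = p_disp
    return result


def permdisp(d: np.ndarray, codes: np.ndarray, n_perm: int = 999,
             rng: np.random.Generator | None = None,
             seed: int | None = None) -> tuple[float, float]:
    """Homogeneity of multivariate dispersion (permutation F-test).

    Samples are embedded by principal-coordinates analysis; each sample's
    distance to its group centroid is computed with the standard correction
    for negative eigenvalues (squared distances on negative axes are
    subtracted).  A one-way F on those distances is compared with its
    permutation distribution.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n = d.shape[0]
    # Gower-centred matrix and eigendecomposition
    a = -0.5 * d ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    w, v = np.linalg.eigh((g + g.T) / 2)
    keep = np.abs(w) > 1e-10 * max(1.0, np.abs(w).max())
    w, v = w[keep], v[:, keep]
    coords = v * np.sqrt(np.abs(w))
    pos = w > 0
    dist_to_centroid = np.empty(n)
    for gcode in np.unique(codes):
        idx = np.flatnonzero(codes == gcode)
        c = coords[idx].mean(axis=0)
        delta2 = (coords[idx] - c) ** 2
        d2c = delta2[:, pos].sum(axis=1) - delta2[:, ~pos].sum(axis=1)
        dist_to_centroid[idx] = np.sqrt(np.maximum(d2c, 0.0))

    def anova_f(y, cds):
        grand = y.mean()
        ss_among = ss_within = 0.0
        k = 0
        for gc in np.unique(cds):
            idx = np.flatnonzero(cds == gc)
            m = y[idx].mean()
            ss_among += len(idx) * (m - grand) ** 2
            ss_within += ((y[idx] - m) ** 2).sum()
            k += 1
        if ss_within <= 0:
            return 0.0 if ss_among <= 0 else np.inf
        return (ss_among / (k - 1)) / (ss_within / (len(y) - k))

    f_obs = anova_f(dist_to_centroid, codes)
    if f_obs == 0.0:
        return 0.0, 1.0
    count = 0
    for _ in range(n_perm):
        if anova_f(dist_to_centroid, codes[rng.permutation(n)]) >= f_obs:
            count += 1
    return float(f_obs), (count + 1) / (n_perm + 1)


def pairwise_permanova(matrix, groups: Sequence, distance: str = "euclidean",
                       n_perm: int = 10_000, alpha: float = 0.05,
                       rng: np.random.Generator | None = None,
                       seed: int | None = None,
                       standardize: bool = False) -> pd.DataFrame:
    """Post hoc pairwise PERMANOVAs with Bonferroni-adjusted threshold."""
    labels = np.asarray(list(groups))
    x = np.asarray(matrix, dtype=float)
    uniq = np.unique(labels)
    pairs = [(a, b) for i, a in enumerate(uniq) for b in uniq[i + 1:]]
    if rng is None:
        rng = np.random.default_rng(seed)
    rows = []
    for a, b in pairs:
        mask = np.isin(labels, [a, b])
        res = permanova(x[mask], labels[mask], distance=distance,
                        n_perm=n_perm, rng=rng, standardize=standardize,
                        dispersion_check=False)
        rows.append(dict(group_a=a, group_b=b, pseudo_F=res.pseudo_F,
                         p=res.p, alpha_adj=alpha / len(pairs),
                         significant=res.p < alpha / len(pairs)))
    return pd.DataFrame(rows)


# ------------------------------------------------- correspondence analysis

@dataclass
class CaResult:
    """Correspondence analysis of an abundance table.

    Coordinates are principal coordinates; ``percent_inertia`` sums to 100
    over all axes.  ``cos2`` per point supports display filtering (e.g.
    keep species with cos^2 > 0.4 on the first plane).  Supplementary
    columns are projected through the transition formulas without
    influencing the axes.
    """

    row_coords: pd.DataFrame
    col_coords: pd.DataFrame
    percent_inertia: np.ndarray
    total_inertia: float
    row_cos2: pd.DataFrame
    col_cos2: pd.DataFrame
    supplementary_coords: Optional[pd.DataFrame] = None
    dropped_columns: list = field(default_factory=list)


def correspondence_analysis(counts: pd.DataFrame,
                            supplementary: Optional[pd.DataFrame] = None,
                            n_axes: int = 2) -> CaResult:
    """Standard CA of ``counts`` with optional supplementary columns.

    All-zero active columns are dropped with a warning; all-zero rows are
    an error.  Total inertia equals the chi-squared statistic of the
    active table divided by its grand total.
    """
    x = counts.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValidationError("CA requires nonnegative counts")
    zero_cols = counts.columns[x.sum(axis=0) == 0]
    if len(zero_cols):
        log.warning("CA: dropping all-zero columns %s", list(zero_cols))
        counts = counts.drop(columns=zero_cols)
        x = counts.to_numpy(dtype=float)
    if (x.sum(axis=1) == 0).any():
        raise ValidationError("CA: all-zero row among active rows")
    total = x.sum()
    p = x / total
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    s = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    u, sig, vt = np.linalg.svd(s, full_matrices=False)
    # drop numerically-null axes (rank of s is min(I,J)-1 at most)
    keep = sig > 1e-12 * max(1.0, sig.max(initial=0.0))
    u, sig, vt = u[:, keep], sig[keep], vt[keep]
    total_inertia = float((sig ** 2).sum())
    if total_inertia > 0:
        percent = 100.0 * sig ** 2 / total_inertia
    else:
        percent = np.zeros_like(sig)
    row_pc = (u * sig) / np.sqrt(r)[:, None]
    col_pc = (vt.T * sig) / np.sqrt(c)[:, None]
    k = min(n_axes, len(sig)) if len(sig) else 0
    axes = [f"axis{i+1}" for i in range(k)]

    # cos2: squared coordinate over squared chi-distance to the centroid
    row_d2 = (s ** 2).sum(axis=1) / r
    col_d2 = (s ** 2).sum(axis=0) / c
    with np.errstate(divide="ignore", invalid="ignore"):
        row_cos2 = np.where(row_d2[:, None] > 0,
                            row_pc ** 2 / row_d2[:, None], 0.0)
        col_cos2 = np.where(col_d2[:, None] > 0,
                            col_pc ** 2 / col_d2[:, None], 0.0)

    supp_df = None
    if supplementary is not None and k:
        sup = supplementary.to_numpy(dtype=float)
        if (sup < 0).any():
            raise ValidationError("supplementary columns must be >= 0")
        coords = np.full((sup.shape[1], k), np.nan)
        row_std = row_pc[:, :k] / sig[:k]          # standard coordinates
        for jcol in range(sup.shape[1]):
            colsum = sup[:, jcol].sum()
            if colsum == 0:
                continue
            profile = sup[:, jcol] / colsum
            coords[jcol] = profile @ row_std
        supp_df = pd.DataFrame(coords, index=supplementary.columns,
                               columns=axes)

    return CaResult(
        row_coords=pd.DataFrame(row_pc[:, :k], index=counts.index,
                                columns=axes),
        col_coords=pd.DataFrame(col_pc[:, :k], index=counts.columns,
                                columns=axes),
        percent_inertia=percent,
        total_inertia=total_inertia,
        row_cos2=pd.DataFrame(row_cos2[:, :k], index=counts.index,
                              columns=axes),
        col_cos2=pd.DataFrame(col_cos2[:, :k], index=counts.columns,
                              columns=axes),
        supplementary_coords=supp_df,
        dropped_columns=list(zero_cols),
    )
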