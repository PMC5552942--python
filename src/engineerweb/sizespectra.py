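"""Juvenile fish size spectra, modal comparison and condition index.

A size spectrum is the binned length-frequency distribution of the
juvenile fish community (left-closed, right-open bins of fixed width,
2 cm by default).  Spectra are compared between the engineered habitat
and the surrounding habitats with a chi-squared homogeneity test; the
species composition of the modal bin identifies who drives a mode shift.
Fulton's condition index K = 100 W / L^3 (W in g, L in cm) checks whether
smaller modal sizes reflect poorer condition.  The tube-spacing estimate
converts an engineer tube density (per m^2) to the spacing of a square
lattice, 100 / sqrt(density) cm.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .datatypes import ValidationError

log = logging.getLogger("engineerweb")

#: Minimum record count for a per-mobility-group spectrum.
MIN_GROUP_RECORDS = 30


def juvenile_filter(lengths: pd.DataFrame,
                    max_length: pd.Series) -> pd.DataFrame:
    """Keep records at or below the species' juvenile maximum length.

    ``max_length`` maps species code to the length (cm) reached at age
    two.  Records of species without a threshold are kept with a logged
    warning.  Negative lengths are an error.
    """
    if (lengths["length_cm"] < 0).any():
        raise ValidationError("negative length record")
    thresh = lengths["species"].map(max_length)
    missing = thresh.isna()
    missing_species = sorted(set(lengths.loc[missing, "species"]))
    if missing_species:
        log.warning("no juvenile length threshold for %s; records kept",
                    missing_species)
    keep = missing | (lengths["length_cm"] <= thresh)
    return lengths[keep].reset_index(drop=True)


@dataclass
class SizeSpectrum:
    """Binned length-frequency distribution.

    ``edges`` are left-closed right-open bin edges (cm); ``counts`` the
    records per bin; ``modal_bin`` the (left, right) edges of the modal
    bin, ties broken toward the smaller bin.  ``species_counts`` is the
    species x bin table whose column sums reproduce ``counts``.
    """

    edges: np.ndarray
    counts: np.ndarray
    modal_bin: tuple
    group: str = "community"
    species_counts: Optional[pd.DataFrame] = None

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def modal_midpoint(self) -> float:
        return 0.5 * (self.modal_bin[0] + self.modal_bin[1])


def build_spectrum(lengths: pd.DataFrame, bin_width: float = 2.0,
                   group: str = "community",
                   edges: Optional[np.ndarray] = None) -> SizeSpectrum:
    """Histogram fish lengths into fixed-width bins anchored at zero.

    ``edges`` overrides the automatic range (used to put two spectra on a
    common binning).  The modal bin is the bin with the highest count;
    ties go to the smaller bin.
    """
    if len(lengths) == 0:
        raise ValidationError("no length records")
    vals = lengths["length_cm"].to_numpy(dtype=float)
    if edges is None:
        top = np.ceil((vals.max() + 1e-9) / bin_width) * bin_width
        edges = np.arange(0.0, top + bin_width / 2, bin_width)
    counts, _ = np.histogram(vals, bins=edges)
    # np.histogram closes the last bin on the right; shift exact-top
    # values into their own [top, top+w) bin to keep bins half-open
    exact_top = vals == edges[-1]
    if exact_top.any():
        edges = np.append(edges, edges[-1] + bin_width)
        counts = np.append(counts, 0)
        counts[-2] -= int(exact_top.sum())
        counts[-1] += int(exact_top.sum())
    mode_i = int(np.argmax(counts))          # argmax takes the first = smaller
    modal_bin = (float(edges[mode_i]), float(edges[mode_i + 1]))

    bins = pd.cut(vals, bins=edges, right=False)
    table = (pd.crosstab(pd.Series(lengths["species"].to_numpy(),
                                   name="species"), bins)
             if "species" in lengths.columns else None)
    return SizeSpectrum(edges=np.asarray(edges, dtype=float),
                        counts=counts.astype(int), modal_bin=modal_bin,
                        group=group, species_counts=table)


@dataclass
class SpectrumComparison:
    chi2: float
    df: int
    p: float
    mode_a: tuple
    mode_b: tuple
    mode_differs: bool
    chi2_modal: float = np.nan
    p_modal: float = np.nan
    low_expected_warning: bool = False


def compare_spectra(spectrum_a: SizeSpectrum, spectrum_b: SizeSpectrum,
                    alpha: float = 0.05,
                    bin_width: Optional[float] = None) -> SpectrumComparison:
    """Chi-squared homogeneity test of two binned length distributions.

    The spectra are recast onto their common binning; bins empty in both
    are dropped.  ``mode_differs`` requires both a different modal bin and
    p < alpha.  A secondary statistic restricts the table to counts inside
    versus outside the union of the two modal bins (the modal-bin-only
    reading of the comparison); both are reported.  A warning flag is set
    when more than 20% of cells have expected counts below 5.
    """
    wa = spectrum_a.edges[1] - spectrum_a.edges[0]
    wb = spectrum_b.edges[1] - spectrum_b.edges[0]
    if not np.isclose(wa, wb):
        raise ValidationError("spectra have different bin widths")
    top = max(spectrum_a.edges[-1], spectrum_b.edges[-1])
    edges = np.arange(0.0, top + wa / 2, wa)

    def recast(sp):
        out = np.zeros(len(edges) - 1, dtype=int)
        idx = np.rint(sp.edges[:-1] / wa).astype(int)
        out[idx] = sp.counts
        return out

    ca, cb = recast(spectrum_a), recast(spectrum_b)
    keep = (ca + cb) > 0
    table = np.array([ca[keep], cb[keep]])
    if table.shape[1] < 2 or min(table.sum(axis=1)) == 0:
        raise ValidationError("not enough occupied bins to compare")
    if np.array_equal(table[0] * table[1].sum(),
                      table[1] * table[0].sum()):
        chi2, p, dof = 0.0, 1.0, table.shape[1] - 1
        expected = table.astype(float)
    else:
        chi2, p, dof, expected = chi2_contingency(table, correction=False)
    low = (expected < 5).mean() > 0.2
    if low:
        log.warning("more than a fifth of cells have expected counts < 5;"
                    " consider wider bins")

    # modal-bin-only reading: inside vs outside the union of modal bins
    modal_edges = {spectrum_a.modal_bin, spectrum_b.modal_bin}
    in_modal = np.zeros(len(edges) - 1, dtype=bool)
    for left, right in modal_edges:
        in_modal[int(round(left / wa))] = True
    modal_table = np.array([[ca[in_modal].sum(), ca[~in_modal].sum()],
                            [cb[in_modal].sum(), cb[~in_modal].sum()]])
    if modal_table.min() >= 0 and modal_table.sum(axis=0).min() > 0:
        if np.array_equal(modal_table[0] * modal_table[1].sum(),
                          modal_table[1] * modal_table[0].sum()):
            chi2_m, p_m = 0.0, 1.0
        else:
            chi2_m, p_m, _, _ = chi2_contingency(modal_table,
                                                 correction=False)
    else:
        chi2_m, p_m = np.nan, np.nan

    differs = (spectrum_a.modal_bin != spectrum_b.modal_bin) and p < alpha
    return SpectrumComparison(chi2=float(chi2), df=int(dof), p=float(p),
                              mode_a=spectrum_a.modal_bin,
                              mode_b=spectrum_b.modal_bin,
                              mode_differs=bool(differs),
                              chi2_modal=float(chi2_m), p_modal=float(p_m),
                              low_expected_warning=bool(low))


def modal_contributions(spectrum: SizeSpectrum) -> pd.Series:
    """Per-species share of the modal-bin count, descending."""
    if spectrum.species_counts is None:
        raise ValidationError("spectrum lacks a species-by-bin table")
    left = spectrum.modal_bin[0]
    col = None
    for c in spectrum.species_counts.columns:
        if np.isclose(c.left, left):
            col = c
            break
    if col is None:
        raise ValidationError("modal bin absent from species table")
    counts = spectrum.species_counts[col]
    total = counts.sum()
    if total == 0:
        raise ValidationError("empty modal bin")
    return (counts / total).sort_values(ascending=False)


def fulton_k(weight_g, length_cm):
    """Fulton's condition index K = 100 W / L^3 (W in g, L in cm)."""
    w = np.asarray(weight_g, dtype=float)
    ln = np.asarray(length_cm, dtype=float)
    if (w <= 0).any() or (ln <= 0).any():
        raise ValidationError("weight and length must be > 0")
    out = 100.0 * w / ln ** 3
    return float(out) if out.ndim == 0 else out


def tube_spacing(density_per_m2: float) -> float:
    """Square-lattice spacing (cm) between tubes at a given density/m^2."""
    if not density_per_m2 > 0:
        raise ValidationError("density must be > 0")
    return 100.0 / float(np.sqrt(density_per_m2))
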