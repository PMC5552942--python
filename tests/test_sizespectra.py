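"""Juvenile filter, spectra, modal comparison, Fulton's K, tube spacing."""
import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from engineerweb import (ValidationError, build_spectrum, compare_spectra,
                         fulton_k, juvenile_filter, modal_contributions,
                         tube_spacing)


def lengths_df(values, species="sp1"):
    if np.isscalar(species):
        species = [species] * len(values)
    return pd.DataFrame({"bay": "BayA", "habitat": "Haploops",
                         "haul": "h1", "species": species,
                         "length_cm": values,
                         "weight_g": np.asarray(values) ** 3 / 100})


# ------------------------------------------------------------------ filter

def test_juvenile_filter_keeps_at_or_below_threshold():
    df = lengths_df([5.0, 12.0])
    out = juvenile_filter(df, pd.Series({"sp1": 10.0}))
    assert list(out["length_cm"]) == [5.0]


def test_juvenile_filter_missing_threshold_kept_with_warning(caplog):
    df = lengths_df([5.0, 12.0], species=["sp1", "ghost"])
    with caplog.at_level("WARNING", logger="engineerweb"):
        out = juvenile_filter(df, pd.Series({"sp1": 10.0}))
    assert len(out) == 2
    assert "ghost" in caplog.text


def test_juvenile_filter_negative_length_rejected():
    with pytest.raises(ValidationError):
        juvenile_filter(lengths_df([-1.0]), pd.Series({"sp1": 10.0}))


def test_juvenile_filter_count_by_construction(rng):
    over = rng.uniform(10.01, 20, 37)
    under = rng.uniform(1, 10, 63)
    df = lengths_df(np.concatenate([over, under]))
    out = juvenile_filter(df, pd.Series({"sp1": 10.0}))
    assert len(out) == 63


# ---------------------------------------------------------------- spectrum

def test_single_value_spectrum():
    sp = build_spectrum(lengths_df([6.0, 6.0, 6.0]), bin_width=2.0)
    assert sp.modal_bin == (6.0, 8.0)
    assert sp.n == 3


def test_tie_breaks_toward_smaller_bin():
    sp = build_spectrum(lengths_df([1.0, 3.0, 5.0, 7.0]), bin_width=2.0)
    assert sp.modal_bin == (0.0, 2.0)


def test_counts_conserved_under_species_marginalisation(rng):
    vals = rng.uniform(0, 20, 60)
    species = rng.choice(["a", "b", "c"], 60)
    sp = build_spectrum(lengths_df(vals, species=list(species)))
    np.testing.assert_array_equal(
        sp.species_counts.sum(axis=0).to_numpy(), sp.counts)


def test_planted_mode_recovered(rng):
    """A log-normal community centred in [6, 8) puts the mode there."""
    vals = 7.0 * np.exp(rng.normal(0, 0.15, 500))
    sp = build_spectrum(lengths_df(vals), bin_width=2.0)
    assert sp.modal_bin == (6.0, 8.0)


# -------------------------------------------------------------- comparison

def test_identical_spectra_compare_equal(rng):
    vals = rng.uniform(0, 16, 80)
    a = build_spectrum(lengths_df(vals))
    b = build_spectrum(lengths_df(vals.copy()))
    comp = compare_spectra(a, b)
    assert comp.chi2 == pytest.approx(0.0)
    assert comp.p == pytest.approx(1.0)
    assert not comp.mode_differs


def test_disjoint_supports_strongly_different(rng):
    a = build_spectrum(lengths_df(rng.uniform(0, 6, 100)))
    b = build_spectrum(lengths_df(rng.uniform(10, 16, 100)))
    comp = compare_spectra(a, b)
    assert comp.p < 1e-3
    assert comp.mode_differs
    # oracle: same table through scipy directly
    keep = (np.pad(a.counts, (0, len(b.counts) - len(a.counts)))
            + b.counts) > 0
    table = np.array([np.pad(a.counts,
                             (0, len(b.counts) - len(a.counts)))[keep],
                      b.counts[keep]])
    chi2 = chi2_contingency(table, correction=False)[0]
    assert comp.chi2 == pytest.approx(chi2)


def test_one_bin_shift_moves_mode_one_bin(rng):
    vals = 7.0 * np.exp(rng.normal(0, 0.12, 400))
    a = build_spectrum(lengths_df(vals))
    b = build_spectrum(lengths_df(vals - 2.0))
    comp = compare_spectra(a, b)
    assert comp.mode_a[0] - comp.mode_b[0] == pytest.approx(2.0)


def test_comparison_is_symmetric(rng):
    a = build_spectrum(lengths_df(rng.uniform(0, 10, 70)))
    b = build_spectrum(lengths_df(rng.uniform(2, 14, 90)))
    ab, ba = compare_spectra(a, b), compare_spectra(b, a)
    assert ab.chi2 == pytest.approx(ba.chi2)
    assert ab.p == pytest.approx(ba.p)


def test_mismatched_bin_widths_rejected(rng):
    a = build_spectrum(lengths_df(rng.uniform(0, 10, 30)), bin_width=2.0)
    b = build_spectrum(lengths_df(rng.uniform(0, 10, 30)), bin_width=1.0)
    with pytest.raises(ValidationError):
        compare_spectra(a, b)


# ------------------------------------------------------ modal composition

def test_modal_contributions_single_species():
    sp = build_spectrum(lengths_df([6.0, 6.5, 7.0]))
    shares = modal_contributions(sp)
    assert shares.iloc[0] == pytest.approx(1.0)


def test_modal_contributions_shares():
    vals = [6.1] * 30 + [6.2] * 10
    species = ["dom"] * 30 + ["rare"] * 10
    sp = build_spectrum(lengths_df(vals, species=species))
    shares = modal_contributions(sp)
    assert shares["dom"] == pytest.approx(0.75)
    assert shares["rare"] == pytest.approx(0.25)


def test_modal_contributions_planted_dominant(rng):
    dom = 7.0 * np.exp(rng.normal(0, 0.1, 120))
    other = 11.0 * np.exp(rng.normal(0, 0.1, 60))
    df = lengths_df(np.concatenate([dom, other]),
                    species=["dom"] * 120 + ["other"] * 60)
    sp = build_spectrum(df)
    assert modal_contributions(sp).index[0] == "dom"


# --------------------------------------------------------------- indices

@pytest.mark.parametrize("w, l, expected", [
    (10.0, 10.0, 1.0),
    (1.0, 10.0, 0.1),
    (8.4, 9.5, 100 * 8.4 / 9.5 ** 3),
])
def test_fulton_k_values(w, l, expected):
    assert fulton_k(w, l) == pytest.approx(expected)


def test_fulton_k_isometric_scaling():
    """Doubling length at fixed K requires 8x the weight."""
    k = fulton_k(10.0, 10.0)
    assert fulton_k(80.0, 20.0) == pytest.approx(k)


def test_fulton_k_rejects_nonpositive():
    with pytest.raises(ValidationError):
        fulton_k(0.0, 10.0)


@pytest.mark.parametrize("density, expected", [
    (2_500.0, 2.0), (10_000.0, 1.0), (1.0, 100.0),
])
def test_tube_spacing(density, expected):
    assert tube_spacing(density) == pytest.approx(expected)


def test_tube_spacing_rejects_nonpositive():
    with pytest.raises(ValidationError):
        tube_spacing(0.0)
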