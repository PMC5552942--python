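"""Diversity indices, PERMANOVA (with oracles) and correspondence analysis."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency, kstest

from engineerweb import ValidationError, diversity_indices, permanova
from engineerweb.community import (correspondence_analysis,
                                   pairwise_permanova)


def as_df(rows, species=None):
    species = species or [f"s{i}" for i in range(len(rows[0]))]
    return pd.DataFrame(rows, columns=species,
                        index=[f"h{i}" for i in range(len(rows))])


# ------------------------------------------------------------- diversity

def test_diversity_examples():
    df = as_df([[1.0, 1.0, 0.0],     # two equal species
                [5.0, 0.0, 0.0],     # monoculture
                [1.0, 3.0, 0.0]])    # densities 1:3
    out = diversity_indices(df)
    assert out.loc["h0", "simpson"] == pytest.approx(0.5)
    assert out.loc["h0", "pielou"] == pytest.approx(1.0)
    assert out.loc["h1", "simpson"] == 0.0
    assert not out.loc["h1", "pielou_defined"]
    assert np.isnan(out.loc["h1", "pielou"])
    assert out.loc["h2", "simpson"] == pytest.approx(0.375)


def test_diversity_invariant_to_species_order(rng):
    x = rng.uniform(0, 10, (5, 8))
    df = as_df(list(x))
    perm = rng.permutation(8)
    shuffled = df.iloc[:, perm]
    a, b = diversity_indices(df), diversity_indices(shuffled)
    np.testing.assert_allclose(a["simpson"], b["simpson"])
    np.testing.assert_allclose(a["pielou"], b["pielou"])


def test_diversity_rejects_empty_haul():
    with pytest.raises(ValidationError, match="zero total"):
        diversity_indices(as_df([[1.0, 0.0], [0.0, 0.0]]))


# -------------------------------------------------------------- permanova

def test_permanova_identical_rows_degenerate():
    x = np.ones((6, 3))
    res = permanova(x, ["a"] * 3 + ["b"] * 3, n_perm=99, seed=0)
    assert res.pseudo_F == 0.0
    assert res.p == 1.0


def test_permanova_matches_enumeration_oracle_on_3_plus_3(rng):
    """Permutation p converges to the exact fraction over all label splits.

    For two well-separated 3-point clouds only the true partition attains
    the observed F, so the exact permutation p is the share of labelings
    reproducing it: 3!3!*2/6! = 0.1.
    """
    a = rng.normal(0, 0.1, (3, 2))
    b = rng.normal(0, 0.1, (3, 2)) + 50.0
    x = np.vstack([a, b])
    labels = np.array(["a"] * 3 + ["b"] * 3)

    # independent oracle: coordinate-based one-way MANOVA trace F over
    # every permutation of the six labels
    def trace_f(lab):
        grand = x.mean(axis=0)
        ss_t = ((x - grand) ** 2).sum()
        ss_w = sum(((x[lab == g] - x[lab == g].mean(axis=0)) ** 2).sum()
                   for g in np.unique(lab))
        return ((ss_t - ss_w) / 1) / (ss_w / 4)

    f_obs = trace_f(labels)
    perms = list(itertools.permutations(range(6)))
    exact_p = np.mean([trace_f(labels[list(p)]) >= f_obs - 1e-9
                       for p in perms])
    assert exact_p == pytest.approx(0.1)

    res = permanova(x, labels, distance="euclidean", n_perm=4999, seed=1,
                    dispersion_check=False)
    assert res.pseudo_F == pytest.approx(f_obs)
    assert res.p == pytest.approx(exact_p, abs=0.02)


def test_permanova_reaches_minimal_p_with_large_groups(rng):
    a = rng.normal(0, 0.1, (12, 2))
    b = rng.normal(0, 0.1, (12, 2)) + 50.0
    res = permanova(np.vstack([a, b]), ["a"] * 12 + ["b"] * 12,
                    n_perm=999, seed=2, dispersion_check=False)
    assert res.p == pytest.approx(1 / 1000)


def test_permanova_agrees_with_skbio(rng):
    from skbio import DistanceMatrix
    from skbio.stats.distance import permanova as sk_permanova

    x = rng.normal(0, 1, (12, 4))
    x[6:] += 1.0
    labels = ["a"] * 6 + ["b"] * 6
    res = permanova(x, labels, distance="bray-curtis" if False
                    else "euclidean", n_perm=999, seed=3,
                    dispersion_check=False)
    from scipy.spatial.distance import pdist, squareform
    dm = DistanceMatrix(squareform(pdist(x)), ids=[str(i)
                                                   for i in range(12)])
    sk = sk_permanova(dm, grouping=labels, permutations=999)
    assert res.pseudo_F == pytest.approx(sk["test statistic"], rel=1e-9)
    assert res.p == pytest.approx(sk["p-value"], abs=0.05)


def test_permanova_null_p_values_are_uniform(rng):
    """Under an exchangeable null, the permutation p-value is uniform."""
    pvals = []
    for _ in range(300):
        x = rng.normal(0, 1, (12, 3))
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        res = permanova(x, labels, n_perm=199, rng=rng,
                        dispersion_check=False)
        pvals.append(res.p)
    stat = kstest(pvals, "uniform").pvalue
    assert stat > 0.01


def test_dispersion_check_flags_unequal_spread(rng):
    tight = rng.normal(0, 0.05, (10, 2))
    loose = rng.normal(0, 5.0, (10, 2))
    res = permanova(np.vstack([tight, loose]), ["a"] * 10 + ["b"] * 10,
                    n_perm=999, seed=5)
    assert res.dispersion_p < 0.05


def test_pairwise_bonferroni_threshold(rng):
    x = np.vstack([rng.normal(i * 10, 0.2, (4, 2)) for i in range(3)])
    labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
    pw = pairwise_permanova(x, labels, n_perm=999, alpha=0.05, seed=6)
    assert len(pw) == 3
    np.testing.assert_allclose(pw["alpha_adj"], 0.05 / 3)


# ------------------------------------------------------------------- CA

def test_ca_rank_one_table_has_zero_inertia():
    r = np.array([1.0, 2.0, 3.0])
    c = np.array([4.0, 1.0, 2.0, 3.0])
    counts = pd.DataFrame(np.outer(r, c))
    res = correspondence_analysis(counts)
    assert res.total_inertia == pytest.approx(0.0, abs=1e-12)


def test_ca_diagonal_2x2_puts_all_inertia_on_axis_one():
    counts = pd.DataFrame([[10.0, 0.0], [0.0, 10.0]])
    res = correspondence_analysis(counts)
    assert res.percent_inertia[0] == pytest.approx(100.0)


def test_ca_total_inertia_equals_chi2_over_n(rng):
    counts = pd.DataFrame(rng.integers(1, 40, (6, 5)).astype(float))
    res = correspondence_analysis(counts)
    chi2 = chi2_contingency(counts.to_numpy(), correction=False)[0]
    assert res.total_inertia == pytest.approx(chi2 / counts.to_numpy().sum())


def test_ca_supplementary_copy_projects_onto_active_column(rng):
    counts = pd.DataFrame(rng.integers(1, 30, (7, 4)).astype(float),
                          columns=list("abcd"))
    supp = counts[["b"]].rename(columns={"b": "b_copy"})
    res = correspondence_analysis(counts, supplementary=supp)
    np.testing.assert_allclose(
        res.supplementary_coords.loc["b_copy"].to_numpy(),
        res.col_coords.loc["b"].to_numpy(), atol=1e-10)


def test_ca_drops_zero_columns_with_warning(caplog):
    counts = pd.DataFrame([[3.0, 0.0, 1.0], [2.0, 0.0, 5.0]],
                          columns=list("xyz"))
    with caplog.at_level("WARNING", logger="engineerweb"):
        res = correspondence_analysis(counts)
    assert res.dropped_columns == ["y"]


def test_ca_inertia_percentages_sum_and_sort(rng):
    counts = pd.DataFrame(rng.integers(1, 50, (8, 6)).astype(float))
    res = correspondence_analysis(counts)
    assert res.percent_inertia.sum() == pytest.approx(100.0)
    assert (np.diff(res.percent_inertia) <= 1e-9).all()
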