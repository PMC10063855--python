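"""Normalization, probe collapsing, batch correction and the DE screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ahrfsig import (batch_correct, collapse_probes, differential_expression,
                     quantile_normalize)
from conftest import make_matrix
from oracles import bh_stepup_bruteforce


# ------------------------------------------------------------ quantile norm
def test_quantile_normalize_two_sample_example():
    m = make_matrix(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]),
                    ["case", "control"])
    out = quantile_normalize(m)
    expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
    np.testing.assert_allclose(out.values.to_numpy(), expected)


def test_quantile_normalize_identical_columns_fixed_point():
    col = np.array([5.0, 1.0, 3.0])
    m = make_matrix(np.column_stack([col, col, col]),
                    ["case", "case", "control"])
    out = quantile_normalize(m)
    np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy())


def test_quantile_normalize_idempotent_and_rank_preserving():
    rng = np.random.default_rng(0)
    vals = rng.normal(size=(40, 6))
    m = make_matrix(vals, ["case"] * 3 + ["control"] * 3)
    once = quantile_normalize(m)
    twice = quantile_normalize(once)
    np.testing.assert_allclose(once.values.to_numpy(),
                               twice.values.to_numpy(), atol=1e-12)
    for j in range(6):
        orig = m.values.iloc[:, j].rank()
        new = once.values.iloc[:, j].rank()
        np.testing.assert_array_equal(orig, new)


def test_quantile_normalize_ties_get_mean_of_span():
    # column 0 has a tie at value 2; positions 1 and 2 of the reference vector
    m = make_matrix(np.array([[1.0, 10.0], [2.0, 20.0], [2.0, 30.0]]),
                    ["case", "control"])
    out = quantile_normalize(m)
    ref = np.array([(1 + 10) / 2, (2 + 20) / 2, (2 + 30) / 2])
    col0 = out.values.iloc[:, 0].to_numpy()
    assert col0[0] == ref[0]
    assert col0[1] == col0[2] == pytest.approx((ref[1] + ref[2]) / 2)


# --------------------------------------------------------- collapse probes
def test_collapse_probes_averages_on_log2_scale():
    m = make_matrix(np.array([[2.0, 8.0], [4.0, 2.0], [1.0, 1.0],
                              [2.0, 2.0], [6.0, 3.0]]),
                    ["case", "control"], level="probe", feature_prefix="P")
    annot = pd.DataFrame({"probe_id": ["P1", "P2", "P3", "P4", "P5"],
                          "gene_id": ["gA", "gA", "gB", "gB", "gB"]})
    out = collapse_probes(m, annot)
    assert out.level == "gene"
    np.testing.assert_allclose(out.values.loc["gA"], [3.0, 5.0])
    np.testing.assert_allclose(out.values.loc["gB"], [3.0, 2.0])


def test_collapse_single_probe_genes_is_renaming():
    m = make_matrix(np.arange(8, dtype=float).reshape(4, 2),
                    ["case", "control"], level="probe", feature_prefix="P")
    annot = pd.DataFrame({"probe_id": [f"P{i}" for i in range(1, 5)],
                          "gene_id": [f"g{i}" for i in range(1, 5)]})
    out = collapse_probes(m, annot)
    np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy())


def test_collapse_rejects_multi_gene_probe_and_drops_unmapped():
    m = make_matrix(np.ones((2, 2)), ["case", "control"], level="probe",
                    feature_prefix="P")
    bad = pd.DataFrame({"probe_id": ["P1", "P1"], "gene_id": ["gA", "gB"]})
    with pytest.raises(ValueError, match="multiple genes"):
        collapse_probes(m, bad)
    partial = pd.DataFrame({"probe_id": ["P1"], "gene_id": ["gA"]})
    out = collapse_probes(m, partial)
    assert list(out.feature_ids) == ["gA"]


# ----------------------------------------------------------- batch correct
def test_batch_correct_zeroes_per_batch_means(small_cohort):
    m, _ = small_cohort
    out = batch_correct(m)
    for batch in out.batches.unique():
        cols = out.batches == batch
        means = out.values.loc[:, cols.to_numpy()].mean(axis=1)
        assert means.abs().max() < 1e-10


def test_batch_correct_single_batch_is_global_zscore():
    rng = np.random.default_rng(1)
    m = make_matrix(rng.normal(size=(10, 8)), ["case"] * 4 + ["control"] * 4)
    out = batch_correct(m)
    np.testing.assert_allclose(out.values.mean(axis=1), 0, atol=1e-12)
    np.testing.assert_allclose(out.values.std(axis=1, ddof=1), 1, atol=1e-12)


def test_batch_correct_constant_gene_flagged_not_dropped():
    vals = np.vstack([np.ones(6), np.random.default_rng(2).normal(size=6)])
    m = make_matrix(vals, ["case"] * 3 + ["control"] * 3)
    out = batch_correct(m)
    assert "G1" in out.meta["constant_genes"]
    np.testing.assert_allclose(out.values.loc["G1"], 0.0)


def test_batch_correct_rejects_singleton_batch():
    m = make_matrix(np.ones((3, 3)), ["case", "case", "control"],
                    batches=["b0", "b0", "b1"])
    with pytest.raises(ValueError, match="single sample"):
        batch_correct(m)


def test_collapse_then_correct_commutes_on_balanced_batches():
    # probes of a gene share the gene signal (small probe noise), so
    # collapse->correct and correct->collapse agree up to per-gene rescaling
    from ahrfsig import CohortSpec, generate_cohort
    spec = CohortSpec(n_cases=20, n_controls=20, n_genes=60, n_informative=5,
                      noise_sd=0.5, n_batches=2, batch_shift_sd=1.5, seed=13)
    m, _ = generate_cohort(spec)
    annot = pd.DataFrame({"probe_id": list(m.meta["annotation"].keys()),
                          "gene_id": list(m.meta["annotation"].values())})
    route1 = batch_correct(collapse_probes(m, annot))
    route2 = collapse_probes(batch_correct(m), annot)
    z1 = route1.values.apply(lambda r: (r - r.mean()) / r.std(), axis=1)
    z2 = route2.values.apply(lambda r: (r - r.mean()) / r.std(), axis=1)
    corr = [np.corrcoef(z1.loc[g], z2.loc[g])[0, 1] for g in z1.index]
    assert min(corr) > 0.98


# ----------------------------------------------------------------- DE screen
def test_differential_expression_matches_welch_and_bh():
    rng = np.random.default_rng(4)
    vals = rng.normal(size=(30, 20))
    vals[:3, :10] += 3.0  # three genes strongly shifted in cases
    m = make_matrix(vals, ["case"] * 10 + ["control"] * 10)
    res = differential_expression(m)
    t = res.table
    assert set(res.significant()) >= set()  # columns exist and q in range
    assert ((t["q"] >= t["p"] - 1e-12).all())
    assert t["q"].between(0, 1).all()
    np.testing.assert_allclose(t["q"], bh_stepup_bruteforce(t["p"]), atol=1e-12)
    assert set(t.sort_values("p").head(3).index) == {"G1", "G2", "G3"}
    assert (t.loc[["G1", "G2", "G3"], "mean_diff"] > 1).all()


def test_de_zero_variance_gene_gets_p_one():
    vals = np.vstack([np.full(8, 3.14),
                      np.random.default_rng(5).normal(size=8)])
    m = make_matrix(vals, ["case"] * 4 + ["control"] * 4)
    res = differential_expression(m)
    assert res.table.loc["G1", "p"] == 1.0


def test_de_null_calibration():
    rng = np.random.default_rng(6)
    m = make_matrix(rng.normal(size=(400, 40)),
                    ["case"] * 20 + ["control"] * 20)
    res = differential_expression(m)
    assert len(res.significant(0.05)) == 0
    # raw p-values roughly uniform
    from scipy.stats import kstest
    assert kstest(res.table["p"], "uniform").pvalue > 1e-3


def test_de_requires_two_per_class():
    m = make_matrix(np.ones((2, 3)), ["case", "control", "control"])
    with pytest.raises(ValueError, match="2 samples per class"):
        differential_expression(m)


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                max_size=100))
def test_bh_oracle_property(pvals):
    """statsmodels BH (used in the screen) equals the literal step-up rule."""
    from statsmodels.stats.multitest import multipletests
    _, q, _, _ = multipletests(pvals, method="fdr_bh")
    np.testing.assert_allclose(q, bh_stepup_bruteforce(pvals), atol=1e-12)
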