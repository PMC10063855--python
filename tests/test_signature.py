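"""Common-gene intersection, metrics, LOOCV, CIs and curve selection."""

import itertools

import numpy as np
import pytest

from ahrfsig import (auprc, auroc, bootstrap_ci, common_genes, evaluate_curve,
                     incremental_sets, loocv_evaluate, select_optimal)
from conftest import make_matrix
from oracles import auprc_bruteforce, auroc_bruteforce


# ------------------------------------------------------------ common genes
def test_common_genes_hand_example():
    a = ["g1", "g2", "g3", "g4"]
    b = ["g3", "g1", "g5", "g2"]
    common = common_genes(a, b, top_k=3)
    assert common.genes == ["g1", "g3"]  # rank sums 3 and 4
    assert common.table.loc["g1", "rank_a"] == 1
    assert common.table.loc["g1", "rank_b"] == 2


def test_common_genes_identical_rankings_keep_order():
    ranking = [f"g{i}" for i in range(50)]
    common = common_genes(ranking, ranking, top_k=20)
    assert common.genes == ranking[:20]


def test_common_genes_disjoint_warns_and_is_empty():
    with pytest.warns(UserWarning, match="no genes"):
        common = common_genes(["a", "b"], ["c", "d"], top_k=2)
    assert len(common) == 0


def test_common_genes_min_rank_tie_break():
    # both pairs have rank sum 5; g1 has min-rank 1, g9 has min-rank 2
    a = ["g1", "g9", "x1", "g2"]
    b = ["x2", "x3", "g9", "g1"]
    common = common_genes(a, b, top_k=4)
    assert common.genes == ["g1", "g9"]


def test_incremental_sets_default_and_explicit():
    ranking = [f"g{i}" for i in range(25)]
    common = common_genes(ranking, ranking, top_k=25)
    sets = incremental_sets(common, step=10)
    assert [len(s) for s in sets] == [10, 20, 25]
    for small, big in zip(sets, sets[1:]):
        assert big[:len(small)] == small
    explicit = incremental_sets(common, explicit_sizes=[5, 12, 25])
    assert [len(s) for s in explicit] == [5, 12, 25]
    single = incremental_sets(common, step=40)
    assert [len(s) for s in single] == [25]
    with pytest.raises(ValueError):
        incremental_sets(common, explicit_sizes=[30])


# ----------------------------------------------------------------- metrics
def test_auroc_examples():
    assert auroc([0.9, 0.8, 0.3, 0.1], [1, 1, 0, 0]) == 1.0
    assert auroc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5
    assert auroc([0.9, 0.8, 0.2, 0.1], [1, 0, 1, 0]) == 0.75


def test_auprc_examples():
    assert auprc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
    assert auprc([0.9, 0.8, 0.2, 0.1], [1, 0, 1, 0]) == pytest.approx(5 / 6)
    # constant scorer recovers prevalence
    assert auprc([0.3] * 10, [1] * 3 + [0] * 7) == pytest.approx(0.3)


def test_metrics_match_bruteforce_and_sklearn():
    from sklearn.metrics import average_precision_score, roc_auc_score
    rng = np.random.default_rng(0)
    for trial in range(300):
        n = int(rng.integers(2, 13))
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            continue
        scores = rng.choice([0.1, 0.25, 0.5, 0.75, 0.9], size=n)  # force ties
        assert auroc(scores, labels) == pytest.approx(
            auroc_bruteforce(scores, labels), abs=1e-12)
        assert auroc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)
        assert auprc(scores, labels) == pytest.approx(
            auprc_bruteforce(scores, labels), abs=1e-12)
        if labels.sum() > 0:
            assert auprc(scores, labels) == pytest.approx(
                average_precision_score(labels, scores), abs=1e-12)


def test_metrics_reject_one_class():
    with pytest.raises(ValueError):
        auroc([0.1, 0.2], [1, 1])
    with pytest.raises(ValueError):
        auprc([0.1, 0.2], [0, 0])


# ------------------------------------------------------------------- LOOCV
def test_loocv_perfect_gene_scores_one():
    rng = np.random.default_rng(1)
    vals = rng.normal(size=(5, 20))
    vals[0] = np.r_[np.full(10, 5.0), np.full(10, -5.0)] + rng.normal(0, 0.1, 20)
    m = make_matrix(vals, ["case"] * 10 + ["control"] * 10)
    _, roc, prc = loocv_evaluate(m, ["G1"])
    assert roc == 1.0
    assert prc == 1.0


def test_loocv_permuted_labels_near_chance():
    rng = np.random.default_rng(2)
    vals = rng.normal(size=(5, 40))
    rocs = []
    for s in range(5):
        perm_rng = np.random.default_rng(s)
        classes = np.array(["case"] * 20 + ["control"] * 20)
        perm_rng.shuffle(classes)
        m = make_matrix(vals, list(classes))
        _, roc, _ = loocv_evaluate(m, ["G1", "G2", "G3"])
        rocs.append(roc)
    assert abs(np.mean(rocs) - 0.5) < 0.2


def test_loocv_deterministic(gene_cohort):
    g, truth = gene_cohort
    genes = truth.informative_genes[:4]
    p1, roc1, prc1 = loocv_evaluate(g, genes)
    p2, roc2, prc2 = loocv_evaluate(g, genes)
    np.testing.assert_array_equal(p1, p2)
    assert (roc1, prc1) == (roc2, prc2)


def test_loocv_input_validation(gene_cohort):
    g, _ = gene_cohort
    with pytest.raises(ValueError, match="non-empty"):
        loocv_evaluate(g, [])
    with pytest.raises(ValueError, match="absent"):
        loocv_evaluate(g, ["NOT_A_GENE"])
    tiny = make_matrix(np.ones((2, 3)), ["case", "control", "control"])
    with pytest.raises(ValueError, match="stratified k-fold"):
        loocv_evaluate(tiny, ["G1"])


# --------------------------------------------------------------------- CIs
def test_bootstrap_ci_contains_point_estimate():
    rng = np.random.default_rng(3)
    labels = np.array([1] * 15 + [0] * 25)
    scores = rng.normal(labels, 1.0)
    point = auroc(scores, labels)
    lo, hi = bootstrap_ci(scores, labels, auroc, n_resample=500, seed=0)
    assert lo <= point <= hi
    assert 0 <= lo <= hi <= 1


def test_bootstrap_ci_perfect_separation_degenerate():
    labels = np.array([1] * 5 + [0] * 5)
    scores = np.array([1.0] * 5 + [0.0] * 5)
    lo, hi = bootstrap_ci(scores, labels, auroc, n_resample=200, seed=1)
    assert (lo, hi) == (1.0, 1.0)


def test_bootstrap_ci_width_shrinks_with_n():
    rng = np.random.default_rng(4)
    widths = []
    for n in (50, 500):
        labels = np.array([1] * (n // 2) + [0] * (n // 2))
        scores = rng.normal(labels, 1.0)
        lo, hi = bootstrap_ci(scores, labels, auroc, n_resample=400, seed=2)
        widths.append(hi - lo)
    assert widths[1] < widths[0]


def test_bootstrap_ci_rejects_small_resample():
    with pytest.raises(ValueError, match=">= 100"):
        bootstrap_ci([1, 0], [1, 0], auroc, n_resample=50)


# ------------------------------------------------------------------- curve
def test_curve_and_optimum(gene_cohort):
    g, truth = gene_cohort
    informative = truth.informative_genes
    noise = [f for f in g.feature_ids if f not in informative][:12]
    sets = [informative[:4], informative[:4] + informative[4:8],
            informative + noise]
    curve = evaluate_curve(g, sets, cohort="test", n_resample=150, seed=3)
    assert list(curve.table["size"]) == [4, 8, 20]
    assert curve.table["auroc"].between(0, 1).all()
    assert (curve.table["auroc_lo"] <= curve.table["auroc"]).all()
    assert (curve.table["auroc"] <= curve.table["auroc_hi"]).all()
    # all planted signal is inside the first two sets; adding noise can't help
    opt = select_optimal(curve)
    assert opt <= 8


def test_select_optimal_tie_goes_to_smallest():
    import pandas as pd
    from ahrfsig.signature import SignatureCurve
    table = pd.DataFrame({"size": [10, 20, 30], "cohort": ["x"] * 3,
                          "auroc": [0.9, 0.9, 0.85],
                          "auprc": [0.7, 0.8, 0.8]})
    curve = SignatureCurve(table=table, gene_lists={})
    assert select_optimal(curve, "auroc") == 10
    assert select_optimal(curve, "auprc") == 20
    with pytest.raises(ValueError):
        select_optimal(curve, "f1")


def test_evaluate_curve_rejects_non_nested(gene_cohort):
    g, _ = gene_cohort
    ids = list(g.feature_ids)
    with pytest.raises(ValueError, match="nested"):
        evaluate_curve(g, [ids[:2], [ids[3], ids[4], ids[5]]],
                       n_resample=150)
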