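"""Cross-cohort signature construction and evaluation.

Takes the two cohorts' stability rankings, intersects their top-k prefixes,
grows the common-gene signature in nested increments, and scores every
signature size by leave-one-out cross-validated AUROC and AUPRC with
stratified percentile-bootstrap confidence intervals.

AUROC is the concordance probability between case and control scores (ties
count 1/2, i.e. the rank-sum formulation); AUPRC is step-wise average
precision, which does not interpolate the PR curve and therefore does not
overestimate under class imbalance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .matrix import ExpressionMatrix


# --------------------------------------------------------------- common genes
@dataclass
class CommonGeneList:
    """Genes present in both cohorts' top-k prefixes, deterministically ordered.

    Order key: ascending rank sum (rankA + rankB), ties by ascending
    min(rankA, rankB), remaining ties lexicographic by gene ID.
    """

    table: pd.DataFrame  # index gene_id (ordered); columns rank_a, rank_b
    top_k: int

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


def common_genes(ranked_a: list[str], ranked_b: list[str],
                 top_k: int = 1500) -> CommonGeneList:
    """Intersect the two rankings' top-k prefixes."""
    top_a = ranked_a[:top_k]
    top_b = ranked_b[:top_k]
    rank_a = {g: i + 1 for i, g in enumerate(top_a)}
    rank_b = {g: i + 1 for i, g in enumerate(top_b)}
    shared = set(rank_a) & set(rank_b)
    if not shared:
        warnings.warn("top-k prefixes share no genes; empty common list",
                      stacklevel=2)
    ordered = sorted(shared, key=lambda g: (rank_a[g] + rank_b[g],
                                            min(rank_a[g], rank_b[g]), g))
    table = pd.DataFrame({"rank_a": [rank_a[g] for g in ordered],
                          "rank_b": [rank_b[g] for g in ordered]},
                         index=pd.Index(ordered, name="gene_id"))
    return CommonGeneList(table=table, top_k=top_k)


def incremental_sets(common: CommonGeneList, step: int = 10,
                     explicit_sizes: list[int] | None = None) -> list[list[str]]:
    """Nested signature prefixes: every ``step`` genes, or at explicit sizes."""
    genes = common.genes
    if not genes:
        raise ValueError("common gene list is empty")
    if explicit_sizes is not None:
        sizes = sorted(set(explicit_sizes))
        bad = [s for s in sizes if s < 1 or s > len(genes)]
        if bad:
            raise ValueError(f"requested sizes outside 1..{len(genes)}: {bad}")
    else:
        if step < 1:
            raise ValueError("step must be >= 1")
        sizes = list(range(step, len(genes), step)) + [len(genes)]
        sizes = sorted(set(sizes))
    return [genes[:s] for s in sizes]


# ------------------------------------------------------------------- metrics
def auroc(scores, labels) -> float:
    """P(random case outscores random control), ties counting 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)  # average ranks handle ties
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def auprc(scores, labels) -> float:
    """Step-wise average precision (no PR interpolation).

    Sum over distinct score thresholds of precision-at-threshold weighted by
    the recall increment; tied scores enter together at one threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    if n_pos == 0:
        raise ValueError("at least one case required")
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    # cut at each distinct threshold (last index of each tied block)
    distinct = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    tp = np.cumsum(y)[distinct]
    n_at = distinct + 1
    precision = tp / n_at
    recall = tp / n_pos
    recall_prev = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - recall_prev) * precision))


# --------------------------------------------------------------------- LOOCV
def loocv_evaluate(m: ExpressionMatrix, gene_list: list[str],
                   l2_strength: float = 1.0) -> tuple[np.ndarray, float, float]:
    """Leave-one-out out-of-fold case probabilities and pooled AUROC/AUPRC.

    Each fold standardizes the signature genes on the training samples only,
    fits an L2-logistic model, and scores the held-out sample; the metrics are
    computed once on the n pooled out-of-fold scores.  Deterministic: no RNG.
    """
    if not gene_list:
        raise ValueError("gene_list must be non-empty")
    missing = [g for g in gene_list if g not in m.feature_ids]
    if missing:
        raise ValueError(f"genes absent from matrix: {missing[:5]}")
    y = m.y
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("a LOOCV training fold would lose a class; "
                         "use stratified k-fold instead")
    x = m.values.loc[gene_list].to_numpy(dtype=float).T  # samples x genes
    n = len(y)
    pooled = np.empty(n)
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        xt, yt = x[train], y[train]
        mu = xt.mean(axis=0)
        sd = xt.std(axis=0)
        sd[sd == 0] = 1.0
        # default penalty is ridge (L2); C is its inverse strength
        model = LogisticRegression(C=l2_strength, solver="lbfgs", max_iter=2000)
        model.fit((xt - mu) / sd, yt)
        pooled[i] = model.predict_proba(((x[i] - mu) / sd).reshape(1, -1))[0, 1]
    return pooled, auroc(pooled, y), auprc(pooled, y)


def bootstrap_ci(scores, labels, metric, n_resample: int = 2000,
                 level: float = 0.95, seed: int = 0) -> tuple[float, float]:
    """Stratified percentile-bootstrap CI for a score-based metric.

    Resamples (score, label) pairs with replacement within each class, so the
    class mix — which AUPRC depends on — is preserved and no resample can
    degenerate to one class.
    """
    if n_resample < 100:
        raise ValueError("n_resample must be >= 100")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    vals = np.empty(n_resample)
    for b in range(n_resample):
        idx = np.concatenate([rng.choice(pos, size=len(pos), replace=True),
                              rng.choice(neg, size=len(neg), replace=True)])
        vals[b] = metric(scores[idx], labels[idx])
    alpha = (1 - level) / 2
    lo, hi = np.quantile(vals, [alpha, 1 - alpha])
    return float(lo), float(hi)


# --------------------------------------------------------------------- curve
@dataclass
class SignatureCurve:
    """Per-signature-size LOOCV metrics with bootstrap CIs."""

    table: pd.DataFrame  # columns size, cohort, auroc, auroc_lo, auroc_hi,
    #                               auprc, auprc_lo, auprc_hi
    gene_lists: dict[int, list[str]]  # size -> nested gene prefix

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.6g")


def evaluate_curve(m: ExpressionMatrix, sets: list[list[str]],
                   cohort: str = "cohort", l2_strength: float = 1.0,
                   n_resample: int = 2000, seed: int = 0) -> SignatureCurve:
    """LOOCV AUROC/AUPRC (with CIs) at every nested signature size."""
    if not sets:
        raise ValueError("no gene sets to evaluate")
    sizes = [len(s) for s in sets]
    if sizes != sorted(set(sizes)):
        raise ValueError("sets must have strictly increasing sizes")
    for small, big in zip(sets, sets[1:]):
        if small != big[:len(small)]:
            raise ValueError("sets must be nested prefixes")
    rows = []
    gene_lists = {}
    for genes in sets:
        pooled, roc, prc = loocv_evaluate(m, genes, l2_strength=l2_strength)
        roc_lo, roc_hi = bootstrap_ci(pooled, m.y, auroc, n_resample=n_resample,
                                      seed=seed)
        prc_lo, prc_hi = bootstrap_ci(pooled, m.y, auprc, n_resample=n_resample,
                                      seed=seed + 1)
        rows.append({"size": len(genes), "cohort": cohort,
                     "auroc": roc, "auroc_lo": roc_lo, "auroc_hi": roc_hi,
                     "auprc": prc, "auprc_lo": prc_lo, "auprc_hi": prc_hi})
        gene_lists[len(genes)] = list(genes)
    return SignatureCurve(table=pd.DataFrame(rows), gene_lists=gene_lists)


def select_optimal(curve: SignatureCurve, metric: str = "auroc") -> int:
    """Signature size maximizing the metric; ties go to the smallest size."""
    if metric not in ("auroc", "auprc"):
        raise ValueError("metric must be 'auroc' or 'auprc'")
    t = curve.table.sort_values("size")
    best = t.loc[t[metric].idxmax()]  # idxmax returns first (smallest size)
    return int(best["size"])
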