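"""Normalization, probe collapsing, batch correction and the DE screen.

The preprocessing chain mirrors standard microarray practice at the
expression-matrix level: quantile normalization to equalize per-sample
distributions, averaging of multi-probe genes on the log2 scale, per-batch
gene-wise standardization against known batch labels, and a Welch-t /
Benjamini-Hochberg differential-expression screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import CASE, CONTROL, ExpressionMatrix

log = logging.getLogger(__name__)


def log2_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(x + pseudocount) for matrices flagged as linear-scale."""
    if (m.values.to_numpy() + pseudocount <= 0).any():
        raise ValueError("values must exceed -pseudocount for log2 transform")
    return m.with_values(np.log2(m.values + pseudocount))


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the common (row-mean) quantile vector.

    Ties within a column receive the mean of the quantile values their
    positions span, so the map is well defined and rank-preserving.
    """
    if m.n_samples < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    x = m.values.to_numpy(dtype=float)
    order = np.sort(x, axis=0)
    ref = order.mean(axis=1)  # shared quantile vector

    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        # positions each value would occupy, ties in first-seen order
        pos = np.empty(len(col), dtype=int)
        pos[np.argsort(col, kind="stable")] = np.arange(len(col))
        assigned = ref[pos]
        # average the reference values over tied input values
        s = pd.Series(assigned).groupby(col).transform("mean")
        out[:, j] = s.to_numpy()
    return m.with_values(pd.DataFrame(out, index=m.values.index,
                                      columns=m.values.columns))


def collapse_probes(m: ExpressionMatrix, annotation: pd.DataFrame) -> ExpressionMatrix:
    """Average multi-probe genes on the log2 scale (one row per mapped gene).

    ``annotation`` must have columns (probe_id, gene_id).  Probes mapping to
    multiple genes are an error; probes without a gene are dropped and logged.
    """
    if m.level != "probe":
        raise ValueError("collapse_probes expects a probe-level matrix")
    dup = annotation["probe_id"].duplicated()
    if dup.any():
        multi = annotation.loc[dup, "probe_id"].unique()
        raise ValueError(f"probes mapped to multiple genes: {list(multi)[:5]}")
    mapping = annotation.set_index("probe_id")["gene_id"]
    probe_gene = mapping.reindex(m.feature_ids)
    unmapped = probe_gene.isna()
    if unmapped.any():
        log.info("dropping %d probes without gene annotation", int(unmapped.sum()))
    kept = m.values.loc[~unmapped.to_numpy()]
    genes = probe_gene[~unmapped]
    collapsed = kept.groupby(genes.to_numpy()).mean()
    collapsed = collapsed.sort_index()
    collapsed.index.name = "gene_id"
    return m.with_values(collapsed, level="gene")


def batch_correct(m: ExpressionMatrix) -> ExpressionMatrix:
    """Gene-wise z-scoring within each known batch.

    Genes with zero variance inside a batch are centered only and recorded in
    ``meta['constant_genes']``; class labels are untouched.
    """
    counts = m.batches.value_counts()
    singletons = counts[counts < 2]
    if len(singletons):
        raise ValueError(f"batches with a single sample: {list(singletons.index)}")
    x = m.values.to_numpy(dtype=float).copy()
    constant: set[str] = set()
    for batch in counts.index:
        cols = (m.batches == batch).to_numpy()
        sub = x[:, cols]
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=1, keepdims=True)
        zero = sd[:, 0] == 0
        if zero.any():
            constant.update(m.feature_ids[zero])
        sd[zero] = 1.0
        x[:, cols] = (sub - mu) / sd
    if constant:
        log.warning("%d genes constant within a batch (centered only)", len(constant))
    meta = dict(m.meta)
    meta["constant_genes"] = sorted(constant)
    return m.with_values(pd.DataFrame(x, index=m.values.index,
                                      columns=m.values.columns), meta=meta)


@dataclass
class DEResult:
    """Per-gene Welch-t differential-expression screen with BH q-values."""

    table: pd.DataFrame  # index gene_id; columns t, p, q, mean_diff

    def significant(self, alpha: float = 0.05) -> pd.Index:
        return self.table.index[self.table["q"] < alpha]

    def write_csv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "gene_id"
        out.to_csv(path, float_format="%.6g")


def differential_expression(m: ExpressionMatrix) -> DEResult:
    """Welch two-sample t-test (case vs control) with BH step-up q-values.

    Genes with zero variance in both classes get p = 1 (no evidence either
    way); mean_diff is case minus control.
    """
    if m.level != "gene":
        raise ValueError("differential_expression expects a gene-level matrix")
    case = m.values.loc[:, m.case_mask]
    ctrl = m.values.loc[:, ~m.case_mask]
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ValueError("need >= 2 samples per class")
    t, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
    degenerate = np.isnan(p)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    table = pd.DataFrame({
        "t": t,
        "p": p,
        "q": q,
        "mean_diff": case.mean(axis=1) - ctrl.mean(axis=1),
    }, index=m.feature_ids)
    return DEResult(table=table)


def preprocess_cohort(m: ExpressionMatrix, annotation: pd.DataFrame | None = None,
                      quantile: bool = True, batch: bool = True) -> ExpressionMatrix:
    """Standard chain: quantile normalize -> collapse probes -> batch correct."""
    out = m
    if quantile:
        out = quantile_normalize(out)
    if out.level == "probe":
        if annotation is None:
            annot_map = out.meta.get("annotation")
            if annot_map is None:
                raise ValueError("probe-level matrix needs an annotation table")
            annotation = pd.DataFrame({"probe_id": list(annot_map.keys()),
                                       "gene_id": list(annot_map.values())})
        out = collapse_probes(out, annotation)
    if batch:
        out = batch_correct(out)
    return out
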