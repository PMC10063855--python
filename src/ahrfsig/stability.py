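"""Bootstrap stability selection with an L1-logistic selector.

A gene's stability score is the fraction of bootstrap resamples in which an
L1-penalized logistic regression (fit on the resample, features standardized
on the resample) gives it a non-negligible coefficient.  With the defaults —
100 stratified with-replacement resamples and a 0.6 score threshold — this is
the classic stability-selection recipe for p >> n expression data: genes that
keep earning a coefficient across perturbed versions of the cohort are the
stable markers.

Sample order is canonicalized (sorted sample IDs) before any draw, so results
are invariant to the column order of the input matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)

#: fraction of skipped (non-convergent) iterations above which a run fails
MAX_SKIP_FRACTION = 0.10


@dataclass
class StabilityConfig:
    """Knobs of the stability-selection run.

    ``penalty_strength`` is sklearn's C (inverse regularization); smaller
    values select fewer genes per iteration.  The default 0.08 is calibrated
    so that on null cohorts (no class signal, ~10^3 genes, ~50/class) no gene
    reaches the 0.6 stability threshold while strongly informative genes stay
    near 1 — the usual way a single-penalty stability selector is tuned.
    ``coef_epsilon`` defines "selected": |coefficient| above it counts.
    """

    n_boot: int = 100
    score_threshold: float = 0.6
    penalty_strength: float = 0.08
    coef_epsilon: float = 1e-8
    stratified: bool = True
    max_iter: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.score_threshold <= 1):
            raise ValueError("score_threshold must be in (0, 1]")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.penalty_strength <= 0 or self.coef_epsilon <= 0:
            raise ValueError("penalty_strength and coef_epsilon must be positive")


@dataclass
class StabilityResult:
    """Per-gene stability scores, coefficients and ranks."""

    table: pd.DataFrame  # index gene_id; columns score, mean_abs_coef, rank, passed
    config: StabilityConfig
    n_skipped: int = 0

    @property
    def passing_genes(self) -> list[str]:
        return list(self.table.index[self.table["passed"]])

    def write_csv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "gene_id"
        out.rename(columns={"passed": "pass"}).to_csv(path, float_format="%.6g")

    def manifest(self) -> dict:
        return {"config": asdict(self.config), "n_skipped": self.n_skipped,
                "n_genes": int(len(self.table)),
                "n_passing": int(self.table["passed"].sum())}


def bootstrap_indices(labels: np.ndarray, iteration: int, seed: int,
                      stratified: bool = True) -> np.ndarray:
    """With-replacement resample indices, deterministic in (seed, iteration).

    Stratified mode draws n_cases case slots and n_controls control slots, so
    every resample keeps the cohort's class mix.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(iteration)]))
    n = len(labels)
    if not stratified:
        return rng.integers(0, n, size=n)
    parts = []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        parts.append(rng.choice(idx, size=len(idx), replace=True))
    return np.concatenate(parts)


def _l1_logistic(penalty_strength: float, max_iter: int) -> LogisticRegression:
    # sklearn >= 1.8 expresses the penalty via l1_ratio; older versions need
    # penalty="l1" (liblinear rejects l1_ratio there)
    import sklearn
    # fixed random_state: liblinear shuffles internally and must stay
    # deterministic; all run-level randomness comes from the bootstrap draws
    kwargs = dict(C=penalty_strength, solver="liblinear",
                  intercept_scaling=100.0, max_iter=max_iter, tol=1e-5,
                  random_state=0)
    major, minor = (int(v) for v in sklearn.__version__.split(".")[:2])
    if (major, minor) >= (1, 8):
        return LogisticRegression(l1_ratio=1.0, **kwargs)
    return LogisticRegression(penalty="l1", **kwargs)  # pragma: no cover


def fit_sparse_logistic(x: np.ndarray, y: np.ndarray,
                        penalty_strength: float = 1.0,
                        max_iter: int = 1000) -> np.ndarray:
    """L1-logistic coefficients on a (standardized) bootstrap draw.

    Raises RuntimeError on non-convergence so callers can skip and count the
    iteration.  Constant features (zero variance on the draw) must already be
    standardized to all-zero columns and come back with coefficient 0.
    """
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in the draw")
    model = _l1_logistic(penalty_strength, max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            model.fit(x, y)
        except ConvergenceWarning as exc:  # pragma: no cover - rare with liblinear
            raise RuntimeError("solver failed to converge") from exc
    return model.coef_.ravel()


def _standardize_on_draw(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0  # constant-on-draw genes become all-zero columns
    return (x - mu) / sd


def stability_select(m: ExpressionMatrix, cfg: StabilityConfig | None = None) -> StabilityResult:
    """Run the full bootstrap stability-selection procedure on a gene matrix."""
    cfg = cfg or StabilityConfig()
    cfg.validate()
    if m.level != "gene":
        raise ValueError("stability_select expects a gene-level matrix")

    # canonical sample order -> column-permutation invariance
    order = np.argsort(m.sample_ids.to_numpy())
    values = m.values.to_numpy(dtype=float)[:, order].T  # samples x genes
    y = m.y[order]
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need >= 2 samples per class")

    genes = m.feature_ids
    n_genes = len(genes)
    sel_count = np.zeros(n_genes)
    coef_sum = np.zeros(n_genes)
    skipped = 0

    for it in range(cfg.n_boot):
        idx = bootstrap_indices(y, it, cfg.seed, stratified=cfg.stratified)
        xb = _standardize_on_draw(values[idx])
        try:
            coef = fit_sparse_logistic(xb, y[idx], cfg.penalty_strength,
                                       cfg.max_iter)
        except RuntimeError:
            skipped += 1
            log.warning("iteration %d skipped: non-convergence", it)
            continue
        selected = np.abs(coef) > cfg.coef_epsilon
        sel_count += selected
        coef_sum += np.where(selected, np.abs(coef), 0.0)

    if skipped > MAX_SKIP_FRACTION * cfg.n_boot:
        raise RuntimeError(
            f"{skipped}/{cfg.n_boot} iterations failed to converge "
            f"(> {MAX_SKIP_FRACTION:.0%}); increase max_iter or penalty")

    score = sel_count / cfg.n_boot  # denominator stays n_boot even with skips
    with np.errstate(invalid="ignore"):
        mean_abs = np.where(sel_count > 0, coef_sum / np.maximum(sel_count, 1), 0.0)

    table = pd.DataFrame({"score": score, "mean_abs_coef": mean_abs},
                         index=genes)
    table["rank"] = _rank_table(table)
    table["passed"] = table["score"] >= cfg.score_threshold
    return StabilityResult(table=table, config=cfg, n_skipped=skipped)


def _rank_table(table: pd.DataFrame) -> np.ndarray:
    ordered = (table.assign(_gene=table.index.to_numpy())
               .sort_values(by=["score", "mean_abs_coef", "_gene"],
                            ascending=[False, False, True], kind="mergesort"))
    ranks = pd.Series(np.arange(1, len(ordered) + 1), index=ordered.index)
    return ranks.reindex(table.index).to_numpy()


def rank_genes(result: StabilityResult) -> list[str]:
    """Ordered gene list: descending score, then descending mean |coef|,
    then lexicographic gene ID."""
    return list(result.table.sort_values("rank").index)
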