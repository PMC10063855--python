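"""Expression-matrix container and the plain-text dialects used throughout.

The central object is :class:`ExpressionMatrix`: a features x samples matrix of
log2-scale expression values with per-sample class and batch labels.  Rows are
probes or genes depending on ``level``; the sample axis is shared with the
label table.  All files are tab-separated text so fixtures stay diff-able.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CASE = "case"
CONTROL = "control"

FLOAT_FMT = "%.6f"


@dataclass
class ExpressionMatrix:
    """Log2 expression values with aligned sample annotations.

    Parameters
    ----------
    values
        DataFrame of shape (n_features, n_samples); index = feature IDs,
        columns = sample IDs.
    classes
        Series indexed by sample ID with values ``"case"`` / ``"control"``.
    batches
        Series indexed by sample ID with batch labels (strings).
    level
        ``"probe"`` or ``"gene"``.
    meta
        Free-form provenance (e.g. genes flagged constant by batch correction).
    """

    values: pd.DataFrame
    classes: pd.Series
    batches: pd.Series
    level: str = "probe"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.level not in ("probe", "gene"):
            raise ValueError(f"level must be 'probe' or 'gene', got {self.level!r}")
        if self.values.index.has_duplicates:
            raise ValueError("feature IDs must be unique")
        if self.values.columns.has_duplicates:
            raise ValueError("sample IDs must be unique")
        self.classes = self.classes.reindex(self.values.columns)
        self.batches = self.batches.reindex(self.values.columns)
        if self.classes.isna().any():
            missing = list(self.classes.index[self.classes.isna()])
            raise ValueError(f"samples without class label: {missing[:5]}")
        bad = set(self.classes.unique()) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"unknown class labels: {sorted(bad)}")
        if self.values.isna().any().any():
            raise ValueError("missing expression values (dense input required)")

    # ------------------------------------------------------------------ props
    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def case_mask(self) -> np.ndarray:
        return (self.classes == CASE).to_numpy()

    @property
    def y(self) -> np.ndarray:
        """Binary labels, case = 1, control = 0 (fixed encoding)."""
        return self.case_mask.astype(int)

    def with_values(self, values: pd.DataFrame, level: str | None = None,
                    meta: dict | None = None) -> "ExpressionMatrix":
        """New matrix sharing this one's sample annotations."""
        return ExpressionMatrix(
            values=values,
            classes=self.classes.copy(),
            batches=self.batches.copy(),
            level=self.level if level is None else level,
            meta=dict(self.meta) if meta is None else meta,
        )

    # ------------------------------------------------------------------ io
    def write(self, expr_path: str | Path, labels_path: str | Path) -> None:
        write_expression_tsv(self, expr_path)
        write_labels_tsv(self, labels_path)


def write_expression_tsv(m: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix: header row of sample IDs, leading feature-ID column."""
    out = m.values.copy()
    out.index.name = "probe_id" if m.level == "probe" else "gene_id"
    out.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def write_labels_tsv(m: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame({
        "sample_id": m.sample_ids,
        "class": m.classes.values,
        "batch": m.batches.values,
    })
    df.to_csv(path, sep="\t", index=False)


def read_expression_matrix(expr_path: str | Path, labels_path: str | Path,
                           level: str = "probe") -> ExpressionMatrix:
    """Load an expression TSV plus its label table.

    Raises on missing values, duplicate IDs, or samples absent from the label
    table — silent imputation hides format bugs.
    """
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    labels = pd.read_csv(labels_path, sep="\t", dtype=str)
    required = {"sample_id", "class"}
    if not required.issubset(labels.columns):
        raise ValueError(f"labels file needs columns {sorted(required)}")
    labels = labels.set_index("sample_id")
    missing = [s for s in values.columns if s not in labels.index]
    if missing:
        raise ValueError(f"samples missing from labels file: {missing[:5]}")
    classes = labels["class"].reindex(values.columns)
    if "batch" in labels.columns:
        batches = labels["batch"].reindex(values.columns)
    else:
        batches = pd.Series("batch0", index=values.columns)
    return ExpressionMatrix(values=values, classes=classes, batches=batches,
                            level=level)


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    """Probe→gene map with columns (probe_id, gene_id)."""
    annot = pd.read_csv(path, sep="\t", dtype=str)
    if not {"probe_id", "gene_id"}.issubset(annot.columns):
        raise ValueError("annotation file needs columns probe_id, gene_id")
    return annot
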