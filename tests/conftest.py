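import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ahrfsig import (CohortSpec, ExpressionMatrix, generate_cohort,
                     generate_paired_cohorts, preprocess_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """Probe-level cohort with batches and a clear planted signal."""
    spec = CohortSpec(n_cases=30, n_controls=20, n_genes=200, n_informative=8,
                      effect_size=1.5, noise_sd=0.5, n_batches=2,
                      batch_shift_sd=2.0, seed=42)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def gene_cohort(small_cohort):
    """The same cohort preprocessed to gene level."""
    m, truth = small_cohort
    return preprocess_cohort(m), truth


@pytest.fixture(scope="session")
def paired_cohorts():
    """Twin cohorts sharing 12 of 20 informative genes."""
    spec_a = CohortSpec(n_cases=40, n_controls=30, n_genes=400,
                        n_informative=20, effect_size=1.0, noise_sd=0.5,
                        seed=7)
    spec_b = CohortSpec(n_cases=45, n_controls=35, n_genes=400,
                        n_informative=20, effect_size=1.0, noise_sd=0.5,
                        seed=8)
    return generate_paired_cohorts(spec_a, spec_b, shared_informative=12)


def make_matrix(values: np.ndarray, classes: list[str],
                level: str = "gene", batches: list[str] | None = None,
                feature_prefix: str = "G") -> ExpressionMatrix:
    """Tiny hand-built ExpressionMatrix for arithmetic examples."""
    n_feat, n_samp = values.shape
    features = [f"{feature_prefix}{i + 1}" for i in range(n_feat)]
    samples = [f"S{i + 1}" for i in range(n_samp)]
    df = pd.DataFrame(values, index=features, columns=samples)
    return ExpressionMatrix(
        values=df,
        classes=pd.Series(classes, index=samples),
        batches=pd.Series(batches or ["b0"] * n_samp, index=samples),
        level=level,
    )
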