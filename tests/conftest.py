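import numpy as np
import pandas as pd
import pytest

from rnadx import CohortConfig, GeneAnnotation, GeneCountMatrix, simulate_counts


@pytest.fixture(scope="session")
def small_cohort():
    """60-sample, 400-gene null cohort without latent structure."""
    cfg = CohortConfig(n_samples=60, n_genes=400, seed=42, q_true=0)
    matrix, annotation, truth = simulate_counts(cfg)
    return cfg, matrix, annotation


@pytest.fixture(scope="session")
def confounded_cohort():
    """Cohort with three strong latent factors, for calibration checks."""
    cfg = CohortConfig(n_samples=100, n_genes=800, seed=11, q_true=3, latent_scale=0.4)
    matrix, annotation, truth = simulate_counts(cfg)
    return cfg, matrix, annotation


@pytest.fixture
def toy_matrix():
    counts = pd.DataFrame(
        [[10, 20, 30], [5, 0, 15]],
        index=pd.Index(["G1", "G2"], name="gene_id"),
        columns=["S1", "S2", "S3"],
    )
    return GeneCountMatrix(counts)


@pytest.fixture
def toy_annotation():
    table = pd.DataFrame(
        {
            "chromosome": ["chr1", "chr2"],
            "start": [1, 1],
            "end": [10_000, 10_000],
            "gene_length": [1000, 2000],
            "n_exons": [5, 10],
        },
        index=pd.Index(["G1", "G2"], name="gene_id"),
    )
    return GeneAnnotation(table, gene_lists={"OMIM": {"G1"}})
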