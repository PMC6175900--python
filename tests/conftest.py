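import numpy as np
import pytest

from espstrat import (
    EmbeddingConfig,
    MutationCohort,
    SimulationConfig,
    simulate_cohort,
)
from espstrat.pipeline import StratifyOptions


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_cohort():
    """A hand-sized binary cohort with one perfectly exclusive gene pair."""
    patients = tuple(f"P{i}" for i in range(8))
    genes = ("TP53", "KRAS", "EGFR", "BRAF")
    calls = np.array(
        [
            [1, 0, 1, 0],
            [1, 0, 0, 0],
            [1, 0, 1, 1],
            [1, 0, 0, 0],
            [0, 1, 1, 0],
            [0, 1, 0, 1],
            [0, 1, 1, 0],
            [0, 1, 0, 0],
        ],
        dtype=np.int8,
    )
    return MutationCohort(patients=patients, genes=genes, calls=calls)


@pytest.fixture
def tiny_sim():
    """Small clean pathway-driven simulation: separable by construction."""
    cfg = SimulationConfig(
        n_tumors=40,
        n_genes=60,
        pathway_size=8,
        muts_per_pathway=2,
        within_density=1.0,
        scenario="fmp_only",
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def fast_options():
    """Reduced clustering settings for fast in-test pipelines."""
    return StratifyOptions(
        embedding=EmbeddingConfig(d_range=(3, 5, 8), kmeans_starts=10, seed=0)
    )
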