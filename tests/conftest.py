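import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from corelnc.config import SimulationConfig
from corelnc import synthetic as syn

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast study: 300 genes, 50 lncRNAs, 8 planted targets."""
    return SimulationConfig(
        seed=7,
        n_genes=300,
        n_lncrnas=50,
        n_target_lncrnas=8,
        n_target_mrnas=20,
        n_assoc_per_side=10,
        assoc_pool_size=50,
        n_datasets=4,
        n_chip_nutlin=3,
        n_chip_nonnutlin=3,
        n_chip_control=2,
        cohort_n=80,
        n_cancer_types=1,
        n_cell_lines=4,
    )


@pytest.fixture(scope="session")
def annotation(small_config):
    return syn.generate_annotation(small_config)


@pytest.fixture(scope="session")
def truth(annotation, small_config):
    return syn.make_truth(annotation, small_config)


@pytest.fixture(scope="session")
def cohort(annotation, truth, small_config):
    return syn.generate_cohort(annotation, truth, small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_counts(counts: np.ndarray, conditions: list[str], dataset_id: str = "T"):
    """Helper: wrap an array into a CountMatrix with generated ids."""
    from corelnc.diffexpr import CountMatrix

    genes = [f"g{i}" for i in range(counts.shape[0])]
    samples = [f"s{i}" for i in range(counts.shape[1])]
    return CountMatrix(
        dataset_id=dataset_id,
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        condition=pd.Series(conditions, index=samples),
    )
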