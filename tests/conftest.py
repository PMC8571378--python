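import numpy as np
import pytest

from tilseq import io as tio
from tilseq import sc, simulate


@pytest.fixture(scope="session")
def toy_thresholds():
    """QC window matched to the small simulated gene space used in tests."""
    return sc.QCThresholds(
        max_total_umis=30000, min_genes=100, max_genes=550, max_mito=0.10, min_ribo=0.05
    )


@pytest.fixture(scope="session")
def toy_count_config(toy_thresholds):
    return simulate.CountSimConfig(
        n_libraries=2,
        cells_per_library=120,
        n_genes=600,
        marker_genes_per_type=5,
        mito_mean=3.0,
        ribo_mean=3.0,
        thresholds=toy_thresholds,
        seed=1,
    )


@pytest.fixture(scope="session")
def toy_counts(toy_count_config):
    """Two small libraries with planted types and QC violators, plus truth."""
    return simulate.simulate_counts(toy_count_config)


@pytest.fixture(scope="session")
def toy_pooled(toy_counts):
    adatas, truth = toy_counts
    return tio.concat_libraries(adatas.values()), truth


@pytest.fixture(scope="session")
def toy_repertoire():
    cfg = simulate.RepertoireSimConfig(library_ids=("lib1",), seed=2)
    contigs, reference, truth = simulate.simulate_repertoire(cfg)
    return cfg, contigs, reference, truth


def random_metric_points(rng: np.random.Generator, n: int, d: int = 3) -> np.ndarray:
    return rng.normal(size=(n, d))
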