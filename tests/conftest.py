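import numpy as np
import pytest

import microsig as ms


@pytest.fixture(scope="session")
def tiny_config():
    """A 4-tissue cohort small enough for fast model iterations."""
    return ms.CohortConfig(
        n_tissues=4,
        samples_per_tissue=20,
        n_species=80,
        signature_tissues=(0, 1),
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return ms.generate_cohort(tiny_config)


@pytest.fixture(scope="session")
def tiny_universe(tiny_cohort):
    counts, meta = tiny_cohort
    cores = [ms.core_microbiome(counts, meta, t) for t in meta.tissues]
    union, _ = ms.core_union_and_intersections(cores)
    return union


@pytest.fixture(scope="session")
def fast_spec():
    """Single grid point, few iterations: exercises the protocol without
    grid-search cost."""
    return ms.ModelSpec(
        interaction_depth_grid=(2,),
        n_trees_grid=(60,),
        iterations=3,
        master_seed=5,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_count_matrix(rng, n_features=50, n_samples=20, density=0.5, scale=40):
    counts = rng.poisson(scale, size=(n_features, n_samples))
    counts[rng.random((n_features, n_samples)) > density] = 0
    return ms.CountMatrix(
        features=[f"f{i:03d}" for i in range(n_features)],
        samples=[f"s{j:03d}" for j in range(n_samples)],
        counts=counts,
    )
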