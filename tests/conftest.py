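import numpy as np
import pytest

from netsi import CohortSpec, Partition, generate_cohort, template_partition


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    """Desk-scale cohort: 6 subjects, 80 nodes, 4 planted communities."""
    return CohortSpec(
        n_subjects=6,
        n_nodes=80,
        community_sizes=(20, 20, 20, 20),
        conditions=(("Rest", 0.0), ("Easy", 0.2), ("Hard", 0.4)),
        n_timepoints=150,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def template_80() -> Partition:
    return template_partition((20, 20, 20, 20))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_partition(n_nodes: int, n_comm: int, rng: np.random.Generator) -> Partition:
    """A uniformly random labeling guaranteed to use every community id."""
    labels = rng.integers(0, n_comm, size=n_nodes)
    labels[rng.choice(n_nodes, size=n_comm, replace=False)] = np.arange(n_comm)
    return Partition(labels)
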