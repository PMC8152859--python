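import numpy as np
import pytest

from bodyrsa.design import BODY_PART_CONDITIONS, DesignSpec, build_design
from bodyrsa.partitions import hypothesized_partition
from bodyrsa.rsa import RDM


@pytest.fixture(scope="session")
def default_spec():
    return DesignSpec()


@pytest.fixture(scope="session")
def schedules(default_spec):
    return build_design(default_spec, seed=11)


def make_clustered_rdm(seed=0, within=(0.0, 0.3), between=(0.7, 1.3)):
    """RDM whose within-category entries all lie below every
    between-category entry for the hypothesized three-way grouping."""
    rng = np.random.default_rng(seed)
    hyp = hypothesized_partition()
    labels = BODY_PART_CONDITIONS
    D = np.zeros((8, 8))
    for i in range(8):
        for j in range(i):
            same = hyp.class_of(labels[i]) == hyp.class_of(labels[j])
            lo, hi = within if same else between
            D[i, j] = D[j, i] = rng.uniform(lo, hi)
    np.fill_diagonal(D, rng.uniform(0.0, 0.1, size=8))
    return RDM(values=D)


def make_random_rdm(seed=0):
    rng = np.random.default_rng(seed)
    A = rng.uniform(0.0, 2.0, size=(8, 8))
    D = (A + A.T) / 2
    np.fill_diagonal(D, 0.0)
    return RDM(values=D)


@pytest.fixture
def clustered_rdm():
    return make_clustered_rdm(seed=3)


@pytest.fixture
def random_rdm():
    return make_random_rdm(seed=4)
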