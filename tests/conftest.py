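import numpy as np
import pytest

from mcistrat.io import FeatureTable, Modality, make_binary_task, TaskName
from mcistrat.synthetic import AdniLikeSpec, DomainPairSpec, make_adni_like, make_gaussian_domains


@pytest.fixture(scope="session")
def small_table() -> FeatureTable:
    """Four-class ADNI-like table, reduced cohort, fixed seed."""
    return make_adni_like(AdniLikeSpec(n_per_class=(60, 70, 50, 45), dim=40, seed=7))


@pytest.fixture(scope="session")
def gaussian_domains():
    """Default paired Gaussian source/target domains (seed 0)."""
    return make_gaussian_domains(DomainPairSpec(seed=0))


@pytest.fixture(scope="session")
def target_task(small_table):
    return make_binary_task(small_table, TaskName.LMCI_vs_EMCI)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def jaccard(a, b) -> float:
    a, b = set(a), set(b)
    return len(a & b) / max(len(a | b), 1)
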