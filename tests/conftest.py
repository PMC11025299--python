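import numpy as np
import pytest

from copritest import HypothesisSpec, StudyData


def make_random_study(seed: int, n1: int = 40, n0: int = 60, m: int = 3,
                      se: float = 0.85, sp: float = 0.75) -> StudyData:
    """Independent-column binomial study data (no special structure)."""
    rng = np.random.default_rng(seed)
    cases = rng.binomial(1, se, size=(n1, m))
    controls = rng.binomial(1, 1 - sp, size=(n0, m))
    d = np.concatenate([np.ones(n1, dtype=int), np.zeros(n0, dtype=int)])
    return StudyData(disease_status=d, test_results=np.vstack([cases, controls]))


@pytest.fixture
def hyp():
    return HypothesisSpec(se0=0.8, sp0=0.7, alpha=0.025)


@pytest.fixture
def random_study():
    return make_random_study


@pytest.fixture
def six_case_study():
    """Six diseased subjects with a hand-checkable agreement pattern.

    Case columns:  T1 = (1,1,0,1,0,1), T2 = (1,0,0,1,1,1).
    Four controls are all test-negative so both tests bind on sensitivity.
    """
    t_cases = np.array([[1, 1], [1, 0], [0, 0], [1, 1], [0, 1], [1, 1]])
    t_controls = np.zeros((4, 2), dtype=int)
    d = np.array([1] * 6 + [0] * 4)
    return StudyData(disease_status=d, test_results=np.vstack([t_cases, t_controls]))
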