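import numpy as np
import pytest

from rctadjust.core import TrialDataset
from rctadjust.simulate import ScenarioConfig, generate_continuous_trial


def make_trial(n=40, p=2, seed=0, **kwargs) -> TrialDataset:
    """A benchmark trial with defaults suitable for unit tests."""
    cfg = ScenarioConfig(n=n, adjust_set=tuple(f"C{j+1}" for j in range(min(p, 6))),
                         seed=seed, **kwargs)
    return generate_continuous_trial(cfg)


@pytest.fixture
def small_trial() -> TrialDataset:
    return make_trial(n=40, p=2, seed=7)


@pytest.fixture
def toy_dataset() -> TrialDataset:
    """6 participants: treated outcomes {10, 12}, controls {5, 6, 7, 8}."""
    return TrialDataset(
        subject_id=np.array([f"s{i}" for i in range(6)]),
        treatment=np.array([1, 1, 0, 0, 0, 0]),
        outcome=np.array([10.0, 12.0, 5.0, 6.0, 7.0, 8.0]),
        covariates=np.array([[0.5], [0.8], [0.5], [0.5], [0.2], [0.2]]),
        covariate_names=("x1",),
    )
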