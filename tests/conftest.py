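import numpy as np
import pytest

from bouncebayes import (
    DesignSpec,
    FitConfig,
    ModelParams,
    TrialRecord,
    build_design,
    simulate_participant,
)


@pytest.fixture
def two_trial_example():
    """The hand-computed pair: a confirmed high cue and a confirmed low cue
    under SP=0.8, pB=0.6 (log-likelihoods ln 8/11 and ln 6/7)."""
    return [
        TrialRecord("grubber", "PC", "high_cue", response="high"),
        TrialRecord("grubber", "PC", "low_cue", response="low"),
    ]


@pytest.fixture(scope="session")
def default_design():
    return build_design(DesignSpec(seed=0))


@pytest.fixture(scope="session")
def fixture_datasets(default_design):
    """Twenty simulated 111-trial participants with known parameters,
    spanning the informative parameter range."""
    rng = np.random.default_rng(2024)
    datasets = []
    for i in range(20):
        true = ModelParams(
            SP=float(rng.uniform(0.3, 0.95)), pB=float(rng.uniform(0.15, 0.85))
        )
        design = build_design(DesignSpec(seed=i))
        datasets.append((true, simulate_participant(design, true, seed=1000 + i)))
    return datasets


@pytest.fixture
def fit_config():
    return FitConfig(seed=0)
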