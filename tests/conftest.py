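import numpy as np
import pytest

from chcq import CriterionConfig, LearningConfig
from chcq.battery import BatteryConfig, run_battery

# (task, system) pairs the acceptance checks need; medians are computed once
ACCEPTANCE_TASKS = ("a_plus", "a_minus", "stimulus_discrimination",
                    "discrimination_reversal", "blocking",
                    "latent_inhibition", "context_shift",
                    "easy_hard_transfer")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def plain_learning():
    """Learning config with unscaled rates, for literal-rule unit tests."""
    return LearningConfig(mu=0.1, instar_scale=1.0, hippocampal_scale=1.0,
                          error_deadzone=0.0)


@pytest.fixture(scope="session")
def battery_medians():
    """25-seed median trials-to-criterion for the acceptance task battery,
    shipped default configuration, as a (task, system, phase) -> float map."""
    cfg = BatteryConfig(tasks=ACCEPTANCE_TASKS, n_seeds=25, base_seed=0)
    res = run_battery(cfg)
    s = res.summary.set_index(["task", "system", "phase"])["trials_median"]
    return {k: float(v) for k, v in s.items()}
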