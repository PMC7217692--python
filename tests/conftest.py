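import numpy as np
import pytest

from speechrecal import PerceptualModel, RuleParams, evaluate_rule

#: Master seed for the full-protocol evaluations shared by the acceptance
#: tests (one four-rule protocol per session keeps the suite fast).
PROTOCOL_SEED = 1


@pytest.fixture
def default_model() -> PerceptualModel:
    """Printed category means with all spreads at 0.1."""
    return PerceptualModel.default()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def rule_evaluations():
    """Full evaluation protocol for the four update rules.

    20 perceptual parameter sets x 100 listeners x 414 trials per rule,
    6000 resampled groups of 27 — the reference protocol at full scale.
    """
    rules = {
        "decay": RuleParams.decay(R1=0.4, D=0.14, R2=0.0),
        "none": RuleParams.none(),
        "bayes": RuleParams.bayes(kappa0=1.0, nu0=1.0),
        "delta": RuleParams.delta(rate_V=0.2, rate_A=0.2),
    }
    return {
        name: evaluate_rule(rp, master_seed=PROTOCOL_SEED)
        for name, rp in rules.items()
    }
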