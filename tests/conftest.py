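import numpy as np
import pytest

import infoval as iv


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def coin_session():
    """A human coin-task session with simulated choices (known chooser)."""
    from infoval.studies import human_wtp_study

    rng = np.random.default_rng(101)
    cfg, params = human_wtp_study(n_trials=4000)
    trials = iv.generate_offers(cfg, rng)
    trials = iv.simulate_choices(trials, params, rng)
    return trials, params


@pytest.fixture(scope="session")
def clock_session():
    """A monkey clock-task session with the ten-attribute chooser."""
    rng = np.random.default_rng(202)
    cfg = iv.SessionConfig.monkey_v2(n_trials=400)
    params = iv.default_behavior("timing10", "ml")
    trials = iv.generate_offers(cfg, rng)
    trials, nu = iv.simulate_choices(
        trials, params, rng, value_noise_sd=1.0, return_value_noise=True
    )
    return trials, params, nu


@pytest.fixture(scope="session")
def clock_fit(clock_session):
    trials, params, _nu = clock_session
    fit = iv.ChoiceModel(trials, params.spec).fit()
    return fit, fit.subjective_values(trials)
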