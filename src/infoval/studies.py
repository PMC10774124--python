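"""Canonical simulation studies: the fixed conditions under which the
package's headline properties are demonstrated.

Each function returns the ingredients of one study (session configuration,
generating chooser, neuron schemes) so that tests, scripts and docs all run
the same experiment.  The conditions are chosen once to emulate the task and
the magnitude of the behavioral effects being modeled:

* choosers weight expected reward strongly, are risk seeking in the monkey
  juice task and mildly risk averse in the human coin task, and place a
  positive Info x Uncertainty weight so that the value of information
  predominantly scales with reward uncertainty rather than being a flat
  bonus;
* the uncertainty-form study uses the dissociating design (both 50/50 and
  25/50/25 lotteries at matched ranges) with offer 2's expected reward
  constrained near offer 1's, the task's device for avoiding trivial
  decisions, which makes non-E[r] attributes pivotal more often.
"""

from __future__ import annotations

from .simulate import BehavioralParams, CodingScheme, SessionConfig
from .task import core_spec

__all__ = [
    "human_wtp_study",
    "uncertainty_form_study",
    "stimulation_study",
    "population_study",
]


def human_wtp_study(n_trials: int = 20_000):
    """Coin-task chooser for willingness-to-pay recovery.

    E[r] weight 0.8 per coin, mild risk aversion, information worth about a
    coin on average and more for uncertain lotteries.
    """
    cfg = SessionConfig.human_coins(n_trials=n_trials)
    params = BehavioralParams(
        core_spec("sd"), beta=(0.8, -0.05, 0.5, 0.02, 0.15)
    )
    return cfg, params


def uncertainty_form_study(n_trials: int = 5_000, form: str = "sd"):
    """Dissociating design plus a chooser whose information value scales
    predominantly with uncertainty, for the SD/range/entropy comparison.

    The SD chooser's weights are per ml of juice (E[r]: 10 log-odds per ml);
    the entropy chooser's uncertainty weights are per bit.
    """
    cfg = SessionConfig.monkey_v1(
        n_trials=n_trials,
        dist_types=("safe", "50_50", "25_50_25"),
        deviations=(0.08, 0.12),
        offer2_er_window=0.08,
    )
    beta = {
        "sd": (10.0, 3.0, 0.1, 0.2, 8.0),
        "entropy": (10.0, 0.3, 0.1, 0.2, 0.8),
    }[form]
    params = BehavioralParams(core_spec(form), beta=beta)
    return cfg, params


def stimulation_study(
    n_trials: int = 10_000,
    stim_prob: tuple[float, float] = (0.25, 0.25),
    value_subtraction: float = 1.0,
    n_sessions: int = 1,
):
    """Offer-period stimulation sessions with a known value subtraction."""
    cfg = SessionConfig.monkey_v2(
        n_trials=n_trials,
        stim_prob=stim_prob,
        stim_value_subtraction=value_subtraction,
    )
    from .pipeline import default_behavior

    params = default_behavior("timing10", "ml")
    return cfg, params


def population_study(
    noise_sd: float = 1.0, gain: float = 1.0, n_trials: int = 300
):
    """Session and chooser used for simulated neural populations."""
    cfg = SessionConfig.monkey_v2(n_trials=n_trials)
    from .pipeline import default_behavior

    params = default_behavior("timing10", "ml")
    return cfg, params
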