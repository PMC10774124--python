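"""Domain types for multi-attribute information-choice tasks.

An *offer* is a four-outcome reward lottery (each outcome drawn with
probability 1/4), an informativeness flag (does choosing it buy an early,
non-instrumental cue revealing the outcome?) and, in the timing variant of
the task, a clock fixing when the cue and the final reveal occur.  A *trial*
is a pair of offers, a binary choice, the delivered outcome, and optional
electrical-stimulation flags.

This module holds the attribute vocabulary shared by the behavioral and
neural models: expected reward E[r], reward uncertainty Unc[r] (SD, range or
entropy of the lottery), informativeness, timing terms and their
interactions.  Attribute construction is pure and vectorized over trial
tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RewardDistribution",
    "TimingClock",
    "Offer",
    "Trial",
    "ModelSpec",
    "ATTRIBUTE_VOCABULARY",
    "UNCERTAINTY_FORMS",
    "expected_reward",
    "uncertainty",
    "build_attributes",
    "attribute_matrix",
    "enumerate_reward_grid",
    "classify_distribution",
    "core_spec",
    "timing_spec",
    "human_timing_spec",
    "value_spec",
    "get_spec",
    "TRIAL_COLUMNS",
]

UNCERTAINTY_FORMS = ("sd", "range", "entropy", "none")

#: every attribute name any registered model may use
ATTRIBUTE_VOCABULARY = (
    "E[r]",
    "Unc[r]",
    "Info",
    "Info:E[r]",
    "Info:Unc[r]",
    "t_out",
    "t_out:E[r]",
    "Info:t_out",
    "Info:t_adv",
    "Info:t_adv:Unc[r]",
    "Stim1",
    "Stim2",
    "Value",
    "EarlyInfo",
)

# fixed event timing of the first task version (seconds after choice)
V1_T_CUE = 0.5
V1_T_REV = 4.0
V1_OUT_DELAY = 0.5
#: reward arrives this long after the reveal in the timing (clock) version
V2_OUT_DELAY = 1.1

#: canonical trial-table column order (offer k in {1, 2})
TRIAL_COLUMNS = (
    ["trial_id", "session_id"]
    + [f"r_{k}_{j}" for k in (1, 2) for j in (1, 2, 3, 4)]
    + [f"{c}_{k}" for k in (1, 2) for c in ("info", "t_cue", "t_rev", "pos")]
    + ["choice", "outcome", "stim", "valid"]
)


# ---------------------------------------------------------------------------
# dataclasses


@dataclass(frozen=True)
class RewardDistribution:
    """Four equiprobable reward magnitudes with a unit tag (ml or coins)."""

    outcomes: tuple[float, float, float, float]
    units: str = "ml"

    def __post_init__(self):
        if len(self.outcomes) != 4:
            raise ValueError("a reward distribution has exactly 4 outcomes")
        if any(o < 0 for o in self.outcomes):
            raise ValueError("reward magnitudes must be nonnegative")


@dataclass(frozen=True)
class TimingClock:
    """Cue and reveal times in seconds after choice.

    ``t_out`` (reward delivery) defaults to the clock-task rule
    ``t_rev + 1.1``; the fixed-timing task uses 0.5 s after the reveal.
    """

    t_cue: float
    t_rev: float
    t_out: float | None = None

    def __post_init__(self):
        if self.t_rev <= self.t_cue:
            raise ValueError("the reveal must follow the cue (t_advance > 0)")
        if self.t_out is None:
            object.__setattr__(self, "t_out", self.t_rev + V2_OUT_DELAY)

    @property
    def t_advance(self) -> float:
        return self.t_rev - self.t_cue

    @classmethod
    def fixed(cls) -> "TimingClock":
        """The first task version's constant timing."""
        return cls(V1_T_CUE, V1_T_REV, V1_T_REV + V1_OUT_DELAY)

    def validate_clock_task(self, atol: float = 1e-9) -> None:
        """Check the clock-task sampling constraints.

        t_cue in [0.4, 5.8], t_rev in [1.2, 6.7], gap >= 0.8 s, and both
        multiples of 0.1 s (to absolute tolerance ``atol`` after rounding).
        """
        if not (0.4 - atol <= self.t_cue <= 5.8 + atol):
            raise ValueError(f"t_cue {self.t_cue} outside [0.4, 5.8]")
        if not (1.2 - atol <= self.t_rev <= 6.7 + atol):
            raise ValueError(f"t_rev {self.t_rev} outside [1.2, 6.7]")
        if self.t_rev - self.t_cue < 0.8 - atol:
            raise ValueError("t_rev must be at least 0.8 s after t_cue")
        for name, t in (("t_cue", self.t_cue), ("t_rev", self.t_rev)):
            if abs(t * 10 - round(t * 10)) > atol * 10:
                raise ValueError(f"{name} {t} is not a multiple of 0.1 s")


@dataclass(frozen=True)
class Offer:
    distribution: RewardDistribution
    informative: bool
    timing: TimingClock = field(default_factory=TimingClock.fixed)
    position: str = "center"  # metadata only; never enters a model


@dataclass(frozen=True)
class Trial:
    offer1: Offer
    offer2: Offer
    choice: int  # 1 or 2
    outcome: float
    stim: str = "none"  # none | stim1 | stim2
    valid: bool = True

    def __post_init__(self):
        if self.choice not in (1, 2):
            raise ValueError("choice must be 1 or 2")
        chosen = self.offer1 if self.choice == 1 else self.offer2
        if self.valid and not any(
            np.isclose(self.outcome, o, rtol=0, atol=1e-9)
            for o in chosen.distribution.outcomes
        ):
            raise ValueError("outcome is not one of the chosen offer's outcomes")


@dataclass(frozen=True)
class ModelSpec:
    """A named, ordered attribute list plus the uncertainty operationalization."""

    name: str
    attributes: tuple[str, ...]
    uncertainty_form: str = "sd"

    def __post_init__(self):
        unknown = [a for a in self.attributes if a not in ATTRIBUTE_VOCABULARY]
        if unknown:
            raise ValueError(f"unknown attributes: {unknown}")
        if self.uncertainty_form not in UNCERTAINTY_FORMS:
            raise ValueError(f"unknown uncertainty form {self.uncertainty_form!r}")
        if self.uncertainty_form == "none" and any(
            "Unc" in a for a in self.attributes
        ):
            raise ValueError("uncertainty_form 'none' cannot carry Unc attributes")

    def with_form(self, form: str) -> "ModelSpec":
        """The same model under a different uncertainty measure.

        ``form='none'`` drops every attribute containing Unc[r].
        """
        if form == "none":
            attrs = tuple(a for a in self.attributes if "Unc" not in a)
        else:
            attrs = self.attributes
        return replace(self, name=f"{self.name.split('|')[0]}|{form}",
                       attributes=attrs, uncertainty_form=form)


# ---------------------------------------------------------------------------
# registered model specs

_CORE = ("E[r]", "Unc[r]", "Info", "Info:E[r]", "Info:Unc[r]")
_TIMING10 = _CORE + ("t_out", "t_out:E[r]", "Info:t_out", "Info:t_adv",
                     "Info:t_adv:Unc[r]")


def core_spec(form: str = "sd") -> ModelSpec:
    """E[r], Unc[r], Info and the Info interactions (fixed-timing tasks)."""
    return ModelSpec("core", _CORE, "sd").with_form(form)


def timing_spec(form: str = "sd") -> ModelSpec:
    """The ten-attribute model of the clock task: core plus t_out, t_out:E[r]
    and the three information-by-time interactions."""
    return ModelSpec("timing10", _TIMING10, "sd").with_form(form)


def human_timing_spec() -> ModelSpec:
    """Early-versus-late-information human variant (all offers 50/50)."""
    return ModelSpec("human-timing", ("E[r]", "EarlyInfo"), "none")


def value_spec() -> ModelSpec:
    """Single-regressor subjective-value model used for neural fits."""
    return ModelSpec("value", ("Value",), "none")


def stim_spec() -> ModelSpec:
    return ModelSpec("stim", ("Value", "Stim1", "Stim2"), "none")


_REGISTRY = {
    "core": core_spec,
    "timing10": timing_spec,
    "human-timing": human_timing_spec,
    "value": value_spec,
    "stim": stim_spec,
}


def get_spec(name: str, form: str = "sd") -> ModelSpec:
    """Look up a registered model spec by name (``core``, ``timing10``, ...)."""
    base = name.split("|")[0]
    if base not in _REGISTRY:
        raise KeyError(f"unknown model spec {name!r}; known: {sorted(_REGISTRY)}")
    if "|" in name:
        form = name.split("|", 1)[1]
    fn = _REGISTRY[base]
    try:
        return fn(form)  # type: ignore[call-arg]
    except TypeError:
        return fn()


# ---------------------------------------------------------------------------
# scalar operations


def expected_reward(dist: RewardDistribution) -> float:
    """Mean of the four equiprobable outcomes."""
    return float(np.mean(dist.outcomes))


def uncertainty(dist: RewardDistribution, form: str = "sd") -> float:
    """Reward uncertainty of a four-outcome lottery.

    ``sd``      population standard deviation over the 4 bars,
                (sum_r p(r) (r - E[r])^2)^0.5 with p = 1/4 each.
    ``range``   max(r) - min(r).
    ``entropy`` Shannon entropy in bits over the probabilities of *distinct*
                magnitudes (equal bars are aggregated first, so a safe offer
                has 0 bits, a 50/50 offer exactly 1 bit and a 25/50/25 offer
                1.5 bits).
    """
    outs = np.asarray(dist.outcomes, dtype=float)
    if form == "sd":
        return float(np.std(outs))
    if form == "range":
        return float(outs.max() - outs.min())
    if form == "entropy":
        return float(_entropy_rows(outs[None, :])[0])
    raise ValueError(f"unknown uncertainty form {form!r}")


def _entropy_rows(outs: np.ndarray, atol: float = 1e-9) -> np.ndarray:
    """Entropy in bits for each row of an (n, 4) outcome array.

    Aggregates (near-)equal magnitudes before forming probabilities:
    -sum_distinct p log2 p == -sum_j (1/4) log2(c_j / 4) where c_j counts the
    bars equal to bar j.
    """
    eq = np.isclose(outs[:, :, None], outs[:, None, :], rtol=0.0, atol=atol)
    counts = eq.sum(axis=2)  # (n, 4): multiplicity of each bar's value
    return -(0.25 * np.log2(counts / 4.0)).sum(axis=1)


def _sd_rows(outs: np.ndarray) -> np.ndarray:
    return outs.std(axis=1)


def _range_rows(outs: np.ndarray) -> np.ndarray:
    return outs.max(axis=1) - outs.min(axis=1)


def _unc_rows(outs: np.ndarray, form: str) -> np.ndarray:
    if form == "sd":
        return _sd_rows(outs)
    if form == "range":
        return _range_rows(outs)
    if form == "entropy":
        return _entropy_rows(outs)
    raise ValueError(f"uncertainty form {form!r} carries no Unc attribute")


def classify_distribution(outcomes: Sequence[float], atol: float = 1e-9) -> str:
    """Recover the distribution type from the multiset of outcomes.

    safe      four equal bars
    50/50     two pairs equidistant from the mean
    25/50/25  {m - d, m, m, m + d}
    25/75     one bar at a, three equal bars at b != a
    """
    s = np.sort(np.asarray(outcomes, dtype=float))
    m = s.mean()
    eq = lambda a, b: np.isclose(a, b, rtol=0, atol=atol)
    if eq(s[0], s[3]):
        return "safe"
    if eq(s[0], s[1]) and eq(s[2], s[3]) and eq(m - s[0], s[3] - m):
        return "50_50"
    if eq(s[1], m) and eq(s[2], m) and eq(m - s[0], s[3] - m):
        return "25_50_25"
    if eq(s[1], s[2]) and (eq(s[0], s[1]) or eq(s[2], s[3])):
        return "25_75"
    return "other"


def enumerate_reward_grid(r_step: float, r_max: float) -> np.ndarray:
    """All admissible reward magnitudes {0, R_step, 2 R_step, ..., R_max}."""
    if r_step <= 0:
        raise ValueError("R_step must be positive")
    if r_max < 0:
        raise ValueError("R_max must be nonnegative")
    n = r_max / r_step
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"R_max {r_max} is not an integer multiple of R_step {r_step}")
    return np.arange(round(n) + 1) * r_step


# ---------------------------------------------------------------------------
# attribute construction


def _offer_arrays(trials: pd.DataFrame, k: int) -> dict[str, np.ndarray]:
    outs = trials[[f"r_{k}_{j}" for j in (1, 2, 3, 4)]].to_numpy(dtype=float)
    info = trials[f"info_{k}"].to_numpy(dtype=float)
    t_cue = trials[f"t_cue_{k}"].to_numpy(dtype=float)
    t_rev = trials[f"t_rev_{k}"].to_numpy(dtype=float)
    return {"outs": outs, "info": info, "t_cue": t_cue, "t_rev": t_rev}


def attribute_matrix(
    trials: pd.DataFrame,
    spec: ModelSpec,
    offer: int,
    value: np.ndarray | None = None,
    out_delay: float = V2_OUT_DELAY,
) -> pd.DataFrame:
    """Attribute design matrix for one offer across a trial table.

    ``value`` supplies the per-trial subjective value of this offer when the
    spec contains the Value attribute.  Stim attributes code the stimulated
    offer as -1 (a value-subtraction indicator) and every other offer as 0.
    """
    if offer not in (1, 2):
        raise ValueError("offer must be 1 or 2")
    a = _offer_arrays(trials, offer)
    e = a["outs"].mean(axis=1)
    info = a["info"]
    t_out = a["t_rev"] + out_delay
    t_adv = a["t_rev"] - a["t_cue"]
    if any("Unc" in name for name in spec.attributes):
        unc = _unc_rows(a["outs"], spec.uncertainty_form)
    else:
        unc = None
    if "stim" in trials.columns:
        stim = trials["stim"].to_numpy()
    else:
        stim = np.full(len(trials), "none")

    cols: dict[str, np.ndarray] = {}
    for name in spec.attributes:
        if name == "E[r]":
            cols[name] = e
        elif name == "Unc[r]":
            cols[name] = unc
        elif name == "Info":
            cols[name] = info
        elif name == "Info:E[r]":
            cols[name] = info * e
        elif name == "Info:Unc[r]":
            cols[name] = info * unc
        elif name == "t_out":
            cols[name] = t_out
        elif name == "t_out:E[r]":
            cols[name] = t_out * e
        elif name == "Info:t_out":
            cols[name] = info * t_out
        elif name == "Info:t_adv":
            cols[name] = info * t_adv
        elif name == "Info:t_adv:Unc[r]":
            cols[name] = info * t_adv * unc
        elif name == "Stim1":
            cols[name] = np.where((stim == "stim1") & (offer == 1), -1.0, 0.0)
        elif name == "Stim2":
            cols[name] = np.where((stim == "stim2") & (offer == 2), -1.0, 0.0)
        elif name == "Value":
            if value is None:
                raise ValueError("spec contains Value but no values were supplied")
            cols[name] = np.asarray(value, dtype=float)
        elif name == "EarlyInfo":
            cols[name] = info
        else:  # pragma: no cover - vocabulary enforced by ModelSpec
            raise ValueError(f"unknown attribute {name!r}")
    return pd.DataFrame(cols, index=trials.index)


def build_attributes(offer: Offer, spec: ModelSpec) -> dict[str, float]:
    """Attribute vector of a single offer (scalar, non-stim attributes)."""
    row = pd.DataFrame(
        {
            "r_1_1": [offer.distribution.outcomes[0]],
            "r_1_2": [offer.distribution.outcomes[1]],
            "r_1_3": [offer.distribution.outcomes[2]],
            "r_1_4": [offer.distribution.outcomes[3]],
            "info_1": [float(offer.informative)],
            "t_cue_1": [offer.timing.t_cue],
            "t_rev_1": [offer.timing.t_rev],
        }
    )
    out_delay = offer.timing.t_out - offer.timing.t_rev
    mat = attribute_matrix(row, spec, offer=1, out_delay=out_delay)
    return {name: float(mat[name].iloc[0]) for name in spec.attributes}
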