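"""Synthetic behavioral sessions, neural populations and stimulation sessions.

Every generator takes an explicit ``numpy.random.Generator`` and is
bit-reproducible for a fixed seed; the generating parameters are kept in a
:class:`SyntheticGroundTruth` sidecar so downstream fits can be scored
against the truth.

The generators emulate the statistical structure of the information-choice
task: offers are four-outcome lotteries whose expected reward, uncertainty
type, reward range and informativeness are drawn independently on 75% of
trials, while the remaining 25% present matched lotteries differing only in
informativeness; choices follow a logistic function of the subjective-value
difference; neurons respond to offers under one of four coding hypotheses
(single attribute, random mixture, partial integration, full integration)
and to reward prediction errors at the cue (informative trials) or the
reveal (non-informative trials); offer-period electrical stimulation is
modeled as subtracting a fixed amount of value from the stimulated offer.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .task import (
    ModelSpec,
    TRIAL_COLUMNS,
    attribute_matrix,
    core_spec,
    enumerate_reward_grid,
    timing_spec,
)

__all__ = [
    "BehavioralParams",
    "CodingScheme",
    "SessionConfig",
    "SyntheticGroundTruth",
    "generate_offers",
    "simulate_choices",
    "simulate_stimulation",
    "simulate_neuron",
    "simulate_population",
    "enumerate_timing_pairs",
    "HYPOTHESES",
]

HYPOTHESES = (
    "single_attribute",
    "random_mixture",
    "partial_integration",
    "full_integration",
)

DIST_TYPES = ("safe", "50_50", "25_50_25", "25_75")


@dataclass(frozen=True)
class BehavioralParams:
    """Generating attribute weights of a logistic chooser (log-odds units)."""

    spec: ModelSpec
    beta: tuple[float, ...]

    def __post_init__(self):
        if len(self.beta) != len(self.spec.attributes):
            raise ValueError("one weight per attribute required")
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("weights must be finite")

    def as_series(self) -> pd.Series:
        return pd.Series(self.beta, index=list(self.spec.attributes))


@dataclass(frozen=True)
class CodingScheme:
    """How one simulated neuron codes offers and prediction errors.

    choice_coupling is the correlation between the neuron's offer-epoch
    residual and the chooser's value noise on that offer; it may be a scalar
    or a per-offer pair, and requires joint simulation of the chooser
    (``value_noise`` from :func:`simulate_choices`).
    """

    hypothesis: str = "full_integration"
    gain: float = 1.0
    sign: int = 1
    noise_sd: float = 1.0
    baseline: float = 0.0
    choice_coupling: float | tuple[float, float] = 0.0
    rpe_gain: float = 0.0
    attribute: str | None = None  # for single_attribute; None = random pick

    def __post_init__(self):
        if self.hypothesis not in HYPOTHESES:
            raise ValueError(f"unknown hypothesis {self.hypothesis!r}")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        c = np.atleast_1d(np.asarray(self.choice_coupling, dtype=float))
        if np.any(c < 0) or np.any(c > 1):
            raise ValueError("choice_coupling must lie in [0, 1]")

    def coupling_for(self, offer: int) -> float:
        c = self.choice_coupling
        if isinstance(c, (tuple, list)):
            return float(c[offer - 1])
        return float(c)


@dataclass(frozen=True)
class SessionConfig:
    """Task parameters of one generated session.

    Defaults follow the monkey clock task; classmethods give the other task
    versions.  ``er_set`` and ``deviations`` (half-ranges d: uncertain
    lotteries span m-d..m+d) are in reward units and must sit on the
    R_step grid; 25/75 lotteries need d to be an even multiple of R_step.
    """

    n_trials: int = 300
    task_version: str = "monkey_v2"
    er_set: tuple[float, ...] = (0.2, 0.3, 0.4, 0.5)
    dist_types: tuple[str, ...] = ("safe", "50_50", "25_50_25")
    deviations: tuple[float, ...] = (0.1, 0.2)
    r_step: float = 0.02
    r_max: float = 1.2
    units: str = "ml"
    matched_fraction: float = 0.25
    offer2_er_window: float | None = None
    stim_prob: tuple[float, float] = (0.0, 0.0)
    stim_value_subtraction: float = 0.0
    session_id: str = "sim"

    def __post_init__(self):
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if not 0 <= self.matched_fraction <= 1:
            raise ValueError("matched_fraction must lie in [0, 1]")
        if any(not 0 <= p <= 1 for p in self.stim_prob) or sum(self.stim_prob) > 1:
            raise ValueError("stimulation probabilities invalid")
        unknown = set(self.dist_types) - set(DIST_TYPES)
        if unknown:
            raise ValueError(f"unknown distribution types {sorted(unknown)}")
        self._ticks  # validate grid representability eagerly

    @property
    def _ticks(self) -> tuple[np.ndarray, np.ndarray]:
        """(er_set, deviations) as integer multiples of R_step."""
        def to_ticks(values, what):
            t = np.asarray(values, dtype=float) / self.r_step
            if np.any(np.abs(t - np.round(t)) > 1e-9):
                raise ValueError(f"{what} not representable on the R_step grid")
            return np.round(t).astype(int)

        er = to_ticks(self.er_set, "er_set")
        dev = to_ticks(self.deviations, "deviations")
        if er.size == 0 or dev.size == 0:
            raise ValueError("er_set and deviations must be nonempty")
        if "25_75" in self.dist_types and np.any(dev % 2):
            raise ValueError("25/75 lotteries need deviations divisible by 2*R_step")
        max_tick = round(self.r_max / self.r_step)
        if abs(self.r_max / self.r_step - max_tick) > 1e-9:
            raise ValueError("R_max is not an integer multiple of R_step")
        uncertain = set(self.dist_types) - {"safe"}
        dmax = dev.max() if uncertain else 0
        # a 25/75 lottery's lone bar sits 1.5 d from the mean (3e with e = d/2)
        if "25_75" in self.dist_types:
            dmax = max(dmax, 3 * (dev.max() // 2))
        if er.max() + dmax > max_tick or er.min() - dmax < 0:
            raise ValueError("er_set +/- deviations leaves the [0, R_max] grid")
        return er, dev

    @classmethod
    def monkey_v1(cls, **kw) -> "SessionConfig":
        kw.setdefault("task_version", "monkey_v1")
        kw.setdefault("er_set", (0.16, 0.24, 0.32, 0.4, 0.48))
        kw.setdefault("dist_types", ("safe", "50_50", "25_50_25", "25_75"))
        kw.setdefault("deviations", (0.04, 0.08))
        kw.setdefault("r_step", 0.02)
        kw.setdefault("r_max", 0.6)
        return cls(**kw)

    @classmethod
    def monkey_v2(cls, **kw) -> "SessionConfig":
        kw.setdefault("task_version", "monkey_v2")
        return cls(**kw)

    @classmethod
    def human_coins(cls, **kw) -> "SessionConfig":
        kw.setdefault("task_version", "human_coins")
        kw.setdefault("er_set", (5.0, 6.0, 7.0))
        kw.setdefault("dist_types", ("safe", "50_50", "25_50_25"))
        kw.setdefault("deviations", (4.0,))
        kw.setdefault("r_step", 1.0)
        kw.setdefault("r_max", 11.0)
        kw.setdefault("units", "coins")
        kw.setdefault("n_trials", 150)
        return cls(**kw)

    @classmethod
    def human_timing(cls, **kw) -> "SessionConfig":
        kw.setdefault("task_version", "human_timing")
        kw.setdefault("er_set", (5.0, 6.0, 7.0))
        kw.setdefault("dist_types", ("50_50",))
        kw.setdefault("deviations", (4.0,))
        kw.setdefault("r_step", 1.0)
        kw.setdefault("r_max", 11.0)
        kw.setdefault("units", "coins")
        kw.setdefault("n_trials", 100)
        return cls(**kw)


@dataclass
class SyntheticGroundTruth:
    """Generating parameters stored alongside every simulated dataset."""

    behavior: BehavioralParams
    schemes: dict[str, CodingScheme] = field(default_factory=dict)
    stim_value_subtraction: float = 0.0
    value_noise_sd: float = 0.0
    seed: int | None = None

    def to_json(self) -> str:
        d = {
            "behavior": {
                "spec": self.behavior.spec.name,
                "uncertainty_form": self.behavior.spec.uncertainty_form,
                "attributes": list(self.behavior.spec.attributes),
                "beta": list(self.behavior.beta),
            },
            "schemes": {k: asdict(v) for k, v in self.schemes.items()},
            "stim_value_subtraction": self.stim_value_subtraction,
            "value_noise_sd": self.value_noise_sd,
            "seed": self.seed,
        }
        return json.dumps(d, indent=2)


# ---------------------------------------------------------------------------
# offer generation


def enumerate_timing_pairs() -> np.ndarray:
    """All valid (t_cue, t_rev) pairs of the clock task, in seconds.

    t_cue in [0.4, 5.8], t_rev in [1.2, 6.7], t_rev - t_cue >= 0.8, both
    multiples of 0.1 s.  Enumerated on an integer decisecond grid so the
    constraints are exact.
    """
    cue = np.arange(4, 59)  # deciseconds
    rev = np.arange(12, 68)
    c, r = np.meshgrid(cue, rev, indexing="ij")
    ok = (r - c) >= 8
    return np.column_stack([c[ok], r[ok]]) / 10.0


def _draw_outcomes(
    cfg: SessionConfig, n: int, rng: np.random.Generator
) -> np.ndarray:
    """(n, 4) outcome ticks for independently generated offers."""
    er, dev = cfg._ticks
    m = rng.choice(er, size=n)
    dt = np.array(cfg.dist_types)
    types = dt[rng.integers(len(dt), size=n)]
    d = rng.choice(dev, size=n)
    outs = np.tile(m[:, None], (1, 4)).astype(int)
    is5050 = types == "50_50"
    outs[is5050, :2] -= d[is5050, None]
    outs[is5050, 2:] += d[is5050, None]
    is2550 = types == "25_50_25"
    outs[is2550, 0] -= d[is2550]
    outs[is2550, 3] += d[is2550]
    is2575 = types == "25_75"
    if is2575.any():
        e = d[is2575] // 2
        up = rng.random(is2575.sum()) < 0.5  # lone bar above vs below mean
        lone = np.where(up, 3 * e, -3 * e)
        rest = np.where(up, -e, e)
        sub = outs[is2575]
        sub[:, 0] += lone
        sub[:, 1:] += rest[:, None]
        outs[is2575] = sub
    return outs


def generate_offers(cfg: SessionConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Generate a session's offer pairs (no choices yet).

    75% of trials (1 - matched_fraction) draw each offer's features
    independently; the rest present the same lottery and timing with opposite
    informativeness.  All rewards lie on the R_step grid.
    """
    n = cfg.n_trials
    matched = rng.random(n) < cfg.matched_fraction
    outs1 = _draw_outcomes(cfg, n, rng)
    outs2 = _draw_outcomes(cfg, n, rng)
    info1 = rng.integers(2, size=n)
    info2 = rng.integers(2, size=n)

    if cfg.offer2_er_window is not None:
        # redraw offer 2's lottery until its mean is near offer 1's
        win = cfg.offer2_er_window + 1e-9
        for _ in range(200):
            bad = (~matched) & (
                np.abs(outs2.mean(axis=1) - outs1.mean(axis=1)) * cfg.r_step > win
            )
            if not bad.any():
                break
            outs2[bad] = _draw_outcomes(cfg, int(bad.sum()), rng)
        else:
            raise ValueError("offer2_er_window incompatible with er_set")

    # matched trials: identical lottery, opposite informativeness
    outs2[matched] = outs1[matched]
    side = rng.integers(2, size=n)  # which offer is the informative one
    info1[matched] = side[matched]
    info2[matched] = 1 - side[matched]

    if cfg.task_version == "monkey_v2":
        pairs = enumerate_timing_pairs()
        t1 = pairs[rng.integers(len(pairs), size=n)]
        t2 = pairs[rng.integers(len(pairs), size=n)]
        t2[matched] = t1[matched]
    else:
        t1 = np.tile([0.5, 4.0], (n, 1))
        t2 = t1.copy()

    positions = np.array(["left", "right"])
    df = pd.DataFrame({"trial_id": np.arange(n), "session_id": cfg.session_id})
    for k, outs, info, t in ((1, outs1, info1, t1), (2, outs2, info2, t2)):
        for j in range(4):
            df[f"r_{k}_{j + 1}"] = outs[:, j] * cfg.r_step
        df[f"info_{k}"] = info.astype(int)
        df[f"t_cue_{k}"] = t[:, 0]
        df[f"t_rev_{k}"] = t[:, 1]
    df["pos_1"] = positions[rng.integers(2, size=n)]
    df["pos_2"] = np.where(df["pos_1"] == "left", "right", "left")
    df["choice"] = 0
    df["outcome"] = np.nan
    df["stim"] = "none"
    df["valid"] = True
    return df[list(TRIAL_COLUMNS)]


# ---------------------------------------------------------------------------
# choices and outcomes


def offer_values(
    trials: pd.DataFrame, params: BehavioralParams
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic subjective value of each offer under the generating model."""
    beta = np.asarray(params.beta)
    v1 = attribute_matrix(trials, params.spec, 1).to_numpy() @ beta
    v2 = attribute_matrix(trials, params.spec, 2).to_numpy() @ beta
    return v1, v2


def _draw_choices_outcomes(
    trials: pd.DataFrame,
    v1: np.ndarray,
    v2: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    out = trials.copy()
    p2 = expit(v2 - v1)
    choice = np.where(rng.random(len(out)) < p2, 2, 1)
    out["choice"] = choice
    bar = rng.integers(4, size=len(out))
    outs = np.stack(
        [
            out[[f"r_1_{j}" for j in (1, 2, 3, 4)]].to_numpy(),
            out[[f"r_2_{j}" for j in (1, 2, 3, 4)]].to_numpy(),
        ],
        axis=1,
    )  # (n, 2, 4)
    out["outcome"] = outs[np.arange(len(out)), choice - 1, bar]
    out["valid"] = True
    return out


def simulate_choices(
    trials: pd.DataFrame,
    params: BehavioralParams,
    rng: np.random.Generator,
    value_noise_sd: float = 0.0,
    return_value_noise: bool = False,
):
    """Draw logistic choices, P(choose 2) = logistic(V2 - V1), and outcomes.

    ``value_noise_sd`` adds trial-by-trial Gaussian noise to each offer's
    value before the logistic draw; the realized noise can be returned so
    simulated neurons may share it (choice coupling).
    """
    v1, v2 = offer_values(trials, params)
    n = len(trials)
    if value_noise_sd > 0:
        nu = rng.normal(0.0, value_noise_sd, size=(n, 2))
    else:
        nu = np.zeros((n, 2))
    out = _draw_choices_outcomes(trials, v1 + nu[:, 0], v2 + nu[:, 1], rng)
    if return_value_noise:
        return out, nu
    return out


def simulate_stimulation(
    trials: pd.DataFrame,
    params: BehavioralParams,
    rng: np.random.Generator,
    stim_prob: tuple[float, float] = (0.25, 0.25),
    value_subtraction: float = 1.0,
    value_noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Assign stimulation flags and draw choices with perturbed values.

    Stimulation of offer k subtracts ``value_subtraction`` log-odds from V_k
    before the logistic draw.
    """
    p1, p2 = stim_prob
    u = rng.random(len(trials))
    stim = np.where(u < p1, "stim1", np.where(u < p1 + p2, "stim2", "none"))
    out = trials.copy()
    out["stim"] = stim
    v1, v2 = offer_values(out, params)
    if value_noise_sd > 0:
        nu = rng.normal(0.0, value_noise_sd, size=(len(out), 2))
        v1, v2 = v1 + nu[:, 0], v2 + nu[:, 1]
    v1 = v1 - value_subtraction * (stim == "stim1")
    v2 = v2 - value_subtraction * (stim == "stim2")
    return _draw_choices_outcomes(out, v1, v2, rng)


# ---------------------------------------------------------------------------
# neurons


def _hypothesis_weights(
    scheme: CodingScheme, params: BehavioralParams, rng: np.random.Generator
) -> np.ndarray:
    beta = np.asarray(params.beta, dtype=float)
    m = len(beta)
    if scheme.hypothesis == "full_integration":
        return beta.copy()
    if scheme.hypothesis == "random_mixture":
        return rng.permutation(beta) * rng.choice([-1.0, 1.0], size=m)
    if scheme.hypothesis == "partial_integration":
        w = rng.permutation(beta) * rng.choice([-1.0, 1.0], size=m)
        keep = rng.permutation(m)[: m // 2]  # value-consistent half
        w[keep] = beta[keep]
        return w
    # single_attribute: unit weight on one (named or random) attribute
    attrs = list(params.spec.attributes)
    j = attrs.index(scheme.attribute) if scheme.attribute else rng.integers(m)
    w = np.zeros(m)
    w[j] = 1.0
    return w


def simulate_neuron(
    trials: pd.DataFrame,
    scheme: CodingScheme,
    params: BehavioralParams,
    rng: np.random.Generator,
    value_noise: np.ndarray | None = None,
    value_noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Per-trial windowed responses (normalized-rate units) of one neuron.

    Offer-window response: baseline + sign * gain * (w . x_k) + shared value
    noise (choice coupling) + independent noise.  Cue/reveal responses carry
    sign * rpe_gain * RPE in the window where information arrives (cue on
    informative trials, reveal otherwise).

    Returns columns rate_offer1, rate_offer2, rate_postcue, rate_postreveal.
    """
    n = len(trials)
    w = _hypothesis_weights(scheme, params, rng)
    if not (trials["choice"].isin((1, 2))).all():
        raise ValueError("simulate choices before simulating neurons")

    out = pd.DataFrame(index=trials.index)
    for k in (1, 2):
        c = scheme.coupling_for(k)
        if c > 0 and (value_noise is None or value_noise_sd <= 0):
            raise ValueError(
                "choice_coupling > 0 requires joint chooser simulation "
                "(pass value_noise and value_noise_sd)"
            )
        x = attribute_matrix(trials, params.spec, k).to_numpy()
        signal = scheme.sign * scheme.gain * (x @ w)
        shared = 0.0
        if c > 0:
            shared = scheme.sign * scheme.noise_sd * c * (
                value_noise[:, k - 1] / value_noise_sd
            )
        eps = rng.normal(0.0, scheme.noise_sd * np.sqrt(1 - c**2), size=n)
        out[f"rate_offer{k}"] = scheme.baseline + signal + shared + eps

    chosen = trials["choice"].to_numpy()
    e_chosen = np.where(
        chosen == 1,
        trials[[f"r_1_{j}" for j in (1, 2, 3, 4)]].mean(axis=1),
        trials[[f"r_2_{j}" for j in (1, 2, 3, 4)]].mean(axis=1),
    )
    rpe = trials["outcome"].to_numpy() - e_chosen
    info_chosen = np.where(
        chosen == 1, trials["info_1"].to_numpy(), trials["info_2"].to_numpy()
    ).astype(bool)
    rpe_signal = scheme.sign * scheme.rpe_gain * rpe
    out["rate_postcue"] = (
        scheme.baseline
        + np.where(info_chosen, rpe_signal, 0.0)
        + rng.normal(0.0, scheme.noise_sd, size=n)
    )
    out["rate_postreveal"] = (
        scheme.baseline
        + np.where(~info_chosen, rpe_signal, 0.0)
        + rng.normal(0.0, scheme.noise_sd, size=n)
    )
    return out


def simulate_population(
    cfg: SessionConfig,
    params: BehavioralParams,
    schemes: Mapping[str, CodingScheme],
    rng: np.random.Generator,
    value_noise_sd: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticGroundTruth]:
    """One session: offers, jointly simulated choices, and a neural table.

    Returns (trials, neural responses in long form, ground truth).
    """
    trials = generate_offers(cfg, rng)
    if cfg.stim_value_subtraction or any(cfg.stim_prob):
        trials = simulate_stimulation(
            trials, params, rng, cfg.stim_prob, cfg.stim_value_subtraction,
            value_noise_sd,
        )
        nu = None
        if any(s.coupling_for(1) > 0 or s.coupling_for(2) > 0
               for s in schemes.values()):
            raise ValueError("choice coupling with stimulation is not modeled")
    else:
        trials, nu = simulate_choices(
            trials, params, rng, value_noise_sd, return_value_noise=True
        )
    frames = []
    for name, scheme in schemes.items():
        resp = simulate_neuron(trials, scheme, params, rng, nu, value_noise_sd)
        resp.insert(0, "neuron_id", name)
        resp.insert(1, "trial_id", trials["trial_id"].to_numpy())
        frames.append(resp)
    neural = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=["neuron_id", "trial_id", "rate_offer1", "rate_offer2",
                     "rate_postcue", "rate_postreveal"]
        )
    )
    truth = SyntheticGroundTruth(
        behavior=params,
        schemes=dict(schemes),
        stim_value_subtraction=cfg.stim_value_subtraction,
        value_noise_sd=value_noise_sd,
    )
    return trials, neural, truth
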