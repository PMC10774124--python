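"""Encoding models of per-offer firing rates.

Each neuron's windowed responses to offer 1 and offer 2 are fitted
*separately* with an ordinary linear regression on the offer's attributes
(:class:`NeuronEncodingModel`), and with a one-regressor model whose single
attribute is the behaviorally estimated subjective value of the offer.
Shuffle-corrected R^2 (R^2 on the data minus the mean R^2 after permuting
the design rows) measures above-chance explained variance on a scale that is
comparable between models with different parameter counts; the value coding
index is the clamped ratio of the value model's to the attribute model's
shuffle-corrected R^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .task import ModelSpec, attribute_matrix, value_spec

__all__ = [
    "ConstantRateError",
    "NeuronEncodingModel",
    "NeuralFitResults",
    "ValueCodingResult",
    "PeristimulusEffect",
    "normalize_rates",
    "shuffle_corrected_r2",
    "classify_attribute_responsive",
    "value_coding_index",
    "crossval_effect_timecourse",
    "coding_hypothesis_index_distributions",
    "STRONG_VALUE_THRESHOLD",
]

#: value coding index above which a neuron counts as strongly value coding
STRONG_VALUE_THRESHOLD = 0.6

#: minimum attribute-model shuffle-corrected R^2 for the index to be defined
R2_GATE = 0.1


class ConstantRateError(ValueError):
    """A silent or constant neuron cannot be z-scored and is excluded."""


def normalize_rates(
    windows: pd.DataFrame, bin_rates: np.ndarray
) -> pd.DataFrame:
    """z-score window rates against the session-wide 500-ms bin rate vector."""
    bins = np.asarray(bin_rates, dtype=float)
    if bins.size == 0:
        raise ConstantRateError("empty session bin-rate vector")
    mu, sd = bins.mean(), bins.std()
    if sd == 0:
        raise ConstantRateError("constant firing rate; cannot z-score")
    return (windows - mu) / sd


@dataclass
class NeuralFitResults:
    """OLS fit of one neuron's responses to one offer."""

    spec: ModelSpec
    offer: int
    params: pd.Series  # includes 'const'
    bse: pd.Series
    pvalues: pd.Series
    rsquared: float
    nobs: int
    resid: np.ndarray = field(repr=False)

    def attribute_pvalues(self) -> pd.Series:
        return self.pvalues.drop("const")

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.params, "se": self.bse, "p": self.pvalues}
        ).assign(offer=self.offer, r2=self.rsquared, n=self.nobs)


class NeuronEncodingModel:
    """Linear attribute model of one neuron's windowed offer responses.

    Rate(offer i) = b_0 + b_1 x_i1 + ... + b_n x_in + noise, fitted by OLS
    with per-weight two-tailed p-values.  Offer 1 and offer 2 responses are
    independent fits.
    """

    def __init__(
        self,
        rates: np.ndarray,
        trials: pd.DataFrame,
        spec: ModelSpec,
        offer: int,
        values: np.ndarray | None = None,
        min_trials: int = 20,
    ):
        keep = trials["valid"].astype(bool).to_numpy()
        self.trials = trials.loc[keep]
        self.rates = np.asarray(rates, dtype=float)[keep]
        if len(self.rates) < min_trials:
            raise ValueError(f"fewer than {min_trials} valid trials")
        self.spec = spec
        self.offer = offer
        v = None if values is None else np.asarray(values)[keep]
        self.exog = attribute_matrix(self.trials, spec, offer, value=v)
        x = self.exog.to_numpy()
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(x)), x])) < x.shape[1] + 1:
            _, r = np.linalg.qr(x - x.mean(axis=0))
            bad = [self.exog.columns[i] for i in range(x.shape[1])
                   if abs(r[i, i]) < 1e-8 * max(1.0, abs(r[0, 0]))]
            raise ValueError(f"rank-deficient design; collinear attributes: {bad}")

    def fit(self) -> NeuralFitResults:
        x = sm.add_constant(self.exog, prepend=True)
        res = sm.OLS(self.rates, x).fit()
        return NeuralFitResults(
            spec=self.spec,
            offer=self.offer,
            params=res.params,
            bse=res.bse,
            pvalues=res.pvalues,
            rsquared=float(res.rsquared),
            nobs=int(res.nobs),
            resid=np.asarray(res.resid),
        )


def _r2_qr(y: np.ndarray, q: np.ndarray) -> float:
    """R^2 given the orthonormal basis q of [1, X] (intercept included)."""
    tss = float(y @ y - len(y) * y.mean() ** 2)
    if tss == 0:
        return 0.0
    proj = q.T @ y
    ess = float(proj @ proj - len(y) * y.mean() ** 2)
    return ess / tss


def shuffle_corrected_r2(
    rates: np.ndarray,
    x: np.ndarray | pd.DataFrame,
    n_shuffles: int = 100,
    rng: np.random.Generator | None = None,
) -> float:
    """R^2 of the fit minus the mean R^2 over row-shuffled designs.

    Permuting the attribute rows against the responses (equivalently,
    inversely permuting the responses) measures the variance the model
    explains by chance given its parameter count.
    """
    if rng is None:
        rng = np.random.default_rng()
    y = np.asarray(rates, dtype=float)
    x = np.asarray(x, dtype=float)
    z = np.column_stack([np.ones(len(y)), x])
    q, _ = np.linalg.qr(z)
    real = _r2_qr(y, q)
    shuf = [_r2_qr(y[rng.permutation(len(y))], q) for _ in range(n_shuffles)]
    return real - float(np.mean(shuf))


def classify_attribute_responsive(
    fit1: NeuralFitResults | None,
    fit2: NeuralFitResults | None,
    alpha: float = 0.05,
) -> bool:
    """True iff any attribute reaches p < alpha in either offer fit."""
    fits = [f for f in (fit1, fit2) if f is not None]
    if not fits:
        raise ValueError("no offer fits available")
    return any((f.attribute_pvalues() < alpha).any() for f in fits)


@dataclass
class ValueCodingResult:
    """Fraction of above-chance attribute variance explained by value.

    ``index`` is None (undefined, not 0) when the neuron fails the
    strong-attribute gate: attribute-responsive and attribute-model
    R^2_cor >= 0.1.
    """

    index: float | None
    strong_attribute: bool
    value_sign: int
    attr_r2cor: float
    value_r2cor: float
    per_offer: dict = field(default_factory=dict)


def value_coding_index(
    rates: Mapping[int, np.ndarray],
    trials: pd.DataFrame,
    spec: ModelSpec,
    behavior_values: pd.DataFrame,
    n_shuffles: int = 100,
    rng: np.random.Generator | None = None,
    r2_gate: float = R2_GATE,
    alpha: float = 0.05,
) -> ValueCodingResult:
    """Value coding index = clamp( R^2_cor(value model) / R^2_cor(attribute model) ).

    ``rates`` maps offer k to that offer's windowed responses;
    ``behavior_values`` carries the per-trial V1, V2 from the behavioral fit.
    Per-offer shuffle-corrected R^2 values are averaged across the two offers
    before the ratio is taken.  The index is undefined unless the neuron is
    attribute-responsive and the averaged attribute R^2_cor reaches the gate.
    """
    if rng is None:
        rng = np.random.default_rng()
    valid = trials["valid"].astype(bool).to_numpy()
    per_offer: dict[int, dict[str, float]] = {}
    fits = {}
    vw = 0.0
    for k, y in rates.items():
        v = behavior_values[f"V{k}"].to_numpy()
        m_attr = NeuronEncodingModel(y, trials, spec, k)
        m_val = NeuronEncodingModel(y, trials, value_spec(), k, values=v)
        fits[k] = m_attr.fit()
        fval = m_val.fit()
        vw += float(fval.params["Value"])
        r2a = shuffle_corrected_r2(m_attr.rates, m_attr.exog, n_shuffles, rng)
        r2v = shuffle_corrected_r2(m_val.rates, m_val.exog, n_shuffles, rng)
        per_offer[k] = {"attr_r2cor": r2a, "value_r2cor": r2v,
                        "value_weight": float(fval.params["Value"])}
    attr_r2 = float(np.mean([d["attr_r2cor"] for d in per_offer.values()]))
    val_r2 = float(np.mean([d["value_r2cor"] for d in per_offer.values()]))
    responsive = classify_attribute_responsive(
        fits.get(1), fits.get(2), alpha=alpha
    )
    strong = responsive and attr_r2 >= r2_gate
    index = None
    if strong:
        index = float(np.clip(val_r2 / attr_r2, 0.0, 1.0))
    sign = int(np.sign(vw)) if vw != 0 else 0
    return ValueCodingResult(
        index=index, strong_attribute=strong, value_sign=sign,
        attr_r2cor=attr_r2, value_r2cor=val_r2, per_offer=per_offer,
    )


# ---------------------------------------------------------------------------
# peristimulus cross-validated effects


@dataclass
class PeristimulusEffect:
    """Cross-validated, sign-normalized population effect over timepoints."""

    effect: str
    mean: np.ndarray
    se: np.ndarray
    n_responses: int


# attributes whose weights define significance/sign per effect
_EFFECT_TERMS = {
    "InfoxUnc": ("Info:Unc[r]",),
    "InfoxUncType": ("Info:Unc[r]",),
    "InfoxTime": ("Info:t_out", "Info:t_adv", "Info:t_adv:Unc[r]"),
}


def _contrast_trace(
    traces: np.ndarray, trials: pd.DataFrame, offer: int, effect: str,
    median_sd: float,
) -> np.ndarray | None:
    """Per-timepoint 2x2 interaction contrast for one neuron-offer response."""
    outs = trials[[f"r_{offer}_{j}" for j in (1, 2, 3, 4)]].to_numpy(float)
    info = trials[f"info_{offer}"].to_numpy() == 1
    sd = outs.std(axis=1)
    if effect == "InfoxUnc":
        hi, lo = sd > median_sd, ~(sd > median_sd)
    elif effect == "InfoxUncType":
        from .task import classify_distribution

        kinds = np.array([classify_distribution(r) for r in outs])
        hi, lo = kinds == "50_50", kinds == "25_50_25"
    else:
        raise ValueError(effect)
    cells = [info & hi, ~info & hi, info & lo, ~info & lo]
    if any(c.sum() == 0 for c in cells):
        return None
    m = [traces[c].mean(axis=0) for c in cells]
    return (m[0] - m[1]) - (m[2] - m[3])


def _net_time_effect(fit: NeuralFitResults, exog_sd: pd.Series) -> float:
    """Pooled Info-x-time effect: coefficient sum scaled by regressor SDs."""
    total = 0.0
    for term in _EFFECT_TERMS["InfoxTime"]:
        total += float(fit.params[term]) * float(exog_sd[term])
    return total


def _regression_trace(
    traces: np.ndarray, trials: pd.DataFrame, offer: int, spec: ModelSpec
) -> np.ndarray:
    """Per-timepoint pooled Info-x-time coefficient trace."""
    x = attribute_matrix(trials, spec, offer)
    z = np.column_stack([np.ones(len(x)), x.to_numpy()])
    coef, *_ = np.linalg.lstsq(z, traces, rcond=None)
    sds = x.std(axis=0)
    trace = np.zeros(traces.shape[1])
    for term in _EFFECT_TERMS["InfoxTime"]:
        j = list(x.columns).index(term) + 1
        trace += coef[j] * float(sds[term])
    return trace


def crossval_effect_timecourse(
    population: Sequence[Mapping],
    effect: str = "InfoxUnc",
    spec: ModelSpec | None = None,
    alpha: float = 0.05,
) -> PeristimulusEffect:
    """Population timecourse of an information effect, selection-bias free.

    Each population record needs ``trials`` (the session's trial table),
    ``traces`` (offer k -> (n_trials, T) rate array over timepoints) and
    ``fits`` (offer k -> main-window :class:`NeuralFitResults` containing the
    effect's terms).  Whether a neuron's offer-k trace is included, and the
    sign it contributes with, are decided solely from its offer-(3-k) fit:
    under the null of no true effect the selected, sign-normalized traces
    average to zero.
    """
    terms = _EFFECT_TERMS[effect]
    contributions: list[np.ndarray] = []
    for rec in population:
        trials = rec["trials"]
        valid = trials["valid"].astype(bool).to_numpy()
        t = trials.loc[valid]
        outs = np.concatenate(
            [t[[f"r_{k}_{j}" for j in (1, 2, 3, 4)]].to_numpy(float)
             for k in (1, 2)]
        )
        median_sd = float(np.median(outs.std(axis=1)))
        for k in (1, 2):
            other = rec["fits"].get(3 - k)
            if other is None or k not in rec["traces"]:
                continue
            pv = other.pvalues
            if not any(pv.get(term, 1.0) < alpha for term in terms):
                continue
            if effect == "InfoxTime":
                x_other = attribute_matrix(t, other.spec, 3 - k)
                signed = _net_time_effect(other, x_other.std(axis=0))
            else:
                signed = float(other.params[terms[0]])
            sign = 1.0 if signed >= 0 else -1.0
            traces = np.asarray(rec["traces"][k], dtype=float)[valid]
            if effect == "InfoxTime":
                sp = spec if spec is not None else other.spec
                trace = _regression_trace(traces, t, k, sp)
            else:
                trace = _contrast_trace(traces, t, k, effect, median_sd)
            if trace is None:
                continue
            contributions.append(sign * trace)
    if not contributions:
        warnings.warn(f"no responses passed cross-validated selection for {effect}")
        return PeristimulusEffect(effect, np.array([]), np.array([]), 0)
    arr = np.stack(contributions)
    return PeristimulusEffect(
        effect=effect,
        mean=arr.mean(axis=0),
        se=arr.std(axis=0, ddof=1) / np.sqrt(len(arr)) if len(arr) > 1
        else np.full(arr.shape[1], np.nan),
        n_responses=len(arr),
    )


# ---------------------------------------------------------------------------
# coding-hypothesis index distributions


def coding_hypothesis_index_distributions(
    trials: pd.DataFrame,
    behavior_values: pd.DataFrame,
    params,
    hypotheses: Sequence[str],
    n_neurons: int,
    rng: np.random.Generator,
    noise_sd: float = 1.0,
    gain: float = 1.0,
    spec: ModelSpec | None = None,
    n_shuffles: int = 50,
) -> dict[str, np.ndarray]:
    """Value-coding-index distribution under each coding hypothesis.

    Simulates ``n_neurons`` per hypothesis at matched gain and noise on the
    given session and returns the defined indexes per hypothesis.
    """
    from .simulate import CodingScheme, simulate_neuron

    if spec is None:
        spec = params.spec
    out: dict[str, np.ndarray] = {}
    for hyp in hypotheses:
        vals = []
        for i in range(n_neurons):
            scheme = CodingScheme(
                hypothesis=hyp, gain=gain, noise_sd=noise_sd,
                sign=int(rng.choice([-1, 1])),
            )
            resp = simulate_neuron(trials, scheme, params, rng)
            res = value_coding_index(
                {1: resp["rate_offer1"].to_numpy(),
                 2: resp["rate_offer2"].to_numpy()},
                trials, spec, behavior_values,
                n_shuffles=n_shuffles, rng=rng,
            )
            if res.index is not None:
                vals.append(res.index)
        out[hyp] = np.asarray(vals)
    return out
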