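"""Per-neuron functional indexes: choice prediction, RPE, and their overlap.

Three complementary measures of what a neuron codes:

* the *choice-predictive index*, the Spearman rank correlation between
  trial-wise behavioral residuals (choice minus the behavioral model's
  predicted choice probability) and neural residuals (normalized value
  signal minus the attribute model's prediction);
* the *RPE index*, the mean of two ROC-area differences contrasting
  positive- against negative-prediction-error activity in the window where
  the outcome information arrives (cue on informative trials, reveal on
  non-informative trials) versus the window where it does not;
* the *combined-coding overlap* permutation test, asking whether more
  neurons than chance jointly show strong value coding, significant choice
  prediction and significant RPE coding with identical signs.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import stats

from .neural import STRONG_VALUE_THRESHOLD, NeuronEncodingModel
from .task import ModelSpec

__all__ = [
    "roc_area",
    "normalized_value_signal",
    "choice_predictive_index",
    "ChoicePredictiveResult",
    "rpe_conditions",
    "rpe_index",
    "RpeIndexResult",
    "combined_coding_overlap",
    "overlap_difference",
    "OverlapResult",
]


def roc_area(x, y) -> float:
    """ROC area between two rate samples with half-credit tie handling.

    area = [ #(x_i > y_j) + 0.5 #(x_i = y_j) ] / (n_x n_y); 0.5 when the
    distributions are the same, > 0.5 when x generally exceeds y.  Computed
    from rank sums (Mann-Whitney U with average ranks), so identical samples
    give exactly 0.5 and roc_area(x, y) + roc_area(y, x) == 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    ranks = stats.rankdata(np.concatenate([x, y]))
    u = ranks[: x.size].sum() - x.size * (x.size + 1) / 2.0
    return float(u / (x.size * y.size))


def normalized_value_signal(rates: np.ndarray, value_sign: int) -> np.ndarray:
    """Sign-flip normalized rates so higher always means neurally higher value."""
    if value_sign == 0:
        raise ValueError("value weight is exactly 0; NVS undefined")
    return np.asarray(rates, dtype=float) * (1 if value_sign > 0 else -1)


@dataclass
class ChoicePredictiveResult:
    index: float
    pvalue: float
    offer: int
    nobs: int


def choice_predictive_index(
    rates: np.ndarray,
    trials: pd.DataFrame,
    offer: int,
    spec: ModelSpec,
    behavior_p2: np.ndarray,
    value_sign: int,
) -> ChoicePredictiveResult | None:
    """Rank correlation of behavioral and neural residuals for one offer.

    Behavioral residual: 1[offer chosen] - p(offer chosen) from the fitted
    choice model.  Neural residual: NVS minus the attribute model's
    prediction of NVS.  Returns None when either residual series is constant
    (index undefined, neuron skipped).
    """
    valid = trials["valid"].astype(bool).to_numpy()
    nvs = normalized_value_signal(np.asarray(rates), value_sign)
    model = NeuronEncodingModel(nvs, trials, spec, offer)
    fit = model.fit()
    d_neural = fit.resid
    chose_k = (trials.loc[valid, "choice"] == offer).astype(float).to_numpy()
    p_k = np.asarray(behavior_p2)[valid]
    if offer == 1:
        p_k = 1.0 - p_k
    d_behav = chose_k - p_k
    if np.ptp(d_behav) == 0 or np.ptp(d_neural) == 0:
        return None
    rho, p = stats.spearmanr(d_behav, d_neural)
    return ChoicePredictiveResult(float(rho), float(p), offer, int(valid.sum()))


# ---------------------------------------------------------------------------
# RPE index


def rpe_conditions(trials: pd.DataFrame, threshold: float = 0.1) -> pd.DataFrame:
    """Per-trial RPE (outcome minus chosen offer's E[r]) and condition label.

    Conditions cross chosen-offer informativeness with RPE sign; trials with
    |RPE| <= threshold (safe or near-zero prediction errors) are excluded.
    The 0.1 threshold matches juice volumes in ml; coin-unit data should
    pass a threshold with the same role.
    """
    t = trials.loc[trials["valid"].astype(bool)]
    chosen = t["choice"].to_numpy()
    e = np.where(
        chosen == 1,
        t[[f"r_1_{j}" for j in (1, 2, 3, 4)]].mean(axis=1),
        t[[f"r_2_{j}" for j in (1, 2, 3, 4)]].mean(axis=1),
    )
    rpe = t["outcome"].to_numpy() - e
    info = np.where(chosen == 1, t["info_1"], t["info_2"]).astype(bool)
    cond = np.where(
        rpe > threshold,
        np.where(info, "InfoPos", "NoinfoPos"),
        np.where(
            rpe < -threshold,
            np.where(info, "InfoNeg", "NoinfoNeg"),
            "excluded",
        ),
    )
    return pd.DataFrame({"rpe": rpe, "condition": cond}, index=t.index)


@dataclass
class RpeIndexResult:
    rpe_cue: float
    rpe_rev: float
    index: float
    p_cue: float
    p_rev: float
    pvalue: float  # Fisher combination of p_cue and p_rev
    n_cells: dict


def _roc_diff(pos_a, neg_a, pos_b, neg_b) -> float:
    return roc_area(pos_a, neg_a) - roc_area(pos_b, neg_b)


def _perm_p(
    obs: float,
    pos_a: np.ndarray,
    neg_a: np.ndarray,
    pos_b: np.ndarray,
    neg_b: np.ndarray,
    n_perms: int,
    rng: np.random.Generator,
) -> float:
    """Two-tailed permutation p: shuffle rates between the Info and Noinfo
    groups within each RPE sign, preserving cell sizes; add-one estimator."""
    pos_pool = np.concatenate([pos_a, pos_b])
    neg_pool = np.concatenate([neg_a, neg_b])
    na_pos, na_neg = len(pos_a), len(neg_a)
    hits = 0
    for _ in range(n_perms):
        pp = pos_pool[rng.permutation(len(pos_pool))]
        nn = neg_pool[rng.permutation(len(neg_pool))]
        a = _roc_diff(pp[:na_pos], nn[:na_neg], pp[na_pos:], nn[na_neg:])
        if abs(a) >= abs(obs) - 1e-12:
            hits += 1
    return (hits + 1) / (n_perms + 1)


def rpe_index(
    postcue: np.ndarray,
    postreveal: np.ndarray,
    conditions: pd.DataFrame,
    n_perms: int = 400,
    rng: np.random.Generator | None = None,
) -> RpeIndexResult | None:
    """RPE index = (RPE_cue + RPE_rev) / 2.

    RPE_cue = ROC(InfoPos, InfoNeg) - ROC(NoinfoPos, NoinfoNeg) on postcue
    rates; RPE_rev = ROC(NoinfoPos, NoinfoNeg) - ROC(InfoPos, InfoNeg) on
    postreveal rates.  Per-component permutation p-values shuffle rates
    between InfoPos and NoinfoPos and between InfoNeg and NoinfoNeg; the
    combined p uses Fisher's method (chi-square, 4 df).  Returns None if any
    condition cell is empty.
    """
    if rng is None:
        rng = np.random.default_rng()
    cond = conditions["condition"].to_numpy()
    cue = np.asarray(postcue, dtype=float)
    rev = np.asarray(postreveal, dtype=float)
    if len(cue) != len(cond) or len(rev) != len(cond):
        raise ValueError("rates must align with the condition table (valid trials)")
    cells = {c: cond == c for c in ("InfoPos", "InfoNeg", "NoinfoPos", "NoinfoNeg")}
    n_cells = {c: int(m.sum()) for c, m in cells.items()}
    if any(v == 0 for v in n_cells.values()):
        return None
    rc = _roc_diff(cue[cells["InfoPos"]], cue[cells["InfoNeg"]],
                   cue[cells["NoinfoPos"]], cue[cells["NoinfoNeg"]])
    rr = _roc_diff(rev[cells["NoinfoPos"]], rev[cells["NoinfoNeg"]],
                   rev[cells["InfoPos"]], rev[cells["InfoNeg"]])
    p_cue = _perm_p(
        rc, cue[cells["InfoPos"]], cue[cells["InfoNeg"]],
        cue[cells["NoinfoPos"]], cue[cells["NoinfoNeg"]], n_perms, rng,
    )
    p_rev = _perm_p(
        rr, rev[cells["NoinfoPos"]], rev[cells["NoinfoNeg"]],
        rev[cells["InfoPos"]], rev[cells["InfoNeg"]], n_perms, rng,
    )
    fisher = -2.0 * (np.log(p_cue) + np.log(p_rev))
    p = float(stats.chi2.sf(fisher, df=4))
    return RpeIndexResult(
        rpe_cue=float(rc), rpe_rev=float(rr), index=float((rc + rr) / 2),
        p_cue=float(p_cue), p_rev=float(p_rev), pvalue=p, n_cells=n_cells,
    )


# ---------------------------------------------------------------------------
# combined-coding overlap


@dataclass
class OverlapResult:
    n_neurons: int
    n_combined: int
    proportion: float
    pvalue: float
    n_perms: int
    flags: pd.DataFrame


def _codes(df: pd.DataFrame, value_threshold: float, alpha: float) -> pd.DataFrame:
    """Signed flag codes per property: 0 = not flagged, +-1 = flagged sign."""
    v = np.where(
        df["value_index"].fillna(-1).to_numpy() > value_threshold,
        df["value_sign"].to_numpy(), 0,
    )
    c = np.where(df["choice_p"].to_numpy() < alpha, df["choice_sign"].to_numpy(), 0)
    r = np.where(df["rpe_p"].to_numpy() < alpha, df["rpe_sign"].to_numpy(), 0)
    return pd.DataFrame(
        {"value": v.astype(np.int8), "choice": c.astype(np.int8),
         "rpe": r.astype(np.int8)}, index=df.index,
    )


def _combined_counts(v, c, r) -> np.ndarray:
    return np.sum((v != 0) & (v == c) & (v == r), axis=-1)


def combined_coding_overlap(
    population: pd.DataFrame,
    value_threshold: float = STRONG_VALUE_THRESHOLD,
    alpha: float = 0.05,
    n_perms: int = 200_000,
    rng: np.random.Generator | None = None,
) -> OverlapResult:
    """Permutation test for above-chance joint coding of all three properties.

    ``population`` needs per-neuron columns value_index, value_sign,
    choice_p, choice_sign, rpe_p, rpe_sign, with signs expressed on raw
    rates (a negative combined neuron has negative value weight, raw-rate
    choice residual correlation and raw-rate RPE index).  A neuron is
    combined coding if it is strongly value coding (index > threshold),
    significantly choice predictive, significantly RPE coding, and all three
    signs agree.  Each permutation independently shuffles each property's
    (flag, sign) pairs across neurons; p uses the add-one estimator.
    """
    if rng is None:
        rng = np.random.default_rng()
    if len(population) < 10:
        import warnings

        warnings.warn("fewer than 10 neurons; permutation p is unstable")
    codes = _codes(population, value_threshold, alpha)
    v = codes["value"].to_numpy()
    c = codes["choice"].to_numpy()
    r = codes["rpe"].to_numpy()
    observed = int(_combined_counts(v, c, r))
    n = len(v)
    vp = rng.permuted(np.broadcast_to(v, (n_perms, n)), axis=1)
    cp = rng.permuted(np.broadcast_to(c, (n_perms, n)), axis=1)
    rp = rng.permuted(np.broadcast_to(r, (n_perms, n)), axis=1)
    counts = _combined_counts(vp, cp, rp)
    p = (np.sum(counts >= observed) + 1) / (n_perms + 1)
    return OverlapResult(
        n_neurons=n, n_combined=observed,
        proportion=observed / n if n else 0.0,
        pvalue=float(p), n_perms=n_perms, flags=codes,
    )


def overlap_difference(
    pop_a: pd.DataFrame,
    pop_b: pd.DataFrame,
    value_threshold: float = STRONG_VALUE_THRESHOLD,
    alpha: float = 0.05,
    n_perms: int = 200_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation p for the combined-coding proportion of A exceeding B."""
    if rng is None:
        rng = np.random.default_rng()
    props = []
    counts = []
    for pop in (pop_a, pop_b):
        codes = _codes(pop, value_threshold, alpha)
        v, c, r = (codes[k].to_numpy() for k in ("value", "choice", "rpe"))
        n = len(v)
        props.append(int(_combined_counts(v, c, r)) / n)
        vp = rng.permuted(np.broadcast_to(v, (n_perms, n)), axis=1)
        cp = rng.permuted(np.broadcast_to(c, (n_perms, n)), axis=1)
        rp = rng.permuted(np.broadcast_to(r, (n_perms, n)), axis=1)
        counts.append(_combined_counts(vp, cp, rp) / n)
    observed = props[0] - props[1]
    null = counts[0] - counts[1]
    return float((np.sum(null >= observed) + 1) / (n_perms + 1))
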