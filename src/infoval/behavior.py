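"""Behavioral value models of multi-attribute information choice.

The central object is :class:`ChoiceModel`, a logistic value-difference GLM:

    log( p(choose 2) / p(choose 1) ) = V(offer 2) - V(offer 1)
    V(offer i) = beta_1 x_i1 + ... + beta_n x_in

fitted by maximum likelihood (no intercept: the model is antisymmetric under
relabeling the offers).  On top of it sit the analyses used to characterize
information seeking: psychometric willingness to pay, shuffle-corrected log
likelihoods for comparing models with different parameter counts,
the SD/range/entropy uncertainty-form comparison, cross-validated greedy
attribute selection, and the stimulation (V2 - V1)/Stim1/Stim2 model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import curve_fit
from scipy.special import expit

from .task import ModelSpec, attribute_matrix, stim_spec

__all__ = [
    "ChoiceModel",
    "ChoiceModelResults",
    "PsychometricModel",
    "PsychometricResults",
    "ModelComparisonResult",
    "RankDeficientError",
    "shuffle_corrected_loglik",
    "compare_uncertainty_forms",
    "select_attributes_cv",
    "fit_stimulation_model",
    "stimulation_psychometric",
]


class RankDeficientError(ValueError):
    """The attribute design is collinear; names the offending attributes."""


def _check_rank(dx: pd.DataFrame) -> None:
    x = dx.to_numpy()
    if np.linalg.matrix_rank(x) < x.shape[1]:
        # report the smallest trailing set of attributes that completes the
        # dependency, via QR column pivoting
        _, r = np.linalg.qr(x)
        bad = [dx.columns[i] for i in range(x.shape[1])
               if abs(r[i, i]) < 1e-8 * max(1.0, abs(r[0, 0]))]
        raise RankDeficientError(f"collinear attributes: {bad or list(dx.columns)}")


def _logit_irls(
    x: np.ndarray, y: np.ndarray, maxiter: int = 100, tol: float = 1e-8
) -> tuple[np.ndarray, float, bool]:
    """Newton/IRLS logistic fit used in shuffle and cross-validation loops.

    Returns (beta, log likelihood, converged).  A tiny ridge keeps the
    Hessian invertible; runaway steps (separation) flag non-convergence.
    """
    k = x.shape[1]
    beta = np.zeros(k)
    converged = False
    for _ in range(maxiter):
        p = expit(x @ beta)
        w = p * (1.0 - p)
        g = x.T @ (y - p)
        h = (x * w[:, None]).T @ x
        h[np.diag_indices(k)] += 1e-10
        try:
            step = np.linalg.solve(h, g)
        except np.linalg.LinAlgError:
            break
        beta += step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
        if np.max(np.abs(beta)) > 1e4:  # separation blow-up
            break
    p = np.clip(expit(x @ beta), 1e-12, 1 - 1e-12)
    llf = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    return beta, llf, converged


@dataclass
class ChoiceModelResults:
    """Fitted weights of a logistic value-difference model.

    Attributes mirror statsmodels results: ``params``, ``bse``, ``pvalues``
    (two-tailed Wald), ``cov_params``, ``llf``, ``nobs``, ``converged``.
    """

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    cov_params: pd.DataFrame
    llf: float
    nobs: int
    converged: bool

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.params, "se": self.bse, "p": self.pvalues}
        ).assign(model=self.spec.name, ll=self.llf, n=self.nobs)

    def subjective_values(
        self, trials: pd.DataFrame, values: tuple | None = None
    ) -> pd.DataFrame:
        """Per-trial V1, V2 and V2 - V1 in log-odds units."""
        beta = self.params.to_numpy()
        vals = {}
        for k in (1, 2):
            v = values[k - 1] if values is not None else None
            x = attribute_matrix(trials, self.spec, k, value=v).to_numpy()
            vals[f"V{k}"] = x @ beta
        out = pd.DataFrame(vals, index=trials.index)
        out["dV"] = out["V2"] - out["V1"]
        return out

    def predict(self, trials: pd.DataFrame, values: tuple | None = None) -> np.ndarray:
        """P(choose offer 2) per trial."""
        return expit(self.subjective_values(trials, values)["dV"].to_numpy())

    def to_reward_units(self, alpha: float = 0.05) -> pd.Series:
        """Rescale weights by the E[r] weight: log odds -> reward units.

        Only meaningful when the E[r] weight is significantly positive.
        """
        if "E[r]" not in self.params.index:
            raise ValueError("model has no E[r] attribute to scale by")
        b = self.params["E[r]"]
        if b <= 0 or self.pvalues["E[r]"] >= alpha:
            raise ValueError(
                "E[r] weight is not significantly positive; "
                "reward-unit conversion is meaningless"
            )
        return self.params / b


class ChoiceModel:
    """Logistic value-difference model of binary offer choice.

    Parameters
    ----------
    trials : trial table (only rows with ``valid`` are fitted)
    spec : the attribute model
    values : optional (V1, V2) arrays when the spec contains ``Value``
    """

    def __init__(
        self,
        trials: pd.DataFrame,
        spec: ModelSpec,
        values: tuple[np.ndarray, np.ndarray] | None = None,
    ):
        self.spec = spec
        keep = trials["valid"].astype(bool).to_numpy()
        self.trials = trials.loc[keep]
        if values is not None:
            values = (np.asarray(values[0])[keep], np.asarray(values[1])[keep])
        self._values = values
        x1 = attribute_matrix(
            self.trials, spec, 1, value=None if values is None else values[0]
        )
        x2 = attribute_matrix(
            self.trials, spec, 2, value=None if values is None else values[1]
        )
        self.exog = x2 - x1
        self.endog = (self.trials["choice"] == 2).astype(float).to_numpy()

    @classmethod
    def from_dataframe(cls, trials: pd.DataFrame, spec: ModelSpec, **kw) -> "ChoiceModel":
        return cls(trials, spec, **kw)

    def fit(self) -> ChoiceModelResults:
        y, dx = self.endog, self.exog
        if len(y) < 2 or y.min() == y.max():
            raise ValueError("need at least 2 valid trials with both choices")
        _check_rank(dx)
        converged = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(y, dx).fit(disp=0, maxiter=200)
                params = res.params
                bse = res.bse
                pvalues = res.pvalues
                cov = res.cov_params()
                llf = float(res.llf)
                converged = bool(res.mle_retvals.get("converged", False))
            except Exception:
                beta, llf, ok = _logit_irls(dx.to_numpy(), y)
                params = pd.Series(beta, index=dx.columns)
                bse = pd.Series(np.inf, index=dx.columns)
                pvalues = pd.Series(np.nan, index=dx.columns)
                cov = pd.DataFrame(np.nan, index=dx.columns, columns=dx.columns)
                converged = False
        if converged and (
            not np.all(np.isfinite(bse))
            or np.max(np.abs(params)) > 1e4
            or np.max(np.asarray(bse)) > 1e6
        ):
            converged = False  # (quasi-)separation: weights or their SEs ran away
        return ChoiceModelResults(
            spec=self.spec,
            params=pd.Series(np.asarray(params), index=dx.columns),
            bse=pd.Series(np.asarray(bse), index=dx.columns),
            pvalues=pd.Series(np.asarray(pvalues), index=dx.columns),
            cov_params=pd.DataFrame(
                np.asarray(cov), index=dx.columns, columns=dx.columns
            ),
            llf=llf,
            nobs=len(y),
            converged=converged,
        )


def fit_choice_glm(
    trials: pd.DataFrame, spec: ModelSpec, values: tuple | None = None
) -> ChoiceModelResults:
    """Convenience wrapper: ``ChoiceModel(trials, spec).fit()``."""
    return ChoiceModel(trials, spec, values=values).fit()


# ---------------------------------------------------------------------------
# shuffle-corrected log likelihood and model comparison


def _cv_loglik(
    x: np.ndarray, y: np.ndarray, k_folds: int, rng: np.random.Generator
) -> float:
    """Held-out log likelihood summed over k folds (fold split seeded)."""
    n = len(y)
    order = rng.permutation(n)
    folds = np.array_split(order, k_folds)
    ll = 0.0
    for test in folds:
        train = np.setdiff1d(order, test, assume_unique=False)
        beta, _, _ = _logit_irls(x[train], y[train])
        p = np.clip(expit(x[test] @ beta), 1e-12, 1 - 1e-12)
        ll += float(np.sum(y[test] * np.log(p) + (1 - y[test]) * np.log(1 - p)))
    return ll


def shuffle_corrected_loglik(
    trials: pd.DataFrame,
    spec: ModelSpec,
    n_shuffles: int = 100,
    rng: np.random.Generator | None = None,
    cv_folds: int | None = None,
    per_trial: bool = False,
) -> float:
    """LL of the fitted model minus its mean LL on choice-shuffled data.

    Permuting choices across valid trials and refitting measures how much
    likelihood the model gains by chance given its parameter count; the
    difference is comparable across models of different size.  With
    ``cv_folds`` both terms are cross-validated held-out likelihoods.
    Failed shuffle fits are redrawn (up to 5x the requested count).
    """
    if rng is None:
        rng = np.random.default_rng()
    model = ChoiceModel(trials, spec)
    x, y = model.exog.to_numpy(), model.endog
    if cv_folds:
        real = _cv_loglik(x, y, cv_folds, rng)
    else:
        beta, real, ok = _logit_irls(x, y)
        if not ok:
            raise ValueError("model did not converge on the real data")
    shuf = []
    attempts = 0
    while len(shuf) < n_shuffles:
        attempts += 1
        if attempts > 5 * n_shuffles:
            raise RuntimeError("too many failed shuffle fits")
        yp = rng.permutation(y)
        if cv_folds:
            shuf.append(_cv_loglik(x, yp, cv_folds, rng))
        else:
            _, ll, ok = _logit_irls(x, yp)
            if not ok:
                continue
            shuf.append(ll)
    corrected = real - float(np.mean(shuf))
    return corrected / len(y) if per_trial else corrected


@dataclass
class ModelComparisonResult:
    """Shuffle-corrected log likelihoods relative to a reference form."""

    reference: str
    table: pd.DataFrame  # index: form; columns: corrected_ll, rel_ll, ci_low, ci_high
    winner: str
    underpowered: bool = False

    def summary(self) -> pd.DataFrame:
        return self.table.assign(winner=self.table.index == self.winner)


def compare_uncertainty_forms(
    trials: pd.DataFrame,
    base_spec: ModelSpec | None = None,
    n_shuffles: int = 100,
    n_boot: int = 2000,
    rng: np.random.Generator | None = None,
    reference: str = "sd",
) -> ModelComparisonResult:
    """Compare SD / range / entropy / no-uncertainty choice models.

    The candidate models are identical except for how Unc[r] is measured.
    Corrected LL = LL(real) - mean LL(choice-shuffled).  Confidence intervals
    for each form's corrected LL relative to the reference come from a trial
    bootstrap of the per-trial likelihood difference between the two real
    fits (the shuffle-correction constants are model-level and added back).

    Only designs containing both 50/50 and 25/50/25 lotteries dissociate SD
    from range and entropy; otherwise the result is flagged underpowered.
    """
    from .task import classify_distribution, core_spec

    if rng is None:
        rng = np.random.default_rng()
    if base_spec is None:
        base_spec = core_spec()
    forms = ("sd", "range", "entropy", "none")

    kinds = set()
    for k in (1, 2):
        outs = trials[[f"r_{k}_{j}" for j in (1, 2, 3, 4)]].to_numpy()
        for row in outs[:200]:
            kinds.add(classify_distribution(row))
    underpowered = not {"50_50", "25_50_25"} <= kinds
    if underpowered:
        warnings.warn(
            "design lacks both 50/50 and 25/50/25 lotteries; the "
            "uncertainty-form comparison is underpowered"
        )

    corrected, lltrial = {}, {}
    for form in forms:
        spec = base_spec.with_form(form)
        model = ChoiceModel(trials, spec)
        x, y = model.exog.to_numpy(), model.endog
        beta, real, ok = _logit_irls(x, y)
        if not ok:
            raise ValueError(f"{form} model did not converge")
        p = np.clip(expit(x @ beta), 1e-12, 1 - 1e-12)
        lltrial[form] = y * np.log(p) + (1 - y) * np.log(1 - p)
        shuf = []
        while len(shuf) < n_shuffles:
            _, ll, ok = _logit_irls(x, rng.permutation(y))
            if ok:
                shuf.append(ll)
        corrected[form] = real - float(np.mean(shuf))

    n = len(lltrial[reference])
    rows = {}
    for form in forms:
        rel = corrected[form] - corrected[reference]
        d = lltrial[form] - lltrial[reference]
        shift = rel - d.sum()  # shuffle-correction constant
        boots = np.array(
            [d[rng.integers(n, size=n)].sum() for _ in range(n_boot)]
        ) + shift
        lo, hi = np.percentile(boots, [2.5, 97.5]) if form != reference else (0.0, 0.0)
        rows[form] = (corrected[form], rel, lo, hi)
    table = pd.DataFrame(
        rows, index=["corrected_ll", "rel_ll", "ci_low", "ci_high"]
    ).T
    winner = table["corrected_ll"].idxmax()
    return ModelComparisonResult(reference, table, winner, underpowered)


# ---------------------------------------------------------------------------
# psychometric willingness to pay


@dataclass
class PsychometricResults:
    """Logistic psychometric fit of info choice against E[r] difference."""

    intercept: float
    slope: float
    indifference: float
    wtp: float  # - indifference, in reward units
    wtp_se: float
    n_boot: int
    level: str
    nobs: int
    extrapolated: bool = False


def _lsq_logistic(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares logistic fit to a mean choice curve."""
    f = lambda x, a, b: expit(a + b * x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        (a, b), _ = curve_fit(f, x, y, p0=(0.0, 1.0), maxfev=10000)
    return float(a), float(b)


class PsychometricModel:
    """Choice of the informative offer as a function of the E[r] difference.

    Keeps only valid trials whose offers differ in informativeness;
    x = E[r](Info offer) - E[r](Noinfo offer), y = chose the Info offer.
    Willingness to pay is minus the 50% indifference point.

    ``level='individual'`` fits the single-trial data with a binomial GLM;
    ``level='population'`` fits the across-individual mean curve by least
    squares (individuals keyed by ``session_id``) and bootstraps over
    individuals.
    """

    def __init__(self, trials: pd.DataFrame, level: str = "individual"):
        if level not in ("individual", "population"):
            raise ValueError("level must be 'individual' or 'population'")
        self.level = level
        t = trials.loc[
            trials["valid"].astype(bool) & (trials["info_1"] != trials["info_2"])
        ]
        if len(t) == 0:
            raise ValueError("no trials with offers differing in informativeness")
        e1 = t[[f"r_1_{j}" for j in (1, 2, 3, 4)]].mean(axis=1).to_numpy()
        e2 = t[[f"r_2_{j}" for j in (1, 2, 3, 4)]].mean(axis=1).to_numpy()
        info_is_2 = (t["info_2"] == 1).to_numpy()
        self.x = np.where(info_is_2, e2 - e1, e1 - e2)
        chose2 = (t["choice"] == 2).to_numpy()
        self.y = np.where(info_is_2, chose2, ~chose2).astype(float)
        self.groups = t["session_id"].to_numpy()

    def _fit_individual(self, x, y) -> tuple[float, float]:
        ex = sm.add_constant(x)
        res = sm.Logit(y, ex).fit(disp=0, maxiter=200)
        return float(res.params[0]), float(res.params[1])

    def _mean_curve(self, groups_subset=None):
        df = pd.DataFrame({"x": self.x, "y": self.y, "g": self.groups})
        if groups_subset is not None:
            parts = [df[df["g"] == g] for g in groups_subset]
            df = pd.concat(parts)
        per = df.groupby(["g", "x"])["y"].mean().reset_index()
        curve = per.groupby("x")["y"].mean()
        return curve.index.to_numpy(), curve.to_numpy()

    def fit(
        self, n_boot: int = 200, rng: np.random.Generator | None = None
    ) -> PsychometricResults:
        if rng is None:
            rng = np.random.default_rng()
        if self.level == "individual":
            a, b = self._fit_individual(self.x, self.y)
        else:
            xs, ys = self._mean_curve()
            a, b = _lsq_logistic(xs, ys)
        indiff = -a / b
        wtp = -indiff
        boots = []
        n = len(self.y)
        uniq = np.unique(self.groups)
        for _ in range(n_boot):
            try:
                if self.level == "individual":
                    idx = rng.integers(n, size=n)
                    ab, bb = self._fit_individual(self.x[idx], self.y[idx])
                else:
                    gs = uniq[rng.integers(len(uniq), size=len(uniq))]
                    xs, ys = self._mean_curve(gs)
                    ab, bb = _lsq_logistic(xs, ys)
                boots.append(ab / bb)
            except Exception:
                continue
        se = float(np.std(boots)) if boots else float("nan")
        extrapolated = b <= 0 or abs(indiff) > np.max(np.abs(self.x))
        if extrapolated:
            warnings.warn("psychometric indifference point is extrapolated")
        return PsychometricResults(
            intercept=a, slope=b, indifference=float(indiff), wtp=float(wtp),
            wtp_se=se, n_boot=len(boots), level=self.level, nobs=n,
            extrapolated=extrapolated,
        )


def psychometric_wtp(
    trials: pd.DataFrame,
    level: str = "individual",
    n_boot: int = 200,
    rng: np.random.Generator | None = None,
) -> PsychometricResults:
    """Convenience wrapper: ``PsychometricModel(trials, level).fit(...)``."""
    return PsychometricModel(trials, level).fit(n_boot=n_boot, rng=rng)


# ---------------------------------------------------------------------------
# attribute selection


def select_attributes_cv(
    trials: pd.DataFrame,
    candidates: Sequence[str],
    coverage: float = 0.99,
    k_folds: int = 5,
    rng: np.random.Generator | None = None,
    form: str = "sd",
) -> list[str]:
    """Greedy forward selection on held-out log likelihood.

    Attributes are added until the selected model reaches ``coverage`` of
    the full candidate model's above-chance cross-validated log likelihood.
    Ties break in candidate-list order.  An at-chance full model selects
    nothing (with a warning).
    """
    if rng is None:
        rng = np.random.default_rng()
    spec_full = ModelSpec("cv-full", tuple(candidates), form)
    model = ChoiceModel(trials, spec_full)
    x_full, y = model.exog.to_numpy(), model.endog
    chance = len(y) * np.log(0.5)
    # one fold split shared by every candidate model so scores are comparable
    n = len(y)
    order = rng.permutation(n)
    folds = np.array_split(order, k_folds)

    def cvll(cols: list[int]) -> float:
        ll = 0.0
        xs = x_full[:, cols]
        for test in folds:
            train = np.setdiff1d(order, test)
            beta, _, _ = _logit_irls(xs[train], y[train])
            p = np.clip(expit(xs[test] @ beta), 1e-12, 1 - 1e-12)
            ll += float(np.sum(y[test] * np.log(p) + (1 - y[test]) * np.log(1 - p)))
        return ll

    above_full = cvll(list(range(x_full.shape[1]))) - chance
    if above_full <= 0:
        warnings.warn("full model is at chance; selecting no attributes")
        return []
    selected: list[int] = []
    remaining = list(range(len(candidates)))
    current = chance
    while remaining:
        scores = [cvll(selected + [j]) for j in remaining]
        best = int(np.argmax(scores))  # first max wins: candidate-order ties
        selected.append(remaining.pop(best))
        current = scores[best]
        if current - chance >= coverage * above_full:
            break
    return [candidates[j] for j in selected]


# ---------------------------------------------------------------------------
# stimulation


def fit_stimulation_model(
    trials: pd.DataFrame,
    values: pd.DataFrame,
    by_session: bool = False,
):
    """Fit choice = logistic( b_v (V2 - V1) + b_s1 Stim1 + b_s2 Stim2 ).

    ``values`` must carry per-trial V1 and V2 estimated from a model fitted
    only on no-stimulation trials, then evaluated on all trials.  The stim
    regressors code the stimulated offer as -1 so that a positive fitted
    weight always means a reduced log odds of choosing the stimulated offer.
    """
    if not (trials["stim"] != "none").any():
        raise ValueError("no stimulation trials present")
    if by_session:
        out = {}
        for sid, sub in trials.groupby("session_id"):
            out[sid] = fit_stimulation_model(sub, values.loc[sub.index])
        return out
    v1 = values["V1"].to_numpy()
    v2 = values["V2"].to_numpy()
    return ChoiceModel(trials, stim_spec(), values=(v1, v2)).fit()


def stimulation_psychometric(
    trials: pd.DataFrame, values: pd.DataFrame
) -> pd.DataFrame:
    """Indifference points of choose-offer-2 psychometrics by stim condition.

    For each of no-stim / stim1 / stim2 trials, fits a logistic of choosing
    offer 2 on the estimated value difference (V2 - V1) and reports the
    intercept, slope and indifference point; stimulation that devalues the
    stimulated offer shifts the stim1 indifference negative and the stim2
    indifference positive.
    """
    dv = (values["V2"] - values["V1"]).to_numpy()
    y = (trials["choice"] == 2).astype(float).to_numpy()
    stim = trials["stim"].to_numpy()
    rows = {}
    for cond in ("none", "stim1", "stim2"):
        m = stim == cond
        if m.sum() < 10:
            continue
        res = sm.Logit(y[m], sm.add_constant(dv[m])).fit(disp=0)
        a, b = float(res.params[0]), float(res.params[1])
        rows[cond] = {"intercept": a, "slope": b, "indifference": -a / b,
                      "n": int(m.sum())}
    return pd.DataFrame(rows).T
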