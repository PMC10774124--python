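"""End-to-end pipeline: simulate -> fit behavior -> fit neurons -> indexes.

Each stage writes plain-text artifacts into the run directory and is skipped
when its outputs already exist (resumable); a manifest records the config
hash and per-file checksums so identical seeds reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, indexes, neural, simulate
from .io import RunConfig, read_trials, substream, write_neural, write_trials
from .task import get_spec

__all__ = ["run_pipeline", "RunManifest", "default_behavior"]

log = logging.getLogger("infoval")

#: generating weights (log-odds per attribute unit) judged realistic for each
#: task version; E[r] weights are per ml (monkey) or per coin (human)
DEFAULT_BETAS = {
    "core|ml": {"E[r]": 10.0, "Unc[r]": 3.0, "Info": 0.1,
                "Info:E[r]": 0.2, "Info:Unc[r]": 8.0},
    "core|coins": {"E[r]": 0.8, "Unc[r]": -0.05, "Info": 0.5,
                   "Info:E[r]": 0.02, "Info:Unc[r]": 0.15},
    "timing10|ml": {"E[r]": 8.0, "Unc[r]": 2.0, "Info": 0.2,
                    "Info:E[r]": 0.3, "Info:Unc[r]": 2.0,
                    "t_out": -0.25, "t_out:E[r]": -0.5,
                    "Info:t_out": -0.05, "Info:t_adv": 0.12,
                    "Info:t_adv:Unc[r]": 0.8},
    "human-timing|coins": {"E[r]": 0.8, "EarlyInfo": 0.4},
}


def default_behavior(
    spec_name: str, units: str = "ml", form: str = "sd"
) -> simulate.BehavioralParams:
    """Default generating chooser for a registered spec and unit system."""
    spec = get_spec(spec_name, form)
    key = f"{spec_name.split('|')[0]}|{units}"
    if key not in DEFAULT_BETAS:
        raise KeyError(f"no default weights for {key}")
    table = DEFAULT_BETAS[key]
    beta = tuple(table[a] for a in spec.attributes if a in table)
    attrs = tuple(a for a in spec.attributes if a in table)
    return simulate.BehavioralParams(
        spec=spec.__class__(spec.name, attrs, spec.uncertainty_form), beta=beta
    )


@dataclass
class RunManifest:
    config_hash: str
    package_version: str
    checksums: dict = field(default_factory=dict)
    timestamps: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _session_config(cfg: RunConfig) -> simulate.SessionConfig:
    factory = {
        "monkey_v1": simulate.SessionConfig.monkey_v1,
        "monkey_v2": simulate.SessionConfig.monkey_v2,
        "human_coins": simulate.SessionConfig.human_coins,
        "human_timing": simulate.SessionConfig.human_timing,
    }[cfg.task_version]
    return factory(
        n_trials=cfg.n_trials,
        stim_prob=tuple(cfg.stim_prob),
        stim_value_subtraction=cfg.stim_value_subtraction,
    )


def _params(cfg: RunConfig) -> simulate.BehavioralParams:
    spec = get_spec(cfg.spec, cfg.uncertainty_form)
    if cfg.beta:
        return simulate.BehavioralParams(spec=spec, beta=tuple(cfg.beta))
    return default_behavior(cfg.spec, cfg.units, cfg.uncertainty_form)


def run_pipeline(cfg: RunConfig, force: bool = False) -> RunManifest:
    """Execute every stage; returns the manifest (also written to disk)."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    version = _package_version()
    cfg_hash = hashlib.sha256(
        json.dumps(asdict(cfg), sort_keys=True).encode()
    ).hexdigest()
    manifest = RunManifest(config_hash=cfg_hash, package_version=version)
    params = _params(cfg)

    def done(stage: str, *paths: Path):
        for p in paths:
            manifest.checksums[p.name] = _sha(p)
        manifest.timestamps[stage] = time.time()
        log.info("stage %s complete", stage)

    # --- simulate ------------------------------------------------------
    trials_path = out / "trials.csv"
    neural_path = out / "neural.csv"
    truth_path = out / "truth.json"
    if force or not trials_path.exists():
        rng = substream(cfg.seed, "simulate")
        schemes = {}
        hyps = list(simulate.HYPOTHESES)
        for i in range(cfg.n_neurons):
            schemes[f"n{i:03d}"] = simulate.CodingScheme(
                hypothesis=hyps[i % len(hyps)],
                gain=cfg.gain,
                sign=int(rng.choice([-1, 1])),
                noise_sd=cfg.noise_sd,
                choice_coupling=cfg.choice_coupling,
                rpe_gain=cfg.rpe_gain,
            )
        trials, neural_df, truth = simulate.simulate_population(
            _session_config(cfg), params, schemes, rng,
            value_noise_sd=cfg.value_noise_sd,
        )
        write_trials(trials, trials_path, units=cfg.units)
        write_neural(neural_df, neural_path)
        truth.seed = cfg.seed
        truth_path.write_text(truth.to_json())
    done("simulate", trials_path, neural_path, truth_path)

    trials, _units = read_trials(trials_path)
    neural_df = pd.read_csv(neural_path)

    # --- fit behavior --------------------------------------------------
    behav_path = out / "behavior_fit.json"
    no_stim = trials.loc[trials["stim"] == "none"]
    fit = behavior.ChoiceModel(no_stim, params.spec).fit()
    if force or not behav_path.exists():
        behav_path.write_text(json.dumps({
            "spec": params.spec.name,
            "attributes": list(params.spec.attributes),
            "coef": fit.params.tolist(),
            "se": fit.bse.tolist(),
            "p": fit.pvalues.tolist(),
            "cov": fit.cov_params.to_numpy().tolist(),
            "ll": fit.llf,
            "n": fit.nobs,
            "converged": fit.converged,
        }, indent=2))
    done("fit-behavior", behav_path)
    values = fit.subjective_values(trials)

    # --- fit neurons -----------------------------------------------------
    neurons_path = out / "neurons.csv"
    index_rows = []
    rng_n = substream(cfg.seed, "fit-neurons")
    rng_i = substream(cfg.seed, "indexes")
    p2 = fit.predict(trials)
    cond = indexes.rpe_conditions(trials, threshold=cfg.rpe_threshold)
    excluded = {"gated": 0, "cp_undefined": 0, "rpe_undefined": 0}
    for nid, resp in neural_df.groupby("neuron_id", sort=True):
        resp = resp.set_index("trial_id").loc[trials["trial_id"]]
        rates = {k: resp[f"rate_offer{k}"].to_numpy() for k in (1, 2)}
        vc = neural.value_coding_index(
            rates, trials, params.spec, values,
            n_shuffles=cfg.n_shuffles, rng=rng_n,
        )
        row = {
            "neuron_id": nid,
            "value_index": vc.index,
            "value_sign": vc.value_sign,
            "attr_r2cor": vc.attr_r2cor,
            "value_r2cor": vc.value_r2cor,
        }
        if vc.index is None:
            excluded["gated"] += 1
        cps = []
        for k in (1, 2):
            if vc.value_sign == 0:
                break
            cp = indexes.choice_predictive_index(
                rates[k], trials, k, params.spec, p2, vc.value_sign
            )
            if cp is not None:
                cps.append(cp)
        if cps:
            best = min(cps, key=lambda c: c.pvalue)
            row["choice_index"] = float(np.mean([c.index for c in cps]))
            row["choice_p"] = best.pvalue
            # sign on raw rates: undo the NVS flip
            row["choice_sign"] = int(np.sign(best.index) * vc.value_sign) or 0
        else:
            excluded["cp_undefined"] += 1
            row["choice_index"] = np.nan
            row["choice_p"] = np.nan
            row["choice_sign"] = 0
        valid = trials["valid"].astype(bool).to_numpy()
        rpe = indexes.rpe_index(
            resp["rate_postcue"].to_numpy()[valid],
            resp["rate_postreveal"].to_numpy()[valid],
            cond, n_perms=cfg.n_perms_rpe, rng=rng_i,
        )
        if rpe is None:
            excluded["rpe_undefined"] += 1
            row.update(rpe_index=np.nan, rpe_p=np.nan, rpe_sign=0)
        else:
            row.update(
                rpe_index=rpe.index, rpe_p=rpe.pvalue,
                rpe_sign=int(np.sign(rpe.index)) or 0,
            )
        index_rows.append(row)
    table = pd.DataFrame(index_rows)
    table.to_csv(neurons_path, index=False)
    log.info("exclusions: %s", excluded)
    done("fit-neurons", neurons_path)

    # --- overlap ---------------------------------------------------------
    overlap_path = out / "overlap.json"
    usable = table.dropna(subset=["choice_p", "rpe_p"])
    ov = indexes.combined_coding_overlap(
        usable, n_perms=cfg.n_perms_overlap, rng=substream(cfg.seed, "overlap")
    )
    overlap_path.write_text(json.dumps({
        "n_neurons": ov.n_neurons, "n_combined": ov.n_combined,
        "proportion": ov.proportion, "p": ov.pvalue, "n_perms": ov.n_perms,
        "exclusions": excluded,
    }, indent=2))
    done("indexes", overlap_path)

    # --- stimulation -----------------------------------------------------
    if (trials["stim"] != "none").any():
        stim_path = out / "stim_fit.json"
        sfit = behavior.fit_stimulation_model(trials, values)
        stim_path.write_text(json.dumps({
            "coef": sfit.params.tolist(), "se": sfit.bse.tolist(),
            "p": sfit.pvalues.tolist(), "attributes": list(sfit.params.index),
            "n": sfit.nobs,
        }, indent=2))
        done("stim-fit", stim_path)

    # --- report ----------------------------------------------------------
    report_path = out / "report.json"
    defined = table["value_index"].dropna()
    report = {
        "n_trials": int(len(trials)),
        "n_valid": int(trials["valid"].sum()),
        "n_neurons": int(table.shape[0]),
        "behavior_converged": fit.converged,
        "mean_value_index": float(defined.mean()) if len(defined) else None,
        "combined_proportion": ov.proportion,
        "combined_p": ov.pvalue,
    }
    report_path.write_text(json.dumps(report, indent=2))
    done("report", report_path)

    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def _package_version() -> str:
    try:
        from importlib.metadata import version

        return version("infoval")
    except Exception:  # pragma: no cover
        return "unknown"
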