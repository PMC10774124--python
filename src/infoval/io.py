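"""Readers and writers for the trial and neural-response tables.

Delimited text (CSV) is the canonical interchange format: a trial table has
one row per trial with both offers' lotteries, informativeness flags and
timing, plus choice, outcome, stimulation flag and validity.  Reward units
(ml vs coins) are declared once in a ``# units=...`` header line, never
inferred.  On load, rows whose outcome is not one of the chosen offer's four
outcomes are flagged invalid (not dropped) and the exclusion is logged.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .task import TRIAL_COLUMNS

__all__ = [
    "read_trials",
    "write_trials",
    "read_neural",
    "write_neural",
    "RunConfig",
    "substream",
]

log = logging.getLogger("infoval")

NEURAL_COLUMNS = (
    "neuron_id", "trial_id", "rate_offer1", "rate_offer2",
    "rate_postcue", "rate_postreveal",
)


def write_trials(trials: pd.DataFrame, path, units: str = "ml") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# units={units}\n")
        trials.to_csv(fh, index=False)


def read_trials(path) -> tuple[pd.DataFrame, str]:
    """Load a trial table; returns (table, units).

    Missing schema columns raise a KeyError naming them.  Rows whose outcome
    does not match any outcome of the chosen offer are marked invalid with a
    logged count.
    """
    path = Path(path)
    units = "ml"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            if "units=" in first:
                units = first.split("units=")[1].strip()
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise KeyError(f"trial table missing columns: {missing}")
    df["valid"] = df["valid"].astype(bool)
    chosen_ok = np.zeros(len(df), dtype=bool)
    decided = df["choice"].isin((1, 2)).to_numpy()
    for k in (1, 2):
        outs = df[[f"r_{k}_{j}" for j in (1, 2, 3, 4)]].to_numpy(float)
        match = np.isclose(
            outs, df["outcome"].to_numpy(float)[:, None], rtol=0, atol=1e-9
        ).any(axis=1)
        chosen_ok |= (df["choice"].to_numpy() == k) & match
    bad = decided & df["valid"].to_numpy() & ~chosen_ok
    if bad.any():
        log.warning(
            "%d rows flagged invalid: outcome not in the chosen offer's "
            "outcome set", int(bad.sum()),
        )
        df.loc[bad, "valid"] = False
    return df, units


def write_neural(neural: pd.DataFrame, path) -> None:
    neural.to_csv(path, index=False)


def read_neural(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in NEURAL_COLUMNS if c not in df.columns]
    if missing:
        raise KeyError(f"neural table missing columns: {missing}")
    return df


@dataclass
class RunConfig:
    """Configuration of a full pipeline run; round-trips via YAML.

    Every stochastic stage derives its generator from ``seed`` plus a stage
    label (see :func:`substream`); no stage reads the wall clock.
    """

    seed: int = 0
    outdir: str = "runs/demo"
    task_version: str = "monkey_v2"
    units: str = "ml"
    n_trials: int = 2000
    n_neurons: int = 60
    spec: str = "timing10"
    uncertainty_form: str = "sd"
    beta: list = field(default_factory=list)  # generating weights; [] = defaults
    noise_sd: float = 1.0
    gain: float = 1.0
    value_noise_sd: float = 1.0
    choice_coupling: float = 0.3
    rpe_gain: float = 1.0
    stim_prob: list = field(default_factory=lambda: [0.0, 0.0])
    stim_value_subtraction: float = 0.0
    n_shuffles: int = 50
    n_boot: int = 200
    n_perms_rpe: int = 200
    n_perms_overlap: int = 10000
    rpe_threshold: float = 0.1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def substream(seed: int, label: str) -> np.random.Generator:
    """A named, reproducible random stream derived from the run seed."""
    import zlib

    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode())])
    )
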