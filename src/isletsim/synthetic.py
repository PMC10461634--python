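"""Synthetic secretion datasets for testing the fitting machinery.

Real secretion time courses must be supplied by the user; these
generators produce datasets with the same shape and statistical
character as typical islet perifusion / batch assays by running the
simulator at known ("ground truth") parameters and adding measurement
noise.  Noise is multiplicative Gaussian by default -- immunoassay
error scales with the signal -- with an optional additive floor.
Ground truth is written to a sidecar JSON so recovery tests never
parse it out of the data file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .chamber import Protocol, simulate, total_secretion
from .parameters import BasalState, ModelParameters
from .scenarios import glucose_step_run

__all__ = ["NoiseModel", "generate_perifusion_dataset", "generate_batch_dataset"]


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise: value * (1 + N(0, mult_sd)) + N(0, add_sd), clipped at 0."""

    multiplicative_sd: float = 0.05
    additive_sd: float = 0.0  # pg/min
    seed: int = 0

    def __post_init__(self) -> None:
        if self.multiplicative_sd < 0 or self.additive_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        noisy = values * (1.0 + rng.normal(0.0, self.multiplicative_sd, values.shape))
        noisy = noisy + rng.normal(0.0, self.additive_sd, values.shape)
        return np.maximum(noisy, 0.0)


def _write(df: pd.DataFrame, truth: dict, path: str | Path | None):
    if path is not None:
        path = Path(path)
        df.to_csv(path, index=False, float_format="%.10g")
        path.with_suffix(".truth.json").write_text(json.dumps(truth, indent=1))


def generate_perifusion_dataset(
    p: ModelParameters | None = None,
    glucose_levels: Iterable[float] = (6.0, 9.0, 12.0, 15.0, 30.0),
    n_islets: float = 15.0,
    noise: NoiseModel | None = None,
    *,
    baseline_glucose: float = 3.0,
    step_time: float = 8.0,
    duration: float = 60.0,
    sample_dt: float = 2.0,
    flow: float = 1.0,
    volume: float = 1.0,
    basal: BasalState | None = None,
    path: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Perifusion time-series dataset: one condition per glucose step.

    Each condition holds ``baseline_glucose`` until ``step_time`` and
    then steps the chamber glucose to the test level (islets start at
    their baseline steady state), sampling whole-chamber insulin and
    glucagon fluxes every ``sample_dt`` minutes.  The stored protocols
    fully describe each experiment, so fitting them back needs no
    extra context.  Returns the tidy dataset and a ground-truth dict
    (parameters, protocols, noise settings); with ``path`` both are
    written (CSV + sidecar ``.truth.json``).
    """
    p = ModelParameters() if p is None else p
    noise = NoiseModel(multiplicative_sd=0.0) if noise is None else noise
    basal = BasalState() if basal is None else basal
    rng = np.random.default_rng(noise.seed)
    t_sample = np.arange(sample_dt, duration + sample_dt / 2, sample_dt)
    frames = []
    protocols = {}
    for g in glucose_levels:
        cond = f"step_{g:g}mM"
        proto = Protocol(
            mode="perifusion",
            volume=volume,
            flow=flow,
            n_islets=n_islets,
            duration=duration,
            glucose_steps=((0.0, baseline_glucose), (step_time, g)),
            basal=basal,
        )
        protocols[cond] = proto.to_dict()
        res = simulate(proto, p)
        r_I = noise.apply(np.interp(t_sample, res.time, res.r_I), rng)
        r_G = noise.apply(np.interp(t_sample, res.time, res.r_G), rng)
        frames.append(
            pd.DataFrame(
                {
                    "condition_id": cond,
                    "time_min": t_sample,
                    "insulin_pg_per_min": r_I,
                    "glucagon_pg_per_min": r_G,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    truth = {
        "kind": "perifusion",
        "parameters": p.to_dict(),
        "protocols": protocols,
        "baseline_glucose_mM": baseline_glucose,
        "step_time_min": step_time,
        "noise": {
            "multiplicative_sd": noise.multiplicative_sd,
            "additive_sd": noise.additive_sd,
            "seed": noise.seed,
        },
    }
    _write(df, truth, path)
    return df, truth


def generate_batch_dataset(
    p: ModelParameters | None = None,
    glucose_levels: Iterable[float] = (1, 4, 7, 10, 15, 20, 30),
    n_islets: float = 10.0,
    duration: float = 60.0,
    noise: NoiseModel | None = None,
    *,
    baseline_glucose: float = 1.0,
    volume: float = 1.0,
    basal: BasalState | None = None,
    path: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Batch dataset: total 1-h secretion per glucose level.

    Emulates static incubation assays (~10 islets in 1 mL): glucose is
    stepped from the baseline to each level at t = 0 and the secreted
    hormone totals over the incubation are reported.
    """
    p = ModelParameters() if p is None else p
    noise = NoiseModel(multiplicative_sd=0.0) if noise is None else noise
    basal = BasalState() if basal is None else basal
    rng = np.random.default_rng(noise.seed)
    rows = []
    protocols = {}
    for g in glucose_levels:
        cond = f"batch_{g:g}mM"
        proto = Protocol(
            mode="batch",
            volume=volume,
            flow=0.0,
            n_islets=n_islets,
            duration=duration,
            glucose_steps=((0.0, g),),
            basal=basal,
        )
        protocols[cond] = proto.to_dict()
        res = glucose_step_run(p, proto, baseline_glucose, g)
        tot = total_secretion(res)
        vals = noise.apply(np.array([tot["insulin"], tot["glucagon"]]), rng)
        rows.append(
            {
                "condition_id": cond,
                "glucose_mM": g,
                "insulin_total_pg": vals[0],
                "glucagon_total_pg": vals[1],
            }
        )
    df = pd.DataFrame(rows)
    truth = {
        "kind": "batch",
        "parameters": p.to_dict(),
        "protocols": protocols,
        "baseline_glucose_mM": baseline_glucose,
        "noise": {
            "multiplicative_sd": noise.multiplicative_sd,
            "additive_sd": noise.additive_sd,
            "seed": noise.seed,
        },
    }
    _write(df, truth, path)
    return df, truth
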