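"""Named computational experiments built on the chamber simulator.

These runners reproduce the study designs the model is meant for:
whole-pancreas steady-state secretion (normal and type 1 diabetic),
pure alpha- or beta-cell populations, islet-count / assay-mode sweeps
of total hormone output, and perifusion with exogenous hormone in the
inlet.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import units
from .chamber import (
    Protocol,
    SimulationResult,
    SystemState,
    _batch_initial_state,
    simulate,
    steady_state,
    total_secretion,
)
from .parameters import REFERENCE_ISLETS, BasalState, ModelParameters

__all__ = [
    "perifusion_rate",
    "whole_pancreas",
    "eliminate_cell_type",
    "glucose_step_run",
    "islet_number_sweep",
    "exogenous_hormone_run",
    "run_scenario",
]

#: Whole-pancreas geometry: ~1 dL of tissue holding ~1e6 islets.
PANCREAS_VOLUME_ML = 100.0
PANCREAS_ISLETS = 1.0e6
PANCREAS_MASS_G = 90.0
BLOOD_FLOW_ML_PER_MIN_PER_100G = 1.3


def perifusion_rate(
    flow_per_100g: float = BLOOD_FLOW_ML_PER_MIN_PER_100G,
    mass_g: float = PANCREAS_MASS_G,
) -> float:
    """Organ perfusion rate in mL/min from specific blood flow and mass."""
    return flow_per_100g * mass_g / 100.0


def whole_pancreas(
    p: ModelParameters | None = None,
    diabetic: bool = False,
    *,
    volume: float = PANCREAS_VOLUME_ML,
    n_islets: float = PANCREAS_ISLETS,
    flow: float | None = None,
    basal: BasalState | None = None,
    glucose_mM: float | None = None,
) -> dict:
    """Steady-state whole-pancreas secretion report.

    The pancreas is treated as one perifusion chamber with basal
    glucose, insulin and glucagon flowing in at the organ blood flow
    rate.  ``diabetic=True`` removes the beta-cell contribution
    entirely: maximal insulin secretion and basal insulin are both set
    to 0, which switches the insulin signal off so the alpha-cells run
    as if beta-cells were absent.  Rates are reported in mg/min and
    concentrations in mg/dL.
    """
    p = ModelParameters() if p is None else p
    basal = BasalState() if basal is None else basal
    if flow is None:
        flow = perifusion_rate()
    if diabetic:
        p = p.replace(m_I=0.0)
        basal = basal.replace(I_ba=0.0)
    g = basal.g_ba if glucose_mM is None else glucose_mM
    proto = Protocol(
        mode="perifusion",
        volume=volume,
        flow=flow,
        n_islets=n_islets,
        duration=60.0,
        glucose_steps=((0.0, g),),
        basal=basal,
    )
    state = steady_state(proto, p)
    scale = n_islets / REFERENCE_ISLETS
    # at the fixed point the secreted flux equals the CSTR excess Q*([H]-[H]_in)
    r_I = flow * (state.chamber.I - proto.inlet_insulin(0.0))
    r_G = flow * (state.chamber.G - proto.inlet_glucagon(0.0))
    return {
        "diabetic": diabetic,
        "n_islets": n_islets,
        "volume_mL": volume,
        "flow_mL_per_min": flow,
        "glucose_mM": g,
        "insulin_secretion_mg_per_min": units.pg_per_min_to_mg_per_min(r_I),
        "glucagon_secretion_mg_per_min": units.pg_per_min_to_mg_per_min(r_G),
        "insulin_mg_per_dL": units.pg_per_ml_to_mg_per_dl(state.chamber.I),
        "glucagon_mg_per_dL": units.pg_per_ml_to_mg_per_dl(state.chamber.G),
        "state": state,
    }


def eliminate_cell_type(p: ModelParameters, which: str) -> ModelParameters:
    """Parameters for a pure population: zero the other cell type's output.

    ``which="alpha"`` removes alpha-cells (``m_G = 0``; no glucagon is
    ever secreted); ``which="beta"`` removes beta-cells (``m_I = 0``).
    Inlet hormone concentrations are left untouched -- a pure
    population can still be perifused with exogenous hormone.  To also
    silence the insulin *signal* (the diabetic whole-organ case), zero
    basal insulin in the protocol's :class:`BasalState`.
    """
    if which == "alpha":
        return p.replace(m_G=0.0)
    if which == "beta":
        return p.replace(m_I=0.0)
    raise ValueError(f"which must be 'alpha' or 'beta', got {which!r}")


def glucose_step_run(
    p: ModelParameters,
    proto: Protocol,
    baseline_glucose: float,
    target_glucose: float,
    **sim_kwargs,
) -> SimulationResult:
    """Simulate a step from ``baseline_glucose`` to ``target_glucose`` at t=0.

    The system starts at its fixed point under the baseline glucose
    (cell-side fixed point for batch) and the chamber glucose steps to
    the target at t = 0.
    """
    init_proto = proto.replace(glucose_steps=((0.0, baseline_glucose),))
    if proto.mode == "batch":
        init: SystemState = _batch_initial_state(init_proto, p)
    else:
        init = steady_state(init_proto, p)
    run_proto = proto.replace(glucose_steps=((0.0, target_glucose),))
    return simulate(run_proto, p, init=init, **sim_kwargs)


def islet_number_sweep(
    p: ModelParameters | None = None,
    glucose_levels: Iterable[float] = (1, 4, 7, 10, 15, 20, 30),
    islet_counts: Iterable[float] = (10, 100, 500),
    mode: str = "batch",
    *,
    baseline_glucose: float = 1.0,
    duration: float = 60.0,
    volume: float = 1.0,
    flow: float = 1.0,
    basal: BasalState | None = None,
    **sim_kwargs,
) -> pd.DataFrame:
    """Total 1-h secretion across glucose levels and islet counts.

    Emulates the assay-condition comparison: a step from 1 mM glucose
    to each test level in a 1 mL chamber, run either as static batch
    or as perifusion at 1 mL/min, for each islet count.  Returns a
    tidy table with whole-chamber and per-islet totals (pg).
    """
    p = ModelParameters() if p is None else p
    basal = BasalState() if basal is None else basal
    rows = []
    for n in islet_counts:
        proto = Protocol(
            mode=mode,
            volume=volume,
            flow=flow if mode == "perifusion" else 0.0,
            n_islets=n,
            duration=duration,
            basal=basal,
        )
        for g in glucose_levels:
            res = glucose_step_run(p, proto, baseline_glucose, g, **sim_kwargs)
            tot = total_secretion(res)
            rows.append(
                {
                    "mode": mode,
                    "n_islets": n,
                    "glucose_mM": g,
                    "insulin_total_pg": tot["insulin"],
                    "glucagon_total_pg": tot["glucagon"],
                    "insulin_total_pg_per_islet": tot["insulin"] / n,
                    "glucagon_total_pg_per_islet": tot["glucagon"] / n,
                }
            )
    return pd.DataFrame(rows)


def exogenous_hormone_run(
    p: ModelParameters | None = None,
    hormone: str = "insulin",
    inlet_level: float = 0.0,
    glucose_levels: Iterable[float] = (1, 4, 7, 10, 15, 20, 30),
    *,
    n_islets: float = 15.0,
    volume: float = 1.0,
    flow: float = 1.0,
    basal: BasalState | None = None,
) -> pd.DataFrame:
    """Perifusion with extra hormone in the inlet, across glucose levels.

    ``inlet_level`` (pg/mL) replaces the basal inlet concentration of
    the chosen hormone.  Reports the steady-state secretion of both
    hormones (whole chamber, pg/min) at each glucose level -- the
    interesting readout is the *other* hormone: exogenous insulin
    suppresses glucagon secretion, exogenous glucagon potentiates
    insulin secretion most at low glucose.
    """
    p = ModelParameters() if p is None else p
    basal = BasalState() if basal is None else basal
    if hormone not in ("insulin", "glucagon"):
        raise ValueError(f"hormone must be 'insulin' or 'glucagon', got {hormone!r}")
    if inlet_level < 0:
        raise ValueError("inlet_level must be >= 0")
    rows = []
    for g in glucose_levels:
        kw = {}
        if hormone == "insulin":
            kw["insulin_steps"] = ((0.0, inlet_level),)
        else:
            kw["glucagon_steps"] = ((0.0, inlet_level),)
        proto = Protocol(
            mode="perifusion",
            volume=volume,
            flow=flow,
            n_islets=n_islets,
            duration=60.0,
            glucose_steps=((0.0, g),),
            basal=basal,
            **kw,
        )
        state = steady_state(proto, p)
        r_I = flow * (state.chamber.I - proto.inlet_insulin(0.0))
        r_G = flow * (state.chamber.G - proto.inlet_glucagon(0.0))
        rows.append(
            {
                "hormone": hormone,
                "inlet_pg_per_mL": inlet_level,
                "glucose_mM": g,
                "insulin_secretion_pg_per_min": r_I,
                "glucagon_secretion_pg_per_min": r_G,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# config-driven dispatch (used by the CLI and the shipped scenario files)
# ---------------------------------------------------------------------------


def _apply_overrides(cfg: Mapping) -> tuple[ModelParameters, BasalState]:
    p = ModelParameters.from_dict(cfg.get("parameters", {})) if cfg.get(
        "parameters"
    ) else ModelParameters()
    p = p.replace(**cfg.get("parameter_overrides", {}))
    basal = BasalState(**cfg.get("basal", {}))
    if cfg.get("basal_overrides"):
        basal = basal.replace(**cfg["basal_overrides"])
    return p, basal


def run_scenario(cfg: Mapping) -> tuple[pd.DataFrame, dict]:
    """Run a scenario described by a config mapping.

    ``cfg["kind"]`` selects the runner: ``whole_pancreas``,
    ``islet_sweep``, ``elimination``, ``exogenous`` or
    ``glucose_step``.  Returns a tidy result table and a JSON-able
    summary dict.
    """
    kind = cfg.get("kind")
    name = cfg.get("name", kind)
    p, basal = _apply_overrides(cfg)

    if kind == "whole_pancreas":
        report = whole_pancreas(
            p,
            diabetic=bool(cfg.get("diabetic", False)),
            basal=basal,
            **{
                k: cfg[k]
                for k in ("volume", "n_islets", "flow", "glucose_mM")
                if k in cfg
            },
        )
        state = report.pop("state")
        summary = dict(report, name=name)
        df = pd.DataFrame([report])
        return df, summary

    if kind == "islet_sweep":
        frames = []
        for mode in cfg.get("modes", ["batch", "perifusion"]):
            frames.append(
                islet_number_sweep(
                    p,
                    glucose_levels=cfg.get("glucose_levels", (1, 4, 7, 10, 15, 20, 30)),
                    islet_counts=cfg.get("islet_counts", (10, 100, 500)),
                    mode=mode,
                    basal=basal,
                    **{k: cfg[k] for k in ("duration", "volume", "flow") if k in cfg},
                )
            )
        df = pd.concat(frames, ignore_index=True)
        summary = {
            "name": name,
            "rows": len(df),
            "glucagon_total_pg_min": float(df["glucagon_total_pg"].min()),
            "glucagon_total_pg_max": float(df["glucagon_total_pg"].max()),
        }
        return df, summary

    if kind == "elimination":
        rows = []
        for which in cfg.get("which", ["alpha", "beta"]):
            pe = eliminate_cell_type(p, which)
            sweep = exogenous_hormone_run(
                pe,
                hormone="insulin",
                inlet_level=basal.I_ba,
                glucose_levels=cfg.get("glucose_levels", (1, 4, 7, 10, 15, 20, 30)),
                n_islets=cfg.get("n_islets", 15),
                basal=basal,
            )
            sweep["eliminated"] = which
            rows.append(sweep)
        base = exogenous_hormone_run(
            p,
            hormone="insulin",
            inlet_level=basal.I_ba,
            glucose_levels=cfg.get("glucose_levels", (1, 4, 7, 10, 15, 20, 30)),
            n_islets=cfg.get("n_islets", 15),
            basal=basal,
        )
        base["eliminated"] = "none"
        df = pd.concat([base, *rows], ignore_index=True)
        summary = {"name": name, "rows": len(df)}
        return df, summary

    if kind == "exogenous":
        frames = []
        for level in cfg["inlet_levels"]:
            frames.append(
                exogenous_hormone_run(
                    p,
                    hormone=cfg.get("hormone", "insulin"),
                    inlet_level=level,
                    glucose_levels=cfg.get("glucose_levels", (1, 4, 7, 10, 15, 20, 30)),
                    n_islets=cfg.get("n_islets", 15),
                    basal=basal,
                )
            )
        df = pd.concat(frames, ignore_index=True)
        summary = {"name": name, "rows": len(df)}
        return df, summary

    if kind == "glucose_step":
        proto = Protocol.from_dict(dict(cfg["protocol"], basal=basal.to_dict()))
        factor = cfg.get("species_scale", 1.0)
        baseline = cfg.get("baseline_glucose", proto.basal.g_ba) * factor
        target = cfg["target_glucose"] * factor
        res = glucose_step_run(p, proto, baseline, target)
        df = res.to_dataframe()
        i_peak = int(np.argmax(res.r_I))
        summary = {
            "name": name,
            "insulin_peak_pg_per_min": float(res.r_I[i_peak]),
            "insulin_peak_time_min": float(res.time[i_peak]),
            "insulin_plateau_pg_per_min": float(res.r_I[-1]),
            "glucagon_final_pg_per_min": float(res.r_G[-1]),
        }
        return df, summary

    raise ValueError(f"unknown scenario kind {kind!r}")
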