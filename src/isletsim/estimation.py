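"""Parameter estimation and one-at-a-time sensitivity analysis.

Fitting minimizes a *normalized* sum of squared errors -- residuals are
divided by the data values so insulin (tens of pg/min) and glucagon
(single pg/min) trajectories contribute comparably -- optionally
weighted per trajectory.  Optimization is bound-constrained nonlinear
least squares (trust-region reflective) restarted from multiple
Latin-hypercube points within the bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .chamber import Protocol, simulate, total_secretion
from .parameters import BasalState, ModelParameters
from .scenarios import glucose_step_run

__all__ = [
    "FitProblem",
    "FitResult",
    "normalized_sse",
    "fit",
    "sensitivity_scan",
    "DATASET_COLUMNS",
]

DATASET_COLUMNS = (
    "condition_id",
    "time_min",
    "insulin_pg_per_min",
    "glucagon_pg_per_min",
)

#: Trajectory weights used for the human perifusion fit: conditions at
#: higher glucose carry more weight (6 mM lowest ... 30 mM highest).
HUMAN_PERIFUSION_WEIGHTS = (1 / 15, 2 / 15, 3 / 15, 4 / 15, 5 / 15)

#: Named bound presets from the calibration workflow.  The glucagon
#: half-point on beta-cells is nM-scale against pM basal levels; the
#: insulin half-point on alpha-cells has a first-pass and a tighter
#: human-refit range.
BOUND_PRESETS = {
    "h_GB": (500.0, 1000.0),
    "h_IA_initial": (1.0, 100.0),
    "h_IA_human": (8.0, 100.0),
}


def normalized_sse(
    model_values: Sequence[np.ndarray] | np.ndarray,
    data_values: Sequence[np.ndarray] | np.ndarray,
    weights: Sequence[float] | float = 1.0,
) -> float:
    """Weighted sum over trajectories of sum_t ((model - data) / data)^2.

    ``model_values``/``data_values`` are either single arrays (one
    trajectory) or sequences of per-trajectory arrays; ``weights`` is
    one weight per trajectory.  Data values used as normalizers must
    be strictly positive.
    """
    if isinstance(model_values, np.ndarray) and model_values.ndim == 1:
        model_values, data_values = [model_values], [np.asarray(data_values)]
    weights = np.broadcast_to(np.asarray(weights, dtype=float), (len(model_values),))
    if np.any(weights < 0):
        raise ValueError("weights must be >= 0")
    sse = 0.0
    for m, d, w in zip(model_values, data_values, weights):
        m = np.asarray(m, dtype=float)
        d = np.asarray(d, dtype=float)
        if m.shape != d.shape:
            raise ValueError("model and data trajectories differ in length")
        if np.any(d <= 0):
            raise ValueError("data values used to normalize residuals must be > 0")
        sse += w * float(np.sum(((m - d) / d) ** 2))
    return sse


@dataclass
class FitProblem:
    """A bound-constrained fit of model parameters to secretion data.

    ``dataset`` follows the package CSV dialect (columns
    ``condition_id, time_min, insulin_pg_per_min, glucagon_pg_per_min``;
    missing values allowed).  Each condition maps to a
    :class:`Protocol` describing how it was (or would be) run.
    ``glucagon_feedback_off`` encodes the common perifusion fitting
    assumption that secreted glucagon is negligible: the glucagon
    secretion maximum and its contribution to the beta-cell signal are
    both zeroed while fitting insulin kinetics.

    ``per_condition_free`` enables grouped fits: each named parameter
    gets an independent copy per condition (e.g. kinetic constants
    re-estimated at every glucose level) while ``free`` parameters
    stay shared across all conditions.
    """

    dataset: pd.DataFrame
    protocols: Mapping[str, Protocol]
    free: Mapping[str, tuple[float, float]]
    per_condition_free: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    fixed: Mapping[str, float] = field(default_factory=dict)
    weights: Mapping[str, float] = field(default_factory=dict)
    mask: Mapping[str, bool] = field(default_factory=dict)  # condition -> use?
    glucagon_feedback_off: bool = False
    n_starts: int = 8
    seed: int = 0
    sim_rtol: float = 1e-6
    sim_dt_out: float = 0.5
    base: ModelParameters = field(default_factory=ModelParameters)

    def __post_init__(self) -> None:
        missing = set(self.dataset["condition_id"].unique()) - set(self.protocols)
        if missing:
            raise ValueError(f"no protocol for condition(s): {sorted(missing)}")
        known = set(ModelParameters.names())
        for group in (self.free, self.per_condition_free):
            for name, (lo, hi) in group.items():
                if name not in known:
                    raise ValueError(f"unknown free parameter {name!r}")
                if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                    raise ValueError(
                        f"bounds for {name} must be finite with lo < hi"
                    )
        overlap = set(self.free) & set(self.per_condition_free)
        if overlap:
            raise ValueError(
                f"parameter(s) both shared and per-condition: {sorted(overlap)}"
            )
        for w in self.weights.values():
            if w < 0:
                raise ValueError("weights must be >= 0")

    def conditions(self) -> list[str]:
        return [
            c
            for c in self.dataset["condition_id"].unique()
            if self.mask.get(c, True)
        ]

    # -- parameter-vector layout: shared block, then one per-condition block

    def x_names(self) -> list[str]:
        names = list(self.free)
        for cond in self.conditions():
            names.extend(f"{n}@{cond}" for n in self.per_condition_free)
        return names

    def x_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        pairs = [self.free[n] for n in self.free]
        for _ in self.conditions():
            pairs.extend(self.per_condition_free[n] for n in self.per_condition_free)
        lo, hi = zip(*pairs)
        return np.array(lo), np.array(hi)

    def _split_x(self, x) -> tuple[dict, dict]:
        x = np.asarray(x, dtype=float)
        n_shared = len(self.free)
        shared = dict(zip(self.free, map(float, x[:n_shared])))
        per: dict[str, dict[str, float]] = {}
        k = n_shared
        width = len(self.per_condition_free)
        for cond in self.conditions():
            per[cond] = dict(
                zip(self.per_condition_free, map(float, x[k : k + width]))
            )
            k += width
        return shared, per

    def parameters_at(self, x, condition: str | None = None) -> ModelParameters:
        """Parameter set at vector ``x``; per-condition values applied
        only when ``condition`` is given."""
        shared, per = self._split_x(x)
        over = dict(self.fixed)
        over.update(shared)
        if condition is not None:
            over.update(per.get(condition, {}))
        p = self.base.replace(**over)
        if self.glucagon_feedback_off:
            p = p.replace(m_G=0.0, m_GB=0.0)
        return p


@dataclass
class FitResult:
    """Outcome of a multistart fit, best solution first.

    ``values`` maps each optimized name (``param`` or
    ``param@condition`` in grouped fits) to its best value;
    ``parameters`` is the full parameter set with shared values
    applied (per-condition copies live only in ``values``).
    """

    parameters: ModelParameters
    values: dict[str, float]
    sse: float
    residuals: dict[str, np.ndarray]
    success: bool
    starts: list[dict]  # ranked: [{"x0":..., "values":..., "sse":..., "success":...}]

    def to_dict(self) -> dict:
        return {
            "values": self.values,
            "sse": self.sse,
            "success": self.success,
            "starts": [
                {k: v for k, v in s.items() if k != "result"} for s in self.starts
            ],
        }


def _condition_residual(problem: FitProblem, x: np.ndarray, cond: str) -> np.ndarray:
    p = problem.parameters_at(x, condition=cond)
    rows = problem.dataset[problem.dataset["condition_id"] == cond]
    res = simulate(
        problem.protocols[cond],
        p,
        rtol=problem.sim_rtol,
        dt_out=problem.sim_dt_out,
    )
    w = np.sqrt(problem.weights.get(cond, 1.0))
    chunks = []
    columns = [("insulin_pg_per_min", res.r_I)]
    if not problem.glucagon_feedback_off:
        # with glucagon assumed negligible only insulin data is fitted
        columns.append(("glucagon_pg_per_min", res.r_G))
    for col, flux in columns:
        if col not in rows:
            continue
        data = rows[col].to_numpy(dtype=float)
        t = rows["time_min"].to_numpy(dtype=float)
        ok = np.isfinite(data)
        if not ok.any():
            continue
        if np.any(data[ok] <= 0):
            raise ValueError(
                f"condition {cond!r}, column {col}: data values used to "
                "normalize residuals must be > 0"
            )
        pred = np.interp(t[ok], res.time, flux)
        chunks.append(w * (pred - data[ok]) / data[ok])
    return np.concatenate(chunks) if chunks else np.empty(0)


def _residual_vector(problem: FitProblem, x: np.ndarray) -> np.ndarray:
    chunks = [_condition_residual(problem, x, c) for c in problem.conditions()]
    out = np.concatenate(chunks) if chunks else np.empty(0)
    if out.size == 0:
        raise ValueError("dataset contains no usable data points")
    return out


def fit(problem: FitProblem, p0: ModelParameters | None = None) -> FitResult:
    """Multistart bound-constrained least squares on the fit problem.

    Starts are the initial guess ``p0`` (defaults to the problem's
    base parameters, clipped into the bounds) plus ``n_starts - 1``
    seeded Latin-hypercube points spread over the bounds.  Each start
    runs a trust-region-reflective least-squares solve; the solution
    with the lowest normalized SSE wins.  In grouped fits the initial
    guess for every per-condition copy is the corresponding ``p0``
    value.
    """
    names = problem.x_names()
    lo, hi = problem.x_bounds()
    p0 = problem.base if p0 is None else p0
    x0_list = [np.clip([p0[n.split("@")[0]] for n in names], lo, hi)]
    if problem.n_starts > 1:
        sampler = qmc.LatinHypercube(d=len(names), seed=problem.seed)
        pts = qmc.scale(sampler.random(problem.n_starts - 1), lo, hi)
        x0_list.extend(pts)

    starts: list[dict] = []
    for x0 in x0_list:
        try:
            sol = least_squares(
                lambda x: _residual_vector(problem, x),
                x0,
                bounds=(lo, hi),
                method="trf",
                xtol=1e-8,
                ftol=1e-8,
            )
            starts.append(
                {
                    "x0": [float(v) for v in x0],
                    "values": dict(zip(names, (float(v) for v in sol.x))),
                    "sse": float(2 * sol.cost),  # cost is 0.5 * sum r^2
                    "success": bool(sol.success),
                    "result": sol,
                }
            )
        except Exception as exc:  # noqa: BLE001 - collect per-start failures
            starts.append(
                {
                    "x0": [float(v) for v in x0],
                    "values": None,
                    "sse": float("inf"),
                    "success": False,
                    "error": str(exc),
                }
            )
    starts.sort(key=lambda s: s["sse"])
    best = starts[0]
    if not np.isfinite(best["sse"]):
        raise RuntimeError(
            "all optimization starts failed: "
            + "; ".join(s.get("error", "?") for s in starts)
        )
    x_best = np.array([best["values"][n] for n in names])
    p_best = problem.parameters_at(x_best)
    residuals = {
        cond: _condition_residual(problem, x_best, cond)
        for cond in problem.conditions()
    }
    return FitResult(
        parameters=p_best,
        values=best["values"],
        sse=best["sse"],
        residuals=residuals,
        success=best["success"],
        starts=starts,
    )


DEFAULT_FACTORS = (0.66, 0.8, 1.0, 1.25, 1.5)


def sensitivity_scan(
    p: ModelParameters | None = None,
    factors: Sequence[float] = DEFAULT_FACTORS,
    *,
    parameters: Sequence[str] | None = None,
    protocol: Protocol | None = None,
    baseline_glucose: float = 1.0,
    target_glucose: float = 15.0,
    basal: BasalState | None = None,
    sim_rtol: float = 1e-7,
    dt_out: float = 0.25,
) -> pd.DataFrame:
    """One-at-a-time sensitivity of total 1-h secretion to each parameter.

    Each parameter is multiplied by each factor (default grid 0.66 to
    1.5 -- the largest symmetric range that keeps ``m_g <= 1``), one
    at a time, and the readout experiment is re-run *from its own
    steady state*: 15 islets under perifusion at 1 mL/min stepped from
    1 mM to 15 mM glucose.  Returns a tidy table of total insulin and
    glucagon secreted over the hour.
    """
    p = ModelParameters() if p is None else p
    if any(f <= 0 for f in factors):
        raise ValueError("factors must be > 0")
    names = list(ModelParameters.names()) if parameters is None else list(parameters)
    unknown = set(names) - set(ModelParameters.names())
    if unknown:
        raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
    if protocol is None:
        protocol = Protocol(
            mode="perifusion",
            volume=1.0,
            flow=1.0,
            n_islets=15,
            duration=60.0,
            basal=BasalState() if basal is None else basal,
        )
    rows = []
    for name in names:
        for f in factors:
            p_mod = p.replace(**{name: p[name] * f})
            res = glucose_step_run(
                p_mod,
                protocol,
                baseline_glucose,
                target_glucose,
                rtol=sim_rtol,
                dt_out=dt_out,
            )
            tot = total_secretion(res)
            rows.append(
                {
                    "parameter": name,
                    "factor": f,
                    "insulin_total_pg": tot["insulin"],
                    "glucagon_total_pg": tot["glucagon"],
                }
            )
    return pd.DataFrame(rows)
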