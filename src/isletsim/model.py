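"""Right-hand sides of the paracrine islet secretion model.

The cell model has eight dynamic variables: four intracellular signals
(glucose in beta-cells ``X_gB``, glucagon in beta-cells ``X_G``,
glucose in alpha-cells ``X_gA``, insulin in alpha-cells ``X_I``) that
relax with first-order kinetics toward the basal-normalized bulk
concentrations, and four granule-pool masses (docked and readily
releasable pools for each hormone).  Net stimulation signals ``X_B``
and ``X_A`` combine the intracellular signals and drive both the
steady-state secretion rates and the Hill-shaped pool transfer
coefficients.

Everything here is a pure function of scalars/arrays so the chamber
integrator, the steady-state solver and the fitting code can share one
implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .parameters import ModelParameters

__all__ = [
    "SignalState",
    "PoolState",
    "NetSignals",
    "hill",
    "insulin_secretion_rate",
    "glucagon_secretion_rate",
    "beta_net_signal",
    "alpha_net_signal",
    "net_signals",
    "signal_rhs",
    "pool_rhs",
    "pool_steady_state",
]


@dataclass(frozen=True)
class SignalState:
    """Intracellular transduction signals (dimensionless, >= 0)."""

    X_gB: float
    X_G: float
    X_gA: float
    X_I: float

    def as_array(self) -> np.ndarray:
        return np.array([self.X_gB, self.X_G, self.X_gA, self.X_I])

    @classmethod
    def from_array(cls, a) -> "SignalState":
        return cls(*(float(v) for v in a))


@dataclass(frozen=True)
class PoolState:
    """Hormone mass in the docked (1) and readily releasable (2) pools.

    Units: pg per 15 islets.  The reserve pool is treated as infinite,
    so it never appears as a state; its outflow into pool 1 equals the
    steady-state secretion rate.
    """

    I1: float
    I2: float
    G1: float
    G2: float

    def as_array(self) -> np.ndarray:
        return np.array([self.I1, self.I2, self.G1, self.G2])

    @classmethod
    def from_array(cls, a) -> "PoolState":
        return cls(*(float(v) for v in a))


@dataclass(frozen=True)
class NetSignals:
    """Composite stimulation signals for beta- (X_B) and alpha-cells (X_A)."""

    X_B: float
    X_A: float


def hill(x, m, h, n):
    """Hill function ``m * x**n / (x**n + h**n)``.

    Evaluated in log space, ``m * sigmoid(n * (log x - log h))``, so
    that steep exponents (n ~ 10) and large signals cannot overflow.
    ``x`` may be a scalar or array; ``x = 0`` maps to 0 exactly.

    Raises
    ------
    ValueError
        If ``h <= 0``, ``n <= 0``, or any ``x < 0`` (signals are
        non-negative by construction, so a negative input indicates a
        bug upstream).
    """
    if h <= 0 or n <= 0:
        raise ValueError(f"hill requires h > 0 and n > 0, got h={h}, n={n}")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("hill input must be non-negative")
    with np.errstate(divide="ignore"):  # log(0) -> -inf -> sigmoid -> 0
        out = m * expit(n * (np.log(x) - np.log(h)))
    return out if out.ndim else float(out)


def insulin_secretion_rate(X_B, p: ModelParameters):
    """Steady-state insulin secretion rate (pg/min per 15 islets)."""
    return hill(X_B, p.m_I, p.h_I, p.n_I)


def glucagon_secretion_rate(X_A, p: ModelParameters):
    """Steady-state glucagon secretion rate (pg/min per 15 islets)."""
    return hill(X_A, p.m_G, p.h_G, p.n_G)


def beta_net_signal(X_gB, X_G, p: ModelParameters):
    """Net beta-cell signal: glucose plus a saturating glucagon boost.

    The glucagon term is gated by the glucose signal (no potentiation
    without glucose) and a background ``X_B0`` accounts for secretion
    observed at zero glucose.  Monotone non-decreasing in both inputs.
    """
    boost = hill(X_G, p.m_GB, p.h_GB, p.n_GB) * hill(X_gB, 1.0, p.h_gB, p.n_gB)
    return X_gB + boost + p.X_B0


def alpha_net_signal(X_gA, X_I, p: ModelParameters):
    """Net alpha-cell signal: glucose minus a saturating insulin brake.

    Insulin removes at most the fraction ``m_g`` of the glucose signal
    plus the whole background ``X_A0``; for ``m_g <= 1`` the result
    stays non-negative, and it is clamped at 0 otherwise.
    """
    brake = (p.m_g * np.asarray(X_gA) + p.X_A0) * hill(X_I, 1.0, p.h_IA, p.n_IA)
    out = np.asarray(X_gA) + p.X_A0 - brake
    out = np.maximum(out, 0.0)
    return out if out.ndim else float(out)


def net_signals(s: SignalState, p: ModelParameters) -> NetSignals:
    return NetSignals(
        X_B=beta_net_signal(s.X_gB, s.X_G, p),
        X_A=alpha_net_signal(s.X_gA, s.X_I, p),
    )


def signal_rhs(
    s: SignalState,
    g_norm: float,
    G_norm: float,
    I_norm: float,
    p: ModelParameters,
) -> np.ndarray:
    """Time derivatives of the four transduction signals.

    Each signal relaxes first-order toward its basal-normalized bulk
    concentration: ``dX/dt = k * (input - X)``.  Inputs are the current
    chamber concentrations divided by basal levels (``g_norm`` feeds
    both cell types).
    """
    return np.array(
        [
            p.k_gB * (g_norm - s.X_gB),
            p.k_G * (G_norm - s.X_G),
            p.k_gA * (g_norm - s.X_gA),
            p.k_I * (I_norm - s.X_I),
        ]
    )


def _transfer_coefficients(X_B, X_A, p: ModelParameters):
    """Hill-shaped pool transfer coefficients (1/min) at the net signals."""
    k1_I = hill(X_B, p.m_I1, p.h_I1, p.n_I1)
    k2_I = hill(X_B, p.m_I2, p.h_I2, p.n_I2)
    k1_G = hill(X_A, p.m_G1, p.h_G1, p.n_G1)
    k2_G = hill(X_A, p.m_G2, p.h_G2, p.n_G2)
    return k1_I, k2_I, k1_G, k2_G


def pool_rhs(
    pools: PoolState, X_B: float, X_A: float, p: ModelParameters
) -> tuple[np.ndarray, float, float]:
    """Granule-pool mass balances and exocytosis fluxes.

    The docked pool is fed at the steady-state secretion rate (the
    reserve pool is unlimited), transfers forward at ``k1(X)`` and the
    readily releasable pool empties into the medium at ``k2(X)``.

    Returns ``(d[I1, I2, G1, G2]/dt, r_I, r_G)`` with the secreted
    fluxes ``r = k2 * pool2`` in pg/min per 15 islets.  At a fixed
    point both fluxes equal the steady-state rates exactly.
    """
    k1_I, k2_I, k1_G, k2_G = _transfer_coefficients(X_B, X_A, p)
    R_I = insulin_secretion_rate(X_B, p)
    R_G = glucagon_secretion_rate(X_A, p)
    r_I = k2_I * pools.I2
    r_G = k2_G * pools.G2
    d = np.array(
        [
            R_I - k1_I * pools.I1,
            k1_I * pools.I1 - r_I,
            R_G - k1_G * pools.G1,
            k1_G * pools.G1 - r_G,
        ]
    )
    return d, r_I, r_G


def pool_steady_state(X_B: float, X_A: float, p: ModelParameters) -> PoolState:
    """Pool masses at flux balance for fixed net signals.

    ``pool1 = R/k1`` and ``pool2 = R/k2`` so that the secreted flux
    equals the steady-state rate.  Where a transfer coefficient
    underflows to 0 (net signal 0) the corresponding secretion rate is
    0 too and the pool mass is set to 0 by convention.
    """
    k1_I, k2_I, k1_G, k2_G = _transfer_coefficients(X_B, X_A, p)
    R_I = insulin_secretion_rate(X_B, p)
    R_G = glucagon_secretion_rate(X_A, p)

    def safe(num, den):
        return num / den if den > 0 else 0.0

    return PoolState(
        I1=safe(R_I, k1_I),
        I2=safe(R_I, k2_I),
        G1=safe(R_G, k1_G),
        G2=safe(R_G, k2_G),
    )
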