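"""Parameter and state containers for the paracrine islet model.

The model couples pancreatic beta-cells (insulin) and alpha-cells
(glucagon) through glucose and through each other's hormone.  All
concentrations entering the cells are normalized by basal levels, so
most parameters are dimensionless Hill constants.  Units used
throughout the package: time in min, volume in mL, hormone mass in pg
(concentrations in pg/mL), glucose in mM.  Secretion maxima ``m_I`` and
``m_G`` are expressed per 15 islets, the reference islet count of the
human perifusion experiments the defaults were calibrated against.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import yaml

__all__ = ["ModelParameters", "BasalState", "REFERENCE_ISLETS"]

#: Islet count the secretion maxima m_I, m_G refer to.
REFERENCE_ISLETS = 15.0


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter set of the coupled alpha/beta-cell secretion model.

    Defaults are the calibrated human-islet values.  Groups:

    * kinetic -- first-order signal-transduction rate constants
      ``k_*`` (1/min) and the Hill constants ``m_*1/2, h_*1/2, n_*1/2``
      of the granule-pool transfer coefficients;
    * interaction -- Hill constants coupling glucagon into the
      beta-cell net signal (``m_GB, h_GB, n_GB, h_gB, n_gB``) and
      insulin into the alpha-cell net signal (``h_IA, n_IA, m_g``);
    * secretion -- steady-state secretion Hill constants
      (``m_I, h_I, n_I, m_G, h_G, n_G``) and background signals
      ``X_B0, X_A0``.
    """

    # --- kinetic: signal transduction rate constants (1/min) ---
    k_gB: float = 0.554
    k_G: float = 0.554
    k_gA: float = 0.022
    k_I: float = 2.77
    # --- kinetic: insulin pool transfer Hill coefficients ---
    m_I1: float = 0.336  # 1/min
    h_I1: float = 3.75
    n_I1: float = 9.97
    m_I2: float = 0.360  # 1/min
    h_I2: float = 0.968
    n_I2: float = 6.68
    # --- kinetic: glucagon pool transfer Hill coefficients ---
    m_G1: float = 0.336  # 1/min
    h_G1: float = 3.75
    n_G1: float = 9.97
    m_G2: float = 0.360  # 1/min
    h_G2: float = 0.968
    n_G2: float = 6.68
    # --- interaction ---
    m_GB: float = 1.11
    h_GB: float = 502.0
    n_GB: float = 0.63
    h_gB: float = 1.07
    n_gB: float = 0.35
    h_IA: float = 10.0
    n_IA: float = 1.17
    m_g: float = 0.60
    # --- secretion ---
    m_I: float = 103.0  # pg/min per 15 islets
    h_I: float = 3.97
    n_I: float = 4.84
    m_G: float = 2.24  # pg/min per 15 islets
    h_G: float = 1.06
    n_G: float = 3.5
    X_B0: float = 2.60
    X_A0: float = 4.40

    def __post_init__(self) -> None:
        for name, value in self.items():
            if not (value == value and abs(value) != float("inf")):
                raise ValueError(f"parameter {name} is not finite: {value!r}")
            if name.startswith(("h_", "n_", "k_")) and value <= 0:
                raise ValueError(f"parameter {name} must be > 0, got {value}")
            if name.startswith("m_") and value < 0:
                raise ValueError(f"parameter {name} must be >= 0, got {value}")
        if self.m_g > 1:
            # the insulin brake on the alpha-cell glucose signal cannot
            # remove more than the whole signal; beyond 1 the net signal
            # could go negative and is clamped downstream
            warnings.warn(
                f"m_g = {self.m_g} exceeds 1; alpha-cell net signal may "
                "be clamped at 0",
                stacklevel=2,
            )

    # -- mapping-style access -------------------------------------------------

    def items(self) -> Iterator[tuple[str, float]]:
        for f in dataclasses.fields(self):
            yield f.name, getattr(self, f.name)

    def __getitem__(self, name: str) -> float:
        if name not in self.names():
            raise KeyError(name)
        return getattr(self, name)

    @classmethod
    def names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls))

    def replace(self, **overrides: float) -> "ModelParameters":
        """Return a copy with the given parameters overridden."""
        unknown = set(overrides) - set(self.names())
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in self.items()}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ModelParameters":
        unknown = set(d) - set(cls.names())
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParameters":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class BasalState:
    """Reference (basal) concentrations used to normalize cell inputs.

    ``g_ba`` in mM, hormones in pg/mL.  Defaults are human values:
    fasting glucose ~5 mM, basal glucagon ~20 pM (~70 pg/mL, i.e.
    7e-6 mg/dL), and basal insulin 100 pg/mL (~17 pM, low-normal
    fasting level); the insulin normalizer is the one basal the
    coupled behavior is genuinely sensitive to, and this value is the
    one at which intact-islet batch assays show the characteristic
    U-shaped glucagon-vs-glucose response while whole-organ secretion
    stays at observed levels.  ``I_ba = 0`` is allowed and means the
    insulin signal is switched off entirely (type 1 diabetes limit);
    ``g_ba`` and ``G_ba`` must stay positive.
    """

    g_ba: float = 5.0
    I_ba: float = 100.0
    G_ba: float = 70.0

    def __post_init__(self) -> None:
        if self.g_ba <= 0 or self.G_ba <= 0:
            raise ValueError("basal glucose and glucagon must be > 0")
        if self.I_ba < 0:
            raise ValueError("basal insulin must be >= 0")

    def replace(self, **overrides: float) -> "BasalState":
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in dataclasses.fields(self)}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "BasalState":
        return cls(**{k: float(v) for k, v in d.items()})
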