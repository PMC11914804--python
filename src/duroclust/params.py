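"""Model parameters, validation, and nondimensionalization.

The model is solved in nondimensional units built from the cell length
scale ``l = 25 um`` (one length unit) and the time scale ``tau = 4 h``
(one time unit).  The derived velocity unit is ``l/tau = 6.25 um/h``, so
a crawling speed of 2 um/h becomes ``Vprop = 0.32``, and the 0.5 mm
observation window becomes a periodic box of side ``Lstar = 20``.

Several coefficients (the durotaxis gain, traction amplitude, steric
strength, rotational diffusion, and the enzyme production/degradation
amplitudes) have no reliably mappable dimensional value; their defaults
are calibrated once, as documented in ``docs/methods.md``, and exposed
here as ordinary configuration fields.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

# Base units of the nondimensionalization.
LENGTH_UNIT_M = 25e-6        # l = 25 um
TIME_UNIT_S = 4.0 * 3600.0   # tau = 4 h

#: Dimensional reference values (SI units) for the quantities whose
#: dimensional magnitudes are meaningful.  Speeds in m/s, diffusivities
#: in m^2/s, rates in 1/s, lengths in m.
DIMENSIONAL_DEFAULTS: dict[str, float] = {
    "L": 0.5e-3,            # box side, 0.5 mm
    "d": 10e-6,             # cell diameter, 10 um
    "Vprop": 2e-6 / 3600.0, # 2 um/h
    "DC": 1.2e-12,          # MMP diffusion coefficient, m^2/s
    "gamma1": 5.5e-5,       # MMP consumption by degradation, 1/s
    "beta": 2e-3,           # MMP decay, 1/s
}

#: Physical kind of each dimensional field, used for unit conversion.
_KINDS: dict[str, str] = {
    "L": "length",
    "d": "length",
    "l0": "length",
    "lT": "length",
    "Vprop": "speed",
    "DC": "diffusivity",
    "gamma1": "rate",
    "beta": "rate",
    "Drot": "rate",
}


def _scale_factor(kind: str, l_unit: float, tau_unit: float) -> float:
    """Division factor taking a dimensional value to nondimensional."""
    if kind == "length":
        return l_unit
    if kind == "time":
        return tau_unit
    if kind == "speed":
        return l_unit / tau_unit
    if kind == "diffusivity":
        return l_unit**2 / tau_unit
    if kind == "rate":
        return 1.0 / tau_unit
    raise ValueError(f"unknown physical kind {kind!r}")


def nondimensionalize(
    dimensional: Mapping[str, float],
    l_unit: float = LENGTH_UNIT_M,
    tau_unit: float = TIME_UNIT_S,
) -> dict[str, float]:
    """Convert a record of dimensional (SI) parameter values to model units.

    Lengths are divided by ``l_unit``, speeds by ``l_unit/tau_unit``,
    diffusivities by ``l_unit**2/tau_unit`` and rates are multiplied by
    ``tau_unit``.  The key ``L`` is returned as ``Lstar = L/l_unit``.

    Parameters
    ----------
    dimensional
        Mapping of field name to SI value; unknown fields raise.
    l_unit, tau_unit
        Base length (m) and time (s) units; must be positive.

    Returns
    -------
    dict
        Nondimensional values under the model's field names.
    """
    if not l_unit > 0:
        raise ValueError(f"l_unit must be positive, got {l_unit}")
    if not tau_unit > 0:
        raise ValueError(f"tau_unit must be positive, got {tau_unit}")
    out: dict[str, float] = {}
    for name, value in dimensional.items():
        if name not in _KINDS:
            raise ValueError(f"unknown dimensional parameter {name!r}")
        if not value > 0:
            raise ValueError(f"parameter {name!r} must be positive, got {value}")
        scaled = value / _scale_factor(_KINDS[name], l_unit, tau_unit)
        out["Lstar" if name == "L" else name] = scaled
    return out


def dimensionalize(
    nondim: Mapping[str, float],
    l_unit: float = LENGTH_UNIT_M,
    tau_unit: float = TIME_UNIT_S,
) -> dict[str, float]:
    """Inverse of :func:`nondimensionalize` (round-trips to float tolerance)."""
    if not l_unit > 0 or not tau_unit > 0:
        raise ValueError("units must be positive")
    out: dict[str, float] = {}
    for name, value in nondim.items():
        key = "L" if name == "Lstar" else name
        if key not in _KINDS:
            raise ValueError(f"unknown nondimensional parameter {name!r}")
        out[key] = value * _scale_factor(_KINDS[key], l_unit, tau_unit)
    return out


@dataclass
class ModelParams:
    """All nondimensional model coefficients and numerical controls.

    Defaults correspond to the reference parameter set: 40 cells of
    diameter 0.4 on a periodic box of side 20, crawling at speed 0.32,
    with both durotaxis and matrix degradation enabled.
    """

    # --- population and geometry -----------------------------------
    Nc: int = 40              # number of cells
    Lstar: float = 20.0       # periodic box side (length units)
    d: float = 0.4            # cell diameter

    # --- cell motility ----------------------------------------------
    Vprop: float = 0.32       # self-propulsion speed
    F0: float = 0.2106        # steric amplitude: an overlapping pair separates to d in one time unit
    l0: float = 0.4           # steric range (= cell diameter)
    k_sigma: float = 400.0    # durotaxis reorientation gain
    Drot: float = 0.1         # rotational diffusion coefficient

    # --- substrate mechanics ----------------------------------------
    eta: float = 1.0          # substrate friction coefficient
    E0: float = 1.0           # elastic modulus scale
    eps: float = 0.5          # elasticity variation with rho
    T0: float = 40.0          # traction dipole amplitude: steady |u| ~ 0.05 one diameter away
    lT: float = 0.05          # traction lobe width (= d/8)

    # --- enzyme kinetics and degradation ----------------------------
    DC: float = 27.648        # MMP diffusion coefficient
    nuC: float = 1.0          # per-cell MMP production amplitude (sets the C scale)
    gamma1: float = 0.792     # MMP consumption by degradation
    beta: float = 28.8        # MMP background decay
    gamma2: float = 45.0      # substrate degradation rate (arrest mid-observation-window)

    # --- condition toggles ------------------------------------------
    durotaxis_on: bool = True
    degradation_on: bool = True

    # --- numerics ----------------------------------------------------
    dt: float = 5e-3          # time step
    dx: float = 0.1           # grid spacing
    T_end: float = 50.0       # final time
    seed: int = 0             # RNG seed
    gs_tol: float = 1e-8      # Gauss-Seidel relative residual tolerance
    gs_max_iter: int = 0      # 0 -> 10*N at construction
    gs_omega: float = 0.0     # over-relaxation; 1.0 = plain Gauss-Seidel, <=0 = auto

    # --- analysis ----------------------------------------------------
    cutoff: float = 2.0       # cluster neighbor cutoff (50 um = 2 units)
    record_every: int = 20    # recording cadence in steps (0.1 time units)

    def __post_init__(self) -> None:
        positive = [
            "Lstar", "d", "Vprop", "l0", "eta", "E0", "eps",
            "T0", "lT", "DC", "nuC", "gamma1", "beta", "gamma2", "dt", "dx",
            "T_end", "gs_tol", "cutoff",
        ]
        for name in positive:
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
                raise ValueError(f"parameter {name!r} must be a positive finite number, got {value}")
        for name in ("F0", "k_sigma", "Drot"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value >= 0):
                raise ValueError(f"parameter {name!r} must be nonnegative, got {value}")
        if self.Nc <= 0:
            raise ValueError(f"parameter 'Nc' must be a positive integer, got {self.Nc}")
        if not self.d < self.Lstar:
            raise ValueError(f"cell diameter d={self.d} must be smaller than the box Lstar={self.Lstar}")
        if not self.gs_omega < 2:
            raise ValueError(f"parameter 'gs_omega' must be below 2, got {self.gs_omega}")
        if self.record_every <= 0:
            raise ValueError(f"parameter 'record_every' must be positive, got {self.record_every}")
        n_float = self.Lstar / self.dx
        n = round(n_float)
        if abs(n_float - n) > 1e-9 * n_float or n < 4:
            raise ValueError(
                f"grid spacing dx={self.dx} must divide the box side Lstar={self.Lstar} "
                "into at least 4 nodes"
            )
        if self.gs_max_iter <= 0:
            self.gs_max_iter = 10 * n

    @property
    def N(self) -> int:
        """Number of grid nodes per side."""
        return round(self.Lstar / self.dx)

    @property
    def condition(self) -> tuple[bool, bool]:
        """(durotaxis_on, degradation_on) condition tuple."""
        return (self.durotaxis_on, self.degradation_on)

    def replace(self, **changes: Any) -> "ModelParams":
        """Return a validated copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, record: Mapping[str, Any]) -> "ModelParams":
        """Build parameters from a flat mapping.

        A nested ``dimensional:`` block may carry Table-style SI values
        (keys of :data:`DIMENSIONAL_DEFAULTS`); those are converted with
        :func:`nondimensionalize` before the flat nondimensional keys,
        which take precedence, are applied.
        """
        record = dict(record)
        values: dict[str, Any] = {}
        dimensional = record.pop("dimensional", None)
        if dimensional:
            values.update(nondimensionalize(dimensional))
        known = {f.name for f in dataclasses.fields(cls)}
        for key, value in record.items():
            if key not in known:
                raise ValueError(f"unknown parameter {key!r}")
            values[key] = value
        values = {k: v for k, v in values.items() if k in known}
        return cls(**values)

    @classmethod
    def from_yaml(cls, path: str) -> "ModelParams":
        """Load parameters from a flat YAML config file."""
        with open(path) as fh:
            record = yaml.safe_load(fh) or {}
        if not isinstance(record, Mapping):
            raise ValueError(f"config {path!r} must be a mapping")
        return cls.from_dict(record)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_params(**overrides: Any) -> ModelParams:
    """Reference parameter set with optional field overrides."""
    return ModelParams(**overrides)
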