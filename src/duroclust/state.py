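"""Agent and substrate state containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ModelParams


@dataclass(frozen=True)
class CellState:
    """A single cell: center-of-mass position and propulsion angle.

    The position lives on the periodic box ``[0, Lstar)^2`` (length unit
    = 25 um); the orientation ``phi`` is the angle of the propulsion
    direction ``p = (cos phi, sin phi)``.
    """

    x: float
    y: float
    phi: float

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y])

    @property
    def p(self) -> np.ndarray:
        """Unit propulsion direction."""
        return np.array([np.cos(self.phi), np.sin(self.phi)])


class Cells:
    """Array-backed collection of cell states.

    Positions are stored as an ``(Nc, 2)`` array wrapped into
    ``[0, Lstar)``; orientations as an ``(Nc,)`` array of angles.
    Supports ``len`` and indexing (returning :class:`CellState`).
    """

    def __init__(self, positions: np.ndarray, phi: np.ndarray, Lstar: float):
        positions = np.asarray(positions, dtype=float)
        phi = np.asarray(phi, dtype=float)
        if positions.ndim != 2 or positions.shape[1] != 2:
            raise ValueError("positions must have shape (Nc, 2)")
        if phi.shape != (positions.shape[0],):
            raise ValueError("phi must have shape (Nc,)")
        if not np.all(np.isfinite(positions)) or not np.all(np.isfinite(phi)):
            raise ValueError("cell state must be finite")
        self.positions = np.mod(positions, Lstar)
        self.phi = phi
        self.Lstar = float(Lstar)

    def __len__(self) -> int:
        return self.positions.shape[0]

    def __getitem__(self, i: int) -> CellState:
        return CellState(self.positions[i, 0], self.positions[i, 1], self.phi[i])

    def __iter__(self):
        return (self[i] for i in range(len(self)))

    @property
    def p(self) -> np.ndarray:
        """(Nc, 2) array of unit propulsion directions."""
        return np.column_stack([np.cos(self.phi), np.sin(self.phi)])

    def copy(self) -> "Cells":
        return Cells(self.positions.copy(), self.phi.copy(), self.Lstar)

    @classmethod
    def from_states(cls, states: list[CellState], Lstar: float) -> "Cells":
        pos = np.array([[s.x, s.y] for s in states], dtype=float)
        phi = np.array([s.phi for s in states], dtype=float)
        return cls(pos, phi, Lstar)


@dataclass
class SubstrateFields:
    """Substrate displacement, enzyme concentration and integrity fields.

    All three live on one ``N x N`` periodic grid with node ``(i, j)``
    at ``x = (i*dx, j*dx)`` (0-based).  ``rho`` is the substrate order
    parameter (1 = intact collagen, 0 = fully degraded), ``C`` the MMP
    concentration (nonnegative), and ``(ux, uy)`` the in-plane
    displacement.
    """

    N: int
    dx: float
    ux: np.ndarray = field(default=None)  # type: ignore[assignment]
    uy: np.ndarray = field(default=None)  # type: ignore[assignment]
    C: np.ndarray = field(default=None)   # type: ignore[assignment]
    rho: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.N < 4:
            raise ValueError(f"grid must have at least 4 nodes per side, got N={self.N}")
        if not self.dx > 0:
            raise ValueError(f"grid spacing must be positive, got dx={self.dx}")
        shape = (self.N, self.N)
        for name, default in (("ux", 0.0), ("uy", 0.0), ("C", 0.0), ("rho", 1.0)):
            value = getattr(self, name)
            if value is None:
                setattr(self, name, np.full(shape, default))
            else:
                value = np.asarray(value, dtype=float)
                if value.shape != shape:
                    raise ValueError(f"field {name!r} must have shape {shape}, got {value.shape}")
                setattr(self, name, value)
        self.validate()

    def validate(self) -> None:
        """Check the field invariants; raise ``ValueError`` on breach."""
        for name in ("ux", "uy", "C", "rho"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"field {name!r} contains non-finite values")
        if np.any(self.C < 0):
            raise ValueError("MMP concentration C must be nonnegative")
        if np.any(self.rho < 0) or np.any(self.rho > 1):
            raise ValueError("substrate order parameter rho must lie in [0, 1]")

    @property
    def Lstar(self) -> float:
        return self.N * self.dx

    def copy(self) -> "SubstrateFields":
        return SubstrateFields(
            self.N, self.dx, self.ux.copy(), self.uy.copy(), self.C.copy(), self.rho.copy()
        )


def init_state(params: ModelParams, rng: np.random.Generator) -> tuple[Cells, SubstrateFields]:
    """Draw the initial configuration.

    Cell positions are i.i.d. uniform on the box, orientations uniform
    on ``[0, 2*pi)``; the substrate starts unperturbed (``rho = 1``,
    ``u = 0``) with no enzyme present (``C = 0``).
    """
    if params.Nc <= 0:
        raise ValueError(f"Nc must be positive, got {params.Nc}")
    positions = rng.uniform(0.0, params.Lstar, size=(params.Nc, 2))
    phi = rng.uniform(0.0, 2.0 * np.pi, size=params.Nc)
    cells = Cells(positions, phi, params.Lstar)
    fields = SubstrateFields(params.N, params.dx)
    return cells, fields
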