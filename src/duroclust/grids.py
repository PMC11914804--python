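"""Periodic finite-difference operators and the semi-implicit time step.

The two linear operators of the continuum part of the model — enzyme
diffusion ``DC*Laplacian`` and the elastic divergence
``(1/eta) div sigma`` with ``sigma = mu (grad u + grad u^T)`` and a
spatially varying shear coefficient ``mu(x) = E0*(1 + eps*rho(x))/2`` —
are discretized in flux form on one uniform periodic grid, so both
annihilate constant fields and conserve the grid mean.

The backward-Euler step ``(I - dt*L) f_{n+1} = f_n + dt*g(f_n)`` is
solved by red-black ordered Gauss-Seidel iteration, optionally
over-relaxed (``omega > 1``), warm-started from the current field.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from . import _kernels


class SolverError(RuntimeError):
    """Raised when the Gauss-Seidel iteration fails to converge."""

    def __init__(self, message: str, residual: float, iterations: int):
        super().__init__(f"{message} (residual {residual:.3e} after {iterations} sweeps)")
        self.residual = residual
        self.iterations = iterations


@dataclass
class PeriodicGrid:
    """A scalar or 2-vector field sampled on an N x N periodic grid."""

    N: int
    dx: float
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.N < 4:
            raise ValueError(f"grid needs at least 4 nodes per side, got N={self.N}")
        if not self.dx > 0:
            raise ValueError(f"grid spacing must be positive, got dx={self.dx}")
        self.values = np.asarray(self.values, dtype=float)
        ok_shapes = {(self.N, self.N), (2, self.N, self.N)}
        if self.values.shape not in ok_shapes:
            raise ValueError(
                f"field shape {self.values.shape} incompatible with N={self.N}"
            )

    @property
    def Lstar(self) -> float:
        return self.N * self.dx


def laplacian(field: Union[PeriodicGrid, np.ndarray], dx: float | None = None) -> np.ndarray:
    """Five-point periodic Laplacian of a scalar field.

    Accepts a :class:`PeriodicGrid` or a raw square array plus ``dx``.
    """
    if isinstance(field, PeriodicGrid):
        values, dx = field.values, field.dx
    else:
        values = np.asarray(field, dtype=float)
        if dx is None:
            raise ValueError("dx is required when passing a raw array")
    if not np.all(np.isfinite(values)):
        raise ValueError("laplacian input must be finite")
    return _kernels.apply_diffusion_op(values, 1.0, dx)


def elastic_divergence(
    ux: np.ndarray, uy: np.ndarray, mu: np.ndarray, dx: float
) -> tuple[np.ndarray, np.ndarray]:
    """``div sigma`` for ``sigma = mu (grad u + grad u^T)``, flux form.

    ``mu`` is the spatially varying shear coefficient
    ``E0*(1 + eps*rho)/2`` and must be strictly positive (intact or
    partially degraded substrate always has ``mu >= E0/2``).
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("shear coefficient mu must be strictly positive everywhere")
    for name, f in (("ux", ux), ("uy", uy)):
        if not np.all(np.isfinite(f)):
            raise ValueError(f"{name} must be finite")
    return _kernels.apply_elastic_op(
        np.asarray(ux, dtype=float), np.asarray(uy, dtype=float), mu, dx
    )


class DiffusionOperator:
    """Linear operator handle ``L = DC * Laplacian`` on a periodic grid."""

    def __init__(self, DC: float, dx: float):
        if not DC > 0:
            raise ValueError(f"diffusivity must be positive, got {DC}")
        self.DC = DC
        self.dx = dx

    def apply(self, field: np.ndarray) -> np.ndarray:
        return _kernels.apply_diffusion_op(field, self.DC, self.dx)

    def auto_omega(self, dt: float) -> float:
        """Near-optimal red-black over-relaxation factor for this system.

        Uses the classical SOR relation ``omega = 2/(1 + sqrt(1 - mu^2))``
        with the Jacobi spectral-radius bound ``mu = 4a/(1 + 4a)``,
        ``a = dt*DC/dx^2``.
        """
        a = dt * self.DC / (self.dx * self.dx)
        mu = 4.0 * a / (1.0 + 4.0 * a)
        return 2.0 / (1.0 + np.sqrt(1.0 - mu * mu))

    def solve(self, field, rhs, dt, tol, max_iter, omega):
        a = dt * self.DC / (self.dx * self.dx)
        if omega <= 0:
            omega = self.auto_omega(dt)
        tol_abs = tol * (1.0 + np.abs(rhs).max())
        out = field.copy()
        iters, res = _kernels.solve_diffusion_gs(out, rhs, a, tol_abs, max_iter, omega)
        return out, iters, res, tol_abs


class ElasticOperator:
    """Linear operator handle ``L = (1/eta) div sigma`` on a periodic grid."""

    def __init__(self, mu: np.ndarray, eta: float, dx: float):
        mu = np.asarray(mu, dtype=float)
        if np.any(mu <= 0):
            raise ValueError("shear coefficient mu must be strictly positive everywhere")
        if not eta > 0:
            raise ValueError(f"friction coefficient must be positive, got {eta}")
        self.mu = mu
        self.eta = eta
        self.dx = dx
        self._mux, self._muy = _kernels.half_node_mu(mu)

    def apply(self, field: np.ndarray) -> np.ndarray:
        ax, ay = _kernels.apply_elastic_op(field[0], field[1], self.mu, self.dx)
        return np.stack([ax, ay]) / self.eta

    def auto_omega(self, dt: float) -> float:
        """Near-optimal over-relaxation factor from the diagonal bound."""
        b = dt / self.eta
        diag = 6.0 * float(self.mu.max()) / (self.dx * self.dx)
        mu_j = b * diag / (1.0 + b * diag)
        return 2.0 / (1.0 + np.sqrt(1.0 - mu_j * mu_j))

    def solve(self, field, rhs, dt, tol, max_iter, omega):
        b = dt / self.eta
        if omega <= 0:
            omega = self.auto_omega(dt)
        tol_abs = tol * (1.0 + np.abs(rhs).max())
        ux = field[0].copy()
        uy = field[1].copy()
        iters, res = _kernels.solve_elastic_gs(
            ux, uy, self._mux, self._muy, rhs[0], rhs[1], b, self.dx,
            tol_abs, max_iter, omega,
        )
        return np.stack([ux, uy]), iters, res, tol_abs


def semi_implicit_step(
    field: np.ndarray,
    linear_op: Union[DiffusionOperator, ElasticOperator],
    forcing: np.ndarray,
    dt: float,
    *,
    tol: float = 1e-8,
    max_iter: int | None = None,
    omega: float = 0.0,
    guess: np.ndarray | None = None,
) -> np.ndarray:
    """One backward-Euler step ``(I - dt*L) f_{n+1} = f_n + dt*forcing``.

    The linear system is solved by red-black Gauss-Seidel sweeps,
    warm-started from ``field``, until the max-norm residual drops below
    ``tol*(1 + max|rhs|)``.  ``omega`` is the over-relaxation factor:
    1 gives the plain Gauss-Seidel sweep, values in (1, 2) accelerate
    it, and any nonpositive value selects a near-optimal factor from
    the operator's diagonal-dominance ratio.  ``guess`` optionally seeds
    the iteration (e.g. an extrapolation of previous steps); the solve
    is warm-started from ``field`` itself otherwise.

    Raises
    ------
    SolverError
        If the iteration does not converge within ``max_iter`` sweeps.
    ValueError
        On non-finite input.
    """
    field = np.asarray(field, dtype=float)
    forcing = np.asarray(forcing, dtype=float)
    if not dt > 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if not np.all(np.isfinite(field)) or not np.all(np.isfinite(forcing)):
        raise ValueError("semi-implicit step received non-finite input")
    if max_iter is None:
        max_iter = 10 * field.shape[-1]
    rhs = field + dt * forcing
    start = field if guess is None else np.asarray(guess, dtype=float)
    out, iters, res, tol_abs = linear_op.solve(start, rhs, dt, tol, max_iter, omega)
    if res > tol_abs:
        raise SolverError("Gauss-Seidel iteration did not converge", res, iters)
    return out
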