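"""Model forces, torques, sources, and the coupled time stepper.

One time step advances, in this fixed order:

1. the cell traction field is assembled from the current cell states;
2. the substrate displacement ``u`` takes a semi-implicit step of
   ``eta*du/dt = div sigma + T`` with stiffness ``mu = E0*(1+eps*rho)/2``;
3. the enzyme concentration ``C`` takes a semi-implicit diffusion step
   with the production/consumption terms treated explicitly;
4. the substrate order parameter ``rho`` decays by the exact exponential
   of ``drho/dt = -gamma2*C*rho`` with ``C`` frozen over the step;
5. cell positions move by explicit Euler (propulsion scaled by the local
   ``rho``, plus steric repulsion) and orientations by the durotaxis
   torque plus an Euler-Maruyama rotational-diffusion increment.

Durotaxis samples the displacement magnitude at the two lateral sides of
the cell and turns it toward the side with the larger displacement; with
degradation this also makes cells follow previously degraded, softened
trails.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .grids import DiffusionOperator, ElasticOperator, SolverError, semi_implicit_step
from .params import ModelParams
from .state import Cells, CellState, SubstrateFields, init_state

SOURCE_CUTOFF_FACTOR = 4.0   # truncate the production Gaussian at 4*d
ARREST_RHO = 0.01            # local-rho threshold defining arrest
ARREST_PERSIST = 10          # consecutive frames below threshold


@dataclass
class TractionField:
    """Summed cell traction on the grid, ``T(x) = sum_i That_i(x) p(phi_i)``."""

    Tx: np.ndarray
    Ty: np.ndarray


@dataclass
class StepDiagnostics:
    """Per-frame observables recorded during a run."""

    time: float
    mean_speed: float
    mean_local_rho: float
    degraded_percent: float
    arrested: bool


def steric_force(ri: np.ndarray, rj: np.ndarray, params: ModelParams) -> np.ndarray:
    """Soft Gaussian repulsion exerted on cell *i* by cell *j*.

    Derivative of the pair potential ``Pi(r) = F0*exp(-r^2/l0^2)`` along
    the minimal-image separation; coincident cells feel zero force (the
    gradient vanishes at the origin).
    """
    L = params.Lstar
    disp = np.asarray(rj, dtype=float) - np.asarray(ri, dtype=float)
    disp -= L * np.round(disp / L)
    r2 = float(disp @ disp)
    if r2 == 0.0:
        import warnings

        warnings.warn("coincident cells: steric force is zero", stacklevel=2)
        return np.zeros(2)
    return -2.0 * params.F0 / params.l0**2 * np.exp(-r2 / params.l0**2) * disp


def steric_forces(positions: np.ndarray, params: ModelParams) -> np.ndarray:
    """Total steric force on every cell (vectorized pair sum)."""
    if params.F0 == 0.0:
        return np.zeros_like(positions)
    return _kernels.steric_pair_forces(
        np.ascontiguousarray(positions, dtype=float), params.F0, params.l0, params.Lstar
    )


def cell_velocity(
    cell: CellState,
    others: "Cells | list[CellState]",
    rho: np.ndarray,
    params: ModelParams,
) -> np.ndarray:
    """Instantaneous velocity of one cell: ``Vprop*rho(r)*p`` plus steric sum.

    ``rho`` is sampled at the cell center by bilinear interpolation, so
    propulsion is maximal (``Vprop``) on intact substrate and vanishes
    on fully degraded substrate.  ``others`` holds the remaining cells
    (excluding ``cell`` itself).
    """
    pos = cell.position
    if params.degradation_on:
        local = _kernels.bilinear_scalar(np.asarray(rho, dtype=float), pos[0], pos[1], params.dx)
    else:
        local = 1.0
    v = params.Vprop * local * cell.p
    for other in others:
        v = v + steric_force(pos, other.position, params)
    return v


def _all_velocities(cells: Cells, rho: np.ndarray, params: ModelParams) -> np.ndarray:
    pos = np.ascontiguousarray(cells.positions)
    if params.degradation_on:
        local = _kernels.bilinear_scalar_many(rho, pos, params.dx)
    else:
        local = np.ones(len(cells))
    v = params.Vprop * local[:, None] * cells.p
    v += steric_forces(pos, params)
    return v


def durotaxis_rate(
    cell: CellState | tuple[np.ndarray, float],
    ux: np.ndarray,
    uy: np.ndarray,
    params: ModelParams,
) -> float:
    """Durotactic angular rate from the lateral displacement contrast.

    Samples ``|u|`` (bilinear interpolation of the components, then the
    Euclidean norm) at the two side points ``r +- (d/2) e_perp`` where
    ``e_perp = (-sin phi, cos phi)``, and returns
    ``k_sigma * (|u(r + (d/2) e_perp)| - |u(r - (d/2) e_perp)|)``:
    a positive (counterclockwise) rate when the ``+e_perp`` side sits on
    the larger displacement, turning the cell toward it.  Returns 0 when
    durotaxis is switched off.
    """
    if not params.durotaxis_on:
        return 0.0
    if isinstance(cell, CellState):
        pos, phi = cell.position, cell.phi
    else:
        pos, phi = cell
    eperp = np.array([-np.sin(phi), np.cos(phi)])
    h = 0.5 * params.d
    xa = pos + h * eperp
    xb = pos - h * eperp
    ua = _kernels.bilinear_vector(ux, uy, xa[0], xa[1], params.dx)
    ub = _kernels.bilinear_vector(ux, uy, xb[0], xb[1], params.dx)
    return params.k_sigma * (np.hypot(*ua) - np.hypot(*ub))


def rotation_noise(params: ModelParams, rng: np.random.Generator, n: int = 1) -> np.ndarray:
    """Euler-Maruyama rotational-diffusion increments ``sqrt(2*Drot*dt)*z``."""
    if params.Drot == 0.0:
        return np.zeros(n)
    return np.sqrt(2.0 * params.Drot * params.dt) * rng.standard_normal(n)


def traction_field(cells: Cells, fields: SubstrateFields, params: ModelParams) -> TractionField:
    """Summed traction of all cells on the substrate.

    Each cell deposits a contractile-style two-lobe profile along its
    polarization (lobes at ``+-d/4``, Gaussian width ``lT``), truncated
    to the disc of diameter ``d`` around the cell center and re-centered
    node-wise so the per-cell grid sum is exactly zero; every node value
    is parallel to the cell's polarization by construction.
    """
    Tx = np.zeros((fields.N, fields.N))
    Ty = np.zeros((fields.N, fields.N))
    if len(cells) > 0:
        _kernels.deposit_traction(
            Tx, Ty,
            np.ascontiguousarray(cells.positions, dtype=float),
            np.ascontiguousarray(cells.phi, dtype=float),
            params.T0, params.lT, params.d, fields.dx,
        )
    return TractionField(Tx, Ty)


def mmp_source(cells: Cells, fields: SubstrateFields, params: ModelParams) -> np.ndarray:
    """Node-wise enzyme production ``sum_i nuC*exp(-|x - r_i|^2/d^2)``."""
    S = np.zeros((fields.N, fields.N))
    if len(cells) > 0:
        _kernels.deposit_source(
            S, np.ascontiguousarray(cells.positions, dtype=float),
            params.nuC, params.d, fields.dx, SOURCE_CUTOFF_FACTOR,
        )
    return S


def degradation_step(rho: np.ndarray, C: np.ndarray, params: ModelParams) -> np.ndarray:
    """Exact exponential decay ``rho <- rho*exp(-gamma2*C*dt)``.

    With ``C`` frozen over the step the linear decay ODE has this closed
    form, which preserves ``0 <= rho <= 1`` and monotone non-increase
    exactly.  A no-op when degradation is switched off.
    """
    if not params.degradation_on:
        return rho
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("negative enzyme concentration passed to degradation step")
    return rho * np.exp(-params.gamma2 * params.dt * C)


def degraded_area(rho: np.ndarray) -> float:
    """Percent of substrate degraded, ``(1 - mean(rho)) * 100``.

    On a uniform periodic grid the arithmetic node mean equals the
    normalized integral.
    """
    return (1.0 - float(np.mean(rho))) * 100.0


def detect_tdegr(
    times: np.ndarray,
    mean_local_rho: np.ndarray,
    eps_rho: float = ARREST_RHO,
    persist: int = ARREST_PERSIST,
) -> float | None:
    """Arrest time: first frame of a sustained collapse of local substrate.

    Returns the time at which the mean-over-cells local ``rho`` (within
    ``d/2`` of each cell) first drops below ``eps_rho`` and stays below
    for ``persist`` consecutive recorded frames; ``None`` if that never
    happens (e.g. with degradation off).
    """
    times = np.asarray(times, dtype=float)
    series = np.asarray(mean_local_rho, dtype=float)
    if times.size == 0 or series.size != times.size:
        raise ValueError("need matching, non-empty time and rho series")
    below = series < eps_rho
    run = 0
    for k in range(below.size):
        if below[k]:
            run += 1
            if run >= persist:
                return float(times[k - persist + 1])
        else:
            run = 0
    return None


@dataclass
class SimRecord:
    """Time series recorded by :meth:`Simulation.run`."""

    times: np.ndarray
    mean_speed: np.ndarray
    mean_local_rho: np.ndarray
    degraded_percent: np.ndarray
    trajectory: np.ndarray | None  # (frames, Nc, 3): x, y, phi
    tdegr: float | None


class Simulation:
    """The coupled agent-continuum model on a periodic box.

    Parameters
    ----------
    params
        Full nondimensional parameter set.
    rng
        Seeded generator; defaults to ``default_rng(params.seed)``.
    cells, fields
        Optional initial state; drawn by :func:`init_state` otherwise.

    Notes
    -----
    The displacement field only feeds back on the cells through the
    durotaxis torque, so its (costly) elastic solve is skipped when
    durotaxis is off; likewise the enzyme/degradation fields are frozen
    at their initial state when degradation is off.
    """

    def __init__(
        self,
        params: ModelParams,
        rng: np.random.Generator | None = None,
        cells: Cells | None = None,
        fields: SubstrateFields | None = None,
    ):
        self.params = params
        self.rng = rng if rng is not None else np.random.default_rng(params.seed)
        if cells is None or fields is None:
            cells0, fields0 = init_state(params, self.rng)
            cells = cells if cells is not None else cells0
            fields = fields if fields is not None else fields0
        self.cells = cells
        self.fields = fields
        self.time = 0.0
        self.step_index = 0
        self.last_velocities = np.zeros((len(cells), 2))
        self._elastic_op: ElasticOperator | None = None
        self._diffusion_op = DiffusionOperator(params.DC, params.dx)
        # previous fields for the extrapolated solver warm start
        self._prev_u: np.ndarray | None = None
        self._prev_C: np.ndarray | None = None

    # -- helpers -----------------------------------------------------
    def _mu(self) -> np.ndarray:
        p = self.params
        return 0.5 * p.E0 * (1.0 + p.eps * self.fields.rho)

    def _elastic(self) -> ElasticOperator:
        # with degradation the stiffness follows rho and the operator is
        # rebuilt each step; without it the operator is constant
        if not self.params.degradation_on and self._elastic_op is not None:
            return self._elastic_op
        op = ElasticOperator(self._mu(), self.params.eta, self.params.dx)
        if not self.params.degradation_on:
            self._elastic_op = op
        return op

    def local_rho(self) -> np.ndarray:
        """Mean rho over nodes within d/2 of each cell."""
        return _kernels.local_rho_means(
            self.fields.rho, np.ascontiguousarray(self.cells.positions),
            0.5 * self.params.d, self.params.dx,
        )

    # -- the step ----------------------------------------------------
    def step(self) -> None:
        """Advance the coupled system by one time step ``dt``."""
        p = self.params
        f = self.fields
        try:
            if p.durotaxis_on:
                T = traction_field(self.cells, f, p)
                u_now = np.stack([f.ux, f.uy])
                guess = None if self._prev_u is None else 2.0 * u_now - self._prev_u
                u = semi_implicit_step(
                    u_now, self._elastic(),
                    np.stack([T.Tx, T.Ty]) / p.eta, p.dt,
                    tol=p.gs_tol, max_iter=p.gs_max_iter, omega=p.gs_omega,
                    guess=guess,
                )
                self._prev_u = u_now
                f.ux, f.uy = u[0], u[1]

            if p.degradation_on:
                source = mmp_source(self.cells, f, p)
                forcing = source - p.gamma1 * f.C * f.rho - p.beta * f.C
                guess = None if self._prev_C is None else 2.0 * f.C - self._prev_C
                C_prev = f.C
                C_new = semi_implicit_step(
                    f.C, self._diffusion_op, forcing, p.dt,
                    tol=p.gs_tol, max_iter=p.gs_max_iter, omega=p.gs_omega,
                    guess=guess,
                )
                self._prev_C = C_prev
                cmin = C_new.min()
                if cmin < -1e-12 * (1.0 + abs(C_new.max())):
                    raise ValueError(f"enzyme concentration overshot zero ({cmin:.3e})")
                np.clip(C_new, 0.0, None, out=C_new)
                f.C = C_new
                f.rho = degradation_step(f.rho, f.C, p)
        except (SolverError, ValueError) as err:
            raise RuntimeError(f"step {self.step_index} failed: {err}") from err

        # cells: explicit Euler with the updated fields
        v = _all_velocities(self.cells, f.rho, p)
        if p.durotaxis_on:
            rate = _kernels.durotaxis_rates(
                f.ux, f.uy, np.ascontiguousarray(self.cells.positions),
                np.ascontiguousarray(self.cells.phi), p.k_sigma, p.d, p.dx,
            )
        else:
            rate = np.zeros(len(self.cells))
        noise = rotation_noise(p, self.rng, len(self.cells))
        self.cells.positions[:] = np.mod(self.cells.positions + p.dt * v, p.Lstar)
        self.cells.phi[:] = self.cells.phi + p.dt * rate + noise
        if not np.all(np.isfinite(self.cells.positions)) or not np.all(np.isfinite(self.cells.phi)):
            raise RuntimeError(f"step {self.step_index}: non-finite cell state")
        self.last_velocities = v
        self.time += p.dt
        self.step_index += 1

    def diagnostics(self) -> StepDiagnostics:
        local = self.local_rho()
        return StepDiagnostics(
            time=self.time,
            mean_speed=float(np.mean(np.hypot(self.last_velocities[:, 0], self.last_velocities[:, 1]))),
            mean_local_rho=float(np.mean(local)),
            degraded_percent=degraded_area(self.fields.rho),
            arrested=bool(np.mean(local) < ARREST_RHO),
        )

    def run(
        self,
        T_end: float | None = None,
        *,
        record_trajectory: bool = True,
        stop_after_arrest: bool = False,
        arrest_margin: float = 5.0,
    ) -> SimRecord:
        """Step to ``T_end``, recording diagnostics every ``record_every`` steps.

        With ``stop_after_arrest`` the run continues for ``arrest_margin``
        time units past the first detected arrest and then stops (all
        cluster observables are frozen once the cells are immobilized).
        """
        p = self.params
        T_end = p.T_end if T_end is None else T_end
        n_steps = int(round(T_end / p.dt))
        times = [self.time]
        speed = [float(np.mean(np.hypot(self.last_velocities[:, 0], self.last_velocities[:, 1])))]
        local = [float(np.mean(self.local_rho()))]
        degraded = [degraded_area(self.fields.rho)]
        traj = [np.column_stack([self.cells.positions, self.cells.phi])] if record_trajectory else None
        stop_time = np.inf
        tdegr: float | None = None
        for k in range(self.step_index, n_steps):
            self.step()
            if (k + 1) % p.record_every == 0 or k + 1 == n_steps:
                d = self.diagnostics()
                times.append(d.time)
                speed.append(d.mean_speed)
                local.append(d.mean_local_rho)
                degraded.append(d.degraded_percent)
                if traj is not None:
                    traj.append(np.column_stack([self.cells.positions, self.cells.phi]))
                if stop_after_arrest and tdegr is None:
                    tdegr = detect_tdegr(np.array(times), np.array(local))
                    if tdegr is not None:
                        stop_time = tdegr + arrest_margin
                if self.time >= stop_time:
                    break
        times_arr = np.array(times)
        local_arr = np.array(local)
        if tdegr is None:
            tdegr = detect_tdegr(times_arr, local_arr)
        return SimRecord(
            times=times_arr,
            mean_speed=np.array(speed),
            mean_local_rho=local_arr,
            degraded_percent=np.array(degraded),
            trajectory=np.array(traj) if traj is not None else None,
            tdegr=tdegr,
        )
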