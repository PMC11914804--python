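"""Numba kernels for the grid solvers and agent-field coupling.

Array convention: scalar fields are ``f[i, j]`` with node ``(i, j)`` at
``x = (i*dx, j*dx)``, periodic in both indices.  All solvers use
red-black ordered Gauss-Seidel sweeps (optionally over-relaxed) so the
result is independent of traversal order.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "solve_diffusion_gs",
    "solve_elastic_gs",
    "apply_diffusion_op",
    "apply_elastic_op",
    "deposit_traction",
    "deposit_source",
    "steric_pair_forces",
    "bilinear_scalar",
    "bilinear_vector",
    "local_rho_means",
]


@njit(cache=True)
def apply_diffusion_op(f, DC, dx):
    """DC * five-point Laplacian of a periodic scalar field."""
    N = f.shape[0]
    out = np.empty_like(f)
    c = DC / (dx * dx)
    for i in range(N):
        im = (i - 1) % N
        ip = (i + 1) % N
        for j in range(N):
            jm = (j - 1) % N
            jp = (j + 1) % N
            out[i, j] = c * (f[ip, j] + f[im, j] + f[i, jp] + f[i, jm] - 4.0 * f[i, j])
    return out


@njit(cache=True, fastmath=True)
def _diffusion_residual(C, rhs, a):
    N = C.shape[0]
    res = 0.0
    for i in range(N):
        im = (i - 1) % N
        ip = (i + 1) % N
        for j in range(N):
            jm = (j - 1) % N
            jp = (j + 1) % N
            r = rhs[i, j] - (1.0 + 4.0 * a) * C[i, j] + a * (
                C[ip, j] + C[im, j] + C[i, jp] + C[i, jm]
            )
            if abs(r) > res:
                res = abs(r)
    return res


@njit(cache=True, fastmath=True)
def _diffusion_sweep(C, rhs, a, omega):
    N = C.shape[0]
    diag = 1.0 + 4.0 * a
    for color in range(2):
        for i in range(N):
            im = (i - 1) % N
            ip = (i + 1) % N
            jstart = (color + i) % 2
            for j in range(jstart, N, 2):
                jm = (j - 1) % N
                jp = (j + 1) % N
                new = (rhs[i, j] + a * (C[ip, j] + C[im, j] + C[i, jp] + C[i, jm])) / diag
                C[i, j] += omega * (new - C[i, j])


@njit(cache=True, fastmath=True)
def solve_diffusion_gs(C, rhs, a, tol_abs, max_iter, omega):
    """Solve ``(I - a*Delta_h) C = rhs`` in place by red-black Gauss-Seidel.

    ``a = dt*DC/dx^2``.  Returns ``(iterations, residual)``; the caller
    checks convergence against ``tol_abs`` (max-norm).  The true
    max-norm residual is evaluated every other sweep and on exit.
    """
    it = 0
    res = _diffusion_residual(C, rhs, a)
    while res > tol_abs and it < max_iter:
        n_do = min(2, max_iter - it)
        for _ in range(n_do):
            _diffusion_sweep(C, rhs, a, omega)
        it += n_do
        res = _diffusion_residual(C, rhs, a)
    return it, res


@njit(cache=True)
def half_node_mu(mu):
    """Half-node shear coefficients ``mux[i,j] = mu_{i+1/2,j}``, ``muy[i,j] = mu_{i,j+1/2}``."""
    N = mu.shape[0]
    mux = np.empty_like(mu)
    muy = np.empty_like(mu)
    for i in range(N):
        ip = (i + 1) % N
        for j in range(N):
            jp = (j + 1) % N
            mux[i, j] = 0.5 * (mu[i, j] + mu[ip, j])
            muy[i, j] = 0.5 * (mu[i, j] + mu[i, jp])
    return mux, muy


@njit(cache=True, fastmath=True, inline="always")
def _elastic_node(ux, uy, mux, muy, dx, i, j):
    """(A u)_x, (A u)_y and the two diagonal coefficients at node (i, j).

    ``A = div sigma`` with ``sigma = mu (grad u + grad u^T)`` in flux
    form: fluxes of ``mu * strain`` at half nodes, differenced back to
    the node, so constants are annihilated and the grid mean conserved.
    """
    N = ux.shape[0]
    im = (i - 1) % N
    ip = (i + 1) % N
    jm = (j - 1) % N
    jp = (j + 1) % N
    inv2 = 1.0 / (dx * dx)

    # x component: d/dx(2 mu dux/dx) + d/dy(mu (dux/dy + duy/dx))
    ax = (
        2.0 * mux[i, j] * (ux[ip, j] - ux[i, j])
        - 2.0 * mux[im, j] * (ux[i, j] - ux[im, j])
        + muy[i, j] * (ux[i, jp] - ux[i, j])
        - muy[i, jm] * (ux[i, j] - ux[i, jm])
    ) * inv2
    # cross flux (duy/dx at y half nodes, averaged from centered differences)
    dxuy_p = (uy[ip, j] + uy[ip, jp] - uy[im, j] - uy[im, jp]) * 0.25
    dxuy_m = (uy[ip, jm] + uy[ip, j] - uy[im, jm] - uy[im, j]) * 0.25
    ax += (muy[i, j] * dxuy_p - muy[i, jm] * dxuy_m) * inv2

    # y component: d/dy(2 mu duy/dy) + d/dx(mu (duy/dx + dux/dy))
    ay = (
        2.0 * muy[i, j] * (uy[i, jp] - uy[i, j])
        - 2.0 * muy[i, jm] * (uy[i, j] - uy[i, jm])
        + mux[i, j] * (uy[ip, j] - uy[i, j])
        - mux[im, j] * (uy[i, j] - uy[im, j])
    ) * inv2
    dyux_p = (ux[i, jp] + ux[ip, jp] - ux[i, jm] - ux[ip, jm]) * 0.25
    dyux_m = (ux[im, jp] + ux[i, jp] - ux[im, jm] - ux[i, jm]) * 0.25
    ay += (mux[i, j] * dyux_p - mux[im, j] * dyux_m) * inv2

    diag_x = (2.0 * mux[i, j] + 2.0 * mux[im, j] + muy[i, j] + muy[i, jm]) * inv2
    diag_y = (2.0 * muy[i, j] + 2.0 * muy[i, jm] + mux[i, j] + mux[im, j]) * inv2
    return ax, ay, diag_x, diag_y


@njit(cache=True)
def apply_elastic_op(ux, uy, mu, dx):
    """Apply ``(1/eta=1) div sigma`` to a periodic displacement field."""
    N = ux.shape[0]
    mux, muy = half_node_mu(mu)
    out_x = np.empty_like(ux)
    out_y = np.empty_like(uy)
    for i in range(N):
        for j in range(N):
            ax, ay, _, _ = _elastic_node(ux, uy, mux, muy, dx, i, j)
            out_x[i, j] = ax
            out_y[i, j] = ay
    return out_x, out_y


@njit(cache=True, fastmath=True)
def _elastic_residual(ux, uy, mux, muy, rhs_x, rhs_y, b, dx):
    N = ux.shape[0]
    res = 0.0
    for i in range(N):
        for j in range(N):
            ax, ay, _, _ = _elastic_node(ux, uy, mux, muy, dx, i, j)
            rx = rhs_x[i, j] - ux[i, j] + b * ax
            ry = rhs_y[i, j] - uy[i, j] + b * ay
            if abs(rx) > res:
                res = abs(rx)
            if abs(ry) > res:
                res = abs(ry)
    return res


@njit(cache=True, fastmath=True)
def _elastic_sweep(ux, uy, mux, muy, rhs_x, rhs_y, b, dx, omega):
    N = ux.shape[0]
    for color in range(2):
        for i in range(N):
            jstart = (color + i) % 2
            for j in range(jstart, N, 2):
                ax, ay, dxx, dyy = _elastic_node(ux, uy, mux, muy, dx, i, j)
                off_x = ax + dxx * ux[i, j]
                off_y = ay + dyy * uy[i, j]
                new_x = (rhs_x[i, j] + b * off_x) / (1.0 + b * dxx)
                new_y = (rhs_y[i, j] + b * off_y) / (1.0 + b * dyy)
                ux[i, j] += omega * (new_x - ux[i, j])
                uy[i, j] += omega * (new_y - uy[i, j])


@njit(cache=True, fastmath=True)
def solve_elastic_gs(ux, uy, mux, muy, rhs_x, rhs_y, b, dx, tol_abs, max_iter, omega):
    """Solve ``(I - b*A) u = rhs`` in place, ``A = div sigma``, ``b = dt/eta``.

    Red-black Gauss-Seidel on the coupled two-component system; the
    cross-derivative coupling has no same-node term, so components are
    updated with their own diagonals.  Returns ``(iterations, residual)``;
    the true max-norm residual is evaluated every other sweep and on exit.
    """
    it = 0
    res = _elastic_residual(ux, uy, mux, muy, rhs_x, rhs_y, b, dx)
    while res > tol_abs and it < max_iter:
        n_do = min(2, max_iter - it)
        for _ in range(n_do):
            _elastic_sweep(ux, uy, mux, muy, rhs_x, rhs_y, b, dx, omega)
        it += n_do
        res = _elastic_residual(ux, uy, mux, muy, rhs_x, rhs_y, b, dx)
    return it, res


@njit(cache=True)
def deposit_traction(Tx, Ty, positions, phi, T0, lT, d, dx):
    """Accumulate the summed cell traction onto the grid.

    Each cell contributes a two-lobe scalar profile along its axis
    (lobes at ``+-d/4``, Gaussian width ``lT``), truncated to the disc
    ``|x - r_i| < d/2`` and discretely re-centered to exact zero sum,
    multiplied by the unit polarization vector.
    """
    N = Tx.shape[0]
    L = N * dx
    half = 0.5 * d
    r2max = half * half
    hw = int(np.ceil(half / dx)) + 1
    nmax = (2 * hw + 1) * (2 * hw + 1)
    vals = np.empty(nmax)
    nodes_i = np.empty(nmax, dtype=np.int64)
    nodes_j = np.empty(nmax, dtype=np.int64)
    for c in range(positions.shape[0]):
        cx = positions[c, 0]
        cy = positions[c, 1]
        px = np.cos(phi[c])
        py = np.sin(phi[c])
        fx = cx + 0.25 * d * px  # front lobe center
        fy = cy + 0.25 * d * py
        bx = cx - 0.25 * d * px  # back lobe center
        by = cy - 0.25 * d * py
        i0 = int(np.floor(cx / dx))
        j0 = int(np.floor(cy / dx))
        count = 0
        total = 0.0
        for di in range(-hw, hw + 1):
            i = (i0 + di) % N
            xi = i * dx
            rx = xi - cx
            rx -= L * np.round(rx / L)
            for dj in range(-hw, hw + 1):
                j = (j0 + dj) % N
                yj = j * dx
                ry = yj - cy
                ry -= L * np.round(ry / L)
                if rx * rx + ry * ry >= r2max:
                    continue
                gfx = xi - fx
                gfx -= L * np.round(gfx / L)
                gfy = yj - fy
                gfy -= L * np.round(gfy / L)
                gbx = xi - bx
                gbx -= L * np.round(gbx / L)
                gby = yj - by
                gby -= L * np.round(gby / L)
                v = T0 * (
                    np.exp(-(gfx * gfx + gfy * gfy) / (lT * lT))
                    - np.exp(-(gbx * gbx + gby * gby) / (lT * lT))
                )
                vals[count] = v
                nodes_i[count] = i
                nodes_j[count] = j
                total += v
                count += 1
        if count == 0:
            continue
        mean = total / count
        for k in range(count):
            v = vals[k] - mean
            Tx[nodes_i[k], nodes_j[k]] += v * px
            Ty[nodes_i[k], nodes_j[k]] += v * py
    return Tx, Ty


@njit(cache=True, fastmath=True)
def deposit_source(S, positions, nuC, d, dx, cutoff_factor):
    """Accumulate the per-cell MMP production ``nuC*exp(-r^2/d^2)``.

    Gaussian weights are truncated beyond ``cutoff_factor * d`` (the
    tail there is ``exp(-cutoff_factor^2)`` of the peak).
    """
    N = S.shape[0]
    L = N * dx
    rad = cutoff_factor * d
    r2max = rad * rad
    inv_d2 = 1.0 / (d * d)
    hw = int(np.ceil(rad / dx))
    for c in range(positions.shape[0]):
        cx = positions[c, 0]
        cy = positions[c, 1]
        i0 = int(np.floor(cx / dx))
        j0 = int(np.floor(cy / dx))
        for di in range(-hw, hw + 1):
            i = (i0 + di) % N
            rx = i * dx - cx
            rx -= L * np.round(rx / L)
            for dj in range(-hw, hw + 1):
                j = (j0 + dj) % N
                ry = j * dx - cy
                ry -= L * np.round(ry / L)
                r2 = rx * rx + ry * ry
                if r2 < r2max:
                    S[i, j] += nuC * np.exp(-r2 * inv_d2)
    return S


@njit(cache=True, fastmath=True)
def steric_pair_forces(positions, F0, l0, L):
    """Pairwise Gaussian steric repulsion with minimal-image distances.

    The force on cell *i* from cell *j* is ``dPi/dr`` along the unit
    separation vector with ``Pi(r) = F0*exp(-r^2/l0^2)``, i.e.
    ``-2*F0/l0^2 * exp(-r^2/l0^2) * (r_j - r_i)`` (net repulsion).
    """
    n = positions.shape[0]
    forces = np.zeros((n, 2))
    pref = -2.0 * F0 / (l0 * l0)
    r2max = 25.0 * l0 * l0  # beyond 5*l0 the Gaussian tail is < 1e-10
    for i in range(n):
        for j in range(i + 1, n):
            dx_ = positions[j, 0] - positions[i, 0]
            dy_ = positions[j, 1] - positions[i, 1]
            dx_ -= L * np.round(dx_ / L)
            dy_ -= L * np.round(dy_ / L)
            r2 = dx_ * dx_ + dy_ * dy_
            if r2 > r2max:
                continue
            w = pref * np.exp(-r2 / (l0 * l0))
            forces[i, 0] += w * dx_
            forces[i, 1] += w * dy_
            forces[j, 0] -= w * dx_
            forces[j, 1] -= w * dy_
    return forces


@njit(cache=True)
def bilinear_scalar(f, x, y, dx):
    """Bilinear interpolation of a periodic scalar field at (x, y)."""
    N = f.shape[0]
    gx = x / dx
    gy = y / dx
    i0 = int(np.floor(gx))
    j0 = int(np.floor(gy))
    tx = gx - i0
    ty = gy - j0
    i0 %= N
    j0 %= N
    i1 = (i0 + 1) % N
    j1 = (j0 + 1) % N
    return (
        f[i0, j0] * (1 - tx) * (1 - ty)
        + f[i1, j0] * tx * (1 - ty)
        + f[i0, j1] * (1 - tx) * ty
        + f[i1, j1] * tx * ty
    )


@njit(cache=True)
def bilinear_vector(fx, fy, x, y, dx):
    """Bilinear interpolation of a periodic vector field at (x, y)."""
    return bilinear_scalar(fx, x, y, dx), bilinear_scalar(fy, x, y, dx)


@njit(cache=True)
def bilinear_scalar_many(f, positions, dx):
    """Bilinear samples of a periodic scalar field at many points."""
    n = positions.shape[0]
    out = np.empty(n)
    for c in range(n):
        out[c] = bilinear_scalar(f, positions[c, 0], positions[c, 1], dx)
    return out


@njit(cache=True)
def durotaxis_rates(ux, uy, positions, phi, k_sigma, d, dx):
    """Durotactic angular rates for all cells (lateral |u| contrast)."""
    n = positions.shape[0]
    out = np.empty(n)
    h = 0.5 * d
    for c in range(n):
        ex = -np.sin(phi[c])
        ey = np.cos(phi[c])
        xa = positions[c, 0] + h * ex
        ya = positions[c, 1] + h * ey
        xb = positions[c, 0] - h * ex
        yb = positions[c, 1] - h * ey
        uax = bilinear_scalar(ux, xa, ya, dx)
        uay = bilinear_scalar(uy, xa, ya, dx)
        ubx = bilinear_scalar(ux, xb, yb, dx)
        uby = bilinear_scalar(uy, xb, yb, dx)
        out[c] = k_sigma * (np.hypot(uax, uay) - np.hypot(ubx, uby))
    return out


@njit(cache=True)
def local_rho_means(rho, positions, radius, dx):
    """Mean of rho over grid nodes within ``radius`` of each cell center."""
    N = rho.shape[0]
    L = N * dx
    r2max = radius * radius
    hw = int(np.ceil(radius / dx)) + 1
    n = positions.shape[0]
    out = np.empty(n)
    for c in range(n):
        cx = positions[c, 0]
        cy = positions[c, 1]
        i0 = int(np.floor(cx / dx))
        j0 = int(np.floor(cy / dx))
        total = 0.0
        count = 0
        for di in range(-hw, hw + 1):
            i = (i0 + di) % N
            rx = i * dx - cx
            rx -= L * np.round(rx / L)
            for dj in range(-hw, hw + 1):
                j = (j0 + dj) % N
                ry = j * dx - cy
                ry -= L * np.round(ry / L)
                if rx * rx + ry * ry <= r2max:
                    total += rho[i, j]
                    count += 1
        if count == 0:
            out[c] = bilinear_scalar(rho, cx, cy, dx)
        else:
            out[c] = total / count
    return out
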