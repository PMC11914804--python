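"""Forces, torques, sources, degradation, and the coupled stepper."""

import numpy as np
import pytest

from duroclust import (
    Cells,
    CellState,
    ModelParams,
    Simulation,
    SubstrateFields,
    cell_velocity,
    degradation_step,
    degraded_area,
    detect_tdegr,
    durotaxis_rate,
    mmp_source,
    rotation_noise,
    steric_force,
    traction_field,
)


def make_fields(params, rho=None, C=None, ux=None, uy=None):
    return SubstrateFields(params.N, params.dx, ux=ux, uy=uy, C=C, rho=rho)


class TestStericForce:
    def test_magnitude_at_range_l0(self, tiny_params):
        p = tiny_params
        f = steric_force(np.array([5.0, 5.0]), np.array([5.0 + p.l0, 5.0]), p)
        # |dPi/dr| at r = l0 is 2*F0/(l0*e)
        assert np.linalg.norm(f) == pytest.approx(2 * p.F0 / (p.l0 * np.e))
        assert f[0] < 0  # repulsion: points from j toward i

    def test_newtons_third_law(self, tiny_params, rng):
        ri, rj = rng.uniform(0, 6, 2), rng.uniform(0, 6, 2)
        f_ij = steric_force(ri, rj, tiny_params)
        f_ji = steric_force(rj, ri, tiny_params)
        np.testing.assert_allclose(f_ij, -f_ji, atol=1e-14)

    def test_gaussian_tail_negligible(self, tiny_params):
        # |dPi/dr| = 2*F0*r/l0^2 * exp(-r^2/l0^2) is ~1e-10*F0/l0 at
        # r = 5*l0 and drops to ~8e-13 at 5.5*l0
        p = tiny_params
        f = steric_force(np.array([1.0, 1.0]), np.array([1.0 + 5.5 * p.l0, 1.0]), p)
        assert np.linalg.norm(f) < 1e-10 * p.F0 / p.l0

    def test_coincident_cells_zero_with_warning(self, tiny_params):
        with pytest.warns(UserWarning, match="coincident"):
            f = steric_force(np.array([1.0, 1.0]), np.array([1.0, 1.0]), tiny_params)
        np.testing.assert_array_equal(f, 0.0)

    def test_minimal_image(self, tiny_params):
        p = tiny_params
        near = steric_force(np.array([0.1, 1.0]), np.array([p.Lstar - 0.1, 1.0]), p)
        direct = steric_force(np.array([0.1, 1.0]), np.array([-0.1, 1.0]), p)
        np.testing.assert_allclose(near, direct, atol=1e-14)


class TestCellVelocity:
    @pytest.mark.parametrize("rho_value,factor", [(1.0, 1.0), (0.0, 0.0), (0.5, 0.5)])
    def test_propulsion_scales_with_local_rho(self, tiny_params, rho_value, factor):
        p = tiny_params
        fields = make_fields(p, rho=np.full((p.N, p.N), rho_value))
        cell = CellState(3.0, 3.0, 0.3)
        v = cell_velocity(cell, [], fields.rho, p)
        np.testing.assert_allclose(v, factor * p.Vprop * cell.p, atol=1e-14)

    def test_degradation_off_ignores_rho(self, tiny_params):
        p = tiny_params.replace(degradation_on=False)
        fields = make_fields(p, rho=np.full((p.N, p.N), 0.2))
        cell = CellState(3.0, 3.0, 1.0)
        v = cell_velocity(cell, [], fields.rho, p)
        assert np.linalg.norm(v) == pytest.approx(p.Vprop)


class TestDurotaxisRate:
    def test_symmetric_field_no_torque(self, tiny_params):
        p = tiny_params
        # |u| depends on x only; cell points along +x so its two lateral
        # sample points see identical magnitudes
        x = p.dx * np.arange(p.N)
        ux = np.sin(2 * np.pi * x / p.Lstar)[:, None] * np.ones(p.N)
        rate = durotaxis_rate(CellState(3.0, 3.0, 0.0), ux, np.zeros_like(ux), p)
        assert rate == pytest.approx(0.0, abs=1e-12)

    def test_signed_contrast(self, tiny_params):
        p = tiny_params.replace(k_sigma=1.0)
        # |u| = 0.3 on the +e_perp side (here +y), 0.1 on the -e_perp side
        y = p.dx * np.arange(p.N)
        ux = np.where(y >= 3.0, 0.3, 0.1)[None, :] * np.ones((p.N, 1))
        rate = durotaxis_rate(CellState(3.0, 2.9, 0.0), ux, np.zeros_like(ux), p)
        assert rate == pytest.approx(0.2)

    def test_mirror_antisymmetry(self, tiny_params, rng):
        p = tiny_params
        ux = rng.standard_normal((p.N, p.N))
        uy = rng.standard_normal((p.N, p.N))
        cell = CellState(3.0, 3.0, 0.0)
        rate = durotaxis_rate(cell, ux, uy, p)
        # reflect the field across the cell axis (y -> 2*y0 - y); magnitudes swap sides
        j0 = int(round(3.0 / p.dx))
        ux_m = np.take(ux, (2 * j0 - np.arange(p.N)) % p.N, axis=1)
        uy_m = np.take(uy, (2 * j0 - np.arange(p.N)) % p.N, axis=1)
        rate_m = durotaxis_rate(cell, ux_m, uy_m, p)
        assert rate_m == pytest.approx(-rate, rel=1e-9, abs=1e-12)

    def test_off_switch(self, tiny_params, rng):
        p = tiny_params.replace(durotaxis_on=False)
        assert durotaxis_rate(CellState(1.0, 1.0, 0.5), rng.random((p.N, p.N)),
                              rng.random((p.N, p.N)), p) == 0.0


class TestRotationNoise:
    def test_zero_diffusion(self, tiny_params, rng):
        p = tiny_params.replace(Drot=0.0)
        np.testing.assert_array_equal(rotation_noise(p, rng, 100), 0.0)

    def test_increment_variance(self, tiny_params):
        p = tiny_params.replace(Drot=5.0)  # 2*Drot*dt = 0.05 with dt = 5e-3
        draws = rotation_noise(p, np.random.default_rng(0), 100_000)
        assert draws.var() == pytest.approx(2 * p.Drot * p.dt, rel=0.03)

    def test_deterministic_under_seed(self, tiny_params):
        a = rotation_noise(tiny_params, np.random.default_rng(9), 50)
        b = rotation_noise(tiny_params, np.random.default_rng(9), 50)
        np.testing.assert_array_equal(a, b)


class TestTractionField:
    def test_no_cells_zero(self, tiny_params):
        p = tiny_params.replace(dx=0.1)
        fields = make_fields(p)
        cells = Cells(np.empty((0, 2)), np.empty(0), p.Lstar)
        T = traction_field(cells, fields, p)
        assert not T.Tx.any() and not T.Ty.any()

    def test_zero_net_force_per_cell(self):
        p = ModelParams(Nc=1, dx=0.1)
        fields = SubstrateFields(p.N, p.dx)
        cells = Cells(np.array([[10.03, 9.97]]), np.array([0.77]), p.Lstar)
        T = traction_field(cells, fields, p)
        total_abs = np.abs(T.Tx).sum() + np.abs(T.Ty).sum()
        assert total_abs > 0
        assert abs(T.Tx.sum()) <= 1e-10 * total_abs
        assert abs(T.Ty.sum()) <= 1e-10 * total_abs

    def test_parallel_to_polarization(self):
        p = ModelParams(Nc=1, dx=0.1)
        fields = SubstrateFields(p.N, p.dx)
        phi = 1.234
        cells = Cells(np.array([[10.0, 10.0]]), np.array([phi]), p.Lstar)
        T = traction_field(cells, fields, p)
        cross = T.Tx * np.sin(phi) - T.Ty * np.cos(phi)
        np.testing.assert_allclose(cross, 0.0, atol=1e-14)

    def test_support_within_cell_disc(self):
        p = ModelParams(Nc=1, dx=0.1)
        fields = SubstrateFields(p.N, p.dx)
        cells = Cells(np.array([[10.0, 10.0]]), np.array([0.3]), p.Lstar)
        T = traction_field(cells, fields, p)
        ii, jj = np.nonzero(np.hypot(T.Tx, T.Ty))
        dist = np.hypot(ii * p.dx - 10.0, jj * p.dx - 10.0)
        assert dist.max() < p.d / 2


class TestMMPSource:
    def test_peak_value_at_cell_center(self, tiny_params):
        p = tiny_params.replace(dx=0.25, nuC=2.5)
        fields = make_fields(p)
        # cell exactly on a grid node
        cells = Cells(np.array([[3.0, 3.0]]), np.array([0.0]), p.Lstar)
        S = mmp_source(cells, fields, p)
        i = int(round(3.0 / p.dx))
        assert S[i, i] == pytest.approx(p.nuC)

    def test_value_one_diameter_away(self, tiny_params):
        p = tiny_params.replace(dx=0.1)
        fields = make_fields(p)
        cells = Cells(np.array([[3.0, 3.0]]), np.array([0.0]), p.Lstar)
        S = mmp_source(cells, fields, p)
        i = int(round(3.0 / p.dx))
        j = int(round((3.0 + p.d) / p.dx))
        assert S[i, j] == pytest.approx(p.nuC / np.e)

    def test_superposition_of_coincident_cells(self, tiny_params):
        p = tiny_params.replace(dx=0.25)
        fields = make_fields(p)
        one = mmp_source(Cells(np.array([[2.0, 2.0]]), np.zeros(1), p.Lstar), fields, p)
        two = mmp_source(Cells(np.array([[2.0, 2.0]] * 2), np.zeros(2), p.Lstar), fields, p)
        np.testing.assert_allclose(two, 2 * one, rtol=1e-12)


class TestDegradation:
    def test_no_enzyme_no_decay(self, tiny_params, rng):
        rho = rng.random((4, 4))
        out = degradation_step(rho, np.zeros((4, 4)), tiny_params)
        np.testing.assert_array_equal(out, rho)

    def test_exact_exponential_closed_form(self, tiny_params):
        p = tiny_params
        rho = np.full((4, 4), 0.8)
        C = np.full((4, 4), 0.3)
        k = 57
        for _ in range(k):
            rho = degradation_step(rho, C, p)
        np.testing.assert_allclose(rho, 0.8 * np.exp(-p.gamma2 * 0.3 * k * p.dt), rtol=1e-12)

    def test_fully_degraded_is_absorbing(self, tiny_params):
        out = degradation_step(np.zeros((4, 4)), np.ones((4, 4)), tiny_params)
        np.testing.assert_array_equal(out, 0.0)

    def test_negative_enzyme_rejected(self, tiny_params):
        with pytest.raises(ValueError, match="negative"):
            degradation_step(np.ones((4, 4)), np.full((4, 4), -1.0), tiny_params)

    def test_off_switch(self, tiny_params, rng):
        p = tiny_params.replace(degradation_on=False)
        rho = rng.random((4, 4))
        np.testing.assert_array_equal(degradation_step(rho, np.ones((4, 4)), p), rho)


class TestDegradedArea:
    @pytest.mark.parametrize("value,expected", [(1.0, 0.0), (0.0, 100.0), (0.3, 70.0)])
    def test_uniform_fields(self, value, expected):
        assert degraded_area(np.full((8, 8), value)) == pytest.approx(expected)


class TestDetectTdegr:
    def test_intact_substrate_never_arrests(self):
        times = np.arange(100) * 0.1
        assert detect_tdegr(times, np.ones(100)) is None

    def test_sustained_collapse_at_frame_37(self):
        times = np.arange(100) * 0.1
        series = np.ones(100)
        series[37:] = 0.0
        assert detect_tdegr(times, series) == pytest.approx(times[37])

    def test_transient_dip_excluded(self):
        times = np.arange(100) * 0.1
        series = np.ones(100)
        series[40:43] = 0.0
        assert detect_tdegr(times, series) is None

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            detect_tdegr(np.array([]), np.array([]))


class TestStep:
    def test_ballistic_limit(self):
        p = ModelParams(Nc=1, dx=0.5, Drot=0.0, durotaxis_on=False,
                        degradation_on=False, T_end=1.0)
        cells = Cells(np.array([[3.0, 3.0]]), np.array([0.5]), p.Lstar)
        sim = Simulation(p, cells=cells, fields=SubstrateFields(p.N, p.dx))
        n = 100
        for _ in range(n):
            sim.step()
        expected = np.array([3.0, 3.0]) + n * p.dt * p.Vprop * np.array(
            [np.cos(0.5), np.sin(0.5)]
        )
        np.testing.assert_allclose(sim.cells.positions[0], expected, atol=1e-12)
        assert sim.cells.phi[0] == 0.5

    def test_rho_monotone_and_c_nonnegative(self):
        p = ModelParams(Nc=8, dx=0.25, T_end=0.5, seed=3)
        sim = Simulation(p)
        prev_min = 1.0
        prev_area = 0.0
        for k in range(100):
            sim.step()
            if k % 10 == 9:
                assert sim.fields.C.min() >= 0.0
                m = sim.fields.rho.min()
                assert m <= prev_min + 1e-15
                area = degraded_area(sim.fields.rho)
                assert area >= prev_area - 1e-12
                prev_min, prev_area = m, area
        assert 0.0 <= sim.fields.rho.min() and sim.fields.rho.max() <= 1.0

    def test_same_seed_identical_runs(self):
        p = ModelParams(Nc=5, dx=0.25, T_end=0.3, seed=11)
        rec_a = Simulation(p).run()
        rec_b = Simulation(p).run()
        np.testing.assert_array_equal(rec_a.trajectory, rec_b.trajectory)
        np.testing.assert_array_equal(rec_a.degraded_percent, rec_b.degraded_percent)

    def test_abp_mean_squared_displacement(self):
        # no-interaction limit: 2D active Brownian motion with
        # MSD(t) = (2 Vprop^2/Drot^2) (Drot t + exp(-Drot t) - 1)
        p = ModelParams(Nc=1000, dx=0.5, F0=0.0, Drot=0.1, durotaxis_on=False,
                        degradation_on=False, T_end=10.0, seed=21, record_every=200)
        sim = Simulation(p)
        start = sim.cells.positions.copy()
        unwrapped = start.copy()
        prev = start.copy()
        checks = {int(round(t / p.dt)): t for t in (2.0, 5.0, 10.0)}
        n_steps = int(round(p.T_end / p.dt))
        for k in range(1, n_steps + 1):
            sim.step()
            cur = sim.cells.positions
            jump = cur - prev
            jump -= p.Lstar * np.round(jump / p.Lstar)
            unwrapped += jump
            prev = cur.copy()
            if k in checks:
                t = checks[k]
                msd = ((unwrapped - start) ** 2).sum(axis=1).mean()
                theory = (2 * p.Vprop**2 / p.Drot**2) * (
                    p.Drot * t + np.exp(-p.Drot * t) - 1.0
                )
                assert msd == pytest.approx(theory, rel=0.15)

    def test_doubling_production_doubles_enzyme_field(self):
        base = ModelParams(Nc=6, dx=0.25, seed=5, durotaxis_on=False)
        rng_state = np.random.default_rng(5)
        cells, fields = None, None
        sim1 = Simulation(base)
        start_cells = sim1.cells.copy()
        sim1.step()
        sim2 = Simulation(base.replace(nuC=2 * base.nuC),
                          cells=start_cells, fields=SubstrateFields(base.N, base.dx))
        sim2.step()
        np.testing.assert_allclose(sim2.fields.C, 2 * sim1.fields.C, rtol=1e-7, atol=1e-15)

    def test_one_step_consistency_under_dt_refinement(self):
        # Richardson-style check: |phi_dt - phi_{dt/2}^2| scales ~ dt^2
        def one_vs_two(dt):
            p = ModelParams(Nc=6, dx=0.25, dt=dt, Drot=0.0, seed=13)
            sim1 = Simulation(p)
            cells0 = sim1.cells.copy()
            sim1.step()
            p2 = p.replace(dt=dt / 2)
            sim2 = Simulation(p2, cells=cells0, fields=SubstrateFields(p.N, p.dx))
            sim2.step()
            sim2.step()
            return np.max(np.abs(sim1.cells.positions - sim2.cells.positions))

        e1 = one_vs_two(2e-2)
        e2 = one_vs_two(1e-2)
        assert e1 / e2 == pytest.approx(4.0, rel=0.5)
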