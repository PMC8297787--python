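import numpy as np
import pytest

from cromics.diffusion import (
    CNSolver,
    LBMSolver,
    MetaboliteField,
    SolverError,
    cn_step,
    diffuse_all,
    lbm_step,
    msd_tracers,
)
from cromics.grid import BoundarySpec, GridSpec, build_grid
from cromics.units import d0_to_internal
from oracles import explicit_euler_diffusion

D0 = d0_to_internal(5e-6)  # mm^2/h


def point_source_grid(n=81, dx=0.02):
    g = build_grid(GridSpec(nx=n, ny=n, nz=1, dx=dx, dz=dx, coarse_factor=1,
                            dims=2))
    rho = np.zeros(g.cn_shape)
    rho[n // 2, n // 2, 0] = 1.0
    return g, rho


def variance_per_axis(rho, dx):
    n = rho.shape[0]
    x = (np.arange(n) - n // 2) * dx
    p = rho[:, :, 0].sum(axis=1)
    return float((p * x**2).sum() / p.sum())


class TestCNStep:
    def test_uniform_field_fixed_point(self):
        g = build_grid(GridSpec(nx=8, ny=8, coarse_factor=1, dims=2))
        bc = BoundarySpec(metabolite={f: "periodic" for f in ("x-", "x+", "y-", "y+")})
        fld = MetaboliteField("m", np.full(g.cn_shape, 3.7), D0)
        cn_step(fld, 1e-4, bc, g)
        assert np.allclose(fld.rho, 3.7, rtol=1e-12)

    def test_gaussian_variance(self):
        """Point source spreads with per-axis variance 2 D t (within 1%)."""
        g, rho = point_source_grid()
        fld = MetaboliteField("m", rho, D0)
        bc = BoundarySpec()
        # keep D dt / dx^2 <= 0.25 so theta = 1/2 stays monotone on the
        # delta initial condition
        dt, n = 3e-6, 200
        solver = CNSolver(g, fld.d_eff, dt, bc, theta=0.5)
        for _ in range(n):
            cn_step(fld, dt, bc, g, solver=solver)
        assert variance_per_axis(fld.rho, 0.02) == pytest.approx(
            2 * D0 * dt * n, rel=0.01
        )

    def test_mass_conserved_zero_flux_and_periodic(self, rng):
        for modes in ({}, {f: "periodic" for f in ("x-", "x+", "y-", "y+")}):
            g = build_grid(GridSpec(nx=7, ny=7, coarse_factor=1, dims=2))
            bc = BoundarySpec(metabolite=modes)
            fld = MetaboliteField("m", rng.uniform(0, 1, g.cn_shape), D0)
            fld.set_gamma(rng.uniform(1, 3, g.cn_shape))
            total = fld.total()
            for _ in range(20):
                cn_step(fld, 1e-3, bc, g)
            assert fld.total() == pytest.approx(total, rel=1e-10)

    def test_heterogeneous_matches_explicit_euler_oracle(self, rng):
        """CN on a random 5x5 heterogeneous-D field agrees with a brute
        force explicit integrator at 1/100 the step (1e-6 relative Linf)."""
        g = build_grid(GridSpec(nx=5, ny=5, coarse_factor=1, dims=2))
        bc = BoundarySpec()
        rho0 = rng.uniform(0.1, 1.0, g.cn_shape)
        d = rng.uniform(0.2, 1.0, g.cn_shape) * D0
        fld = MetaboliteField("m", rho0.copy(), D0, d_eff=d.copy())
        dt, n = 5e-8, 200
        solver = CNSolver(g, fld.d_eff, dt, bc, theta=0.5)
        for _ in range(n):
            cn_step(fld, dt, bc, g, solver=solver)
        oracle = explicit_euler_diffusion(
            rho0[:, :, 0], d[:, :, 0], 0.05, dt / 200, n * 200
        )
        err = np.max(np.abs(fld.rho[:, :, 0] - oracle)) / oracle.max()
        assert err < 1e-6

    def test_symmetry_preserved(self):
        g, rho = point_source_grid(n=21)
        fld = MetaboliteField("m", rho, D0)
        bc = BoundarySpec()
        solver = CNSolver(g, fld.d_eff, 4e-6, bc, theta=0.5)
        for _ in range(30):
            cn_step(fld, 4e-6, bc, g, solver=solver)
        r = fld.rho[:, :, 0]
        assert np.allclose(r, r[::-1, :], atol=1e-18)
        assert np.allclose(r, r.T, atol=1e-18)

    def test_absorbing_boundary_drains(self):
        g = build_grid(GridSpec(nx=5, ny=5, coarse_factor=1, dims=2))
        bc = BoundarySpec(metabolite={f: "absorbing" for f in ("x-", "x+", "y-", "y+")})
        fld = MetaboliteField("m", np.ones(g.cn_shape), D0)
        total0 = fld.total()
        for _ in range(30):
            cn_step(fld, 1e-4, bc, g)
        assert fld.total() < 0.1 * total0

    def test_fixed_face_reset(self):
        g = build_grid(GridSpec(nx=4, ny=1, nz=4, dx=0.05, coarse_factor=1, dims=3))
        bc = BoundarySpec(metabolite={"z+": ("fixed", 5.0)})
        fld = MetaboliteField("m", np.zeros(g.cn_shape), D0)
        cn_step(fld, 1e-4, bc, g)
        from cromics.units import L_PER_MM3

        expected = 5.0 * g.v_cn_box / L_PER_MM3
        assert np.allclose(fld.rho[:, :, -1], expected)
        assert fld.total() > expected  # influx reached lower layers

    def test_negativity_is_an_error(self):
        g = build_grid(GridSpec(nx=3, ny=3, coarse_factor=1, dims=2))
        with pytest.raises(SolverError):
            MetaboliteField("m", np.array([[[1.0]], [[-0.5]], [[1.0]]]) *
                            np.ones((3, 3, 1))[:1].T, D0)  # malformed on purpose


class TestLBMStep:
    def test_uniform_periodic_fixed_point(self):
        g = build_grid(GridSpec(nx=8, ny=8, coarse_factor=1, dims=2))
        bc = BoundarySpec(metabolite={f: "periodic" for f in ("x-", "x+", "y-", "y+")})
        fld = MetaboliteField("m", np.full(g.cn_shape, 2.5), D0)
        for _ in range(5):
            lbm_step(fld, 1e-4, bc, g)
        assert np.allclose(fld.rho, 2.5, rtol=1e-12)

    def test_gaussian_variance(self):
        """LBM point source variance matches 2 D t within 2%."""
        g, rho = point_source_grid(n=61)
        fld = MetaboliteField("m", rho, D0)
        bc = BoundarySpec()
        # tau ~ 1 keeps the BGK collision non-negative on a delta source
        dt, n = 4e-6, 200
        solver = LBMSolver(g, fld.d_eff, dt, bc)
        for _ in range(n):
            lbm_step(fld, dt, bc, g, solver=solver)
        assert variance_per_axis(fld.rho, 0.02) == pytest.approx(
            2 * D0 * dt * n, rel=0.02
        )

    def test_mass_conserved(self, rng):
        g = build_grid(GridSpec(nx=6, ny=6, coarse_factor=1, dims=2))
        bc = BoundarySpec()
        fld = MetaboliteField("m", rng.uniform(0, 1, g.cn_shape), D0)
        total = fld.total()
        for _ in range(50):
            lbm_step(fld, 1e-5, bc, g)
        assert fld.total() == pytest.approx(total, rel=1e-10)

    def test_matches_cn_heterogeneous(self, rng):
        """Cross-solver equivalence on a heterogeneous D_eff field:
        relative L2 difference < 1% after equal elapsed time."""
        g = build_grid(GridSpec(nx=21, ny=21, coarse_factor=1, dims=2))
        bc = BoundarySpec(
            metabolite={f: "periodic" for f in ("x-", "x+", "y-", "y+")}
        )
        ii, jj = np.meshgrid(np.arange(21), np.arange(21), indexing="ij")
        rho0 = np.exp(-((ii - 10) ** 2 + (jj - 10) ** 2) / (2 * 1.5**2))
        rho0 = rho0[:, :, None]
        # smoothly varying crowding (grid-scale noise probes the two
        # schemes' different interface treatments, not the physics)
        gamma = (1.75 + 0.75 * np.sin(2 * np.pi * ii / 21)
                 * np.cos(2 * np.pi * jj / 21))[:, :, None]
        f_cn = MetaboliteField("m", rho0.copy(), D0)
        f_cn.set_gamma(gamma)
        f_lb = MetaboliteField("m", rho0.copy(), D0)
        f_lb.set_gamma(gamma)
        t_end, dt_cn_, dt_lb = 2e-3, 2e-6, 4e-5  # tau in [0.85, 1.4]
        solver_cn = CNSolver(g, f_cn.d_eff, dt_cn_, bc, theta=0.5)
        for _ in range(int(t_end / dt_cn_)):
            cn_step(f_cn, dt_cn_, bc, g, solver=solver_cn)
        solver_lb = LBMSolver(g, f_lb.d_eff, dt_lb, bc)
        for _ in range(int(t_end / dt_lb)):
            lbm_step(f_lb, dt_lb, bc, g, solver=solver_lb)
        diff = np.linalg.norm(f_cn.rho - f_lb.rho) / np.linalg.norm(f_cn.rho)
        assert diff < 0.01

    def test_tau_stability_guard(self):
        g = build_grid(GridSpec(nx=4, ny=4, coarse_factor=1, dims=2))
        with pytest.raises(SolverError):
            LBMSolver(g, np.zeros(g.cn_shape), 1e-4, BoundarySpec())

    def test_anisotropic_spacing_rejected(self):
        g = build_grid(GridSpec(nx=4, ny=4, dx=0.05, dy=0.02, coarse_factor=1,
                                dims=2))
        with pytest.raises(SolverError):
            LBMSolver(g, np.full(g.cn_shape, D0), 1e-4, BoundarySpec())


class TestDiffuseAll:
    def test_clamped_fields_hold_target(self, rng):
        g = build_grid(GridSpec(nx=5, ny=5, coarse_factor=1, dims=2))
        bc = BoundarySpec(clamped={"a": 2.92, "b": 0.21})
        fields = {
            n: MetaboliteField(n, rng.uniform(0, 1e-9, g.cn_shape), D0)
            for n in ("a", "b")
        }
        fields["a"].set_gamma(rng.uniform(1, 2, g.cn_shape))
        diffuse_all(fields, 1e-3, 3, bc, g)
        from cromics.units import L_PER_MM3

        for n, target in (("a", 2.92), ("b", 0.21)):
            c_eff = fields[n].rho * fields[n].gamma * L_PER_MM3 / g.v_cn_box
            assert np.allclose(c_eff, target)

    def test_zero_d0_field_unchanged(self):
        g = build_grid(GridSpec(nx=5, ny=5, coarse_factor=1, dims=2))
        rho = np.arange(25.0).reshape(g.cn_shape)
        fld = MetaboliteField("immobile", rho.copy(), 0.0)
        diffuse_all({"immobile": fld}, 1e-3, 5, BoundarySpec(), g)
        assert np.array_equal(fld.rho, rho)

    def test_variance_ratio_tracks_d0(self):
        """Two point sources with different D0 spread with variances in
        the ratio of their diffusivities (within 2%)."""
        g, rho = point_source_grid(n=61)
        bc = BoundarySpec()
        fields = {
            "fast": MetaboliteField("fast", rho.copy(), D0),
            "slow": MetaboliteField("slow", rho.copy(), D0 / 4),
        }
        diffuse_all(fields, 4e-6, 200, bc, g, theta=0.5)
        v_fast = variance_per_axis(fields["fast"].rho, 0.02)
        v_slow = variance_per_axis(fields["slow"].rho, 0.02)
        assert v_fast / v_slow == pytest.approx(4.0, rel=0.02)


class TestMSD:
    def test_immobile_tracers(self):
        pos = np.zeros((10, 5, 2))
        lags, msd = msd_tracers(pos, dt=0.1)
        assert np.all(msd == 0)

    def test_free_random_walk_2d(self, rng):
        """Lattice random walk MSD = 4 D t with D = dx^2/(4 dt)."""
        n_steps, n_tracers, dx = 400, 400, 1.0
        steps = rng.integers(0, 4, size=(n_steps, n_tracers))
        moves = np.array([[1, 0], [-1, 0], [0, 1], [0, -1]])[steps] * dx
        pos = np.concatenate(
            [np.zeros((1, n_tracers, 2)), np.cumsum(moves, axis=0)]
        )
        lags, msd = msd_tracers(pos, dt=1.0)
        d = dx**2 / 4
        k = 40  # early lags: best statistics
        expected = 4 * d * lags[:k]
        se = expected * np.sqrt(2.0 / n_tracers)
        assert np.all(np.abs(msd[:k] - expected) < 3 * se + 1e-9)

    def test_insufficient_samples_flagged(self):
        with pytest.raises(ValueError):
            msd_tracers(np.zeros((1, 5, 2)))
        with pytest.raises(ValueError):
            msd_tracers(np.zeros((10, 1, 2)))
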