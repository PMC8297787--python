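import numpy as np
import pytest

from cromics.agents import (
    AgentRegistry,
    DomainFullError,
    SpeciesSpec,
    classify_phenotype,
    phenotype_indicator,
    shove,
)
from cromics.grid import GridSpec, build_grid
from cromics.metabolism import FluxResponse
from cromics.toymodels import toy_glucose_aerobe


def small_registry(nx=5, ny=5, metab=1000, f_eps=0.0, d_sp=0.0,
                   m_min_sp=0.0):
    grid = build_grid(GridSpec(nx=nx, ny=ny, dx=0.05, dz=0.05,
                               coarse_factor=1, dims=2))
    sp = SpeciesSpec("cell", toy_glucose_aerobe(f_eps), metab=metab,
                     f_eps=f_eps, d_sp=d_sp, m_min_sp=m_min_sp)
    return grid, AgentRegistry(grid, [sp])


class TestMassUpdate:
    def test_linear_growth_update(self):
        _, reg = small_registry()
        i = reg.add("cell", 0, 1e-10)
        reg.update_agent(i, FluxResponse(0.5, {}), 0.01)
        assert reg.mass[i] == pytest.approx(1.005e-10)

    def test_exchange_delta(self):
        _, reg = small_registry()
        i = reg.add("cell", 0, 1e-10)
        delta = reg.update_agent(i, FluxResponse(0.0, {"glucose": -2.0}), 0.01)
        assert delta["glucose"] == pytest.approx(-2e-12)

    def test_eps_yield_coupling(self):
        _, reg = small_registry(f_eps=0.43)
        i = reg.add("cell", 0, 1e-10)
        # v_bio * M * dt = 1e-12 g_DW of new biomass -> 4.3e-13 g EPS
        reg.update_agent(i, FluxResponse(0.01, {}), 0.1)
        assert reg.eps[i] == pytest.approx(0.43 * 1e-12, rel=1e-12)

    def test_no_eps_while_shrinking(self):
        _, reg = small_registry(f_eps=0.43)
        i = reg.add("cell", 0, 1e-10)
        reg.update_agent(i, FluxResponse(-0.016, {}), 0.1)
        assert reg.eps[i] == 0.0
        assert reg.mass[i] < 1e-10


class TestPhenotype:
    def test_per_flux_indicator(self):
        assert phenotype_indicator(5e-5) == 1
        assert phenotype_indicator(1e-4) == 2

    def test_inactive_below_threshold(self):
        r = FluxResponse(5e-5, {"O2": -3.0, "acetate": 1.0})
        assert classify_phenotype(r) == "inactive"

    def test_respiratory(self):
        r = FluxResponse(0.5, {"O2": -3.0, "acetate": 0.0})
        assert classify_phenotype(r) == "respiratory"

    def test_fermentative(self):
        r = FluxResponse(0.3, {"O2": -5e-5, "acetate": 2.0})
        assert classify_phenotype(r) == "fermentative"

    def test_other(self):
        r = FluxResponse(0.3, {"O2": 0.0, "acetate": 0.0})
        assert classify_phenotype(r) == "other"

    def test_invalid_theta(self):
        with pytest.raises(ValueError):
            classify_phenotype(FluxResponse(1.0, {}), theta=0.0)


class TestDivision:
    def threshold(self, reg):
        return reg.species[0].m_div

    def test_no_division_below_threshold(self, rng):
        _, reg = small_registry()
        i = reg.add("cell", 12, 0.9 * self.threshold(reg))
        assert reg.maybe_divide(i, rng) is None

    def test_symmetric_split_conserves_mass(self, rng):
        _, reg = small_registry()
        m0 = self.threshold(reg)
        i = reg.add("cell", 12, m0)
        j, moves = reg.maybe_divide(i, rng)
        assert moves == []
        assert reg.mass[i] == pytest.approx(m0 / 2)
        assert reg.mass[i] + reg.mass[j] == pytest.approx(m0, rel=1e-15)
        assert reg.box[j] != reg.box[i]
        reg.check_occupancy()

    def test_wt_threshold_value(self):
        sp = SpeciesSpec("wt", toy_glucose_aerobe(0.0), metab=27)
        assert sp.m_div == pytest.approx(27 * 1.172e-12)

    def test_daughter_in_neighboring_box(self, rng):
        grid, reg = small_registry()
        i = reg.add("cell", 12, self.threshold(reg))
        j, _ = reg.maybe_divide(i, rng)
        mother = np.unravel_index(reg.box[i], grid.ibm_shape)
        daughter = np.unravel_index(reg.box[j], grid.ibm_shape)
        assert sum(abs(a - b) for a, b in zip(mother, daughter)) == 1

    def test_division_with_shove(self, rng):
        """All neighbors occupied: the daughter still lands next to the
        mother and the displaced chain keeps one agent per box."""
        grid, reg = small_registry(nx=3, ny=3)
        m0 = self.threshold(reg)
        center = int(np.ravel_multi_index((1, 1, 0), grid.ibm_shape))
        reg.add("cell", center, m0)
        for b in range(9):
            if b != center and b != 8:  # leave corner (2,2) free
                reg.add("cell", b, m0 / 2)
        res = reg.maybe_divide(0, rng)
        assert res is not None and len(res[1]) >= 1
        reg.check_occupancy()
        assert reg.n_alive == 9

    def test_eps_splits_with_mass(self, rng):
        _, reg = small_registry(f_eps=0.11)
        i = reg.add("cell", 12, self.threshold(reg), eps=4e-12)
        j, _ = reg.maybe_divide(i, rng)
        assert reg.eps[i] + reg.eps[j] == pytest.approx(4e-12, rel=1e-15)


class TestShove:
    def board(self):
        from cromics.scenarios import make_fixture

        return make_fixture("shove_board_3x3")

    def test_single_free_neighbor_chain(self, rng):
        grid, reg = small_registry(nx=3, ny=3)
        a = reg.add("cell", int(np.ravel_multi_index((1, 1, 0), grid.ibm_shape)), 1e-10)
        moves = shove(grid, reg.occupancy, reg.box[a], rng)
        assert len(moves) == 1
        assert reg.occupancy[reg.box[a]] == -1

    def test_full_board_chain_reaches_free_corner(self, rng):
        grid, reg = self.board()
        start = int(np.ravel_multi_index((0, 0, 0), grid.ibm_shape))
        before = set(reg.box[np.flatnonzero(reg.alive)])
        moves = shove(grid, reg.occupancy, start, rng)
        for ai, _src, dst in moves:
            reg.box[ai] = dst
        reg.check_occupancy()
        assert reg.occupancy[start] == -1
        # chain along a shortest path: manhattan distance to the corner
        assert len(moves) <= 4
        assert reg.n_alive == 8

    def test_agent_count_and_mass_preserved(self, rng):
        grid, reg = self.board()
        masses = np.sort(reg.mass.copy())
        start = int(np.ravel_multi_index((1, 1, 0), grid.ibm_shape))
        moves = shove(grid, reg.occupancy, start, rng)
        for ai, _src, dst in moves:
            reg.box[ai] = dst
        assert reg.n_alive == 8
        assert np.array_equal(np.sort(reg.mass), masses)

    def test_deterministic_under_seed(self):
        res = []
        for _ in range(2):
            grid, reg = self.board()
            r = np.random.default_rng(99)
            start = int(np.ravel_multi_index((1, 1, 0), grid.ibm_shape))
            res.append(shove(grid, reg.occupancy, start, r))
        assert res[0] == res[1]

    def test_no_free_box_raises(self, rng):
        grid, reg = small_registry(nx=2, ny=2)
        for b in range(4):
            reg.add("cell", b, 1e-10)
        with pytest.raises(DomainFullError):
            shove(grid, reg.occupancy, 0, rng)


class TestRandomWalk:
    def test_zero_diffusivity_never_moves(self, rng):
        _, reg = small_registry(d_sp=0.0)
        i = reg.add("cell", 12, 1e-10)
        for _ in range(20):
            assert not reg.random_walk(i, 0.01, rng)

    def test_hop_probability_too_large_rejected(self, rng):
        _, reg = small_registry(d_sp=1.0)  # mm^2/h, huge
        i = reg.add("cell", 12, 1e-10)
        with pytest.raises(ValueError):
            reg.random_walk(i, 1.0, rng)

    def test_occupied_target_rejected(self, rng):
        grid, reg = small_registry(nx=2, ny=1, d_sp=1e-3)
        i = reg.add("cell", 0, 1e-10)
        reg.add("cell", 1, 1e-10)
        for _ in range(50):
            reg.random_walk(i, 0.1, rng)
        reg.check_occupancy()

    def test_msd_matches_free_diffusion(self):
        """Ensemble of free walkers: MSD = 4 D t in 2D within 3 s.e."""
        grid = build_grid(GridSpec(nx=41, ny=41, dx=0.05, dz=0.05,
                                   coarse_factor=1, dims=2))
        d_sp = 1e-3  # mm^2/h
        sp = SpeciesSpec("w", toy_glucose_aerobe(0.0), d_sp=d_sp, metab=1)

        # independent single-walker registries avoid excluded-volume bias
        rng = np.random.default_rng(5)
        dt, n_steps, n_walkers = 0.05, 60, 300
        disp = np.zeros((n_walkers, 2))
        start = (20, 20, 0)
        for w in range(n_walkers):
            reg = AgentRegistry(grid, [sp])
            i = reg.add("w", int(np.ravel_multi_index(start, grid.ibm_shape)), 1e-10)
            for _ in range(n_steps):
                reg.random_walk(i, dt, rng, periodic=(True, True, False))
            # displacement, unwrapping not needed at these step counts
            end = np.unravel_index(reg.box[i], grid.ibm_shape)
            d_box = [
                (end[k] - start[k] + 20) % 41 - 20 for k in range(2)
            ]
            disp[w] = np.array(d_box) * grid.ibm_spacing[0]
        msd = (disp**2).sum(axis=1).mean()
        expected = 4 * d_sp * dt * n_steps
        se = expected * np.sqrt(2.0 / n_walkers)
        assert abs(msd - expected) < 3 * se


class TestCull:
    def test_zero_threshold_never_culls(self):
        _, reg = small_registry(m_min_sp=0.0)
        i = reg.add("cell", 3, 1e-16)
        assert reg.cull(i)

    def test_below_threshold_culled_and_box_freed(self):
        _, reg = small_registry(m_min_sp=1e-13, metab=1)
        i = reg.add("cell", 3, 9e-14)
        assert not reg.cull(i)
        assert not reg.alive[i]
        assert reg.occupancy[3] == -1

    def test_freed_box_accepts_daughter(self, rng):
        grid, reg = small_registry(nx=2, ny=1, m_min_sp=1e-13, metab=1)
        dying = reg.add("cell", 1, 9e-14)
        mother = reg.add("cell", 0, reg.species[0].m_div)
        reg.cull(dying)
        j, _ = reg.maybe_divide(mother, rng)
        assert reg.box[j] == 1


class TestIbmStepInvariants:
    def test_fixed_point_with_zero_fluxes(self, rng):
        grid, reg = small_registry(d_sp=0.0)
        for b in (0, 7, 13):
            reg.add("cell", b, 1e-10)
        before = (reg.mass.copy(), reg.box.copy())
        reg.ibm_step(0.01, rng, rng)
        assert np.array_equal(reg.mass, before[0])
        assert np.array_equal(reg.box, before[1])

    def test_occupancy_unique_after_many_steps(self, rng):
        grid, reg = small_registry(nx=6, ny=6, d_sp=5e-4)
        for b in range(0, 36, 3):
            reg.add("cell", b, reg.species[0].m_div * 0.9)
        reg.mass[:4] = reg.species[0].m_div  # force a few divisions
        for _ in range(10):
            reg.ibm_step(0.02, rng, rng)
            reg.check_occupancy()

    def test_division_conserves_total_mass(self, rng):
        grid, reg = small_registry()
        for b in range(0, 25, 4):
            reg.add("cell", b, reg.species[0].m_div)
        total = reg.mass.sum()
        reg.ibm_step(0.01, rng, rng)
        assert reg.mass.sum() == pytest.approx(total, rel=1e-14)
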