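import numpy as np
import pytest

from cromics.metabolism import (
    FluxResponse,
    ModelDefinitionError,
    Reaction,
    ToyStoichModel,
    fit_surrogate,
    shrinkage_response,
    solve_fluxes,
    surrogate_predict,
    uptake_bound_active,
    uptake_bound_passive,
)
from cromics.toymodels import (
    toy_glucose_aerobe,
    toy_lactose_consumer,
    toy_methionine_secreter,
)
from oracles import lp_vertex_maximize


class TestUptakeBounds:
    def test_half_saturation(self):
        assert uptake_bound_active(10.0, 0.5, 0.5) == pytest.approx(5.0)

    def test_zero_concentration(self):
        assert uptake_bound_active(10.0, 0.01, 0.0) == 0.0

    def test_lactose_working_point(self):
        # V_M = 10, K_M = 0.01 mM at the 2.92 mM clamp
        assert uptake_bound_active(10.0, 0.01, 2.92) == pytest.approx(9.9659, abs=1e-4)

    def test_never_reaches_vmax(self):
        assert uptake_bound_active(10.0, 0.01, 1e9) < 10.0

    def test_passive_abundant_pool(self):
        assert uptake_bound_passive(15.0, 1e-3, 7.5e-10, 1.0) == 15.0

    def test_passive_empty_pool(self):
        assert uptake_bound_passive(15.0, 0.0, 7.5e-10, 1.0) == 0.0

    def test_passive_drawdown_cap(self):
        v = uptake_bound_passive(15.0, 1e-15, 7.5e-10, 3.472e-4)
        assert v == pytest.approx(3.84e-3, rel=1e-2)

    def test_passive_zero_mass_rejected(self):
        with pytest.raises(ValueError):
            uptake_bound_passive(15.0, 1e-15, 0.0, 1.0)


def tiny_model():
    """A <= 6-reaction network small enough for vertex enumeration."""
    return ToyStoichModel(
        name="tiny",
        reactions=[
            Reaction("EX_a", {"A": -1}, lb=-5, ub=0),
            Reaction("EX_b", {"B": -1}, lb=0, ub=100),
            Reaction("r1", {"A": -1, "B": 1, "E": 2}, lb=0, ub=100),
            Reaction("r2", {"A": -1, "E": 5}, lb=0, ub=1.5),
            Reaction("v_bio", {"E": -4}, lb=0, ub=100),
        ],
        objective="v_bio",
        exchanges={"EX_a": "a", "EX_b": "b"},
    )


class TestSolveFluxes:
    @pytest.mark.parametrize("bound_a", [0.0, 1.0, 2.5, 5.0])
    def test_matches_vertex_enumeration_oracle(self, bound_a):
        """LP optimum equals brute-force vertex enumeration to 1e-9."""
        m = tiny_model()
        resp = solve_fluxes(m, {"a": bound_a, "b": 0.0})
        lb = m._lb.copy()
        ub = m._ub.copy()
        lb[0] = -bound_a
        c = np.zeros(m.n_reactions)
        c[m.reaction_index("v_bio")] = 1.0
        best = lp_vertex_maximize(c, m._S, np.zeros(m._S.shape[0]), lb, ub)
        assert best is not None
        assert resp.v_bio == pytest.approx(best[0], abs=1e-9)

    def test_oracle_on_secreter_coupling(self):
        m = toy_methionine_secreter(0.5, maintenance=0.1)
        bounds = {"acetate": 4.0, "galactose": 2.0, "methionine": 0.0}
        resp = solve_fluxes(m, bounds)
        lb, ub = m._lb.copy(), m._ub.copy()
        for rid, met in m.exchanges.items():
            j = m.reaction_index(rid)
            lb[j] = max(lb[j], -bounds[met])
        # equality rows: mass balance plus the coupling v_meth = 0.5 v_bio
        n = m.n_reactions
        row = np.zeros(n)
        row[m.reaction_index("v_meth")] = 1.0
        row[m.reaction_index("v_bio")] = -0.5
        a_eq = np.vstack([m._S, row])
        b_eq = np.zeros(a_eq.shape[0])
        c = np.zeros(n)
        c[m.reaction_index("v_bio")] = 1.0
        best = lp_vertex_maximize(c, a_eq, b_eq, lb, ub)
        assert resp.v_bio == pytest.approx(best[0], abs=1e-9)

    def test_maintenance_overflow_at_zero_growth(self):
        """No methionine: growth is zero but ATP maintenance still forces
        lactose consumption with acetate and galactose secretion."""
        m = toy_lactose_consumer(maintenance=2.0)
        r = solve_fluxes(m, {"lactose": 9.97, "methionine": 0.0,
                             "acetate": 0.0, "galactose": 0.0})
        assert r.feasible and r.v_bio == pytest.approx(0.0, abs=1e-9)
        assert r.secretion("acetate") > 0
        assert r.secretion("galactose") > 0

    def test_no_carbon_with_maintenance_infeasible(self):
        m = toy_lactose_consumer(maintenance=2.0)
        r = solve_fluxes(m, {"lactose": 0.0, "methionine": 0.0,
                             "acetate": 0.0, "galactose": 0.0})
        assert not r.feasible

    @pytest.mark.parametrize("f_eps,expected", [(0.11, 1 / 1.11), (0.43, 1 / 1.43)])
    def test_eps_growth_penalty_closed_form(self, f_eps, expected):
        """Equal per-gram EPS cost with fixed substrate supply scales the
        optimum by exactly 1/(1 + f_EPS): 0.9009 and 0.6993."""
        bounds = {"glucose": 10.0, "O2": 14.3, "acetate": 0.0}
        v0 = solve_fluxes(toy_glucose_aerobe(0.0), bounds).v_bio
        vf = solve_fluxes(toy_glucose_aerobe(f_eps), bounds).v_bio
        assert vf / v0 == pytest.approx(expected, abs=1e-6)

    def test_coupling_ratio_exact_at_optimum(self):
        m = toy_methionine_secreter(0.5)
        r = solve_fluxes(m, {"acetate": 8.0, "galactose": 8.0, "methionine": 0.0})
        assert r.v_bio > 0
        assert r.secretion("methionine") == pytest.approx(0.5 * r.v_bio, rel=1e-9)

    def test_monotone_in_bounds(self):
        """Relaxing any uptake bound never decreases the optimum."""
        m = toy_methionine_secreter(0.5)
        base = {"acetate": 2.0, "galactose": 2.0, "methionine": 0.0}
        v0 = solve_fluxes(m, base).v_bio
        for met in ("acetate", "galactose"):
            relaxed = dict(base)
            relaxed[met] *= 2
            assert solve_fluxes(m, relaxed).v_bio >= v0 - 1e-12

    def test_bounds_respected_post_hoc(self):
        m = toy_glucose_aerobe(0.0)
        r = solve_fluxes(m, {"glucose": 3.3, "O2": 1.7, "acetate": 0.5})
        assert r.uptake("glucose") <= 3.3 + 1e-9
        assert r.uptake("O2") <= 1.7 + 1e-9

    def test_unbounded_model_rejected(self):
        m = ToyStoichModel(
            name="bad",
            reactions=[Reaction("v_bio", {}, lb=0, ub=np.inf)],
            objective="v_bio",
        )
        with pytest.raises(ModelDefinitionError):
            solve_fluxes(m, {})


class TestShrinkage:
    def test_rate_and_zero_exchange(self):
        m = toy_methionine_secreter(0.5)
        r = shrinkage_response(m)
        assert r.v_bio == pytest.approx(-1.6e-2)
        assert all(v == 0.0 for v in r.exchange.values())
        assert not r.feasible

    def test_two_steps_multiplicative_decay(self):
        m_cell, dt = 1e-10, 1.0
        rate = shrinkage_response(toy_methionine_secreter(0.5)).v_bio
        after = m_cell * (1 + rate * dt) ** 2
        assert after == pytest.approx(m_cell * (1 - 1.6e-2) ** 2)

    def test_mass_loss_example(self):
        # 1.6e-2 1/h on 1e-10 g over 1 h removes 1.6e-12 g
        rate = shrinkage_response(toy_lactose_consumer()).v_bio
        assert 1e-10 * rate * 1.0 == pytest.approx(-1.6e-12)


class TestSerialization:
    def test_json_roundtrip(self):
        m = toy_methionine_secreter(0.5)
        m2 = ToyStoichModel.from_json(m.to_json())
        r1 = solve_fluxes(m, {"acetate": 5, "galactose": 5, "methionine": 0})
        r2 = solve_fluxes(m2, {"acetate": 5, "galactose": 5, "methionine": 0})
        assert r1.v_bio == pytest.approx(r2.v_bio, rel=1e-12)
        assert r1.exchange == r2.exchange


@pytest.fixture(scope="module")
def fitted():
    m = toy_glucose_aerobe(0.0)
    ranges = {"glucose": (0.0, 10.0), "O2": (0.0, 15.0), "acetate": (0.0, 5.0)}
    return fit_surrogate(m, ranges, n_samples=1500, seed=7)


class TestSurrogate:
    def test_held_out_quality(self, fitted):
        assert fitted.pearson_r >= 0.99
        assert fitted.nmse <= 1e-2

    def test_prediction_close_to_lp(self, fitted):
        rng = np.random.default_rng(3)
        errs = []
        for _ in range(30):
            b = {
                "glucose": rng.uniform(0, 10),
                "O2": rng.uniform(0, 15),
                "acetate": rng.uniform(0, 5),
            }
            exact = solve_fluxes(fitted.model, b)
            pred = surrogate_predict(fitted, b)
            errs.append(abs(pred.v_bio - exact.v_bio))
        assert np.mean(errs) < 0.05

    def test_uptake_clipped_to_bounds(self, fitted):
        b = {"glucose": 0.05, "O2": 0.05, "acetate": 0.0}
        pred = surrogate_predict(fitted, b)
        for met, v_u in b.items():
            assert pred.uptake(met) <= v_u + 1e-12

    def test_extrapolation_falls_back_to_lp(self, fitted):
        b = {"glucose": 50.0, "O2": 5.0, "acetate": 0.0}
        with pytest.warns(UserWarning):
            pred = surrogate_predict(fitted, b)
        exact = solve_fluxes(fitted.model, b)
        assert pred.v_bio == pytest.approx(exact.v_bio, rel=1e-9)

    def test_constant_model_reproduced(self):
        m = ToyStoichModel(
            name="const",
            reactions=[
                Reaction("EX_x", {"X": -1}, lb=-1, ub=0),
                Reaction("v_bio", {"X": -2}, lb=0, ub=0.123),
            ],
            objective="v_bio",
            exchanges={"EX_x": "x"},
        )
        from sklearn.linear_model import LinearRegression

        s = fit_surrogate(m, {"x": (0.5, 1.0)}, n_samples=200, seed=0,
                          regressor=LinearRegression())
        # bound x >= 0.5 always saturates the objective cap: constant output
        pred = surrogate_predict(s, {"x": 0.7})
        assert pred.v_bio == pytest.approx(0.123, abs=1e-6)


class TestFluxResponse:
    def test_sign_helpers(self):
        r = FluxResponse(0.5, {"a": -2.0, "b": 3.0})
        assert r.uptake("a") == 2.0 and r.secretion("a") == 0.0
        assert r.secretion("b") == 3.0 and r.uptake("missing") == 0.0
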