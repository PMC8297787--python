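"""Executable validation experiments.

Three tiers:

* ``run_worked_examples``: closed-form sizing and LP targets that need
  no simulation (cells per metabacterium, division-threshold ratio,
  EPS growth penalties, box heights for target crowding, the packing
  factor);
* ``run_property_suites``: numerical property checks (SPT limits, a
  Widom-insertion cross-check, solver-vs-oracle and solver-vs-solver
  agreement, ledger closure, determinism) at desk scale;
* ``run_qualitative_replications``: reduced-scale stochastic
  replications of the qualitative community-level findings, asserted
  as seed-averaged directions (never magnitudes).

Genome-scale-model targets (the 76.3/23.7 species-ratio convergence
and the 7% growth penalty of the methionine secreter) depend on
external SBML files and are registered as opt-in external targets,
excluded from the default suite.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .analysis import fitness, relative_fitness
from .crowding import gamma_from_moments, spt_moments
from .diffusion import MetaboliteField, cn_step, lbm_step
from .engine import EngineParams, run
from .grid import BoundarySpec, GridSpec, build_grid
from .metabolism import solve_fluxes
from .scenarios import (
    M_MAX_SP,
    M_METAB_NOMINAL,
    PACKING_FACTOR,
    V_EPS,
    V_SP,
    build_crossfeed_scenario,
    build_eps_scenario,
    height_for_crowding,
    metabacteria_count,
)
from .toymodels import toy_glucose_aerobe
from .units import d0_to_internal

__all__ = [
    "AcceptanceReport",
    "run_worked_examples",
    "run_property_suites",
    "run_qualitative_replications",
    "EXTERNAL_TARGETS",
    "run_external_targets",
]


@dataclass
class AcceptanceReport:
    target: str
    value: float
    expected: float
    comparator: str
    passed: bool
    runtime_s: float = 0.0
    note: str = ""


def _report(target, value, expected, cmp="eq", tol=0.0, t0=None, note=""):
    if cmp == "eq":
        ok = abs(value - expected) <= tol
    elif cmp == "le":
        ok = value <= expected + tol
    elif cmp == "ge":
        ok = value >= expected - tol
    else:
        raise ValueError(cmp)
    return AcceptanceReport(
        target=target,
        value=value,
        expected=expected,
        comparator=cmp,
        passed=bool(ok),
        runtime_s=0.0 if t0 is None else time.perf_counter() - t0,
        note=note,
    )


def eps_growth_penalty(f_eps: float, bounds=None) -> float:
    """Percent growth-rate reduction of an EPS secreter vs wild type,
    from the LP optima under identical uptake bounds."""
    if bounds is None:
        bounds = {"glucose": 10.0, "O2": 14.3, "acetate": 0.0}
    v0 = solve_fluxes(toy_glucose_aerobe(0.0), bounds).v_bio
    vf = solve_fluxes(toy_glucose_aerobe(f_eps), bounds).v_bio
    return 100.0 * (1.0 - vf / v0)


def run_worked_examples() -> list[AcceptanceReport]:
    """Evaluate the closed-form targets; all should pass."""
    dx = 5.7e-3
    reports = [
        _report("metaB_wt", metabacteria_count(dx, M_MAX_SP, V_SP, 0.0, V_EPS), 27),
        _report("metaB_eps+", metabacteria_count(dx, M_MAX_SP, V_SP, 0.11, V_EPS), 20),
        _report("metaB_eps++", metabacteria_count(dx, M_MAX_SP, V_SP, 0.43, V_EPS), 12),
        _report(
            "mass_threshold_ratio",
            round(
                metabacteria_count(dx, M_MAX_SP, V_SP, 0.11, V_EPS)
                / metabacteria_count(dx, M_MAX_SP, V_SP, 0.0, V_EPS),
                2,
            ),
            0.74,
        ),
        _report("eps_penalty_pct_0.11", round(eps_growth_penalty(0.11)), 10),
        _report("eps_penalty_pct_0.43", round(eps_growth_penalty(0.43)), 30),
        _report(
            "dz_40pct",
            float(f"{height_for_crowding(M_METAB_NOMINAL, V_SP, 0.40, 0.025):.1g}"),
            0.009,
        ),
        _report(
            "dz_2pct",
            round(height_for_crowding(M_METAB_NOMINAL, V_SP, 0.02, 0.025), 2),
            0.18,
        ),
        _report("packing_factor", PACKING_FACTOR, round(math.pi / 6, 2)),
    ]
    return reports


# ---------------------------------------------------------------------------
# property suites
# ---------------------------------------------------------------------------


def widom_insertion_gamma(
    radii: np.ndarray, centers: np.ndarray, box: float, r_probe: float,
    n_trials: int, rng: np.random.Generator,
):
    """Monte-Carlo hard-sphere insertion estimate of 1/gamma.

    Returns (acceptance probability, standard error): the fraction of
    random probe placements that overlap no crowder, in a periodic box.
    """
    hits = 0
    pts = rng.uniform(0, box, size=(n_trials, 3))
    for p in pts:
        d = np.abs(centers - p)
        d = np.minimum(d, box - d)  # periodic minimum image
        if np.all(np.sqrt((d**2).sum(axis=1)) >= radii + r_probe):
            hits += 1
    p_acc = hits / n_trials
    se = math.sqrt(max(p_acc * (1 - p_acc), 1e-12) / n_trials)
    return p_acc, se


def random_sphere_packing(
    phi: float, radius: float, box: float, rng: np.random.Generator
) -> np.ndarray:
    """Random sequential addition of equal spheres to volume fraction phi."""
    v_one = 4 / 3 * math.pi * radius**3
    n = int(round(phi * box**3 / v_one))
    centers = []
    for _ in range(100000):
        if len(centers) == n:
            break
        p = rng.uniform(0, box, size=3)
        ok = True
        for c in centers:
            d = np.abs(np.asarray(c) - p)
            d = np.minimum(d, box - d)
            if np.sqrt((d**2).sum()) < 2 * radius:
                ok = False
                break
        if ok:
            centers.append(p)
    if len(centers) < n:
        raise RuntimeError(f"could not pack {n} spheres at phi={phi}")
    return np.array(centers)


def run_property_suites(seed: int = 0) -> list[AcceptanceReport]:
    """Numerical property checks; each entry names the property."""
    rng = np.random.default_rng(seed)
    reports = []

    # SPT limit: gamma(R=0) == 1/(1-S3) for random moment sets
    s = rng.uniform(0, 1, size=(100, 4))
    s[:, 3] = rng.uniform(0, 0.95, size=100)
    g = gamma_from_moments(s[:, 0], s[:, 1], s[:, 2], s[:, 3], 0.0)
    err = np.max(np.abs(g - 1.0 / (1.0 - s[:, 3])))
    reports.append(_report("spt_zero_radius_identity", float(err), 0.0, "le", 1e-12))

    # Widom-insertion cross-check at phi = 0.1
    phi, r_c, box = 0.1, 1.0, 12.0
    centers = random_sphere_packing(phi, r_c, box, rng)
    r_probe = 0.3
    mom = spt_moments([r_c] * len(centers), [], box**3)
    g = gamma_from_moments(mom.s0, mom.s1, mom.s2, mom.s3, r_probe)
    p_acc, se = widom_insertion_gamma(
        np.full(len(centers), r_c), centers, box, r_probe, 20000, rng
    )
    reports.append(
        _report("widom_vs_spt", abs(1.0 / g - p_acc), 0.0, "le", 3 * se,
                note=f"1/gamma={1/g:.4f}, P_insert={p_acc:.4f}")
    )

    # Gaussian variance: CN on a point source
    gspec = GridSpec(nx=81, ny=81, nz=1, dx=0.02, dz=0.02, coarse_factor=1, dims=2)
    grid = build_grid(gspec)
    rho = np.zeros(grid.cn_shape)
    rho[40, 40, 0] = 1.0
    d0 = d0_to_internal(5e-6)
    fld = MetaboliteField("tracer", rho, d0)
    bc = BoundarySpec()
    dt, n = 3e-6, 150  # D dt/dx^2 <= 0.25: theta = 1/2 stays monotone
    from .diffusion import CNSolver

    solver = CNSolver(grid, fld.d_eff, dt, bc, theta=0.5)
    for _ in range(n):
        cn_step(fld, dt, bc, grid, theta=0.5, solver=solver)
    x = (np.arange(81) - 40) * 0.02
    var = float((fld.rho[:, :, 0].sum(axis=1) * x**2).sum() / fld.rho.sum())
    expected = 2 * d0 * dt * n
    reports.append(
        _report("cn_gaussian_variance", abs(var / expected - 1.0), 0.0, "le", 0.01)
    )

    # determinism: two identical seeded runs agree exactly
    pars = dict(nx_ibm=16, n_spots=1, spot_size=9, t_sim=0.1, seed=123)
    _, s1 = build_crossfeed_scenario(**pars)
    _, s2 = build_crossfeed_scenario(**pars)
    t1 = run(s1, s1_params := EngineParams(dt=0.01, dt_cn=0.01, t_sim=0.1, theta=1.0))
    t2 = run(s2, s1_params)
    same = (
        np.array_equal(s1.registry.mass, s2.registry.mass)
        and np.array_equal(s1.registry.box, s2.registry.box)
        and all(
            np.array_equal(s1.fields[m].rho, s2.fields[m].rho) for m in s1.fields
        )
    )
    reports.append(_report("determinism", float(same), 1.0))
    # ledger closure was asserted inside run(); reaching here means it held
    reports.append(_report("ledger_closure", 1.0, 1.0, note="asserted every step"))
    return reports


# ---------------------------------------------------------------------------
# qualitative replications (directions only)
# ---------------------------------------------------------------------------


def crossfeed_final_biomass(seed: int, crowding_on: bool, t_sim: float = 4.0,
                            v_occ: float = 0.40) -> float:
    """Final total biomass of the cross-feeding pair on a small grid.

    Single-species colonies (segregated spots) keep the exchange
    transport-limited, the regime in which crowding hinders the
    redistribution of the shared metabolites.
    """
    cfg, state = build_crossfeed_scenario(
        nx_ibm=24, n_spots=4, spot_size=16, segregated=True, v_occ=v_occ,
        t_sim=t_sim, crowding_on=crowding_on, seed=seed,
    )
    traj = run(state, cfg.params, stop_on_full=True)
    return sum(traj.biomass[sp][-1] for sp in traj.biomass)


def methp_fitness(seed: int, v_occ: float, n_methp: int, t_sim: float = 5.0,
                  crowding_on: bool = True) -> float:
    """Fitness of the methionine-secreting subpopulation."""
    cfg, state = build_crossfeed_scenario(
        nx_ibm=24, n_spots=3, spot_size=16, subpopulations=True,
        n_methp=n_methp, v_occ=v_occ, t_sim=t_sim, crowding_on=crowding_on,
        seed=seed,
    )
    rho0 = state.total_biomass("meth+")
    traj = run(state, cfg.params, stop_on_full=True)
    return fitness(rho0, traj.biomass["meth+"][-1], traj.times[-1])


def eps_relative_fitness(seed: int, f_eps: float, t_sim: float = 8.0,
                         crowding_on: bool = True) -> float:
    """Relative fitness w = F_eps / F_wt in the biofilm scenario."""
    cfg, state = build_eps_scenario(
        nx_ibm=8, nz_ibm=16, f_eps=f_eps, t_sim=t_sim,
        crowding_on=crowding_on, seed=seed,
    )
    rho0 = {sp: state.total_biomass(sp) for sp in ("wt", "eps")}
    traj = run(state, cfg.params, stop_on_full=True)
    f_wt = fitness(rho0["wt"], traj.biomass["wt"][-1], traj.times[-1])
    f_e = fitness(rho0["eps"], traj.biomass["eps"][-1], traj.times[-1])
    return relative_fitness(f_e, f_wt)


def run_qualitative_replications(seeds=(0, 1, 2, 3, 4)) -> list[AcceptanceReport]:
    """Seed-averaged directional assertions on the reduced scenarios.

    (a) final biomass with crowding on < off; (b) secreting-mutant
    fitness increases with initial crowding; (c) and with initial
    frequency; (d) EPS-secreter relative fitness > 1 and larger at the
    higher yield.
    """
    reports = []
    t0 = time.perf_counter()
    on = np.mean([crossfeed_final_biomass(s, True) for s in seeds])
    off = np.mean([crossfeed_final_biomass(s, False) for s in seeds])
    reports.append(
        _report("crowding_lowers_biomass", float(on), float(off), "le", t0=t0,
                note=f"on={on:.3e}, off={off:.3e} g_DW")
    )
    t0 = time.perf_counter()
    f_low = np.mean([methp_fitness(s, 0.02, 4) for s in seeds])
    f_high = np.mean([methp_fitness(s, 0.40, 4) for s in seeds])
    reports.append(
        _report("methp_fitness_vs_crowding", float(f_high), float(f_low), "ge",
                t0=t0, note=f"F(40%)={f_high:.3f}, F(2%)={f_low:.3f} 1/h")
    )
    t0 = time.perf_counter()
    f_lo = np.mean([methp_fitness(s, 0.40, 2) for s in seeds])
    f_hi = np.mean([methp_fitness(s, 0.40, 6) for s in seeds])
    reports.append(
        _report("methp_fitness_vs_frequency", float(f_hi), float(f_lo), "ge",
                t0=t0, note=f"F(n=6)={f_hi:.3f}, F(n=2)={f_lo:.3f} 1/h")
    )
    t0 = time.perf_counter()
    w_low = np.mean([eps_relative_fitness(s, 0.11) for s in seeds])
    w_high = np.mean([eps_relative_fitness(s, 0.43) for s in seeds])
    reports.append(
        _report("w_eps_above_1", float(min(w_low, w_high)), 1.0, "ge", t0=t0,
                note=f"w(0.11)={w_low:.3f}, w(0.43)={w_high:.3f}")
    )
    reports.append(
        _report("w_eps_increases_with_yield", float(w_high), float(w_low), "ge",
                note=f"w(0.43)={w_high:.3f} vs w(0.11)={w_low:.3f}")
    )
    return reports


# ---------------------------------------------------------------------------
# opt-in external (genome-scale) targets
# ---------------------------------------------------------------------------

EXTERNAL_TARGETS = {
    "t10": {
        "claim": "species ratio converges to 76.3% / 23.7% regardless of inoculum",
        "requires": ["iJO1366_core.xml", "iRR1083.xml"],
        "included_by_default": False,
    },
    "t11": {
        "claim": "methionine-secreting mutant grows 7% slower than wild type",
        "requires": ["iRR1083.xml"],
        "included_by_default": False,
    },
}


def load_sbml_backend(path):
    """Wrap an SBML genome-scale model as a flux backend (opt-in).

    Returns a callable bounds -> FluxResponse backed by COBRApy.  The
    SBML file must be supplied by the user; none ships with the package.
    """
    import cobra  # deferred: only needed for the opt-in GEM targets

    from .metabolism import FluxResponse

    gem = cobra.io.read_sbml_model(str(path))

    def backend(bounds):
        with gem as m:
            for met, v_u in bounds.items():
                rid = f"EX_{met}_e"
                if rid in m.reactions:
                    m.reactions.get_by_id(rid).lower_bound = -abs(v_u)
            sol = m.optimize()
            if sol.status != "optimal":
                return FluxResponse(0.0, {}, feasible=False)
            ex = {
                r.id.removeprefix("EX_").removesuffix("_e"): sol.fluxes[r.id]
                for r in m.exchanges
            }
            return FluxResponse(float(sol.objective_value), ex, feasible=True)

    return backend


def run_external_targets(gem_dir: Optional[str] = None) -> list[AcceptanceReport]:
    """Evaluate the opt-in genome-scale targets, if model files exist."""
    from pathlib import Path

    if gem_dir is None:
        return [
            AcceptanceReport(t, float("nan"), float("nan"), "eq", False,
                             note="excluded: no --gem-dir supplied")
            for t in EXTERNAL_TARGETS
        ]
    gem_dir = Path(gem_dir)
    reports = []
    for tid, spec in EXTERNAL_TARGETS.items():
        missing = [f for f in spec["requires"] if not (gem_dir / f).exists()]
        if missing:
            reports.append(
                AcceptanceReport(tid, float("nan"), float("nan"), "eq", False,
                                 note=f"missing model files: {missing}")
            )
            continue
        raise NotImplementedError(
            "genome-scale replication requires a scenario wiring step that "
            "depends on the supplied models' exchange namespaces; use "
            "load_sbml_backend and the engine API directly"
        )
    return reports
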