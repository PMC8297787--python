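"""Master simulation loop.

Each macro step of length dt (h):

1. recompute the SPT crowding state (gamma and D_eff per CN box and
   metabolite) from the current cells and attached EPS;
2. for each of the dt_cn substeps: build per-agent uptake bounds from
   local effective concentrations (agents sharing a CN box receive
   pool shares proportional to V_M * M_cell, so results do not depend
   on agent iteration order), evaluate the metabolic backend, apply the
   linear mass/metabolite updates, then advance diffusion one substep;
3. one IbM step: cull, divide/shove, random walks.

A per-step mass ledger itemizes, for every metabolite, the cellular
exchange, boundary loss and clamp injection and asserts that they
account for the total change to 1e-8 relative.  All randomness flows
from one master seed through independent named substreams, so two runs
with identical config and seed produce identical trajectories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import numpy as np

from .agents import AgentRegistry, DomainFullError, classify_phenotype
from .crowding import (
    MoleculeSpec,
    OverfilledBoxError,
    gamma_from_moments,
    molecule_radius,
)
from .diffusion import MetaboliteField, diffuse_all
from .grid import BoundarySpec, Grid
from .metabolism import (
    shrinkage_response,
    solve_fluxes,
    surrogate_predict,
    uptake_bound_active,
)
from .units import AVOGADRO, L_PER_MM3

__all__ = ["EngineParams", "SimulationState", "Trajectory", "step", "run", "make_streams"]

#: EPS molecular weight (Da) and specific volume (mm^3/g) of the attached pool
MW_EPS = 2.5e8
V_EPS = 9.2e3

RNG_STREAMS = ("placement", "walk", "division", "sampling")


def make_streams(seed: int, names=RNG_STREAMS) -> dict[str, np.random.Generator]:
    """Independent named RNG substreams derived from one master seed."""
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


@dataclass
class EngineParams:
    """Time stepping and numerical knobs of a run."""

    dt: float = 0.01  # h, IbM macro step
    dt_cn: float = 0.01  # h, metabolism/diffusion substep
    t_sim: float = 1.0  # h
    scheme: str = "cn"  # "cn" | "clbm"
    theta: float = 1.0  # diffusion time weighting; 1 = backward Euler
    crowding_on: bool = True
    division_split: float = 0.5
    division_asymmetry: float = 0.0
    metabolism_every: int = 1  # re-evaluate fluxes every n substeps
    snapshot_every: int = 10  # macro steps between trajectory records
    quantize_digits: int = 2  # significant digits for the LP response cache
    ledger_rtol: float = 1e-8

    def __post_init__(self) -> None:
        n = self.dt / self.dt_cn
        if self.dt_cn > self.dt + 1e-15 or abs(n - round(n)) > 1e-9:
            raise ValueError("require dt_cn <= dt with dt/dt_cn integral")

    @property
    def n_substeps(self) -> int:
        return int(round(self.dt / self.dt_cn))


@dataclass
class SimulationState:
    """Everything a run carries between steps."""

    grid: Grid
    bc: BoundarySpec
    molecules: dict[str, MoleculeSpec]
    fields: dict[str, MetaboliteField]
    registry: AgentRegistry
    t: float = 0.0
    rng: dict[str, np.random.Generator] = dc_field(default_factory=dict)
    ledger: list[dict] = dc_field(default_factory=list)
    halted: bool = False
    surrogates: dict[str, object] = dc_field(default_factory=dict)
    _flux_cache: dict = dc_field(default_factory=dict, repr=False)
    _cached_responses: Optional[dict] = dc_field(default=None, repr=False)

    def total_biomass(self, species: Optional[str] = None) -> float:
        reg = self.registry
        mask = reg.alive.copy()
        if species is not None:
            mask &= reg.sp == reg.species_index(species)
        return float(reg.mass[mask].sum())


# ---------------------------------------------------------------------------
# crowding state
# ---------------------------------------------------------------------------


def compute_crowding(state: SimulationState, crowding_on: bool = True) -> None:
    """Refresh gamma and D_eff of every field from cells + attached EPS."""
    grid = state.grid
    n = grid.n_cn
    if not crowding_on:
        ones = np.ones(grid.cn_shape)
        for fld in state.fields.values():
            fld.set_gamma(ones)
        return
    reg = state.registry
    live = np.flatnonzero(reg.alive)
    s_cell = np.zeros((4, n))
    s_macro = np.zeros((4, n))
    if live.size:
        cn = grid.cn_of_ibm_array(reg.box[live])
        d = 2.0 * reg.radii()[live]
        for x in range(4):
            np.add.at(s_cell[x], cn, d**x)
        eps = reg.eps[live]
        if np.any(eps > 0):
            r_eps = molecule_radius(MW_EPS, V_EPS)
            n_mol = eps / (MW_EPS / AVOGADRO)
            de = 2.0 * r_eps
            for x in range(4):
                np.add.at(s_macro[x], cn, n_mol * de**x)
    pref = np.pi / (6.0 * grid.v_cn_box)
    s_all = pref * (s_cell + s_macro)
    s_nocell = pref * s_macro
    if np.any(s_all[3] >= 1.0):
        i = int(np.argmax(s_all[3]))
        raise OverfilledBoxError(
            f"box {np.unravel_index(i, grid.cn_shape)} overfilled: "
            f"S3 = {s_all[3][i]:.3f} >= 1"
        )
    for name, fld in state.fields.items():
        mol = state.molecules[name]
        s = s_nocell if mol.penetrates_membrane else s_all
        gamma = gamma_from_moments(s[0], s[1], s[2], s[3], mol.radius)
        fld.set_gamma(np.asarray(gamma).reshape(grid.cn_shape))


# ---------------------------------------------------------------------------
# metabolism substep
# ---------------------------------------------------------------------------


def _quantize_down(v: float, digits: int) -> float:
    """Round v down to ``digits`` significant figures (never up, so a
    cached LP solution can never overdraw the pool its bound came from)."""
    if v <= 0:
        return 0.0
    exp = np.floor(np.log10(v))
    scale = 10.0 ** (exp - digits + 1)
    return float(np.floor(v / scale) * scale)


def metabolism_substep(state: SimulationState, params: EngineParams, dt: float,
                       reevaluate: bool = True) -> dict[str, float]:
    """One substep of per-agent flux evaluation and Eq-of-motion updates.

    Returns the net cellular exchange per metabolite (mmol added to the
    fields; negative = net uptake).
    """
    grid = state.grid
    reg = state.registry
    live = np.flatnonzero(reg.alive)
    cell_delta = {name: 0.0 for name in state.fields}
    if live.size == 0:
        return cell_delta
    cn = grid.cn_of_ibm_array(reg.box[live])
    mass = reg.mass[live]
    v_box = grid.v_cn_box

    # uptake bounds per agent and metabolite.  Field-wide clamped
    # metabolites are an externally maintained bath: their bound is the
    # Michaelis-Menten cap alone (the clamp restores the target after
    # the substep); all other pools carry the fair-share drawdown cap.
    clamped = set(state.bc.clamped)
    bounds_per_met: dict[str, np.ndarray] = {}
    consumes = {
        name: np.array(
            [name in sp.model.uptake_metabolites for sp in reg.species]
        )
        for name in state.fields
    }
    for name, fld in state.fields.items():
        mol = state.molecules[name]
        can = consumes[name][reg.sp[live]]
        if mol.v_max <= 0 or not np.any(can):
            bounds_per_met[name] = np.zeros(live.size)
            continue
        c_eff = fld.rho.ravel()[cn] * fld.gamma.ravel()[cn] * L_PER_MM3 / v_box
        if name in clamped:
            cap = np.inf
        else:
            w = np.where(can, mol.v_max * mass, 0.0)
            wsum = np.zeros(grid.n_cn)
            np.add.at(wsum, cn, w)
            with np.errstate(invalid="ignore", divide="ignore"):
                share = np.where(wsum[cn] > 0, fld.rho.ravel()[cn] * w / wsum[cn], 0.0)
            cap = share / (mass * dt)
        if mol.transport == "active":
            mm = uptake_bound_active(mol.v_max, mol.k_m, np.maximum(c_eff, 0.0))
            bounds_per_met[name] = np.minimum(mm, cap)
        else:
            bounds_per_met[name] = np.minimum(mol.v_max, cap)

    # group agents by (species, quantized bounds) and evaluate the backend
    met_names = list(state.fields)
    if reevaluate or state._cached_responses is None:
        responses: dict[tuple, object] = {}
        keys = []
        q = params.quantize_digits
        for a in range(live.size):
            spi = int(reg.sp[live[a]])
            sp = reg.species[spi]
            key = (spi,) + tuple(
                _quantize_down(bounds_per_met[m][a], q)
                for m in met_names
                if m in sp.model.uptake_metabolites
            )
            keys.append(key)
            if key not in responses:
                responses[key] = _evaluate_backend(state, sp, key, met_names)
        state._cached_responses = (met_names, keys, responses)
    else:
        _met_names, keys, responses = state._cached_responses

    v_bio = np.empty(live.size)
    v_ex = {m: np.zeros(live.size) for m in met_names}
    phen = []
    for a, key in enumerate(keys):
        resp = responses[key]
        v_bio[a] = resp.v_bio
        for m, v in resp.exchange.items():
            if m in v_ex:
                v_ex[m][a] = v
        phen.append(classify_phenotype(resp))

    # Eq-of-motion updates (linear in dt)
    for m in met_names:
        d_rho = np.zeros(grid.n_cn)
        np.add.at(d_rho, cn, v_ex[m] * mass * dt)
        fld = state.fields[m]
        rho = fld.rho.ravel()
        rho += d_rho
        tiny = rho.min()
        if tiny < 0:
            # clamped baths may transiently overdraw: the clamp restores
            # the target before anything else sees the field
            if m not in clamped and tiny < -1e-9 * max(1.0, rho.max()):
                raise AssertionError(
                    f"metabolite pool of {m} overdrawn ({tiny:.3e} mmol): "
                    "uptake bounds failed to preclude negativity"
                )
            if m not in clamped:
                np.clip(rho, 0.0, None, out=rho)
        cell_delta[m] = float(d_rho.sum())
    f_eps = reg.per_agent("f_eps")[live]
    grow = np.maximum(v_bio, 0.0)
    reg.eps[live] += f_eps * grow * mass * dt
    reg.mass[live] = mass * (1.0 + v_bio * dt)
    reg.phen[live] = phen
    return cell_delta


def _evaluate_backend(state, sp, key, met_names):
    bounds = {}
    ki = 1
    for m in met_names:
        if m in sp.model.uptake_metabolites:
            bounds[m] = key[ki]
            ki += 1
    cache_key = (sp.name,) + key[1:]
    cached = state._flux_cache.get(cache_key)
    if cached is not None:
        return cached
    if sp.name in state.surrogates:
        resp = surrogate_predict(state.surrogates[sp.name], bounds)
    else:
        resp = solve_fluxes(sp.model, bounds)
        if not resp.feasible:
            resp = shrinkage_response(sp.model)
    state._flux_cache[cache_key] = resp
    return resp


# ---------------------------------------------------------------------------
# step and run
# ---------------------------------------------------------------------------


def step(state: SimulationState, params: EngineParams) -> SimulationState:
    """Advance the simulation by one macro step dt."""
    compute_crowding(state, params.crowding_on)
    totals_before = {m: f.total() for m, f in state.fields.items()}
    ledger_entry = {
        "t": state.t,
        "cell": dict.fromkeys(state.fields, 0.0),
        "boundary": dict.fromkeys(state.fields, 0.0),
        "clamp": dict.fromkeys(state.fields, 0.0),
    }
    # re-pin clamped fields to their targets under the fresh gamma
    pre = diffuse_all(state.fields, params.dt_cn, 0, state.bc, state.grid,
                      scheme="cn", theta=params.theta)
    for m, d in pre.items():
        ledger_entry["clamp"][m] += d["clamp"]
    solvers: dict = {}
    for sub in range(params.n_substeps):
        reevaluate = sub % params.metabolism_every == 0
        cell = metabolism_substep(state, params, params.dt_cn, reevaluate)
        for m, v in cell.items():
            ledger_entry["cell"][m] += v
        dl = diffuse_all(
            state.fields, params.dt_cn, 1, state.bc, state.grid,
            scheme=params.scheme, theta=params.theta, solvers=solvers,
        )
        for m, d in dl.items():
            ledger_entry["boundary"][m] += d["boundary"]
            ledger_entry["clamp"][m] += d["clamp"]
    state._cached_responses = None
    # IbM step on the macro time scale
    periodic = state.bc.periodic_axes("agent")
    state.registry.ibm_step(
        params.dt, state.rng["division"], state.rng["walk"], periodic,
        params.division_split, params.division_asymmetry,
    )
    state.registry.check_occupancy()
    # close the ledger
    for m, fld in state.fields.items():
        change = fld.total() - totals_before[m]
        explained = (
            ledger_entry["cell"][m]
            + ledger_entry["boundary"][m]
            + ledger_entry["clamp"][m]
        )
        scale = max(abs(totals_before[m]), abs(fld.total()), 1e-30)
        if abs(change - explained) > params.ledger_rtol * max(scale, 1.0):
            raise AssertionError(
                f"mass ledger failed to close for {m} at t={state.t:.4f}: "
                f"change {change:.3e} vs explained {explained:.3e}"
            )
    state.ledger.append(ledger_entry)
    state.t += params.dt
    return state


@dataclass
class Trajectory:
    """Recorded time series of a run."""

    times: list = dc_field(default_factory=list)
    biomass: dict[str, list] = dc_field(default_factory=dict)
    n_agents: list = dc_field(default_factory=list)
    mean_crowding: list = dc_field(default_factory=list)
    halted: bool = False

    def record(self, state: SimulationState) -> None:
        from .analysis import crowding_map

        self.times.append(state.t)
        for sp in state.registry.species:
            self.biomass.setdefault(sp.name, []).append(state.total_biomass(sp.name))
        self.n_agents.append(state.registry.n_alive)
        cm = crowding_map(state)
        occ = cm[cm > 0]
        self.mean_crowding.append(float(occ.mean()) if occ.size else 0.0)

    def final_biomass(self, species: str) -> float:
        return self.biomass[species][-1]


def run(
    state: SimulationState,
    params: EngineParams,
    out_dir: Optional[str | Path] = None,
    stop_on_full: bool = False,
) -> Trajectory:
    """Iterate :func:`step` until t >= t_sim, recording a trajectory.

    ``stop_on_full`` ends the run gracefully (trajectory flagged
    ``halted``) when no free box remains for a daughter cell; otherwise
    the condition propagates as :class:`DomainFullError` after partial
    outputs are flushed.
    """
    traj = Trajectory()
    traj.record(state)
    n_steps = int(round(params.t_sim / params.dt)) if params.dt > 0 else 0
    try:
        for k in range(n_steps):
            step(state, params)
            if (k + 1) % params.snapshot_every == 0 or k == n_steps - 1:
                traj.record(state)
    except DomainFullError:
        state.halted = True
        traj.halted = True
        traj.record(state)
        if out_dir is not None:
            write_snapshot(state, out_dir)
        if not stop_on_full:
            raise
    if out_dir is not None:
        write_snapshot(state, out_dir)
    return traj


# ---------------------------------------------------------------------------
# snapshots and checkpoints
# ---------------------------------------------------------------------------


def write_snapshot(state: SimulationState, out_dir: str | Path) -> Path:
    """Write agent table (CSV), field arrays (NPZ), ledger (CSV) and run
    metadata (JSON) into ``out_dir``."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reg = state.registry
    idx3 = np.array([np.unravel_index(b, state.grid.ibm_shape) for b in reg.box]) \
        if len(reg) else np.zeros((0, 3), dtype=int)
    pd.DataFrame(
        {
            "id": reg.ids,
            "species": [reg.species[s].name for s in reg.sp],
            "i": idx3[:, 0] if len(reg) else [],
            "j": idx3[:, 1] if len(reg) else [],
            "k": idx3[:, 2] if len(reg) else [],
            "mass_gdw": reg.mass,
            "radius_mm": reg.radii(),
            "phen": reg.phen,
            "eps_g": reg.eps,
            "alive": reg.alive,
        }
    ).to_csv(out / "agents.csv", index=False)
    np.savez(
        out / "fields.npz",
        **{f"rho_{m}": f.rho for m, f in state.fields.items()},
        **{f"gamma_{m}": f.gamma for m, f in state.fields.items()},
    )
    rows = []
    for entry in state.ledger:
        for m in entry["cell"]:
            rows.append(
                {
                    "t": entry["t"],
                    "metabolite": m,
                    "cell_exchange_mmol": entry["cell"][m],
                    "boundary_mmol": entry["boundary"][m],
                    "clamp_mmol": entry["clamp"][m],
                }
            )
    pd.DataFrame(rows).to_csv(out / "ledger.csv", index=False)
    meta = {
        "t": state.t,
        "halted": state.halted,
        "n_agents": int(len(reg)),
        "n_alive": int(reg.n_alive),
        "species": [sp.name for sp in reg.species],
        "metabolites": list(state.fields),
    }
    (out / "run.json").write_text(json.dumps(meta, indent=1))
    return out


def save_checkpoint(state: SimulationState, path: str | Path) -> None:
    """Serialize the full mutable state (including RNG streams) to NPZ."""
    reg = state.registry
    rng_states = {n: json.dumps(g.bit_generator.state) for n, g in state.rng.items()}
    np.savez(
        path,
        t=state.t,
        mass=reg.mass,
        eps=reg.eps,
        box=reg.box,
        sp=reg.sp,
        alive=reg.alive,
        phen=np.array(reg.phen, dtype="U24"),
        ids=reg.ids,
        next_id=reg._next_id,
        occupancy=reg.occupancy,
        rng_names=np.array(list(rng_states), dtype="U32"),
        rng_states=np.array(list(rng_states.values()), dtype="U4096"),
        **{f"rho_{m}": f.rho for m, f in state.fields.items()},
    )


def load_checkpoint(state: SimulationState, path: str | Path) -> SimulationState:
    """Restore a checkpoint into a freshly built state (same config)."""
    d = np.load(path, allow_pickle=False)
    reg = state.registry
    state.t = float(d["t"])
    reg.mass = d["mass"].copy()
    reg.eps = d["eps"].copy()
    reg.box = d["box"].copy()
    reg.sp = d["sp"].copy()
    reg.alive = d["alive"].copy()
    reg.phen = d["phen"].astype(object)
    reg.ids = d["ids"].copy()
    reg._next_id = int(d["next_id"])
    reg.occupancy = d["occupancy"].copy()
    for m, f in state.fields.items():
        f.rho = d[f"rho_{m}"].copy()
        f.lbm_populations = None
    names = [str(x) for x in d["rng_names"]]
    for n, s in zip(names, d["rng_states"]):
        state.rng[n].bit_generator.state = json.loads(str(s))
    return state
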