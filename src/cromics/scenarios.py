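"""Scenario builders, sizing formulas and deterministic test fixtures.

Two archetypal communities are shipped at reduced spatial scale (the
per-box physics — box sizes, concentrations, kinetic and size
parameters — are the published study conditions; only the box counts,
spot counts and simulated time are scaled down to desk scale):

* ``build_crossfeed_scenario``: a 2D mutualistic pair, a methionine-
  auxotroph lactose consumer plus an acetate/galactose consumer whose
  mutant subpopulation secretes methionine.  Lactose and O2 are clamped
  at 2.92 and 0.21 mM effective concentration everywhere, exchanged
  metabolites leave through absorbing boundaries, and the box height
  dz sets the initial crowding (2%, 20% or 40%).
* ``build_eps_scenario``: a 3D biofilm of a glucose/O2 consumer where a
  mutant secretes EPS (0.11 or 0.43 g per g_DW of growth), nutrients
  are held at 5 mM glucose / 0.21 mM O2 at the top face, and x/y are
  periodic.

Sizing formulas: ``metabacteria_count`` gives the number of single
cells represented by one lattice metabacterium from the densest square
packing of spheres (factor 0.52 ~ pi/6), and ``height_for_crowding``
the monolayer box height that realizes a target occupied volume
fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

from .agents import AgentRegistry, SpeciesSpec
from .crowding import MoleculeSpec
from .diffusion import MetaboliteField
from .engine import (
    EngineParams,
    SimulationState,
    compute_crowding,
    make_streams,
)
from .grid import BoundarySpec, Grid, GridSpec, build_grid
from .toymodels import toy_glucose_aerobe, toy_lactose_consumer, toy_methionine_secreter
from .units import L_PER_MM3, d0_to_internal

__all__ = [
    "PACKING_FACTOR",
    "M_CELL_MEAN",
    "M_CELL_SD",
    "M_MAX_SP",
    "V_SP",
    "V_EPS",
    "metabacteria_count",
    "height_for_crowding",
    "ScenarioConfig",
    "build_crossfeed_scenario",
    "build_eps_scenario",
    "make_fixture",
]

#: densest packing of spheres on a square lattice, pi/6 to two decimals
PACKING_FACTOR = 0.52

# single-cell parameters (study conditions)
M_CELL_MEAN = 4.89e-13  # g_DW, mean initial single-cell mass
M_CELL_SD = 1.32e-13  # g_DW
M_MAX_SP = 1.172e-12  # g_DW, division mass of a single cell
V_SP = 3.07e3  # mm^3 g_DW^-1, cell specific volume
V_EPS = 9.2e3  # mm^3 g^-1, polysaccharide specific volume
MW_EPS = 2.5e8  # Da

#: nominal metabacterium mass of the 2D community (3e-7 g_DW per spot
#: spread over 400 metabacteria)
M_METAB_NOMINAL = 7.5e-10


def metabacteria_count(
    dx_ibm: float,
    m_max_sp: float = M_MAX_SP,
    v_sp: float = V_SP,
    f_eps: float = 0.0,
    v_eps: float = V_EPS,
) -> int:
    """Cells per metabacterium in a cubic IbM box.

    metaB = round(0.52 dx^3 / (M_max v_sp + M_EPS v_eps)) with
    M_EPS = f_eps * M_max: the densest square-lattice sphere packing of
    the box volume divided by the maximum volume one cell and its
    attached EPS occupy.
    """
    if min(dx_ibm, m_max_sp, v_sp, v_eps) <= 0 or f_eps < 0:
        raise ValueError("sizing parameters must be positive")
    per_cell = m_max_sp * v_sp + f_eps * m_max_sp * v_eps
    n = round(PACKING_FACTOR * dx_ibm**3 / per_cell)
    if n < 1:
        raise ValueError("box too small: less than one cell per metabacterium")
    return int(n)


def height_for_crowding(
    m_metab: float,
    v_sp: float = V_SP,
    v_occ: float = 0.4,
    dx_ibm: float = 0.025,
) -> float:
    """Monolayer box height dz (mm) giving occupied fraction ``v_occ``.

    dz = M v_sp / (V_occ dx^2): one metabacterium of mass ``m_metab``
    then occupies exactly ``v_occ`` of its dx * dx * dz box.
    """
    if not 0 < v_occ < 1:
        raise ValueError("V_occ must be in (0, 1)")
    return m_metab * v_sp / (v_occ * dx_ibm**2)


@dataclass
class ScenarioConfig:
    """Full parameterization of a run (grid, chemistry, species, steps)."""

    grid_spec: GridSpec
    bc: BoundarySpec
    molecules: dict[str, MoleculeSpec]
    species: list[SpeciesSpec]
    params: EngineParams
    initial_concentrations: dict[str, float] = dc_field(default_factory=dict)  # mM
    inoculation: dict = dc_field(default_factory=dict)


def _assemble_state(
    config: ScenarioConfig, seed: int, place_agents
) -> SimulationState:
    grid = build_grid(config.grid_spec)
    config.bc.validate(grid.dims)
    registry = AgentRegistry(grid, config.species)
    streams = make_streams(seed)
    place_agents(grid, registry, streams["placement"], streams["sampling"])
    fields = {
        name: MetaboliteField(
            name=name,
            rho=np.zeros(grid.cn_shape),
            d0=d0_to_internal(mol.d0),
        )
        for name, mol in config.molecules.items()
    }
    state = SimulationState(
        grid=grid,
        bc=config.bc,
        molecules=config.molecules,
        fields=fields,
        registry=registry,
        rng=streams,
    )
    compute_crowding(state, config.params.crowding_on)
    for name, c_mm in config.initial_concentrations.items():
        fld = state.fields[name]
        fld.rho = c_mm * grid.v_cn_box / (fld.gamma * L_PER_MM3)
    return state


def _sample_masses(rng: np.random.Generator, n: int, metab: int) -> np.ndarray:
    """Initial metabacterium masses: per-cell normal times cell count,
    truncated below at 0.1x the mean to keep masses positive."""
    m = rng.normal(M_CELL_MEAN, M_CELL_SD, size=n) * metab
    lo = 0.1 * M_CELL_MEAN * metab
    while np.any(m < lo):
        bad = m < lo
        m[bad] = rng.normal(M_CELL_MEAN, M_CELL_SD, size=int(bad.sum())) * metab
    return m


def _spot_boxes(
    grid: Grid, center: tuple[int, int], n: int, occupancy: np.ndarray
) -> list[int]:
    """The n free IbM boxes nearest to a spot center (monolayer)."""
    nx, ny, _ = grid.ibm_shape
    cx, cy = center
    coords = [
        (max(abs(i - cx), abs(j - cy)), (i - cx) ** 2 + (j - cy) ** 2, i, j)
        for i in range(nx)
        for j in range(ny)
    ]
    coords.sort()
    out = []
    for _, _, i, j in coords:
        b = int(np.ravel_multi_index((i, j, 0), grid.ibm_shape))
        if occupancy[b] == -1:
            out.append(b)
            if len(out) == n:
                break
    if len(out) < n:
        raise ValueError("infeasible inoculation: more agents than free boxes")
    return out


def build_crossfeed_scenario(
    nx_ibm: int = 50,
    n_spots: int = 4,
    spot_size: int = 25,
    ratio_ecoli: float = 0.99,
    v_occ: float = 0.02,
    segregated: bool = False,
    subpopulations: bool = False,
    n_methp: int = 4,
    r_meth: float = 0.5,
    dt: float = 0.01,
    dt_cn: float = 0.01,
    t_sim: float = 10.0,
    crowding_on: bool = True,
    seed: int = 0,
    maintenance_ecoli: float = 2.0,
    maintenance_partner: float = 0.0,
    metabolite_boundary: str = "absorbing",
    diffusion_scale: Optional[float] = None,
) -> tuple[ScenarioConfig, SimulationState]:
    """Reduced-scale 2D cross-feeding community.

    Without ``subpopulations``: each spot mixes the lactose consumer
    and the methionine-secreting partner in proportion
    ``ratio_ecoli`` : 1 - ratio_ecoli.  With ``segregated``: spots
    alternate between single-species colonies of the two partners, so
    all cross-feeding has to pass through the bulk medium (the
    transport-limited regime a large sparse system is in).  With
    ``subpopulations``: spots are 50:50 lactose consumer :
    non-secreting partner, and only the first spot ("colony A")
    carries ``n_methp`` secreting mutants.
    """
    if nx_ibm % 2:
        raise ValueError("nx_ibm must be even (coarse factor 2)")
    dx_ibm = 0.025
    dz = height_for_crowding(M_METAB_NOMINAL, V_SP, v_occ, dx_ibm)
    gspec = GridSpec(
        nx=nx_ibm // 2, ny=nx_ibm // 2, nz=1,
        dx=0.05, dz=dz, coarse_factor=2, dims=2,
    )
    # the published full-scale setup drains exchanged metabolites at the
    # four open boundaries; a "zero_flux" (sealed) variant emulates the
    # interior of a much larger system at reduced scale
    bc = BoundarySpec(
        metabolite={f: metabolite_boundary for f in ("x-", "x+", "y-", "y+")},
        agent={},
        clamped={"lactose": 2.92, "O2": 0.21},
    )
    # Scale reduction preserves the transport-limited regime: the full
    # 400-box (10 mm) system has a domain-crossing diffusion time of
    # hours, comparable to the growth time scale.  Shrinking the box
    # count while keeping D0 would make the reduced domain well mixed,
    # so diffusivities are rescaled by (L / L_full)^2 by default, which
    # keeps the domain-crossing time (and the exchange-vs-leakage
    # balance) invariant.  At nx_ibm = 400 the factor is 1.
    if diffusion_scale is None:
        diffusion_scale = (nx_ibm / 400.0) ** 2
    d0 = 5e-6 * diffusion_scale
    mol = dict(
        lactose=MoleculeSpec("lactose", mw=342.3, d0=d0, v_max=10, k_m=1e-2),
        O2=MoleculeSpec("O2", mw=32.0, d0=d0, v_max=10, k_m=1e-2),
        methionine=MoleculeSpec("methionine", mw=149.2, d0=d0, v_max=10, k_m=1e-2),
        acetate=MoleculeSpec("acetate", mw=59.0, d0=d0, v_max=10, k_m=1e-2),
        galactose=MoleculeSpec("galactose", mw=180.2, d0=d0, v_max=10, k_m=1e-2),
    )
    metab = round(M_METAB_NOMINAL / M_CELL_MEAN)  # cells per metabacterium
    d_sp = d0_to_internal(3e-9 * diffusion_scale)  # mm^2/h
    common = dict(v_sp=V_SP, m_min_sp=0.0, m_max_sp=M_MAX_SP, metab=metab, d_sp=d_sp)
    species = [
        SpeciesSpec("ecoli", toy_lactose_consumer(maintenance_ecoli), **common),
    ]
    if subpopulations:
        species += [
            SpeciesSpec("meth-", toy_methionine_secreter(0.0, maintenance_partner), **common),
            SpeciesSpec("meth+", toy_methionine_secreter(r_meth, maintenance_partner), **common),
        ]
    else:
        species.append(
            SpeciesSpec("meth+", toy_methionine_secreter(r_meth, maintenance_partner), **common)
        )

    def place(grid, registry, rng_place, rng_sample):
        nx, ny, _ = grid.ibm_shape
        margin = max(2, int(math.ceil(math.sqrt(spot_size))))
        for s in range(n_spots):
            center = (
                int(rng_place.integers(margin, nx - margin)),
                int(rng_place.integers(margin, ny - margin)),
            )
            boxes = _spot_boxes(grid, center, spot_size, registry.occupancy)
            if segregated:
                labels = ["ecoli" if s % 2 == 0 else "meth+"] * spot_size
            elif subpopulations:
                n_e = spot_size // 2
                labels = ["ecoli"] * n_e + ["meth-"] * (spot_size - n_e)
                if s == 0:
                    n_p = min(n_methp, spot_size - n_e)
                    for k in range(n_p):
                        labels[n_e + k] = "meth+"
            else:
                n_e = int(round(ratio_ecoli * spot_size))
                n_e = min(max(n_e, 1), spot_size - 1)
                labels = ["ecoli"] * n_e + ["meth+"] * (spot_size - n_e)
            order = rng_place.permutation(spot_size)
            masses = _sample_masses(rng_sample, spot_size, metab)
            for k, b in enumerate(boxes):
                registry.add(labels[order[k]], b, masses[k])

    config = ScenarioConfig(
        grid_spec=gspec,
        bc=bc,
        molecules=mol,
        species=species,
        params=EngineParams(
            dt=dt, dt_cn=dt_cn, t_sim=t_sim, scheme="cn", theta=1.0,
            crowding_on=crowding_on,
        ),
        initial_concentrations={"lactose": 2.92, "O2": 0.21},
        inoculation={
            "n_spots": n_spots, "spot_size": spot_size,
            "ratio_ecoli": ratio_ecoli, "v_occ": v_occ, "metab": metab,
            "subpopulations": subpopulations, "n_methp": n_methp,
        },
    )
    state = _assemble_state(config, seed, place)
    return config, state


def build_eps_scenario(
    nx_ibm: int = 8,
    nz_ibm: int = 16,
    f_eps: float = 0.11,
    fill_layers: int = 2,
    fill_fraction: float = 0.84,
    dt: float = 0.01,
    dt_cn: float = 0.0025,
    t_sim: float = 10.0,
    crowding_on: bool = True,
    seed: int = 0,
    diffusion_scale: Optional[float] = None,
) -> tuple[ScenarioConfig, SimulationState]:
    """Reduced-scale 3D biofilm: non-secreting wild type (left half)
    versus an EPS-secreting mutant (right half), fed from the top.

    Box edge, nutrient levels and all kinetic/size parameters are the
    published study conditions; the full-scale geometry is 22x22x68 IbM
    boxes with 1220 metabacteria in the bottom layers.  As in the 2D
    community, diffusivities are rescaled by the squared height ratio
    (nz_ibm / 68)^2 by default so the nutrient column stays
    flux-limited (bottom layers starve once the biofilm thickens)
    rather than becoming well mixed at reduced height.
    """
    if nx_ibm % 2 or nz_ibm % 2:
        raise ValueError("IbM box counts must be even (coarse factor 2)")
    dx_ibm = 5.7e-3
    gspec = GridSpec(
        nx=nx_ibm // 2, ny=nx_ibm // 2, nz=nz_ibm // 2,
        dx=2 * dx_ibm, coarse_factor=2, dims=3,
    )
    bc = BoundarySpec(
        metabolite={
            "x-": "periodic", "x+": "periodic",
            "y-": "periodic", "y+": "periodic",
            "z-": "zero_flux",
            "z+": "zero_flux",  # top handled per-metabolite below
        },
        agent={"x-": "periodic", "x+": "periodic", "y-": "periodic", "y+": "periodic"},
        clamped={},
    )
    if diffusion_scale is None:
        diffusion_scale = (nz_ibm / 68.0) ** 2
    mol = dict(
        glucose=MoleculeSpec("glucose", mw=180.2, d0=6.7e-7 * diffusion_scale,
                             v_max=10, k_m=1.5e-2),
        O2=MoleculeSpec("O2", mw=32.0, d0=2e-6 * diffusion_scale, v_max=15, k_m=1e-2),
        acetate=MoleculeSpec("acetate", mw=59.0, d0=1.21e-6 * diffusion_scale,
                             v_max=17, k_m=1e-2),
    )
    metab_wt = metabacteria_count(dx_ibm, M_MAX_SP, V_SP, 0.0, V_EPS)
    metab_eps = metabacteria_count(dx_ibm, M_MAX_SP, V_SP, f_eps, V_EPS)
    species = [
        SpeciesSpec(
            "wt", toy_glucose_aerobe(0.0),
            v_sp=V_SP, m_max_sp=M_MAX_SP, metab=metab_wt, d_sp=0.0, f_eps=0.0,
        ),
        SpeciesSpec(
            "eps", toy_glucose_aerobe(f_eps),
            v_sp=V_SP, m_max_sp=M_MAX_SP, metab=metab_eps, d_sp=0.0, f_eps=f_eps,
        ),
    ]

    def place(grid, registry, rng_place, rng_sample):
        nx, ny, _ = grid.ibm_shape
        boxes = [
            (i, j, k)
            for i in range(nx)
            for j in range(ny)
            for k in range(fill_layers)
        ]
        keep = rng_place.random(len(boxes)) < fill_fraction
        for (i, j, k), ok in zip(boxes, keep):
            if not ok:
                continue
            name = "wt" if i < nx // 2 else "eps"
            mb = metab_wt if name == "wt" else metab_eps
            b = int(np.ravel_multi_index((i, j, k), grid.ibm_shape))
            registry.add(name, b, _sample_masses(rng_sample, 1, mb)[0])

    config = ScenarioConfig(
        grid_spec=gspec,
        bc=bc,
        molecules=mol,
        species=species,
        params=EngineParams(
            dt=dt, dt_cn=dt_cn, t_sim=t_sim, scheme="cn", theta=1.0,
            crowding_on=crowding_on,
        ),
        initial_concentrations={"glucose": 5.0, "O2": 0.21, "acetate": 0.0},
        inoculation={"f_eps": f_eps, "metab_wt": metab_wt, "metab_eps": metab_eps},
    )
    # per-metabolite top boundary: nutrients fixed, acetate reflecting.
    # BoundarySpec modes are field-class-wide; nutrient pinning at the top
    # is expressed through per-metabolite overrides consumed by the engine.
    config.bc.metabolite["z+"] = ("fixed_by_name", {"glucose": 5.0, "O2": 0.21})
    state = _assemble_state(config, seed, place)
    return config, state


def make_fixture(name: str, seed: int = 0):
    """Small deterministic states for unit tests.

    Known names: "single_agent", "shove_board_3x3", "point_source",
    "two_species_checkerboard".
    """
    rng = np.random.default_rng(seed)
    if name == "single_agent":
        gspec = GridSpec(nx=1, ny=1, nz=1, dx=0.05, dz=0.05, coarse_factor=1, dims=2)
        grid = build_grid(gspec)
        sp = SpeciesSpec("cell", toy_glucose_aerobe(0.0), metab=1000)
        reg = AgentRegistry(grid, [sp])
        reg.add("cell", 0, 5e-10)
        bc = BoundarySpec(clamped={"glucose": 5.0, "O2": 0.21, "acetate": 0.0})
        mol = dict(
            glucose=MoleculeSpec("glucose", mw=180.2, d0=6.7e-7, v_max=10, k_m=1.5e-2),
            O2=MoleculeSpec("O2", mw=32.0, d0=2e-6, v_max=15, k_m=1e-2),
            acetate=MoleculeSpec("acetate", mw=59.0, d0=1.21e-6, v_max=17, k_m=1e-2),
        )
        fields = {
            n: MetaboliteField(n, np.zeros(grid.cn_shape), d0_to_internal(m.d0))
            for n, m in mol.items()
        }
        state = SimulationState(
            grid=grid, bc=bc, molecules=mol, fields=fields, registry=reg,
            rng=make_streams(seed),
        )
        compute_crowding(state, True)
        for n, c in (("glucose", 5.0), ("O2", 0.21)):
            state.fields[n].rho = c * grid.v_cn_box / (state.fields[n].gamma * L_PER_MM3)
        return state
    if name == "shove_board_3x3":
        gspec = GridSpec(nx=3, ny=3, nz=1, dx=0.05, dz=0.05, coarse_factor=1, dims=2)
        grid = build_grid(gspec)
        sp = SpeciesSpec("cell", toy_glucose_aerobe(0.0), metab=1000)
        reg = AgentRegistry(grid, [sp])
        for i in range(3):
            for j in range(3):
                if (i, j) != (2, 2):  # one free corner
                    b = int(np.ravel_multi_index((i, j, 0), grid.ibm_shape))
                    reg.add("cell", b, 5e-10)
        return grid, reg
    if name == "point_source":
        gspec = GridSpec(nx=11, ny=11, nz=1, dx=0.05, dz=0.05, coarse_factor=1, dims=2)
        grid = build_grid(gspec)
        rho = np.zeros(grid.cn_shape)
        rho[5, 5, 0] = 1.0
        fld = MetaboliteField("tracer", rho, d0_to_internal(5e-6))
        return grid, fld
    if name == "two_species_checkerboard":
        cfg, state = build_crossfeed_scenario(
            nx_ibm=8, n_spots=1, spot_size=16, ratio_ecoli=0.5, seed=seed,
        )
        return cfg, state
    raise KeyError(f"unknown fixture {name!r}")
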