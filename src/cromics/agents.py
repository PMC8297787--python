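"""Individual-based layer: metabacterium state, division, shoving,
death and random-walk motility on the fine (IbM) lattice.

A metabacterium is a super-individual: a fixed count (``metab``) of
identical cells treated as one agent so agent numbers stay tractable.
Each IbM box holds at most one living metabacterium.  Agent state is
stored column-wise (struct-of-arrays) so the per-step mass and exchange
updates vectorize; the rule-based operations (division, shoving,
walking, culling) act on individual rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .grid import Grid
from .metabolism import FluxResponse, ToyStoichModel, V_SHRINKAGE

__all__ = [
    "SpeciesSpec",
    "AgentRegistry",
    "classify_phenotype",
    "phenotype_indicator",
    "shove",
    "DomainFullError",
]

PHEN_INACTIVE = "inactive"
PHEN_RESPIRATORY = "respiratory"
PHEN_FERMENTATIVE = "fermentative"
PHEN_OTHER = "other"

#: default per-flux threshold theta, mmol g_DW^-1 h^-1
PHEN_THETA = 1e-4


class DomainFullError(RuntimeError):
    """No free IbM box anywhere: a daughter cell cannot be placed."""


@dataclass(frozen=True)
class SpeciesSpec:
    """Per-species parameters.

    Masses are per *single cell* (g_DW); a metabacterium of ``metab``
    cells divides at m_max_sp * metab and dies below m_min_sp * metab.
    ``d_sp`` is the agent diffusivity in mm^2/h (0 = attached cells that
    move only by shoving).  ``f_eps`` is the EPS yield, g per g_DW of
    new biomass.
    """

    name: str
    model: ToyStoichModel
    v_sp: float = 3.07e3  # mm^3 g_DW^-1
    m_min_sp: float = 0.0
    m_max_sp: float = 1.172e-12
    metab: int = 1
    d_sp: float = 0.0  # mm^2 h^-1
    v_shrinkage: float = V_SHRINKAGE
    f_eps: float = 0.0

    def __post_init__(self) -> None:
        if self.m_max_sp <= self.m_min_sp or self.m_min_sp < 0:
            raise ValueError("require m_max_sp > m_min_sp >= 0")
        if self.metab < 1 or int(self.metab) != self.metab:
            raise ValueError("metab must be a positive integer")

    @property
    def m_div(self) -> float:
        """Metabacterium division threshold, g_DW."""
        return self.m_max_sp * self.metab

    @property
    def m_min(self) -> float:
        """Metabacterium death threshold, g_DW."""
        return self.m_min_sp * self.metab


def phenotype_indicator(v_flux: float, theta: float = PHEN_THETA) -> int:
    """Per-flux binary indicator: 1 below the threshold theta, else 2."""
    if theta <= 0:
        raise ValueError("theta must be > 0")
    return 2 if v_flux >= theta else 1


def classify_phenotype(
    flux: FluxResponse,
    theta: float = PHEN_THETA,
    o2: str = "O2",
    acetate: str = "acetate",
) -> str:
    """Composite metabolic phenotype from the flux response.

    inactive if v_bio < theta; else respiratory if O2 uptake >= theta;
    else fermentative if acetate secretion >= theta; else "other".
    """
    if theta <= 0:
        raise ValueError("theta must be > 0")
    if flux.v_bio < theta:
        return PHEN_INACTIVE
    if flux.uptake(o2) >= theta:
        return PHEN_RESPIRATORY
    if flux.secretion(acetate) >= theta:
        return PHEN_FERMENTATIVE
    return PHEN_OTHER


class AgentRegistry:
    """Column-wise store of all metabacteria plus the box occupancy map."""

    def __init__(self, grid: Grid, species: list[SpeciesSpec]):
        self.grid = grid
        self.species = list(species)
        self._sp_index = {sp.name: i for i, sp in enumerate(self.species)}
        self.mass = np.empty(0)
        self.eps = np.empty(0)  # attached EPS mass, g
        self.box = np.empty(0, dtype=np.int64)  # flat IbM index
        self.sp = np.empty(0, dtype=np.int32)
        self.alive = np.empty(0, dtype=bool)
        self.phen = np.empty(0, dtype=object)
        self.ids = np.empty(0, dtype=np.int64)
        self._next_id = 0
        self.occupancy = np.full(grid.n_ibm, -1, dtype=np.int64)

    # -- bookkeeping ---------------------------------------------------------

    def __len__(self) -> int:
        return self.mass.size

    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())

    def species_index(self, name: str) -> int:
        return self._sp_index[name]

    def add(self, species: str | int, box_flat: int, mass: float, eps: float = 0.0) -> int:
        """Append one agent; returns its row index."""
        if self.occupancy[box_flat] != -1:
            raise ValueError(f"IbM box {box_flat} already occupied")
        si = species if isinstance(species, (int, np.integer)) else self._sp_index[species]
        i = len(self)
        self.mass = np.append(self.mass, mass)
        self.eps = np.append(self.eps, eps)
        self.box = np.append(self.box, box_flat)
        self.sp = np.append(self.sp, si)
        self.alive = np.append(self.alive, True)
        self.phen = np.append(self.phen, PHEN_INACTIVE)
        self.ids = np.append(self.ids, self._next_id)
        self._next_id += 1
        self.occupancy[box_flat] = i
        return i

    def per_agent(self, attr: str) -> np.ndarray:
        """Broadcast a SpeciesSpec attribute over agents."""
        vals = np.array([getattr(sp, attr) for sp in self.species], dtype=float)
        return vals[self.sp]

    def radii(self) -> np.ndarray:
        """Current cell radii (mm) of all agents (0 for the dead)."""
        v = self.per_agent("v_sp")
        m = np.where(self.alive, self.mass, 0.0)
        return (3.0 * m * v / (4.0 * np.pi)) ** (1.0 / 3.0)

    def check_occupancy(self) -> None:
        """Assert at most one living agent per box and map consistency."""
        live = np.flatnonzero(self.alive)
        boxes = self.box[live]
        if len(np.unique(boxes)) != len(boxes):
            raise AssertionError("two living agents share an IbM box")
        occ = np.full(self.grid.n_ibm, -1, dtype=np.int64)
        occ[boxes] = live
        if not np.array_equal(occ, self.occupancy):
            raise AssertionError("occupancy map out of sync with agent boxes")

    # -- Eqs of motion -------------------------------------------------------

    def update_agent(self, i: int, flux: FluxResponse, dt: float):
        """Apply one substep of the mass/exchange update to agent ``i``.

        M' = M (1 + v_bio dt); the returned dict gives the amount change
        of each exchanged metabolite in the agent's CN box,
        delta_rho = v_ex * M * dt (positive = secreted into the box).
        Attached EPS grows by f_eps * v_bio * M * dt while growing.
        """
        if not self.alive[i]:
            raise ValueError(f"agent {i} is dead")
        m = self.mass[i]
        delta = {met: v * m * dt for met, v in flux.exchange.items()}
        self.mass[i] = m * (1.0 + flux.v_bio * dt)
        if self.mass[i] < 0:
            raise AssertionError("negative mass: shrinkage overran the cell")
        f_eps = self.species[self.sp[i]].f_eps
        if flux.v_bio > 0 and f_eps > 0:
            self.eps[i] += f_eps * flux.v_bio * m * dt
        return delta

    # -- IbM rules -----------------------------------------------------------

    def cull(self, i: int) -> bool:
        """Kill agent ``i`` if below the death threshold; frees its box."""
        spi = self.species[self.sp[i]]
        if self.alive[i] and self.mass[i] < spi.m_min:
            self.alive[i] = False
            self.occupancy[self.box[i]] = -1
            return False
        return bool(self.alive[i])

    def maybe_divide(
        self,
        i: int,
        rng: np.random.Generator,
        periodic: tuple[bool, bool, bool] = (False, False, False),
        split: float = 0.5,
        asymmetry: float = 0.0,
    ) -> Optional[tuple[int, list]]:
        """Divide agent ``i`` if its mass reached the species threshold.

        The mother keeps her box; the daughter takes a uniformly random
        free face-neighboring box, shoving a chain of neighbors toward
        the nearest free box when none is free.  Mass (and attached EPS)
        is split s : 1-s with s = split +- Uniform(asymmetry); the total
        is conserved exactly.  Returns (daughter index, shove moves) or
        None when no division occurs.
        """
        spi = self.species[self.sp[i]]
        if not self.alive[i] or self.mass[i] < spi.m_div:
            return None
        s = split if asymmetry == 0 else split + rng.uniform(-asymmetry, asymmetry)
        s = min(max(s, 0.05), 0.95)
        grid = self.grid
        mother_box = np.unravel_index(self.box[i], grid.ibm_shape)
        nbrs = grid.neighbors(mother_box, "face", "ibm", periodic)
        flat = [int(np.ravel_multi_index(b, grid.ibm_shape)) for b in nbrs]
        free = [b for b in flat if self.occupancy[b] == -1]
        moves: list = []
        if free:
            target = int(free[rng.integers(len(free))])
        else:
            target = int(flat[rng.integers(len(flat))])
            moves = shove(grid, self.occupancy, target, rng, periodic)
            for ai, _src, dst in moves:
                self.box[ai] = dst
        m_tot, e_tot = self.mass[i], self.eps[i]
        self.mass[i] = m_tot * s
        self.eps[i] = e_tot * s
        j = self.add(int(self.sp[i]), target, m_tot - self.mass[i], e_tot - self.eps[i])
        self.phen[j] = self.phen[i]
        return j, moves

    def random_walk(
        self,
        i: int,
        dt: float,
        rng: np.random.Generator,
        periodic: tuple[bool, bool, bool] = (False, False, False),
    ) -> bool:
        """One diffusive hop attempt: p = 2 * dims * D_sp * dt / dx^2.

        The hop direction is uniform over face neighbors; moves into
        occupied boxes are rejected (the agent stays).  p > 1 means the
        time step is too large for the hop discretization.
        """
        spi = self.species[self.sp[i]]
        if spi.d_sp <= 0 or not self.alive[i]:
            return False
        grid = self.grid
        dx = grid.ibm_spacing[0]
        p = 2.0 * grid.dims * spi.d_sp * dt / dx**2
        if p > 1.0:
            raise ValueError(
                f"hop probability {p:.3f} > 1 for species {spi.name}; reduce dt"
            )
        if rng.random() >= p:
            return False
        box = np.unravel_index(self.box[i], grid.ibm_shape)
        nbrs = grid.neighbors(box, "face", "ibm", periodic)
        target = nbrs[rng.integers(len(nbrs))]
        tf = int(np.ravel_multi_index(target, grid.ibm_shape))
        if self.occupancy[tf] != -1:
            return False
        self.occupancy[self.box[i]] = -1
        self.occupancy[tf] = i
        self.box[i] = tf
        return True

    def ibm_step(
        self,
        dt: float,
        rng_division: np.random.Generator,
        rng_walk: np.random.Generator | None = None,
        periodic: tuple[bool, bool, bool] = (False, False, False),
        split: float = 0.5,
        asymmetry: float = 0.0,
    ) -> dict:
        """One full IbM step: cull, then divisions in random agent order,
        then random walks.  Division/placement and walking draw from
        separate streams so toggling one feature does not shift the
        other.  Returns counts of each event."""
        if rng_walk is None:
            rng_walk = rng_division
        stats = {"culled": 0, "divided": 0, "moved": 0}
        for i in np.flatnonzero(self.alive):
            if not self.cull(int(i)):
                stats["culled"] += 1
        order = np.flatnonzero(self.alive)
        rng_division.shuffle(order)
        for i in order:
            if self.maybe_divide(int(i), rng_division, periodic, split, asymmetry) is not None:
                stats["divided"] += 1
        walkers = np.flatnonzero(self.alive)
        if any(self.species[s].d_sp > 0 for s in np.unique(self.sp[walkers])) if walkers.size else False:
            for i in walkers:
                if self.random_walk(int(i), dt, rng_walk, periodic):
                    stats["moved"] += 1
        return stats


def shove(
    grid: Grid,
    occupancy: np.ndarray,
    start_box: int,
    rng: np.random.Generator,
    periodic: tuple[bool, bool, bool] = (False, False, False),
) -> list[tuple[int, int, int]]:
    """Free ``start_box`` by displacing a chain of agents one box outward.

    A breadth-first search (randomized neighbor order, so equidistant
    free boxes are chosen uniformly under a seeded rng) finds the
    nearest free box; every agent on the BFS path then shifts one box
    toward it.  Returns [(agent index, from_flat, to_flat), ...] in the
    order applied; ``occupancy`` is updated in place, but the caller
    must update its own agent -> box records.
    """
    if occupancy[start_box] == -1:
        return []
    shape = grid.ibm_shape
    parent = {int(start_box): None}
    frontier = [int(start_box)]
    free = None
    while frontier and free is None:
        nxt = []
        for b in frontier:
            nbrs = grid.neighbors(np.unravel_index(b, shape), "face", "ibm", periodic)
            order = rng.permutation(len(nbrs))
            for k in order:
                nb = int(np.ravel_multi_index(nbrs[k], shape))
                if nb in parent:
                    continue
                parent[nb] = b
                if occupancy[nb] == -1:
                    free = nb
                    break
                nxt.append(nb)
            if free is not None:
                break
        frontier = nxt
    if free is None:
        raise DomainFullError("no free IbM box anywhere in the domain")
    path = [free]
    while parent[path[-1]] is not None:
        path.append(parent[path[-1]])
    path.reverse()  # start_box ... free
    moves = []
    # shift occupants from the free end back to start_box
    for k in range(len(path) - 1, 0, -1):
        src, dst = path[k - 1], path[k]
        ai = int(occupancy[src])
        occupancy[dst] = ai
        occupancy[src] = -1
        moves.append((ai, src, dst))
    return moves
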