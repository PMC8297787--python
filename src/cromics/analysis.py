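"""Fitness and abundance metrics, spatial profiles and crowding maps.

Fitness of a species over a run is the average exponential growth rate
F = ln(rho_T / rho_0) / t_sim; the relative fitness of two competitors
is the ratio of their fitnesses.  Spatial structure is summarized by
annulus profiles (per-ring means over boxes whose center falls between
two concentric circles), rectangular region partitions, and per-box
occupied-volume-fraction maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

from .engine import SimulationState, V_EPS

__all__ = [
    "AbundanceRecord",
    "fitness",
    "relative_fitness",
    "annulus_profile",
    "abundance_table",
    "crowding_map",
]


@dataclass
class AbundanceRecord:
    """Per-region biomass bookkeeping at one time point."""

    time: float
    region: str
    biomass: dict[str, float]  # g_DW per living species
    fractions: dict[str, float] = dc_field(default_factory=dict)
    mean_occupied_fraction: float = 0.0

    def __post_init__(self) -> None:
        total = sum(self.biomass.values())
        if not self.fractions:
            self.fractions = {
                sp: (m / total if total > 0 else 0.0) for sp, m in self.biomass.items()
            }


def fitness(rho_0: float, rho_t: float, t_sim: float) -> float:
    """Average fitness F = ln(rho_T / rho_0) / t_sim (h^-1).

    For a purely exponential trajectory this recovers the growth rate
    exactly; negative values mean net shrinkage.
    """
    if rho_0 <= 0 or rho_t <= 0:
        raise ValueError("biomasses must be > 0 (species absent or extinct)")
    if t_sim <= 0:
        raise ValueError("t_sim must be > 0")
    return float(np.log(rho_t / rho_0) / t_sim)


def relative_fitness(f1: float, f2: float) -> float:
    """Relative fitness w = F1 / F2 of species 1 in competition with 2.

    Undefined at F2 = 0; a negative w flags one shrinking and one
    growing competitor.
    """
    if f2 == 0:
        raise ZeroDivisionError("relative fitness undefined: reference fitness is 0")
    return f1 / f2


def annulus_profile(
    values: np.ndarray,
    center_box: tuple[int, int],
    dx: float,
    n_rings: int,
    counts: bool = False,
):
    """Ring-averaged radial profile of a 2D per-box metric.

    Ring r collects boxes whose center-to-center distance from the
    center box lies in [r*dx, (r+1)*dx).  Returns (means, sds, counts)
    arrays of length n_rings; empty rings hold NaN means.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim == 3 and v.shape[2] == 1:
        v = v[:, :, 0]
    if v.ndim != 2:
        raise ValueError("annulus_profile expects a 2D slab (or nz=1 slice)")
    ci, cj = center_box
    if not (0 <= ci < v.shape[0] and 0 <= cj < v.shape[1]):
        raise ValueError(f"center box {center_box} outside grid {v.shape}")
    ii, jj = np.meshgrid(np.arange(v.shape[0]), np.arange(v.shape[1]), indexing="ij")
    dist = dx * np.hypot(ii - ci, jj - cj)
    ring = np.floor(dist / dx).astype(int)
    means = np.full(n_rings, np.nan)
    sds = np.full(n_rings, np.nan)
    ns = np.zeros(n_rings, dtype=int)
    for r in range(n_rings):
        sel = ring == r
        ns[r] = int(sel.sum())
        if ns[r]:
            means[r] = v[sel].mean()
            sds[r] = v[sel].std()
    return means, sds, ns


def _region_masks(state: SimulationState, partition) -> dict[str, np.ndarray]:
    """Region name -> boolean mask over flat IbM boxes."""
    grid = state.grid
    nx, ny, nz = grid.ibm_shape
    i, j, k = np.unravel_index(np.arange(grid.n_ibm), grid.ibm_shape)
    if partition == "global":
        return {"global": np.ones(grid.n_ibm, dtype=bool)}
    if partition == "quadrants":
        px, py = 2, 2
    elif isinstance(partition, tuple):
        px, py = partition
    elif partition == "z-layers":
        return {f"z{z}": k == z for z in range(nz)}
    else:
        raise ValueError(f"unknown partition {partition!r}")
    ei = np.minimum(i * px // nx, px - 1)
    ej = np.minimum(j * py // ny, py - 1)
    return {
        f"r{a}{b}": (ei == a) & (ej == b) for a in range(px) for b in range(py)
    }


def abundance_table(state: SimulationState, partition="global") -> list[AbundanceRecord]:
    """Per-region biomass and relative abundance of the living species.

    ``partition`` is "global", "quadrants" (2x2), a (px, py) tuple of
    rectangular tile counts, or "z-layers".  Regions tile the grid
    exactly, so region sums recover the global totals.
    """
    reg = state.registry
    cm = crowding_map(state).ravel()
    masks = _region_masks(state, partition)
    live = np.flatnonzero(reg.alive)
    out = []
    for name, mask in masks.items():
        in_region = mask[reg.box[live]]
        biomass = {}
        for si, sp in enumerate(reg.species):
            sel = in_region & (reg.sp[live] == si)
            biomass[sp.name] = float(reg.mass[live[sel]].sum())
        occ = cm[mask]
        occ = occ[occ > 0]
        out.append(
            AbundanceRecord(
                time=state.t,
                region=name,
                biomass=biomass,
                mean_occupied_fraction=float(occ.mean()) if occ.size else 0.0,
            )
        )
    return out


def crowding_map(state: SimulationState) -> np.ndarray:
    """Occupied volume fraction (cells + attached EPS) per IbM box."""
    grid = state.grid
    reg = state.registry
    vol = np.zeros(grid.n_ibm)
    live = np.flatnonzero(reg.alive)
    if live.size:
        v_sp = reg.per_agent("v_sp")[live]
        np.add.at(vol, reg.box[live], reg.mass[live] * v_sp + reg.eps[live] * V_EPS)
    frac = vol / grid.v_ibm_box
    if np.any(frac >= 1.0):
        b = int(np.argmax(frac))
        raise AssertionError(
            f"IbM box {np.unravel_index(b, grid.ibm_shape)} occupied fraction "
            f"{frac[b]:.3f} >= 1"
        )
    return frac.reshape(grid.ibm_shape)
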