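"""Scaled-particle-theory (SPT) excluded-volume calculations.

Cells and macromolecules are hard spheres.  The local crowder population
of a box is summarized by four size moments S0..S3 (S3 is the occupied
volume fraction); the activity coefficient gamma_met of a metabolite of
radius R_met follows from SPT and equals the ratio of total box volume
to the volume available to that metabolite.  gamma raises the effective
concentration a cell senses and lowers the effective diffusion
coefficient: C_eff = rho * gamma * 1e6 / V_box and D_eff = D0 / gamma.

Only macromolecules above a molecular-weight threshold (default 400 Da)
occupy explicit volume; smaller solutes are treated as volumeless
(R_met = 0), for which gamma reduces exactly to 1/(1 - S3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .units import AVOGADRO, L_PER_MM3

__all__ = [
    "MoleculeSpec",
    "CrowdingMoments",
    "OverfilledBoxError",
    "CROWDER_MW_THRESHOLD",
    "molecule_radius",
    "cell_radius",
    "spt_moments",
    "activity_coefficient",
    "effective_concentration",
    "effective_diffusion",
]

#: molecular weight (Da) above which a molecule occupies explicit volume
CROWDER_MW_THRESHOLD = 400.0


class OverfilledBoxError(ValueError):
    """Occupied volume fraction S3 >= 1 in some box."""


@dataclass(frozen=True)
class MoleculeSpec:
    """A diffusible chemical species and its transport/crowding parameters.

    Parameters
    ----------
    name : str
    mw : float
        Molecular weight, Da.
    d0 : float
        Dilute-solution diffusion coefficient, mm^2/ms.
    v_max : float
        Maximum uptake flux V_M, mmol g_DW^-1 h^-1.
    k_m : float
        Michaelis constant, mM (required > 0 for active transport).
    transport : {"active", "passive"}
    specific_volume : float
        Partial specific volume, mm^3 per g of molecule.
    penetrates_membrane : bool
        If True, cell volume is omitted from this metabolite's crowding
        moments (penetrants are not excluded by cell interiors).
    crowder_threshold : float
        MW threshold above which the molecule is an explicit crowder.
    """

    name: str
    mw: float
    d0: float
    v_max: float = 0.0
    k_m: float = 1e-2
    transport: str = "active"
    specific_volume: float = 730.0
    penetrates_membrane: bool = False
    crowder_threshold: float = CROWDER_MW_THRESHOLD

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError(f"{self.name}: D0 must be >= 0")
        if self.v_max < 0:
            raise ValueError(f"{self.name}: V_M must be >= 0")
        if self.transport == "active" and self.k_m <= 0:
            raise ValueError(f"{self.name}: K_M must be > 0 for active transport")

    @property
    def is_crowder(self) -> bool:
        return self.mw > self.crowder_threshold

    @property
    def radius(self) -> float:
        """Hard-sphere radius, mm; 0 for sub-threshold (volumeless) solutes."""
        if not self.is_crowder:
            return 0.0
        return molecule_radius(self.mw, self.specific_volume)


@dataclass
class CrowdingMoments:
    """SPT size moments of one box's crowder population.

    S_x has units mm^(x-3): S3 is the dimensionless occupied volume
    fraction, S0 the crowder number density (mm^-3) times pi/6... the
    common prefactor pi/(6 V_box) is already applied.
    """

    s0: float = 0.0
    s1: float = 0.0
    s2: float = 0.0
    s3: float = 0.0
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if min(self.s0, self.s1, self.s2, self.s3) < 0:
            raise ValueError("crowding moments must be non-negative")
        if self.s3 >= 1.0:
            raise OverfilledBoxError(
                f"occupied volume fraction S3 = {self.s3:.4f} >= 1"
            )

    def __add__(self, other: "CrowdingMoments") -> "CrowdingMoments":
        return CrowdingMoments(
            self.s0 + other.s0,
            self.s1 + other.s1,
            self.s2 + other.s2,
            self.s3 + other.s3,
            self.provenance + other.provenance,
        )


def molecule_radius(mw: float, specific_volume: float) -> float:
    """Hard-sphere radius (mm) of a molecule of weight ``mw`` (Da).

    The per-molecule volume is (mw / N_A) grams times the specific
    volume (mm^3/g); the radius follows from the sphere volume.
    """
    if mw <= 0 or specific_volume <= 0:
        raise ValueError("molecular weight and specific volume must be > 0")
    v = (mw / AVOGADRO) * specific_volume
    return (3.0 * v / (4.0 * np.pi)) ** (1.0 / 3.0)


def cell_radius(m_cell, v_sp: float):
    """Cell radius (mm) from dry mass (g_DW) and specific volume (mm^3/g_DW).

    The cell volume is exactly M_cell * v_sp.  Accepts scalars or arrays.
    """
    m = np.asarray(m_cell, dtype=float)
    if np.any(m < 0):
        raise ValueError("cell mass must be non-negative")
    r = (3.0 * m * v_sp / (4.0 * np.pi)) ** (1.0 / 3.0)
    return float(r) if np.isscalar(m_cell) else r


def spt_moments(
    cell_radii: Iterable[float],
    macromolecules: Iterable[tuple[float, float]],
    v_box: float,
    box_label: str = "",
) -> CrowdingMoments:
    """SPT moments S0..S3 of one box.

    Parameters
    ----------
    cell_radii
        Radii (mm) of the cells present in the box.
    macromolecules
        Pairs (rho_l, R_l): amount of macromolecule l in mmol and its
        molecular radius in mm.
    v_box
        Box volume, mm^3.

    Each moment is (pi / 6 V_box) * [sum_l rho_l*N_A/1e3 * (2R_l)^x +
    sum_cells (2R_cell)^x]; S3 is the occupied volume fraction and must
    stay below 1.
    """
    if v_box <= 0:
        raise ValueError("V_box must be > 0")
    sums = np.zeros(4)
    names = []
    for r in cell_radii:
        if r < 0:
            raise ValueError("cell radii must be >= 0")
        d = 2.0 * r
        sums += [1.0, d, d * d, d * d * d]
        names.append("cell")
    for rho, r in macromolecules:
        if rho < 0 or r < 0:
            raise ValueError("macromolecule amounts and radii must be >= 0")
        n_mol = rho * AVOGADRO * 1e-3  # mmol -> number of molecules
        d = 2.0 * r
        sums += n_mol * np.array([1.0, d, d * d, d * d * d])
        names.append("macromolecule")
    pref = np.pi / (6.0 * v_box)
    s = pref * sums
    if s[3] >= 1.0:
        where = f" in box {box_label}" if box_label else ""
        raise OverfilledBoxError(
            f"occupied volume fraction S3 = {s[3]:.4f} >= 1{where}"
        )
    return CrowdingMoments(*s, provenance=tuple(dict.fromkeys(names)))


def activity_coefficient(s: CrowdingMoments | Sequence[float], r_met: float = 0.0):
    """SPT activity coefficient gamma for a metabolite of radius ``r_met``.

    ln gamma = -ln(1-S3) + [6 S2/(1-S3)] R + [12 S1/(1-S3) +
    18 S2^2/(1-S3)^2] R^2 + [8 S0/(1-S3) + 24 S1 S2/(1-S3)^2 +
    24 S2^3/(1-S3)^3] R^3.  For R = 0 this is exactly 1/(1-S3), the
    reciprocal of the free volume fraction.  gamma >= 1 always.
    """
    if isinstance(s, CrowdingMoments):
        s0, s1, s2, s3 = s.s0, s.s1, s.s2, s.s3
    else:
        s0, s1, s2, s3 = s
    return gamma_from_moments(s0, s1, s2, s3, r_met)


def gamma_from_moments(s0, s1, s2, s3, r_met: float = 0.0):
    """Vectorized SPT gamma from raw moment arrays (see activity_coefficient)."""
    s3 = np.asarray(s3, dtype=float)
    if np.any(s3 >= 1.0):
        raise OverfilledBoxError("occupied volume fraction S3 >= 1")
    if np.any(np.asarray(r_met) < 0):
        raise ValueError("metabolite radius must be >= 0")
    q = 1.0 - s3
    ln_g = -np.log(q)
    if np.any(np.asarray(r_met) > 0):
        r = r_met
        ln_g = ln_g + (6.0 * np.asarray(s2) / q) * r
        ln_g = ln_g + (12.0 * np.asarray(s1) / q + 18.0 * np.asarray(s2) ** 2 / q**2) * r * r
        ln_g = ln_g + (
            8.0 * np.asarray(s0) / q
            + 24.0 * np.asarray(s1) * np.asarray(s2) / q**2
            + 24.0 * np.asarray(s2) ** 3 / q**3
        ) * r**3
    g = np.exp(ln_g)
    return float(g) if np.isscalar(s3) or g.ndim == 0 else g


def effective_concentration(rho, v_box: float, gamma=1.0):
    """Effective concentration (mM) = amount per *available* volume.

    C_eff = rho * gamma * 1e6 / V_box, with rho in mmol and V_box in
    mm^3 (1 mm^3 = 1e-6 L).  Crowding (gamma > 1) raises C_eff.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0):
        raise ValueError("metabolite amounts must be >= 0")
    if np.any(np.asarray(gamma) < 1.0 - 1e-12):
        raise ValueError("gamma must be >= 1")
    c = rho * np.asarray(gamma) * L_PER_MM3 / v_box
    return float(c) if c.ndim == 0 else c


def effective_diffusion(gamma, d0):
    """Crowded diffusion coefficient D_eff = D0 / gamma (same units as D0)."""
    if np.any(np.asarray(gamma) < 1.0 - 1e-12):
        raise ValueError("gamma must be >= 1")
    d = np.asarray(d0, dtype=float) / np.asarray(gamma, dtype=float)
    return float(d) if d.ndim == 0 else d
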