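"""Lattice geometry for the two coupled grids.

Metabolite fields live on a coarse lattice (the "CN lattice", after the
Crank-Nicolson solver that advances them) while agents occupy a finer
"IbM lattice"; every CN box owns ``coarse_factor**dims`` IbM boxes.  2D
systems are a monolayer of rectangular prisms (nz = 1) with an explicit
height dz, so no math is special-cased on dimensionality.

Indices are 0-based tuples in axis order (x, y, z); a box "position"
refers to its center.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import numpy as np

__all__ = [
    "GridSpec",
    "BoundarySpec",
    "Grid",
    "build_grid",
]

Face = Literal["x-", "x+", "y-", "y+", "z-", "z+"]
FACES: tuple[Face, ...] = ("x-", "x+", "y-", "y+", "z-", "z+")

# face -> (axis, side) with side 0 = low, 1 = high
_FACE_AXIS: dict[Face, tuple[int, int]] = {
    "x-": (0, 0), "x+": (0, 1),
    "y-": (1, 0), "y+": (1, 1),
    "z-": (2, 0), "z+": (2, 1),
}


class ConfigurationError(ValueError):
    """Raised when a grid or boundary specification is inconsistent."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the coarse (CN) lattice.

    Parameters
    ----------
    nx, ny, nz
        CN box counts per axis.  A 2D system is a monolayer, nz = 1.
    dx, dy, dz
        CN box edge lengths in mm.  V_box = dx*dy*dz.
    coarse_factor
        Integer number of IbM boxes per CN box edge (in x and y, and in z
        for 3D systems).
    dims
        2 or 3.  dims = 2 requires nz = 1.
    """

    nx: int
    ny: int
    nz: int = 1
    dx: float = 0.05
    dy: float | None = None
    dz: float | None = None
    coarse_factor: int = 2
    dims: int = 2

    def __post_init__(self) -> None:
        dy = self.dx if self.dy is None else self.dy
        dz = self.dx if self.dz is None else self.dz
        object.__setattr__(self, "dy", dy)
        object.__setattr__(self, "dz", dz)
        if min(self.nx, self.ny, self.nz) < 1:
            raise ConfigurationError("box counts must be >= 1")
        if min(self.dx, self.dy, self.dz) <= 0:
            raise ConfigurationError("box edge lengths must be > 0")
        if self.dims not in (2, 3):
            raise ConfigurationError("dims must be 2 or 3")
        if self.dims == 2 and self.nz != 1:
            raise ConfigurationError("a 2D grid is a monolayer: nz must be 1")
        cf = self.coarse_factor
        if cf < 1 or int(cf) != cf:
            raise ConfigurationError("coarse_factor must be a positive integer")
        if self.nx % 1 or self.ny % 1:
            raise ConfigurationError("box counts must be integers")


@dataclass
class BoundarySpec:
    """Per-face boundary dialects for metabolite fields and agents.

    ``metabolite`` maps a face to one of:

    - ``("fixed", value_mM)`` : concentration held at a constant effective
      concentration in the layer of boxes adjacent to the face,
    - ``"zero_flux"``         : reflecting,
    - ``"periodic"``          : wraps to the opposite face,
    - ``"absorbing"``         : concentration 0 just outside the face.

    ``agent`` maps a face to ``"zero_flux"`` or ``"periodic"``.
    ``clamped`` lists metabolites held at a constant effective
    concentration in *every* box (field-wide clamp), name -> target mM.
    """

    metabolite: dict[Face, object] = field(default_factory=dict)
    agent: dict[Face, str] = field(default_factory=dict)
    clamped: dict[str, float] = field(default_factory=dict)

    def metabolite_mode(self, face: Face, name: str | None = None):
        mode = self.metabolite.get(face, "zero_flux")
        if isinstance(mode, tuple) and mode[0] == "fixed_by_name":
            if name is not None and name in mode[1]:
                return ("fixed", mode[1][name])
            return "zero_flux"
        return mode

    def agent_mode(self, face: Face) -> str:
        return self.agent.get(face, "zero_flux")

    def validate(self, dims: int) -> None:
        for kind in ("metabolite", "agent"):
            table = getattr(self, kind)
            for axis, lo, hi in (("x", "x-", "x+"), ("y", "y-", "y+"), ("z", "z-", "z+")):
                a = table.get(lo, "zero_flux")
                b = table.get(hi, "zero_flux")
                if ("periodic" in (a, b)) and a != b:
                    raise ConfigurationError(
                        f"periodic faces must come in opposing pairs ({kind}, axis {axis})"
                    )

    def periodic_axes(self, kind: str = "metabolite") -> tuple[bool, bool, bool]:
        table = getattr(self, kind)
        return (
            table.get("x-", "zero_flux") == "periodic",
            table.get("y-", "zero_flux") == "periodic",
            table.get("z-", "zero_flux") == "periodic",
        )


@dataclass(frozen=True)
class Grid:
    """Index spaces and volumes for the coupled CN and IbM lattices."""

    spec: GridSpec
    cn_shape: tuple[int, int, int]
    ibm_shape: tuple[int, int, int]
    cn_spacing: tuple[float, float, float]
    ibm_spacing: tuple[float, float, float]

    @property
    def dims(self) -> int:
        return self.spec.dims

    @property
    def coarse_factor(self) -> int:
        return self.spec.coarse_factor

    @property
    def v_cn_box(self) -> float:
        dx, dy, dz = self.cn_spacing
        return dx * dy * dz

    @property
    def v_ibm_box(self) -> float:
        dx, dy, dz = self.ibm_spacing
        return dx * dy * dz

    @property
    def n_cn(self) -> int:
        return int(np.prod(self.cn_shape))

    @property
    def n_ibm(self) -> int:
        return int(np.prod(self.ibm_shape))

    # -- coarse/fine mapping -------------------------------------------------

    def _check(self, idx: Sequence[int], shape: tuple[int, int, int]) -> None:
        if len(idx) != 3:
            raise IndexError(f"expected a 3-tuple index, got {idx!r}")
        for c, n in zip(idx, shape):
            if not 0 <= c < n:
                raise IndexError(f"index {tuple(idx)} out of range for shape {shape}")

    def cn_of_ibm(self, ibm_index: Sequence[int]) -> tuple[int, int, int]:
        """CN box owning a given IbM box."""
        self._check(ibm_index, self.ibm_shape)
        f = self.coarse_factor
        fz = f if self.dims == 3 else 1
        i, j, k = ibm_index
        return (i // f, j // f, k // fz)

    def ibm_children(self, cn_index: Sequence[int]) -> list[tuple[int, int, int]]:
        """All IbM boxes owned by a CN box (coarse_factor**dims of them)."""
        self._check(cn_index, self.cn_shape)
        f = self.coarse_factor
        fz = f if self.dims == 3 else 1
        i, j, k = cn_index
        return [
            (i * f + a, j * f + b, k * fz + c)
            for a in range(f)
            for b in range(f)
            for c in range(fz)
        ]

    def cn_of_ibm_array(self, ibm_flat: np.ndarray) -> np.ndarray:
        """Vectorized owner lookup: flat IbM indices -> flat CN indices."""
        f = self.coarse_factor
        fz = f if self.dims == 3 else 1
        i, j, k = np.unravel_index(ibm_flat, self.ibm_shape)
        return np.ravel_multi_index((i // f, j // f, k // fz), self.cn_shape)

    # -- neighborhoods -------------------------------------------------------

    def neighbors(
        self,
        box: Sequence[int],
        connectivity: str = "face",
        lattice: str = "ibm",
        periodic: tuple[bool, bool, bool] = (False, False, False),
    ) -> list[tuple[int, int, int]]:
        """In-bounds neighbors of a box; periodic axes wrap, others truncate."""
        shape = self.ibm_shape if lattice == "ibm" else self.cn_shape
        self._check(box, shape)
        if connectivity == "face":
            offsets: Iterator = (
                tuple(s * e for e in np.eye(3, dtype=int)[ax])
                for ax in range(3)
                for s in (-1, 1)
                if shape[ax] > 1
            )
        elif connectivity == "moore":
            offsets = (
                off
                for off in itertools.product((-1, 0, 1), repeat=3)
                if any(off) and all(shape[ax] > 1 or off[ax] == 0 for ax in range(3))
            )
        else:
            raise ValueError(f"unknown connectivity {connectivity!r}")
        out = []
        for off in offsets:
            cand = []
            ok = True
            for ax in range(3):
                c = box[ax] + off[ax]
                if periodic[ax]:
                    c %= shape[ax]
                elif not 0 <= c < shape[ax]:
                    ok = False
                    break
                cand.append(c)
            if ok:
                out.append(tuple(cand))
        return out

    def box_centers(self, lattice: str = "ibm") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Center coordinates (mm) along each axis for the chosen lattice."""
        shape = self.ibm_shape if lattice == "ibm" else self.cn_shape
        spacing = self.ibm_spacing if lattice == "ibm" else self.cn_spacing
        return tuple((np.arange(n) + 0.5) * d for n, d in zip(shape, spacing))


def build_grid(spec: GridSpec) -> Grid:
    """Build the coupled CN/IbM index spaces from a validated spec.

    The IbM lattice refines the CN lattice by ``coarse_factor`` along x
    and y (and z for 3D grids); IbM box edge = CN box edge / factor.
    """
    f = spec.coarse_factor
    fz = f if spec.dims == 3 else 1
    cn_shape = (spec.nx, spec.ny, spec.nz)
    ibm_shape = (spec.nx * f, spec.ny * f, spec.nz * fz)
    cn_spacing = (spec.dx, spec.dy, spec.dz)
    ibm_spacing = (spec.dx / f, spec.dy / f, spec.dz / fz)
    return Grid(
        spec=spec,
        cn_shape=cn_shape,
        ibm_shape=ibm_shape,
        cn_spacing=cn_spacing,
        ibm_spacing=ibm_spacing,
    )
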