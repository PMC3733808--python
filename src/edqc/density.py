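"""Per-residue RSR and RSCC from density grids.

A calculated density is synthesised as one isotropic Gaussian per atom,

    rho(r) = occ * Z * (4*pi / (B + b_added))**1.5
                 * exp(-4*pi**2 * |r - r_atom|**2 / (B + b_added)),

whose integral over space is ``occ * Z``.  Each residue is scored over the
voxels within ``mask_radius`` of its atoms:

    RSR  = sum |rho_obs - rho_calc| / sum (|rho_obs| + |rho_calc|)
    RSCC = Pearson correlation of the two value sets on the mask

Grids are orthogonal-axis only; values are evaluated at voxel centers.  This
module exists so the whole engine can be exercised offline — it makes no
attempt at numeric parity with any databank pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model_io import ResidueKey, StructureModel, residue_average_occupancy
from .stats import ResidueStats

__all__ = [
    "DensityGrid",
    "AtomDensityParams",
    "rho_calc",
    "residue_mask",
    "rsr",
    "rscc",
    "compute_residue_stats",
    "grid_for_model",
    "read_grid",
    "write_grid",
]

# Atomic numbers for elements seen in typical models; unknowns fall back to carbon.
ATOMIC_NUMBER = {
    "H": 1, "D": 1, "B": 5, "C": 6, "N": 7, "O": 8, "F": 9, "NA": 11, "MG": 12,
    "AL": 13, "SI": 14, "P": 15, "S": 16, "CL": 17, "K": 19, "CA": 20, "MN": 25,
    "FE": 26, "CO": 27, "NI": 28, "CU": 29, "ZN": 30, "SE": 34, "BR": 35,
    "RB": 37, "SR": 38, "AG": 47, "CD": 48, "I": 53, "CS": 55, "BA": 56,
    "YB": 70, "PT": 78, "AU": 79, "HG": 80, "PB": 82,
}


@dataclass
class DensityGrid:
    origin: np.ndarray  # Å, position of voxel (0,0,0) center
    spacing: np.ndarray  # Å per axis
    dims: tuple[int, int, int]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.dims = tuple(int(d) for d in self.dims)
        if np.any(self.spacing <= 0):
            raise ValueError("grid spacing must be positive")
        if any(d <= 0 for d in self.dims):
            raise ValueError("grid dims must be positive")
        self.values = np.asarray(self.values, dtype=float).reshape(self.dims)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must be finite")

    @classmethod
    def empty(cls, origin, spacing, dims) -> "DensityGrid":
        dims = tuple(int(d) for d in dims)
        return cls(origin=origin, spacing=spacing, dims=dims, values=np.zeros(dims))

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[i] + self.spacing[i] * np.arange(self.dims[i]) for i in range(3)
        )

    def congruent(self, other: "DensityGrid") -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.origin, other.origin)
            and np.allclose(self.spacing, other.spacing)
        )

    def upper(self) -> np.ndarray:
        return self.origin + self.spacing * (np.array(self.dims) - 1)


@dataclass(frozen=True)
class AtomDensityParams:
    b_added: float = 10.0  # Å² smearing added to each atomic B
    mask_radius: float = 1.5  # Å integration region around atoms

    def __post_init__(self) -> None:
        if self.b_added <= 0 or self.mask_radius <= 0:
            raise ValueError("b_added and mask_radius must be positive")


def grid_for_model(
    model: StructureModel, spacing: float = 0.5, margin: float = 3.0
) -> DensityGrid:
    """An empty grid covering the model's bounding box plus a margin."""
    pos = np.array([a.position for r in model.residues for a in r.atoms])
    lo = pos.min(axis=0) - margin
    hi = pos.max(axis=0) + margin
    dims = np.ceil((hi - lo) / spacing).astype(int) + 1
    return DensityGrid.empty(origin=lo, spacing=(spacing,) * 3, dims=tuple(dims))


def _check_inside(grid: DensityGrid, position, margin: float = 0.0) -> None:
    p = np.asarray(position, dtype=float)
    if np.any(p < grid.origin + margin - 1e-9) or np.any(p > grid.upper() - margin + 1e-9):
        raise ValueError(f"atom at {tuple(p)} outside grid bounds")


def rho_calc(
    model: StructureModel, grid_spec: DensityGrid, params: AtomDensityParams
) -> DensityGrid:
    """Sum of per-atom Gaussians on the geometry of ``grid_spec``."""
    out = DensityGrid.empty(grid_spec.origin, grid_spec.spacing, grid_spec.dims)
    ax, ay, az = out.axes()
    values = out.values
    for res in model.residues:
        for atom in res.atoms:
            _check_inside(out, atom.position, margin=params.mask_radius)
            if atom.occupancy == 0.0:
                continue
            b_eff = atom.b_factor + params.b_added
            z = ATOMIC_NUMBER.get(atom.element.upper(), 6)
            amp = atom.occupancy * z * (4.0 * math.pi / b_eff) ** 1.5
            alpha = 4.0 * math.pi**2 / b_eff
            # contributions below 1e-12 of peak are dropped (local box)
            reach = math.sqrt(12.0 * math.log(10.0) / alpha)
            px, py, pz = atom.position
            ix = _axis_window(ax, px, reach)
            iy = _axis_window(ay, py, reach)
            iz = _axis_window(az, pz, reach)
            if ix is None or iy is None or iz is None:
                continue
            dx2 = (ax[ix] - px) ** 2
            dy2 = (ay[iy] - py) ** 2
            dz2 = (az[iz] - pz) ** 2
            r2 = dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :]
            values[np.ix_(ix, iy, iz)] += amp * np.exp(-alpha * r2)
    return out


def _axis_window(axis: np.ndarray, center: float, reach: float):
    idx = np.nonzero(np.abs(axis - center) <= reach)[0]
    return idx if idx.size else None


def residue_mask(grid: DensityGrid, atoms, mask_radius: float) -> np.ndarray:
    """Boolean grid mask of voxels whose center is within ``mask_radius`` of
    any atom center.  An empty mask is an error."""
    if mask_radius <= 0:
        raise ValueError("mask_radius must be positive")
    mask = np.zeros(grid.dims, dtype=bool)
    ax, ay, az = grid.axes()
    for atom in atoms:
        pos = atom.position if hasattr(atom, "position") else atom
        px, py, pz = pos
        ix = _axis_window(ax, px, mask_radius)
        iy = _axis_window(ay, py, mask_radius)
        iz = _axis_window(az, pz, mask_radius)
        if ix is None or iy is None or iz is None:
            continue
        r2 = (
            (ax[ix] - px)[:, None, None] ** 2
            + (ay[iy] - py)[None, :, None] ** 2
            + (az[iz] - pz)[None, None, :] ** 2
        )
        sub = mask[np.ix_(ix, iy, iz)]
        mask[np.ix_(ix, iy, iz)] = sub | (r2 <= mask_radius**2)
    if not mask.any():
        raise ValueError("empty residue mask: atoms fall outside the grid geometry")
    return mask


def _masked(obs: DensityGrid, calc: DensityGrid, mask) -> tuple[np.ndarray, np.ndarray]:
    if not obs.congruent(calc):
        raise ValueError("grids are not congruent")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != obs.values.shape:
        raise ValueError("mask shape does not match grid dims")
    if not mask.any():
        raise ValueError("empty mask")
    return obs.values[mask], calc.values[mask]


def rsr(obs: DensityGrid, calc: DensityGrid, mask) -> float:
    """Real-space residual: sum|o-c| / sum(|o|+|c|) over the mask; in [0, 1]."""
    o, c = _masked(obs, calc, mask)
    denom = np.sum(np.abs(o) + np.abs(c))
    if denom == 0.0:
        raise ValueError("zero denominator: no density on mask")
    return float(np.sum(np.abs(o - c)) / denom)


def rscc(obs: DensityGrid, calc: DensityGrid, mask) -> float:
    """Pearson correlation of observed vs calculated values over the mask."""
    o, c = _masked(obs, calc, mask)
    if o.size < 2:
        raise ValueError("mask must cover at least 2 voxels")
    if np.var(o) == 0.0 or np.var(c) == 0.0:
        raise ValueError("zero variance on mask")
    r = np.corrcoef(o, c)[0, 1]
    return float(min(1.0, max(-1.0, r)))


def compute_residue_stats(
    model: StructureModel, obs: DensityGrid, params: AtomDensityParams
) -> dict[ResidueKey, ResidueStats]:
    """RSR/RSCC per residue against the full-model calculated density, plus
    coordinate-derived average occupancy and OWAB."""
    calc = rho_calc(model, obs, params)
    out: dict[ResidueKey, ResidueStats] = {}
    for res in model.residues:
        mask = residue_mask(obs, res.atoms, params.mask_radius)
        occ_sum = sum(a.occupancy for a in res.atoms)
        owab = (
            sum(a.occupancy * a.b_factor for a in res.atoms) / occ_sum
            if occ_sum > 0
            else None
        )
        out[res.key] = ResidueStats(
            rsr=rsr(obs, calc, mask),
            rscc=rscc(obs, calc, mask),
            avg_occupancy=residue_average_occupancy(res),
            owab=owab,
        )
    return out


def write_grid(grid: DensityGrid) -> str:
    """Internal text format: header lines then row-major values."""
    header = [
        f"#origin {grid.origin[0]:.6g} {grid.origin[1]:.6g} {grid.origin[2]:.6g}",
        f"#spacing {grid.spacing[0]:.6g} {grid.spacing[1]:.6g} {grid.spacing[2]:.6g}",
        f"#dims {grid.dims[0]} {grid.dims[1]} {grid.dims[2]}",
    ]
    body = " ".join(repr(float(v)) for v in grid.values.ravel())
    return "\n".join(header) + "\n" + body + "\n"


def read_grid(text: str) -> DensityGrid:
    origin = spacing = dims = None
    values: list[float] = []
    for line in text.splitlines():
        if line.startswith("#origin"):
            origin = [float(x) for x in line.split()[1:4]]
        elif line.startswith("#spacing"):
            spacing = [float(x) for x in line.split()[1:4]]
        elif line.startswith("#dims"):
            dims = [int(x) for x in line.split()[1:4]]
        elif line.startswith("#"):
            continue
        else:
            values.extend(float(x) for x in line.split())
    if origin is None or spacing is None or dims is None:
        raise ValueError("grid header incomplete (need #origin, #spacing, #dims)")
    return DensityGrid(origin=origin, spacing=spacing, dims=tuple(dims), values=np.array(values))
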