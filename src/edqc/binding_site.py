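"""Distance-based binding-site detection.

The site of a ligand is every polymer residue, plus every non-water,
non-blacklisted hetero residue (metals included), with any atom within the
cutoff distance (default 4.5 Å, boundary inclusive) of any ligand atom.
Neighbor finding uses a cell list with cell edge equal to the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

from .model_io import Residue, ResidueKey, StructureModel

if TYPE_CHECKING:  # pragma: no cover
    from .ligand_extraction import ExclusionLists, LigandGroup

__all__ = ["BindingSite", "ConsistencyError", "neighbor_search", "find_binding_site"]

DEFAULT_SITE_CUTOFF = 4.5


class ConsistencyError(ValueError):
    """A ligand references residues that are not present in the model."""


@dataclass
class BindingSite:
    ligand: "LigandGroup"
    residues: tuple[ResidueKey, ...]
    cutoff: float


def _as_positions(atoms) -> np.ndarray:
    arr = np.asarray(atoms, dtype=float)
    if arr.size == 0:
        return arr.reshape(0, 3)
    return arr.reshape(-1, 3)


def atom_pairs_within(
    pos_a, pos_b, cutoff: float, strict: bool = False
) -> set[tuple[int, int]]:
    """All (i, j) index pairs with ``|a_i - b_j| <= cutoff`` (``<`` if strict).

    Spatial binning with cell edge >= cutoff; each query atom only inspects
    the 27 surrounding cells.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    a = _as_positions(pos_a)
    b = _as_positions(pos_b)
    pairs: set[tuple[int, int]] = set()
    if len(a) == 0 or len(b) == 0:
        return pairs

    edge = max(cutoff, 1e-9)
    cells: dict[tuple[int, int, int], list[int]] = {}
    cell_b = np.floor(b / edge).astype(np.int64)
    for j in range(len(b)):
        cells.setdefault(tuple(cell_b[j]), []).append(j)

    cutoff2 = cutoff * cutoff
    cell_a = np.floor(a / edge).astype(np.int64)
    offsets = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)]
    for i in range(len(a)):
        cx, cy, cz = cell_a[i]
        cand: list[int] = []
        for dx, dy, dz in offsets:
            cand.extend(cells.get((cx + dx, cy + dy, cz + dz), ()))
        if not cand:
            continue
        d2 = np.sum((b[cand] - a[i]) ** 2, axis=1)
        hit = d2 < cutoff2 if strict else d2 <= cutoff2
        for j_idx in np.nonzero(hit)[0]:
            pairs.add((i, cand[j_idx]))
    return pairs


def neighbor_search(atoms_a, atoms_b, cutoff: float) -> set[tuple[int, int]]:
    """Exactly the index pairs at Euclidean distance <= cutoff (cell list)."""
    return atom_pairs_within(atoms_a, atoms_b, cutoff, strict=False)


def _gather(residues: Iterable[Residue]) -> tuple[np.ndarray, list[ResidueKey]]:
    positions: list[tuple[float, float, float]] = []
    owner: list[ResidueKey] = []
    for res in residues:
        for a in res.atoms:
            positions.append(a.position)
            owner.append(res.key)
    return _as_positions(positions), owner


def residue_pairs_within(
    residues: Sequence[Residue], cutoff: float, strict: bool = True
) -> set[frozenset[ResidueKey]]:
    """Unordered pairs of distinct residues with any inter-atomic distance
    below (strict) or within (inclusive) the cutoff."""
    pos, owner = _gather(residues)
    out: set[frozenset[ResidueKey]] = set()
    for i, j in atom_pairs_within(pos, pos, cutoff, strict=strict):
        if owner[i] != owner[j]:
            out.add(frozenset((owner[i], owner[j])))
    return out


def find_binding_site(
    model: StructureModel,
    ligand: "LigandGroup",
    lists: "ExclusionLists",
    cutoff: float = DEFAULT_SITE_CUTOFF,
) -> BindingSite:
    """All eligible residues with any atom within ``cutoff`` of any ligand atom.

    Eligible residues are polymer residues and non-water, non-blacklisted
    hetero residues (non-propagating metals included); the ligand's own
    components are excluded.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    own = set(ligand.components)
    missing = [k for k in own if k not in model]
    if missing:
        raise ConsistencyError(f"ligand components missing from model: {missing}")

    lig_pos, _ = _gather(model.residue(k) for k in ligand.components)
    candidates = [
        r
        for r in model.residues
        if r.key not in own
        and (
            r.is_polymer
            or (not r.is_water and r.key.comp_id not in lists.blacklist)
        )
    ]
    cand_pos, owner = _gather(candidates)
    hits = atom_pairs_within(lig_pos, cand_pos, cutoff, strict=False)
    keys = sorted({owner[j] for _, j in hits})
    return BindingSite(ligand=ligand, residues=tuple(keys), cutoff=cutoff)
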