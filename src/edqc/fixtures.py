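"""Deterministic synthetic structures, stats tables and density grids.

The geometry is deliberately unphysical: a glycine-like chain runs along a
gently curved, jittered line, and ligand/decoy atoms are placed at exact
planned minimum distances from designated residues.  Only distances matter
to the engine under test.  Stats tables are drawn from within the region of
stat-space that a given profile maps to each component's target label, so
full-pipeline label recovery is exact.

All randomness flows from a single ``numpy`` generator seeded from
``FixtureSpec.seed``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classify import Label, Profile
from .density import AtomDensityParams, DensityGrid, grid_for_model, residue_mask, rho_calc
from .model_io import (
    Atom,
    ModelMeta,
    Residue,
    ResidueKey,
    StructureModel,
    write_structure,
)
from .stats import ResidueStats, StatsBundle, write_stats_table

__all__ = [
    "LigandPlan",
    "DecoyPlan",
    "FixtureSpec",
    "FixtureGeometryError",
    "polymer_key",
    "ligand_component_key",
    "decoy_key",
    "make_complex",
    "make_stats",
    "make_observed_map",
    "random_spec",
    "generate_data_dir",
]

POLYMER_CHAIN = "A"
LIGAND_CHAIN = "L"
DECOY_CHAIN = "D"

_RESIDUE_SPACING = 5.0
# intra-residue offsets keep y = 0 so a contact atom placed straight above the
# CA realizes its planned distance as the exact minimum over residue atoms
_BACKBONE = (
    ("N", "N", (-0.45, 0.0, 0.20)),
    ("CA", "C", (0.00, 0.0, 0.00)),
    ("C", "C", (0.45, 0.0, 0.20)),
    ("O", "O", (0.60, 0.0, -0.35)),
)


class FixtureGeometryError(ValueError):
    """A planned placement could not be realized."""


@dataclass(frozen=True)
class LigandPlan:
    comp_ids: tuple[str, ...] = ("LIG",)
    contacts: tuple[tuple[int, float], ...] = ()  # (polymer residue index, distance Å)


@dataclass(frozen=True)
class DecoyPlan:
    comp_id: str
    distance: float  # exact minimum distance to ligand 0


@dataclass
class FixtureSpec:
    seed: int = 0
    n_polymer_residues: int = 10
    ligands: list[LigandPlan] = field(default_factory=lambda: [LigandPlan(contacts=((4, 4.0),))])
    decoys: list[DecoyPlan] = field(default_factory=list)
    target_labels: dict[ResidueKey, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for plan in self.ligands:
            for idx, dist in plan.contacts:
                if dist <= 0:
                    raise ValueError("contact distances must be positive")
                if not 0 <= idx < self.n_polymer_residues:
                    raise ValueError(f"contact residue index {idx} out of range")
        for decoy in self.decoys:
            if decoy.distance <= 0:
                raise ValueError("decoy distances must be positive")
        if self.decoys and not self.ligands:
            raise ValueError("decoys require at least one ligand")
        for label in self.target_labels.values():
            Label[label]  # raises KeyError on bad names


def polymer_key(i: int) -> ResidueKey:
    return ResidueKey(chain_id=POLYMER_CHAIN, res_seq=i + 1, insertion_code="", comp_id="GLY")


def ligand_component_key(spec: FixtureSpec, lig_idx: int, comp_idx: int) -> ResidueKey:
    comp_id = spec.ligands[lig_idx].comp_ids[comp_idx]
    return ResidueKey(
        chain_id=LIGAND_CHAIN,
        res_seq=1001 + 10 * lig_idx + comp_idx,
        insertion_code="",
        comp_id=comp_id,
    )


def decoy_key(spec: FixtureSpec, decoy_idx: int) -> ResidueKey:
    return ResidueKey(
        chain_id=DECOY_CHAIN,
        res_seq=2001 + decoy_idx,
        insertion_code="",
        comp_id=spec.decoys[decoy_idx].comp_id,
    )


def _round3(p) -> tuple[float, float, float]:
    # PDB coordinates carry 3 decimals; snapping here keeps planned distances
    # exact through a write/parse round trip
    return (round(p[0], 3), round(p[1], 3), round(p[2], 3))


def make_complex(spec: FixtureSpec) -> StructureModel:
    """Build the planned model; raises if any planned distance is not
    realized within 0.01 Å."""
    rng = np.random.default_rng(spec.seed)
    residues: list[Residue] = []
    serial = 1

    centers = []
    for i in range(spec.n_polymer_residues):
        base = np.array([_RESIDUE_SPACING * i, 0.0, 0.6 * math.sin(0.7 * i)])
        centers.append(base + rng.normal(0.0, 0.02, 3))

    ca_pos: list[np.ndarray] = []
    for i, center in enumerate(centers):
        atoms = []
        for name, element, offset in _BACKBONE:
            pos = center + np.array(offset)
            if name == "CA":
                ca_pos.append(pos)
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element=element,
                    alt_loc="",
                    position=_round3(pos),
                    occupancy=1.0,
                    b_factor=20.0,
                    is_hetero=False,
                )
            )
            serial += 1
        residues.append(Residue(key=polymer_key(i), atoms=atoms, is_polymer=True, is_water=False))

    lig_atoms_all: list[list[tuple[float, float, float]]] = []
    for lig_idx, plan in enumerate(spec.ligands):
        contacts = []
        for idx, dist in plan.contacts:
            contacts.append(_round3(ca_pos[idx] + np.array([0.0, dist, 0.0])))
        if contacts:
            anchor = np.mean(np.array(contacts), axis=0) + np.array([0.0, 2.0, 0.0])
        else:
            anchor = np.array(
                [_RESIDUE_SPACING * spec.n_polymer_residues / 2.0, 10.0, 0.0]
            )
        anchor = _round3(anchor)

        comp_atoms: list[list[tuple[float, float, float]]] = []
        comp_atoms.append(contacts + [anchor])
        for c in range(1, len(plan.comp_ids)):
            comp_atoms.append([_round3(np.array(anchor) + np.array([0.0, 1.45 * c, 0.0]))])

        group_atoms: list[tuple[float, float, float]] = []
        for comp_idx, positions in enumerate(comp_atoms):
            atoms = []
            for n, pos in enumerate(positions, start=1):
                atoms.append(
                    Atom(
                        serial=serial,
                        name=f"C{n}",
                        element="C",
                        alt_loc="",
                        position=pos,
                        occupancy=1.0,
                        b_factor=20.0,
                        is_hetero=True,
                    )
                )
                serial += 1
                group_atoms.append(pos)
            residues.append(
                Residue(
                    key=ligand_component_key(spec, lig_idx, comp_idx),
                    atoms=atoms,
                    is_polymer=False,
                    is_water=False,
                )
            )
        lig_atoms_all.append(group_atoms)

    for decoy_idx, decoy in enumerate(spec.decoys):
        ref = max(lig_atoms_all[0], key=lambda p: (p[1], p[0]))
        theta = 0.35 * ((decoy_idx + 1) // 2) * (1 if decoy_idx % 2 == 0 else -1)
        direction = np.array([math.sin(theta), math.cos(theta), 0.0])
        pos = _round3(np.array(ref) + decoy.distance * direction)
        elem = decoy.comp_id if len(decoy.comp_id) <= 2 else decoy.comp_id[:1]
        residues.append(
            Residue(
                key=decoy_key(spec, decoy_idx),
                atoms=[
                    Atom(
                        serial=serial,
                        name=decoy.comp_id[:2],
                        element=elem,
                        alt_loc="",
                        position=pos,
                        occupancy=1.0,
                        b_factor=20.0,
                        is_hetero=True,
                    )
                ],
                is_polymer=False,
                is_water=False,
            )
        )
        serial += 1

    model = StructureModel(model_id="FIXT", residues=residues, meta=ModelMeta())
    _validate_geometry(spec, model)
    return model


def _min_dist(atoms_a, atoms_b) -> float:
    a = np.array([at.position for at in atoms_a])
    b = np.array([at.position for at in atoms_b])
    return float(np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)).min())


def _validate_geometry(spec: FixtureSpec, model: StructureModel) -> None:
    for lig_idx, plan in enumerate(spec.ligands):
        lig_atoms = [
            a
            for c in range(len(plan.comp_ids))
            for a in model.residue(ligand_component_key(spec, lig_idx, c)).atoms
        ]
        contact_idx = {idx for idx, _ in plan.contacts}
        for idx, dist in plan.contacts:
            realized = _min_dist(lig_atoms, model.residue(polymer_key(idx)).atoms)
            if abs(realized - dist) > 0.01:
                raise FixtureGeometryError(
                    f"ligand {lig_idx} to residue {idx}: planned {dist}, realized {realized:.3f}"
                )
        for i in range(spec.n_polymer_residues):
            if i in contact_idx:
                continue
            realized = _min_dist(lig_atoms, model.residue(polymer_key(i)).atoms)
            if realized <= 4.6:
                raise FixtureGeometryError(
                    f"non-contact residue {i} only {realized:.3f} Å from ligand {lig_idx}"
                )
    lig0_atoms = (
        [
            a
            for c in range(len(spec.ligands[0].comp_ids))
            for a in model.residue(ligand_component_key(spec, 0, c)).atoms
        ]
        if spec.ligands
        else []
    )
    for decoy_idx, decoy in enumerate(spec.decoys):
        realized = _min_dist(model.residue(decoy_key(spec, decoy_idx)).atoms, lig0_atoms)
        if abs(realized - decoy.distance) > 0.01:
            raise FixtureGeometryError(
                f"decoy {decoy_idx}: planned {decoy.distance}, realized {realized:.3f}"
            )


def _draw_stats(rng: np.random.Generator, label: Label, profile: Profile) -> ResidueStats:
    def good_rsr() -> float:
        return round(float(rng.uniform(0.3, 0.75)) * profile.rsr_good_max, 3)

    def good_rscc() -> float:
        lo = min(profile.rscc_min + 0.015, 0.985)
        return round(float(rng.uniform(lo, 0.995)), 3)

    def bad_rscc() -> float:
        return round(float(rng.uniform(max(-0.5, profile.rscc_min - 0.4), profile.rscc_min - 0.015)), 3)

    def bad_occ() -> float:
        return round(float(rng.uniform(0.3, profile.occupancy_min - 0.05)), 3)

    rsr_v, rscc_v, occ_v = good_rsr(), good_rscc(), round(profile.occupancy_min, 3)
    if label == Label.Dubious:
        if profile.tolerance < 1:
            raise ValueError("Dubious is unreachable at tolerance 0")
        mode = rng.integers(0, 3)
        if mode == 0:
            rscc_v = bad_rscc()
        elif mode == 1:
            rsr_v = round(
                float(rng.uniform(profile.rsr_good_max + 0.01, profile.rsr_max - 0.01)), 3
            )
        else:
            occ_v = bad_occ()
    elif label == Label.Bad:
        if profile.tolerance <= 1 and rng.integers(0, 2) == 0:
            rscc_v = bad_rscc()
            occ_v = bad_occ()
        else:
            rsr_v = round(float(rng.uniform(profile.rsr_max + 0.01, profile.rsr_max + 0.25)), 3)
    owab = round(float(rng.uniform(10.0, 35.0)), 3)
    return ResidueStats(rsr=rsr_v, rscc=rscc_v, avg_occupancy=occ_v, owab=owab)


def make_stats(spec: FixtureSpec, profile: Profile) -> StatsBundle:
    """A stats table whose values classify each component to its target label
    under ``profile`` (components without a target are Good)."""
    rng = np.random.default_rng(spec.seed + 1)
    per_residue: dict[ResidueKey, ResidueStats] = {}

    keys: list[ResidueKey] = [polymer_key(i) for i in range(spec.n_polymer_residues)]
    for lig_idx, plan in enumerate(spec.ligands):
        keys.extend(ligand_component_key(spec, lig_idx, c) for c in range(len(plan.comp_ids)))
    keys.extend(decoy_key(spec, d) for d in range(len(spec.decoys)))

    for key in keys:
        label = Label[spec.target_labels.get(key, "Good")]
        per_residue[key] = _draw_stats(rng, label, profile)

    resolution = (
        round(float(rng.uniform(1.0, 2.5)), 3)
        if profile.resolution_max is None
        else round(profile.resolution_max * 0.8, 3)
    )
    r_free = (
        round(float(rng.uniform(0.15, 0.25)), 3)
        if profile.r_free_max is None
        else round(profile.r_free_max * 0.8, 3)
    )
    meta = ModelMeta(resolution=resolution, r_free=r_free, source=profile.source)
    return StatsBundle(model_stats=meta, per_residue=per_residue, source=profile.source)


def make_observed_map(
    model: StructureModel,
    params: AtomDensityParams,
    noise_sd: float,
    degraded: set[ResidueKey] = frozenset(),
    seed: int = 0,
    spacing: float = 0.5,
) -> DensityGrid:
    """Calculated density plus seeded Gaussian noise; degraded residues get
    5x extra noise inside their masks."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    grid_spec = grid_for_model(model, spacing=spacing, margin=params.mask_radius + 2.0)
    grid = rho_calc(model, grid_spec, params)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        grid.values = grid.values + rng.normal(0.0, noise_sd, grid.dims)
        for key in sorted(degraded):
            mask = residue_mask(grid, model.residue(key).atoms, params.mask_radius)
            extra = rng.normal(0.0, 5.0 * noise_sd, int(mask.sum()))
            grid.values[mask] += extra
    return grid


def random_spec(seed: int, profile: Profile, rng: np.random.Generator | None = None) -> FixtureSpec:
    """A small random spec with achievable random target labels."""
    rng = np.random.default_rng(seed) if rng is None else rng
    n_polymer = int(rng.integers(8, 14))
    n_comps = int(rng.integers(1, 4))
    n_contacts = int(rng.integers(1, 4))
    contact_idx = rng.choice(np.arange(1, n_polymer - 1), size=n_contacts, replace=False)
    contacts = tuple(
        (int(i), round(float(rng.uniform(3.2, 4.35)), 2)) for i in sorted(contact_idx)
    )
    comp_ids = tuple(f"L{k:02d}" for k in range(n_comps))
    decoys = []
    if rng.random() < 0.3:
        decoys.append(DecoyPlan(comp_id="ZN", distance=round(float(rng.uniform(3.0, 4.0)), 2)))
    if rng.random() < 0.3:
        decoys.append(DecoyPlan(comp_id="SO4", distance=round(float(rng.uniform(3.0, 4.4)), 2)))

    spec = FixtureSpec(
        seed=seed,
        n_polymer_residues=n_polymer,
        ligands=[LigandPlan(comp_ids=comp_ids, contacts=contacts)],
        decoys=decoys,
    )
    labels = [Label.Good, Label.Dubious, Label.Bad]
    targets: dict[ResidueKey, str] = {}
    for c in range(n_comps):
        targets[ligand_component_key(spec, 0, c)] = labels[
            int(rng.choice(3, p=[0.6, 0.2, 0.2]))
        ].name
    for idx, _ in contacts:
        targets[polymer_key(idx)] = labels[int(rng.choice(3, p=[0.6, 0.2, 0.2]))].name
    spec.target_labels = targets
    return spec


def expected_pair_labels(spec: FixtureSpec, lig_idx: int = 0) -> tuple[str, str]:
    """Ground-truth (ligand_label, site_label) implied by a spec's targets."""
    plan = spec.ligands[lig_idx]
    lig = max(
        Label[spec.target_labels.get(ligand_component_key(spec, lig_idx, c), "Good")]
        for c in range(len(plan.comp_ids))
    )
    site_members = [polymer_key(idx) for idx, _ in plan.contacts]
    site_members += [
        decoy_key(spec, d)
        for d, decoy in enumerate(spec.decoys)
        if lig_idx == 0 and decoy.comp_id in ("ZN", "MG") and decoy.distance <= 4.5
    ]
    site = max(
        (Label[spec.target_labels.get(k, "Good")] for k in site_members),
        default=Label.Good,
    )
    return lig.name, site.name


def generate_data_dir(
    out_dir: str | Path,
    n_structures: int,
    seed: int,
    profile: Profile,
    include_maps: bool = False,
) -> list[str]:
    """Emit a ready-to-run data directory (structures, stats tables, optional
    maps) plus a ``manifest.json`` of ground-truth labels."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest: dict = {"profile": profile.name, "source": profile.source, "structures": {}}
    ids: list[str] = []
    for i in range(n_structures):
        model_id = f"F{i:03d}"
        spec = random_spec(int(rng.integers(0, 2**31)), profile)
        model = make_complex(spec)
        model.model_id = model_id
        bundle = make_stats(spec, profile)
        (out / f"{model_id}.pdb").write_text(write_structure(model))
        (out / f"{model_id}.stats.tsv").write_text(write_stats_table(bundle))
        if include_maps:
            from .density import write_grid

            grid = make_observed_map(
                model, AtomDensityParams(), noise_sd=0.0, seed=spec.seed
            )
            (out / f"{model_id}.grid.txt").write_text(write_grid(grid))
        lig_label, site_label = expected_pair_labels(spec)
        manifest["structures"][model_id] = {
            "seed": spec.seed,
            "ligand_label": lig_label,
            "site_label": site_label,
            "component_labels": {str(k): v for k, v in sorted(spec.target_labels.items(), key=lambda kv: kv[0])},
        }
        ids.append(model_id)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return ids
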