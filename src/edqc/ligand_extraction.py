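"""Candidate-ligand identification, covalent grouping and exclusion rules.

Hetero residues that are not waters and not on either exclusion list are
candidate ligand components.  Components closer than the covalent-bond
cutoff (strictly below, default 2.1 Å) are merged into one multi-component
ligand.  A group is rejected when covalently close to a polymer residue or a
blacklisted residue; contacts to non-propagating residues (mainly metal
ions) neither reject nor merge.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .binding_site import residue_pairs_within
from .model_io import ResidueKey, StructureModel

__all__ = [
    "ExclusionLists",
    "LigandGroup",
    "RejectionRecord",
    "REJECTION_REASONS",
    "default_exclusion_lists",
    "load_code_list",
    "covalent_pairs",
    "extract_ligands",
]

DEFAULT_BOND_CUTOFF = 2.1

REASON_NO_STATS = "no_stats_data"
REASON_COVALENT_POLYMER = "covalent_to_polymer"
REASON_BLACKLISTED = "blacklisted"
REASON_COVALENT_BLACKLISTED = "covalent_to_blacklisted"
REJECTION_REASONS = frozenset(
    {REASON_NO_STATS, REASON_COVALENT_POLYMER, REASON_BLACKLISTED, REASON_COVALENT_BLACKLISTED}
)


@dataclass
class ExclusionLists:
    blacklist: frozenset[str]
    non_propagating: frozenset[str]

    def __post_init__(self) -> None:
        self.blacklist = frozenset(self.blacklist)
        self.non_propagating = frozenset(self.non_propagating)
        overlap = self.blacklist & self.non_propagating
        if overlap:
            raise ValueError(f"codes on both exclusion lists: {sorted(overlap)}")


@dataclass(frozen=True)
class LigandGroup:
    components: tuple[ResidueKey, ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("ligand group needs at least one component")

    @property
    def group_id(self) -> str:
        return "+".join(str(k) for k in self.components)


@dataclass(frozen=True)
class RejectionRecord:
    subject: str
    reason: str

    def __post_init__(self) -> None:
        if self.reason not in REJECTION_REASONS:
            raise ValueError(f"unknown rejection reason {self.reason!r}")


def load_code_list(source: str | Path) -> frozenset[str]:
    """Read a plain-text compound-code list ('#' comments, one code/line)."""
    text = Path(source).read_text() if isinstance(source, (str, Path)) else source
    codes = set()
    for line in text.splitlines():
        code = line.split("#", 1)[0].strip().upper()
        if code:
            codes.add(code)
    return frozenset(codes)


def _read_packaged(name: str) -> frozenset[str]:
    text = resources.files("edqc.data").joinpath(name).read_text()
    codes = set()
    for line in text.splitlines():
        code = line.split("#", 1)[0].strip().upper()
        if code:
            codes.add(code)
    return frozenset(codes)


def default_exclusion_lists() -> ExclusionLists:
    """The shipped blacklist (solvents/buffers/additives) and
    non-propagating list (metal ions)."""
    return ExclusionLists(
        blacklist=_read_packaged("blacklist.txt"),
        non_propagating=_read_packaged("non_propagating.txt"),
    )


def covalent_pairs(
    model: StructureModel, cutoff: float = DEFAULT_BOND_CUTOFF
) -> set[frozenset[ResidueKey]]:
    """Unordered pairs of distinct residues with any inter-atomic distance
    strictly below the cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return residue_pairs_within(model.residues, cutoff, strict=True)


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def extract_ligands(
    model: StructureModel,
    lists: ExclusionLists,
    bond_cutoff: float = DEFAULT_BOND_CUTOFF,
) -> tuple[list[LigandGroup], list[RejectionRecord]]:
    """Group candidate hetero residues into ligands and apply rejection rules.

    Returns surviving groups sorted by their first component key, plus one
    rejection record per discarded group.
    """
    candidates = [
        r
        for r in model.residues
        if not r.is_polymer
        and not r.is_water
        and r.key.comp_id not in lists.blacklist
        and r.key.comp_id not in lists.non_propagating
    ]
    if not candidates:
        return [], []

    pairs = residue_pairs_within(model.residues, bond_cutoff, strict=True)

    cand_keys = {r.key for r in candidates}
    uf = _UnionFind(sorted(cand_keys))
    polymer_contact: set[ResidueKey] = set()
    blacklist_contact: set[ResidueKey] = set()
    by_key = {r.key: r for r in model.residues}

    for pair in pairs:
        a, b = sorted(pair)
        if a in cand_keys and b in cand_keys:
            uf.union(a, b)
            continue
        for cand, other in ((a, b), (b, a)):
            if cand not in cand_keys:
                continue
            other_res = by_key[other]
            if other_res.is_polymer:
                polymer_contact.add(cand)
            elif (
                other_res.key.comp_id in lists.blacklist
                and not other_res.is_water
            ):
                blacklist_contact.add(cand)
            # non-propagating contacts: ignored entirely

    groups_by_root: dict[ResidueKey, list[ResidueKey]] = {}
    for key in sorted(cand_keys):
        groups_by_root.setdefault(uf.find(key), []).append(key)

    ligands: list[LigandGroup] = []
    rejections: list[RejectionRecord] = []
    for root in sorted(groups_by_root):
        comps = tuple(sorted(groups_by_root[root]))
        group = LigandGroup(components=comps)
        if any(k in polymer_contact for k in comps):
            rejections.append(RejectionRecord(group.group_id, REASON_COVALENT_POLYMER))
        elif any(k in blacklist_contact for k in comps):
            rejections.append(RejectionRecord(group.group_id, REASON_COVALENT_BLACKLISTED))
        else:
            ligands.append(group)

    ligands.sort(key=lambda g: g.components)
    return ligands, rejections
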