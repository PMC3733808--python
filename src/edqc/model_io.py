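"""Read and write PDB-format coordinate files into an internal structure model.

Only fixed-column ATOM/HETATM/TER/MODEL/ENDMDL records of PDB format v3.3 are
interpreted; everything else (ANISOU, CONECT, REMARK, ...) is ignored.  Only
the first coordinate model of a multi-MODEL file is represented.  Alternate
locations are resolved at parse time: for each atom name within a residue the
conformer with the highest occupancy is kept (ties break to the
alphabetically first alt-loc identifier).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

__all__ = [
    "Atom",
    "ResidueKey",
    "Residue",
    "ModelMeta",
    "StructureModel",
    "PDBParseError",
    "parse_structure",
    "write_structure",
    "residue_average_occupancy",
]

log = logging.getLogger(__name__)

WATER_CODES = frozenset({"HOH", "DOD", "WAT"})

SOURCE_PDB = "PDB"
SOURCE_PDB_REDO = "PDB_REDO"
SOURCES = (SOURCE_PDB, SOURCE_PDB_REDO)


class PDBParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    element: str
    alt_loc: str
    position: tuple[float, float, float]
    occupancy: float
    b_factor: float
    is_hetero: bool

    def __post_init__(self) -> None:
        if not all(p == p and abs(p) != float("inf") for p in self.position):
            raise ValueError(f"non-finite position for atom {self.name!r}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")
        if self.b_factor < 0.0:
            raise ValueError(f"negative B-factor {self.b_factor}")


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Identity of one residue: chain, sequence number, insertion code, compound."""

    chain_id: str
    res_seq: int
    insertion_code: str
    comp_id: str

    def __str__(self) -> str:
        return f"{self.comp_id}:{self.chain_id}:{self.res_seq}{self.insertion_code}"


@dataclass
class Residue:
    key: ResidueKey
    atoms: list[Atom]
    is_polymer: bool
    is_water: bool

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"residue {self.key} has no atoms")

    @property
    def positions(self) -> list[tuple[float, float, float]]:
        return [a.position for a in self.atoms]


@dataclass
class ModelMeta:
    resolution: float | None = None
    r_free: float | None = None
    source: str = SOURCE_PDB

    def __post_init__(self) -> None:
        if self.resolution is not None and not self.resolution > 0:
            raise ValueError(f"resolution must be positive, got {self.resolution}")
        if self.r_free is not None and not 0.0 <= self.r_free <= 1.0:
            raise ValueError(f"r_free must be in [0, 1], got {self.r_free}")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")


@dataclass
class StructureModel:
    model_id: str
    residues: list[Residue]
    meta: ModelMeta = field(default_factory=ModelMeta)

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate residue keys in model")

    def residue(self, key: ResidueKey) -> Residue:
        for r in self.residues:
            if r.key == key:
                return r
        raise KeyError(key)

    def __contains__(self, key: ResidueKey) -> bool:
        return any(r.key == key for r in self.residues)

    @property
    def atom_count(self) -> int:
        return sum(len(r.atoms) for r in self.residues)


def _field(line: str, start: int, stop: int, lineno: int, name: str, cast, default=None):
    raw = line[start:stop].strip()
    if not raw:
        if default is not None:
            return default
        raise PDBParseError(f"line {lineno}: empty {name} field")
    try:
        return cast(raw)
    except ValueError:
        raise PDBParseError(f"line {lineno}: malformed {name} field {raw!r}") from None


def _guess_element(name: str) -> str:
    letters = "".join(c for c in name if c.isalpha())
    return letters[:1].upper() if letters else "X"


def parse_structure(text: str, model_id: str = "XXXX") -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel`.

    Atoms of the first coordinate model only; alternate locations resolved to
    the highest-occupancy conformer per atom name; occupancies outside [0, 1]
    and negative B-factors are clamped with a warning.
    """
    raw: dict[tuple[str, int, str, str], list[tuple[Atom, bool]]] = {}
    order: list[tuple[str, int, str, str]] = []
    models_seen = 0
    in_later_model = False

    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip().upper()
        if rec == "MODEL":
            models_seen += 1
            if models_seen > 1:
                in_later_model = True
        elif rec == "ENDMDL":
            if models_seen >= 1:
                in_later_model = True
        if in_later_model or rec not in ("ATOM", "HETATM"):
            continue

        is_het = rec == "HETATM"
        serial = _field(line, 6, 11, lineno, "serial", int)
        name = line[12:16].strip()
        if not name:
            raise PDBParseError(f"line {lineno}: empty atom name")
        alt_loc = line[16:17].strip()
        comp_id = line[17:20].strip()
        chain_id = line[21:22].strip()
        res_seq = _field(line, 22, 26, lineno, "residue number", int)
        icode = line[26:27].strip()
        x = _field(line, 30, 38, lineno, "x coordinate", float)
        y = _field(line, 38, 46, lineno, "y coordinate", float)
        z = _field(line, 46, 54, lineno, "z coordinate", float)
        occ = _field(line, 54, 60, lineno, "occupancy", float, default=1.0)
        b = _field(line, 60, 66, lineno, "B-factor", float, default=0.0)
        element = line[76:78].strip().upper() or _guess_element(name)

        if not 0.0 <= occ <= 1.0:
            log.warning("line %d: occupancy %s clamped to [0, 1]", lineno, occ)
            occ = min(max(occ, 0.0), 1.0)
        if b < 0.0:
            log.warning("line %d: negative B-factor %s clamped to 0", lineno, b)
            b = 0.0

        atom = Atom(
            serial=serial,
            name=name,
            element=element,
            alt_loc=alt_loc,
            position=(x, y, z),
            occupancy=occ,
            b_factor=b,
            is_hetero=is_het,
        )
        key = (chain_id, res_seq, icode, comp_id)
        if key not in raw:
            raw[key] = []
            order.append(key)
        raw[key].append((atom, is_het))

    if not raw:
        raise PDBParseError("no parsable ATOM or HETATM record found")

    residues: list[Residue] = []
    for key in order:
        entries = raw[key]
        flags = {h for _, h in entries}
        if len(flags) > 1:
            raise PDBParseError(
                f"residue {key} mixes ATOM and HETATM records"
            )
        is_het = flags.pop()
        atoms = _resolve_alt_locs([a for a, _ in entries])
        comp_id = key[3]
        residues.append(
            Residue(
                key=ResidueKey(
                    chain_id=key[0], res_seq=key[1], insertion_code=key[2], comp_id=comp_id
                ),
                atoms=atoms,
                is_polymer=not is_het,
                is_water=comp_id in WATER_CODES,
            )
        )

    return StructureModel(model_id=model_id, residues=residues)


def _resolve_alt_locs(atoms: list[Atom]) -> list[Atom]:
    """Keep, per atom name, the conformer with highest occupancy (ties:
    alphabetically first alt-loc)."""
    best: dict[str, Atom] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in best:
            best[a.name] = a
            order.append(a.name)
            continue
        b = best[a.name]
        if (a.occupancy, _altloc_rank(b.alt_loc)) > (b.occupancy, _altloc_rank(a.alt_loc)):
            best[a.name] = a
    return [best[n] for n in order]


def _altloc_rank(alt: str) -> str:
    # empty alt-loc sorts before 'A'; used inverted so that the smaller
    # identifier wins occupancy ties
    return alt


def _format_name(name: str, element: str) -> str:
    if len(name) > 4:
        raise ValueError(f"atom name {name!r} longer than 4 characters")
    if len(name) == 4 or len(element) == 2:
        return f"{name:<4}"
    return f" {name:<3}"


def write_structure(model: StructureModel) -> str:
    """Serialize a model to PDB-format text (round-trips on retained fields)."""
    if not model.residues:
        raise ValueError("cannot write an empty model")
    lines: list[str] = []
    n = len(model.residues)
    for i, res in enumerate(model.residues):
        rec = "ATOM" if res.is_polymer else "HETATM"
        k = res.key
        for a in res.atoms:
            x, y, z = a.position
            lines.append(
                f"{rec:<6}{a.serial % 100000:>5} {_format_name(a.name, a.element)}"
                f"{a.alt_loc:1}{k.comp_id:>3} {k.chain_id:1}{k.res_seq:>4}"
                f"{k.insertion_code:1}   {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{a.occupancy:6.2f}{a.b_factor:6.2f}          {a.element:>2}"
            )
        nxt = model.residues[i + 1] if i + 1 < n else None
        if res.is_polymer and (nxt is None or not nxt.is_polymer or nxt.key.chain_id != k.chain_id):
            lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def residue_average_occupancy(residue: Residue) -> float:
    """Arithmetic mean of per-atom occupancies after alt-loc resolution."""
    return sum(a.occupancy for a in residue.atoms) / len(residue.atoms)


def with_meta(model: StructureModel, meta: ModelMeta) -> StructureModel:
    return replace(model, meta=meta)
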