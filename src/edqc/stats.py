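"""Per-residue fit statistics (RSR, RSCC, average occupancy, OWAB).

A single TSV dialect stands in for the per-residue data normally retrieved
from the databanks: a header row with columns ``chain res_seq icode comp_id
rsr rscc occ owab``, missing values written as ``.``, and ``#meta`` header
lines carrying model-level numbers::

    #meta resolution 1.80
    #meta r_free 0.22
    #meta source PDB_REDO
    chain	res_seq	icode	comp_id	rsr	rscc	occ	owab
    A	1	.	GLY	0.120	0.950	1.000	18.000

Structures and stats live side by side in a data directory as
``<id>.pdb`` / ``<id>.stats.tsv``; a structure without a stats file is
rejected with reason ``no_stats_data`` downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .model_io import (
    ModelMeta,
    ResidueKey,
    StructureModel,
    parse_structure,
    residue_average_occupancy,
)

__all__ = [
    "ResidueStats",
    "StatsBundle",
    "StatsParseError",
    "MissingStatsError",
    "parse_stats_table",
    "write_stats_table",
    "stats_for",
    "LocalDataProvider",
]

_COLUMNS = ("chain", "res_seq", "icode", "comp_id", "rsr", "rscc", "occ", "owab")


class StatsParseError(ValueError):
    pass


class MissingStatsError(FileNotFoundError):
    """No fit-statistics data available for a structure."""


@dataclass(frozen=True)
class ResidueStats:
    rsr: float | None = None
    rscc: float | None = None
    avg_occupancy: float | None = None
    owab: float | None = None

    def __post_init__(self) -> None:
        if self.rscc is not None and not -1.0 <= self.rscc <= 1.0:
            raise ValueError(f"rscc {self.rscc} outside [-1, 1]")
        if self.rsr is not None and (self.rsr < 0 or self.rsr != self.rsr):
            raise ValueError(f"rsr must be finite and >= 0, got {self.rsr}")

    @property
    def empty(self) -> bool:
        return all(v is None for v in (self.rsr, self.rscc, self.avg_occupancy, self.owab))


@dataclass
class StatsBundle:
    model_stats: ModelMeta = field(default_factory=ModelMeta)
    per_residue: dict[ResidueKey, ResidueStats] = field(default_factory=dict)
    source: str = "PDB"


def _num(raw: str, lineno: int, col: str) -> float | None:
    if raw in (".", ""):
        return None
    try:
        return float(raw)
    except ValueError:
        raise StatsParseError(f"line {lineno}: non-numeric {col} value {raw!r}") from None


def parse_stats_table(text: str) -> StatsBundle:
    """Parse the stats TSV dialect; duplicate residue keys are an error."""
    meta: dict[str, str] = {}
    header: list[str] | None = None
    per_residue: dict[ResidueKey, ResidueStats] = {}

    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("#meta"):
            parts = line.split(None, 2)
            if len(parts) != 3:
                raise StatsParseError(f"line {lineno}: malformed #meta line")
            meta[parts[1]] = parts[2].strip()
            continue
        if line.startswith("#"):
            continue
        cells = line.rstrip("\n").split("\t")
        if header is None:
            header = [c.strip() for c in cells]
            unknown = set(header) - set(_COLUMNS)
            if unknown:
                raise StatsParseError(f"line {lineno}: unknown column(s) {sorted(unknown)}")
            missing = set(_COLUMNS) - set(header)
            if missing:
                raise StatsParseError(f"line {lineno}: missing column(s) {sorted(missing)}")
            continue
        if len(cells) != len(header):
            raise StatsParseError(f"line {lineno}: expected {len(header)} fields, got {len(cells)}")
        row = dict(zip(header, (c.strip() for c in cells)))
        try:
            res_seq = int(row["res_seq"])
        except ValueError:
            raise StatsParseError(
                f"line {lineno}: non-numeric res_seq value {row['res_seq']!r}"
            ) from None
        icode = "" if row["icode"] in (".", "") else row["icode"]
        key = ResidueKey(
            chain_id=row["chain"], res_seq=res_seq, insertion_code=icode, comp_id=row["comp_id"]
        )
        if key in per_residue:
            raise StatsParseError(f"line {lineno}: duplicate residue key {key}")
        stats = ResidueStats(
            rsr=_num(row["rsr"], lineno, "rsr"),
            rscc=_num(row["rscc"], lineno, "rscc"),
            avg_occupancy=_num(row["occ"], lineno, "occ"),
            owab=_num(row["owab"], lineno, "owab"),
        )
        if stats.empty:
            raise StatsParseError(f"line {lineno}: row for {key} has no values")
        per_residue[key] = stats

    if header is None:
        raise StatsParseError("missing header row")

    model_stats = ModelMeta(
        resolution=float(meta["resolution"]) if "resolution" in meta else None,
        r_free=float(meta["r_free"]) if "r_free" in meta else None,
        source=meta.get("source", "PDB"),
    )
    return StatsBundle(model_stats=model_stats, per_residue=per_residue, source=model_stats.source)


def _fmt(v: float | None) -> str:
    return "." if v is None else f"{v:.3f}"


def write_stats_table(bundle: StatsBundle) -> str:
    """Serialize a bundle back to the TSV dialect (3-decimal round trip)."""
    lines: list[str] = []
    ms = bundle.model_stats
    if ms.resolution is not None:
        lines.append(f"#meta resolution {ms.resolution:.3f}")
    if ms.r_free is not None:
        lines.append(f"#meta r_free {ms.r_free:.3f}")
    lines.append(f"#meta source {bundle.source}")
    lines.append("\t".join(_COLUMNS))
    for key in sorted(bundle.per_residue):
        s = bundle.per_residue[key]
        lines.append(
            "\t".join(
                (
                    key.chain_id,
                    str(key.res_seq),
                    key.insertion_code or ".",
                    key.comp_id,
                    _fmt(s.rsr),
                    _fmt(s.rscc),
                    _fmt(s.avg_occupancy),
                    _fmt(s.owab),
                )
            )
        )
    return "\n".join(lines) + "\n"


def stats_for(
    model: StructureModel,
    bundle: StatsBundle,
    keys: set[ResidueKey],
) -> dict[ResidueKey, ResidueStats]:
    """Table entries for the requested keys, with coordinate-derived average
    occupancy filled in where the table has none."""
    out: dict[ResidueKey, ResidueStats] = {}
    for key in keys:
        entry = bundle.per_residue.get(key)
        if entry is not None:
            rsr, rscc, occ, owab = entry.rsr, entry.rscc, entry.avg_occupancy, entry.owab
        else:
            rsr = rscc = occ = owab = None
        if occ is None and key in model:
            occ = residue_average_occupancy(model.residue(key))
        out[key] = ResidueStats(rsr=rsr, rscc=rscc, avg_occupancy=occ, owab=owab)
    return out


class LocalDataProvider:
    """Provider contract ``get(model_id) -> (StructureModel, StatsBundle)``
    backed by a local directory of ``<id>.pdb`` + ``<id>.stats.tsv`` files.

    Network-backed providers (databank retrieval, accession mapping) are
    deliberately not implemented; this is the only shipped provider.
    """

    def __init__(self, data_dir: str | Path):
        self.data_dir = Path(data_dir)

    def get(self, model_id: str) -> tuple[StructureModel, StatsBundle]:
        pdb_path = self.data_dir / f"{model_id}.pdb"
        stats_path = self.data_dir / f"{model_id}.stats.tsv"
        if not pdb_path.exists():
            raise FileNotFoundError(f"no structure file for {model_id}: {pdb_path}")
        if not stats_path.exists():
            raise MissingStatsError(f"no stats data for {model_id}: {stats_path}")
        model = parse_structure(pdb_path.read_text(), model_id=model_id)
        bundle = parse_stats_table(stats_path.read_text())
        model.meta = bundle.model_stats
        return model, bundle
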