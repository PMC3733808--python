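"""End-to-end run driver and file outputs.

``run`` walks a list of structure ids through extraction, site detection and
classification, collecting one :class:`RunResult` per surviving ligand/site
pair and one rejection record per discarded structure or ligand.  Outputs
are a results CSV (one row per pair), a companion per-component CSV, and a
TSV rejection report.  Identical inputs produce byte-identical outputs.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

from .binding_site import BindingSite, find_binding_site
from .classify import Label, PairResult, Profile, classify_pair, worst_label
from .ligand_extraction import (
    REASON_NO_STATS,
    ExclusionLists,
    LigandGroup,
    RejectionRecord,
    default_exclusion_lists,
    extract_ligands,
)
from .stats import LocalDataProvider, MissingStatsError, stats_for

__all__ = [
    "RunConfig",
    "RunResult",
    "ProfileFileError",
    "run",
    "write_results",
    "write_rejections",
    "load_profile",
    "save_profile",
    "load_overrides",
    "load_id_list",
]

log = logging.getLogger(__name__)

RESULTS_COLUMNS = (
    "model_id",
    "source",
    "ligand_id",
    "ligand_label",
    "ligand_worst_score",
    "site_label",
    "site_worst_score",
    "n_site_residues",
    "failed_conditions",
    "missing_conditions",
)

COMPONENT_COLUMNS = (
    "model_id",
    "ligand_id",
    "role",
    "component",
    "score",
    "label",
    "failed_conditions",
    "missing_conditions",
)


@dataclass
class RunConfig:
    ids: list[str]
    data_dir: str | Path
    profile: Profile
    lists: ExclusionLists = field(default_factory=default_exclusion_lists)
    overrides: dict[str, Label] = field(default_factory=dict)


@dataclass
class RunResult:
    model_id: str
    source: str
    ligand: LigandGroup
    site: BindingSite
    pair: PairResult

    @property
    def ligand_id(self) -> str:
        return self.ligand.group_id


def run(config: RunConfig) -> tuple[list[RunResult], list[RejectionRecord]]:
    """Process every id independently; per-id failures are logged and do not
    abort the run."""
    provider = LocalDataProvider(config.data_dir)
    profile = config.profile
    results: list[RunResult] = []
    rejections: list[RejectionRecord] = []

    for model_id in config.ids:
        try:
            model, bundle = provider.get(model_id)
        except MissingStatsError:
            rejections.append(RejectionRecord(model_id, REASON_NO_STATS))
            log.warning("%s: no stats data, rejected", model_id)
            continue
        except Exception as exc:  # per-id errors are recorded, not fatal
            log.error("%s: failed to load (%s)", model_id, exc)
            continue
        if bundle.source != profile.source:
            log.warning(
                "%s: stats dialect %s does not match profile source %s",
                model_id,
                bundle.source,
                profile.source,
            )
        try:
            ligands, rejected = extract_ligands(model, config.lists, profile.bond_cutoff)
            rejections.extend(
                RejectionRecord(f"{model_id}/{r.subject}", r.reason) for r in rejected
            )
            for ligand in ligands:
                site = find_binding_site(model, ligand, config.lists, profile.site_cutoff)
                keys = set(ligand.components) | set(site.residues)
                smap = stats_for(model, bundle, keys)
                pair = classify_pair(ligand, site, smap, bundle.model_stats, profile)
                pair = _apply_overrides(model_id, ligand, pair, config.overrides)
                results.append(
                    RunResult(
                        model_id=model_id,
                        source=bundle.source,
                        ligand=ligand,
                        site=site,
                        pair=pair,
                    )
                )
        except Exception as exc:
            log.error("%s: processing failed (%s)", model_id, exc)
            continue
        log.info("%s: %d ligand/site pair(s)", model_id, len(ligands))
    return results, rejections


def _apply_overrides(
    model_id: str, ligand: LigandGroup, pair: PairResult, overrides: dict[str, Label]
) -> PairResult:
    """Non-interactive re-classification: component keys are
    ``<model_id>:<comp>:<chain>:<seq>``, aggregates are
    ``<model_id>:ligand:<group_id>`` / ``<model_id>:site:<group_id>``."""
    if not overrides:
        return pair
    changed = False
    for comp in pair.ligand_components + pair.site_components:
        key = f"{model_id}:{comp.key}"
        if key in overrides:
            comp.label = overrides[key]
            changed = True
    lig_label = worst_label(c.label for c in pair.ligand_components)
    site_label = worst_label(c.label for c in pair.site_components)
    lig_key = f"{model_id}:ligand:{ligand.group_id}"
    site_key = f"{model_id}:site:{ligand.group_id}"
    if lig_key in overrides:
        lig_label = overrides[lig_key]
        changed = True
    if site_key in overrides:
        site_label = overrides[site_key]
        changed = True
    if not changed:
        return pair
    pair.ligand_label = lig_label
    pair.site_label = site_label
    return pair


def _summary(components) -> tuple[str, str]:
    failed = sorted(
        {f"{c.key}:{cond}" for c in components for cond in c.failed_conditions}
    )
    missing = sorted(
        {f"{c.key}:{cond}" for c in components for cond in c.missing_conditions}
    )
    return ";".join(failed), ";".join(missing)


def results_csv_text(results: list[RunResult]) -> tuple[str, str]:
    """(main CSV, per-component CSV) as text with RFC-4180 quoting."""
    main = io.StringIO()
    w = csv.writer(main, lineterminator="\n")
    w.writerow(RESULTS_COLUMNS)
    for r in results:
        all_comps = r.pair.ligand_components + r.pair.site_components
        failed, missing = _summary(all_comps)
        w.writerow(
            (
                r.model_id,
                r.source,
                r.ligand_id,
                str(r.pair.ligand_label),
                r.pair.ligand_worst_score,
                str(r.pair.site_label),
                r.pair.site_worst_score,
                len(r.site.residues),
                failed,
                missing,
            )
        )

    comp = io.StringIO()
    w = csv.writer(comp, lineterminator="\n")
    w.writerow(COMPONENT_COLUMNS)
    for r in results:
        for role, comps in (("ligand", r.pair.ligand_components), ("site", r.pair.site_components)):
            for c in comps:
                w.writerow(
                    (
                        r.model_id,
                        r.ligand_id,
                        role,
                        str(c.key),
                        c.score,
                        str(c.label),
                        ";".join(c.failed_conditions),
                        ";".join(c.missing_conditions),
                    )
                )
    return main.getvalue(), comp.getvalue()


def write_results(
    results: list[RunResult], path: str | Path, components_path: str | Path | None = None
) -> None:
    """Write the main results CSV and its per-component companion."""
    path = Path(path)
    if components_path is None:
        components_path = path.with_name(path.stem + "_components.csv")
    main, comp = results_csv_text(results)
    path.write_text(main)
    Path(components_path).write_text(comp)


def rejections_text(records: list[RejectionRecord]) -> str:
    lines = ["subject\treason"]
    lines.extend(f"{r.subject}\t{r.reason}" for r in sorted(records, key=lambda r: (r.subject, r.reason)))
    return "\n".join(lines) + "\n"


def write_rejections(records: list[RejectionRecord], path: str | Path) -> None:
    Path(path).write_text(rejections_text(records))


class ProfileFileError(ValueError):
    pass


_PROFILE_FIELDS = {f.name: f for f in fields(Profile)}
_OPTIONAL = ("owab_max", "r_free_max", "resolution_max")


def save_profile(profile: Profile, path: str | Path) -> None:
    lines = []
    for name in _PROFILE_FIELDS:
        value = getattr(profile, name)
        if value is None:
            value = "off"
        lines.append(f"{name}={value}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_profile(path: str | Path) -> Profile:
    """Read a flat key=value profile file; 'off' disables a threshold."""
    values: dict[str, object] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ProfileFileError(f"line {lineno}: expected key=value, got {line!r}")
        key, _, raw = line.partition("=")
        key, raw = key.strip(), raw.strip()
        if key not in _PROFILE_FIELDS:
            raise ProfileFileError(f"line {lineno}: unknown profile key {key!r}")
        if key in ("name", "source"):
            values[key] = raw
        elif raw.lower() == "off":
            if key not in _OPTIONAL:
                raise ProfileFileError(f"line {lineno}: {key} cannot be disabled")
            values[key] = None
        elif key == "tolerance":
            values[key] = int(raw)
        else:
            try:
                values[key] = float(raw)
            except ValueError:
                raise ProfileFileError(f"line {lineno}: bad value for {key}: {raw!r}") from None
    missing = {"name", "source", "rscc_min", "occupancy_min", "rsr_good_max", "rsr_max"} - set(values)
    if missing:
        raise ProfileFileError(f"profile file missing keys: {sorted(missing)}")
    try:
        return Profile(**values)  # type: ignore[arg-type]
    except ValueError as exc:
        raise ProfileFileError(str(exc)) from None


def load_overrides(path: str | Path) -> dict[str, Label]:
    """Override file: one ``subject<TAB>label`` per line, '#' comments."""
    out: dict[str, Label] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"line {lineno}: expected subject<TAB>label")
        try:
            out[parts[0]] = Label[parts[1]]
        except KeyError:
            raise ValueError(f"line {lineno}: unknown label {parts[1]!r}") from None
    return out


def load_id_list(path: str | Path) -> list[str]:
    """Plain-text id list: one id per line, '#' comments."""
    ids = []
    for line in Path(path).read_text().splitlines():
        token = line.split("#", 1)[0].strip()
        if token:
            ids.append(token)
    return ids


def profile_with(profile: Profile, **kwargs) -> Profile:
    return replace(profile, **kwargs)
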