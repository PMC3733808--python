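"""Score components against a threshold profile and label them Good/Dubious/Bad.

Each ligand component and binding-site residue starts at score 0 and gains
one point per enabled, unmet condition (RSCC, average occupancy, RSR, OWAB,
R-free, resolution).  Score 0 is Good, a score above the tolerance is Bad,
anything in between is Dubious.  Ligands and sites take the worst label of
their components.  Two RSR limits apply: ``rsr <= rsr_good_max`` is the
scored condition, while ``rsr > rsr_max`` forces the component Bad outright.
Threshold comparisons are inclusive; an enabled condition whose input is
absent counts as unmet and is additionally reported as missing.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace

from .model_io import ModelMeta, ResidueKey, SOURCE_PDB, SOURCE_PDB_REDO, SOURCES
from .stats import ResidueStats

__all__ = [
    "Label",
    "Profile",
    "ComponentResult",
    "PairResult",
    "default_profiles",
    "evaluate_component",
    "label_from_score",
    "classify_pair",
    "worst_label",
]

log = logging.getLogger(__name__)

CONDITIONS = ("rscc", "occupancy", "rsr", "owab", "r_free", "resolution")
RSR_CAP_CONDITION = "rsr_cap"


class Label(enum.IntEnum):
    """Classification label; ordered so that max() yields the worst."""

    Good = 0
    Dubious = 1
    Bad = 2

    def __str__(self) -> str:  # CSV-friendly
        return self.name


@dataclass(frozen=True)
class Profile:
    """A named threshold set. ``None`` disables an optional threshold."""

    name: str
    source: str
    rscc_min: float
    occupancy_min: float
    rsr_good_max: float
    rsr_max: float
    owab_max: float | None = None
    r_free_max: float | None = None
    resolution_max: float | None = None
    tolerance: int = 1
    site_cutoff: float = 4.5
    bond_cutoff: float = 2.1

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.rsr_good_max > self.rsr_max:
            raise ValueError(
                f"rsr_good_max ({self.rsr_good_max}) must not exceed rsr_max ({self.rsr_max})"
            )
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if self.site_cutoff <= 0 or self.bond_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        for fname in ("rscc_min", "occupancy_min", "rsr_good_max", "rsr_max"):
            v = getattr(self, fname)
            if v != v or abs(v) == float("inf"):
                raise ValueError(f"{fname} must be finite")


@dataclass
class ComponentResult:
    key: ResidueKey | None
    score: int
    failed_conditions: list[str]
    label: Label
    missing_conditions: list[str] = field(default_factory=list)


@dataclass
class PairResult:
    ligand_components: list[ComponentResult]
    site_components: list[ComponentResult]
    ligand_label: Label
    site_label: Label

    @property
    def ligand_worst_score(self) -> int:
        return max((c.score for c in self.ligand_components), default=0)

    @property
    def site_worst_score(self) -> int:
        return max((c.score for c in self.site_components), default=0)


def default_profiles() -> list[Profile]:
    """The two shipped defaults; they differ only in the good-RSR cutoff,
    which absorbs the dialect difference between the two data sources."""
    base = dict(
        rscc_min=0.9,
        occupancy_min=1.0,
        rsr_max=0.4,
        tolerance=1,
        site_cutoff=4.5,
        bond_cutoff=2.1,
    )
    return [
        Profile(name="Default (PDB)", source=SOURCE_PDB, rsr_good_max=0.24, **base),
        Profile(name="Default (PDB_REDO)", source=SOURCE_PDB_REDO, rsr_good_max=0.165, **base),
    ]


def label_from_score(score: int, tolerance: int) -> Label:
    if score < 0 or tolerance < 0:
        raise ValueError("score and tolerance must be non-negative")
    if score == 0:
        return Label.Good
    if score > tolerance:
        return Label.Bad
    return Label.Dubious


def evaluate_component(
    stats: ResidueStats,
    model_stats: ModelMeta | None,
    profile: Profile,
    key: ResidueKey | None = None,
) -> ComponentResult:
    """Score one component: +1 per enabled, unmet condition; an RSR above the
    hard cap forces the label to Bad."""
    r_free = model_stats.r_free if model_stats is not None else None
    resolution = model_stats.resolution if model_stats is not None else None

    checks: list[tuple[str, float | None, float | None, bool]] = [
        # (condition, value, threshold, is_minimum)
        ("rscc", stats.rscc, profile.rscc_min, True),
        ("occupancy", stats.avg_occupancy, profile.occupancy_min, True),
        ("rsr", stats.rsr, profile.rsr_good_max, False),
        ("owab", stats.owab, profile.owab_max, False),
        ("r_free", r_free, profile.r_free_max, False),
        ("resolution", resolution, profile.resolution_max, False),
    ]

    failed: list[str] = []
    missing: list[str] = []
    for cond, value, threshold, is_min in checks:
        if threshold is None:  # disabled
            continue
        if value is None:
            failed.append(cond)
            missing.append(cond)
        elif (value < threshold) if is_min else (value > threshold):
            failed.append(cond)

    score = len(failed)
    if stats.rsr is not None and stats.rsr > profile.rsr_max:
        failed.append(RSR_CAP_CONDITION)
        score = max(score, profile.tolerance + 1)

    return ComponentResult(
        key=key,
        score=score,
        failed_conditions=failed,
        label=label_from_score(score, profile.tolerance),
        missing_conditions=missing,
    )


def worst_label(labels) -> Label:
    """Worst-of aggregation over the Good < Dubious < Bad order."""
    return max(labels, default=Label.Good)


def classify_pair(ligand, site, stats, model_stats, profile: Profile) -> PairResult:
    """Per-component results for a ligand/site pair plus worst-of labels.

    ``stats`` maps every ligand component and site residue to its
    :class:`ResidueStats` (possibly empty — the missing-data policy then
    applies per condition).
    """
    lig = [
        evaluate_component(stats.get(k, ResidueStats()), model_stats, profile, key=k)
        for k in ligand.components
    ]
    sit = [
        evaluate_component(stats.get(k, ResidueStats()), model_stats, profile, key=k)
        for k in site.residues
    ]
    if not sit:
        log.warning("empty binding site for ligand %s", ligand.group_id)
    return PairResult(
        ligand_components=lig,
        site_components=sit,
        ligand_label=worst_label(c.label for c in lig),
        site_label=worst_label(c.label for c in sit),
    )


def disable_threshold(profile: Profile, name: str) -> Profile:
    if name not in ("owab_max", "r_free_max", "resolution_max"):
        raise ValueError(f"threshold {name!r} cannot be disabled")
    return replace(profile, **{name: None})
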