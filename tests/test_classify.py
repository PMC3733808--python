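import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edqc.binding_site import BindingSite
from edqc.classify import (
    Label,
    Profile,
    classify_pair,
    default_profiles,
    evaluate_component,
    label_from_score,
    worst_label,
)
from edqc.ligand_extraction import LigandGroup
from edqc.model_io import ModelMeta, ResidueKey
from edqc.stats import ResidueStats


@pytest.fixture(scope="module")
def profile_pdb():
    return default_profiles()[0]


@pytest.fixture(scope="module")
def profile_redo():
    return default_profiles()[1]


class TestDefaultProfiles:
    def test_exactly_two(self):
        profiles = default_profiles()
        assert [p.name for p in profiles] == ["Default (PDB)", "Default (PDB_REDO)"]
        assert [p.source for p in profiles] == ["PDB", "PDB_REDO"]

    def test_shared_thresholds(self, profile_pdb, profile_redo):
        for p in (profile_pdb, profile_redo):
            assert p.rscc_min == 0.9
            assert p.occupancy_min == 1.0
            assert p.rsr_max == 0.4
            assert p.tolerance == 1
            assert p.site_cutoff == 4.5
            assert p.bond_cutoff == 2.1
            assert p.owab_max is None and p.r_free_max is None and p.resolution_max is None

    def test_good_rsr_cutoffs_differ_by_dialect(self, profile_pdb, profile_redo):
        assert profile_pdb.rsr_good_max == 0.24
        assert profile_redo.rsr_good_max == 0.165

    def test_invariant_good_below_cap(self, profile_pdb, profile_redo):
        assert profile_pdb.rsr_good_max <= profile_pdb.rsr_max
        assert profile_redo.rsr_good_max <= profile_redo.rsr_max

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError, match="rsr_good_max"):
            Profile(name="x", source="PDB", rscc_min=0.9, occupancy_min=1.0,
                    rsr_good_max=0.5, rsr_max=0.4)
        with pytest.raises(ValueError, match="tolerance"):
            Profile(name="x", source="PDB", rscc_min=0.9, occupancy_min=1.0,
                    rsr_good_max=0.2, rsr_max=0.4, tolerance=-1)


class TestLabelFromScore:
    @pytest.mark.parametrize(
        "score,tolerance,expected",
        [
            (0, 1, Label.Good),
            (2, 1, Label.Bad),
            (1, 1, Label.Dubious),
            (0, 0, Label.Good),
            (1, 0, Label.Bad),
            (3, 5, Label.Dubious),
        ],
    )
    def test_bands(self, score, tolerance, expected):
        assert label_from_score(score, tolerance) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            label_from_score(-1, 1)


class TestEvaluateComponent:
    def test_clean_component_under_redo(self, profile_redo):
        # the ligand that improves on re-refinement: all conditions met
        stats = ResidueStats(rsr=0.065, rscc=0.97, avg_occupancy=1.0)
        result = evaluate_component(stats, None, profile_redo)
        assert result.score == 0
        assert result.label == Label.Good
        assert not result.failed_conditions

    def test_marginal_component_under_pdb(self, profile_pdb):
        # same ligand as deposited: only RSCC fails -> Dubious
        stats = ResidueStats(rsr=0.154, rscc=0.86, avg_occupancy=1.0)
        result = evaluate_component(stats, None, profile_pdb)
        assert result.score == 1
        assert result.failed_conditions == ["rscc"]
        assert result.label == Label.Dubious

    def test_boundaries_inclusive(self, profile_pdb):
        stats = ResidueStats(rsr=0.24, rscc=0.90, avg_occupancy=1.0)
        result = evaluate_component(stats, None, profile_pdb)
        assert result.score == 0 and result.label == Label.Good

    def test_rsr_above_cap_forces_bad(self, profile_pdb, profile_redo):
        for profile in (profile_pdb, profile_redo):
            stats = ResidueStats(rsr=0.45, rscc=0.99, avg_occupancy=1.0)
            result = evaluate_component(stats, None, profile)
            assert result.label == Label.Bad
            assert "rsr_cap" in result.failed_conditions
            assert result.score > profile.tolerance

    def test_missing_enabled_condition_counts_as_unmet(self, profile_pdb):
        stats = ResidueStats(rsr=0.1)  # rscc and occupancy absent
        result = evaluate_component(stats, None, profile_pdb)
        assert result.score == 2
        assert set(result.missing_conditions) == {"rscc", "occupancy"}
        assert result.label == Label.Bad

    def test_model_level_conditions(self, profile_pdb):
        profile = dataclasses.replace(profile_pdb, r_free_max=0.25, resolution_max=2.0)
        stats = ResidueStats(rsr=0.1, rscc=0.95, avg_occupancy=1.0)
        good_meta = ModelMeta(resolution=1.8, r_free=0.20)
        bad_meta = ModelMeta(resolution=2.6, r_free=0.30)
        assert evaluate_component(stats, good_meta, profile).score == 0
        result = evaluate_component(stats, bad_meta, profile)
        assert result.score == 2
        assert set(result.failed_conditions) == {"r_free", "resolution"}

    def test_disabled_conditions_ignored(self, profile_pdb):
        stats = ResidueStats(rsr=0.1, rscc=0.95, avg_occupancy=1.0, owab=500.0)
        assert evaluate_component(stats, None, profile_pdb).score == 0
        enabled = dataclasses.replace(profile_pdb, owab_max=60.0)
        assert evaluate_component(stats, None, enabled).score == 1


stats_values = st.builds(
    ResidueStats,
    rsr=st.one_of(st.none(), st.floats(0, 0.8).map(lambda v: round(v, 3))),
    rscc=st.one_of(st.none(), st.floats(-1, 1).map(lambda v: round(v, 3))),
    avg_occupancy=st.one_of(st.none(), st.floats(0, 1).map(lambda v: round(v, 3))),
    owab=st.one_of(st.none(), st.floats(0, 120).map(lambda v: round(v, 2))),
)


def oracle_score(stats: ResidueStats, meta, profile: Profile) -> int:
    """Independent condition counter (data-driven, no shared code path)."""
    failures = 0
    minima = {"rscc": (stats.rscc, profile.rscc_min), "occ": (stats.avg_occupancy, profile.occupancy_min)}
    maxima = {
        "rsr": (stats.rsr, profile.rsr_good_max),
        "owab": (stats.owab, profile.owab_max),
        "r_free": (meta.r_free if meta else None, profile.r_free_max),
        "res": (meta.resolution if meta else None, profile.resolution_max),
    }
    for value, threshold in minima.values():
        if threshold is not None and (value is None or value < threshold):
            failures += 1
    for value, threshold in maxima.values():
        if threshold is not None and (value is None or value > threshold):
            failures += 1
    if stats.rsr is not None and stats.rsr > profile.rsr_max:
        failures = max(failures, profile.tolerance + 1)
    return failures


class TestOracleEquivalence:
    @given(stats=stats_values, owab_max=st.one_of(st.none(), st.floats(20, 100)),
           tolerance=st.integers(0, 3))
    @settings(max_examples=200, deadline=None)
    def test_score_matches_brute_force_counter(self, stats, owab_max, tolerance):
        profile = Profile(
            name="t", source="PDB", rscc_min=0.9, occupancy_min=1.0,
            rsr_good_max=0.24, rsr_max=0.4, owab_max=owab_max, tolerance=tolerance,
        )
        result = evaluate_component(stats, None, profile)
        assert result.score == oracle_score(stats, None, profile)
        assert result.label == label_from_score(result.score, tolerance)


class TestMonotonicity:
    @given(
        stats=stats_values,
        drop_rscc=st.floats(0, 0.3),
        drop_occ=st.floats(0, 0.3),
        raise_rsr=st.floats(0, 0.3),
    )
    @settings(max_examples=150, deadline=None)
    def test_relaxing_thresholds_never_worsens_label(self, stats, drop_rscc, drop_occ, raise_rsr):
        tight = default_profiles()[0]
        relaxed = dataclasses.replace(
            tight,
            rscc_min=tight.rscc_min - drop_rscc,
            occupancy_min=tight.occupancy_min - drop_occ,
            rsr_good_max=tight.rsr_good_max + raise_rsr,
            rsr_max=tight.rsr_max + raise_rsr,
        )
        before = evaluate_component(stats, None, tight).label
        after = evaluate_component(stats, None, relaxed).label
        assert after <= before


labels = st.sampled_from([Label.Good, Label.Dubious, Label.Bad])


class TestWorstOfAggregation:
    @given(st.lists(labels, min_size=1, max_size=8))
    def test_idempotent_commutative_associative(self, values):
        assert worst_label(values) == worst_label(reversed(list(values)))
        assert worst_label([worst_label(values), worst_label(values)]) == worst_label(values)
        split = len(values) // 2
        left, right = values[:split], values[split:]
        assert worst_label([worst_label(left), worst_label(right)]) == worst_label(values)

    @given(st.lists(labels, min_size=1, max_size=8))
    def test_adding_good_never_changes_aggregate(self, values):
        assert worst_label(values + [Label.Good]) == worst_label(values)


def _pair(component_labels_site, component_labels_lig, profile):
    """Build a classified pair from target per-component stats."""
    by_label = {
        Label.Good: ResidueStats(rsr=0.05, rscc=0.95, avg_occupancy=1.0),
        Label.Dubious: ResidueStats(rsr=0.05, rscc=0.80, avg_occupancy=1.0),
        Label.Bad: ResidueStats(rsr=0.45, rscc=0.80, avg_occupancy=1.0),
    }
    lig_keys = tuple(
        ResidueKey("B", i + 1, "", "LIG") for i in range(len(component_labels_lig))
    )
    site_keys = tuple(
        ResidueKey("A", i + 1, "", "GLY") for i in range(len(component_labels_site))
    )
    ligand = LigandGroup(components=lig_keys)
    site = BindingSite(ligand=ligand, residues=site_keys, cutoff=4.5)
    stats = {k: by_label[l] for k, l in zip(lig_keys, component_labels_lig)}
    stats.update({k: by_label[l] for k, l in zip(site_keys, component_labels_site)})
    return classify_pair(ligand, site, stats, None, profile)


class TestClassifyPair:
    def test_site_dubious_when_one_dubious(self, profile_pdb):
        pair = _pair([Label.Good, Label.Good, Label.Dubious], [Label.Good], profile_pdb)
        assert pair.site_label == Label.Dubious
        assert pair.ligand_label == Label.Good

    def test_one_bad_among_ten_good(self, profile_pdb):
        pair = _pair([Label.Good] * 10 + [Label.Bad], [Label.Good], profile_pdb)
        assert pair.site_label == Label.Bad

    def test_all_good(self, profile_pdb):
        pair = _pair([Label.Good, Label.Good], [Label.Good], profile_pdb)
        assert (pair.ligand_label, pair.site_label) == (Label.Good, Label.Good)

    def test_empty_site_is_good_with_warning(self, profile_pdb, caplog):
        with caplog.at_level("WARNING"):
            pair = _pair([], [Label.Good], profile_pdb)
        assert pair.site_label == Label.Good
        assert any("empty binding site" in rec.message for rec in caplog.records)

    def test_worked_example_both_dialects(self, profile_pdb, profile_redo):
        # deposited vs re-refined numbers for the same ligand
        deposited = ResidueStats(rsr=0.154, rscc=0.86, avg_occupancy=1.0)
        rerefined = ResidueStats(rsr=0.065, rscc=0.97, avg_occupancy=1.0)
        key = ResidueKey("C", 1, "", "5GP")
        ligand = LigandGroup(components=(key,))
        site = BindingSite(ligand=ligand, residues=(), cutoff=4.5)
        pdb_pair = classify_pair(ligand, site, {key: deposited}, None, profile_pdb)
        redo_pair = classify_pair(ligand, site, {key: rerefined}, None, profile_redo)
        assert pdb_pair.ligand_label == Label.Dubious
        assert redo_pair.ligand_label == Label.Good
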