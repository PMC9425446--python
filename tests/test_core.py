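"""Compatibility, filtering, discriminatory power, ranking and validation."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from platykey.core import (
    CharacterDef,
    CharacterKind,
    KBError,
    KnowledgeBase,
    Observation,
    ProfileError,
    RankingOptions,
    SpecimenProfile,
    TaxonDescription,
    Weight,
    compatible,
    discriminatory_power,
    filter_taxa,
    rank_characters,
    validate_kb,
)
from platykey.synth import SynthConfig, random_kb

from conftest import make_kb


# ---------------------------------------------------------------------------
# compatible / filter_taxa
# ---------------------------------------------------------------------------

class TestCompatible:
    def test_empty_profile_matches_everything(self, kb):
        empty = SpecimenProfile({})
        assert all(compatible(kb, t, empty) for t in kb.taxa)

    def test_hairy_observation_excludes_glabrous_species(self, kb):
        hairy = SpecimenProfile({"hairs_upperside": {"present"}})
        assert not compatible(kb, kb.taxon("agonum_marginatum"), hairy)
        assert compatible(kb, kb.taxon("atranus_ruficollis"), hairy)

    def test_unknown_cell_is_always_compatible(self, kb):
        # Atranus is unscored for the mentum tooth: either answer keeps it
        for state in ("present", "absent"):
            assert compatible(kb, kb.taxon("atranus_ruficollis"),
                              SpecimenProfile({"mentum_tooth": {state}}))

    def test_numerical_point_must_fall_in_interval(self, kb):
        small = SpecimenProfile({"body_length": 5.5})
        big = SpecimenProfile({"body_length": 12.0})
        orth = kb.taxon("orthotrichus_cymindoides")  # 9-12 mm
        assert not compatible(kb, orth, small)
        assert compatible(kb, orth, big)  # closed interval: boundary matches

    def test_unknown_character_or_state_is_an_input_error(self, kb):
        with pytest.raises(ProfileError):
            compatible(kb, kb.taxa[0], SpecimenProfile({"no_such_char": {"x"}}))
        with pytest.raises(ProfileError):
            compatible(kb, kb.taxa[0], SpecimenProfile({"hairs_upperside": {"shaggy"}}))


class TestFilterTaxa:
    def test_empty_profile_keeps_all_14_taxa(self, kb):
        assert len(filter_taxa(kb, SpecimenProfile({}))) == 14

    def test_hairy_upperside_leaves_the_two_pubescent_species(self, kb):
        got = [t.taxon_id for t in filter_taxa(kb, SpecimenProfile({"hairs_upperside": {"present"}}))]
        assert got == ["atranus_ruficollis", "orthotrichus_cymindoides"]

    def test_adding_pronotum_proportion_isolates_orthotrichus(self, kb):
        p = SpecimenProfile({"hairs_upperside": {"present"},
                             "pronotum_proportion": {"clearly_wider"}})
        assert [t.taxon_id for t in filter_taxa(kb, p)] == ["orthotrichus_cymindoides"]

    def test_result_preserves_declaration_order(self, kb):
        got = filter_taxa(kb, SpecimenProfile({"mentum_tooth": {"present"}}))
        ids = [t.taxon_id for t in got]
        assert ids == [t for t in kb.taxon_ids if t in set(ids)]


# ---------------------------------------------------------------------------
# Brute-force oracle equivalence and elimination properties
# ---------------------------------------------------------------------------

def brute_force_filter(kb, profile):
    """Independent evaluator: exhaustive set/interval checks on raw values."""
    kept = []
    for taxon in kb.taxa:
        ok = True
        for cid, ans in profile.answers.items():
            obs = taxon.observations[cid]
            if obs.status.value != "scored":
                continue
            if isinstance(ans, float):
                lo, hi = obs.interval
                if ans < lo or ans > hi:
                    ok = False
            else:
                if len(set(ans) & set(obs.states)) == 0:
                    ok = False
        if ok:
            kept.append(taxon.taxon_id)
    return kept


def _random_profile(kb, seed):
    import numpy as np

    rng = np.random.default_rng(seed)
    answers = {}
    for char in kb.characters:
        if rng.random() < 0.5:
            continue
        if char.kind is CharacterKind.categorical:
            k = int(rng.integers(1, len(char.state_ids) + 1))
            answers[char.char_id] = set(rng.choice(char.state_ids, size=k, replace=False))
        else:
            answers[char.char_id] = float(rng.uniform(-1, 12))
    return SpecimenProfile(answers)


@given(seed=st.integers(0, 10_000))
def test_filter_equals_brute_force_on_random_kbs(seed):
    kb = random_kb(SynthConfig(n_taxa=6, n_characters=5, seed=seed,
                               states_range=(2, 4), n_numerical=1,
                               p_polymorphism=0.3, p_unknown=0.2))
    profile = _random_profile(kb, seed + 1)
    assert [t.taxon_id for t in filter_taxa(kb, profile)] == brute_force_filter(kb, profile)


@given(seed=st.integers(0, 10_000))
def test_elimination_is_monotone_in_the_profile(seed):
    kb = random_kb(SynthConfig(n_taxa=7, n_characters=6, seed=seed,
                               p_polymorphism=0.25, p_unknown=0.2, n_numerical=1))
    full = _random_profile(kb, seed + 7)
    items = sorted(full.answers.items())
    partial = SpecimenProfile(dict(items[: len(items) // 2]))
    sub = {t.taxon_id for t in filter_taxa(kb, full)}
    sup = {t.taxon_id for t in filter_taxa(kb, partial)}
    assert sub <= sup


@given(seed=st.integers(0, 10_000))
def test_noiseless_self_profile_never_eliminates_the_taxon(seed):
    from platykey.keygen import noiseless_profile

    kb = random_kb(SynthConfig(n_taxa=6, n_characters=5, seed=seed,
                               p_polymorphism=0.3, p_unknown=0.3, n_numerical=1))
    for taxon in kb.taxa:
        remaining = filter_taxa(kb, noiseless_profile(kb, taxon))
        assert taxon.taxon_id in {t.taxon_id for t in remaining}


# ---------------------------------------------------------------------------
# discriminatory_power
# ---------------------------------------------------------------------------

class TestDiscriminatoryPower:
    def test_identically_scored_character_has_zero_power(self):
        kb = make_kb({"a": {"c": ["x"]}, "b": {"c": ["x"]}}, {"c": ["x", "y"]})
        assert discriminatory_power(kb, "c") == 0.0

    def test_perfectly_splitting_character_has_power_one(self):
        kb = make_kb({"a": {"c": ["x"]}, "b": {"c": ["y"]}}, {"c": ["x", "y"]})
        assert discriminatory_power(kb, "c") == 1.0

    def test_hairs_on_full_base_is_24_of_91(self, kb):
        assert discriminatory_power(kb, "hairs_upperside", kb.taxa) == pytest.approx(24 / 91)

    def test_invariant_under_taxon_reordering(self, kb):
        fwd = discriminatory_power(kb, "pronotum_proportion", kb.taxa)
        rev = discriminatory_power(kb, "pronotum_proportion", tuple(reversed(kb.taxa)))
        assert fwd == rev

    def test_all_unknown_extra_taxa_change_nothing_but_the_denominator(self):
        kb = make_kb({"a": {"c": ["x"]}, "b": {"c": ["y"]}, "u": {}}, {"c": ["x", "y"]})
        # the unknown taxon joins no scored pair: power stays 1/1
        assert discriminatory_power(kb, "c") == 1.0

    def test_fewer_than_two_taxa_is_an_error(self, kb):
        with pytest.raises(KBError):
            discriminatory_power(kb, "hairs_upperside", kb.taxa[:1])

    def test_disjoint_intervals_separate_but_touching_do_not(self):
        kb = make_kb({"a": {"n": (1, 2)}, "b": {"n": (2, 3)}, "c": {"n": (5, 6)}},
                     {"n": None})
        # touching closed intervals share the boundary: 2 of 3 pairs disjoint
        assert discriminatory_power(kb, "n") == pytest.approx(2 / 3)


# ---------------------------------------------------------------------------
# rank_characters
# ---------------------------------------------------------------------------

class TestRankCharacters:
    def test_perfect_separator_ranks_first(self):
        kb = make_kb(
            {"a": {"c": ["x"], "d": ["p"]}, "b": {"c": ["x", "y"], "d": ["q"]}},
            {"c": ["x", "y"], "d": ["p", "q"]},
        )
        assert rank_characters(kb, kb.taxa)[0].char_id == "d"

    def test_prefer_fewer_states_breaks_power_ties_by_state_count(self):
        kb = make_kb(
            {"a": {"many": ["m1"], "two": ["x"]}, "b": {"many": ["m2"], "two": ["y"]}},
            {"many": [f"m{i}" for i in range(1, 13)], "two": ["x", "y"]},
        )
        opts = RankingOptions(prefer_fewer_states=True)
        assert [c.char_id for c in rank_characters(kb, kb.taxa, options=opts)] == ["two", "many"]

    def test_use_weights_prefers_strong_over_weak_at_equal_power_and_states(self):
        kb = make_kb(
            {"a": {"w": ["x"], "s": ["x"]}, "b": {"w": ["y"], "s": ["y"]}},
            {"w": ["x", "y"], "s": ["x", "y"]},
        ).with_weights({"w": Weight.weak, "s": Weight.strong})
        opts = RankingOptions(use_weights=True)
        assert [c.char_id for c in rank_characters(kb, kb.taxa, options=opts)] == ["s", "w"]

    def test_answered_and_powerless_characters_are_excluded(self):
        kb = make_kb(
            {"a": {"c": ["x"], "dead": ["z"]}, "b": {"c": ["y"], "dead": ["z"]}},
            {"c": ["x", "y"], "dead": ["z", "zz"]},
        )
        assert rank_characters(kb, kb.taxa, answered={"c"}) == []

    def test_conflicting_state_count_policies_rejected(self):
        with pytest.raises(ValueError):
            RankingOptions(prefer_fewer_states=True, most_states_first=True)


# ---------------------------------------------------------------------------
# validate_kb
# ---------------------------------------------------------------------------

class TestValidateKb:
    def test_packaged_base_has_no_structural_errors(self, kb):
        report = validate_kb(kb)
        assert report.errors == []
        assert report.ok

    def test_identically_scored_taxa_trigger_indistinguishable_warning(self):
        kb = make_kb({"a": {"c": ["x"]}, "b": {"c": ["x"]}}, {"c": ["x", "y"]})
        report = validate_kb(kb)
        assert ("a", "b") in report.indistinguishable_pairs

    def test_all_unknown_character_is_flagged(self):
        kb = make_kb({"a": {"c": ["x"]}, "b": {"c": ["y"]}},
                     {"c": ["x", "y"], "ghost": ["g1", "g2"]})
        assert validate_kb(kb).all_unknown_characters == ["ghost"]

    def test_missing_observation_is_a_structural_error(self):
        chars = (CharacterDef("c", "c", CharacterKind.categorical, (("x", "x"),)),)
        taxa = (TaxonDescription("a", "a", True, {}),)
        report = validate_kb(KnowledgeBase("broken", chars, taxa))
        assert any("no observation" in e for e in report.errors)

    def test_undeclared_state_is_a_structural_error(self):
        chars = (CharacterDef("c", "c", CharacterKind.categorical, (("x", "x"),)),)
        taxa = (TaxonDescription("a", "a", True, {"c": Observation.scored_states(["zz"])}),)
        assert not validate_kb(KnowledgeBase("broken", chars, taxa)).ok


def test_observation_invariants_rejected_at_construction():
    with pytest.raises(KBError):
        Observation.scored_interval(5, 2)
    with pytest.raises(KBError):
        Observation("scored")  # no value
    with pytest.raises(KBError):
        CharacterDef("c", "c", CharacterKind.categorical, ())
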