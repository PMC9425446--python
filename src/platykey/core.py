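"""Domain model for descriptive knowledge bases.

A knowledge base is a characters × taxa matrix in the style of matrix-based
identification tools (Xper, Lucid, DELTA): each *character* (descriptor) is
either categorical, with a fixed ordered list of states, or numerical, with a
unit; each *taxon* scores every character either with a value (a non-empty
state subset, allowing polymorphism, or a closed numerical interval), or as
unknown, or as inapplicable.

The semantics implemented here drive everything else in the package:

* a specimen observation is *compatible* with a taxon unless it positively
  contradicts the taxon's scored value — unknown and inapplicable cells never
  eliminate anything;
* a character *separates* a pair of taxa iff both are scored and their values
  are disjoint (empty state intersection, or non-overlapping intervals);
* the *discriminatory power* of a character over a set of remaining taxa is
  the fraction of scored pairs it separates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Weight",
    "CharacterKind",
    "ObservationStatus",
    "CharacterDef",
    "Observation",
    "TaxonDescription",
    "KnowledgeBase",
    "SpecimenProfile",
    "ValidationReport",
    "RankingOptions",
    "KBError",
    "ProfileError",
    "compatible",
    "filter_taxa",
    "separates_pair",
    "discriminatory_power",
    "effective_state_count",
    "rank_characters",
    "validate_kb",
]


class KBError(ValueError):
    """A structural problem in a knowledge base."""


class ProfileError(ValueError):
    """A specimen profile refers to characters or states the knowledge base lacks."""


class Weight(int, Enum):
    """Three-level character weighting (weak < medium < strong)."""

    weak = 1
    medium = 2
    strong = 3

    @classmethod
    def coerce(cls, value: "int | str | Weight") -> "Weight":
        if isinstance(value, Weight):
            return value
        if isinstance(value, str):
            return cls[value]
        return cls(value)


class CharacterKind(str, Enum):
    categorical = "categorical"
    numerical = "numerical"


class ObservationStatus(str, Enum):
    scored = "scored"
    unknown = "unknown"
    inapplicable = "inapplicable"


@dataclass(frozen=True)
class CharacterDef:
    """One descriptor of the knowledge base.

    Categorical characters carry an ordered list of ``(state_id, label)``
    pairs; numerical ones carry a measurement unit instead.  ``weight`` feeds
    the ``use_weights`` ranking option, ``group`` is a free organisational tag
    (e.g. ``"pronotum"``).
    """

    char_id: str
    name: str
    kind: CharacterKind
    states: tuple[tuple[str, str], ...] = ()
    units: str = ""
    weight: Weight = Weight.medium
    group: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", CharacterKind(self.kind))
        object.__setattr__(self, "weight", Weight.coerce(self.weight))
        object.__setattr__(self, "states", tuple((str(s), str(l)) for s, l in self.states))
        if self.kind is CharacterKind.categorical:
            if not self.states:
                raise KBError(f"categorical character {self.char_id!r} declares no states")
        elif self.states:
            raise KBError(f"numerical character {self.char_id!r} must not declare states")
        ids = [s for s, _ in self.states]
        if len(ids) != len(set(ids)):
            raise KBError(f"duplicate state ids in character {self.char_id!r}")

    @property
    def state_ids(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.states)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_label(self, state_id: str) -> str:
        for sid, label in self.states:
            if sid == state_id:
                return label
        raise KeyError(state_id)


@dataclass(frozen=True)
class Observation:
    """One cell of the matrix: a taxon's scoring of one character.

    ``states`` (categorical) is a frozenset of state ids — more than one means
    the taxon is polymorphic for the character.  ``interval`` (numerical) is a
    closed ``[lo, hi]`` range.  ``note`` records provenance (which printed
    source the cell was transcribed from) for curated matrices.
    """

    status: ObservationStatus = ObservationStatus.unknown
    states: frozenset[str] = frozenset()
    interval: tuple[float, float] | None = None
    note: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "status", ObservationStatus(self.status))
        object.__setattr__(self, "states", frozenset(self.states))
        if self.status is ObservationStatus.scored:
            if bool(self.states) == (self.interval is not None):
                raise KBError("a scored cell needs exactly one of states / interval")
            if self.interval is not None:
                lo, hi = self.interval
                if lo > hi:
                    raise KBError(f"interval lo > hi: {self.interval}")
                object.__setattr__(self, "interval", (float(lo), float(hi)))
        elif self.states or self.interval is not None:
            raise KBError(f"{self.status.value} cell must carry no value")

    @classmethod
    def scored_states(cls, states: Iterable[str], note: str = "") -> "Observation":
        return cls(ObservationStatus.scored, frozenset(states), None, note)

    @classmethod
    def scored_interval(cls, lo: float, hi: float, note: str = "") -> "Observation":
        return cls(ObservationStatus.scored, frozenset(), (lo, hi), note)

    @classmethod
    def unknown(cls, note: str = "") -> "Observation":
        return cls(ObservationStatus.unknown, note=note)

    @classmethod
    def inapplicable(cls, note: str = "") -> "Observation":
        return cls(ObservationStatus.inapplicable, note=note)

    @property
    def is_scored(self) -> bool:
        return self.status is ObservationStatus.scored


@dataclass(frozen=True)
class TaxonDescription:
    """One item (species) of the knowledge base with its full observation row."""

    taxon_id: str
    name: str
    in_region: bool = True
    observations: Mapping[str, Observation] = field(default_factory=dict)
    notes: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "observations", dict(self.observations))

    def observation(self, char_id: str) -> Observation:
        return self.observations[char_id]


@dataclass(frozen=True)
class SpecimenProfile:
    """A (partial) set of answers about one specimen.

    Categorical answers are non-empty state-id sets (a single selection is a
    singleton); numerical answers are measured points.
    """

    answers: Mapping[str, frozenset[str] | float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        norm: dict[str, frozenset[str] | float] = {}
        for cid, ans in dict(self.answers).items():
            if isinstance(ans, (int, float)) and not isinstance(ans, bool):
                norm[cid] = float(ans)
            elif isinstance(ans, str):
                norm[cid] = frozenset({ans})
            else:
                norm[cid] = frozenset(ans)
        object.__setattr__(self, "answers", norm)

    def extended(self, char_id: str, answer: "frozenset[str] | float | str | Iterable[str]") -> "SpecimenProfile":
        if char_id in self.answers:
            raise ProfileError(f"character {char_id!r} already answered")
        merged = dict(self.answers)
        merged[char_id] = answer  # type: ignore[assignment]
        return SpecimenProfile(merged)

    def __len__(self) -> int:
        return len(self.answers)


@dataclass(frozen=True)
class KnowledgeBase:
    """The full descriptive matrix plus metadata; the unit every module consumes."""

    title: str
    characters: tuple[CharacterDef, ...]
    taxa: tuple[TaxonDescription, ...]
    notes: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "characters", tuple(self.characters))
        object.__setattr__(self, "taxa", tuple(self.taxa))

    # -- lookups -----------------------------------------------------------
    def character(self, char_id: str) -> CharacterDef:
        for c in self.characters:
            if c.char_id == char_id:
                return c
        raise KeyError(char_id)

    def taxon(self, taxon_id: str) -> TaxonDescription:
        for t in self.taxa:
            if t.taxon_id == taxon_id:
                return t
        raise KeyError(taxon_id)

    @property
    def char_ids(self) -> tuple[str, ...]:
        return tuple(c.char_id for c in self.characters)

    @property
    def taxon_ids(self) -> tuple[str, ...]:
        return tuple(t.taxon_id for t in self.taxa)

    def char_index(self, char_id: str) -> int:
        return self.char_ids.index(char_id)

    def with_weights(self, weights: Mapping[str, "Weight | int | str"]) -> "KnowledgeBase":
        """Return a copy with per-character weights overridden."""
        unknown = set(weights) - set(self.char_ids)
        if unknown:
            raise KBError(f"weight override for unknown characters: {sorted(unknown)}")
        chars = tuple(
            CharacterDef(
                c.char_id, c.name, c.kind, c.states, c.units,
                Weight.coerce(weights.get(c.char_id, c.weight)), c.group,
            )
            for c in self.characters
        )
        return KnowledgeBase(self.title, chars, self.taxa, self.notes)

    def check_profile(self, profile: SpecimenProfile) -> None:
        """Raise ProfileError unless every answer is legal for this base."""
        for cid, ans in profile.answers.items():
            try:
                char = self.character(cid)
            except KeyError:
                raise ProfileError(f"unknown character {cid!r}") from None
            if isinstance(ans, float):
                if char.kind is not CharacterKind.numerical:
                    raise ProfileError(f"numerical answer for categorical character {cid!r}")
            else:
                if char.kind is not CharacterKind.categorical:
                    raise ProfileError(f"state answer for numerical character {cid!r}")
                if not ans:
                    raise ProfileError(f"empty state set for character {cid!r}")
                bad = ans - set(char.state_ids)
                if bad:
                    raise ProfileError(f"unknown states {sorted(bad)} for character {cid!r}")


# ---------------------------------------------------------------------------
# Compatibility and filtering
# ---------------------------------------------------------------------------

def compatible(kb: KnowledgeBase, desc: TaxonDescription, profile: SpecimenProfile) -> bool:
    """True iff no answered character positively contradicts the taxon.

    Unknown and inapplicable cells are compatible with any answer; categorical
    answers must intersect the taxon's state set; numerical points must fall
    inside the taxon's closed interval.
    """
    kb.check_profile(profile)
    for cid, ans in profile.answers.items():
        obs = desc.observations.get(cid, Observation.unknown())
        if not obs.is_scored:
            continue
        if isinstance(ans, float):
            lo, hi = obs.interval  # type: ignore[misc]
            if not (lo <= ans <= hi):
                return False
        else:
            if not (ans & obs.states):
                return False
    return True


def filter_taxa(kb: KnowledgeBase, profile: SpecimenProfile) -> list[TaxonDescription]:
    """Taxa compatible with the profile, in knowledge-base order."""
    kb.check_profile(profile)
    return [t for t in kb.taxa if compatible(kb, t, profile)]


# ---------------------------------------------------------------------------
# Discriminatory power and character ranking
# ---------------------------------------------------------------------------

def separates_pair(char: CharacterDef, a: Observation, b: Observation) -> bool:
    """A character separates two taxa iff both cells are scored and disjoint."""
    if not (a.is_scored and b.is_scored):
        return False
    if char.kind is CharacterKind.categorical:
        return not (a.states & b.states)
    (alo, ahi), (blo, bhi) = a.interval, b.interval  # type: ignore[misc]
    return ahi < blo or bhi < alo


def discriminatory_power(
    kb: KnowledgeBase, char_id: str, remaining: Sequence[TaxonDescription] | None = None
) -> float:
    """Pairwise-separation index of a character over the remaining taxa.

    (number of scored pairs the character separates) / (number of pairs with
    both taxa scored); 0 when no scored pair exists.
    """
    if remaining is None:
        remaining = kb.taxa
    if len(remaining) < 2:
        raise KBError("discriminatory power needs at least two remaining taxa")
    char = kb.character(char_id)
    separated = scored_pairs = 0
    for ta, tb in itertools.combinations(remaining, 2):
        oa, ob = ta.observations.get(char_id), tb.observations.get(char_id)
        if oa is None or ob is None or not (oa.is_scored and ob.is_scored):
            continue
        scored_pairs += 1
        if separates_pair(char, oa, ob):
            separated += 1
    return separated / scored_pairs if scored_pairs else 0.0


def effective_state_count(char: CharacterDef) -> int:
    """State count used by the fewer/more-states ranking criteria.

    Numerical characters count as 2: key generation binarises them at interval
    gaps, so they behave like (a cascade of) two-state characters.
    """
    return char.n_states if char.kind is CharacterKind.categorical else 2


@dataclass(frozen=True)
class RankingOptions:
    """Character-ranking policy, mirroring the options of matrix key builders.

    ``prefer_fewer_states`` makes the state count (ascending) the primary sort
    criterion; ``most_states_first`` makes it primary descending (the policy
    under which a many-state character such as overall coloration is asked
    first). ``use_weights`` inserts the declared character weight (descending)
    immediately after the primary criterion. Discriminatory power (descending)
    and declaration order break the remaining ties.
    """

    use_weights: bool = False
    prefer_fewer_states: bool = False
    most_states_first: bool = False

    def __post_init__(self) -> None:
        if self.prefer_fewer_states and self.most_states_first:
            raise ValueError("prefer_fewer_states and most_states_first are mutually exclusive")

    def sort_key(self, kb: KnowledgeBase, char: CharacterDef, power: float):
        crit: list[float] = []
        if self.prefer_fewer_states:
            crit.append(effective_state_count(char))
        elif self.most_states_first:
            crit.append(-effective_state_count(char))
        else:
            crit.append(-power)
        if self.use_weights:
            crit.append(-int(char.weight))
        if self.prefer_fewer_states or self.most_states_first:
            crit.append(-power)
        crit.append(kb.char_index(char.char_id))
        return tuple(crit)


def rank_characters(
    kb: KnowledgeBase,
    remaining: Sequence[TaxonDescription],
    answered: Iterable[str] = (),
    options: RankingOptions = RankingOptions(),
) -> list[CharacterDef]:
    """Characters ordered by usefulness for the next identification step.

    Already-answered characters and characters with zero discriminatory power
    over the remaining taxa are excluded.
    """
    if len(remaining) < 2:
        raise KBError("ranking needs at least two remaining taxa")
    answered = set(answered)
    ranked: list[tuple[tuple, CharacterDef]] = []
    for char in kb.characters:
        if char.char_id in answered:
            continue
        power = discriminatory_power(kb, char.char_id, remaining)
        if power == 0.0:
            continue
        ranked.append((options.sort_key(kb, char, power), char))
    ranked.sort(key=lambda kv: kv[0])
    return [c for _, c in ranked]


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Outcome of structural and completeness checks on a knowledge base.

    ``errors`` are structural violations (the base is unusable while any
    exist); ``warnings`` flag completeness problems: characters unknown for
    every taxon, taxon pairs no character separates, and characters that
    separate no pair.
    """

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    all_unknown_characters: list[str] = field(default_factory=list)
    indistinguishable_pairs: list[tuple[str, str]] = field(default_factory=list)
    non_separating_characters: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_kb(kb: KnowledgeBase) -> ValidationReport:
    report = ValidationReport()
    err = report.errors.append

    if not kb.taxa:
        err("knowledge base has no taxa")
    if not kb.characters:
        err("knowledge base has no characters")
    if len(set(kb.char_ids)) != len(kb.char_ids):
        err("duplicate character ids")
    if len(set(kb.taxon_ids)) != len(kb.taxon_ids):
        err("duplicate taxon ids")

    chars = {c.char_id: c for c in kb.characters}
    for t in kb.taxa:
        missing = set(chars) - set(t.observations)
        extra = set(t.observations) - set(chars)
        if missing:
            err(f"taxon {t.taxon_id!r}: no observation for {sorted(missing)}")
        if extra:
            err(f"taxon {t.taxon_id!r}: observations for undeclared {sorted(extra)}")
        for cid, obs in t.observations.items():
            char = chars.get(cid)
            if char is None or not obs.is_scored:
                continue
            if char.kind is CharacterKind.categorical:
                if obs.interval is not None:
                    err(f"cell ({t.taxon_id}, {cid}): interval on categorical character")
                elif not obs.states <= set(char.state_ids):
                    bad = sorted(obs.states - set(char.state_ids))
                    err(f"cell ({t.taxon_id}, {cid}): undeclared states {bad}")
            else:
                if obs.interval is None:
                    err(f"cell ({t.taxon_id}, {cid}): states on numerical character")

    if report.errors:
        return report

    for char in kb.characters:
        if kb.taxa and all(not t.observations[char.char_id].is_scored for t in kb.taxa):
            report.all_unknown_characters.append(char.char_id)
            report.warnings.append(f"character {char.char_id!r} is unknown for every taxon")
        elif len(kb.taxa) >= 2 and discriminatory_power(kb, char.char_id, kb.taxa) == 0.0:
            report.non_separating_characters.append(char.char_id)
            report.warnings.append(f"character {char.char_id!r} separates no taxon pair")

    for ta, tb in itertools.combinations(kb.taxa, 2):
        if not any(
            separates_pair(c, ta.observations[c.char_id], tb.observations[c.char_id])
            for c in kb.characters
        ):
            report.indistinguishable_pairs.append((ta.taxon_id, tb.taxon_id))
            report.warnings.append(
                f"taxa {ta.taxon_id!r} and {tb.taxon_id!r} are indistinguishable"
            )
    return report
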