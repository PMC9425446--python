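"""Stateful multi-access identification sessions.

A :class:`Session` wraps a knowledge base and an ordered answer log; after
every answer the remaining (still-compatible) taxa are recomputed by
elimination.  Characters can be answered in any order — the endpoint depends
only on the set of answers, not their sequence.  :func:`decision_profile`
measures how many answers a simulated, noiseless user needs per taxon under a
given character-ranking policy, the efficiency statistic used to compare
ranking policies (asking the many-state coloration character first resolves
most species in very few steps; prioritising few-state characters costs more
steps but keeps each question simple).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .core import (
    CharacterDef,
    CharacterKind,
    KBError,
    KnowledgeBase,
    ProfileError,
    RankingOptions,
    SpecimenProfile,
    TaxonDescription,
    filter_taxa,
    rank_characters,
)
from .keygen import noiseless_profile

__all__ = ["Session", "DecisionCount", "DecisionProfile", "decision_profile"]


@dataclass(frozen=True)
class Session:
    """One identification session; immutable — :meth:`step` returns a new one."""

    kb: KnowledgeBase
    options: RankingOptions = RankingOptions()
    answers: tuple[tuple[str, frozenset[str] | float], ...] = ()

    @property
    def profile(self) -> SpecimenProfile:
        return SpecimenProfile(dict(self.answers))

    @property
    def remaining(self) -> list[TaxonDescription]:
        return filter_taxa(self.kb, self.profile)

    @property
    def answered(self) -> tuple[str, ...]:
        return tuple(cid for cid, _ in self.answers)

    def step(self, char_id: str, answer: "frozenset[str] | float | str | Iterable[str]") -> "Session":
        """Answer one character; remaining taxa shrink monotonically."""
        if char_id in self.answered:
            raise ProfileError(f"character {char_id!r} already answered")
        profile = self.profile.extended(char_id, answer)
        self.kb.check_profile(profile)  # reject unknown chars/states up front
        return Session(self.kb, self.options, self.answers + ((char_id, profile.answers[char_id]),))

    def suggest_next(self) -> list[CharacterDef]:
        """Characters ranked for the next step; empty once a single taxon remains."""
        remaining = self.remaining
        if len(remaining) < 2:
            return []
        return rank_characters(self.kb, remaining, self.answered, self.options)

    def transcript(self) -> dict:
        """JSON-serialisable session record."""
        log = []
        for cid, ans in self.answers:
            char = self.kb.character(cid)
            log.append({
                "character": cid,
                "answer": sorted(ans) if isinstance(ans, frozenset) else ans,
                "kind": char.kind.value,
            })
        return {
            "knowledge_base": self.kb.title,
            "answers": log,
            "remaining": [t.taxon_id for t in self.remaining],
        }


@dataclass(frozen=True)
class DecisionCount:
    """Answers needed before the remaining set collapsed to one taxon."""

    taxon_id: str
    decisions: int


@dataclass
class DecisionProfile:
    """Per-taxon decision counts for one ranking policy, plus unresolved taxa
    (those whose remaining set no available character could shrink further)."""

    counts: dict[str, DecisionCount] = field(default_factory=dict)
    unresolved: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def decisions(self) -> dict[str, int]:
        return {t: c.decisions for t, c in self.counts.items()}

    def to_dict(self) -> dict:
        out: dict = {"decisions": dict(sorted(self.decisions.items()))}
        if self.counts:
            vals = list(self.decisions.values())
            out["min_decisions"] = min(vals)
            out["max_decisions"] = max(vals)
        out["unresolved"] = {t: list(r) for t, r in sorted(self.unresolved.items())}
        return out


def decision_profile(kb: KnowledgeBase, options: RankingOptions = RankingOptions()) -> DecisionProfile:
    """Simulate a noiseless identification of every taxon under one policy.

    For each taxon, the top suggested character is answered with the taxon's
    true value (its full state set, or the interval midpoint); characters the
    taxon is unknown for are skipped to the next suggestion — a user cannot
    answer what the specimen does not show.  The count is the number of
    answers given when the remaining set first equals the taxon alone.
    """
    if len(kb.taxa) < 2:
        raise KBError("decision profile needs at least two taxa")
    profile = DecisionProfile()
    for taxon in kb.taxa:
        truth = noiseless_profile(kb, taxon)
        session = Session(kb, options)
        while True:
            remaining = session.remaining
            if [t.taxon_id for t in remaining] == [taxon.taxon_id]:
                profile.counts[taxon.taxon_id] = DecisionCount(taxon.taxon_id, len(session.answers))
                break
            chosen = None
            for char in session.suggest_next():
                if char.char_id in truth.answers:
                    chosen = char
                    break
            if chosen is None:
                profile.unresolved[taxon.taxon_id] = tuple(t.taxon_id for t in remaining)
                break
            session = session.step(chosen.char_id, truth.answers[chosen.char_id])
    return profile
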