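"""Synthetic knowledge bases and specimens.

Random matrices make every engine property testable without any curated
data: elimination must equal brute force, noiseless specimens must always
contain their true taxon, and identification accuracy must degrade as
observation noise rises.  Generation is driven by a single explicitly seeded
NumPy generator per call — identical seeds give identical output, and no
global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    CharacterDef,
    CharacterKind,
    KBError,
    KnowledgeBase,
    Observation,
    SpecimenProfile,
    TaxonDescription,
)

__all__ = ["SynthConfig", "random_kb", "sample_specimen"]


@dataclass(frozen=True)
class SynthConfig:
    """Shape and noise parameters of a random knowledge base.

    ``states_range`` bounds the number of states per categorical character
    (inclusive); ``n_numerical`` of the characters are numerical instead.
    ``p_polymorphism`` is the chance a scored categorical cell carries two
    states rather than one, ``p_unknown`` the chance a cell is unknown, and
    ``noise_rate`` the default observation-error rate for sampled specimens
    (probability an answered value is replaced by a wrong one).
    """

    n_taxa: int
    n_characters: int
    seed: int
    states_range: tuple[int, int] = (2, 4)
    n_numerical: int = 0
    p_polymorphism: float = 0.15
    p_unknown: float = 0.1
    noise_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_taxa < 2 or self.n_characters < 1:
            raise KBError("need at least 2 taxa and 1 character")
        lo, hi = self.states_range
        if not (2 <= lo <= hi):
            raise KBError(f"degenerate states_range {self.states_range}")
        if not (0 <= self.n_numerical <= self.n_characters):
            raise KBError("n_numerical out of range")
        for name in ("p_polymorphism", "p_unknown", "noise_rate"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise KBError(f"{name}={p} outside [0, 1]")


def random_kb(cfg: SynthConfig) -> KnowledgeBase:
    """A structurally valid random knowledge base; deterministic in the seed."""
    rng = np.random.default_rng(cfg.seed)
    chars: list[CharacterDef] = []
    for i in range(cfg.n_characters):
        cid = f"char_{i:02d}"
        if i < cfg.n_numerical:
            chars.append(CharacterDef(cid, cid, CharacterKind.numerical, units="u"))
        else:
            k = int(rng.integers(cfg.states_range[0], cfg.states_range[1] + 1))
            states = tuple((f"s{j}", f"state {j}") for j in range(k))
            chars.append(CharacterDef(cid, cid, CharacterKind.categorical, states))

    taxa: list[TaxonDescription] = []
    for j in range(cfg.n_taxa):
        obs: dict[str, Observation] = {}
        for char in chars:
            if rng.random() < cfg.p_unknown:
                obs[char.char_id] = Observation.unknown()
            elif char.kind is CharacterKind.numerical:
                lo = float(np.round(rng.uniform(0.0, 10.0), 2))
                hi = float(np.round(lo + rng.uniform(0.0, 3.0), 2))
                obs[char.char_id] = Observation.scored_interval(lo, hi)
            else:
                ids = list(char.state_ids)
                picked = {ids[int(rng.integers(len(ids)))]}
                if len(ids) > 1 and rng.random() < cfg.p_polymorphism:
                    rest = [s for s in ids if s not in picked]
                    picked.add(rest[int(rng.integers(len(rest)))])
                obs[char.char_id] = Observation.scored_states(picked)
        taxa.append(TaxonDescription(f"taxon_{j:02d}", f"Taxon {j:02d}", True, obs))
    return KnowledgeBase(f"synthetic (seed={cfg.seed})", tuple(chars), tuple(taxa))


def sample_specimen(
    kb: KnowledgeBase,
    taxon_id: str,
    noise_rate: float = 0.0,
    unknown_rate: float = 0.0,
    seed: int = 0,
) -> SpecimenProfile:
    """Draw one specimen observation vector from a taxon's description.

    Each scored character is answered (with probability ``1 - unknown_rate``)
    by one of the taxon's states, or a uniform point inside its interval; with
    probability ``noise_rate`` the answer is replaced by a wrong one (a state
    the taxon does not exhibit, or a point outside its interval).
    """
    rng = np.random.default_rng(seed)
    taxon = kb.taxon(taxon_id)
    answers: dict[str, frozenset[str] | float] = {}
    for char in kb.characters:
        obs = taxon.observations.get(char.char_id)
        if obs is None or not obs.is_scored:
            continue
        if rng.random() < unknown_rate:
            continue
        if char.kind is CharacterKind.categorical:
            own = [s for s in char.state_ids if s in obs.states]
            wrong = [s for s in char.state_ids if s not in obs.states]
            if rng.random() < noise_rate and wrong:
                answers[char.char_id] = frozenset({wrong[int(rng.integers(len(wrong)))]})
            else:
                answers[char.char_id] = frozenset({own[int(rng.integers(len(own)))]})
        else:
            lo, hi = obs.interval  # type: ignore[misc]
            if rng.random() < noise_rate:
                span = max(hi - lo, 1.0)
                offset = float(rng.uniform(0.5, 1.5)) * span
                answers[char.char_id] = hi + offset if rng.random() < 0.5 else lo - offset
            else:
                answers[char.char_id] = float(rng.uniform(lo, hi))
    return SpecimenProfile(answers)
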