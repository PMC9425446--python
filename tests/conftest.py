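import pytest
from hypothesis import HealthCheck, settings

from platykey import platynini_kb, platynini_key
from platykey.core import (
    CharacterDef,
    CharacterKind,
    KnowledgeBase,
    Observation,
    TaxonDescription,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    database=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def kb() -> KnowledgeBase:
    return platynini_kb()


@pytest.fixture(scope="session")
def key():
    return platynini_key()


def make_kb(cells: dict[str, dict[str, object]], characters: dict[str, list[str] | None],
            title: str = "toy") -> KnowledgeBase:
    """Compact builder for hand-written toy bases.

    ``characters`` maps char_id -> state id list (None = numerical);
    ``cells`` maps taxon_id -> {char_id: states-iterable | (lo, hi) | None=unknown}.
    """
    chars = tuple(
        CharacterDef(cid, cid, CharacterKind.numerical, units="u")
        if states is None
        else CharacterDef(cid, cid, CharacterKind.categorical,
                          tuple((s, s) for s in states))
        for cid, states in characters.items()
    )
    taxa = []
    for tid, row in cells.items():
        obs = {}
        for cid in characters:
            v = row.get(cid)
            if v is None:
                obs[cid] = Observation.unknown()
            elif characters[cid] is None:
                lo, hi = v  # type: ignore[misc]
                obs[cid] = Observation.scored_interval(lo, hi)
            else:
                obs[cid] = Observation.scored_states(v)  # type: ignore[arg-type]
        taxa.append(TaxonDescription(tid, tid, True, obs))
    return KnowledgeBase(title, chars, tuple(taxa))
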