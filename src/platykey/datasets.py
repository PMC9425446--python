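"""Packaged knowledge bases and keys.

The "Platynini, southern Levant" base covers the 14 ground-beetle species
(tribe Platynini, Carabidae) recorded from or expected near the southern
Levant, scored for 16 morphological characters; the companion dichotomous key
is its 13-couplet printed counterpart.  Both were transcribed from the
published key couplets and character overview table — every scored cell of
the matrix carries a provenance note naming its source.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .core import KnowledgeBase
from .io import load_kb
from .keygen import DichotomousKey, load_dichotomous_key

__all__ = ["platynini_kb", "platynini_key", "platynini_kb_path", "platynini_key_path"]


def _data_path(name: str) -> Path:
    return Path(str(resources.files("platykey").joinpath("data", name)))


def platynini_kb_path() -> Path:
    return _data_path("platynini_kb.json")


def platynini_key_path() -> Path:
    return _data_path("platynini_key.json")


def platynini_kb() -> KnowledgeBase:
    """The packaged Platynini (southern Levant) matrix: 14 taxa × 16 characters."""
    return load_kb(platynini_kb_path())


def platynini_key() -> DichotomousKey:
    """The packaged 13-couplet dichotomous key to the same 14 taxa."""
    return load_dichotomous_key(platynini_key_path())
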