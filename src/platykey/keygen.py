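"""Single-access keys: generation, interpretation and metrics.

Two key structures live here:

* :class:`DichotomousKey` — a hand-written, couplet-numbered key (ordered
  couplets of two or more contrasting leads, each lead carrying diagnostic
  text, machine predicates on matrix characters, and a target: another couplet
  or a terminal taxon).  The packaged Platynini key is one of these.
* :class:`SingleAccessKey` — a decision tree generated from a knowledge base
  by repeatedly asking the top-ranked character and branching on its observed
  states (or on numerical interval clusters).  Taxa unknown for the branching
  character are copied into every branch, and polymorphic taxa are copied
  into every branch whose state they exhibit — which is why generated keys
  can list the same species at two or three leaves.

The shared efficiency metric is the *alternative*: one numbered couplet/node.
A taxon's decision count is the number of numbered steps traversed from the
entry to the lead naming it, inclusive.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .core import (
    CharacterKind,
    KBError,
    KnowledgeBase,
    Observation,
    RankingOptions,
    SpecimenProfile,
    TaxonDescription,
    rank_characters,
)

__all__ = [
    "Predicate",
    "LeadTarget",
    "Lead",
    "Couplet",
    "DichotomousKey",
    "KeyNode",
    "SingleAccessKey",
    "KeyMetrics",
    "KeyError_",
    "InconsistentSpecimenError",
    "AmbiguousLeadError",
    "ConsistencyReport",
    "noiseless_profile",
    "load_dichotomous_key",
    "save_dichotomous_key",
    "traverse_dichotomous",
    "check_consistency",
    "build_single_access_key",
    "key_metrics",
    "render_key_text",
    "parse_key_text",
]


class KeyError_(ValueError):
    """A structural problem in a key, or a traversal failure."""


class InconsistentSpecimenError(KeyError_):
    """No lead of a couplet is satisfied by the specimen."""


class AmbiguousLeadError(KeyError_):
    """More than one lead of a couplet is satisfied by the specimen."""


# ---------------------------------------------------------------------------
# Predicates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Predicate:
    """An assertion about one character: a state subset or a closed interval."""

    char_id: str
    states: frozenset[str] | None = None
    interval: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if (self.states is None) == (self.interval is None):
            raise KeyError_("predicate needs exactly one of states / interval")
        if self.states is not None:
            object.__setattr__(self, "states", frozenset(self.states))

    def satisfied_by(self, answer: frozenset[str] | float) -> bool:
        if self.states is not None:
            if not isinstance(answer, frozenset):
                raise KeyError_(f"state predicate on {self.char_id!r} needs a state answer")
            return bool(answer & self.states)
        if not isinstance(answer, float):
            raise KeyError_(f"interval predicate on {self.char_id!r} needs a numerical answer")
        lo, hi = self.interval  # type: ignore[misc]
        return lo <= answer <= hi

    def admits(self, obs: Observation) -> bool:
        """Would a taxon with this (scored) observation pass this predicate?"""
        if not obs.is_scored:
            return True
        if self.states is not None:
            return bool(obs.states & self.states)
        lo, hi = self.interval  # type: ignore[misc]
        olo, ohi = obs.interval  # type: ignore[misc]
        return not (ohi < lo or hi < olo)


@dataclass(frozen=True)
class LeadTarget:
    """Where a lead points: a couplet/node number, or a list of taxa."""

    couplet: int | None = None
    taxa: tuple[str, ...] = ()
    parenthesized: bool = False

    def __post_init__(self) -> None:
        if (self.couplet is None) == (not self.taxa):
            raise KeyError_("lead target needs exactly one of couplet / taxa")
        object.__setattr__(self, "taxa", tuple(self.taxa))

    @property
    def is_terminal(self) -> bool:
        return self.couplet is None


@dataclass(frozen=True)
class Lead:
    text: str
    predicates: tuple[Predicate, ...]
    target: LeadTarget

    def satisfied_by(self, profile: SpecimenProfile) -> bool:
        for p in self.predicates:
            if p.char_id not in profile.answers:
                raise KeyError_(f"character {p.char_id!r} not answered")
            if not p.satisfied_by(profile.answers[p.char_id]):
                return False
        return True


@dataclass(frozen=True)
class Couplet:
    number: int
    leads: tuple[Lead, ...]

    def __post_init__(self) -> None:
        if len(self.leads) < 2:
            raise KeyError_(f"couplet {self.number} has fewer than two leads")


@dataclass(frozen=True)
class DichotomousKey:
    """An ordered, couplet-numbered identification key."""

    title: str
    couplets: tuple[Couplet, ...]
    notes: str = ""

    def __post_init__(self) -> None:
        numbers = [c.number for c in self.couplets]
        if len(set(numbers)) != len(numbers):
            raise KeyError_("duplicate couplet numbers")
        by_num = {c.number: c for c in self.couplets}
        if self.couplets and self.entry not in by_num:
            raise KeyError_("entry couplet missing")
        for c in self.couplets:
            for lead in c.leads:
                t = lead.target
                if not t.is_terminal and t.couplet not in by_num:
                    raise KeyError_(f"couplet {c.number}: target {t.couplet} does not resolve")

    @property
    def entry(self) -> int:
        return min(c.number for c in self.couplets) if self.couplets else 1

    def couplet(self, number: int) -> Couplet:
        for c in self.couplets:
            if c.number == number:
                return c
        raise KeyError_(f"no couplet {number}")

    @property
    def taxon_leads(self) -> dict[str, int]:
        """taxon_id -> number of the couplet whose lead names it (first occurrence)."""
        out: dict[str, int] = {}
        for c in self.couplets:
            for lead in c.leads:
                for tid in lead.target.taxa:
                    out.setdefault(tid, c.number)
        return out


# ---------------------------------------------------------------------------
# Key JSON I/O
# ---------------------------------------------------------------------------

def _pred_from_dict(d: dict) -> Predicate:
    if "states" in d:
        return Predicate(d["char"], states=frozenset(d["states"]))
    lo, hi = d["interval"]
    return Predicate(d["char"], interval=(float(lo), float(hi)))


def _pred_to_dict(p: Predicate) -> dict:
    if p.states is not None:
        return {"char": p.char_id, "states": sorted(p.states)}
    return {"char": p.char_id, "interval": list(p.interval)}  # type: ignore[arg-type]


def load_dichotomous_key(path: str | Path) -> DichotomousKey:
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    couplets = []
    for c in data["couplets"]:
        leads = []
        for l in c["leads"]:
            t = l["target"]
            if "couplet" in t:
                target = LeadTarget(couplet=int(t["couplet"]))
            else:
                taxa = t.get("taxa") or [t["taxon"]]
                target = LeadTarget(taxa=tuple(taxa),
                                    parenthesized=bool(t.get("parenthesized", False)))
            leads.append(Lead(l.get("text", ""),
                              tuple(_pred_from_dict(p) for p in l.get("predicates", [])),
                              target))
        couplets.append(Couplet(int(c["number"]), tuple(leads)))
    return DichotomousKey(data.get("title", ""), tuple(couplets), data.get("notes", ""))


def save_dichotomous_key(key: DichotomousKey, path: str | Path) -> Path:
    data = {
        "title": key.title,
        "notes": key.notes,
        "couplets": [
            {
                "number": c.number,
                "leads": [
                    {
                        "text": l.text,
                        "predicates": [_pred_to_dict(p) for p in l.predicates],
                        "target": (
                            {"couplet": l.target.couplet}
                            if not l.target.is_terminal
                            else {"taxa": list(l.target.taxa),
                                  **({"parenthesized": True} if l.target.parenthesized else {})}
                        ),
                    }
                    for l in c.leads
                ],
            }
            for c in key.couplets
        ],
    }
    path = Path(path)
    path.write_text(json.dumps(data, indent=2, ensure_ascii=False) + "\n", encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# Traversal and consistency
# ---------------------------------------------------------------------------

def noiseless_profile(kb: KnowledgeBase, taxon: TaxonDescription | str) -> SpecimenProfile:
    """The full, faithful answer set for a taxon: every scored character is
    answered with the taxon's complete state set (numerical: interval midpoint)."""
    if isinstance(taxon, str):
        taxon = kb.taxon(taxon)
    answers: dict[str, frozenset[str] | float] = {}
    for c in kb.characters:
        obs = taxon.observations.get(c.char_id)
        if obs is None or not obs.is_scored:
            continue
        if c.kind is CharacterKind.categorical:
            answers[c.char_id] = obs.states
        else:
            lo, hi = obs.interval  # type: ignore[misc]
            answers[c.char_id] = (lo + hi) / 2.0
    return SpecimenProfile(answers)


def traverse_dichotomous(
    key: DichotomousKey, profile: SpecimenProfile
) -> tuple[tuple[str, ...], list[int]]:
    """Follow the key from its entry couplet; return (terminal taxa, path).

    Raises :class:`InconsistentSpecimenError` when no lead of a couplet is
    satisfied, :class:`AmbiguousLeadError` when several are (an internally
    contradictory answer set), and :class:`KeyError_` when a needed character
    is unanswered.
    """
    if not key.couplets:
        raise KeyError_("empty key")
    path: list[int] = []
    number = key.entry
    seen: set[int] = set()
    while True:
        if number in seen:
            raise KeyError_(f"cycle through couplet {number}")
        seen.add(number)
        path.append(number)
        couplet = key.couplet(number)
        hits = []
        for lead in couplet.leads:
            try:
                ok = lead.satisfied_by(profile)
            except KeyError_ as exc:
                raise KeyError_(f"couplet {number}: {exc}") from exc
            if ok:
                hits.append(lead)
        if not hits:
            raise InconsistentSpecimenError(
                f"couplet {number}: no lead matches the specimen")
        if len(hits) > 1:
            raise AmbiguousLeadError(
                f"couplet {number}: {len(hits)} leads match the specimen")
        target = hits[0].target
        if target.is_terminal:
            return target.taxa, path
        number = target.couplet  # type: ignore[assignment]


@dataclass
class ConsistencyReport:
    """Per-taxon outcome of running each noiseless profile through a key."""

    results: dict[str, str] = field(default_factory=dict)  # taxon -> reached/error text
    mismatches: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.mismatches


def check_consistency(key: DichotomousKey, kb: KnowledgeBase) -> ConsistencyReport:
    """Every taxon's noiseless profile must traverse the key to that taxon."""
    if not kb.taxa:
        raise KBError("empty knowledge base")
    report = ConsistencyReport()
    for t in kb.taxa:
        try:
            taxa, _ = traverse_dichotomous(key, noiseless_profile(kb, t))
            report.results[t.taxon_id] = ",".join(taxa)
            if t.taxon_id not in taxa:
                report.mismatches.append(
                    f"{t.taxon_id}: reached {taxa}")
        except KeyError_ as exc:
            report.results[t.taxon_id] = f"error: {exc}"
            report.mismatches.append(f"{t.taxon_id}: {exc}")
    return report


# ---------------------------------------------------------------------------
# Single-access key generation
# ---------------------------------------------------------------------------

@dataclass
class KeyNode:
    """One numbered step of a generated key: a character and its branches."""

    node_id: int
    char_id: str
    branches: list[tuple[Predicate, "KeyNode | tuple[str, ...]"]]


@dataclass
class SingleAccessKey:
    title: str
    root: KeyNode
    nodes: list[KeyNode]

    def leaves(self) -> list[tuple[tuple[str, ...], int]]:
        """All (taxa, depth) leaves, depth = numbered nodes traversed inclusive."""
        out: list[tuple[tuple[str, ...], int]] = []

        def walk(node: KeyNode, depth: int) -> None:
            for _, tgt in node.branches:
                if isinstance(tgt, KeyNode):
                    walk(tgt, depth + 1)
                else:
                    out.append((tgt, depth))

        walk(self.root, 1)
        return out


def _categorical_branches(
    char_states: Sequence[str], remaining: Sequence[TaxonDescription], char_id: str
) -> list[tuple[Predicate, list[TaxonDescription]]]:
    observed = [
        s for s in char_states
        if any(t.observations[char_id].is_scored and s in t.observations[char_id].states
               for t in remaining)
    ]
    branches = []
    for s in observed:
        members = [
            t for t in remaining
            if not t.observations[char_id].is_scored or s in t.observations[char_id].states
        ]
        branches.append((Predicate(char_id, states=frozenset({s})), members))
    return branches


def _numerical_branches(
    remaining: Sequence[TaxonDescription], char_id: str
) -> list[tuple[Predicate, list[TaxonDescription]]]:
    # cluster scored intervals at gaps; each maximal gap separates two branches
    scored = [t for t in remaining if t.observations[char_id].is_scored]
    intervals = sorted((t.observations[char_id].interval, t.taxon_id) for t in scored)
    clusters: list[tuple[float, float]] = []
    for (lo, hi), _ in intervals:
        if clusters and lo <= clusters[-1][1]:
            clusters[-1] = (clusters[-1][0], max(clusters[-1][1], hi))
        else:
            clusters.append((lo, hi))
    unknown = [t for t in remaining if not t.observations[char_id].is_scored]
    branches = []
    for lo, hi in clusters:
        pred = Predicate(char_id, interval=(lo, hi))
        members = [t for t in scored if pred.admits(t.observations[char_id])] + unknown
        members.sort(key=lambda t: [x.taxon_id for x in remaining].index(t.taxon_id))
        branches.append((pred, members))
    return branches


def build_single_access_key(
    kb: KnowledgeBase, options: RankingOptions = RankingOptions()
) -> SingleAccessKey:
    """Generate a single-access key by recursive character ranking.

    At each node the top-ranked character (under ``options``) is asked and the
    remaining taxa are partitioned over its observed states / interval
    clusters; taxa unknown for the character go into every branch and
    polymorphic taxa into every branch they exhibit.  Recursion stops at
    singletons, or at groups no remaining character discriminates (rendered as
    an unresolved multi-taxon leaf).  Deterministic for a given base+options.
    """
    if len(kb.taxa) < 2:
        raise KBError("key generation needs at least two taxa")
    nodes: list[KeyNode] = []
    counter = [0]

    def build(remaining: list[TaxonDescription], used: frozenset[str]) -> KeyNode | tuple[str, ...]:
        if len(remaining) == 1:
            return (remaining[0].taxon_id,)
        ranked = rank_characters(kb, remaining, answered=used, options=options)
        if not ranked:
            return tuple(t.taxon_id for t in remaining)  # unresolved group
        char = ranked[0]
        if char.kind is CharacterKind.categorical:
            raw = _categorical_branches(char.state_ids, remaining, char.char_id)
        else:
            raw = _numerical_branches(remaining, char.char_id)
        counter[0] += 1
        node = KeyNode(counter[0], char.char_id, [])
        nodes.append(node)
        for pred, members in raw:
            node.branches.append((pred, build(members, used | {char.char_id})))
        return node

    root = build(list(kb.taxa), frozenset())
    if not isinstance(root, KeyNode):
        raise KBError("no character discriminates any pair of taxa")
    return SingleAccessKey(kb.title, root, nodes)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class KeyMetrics:
    """Structural efficiency metrics shared by both key flavours.

    ``alternatives`` counts numbered couplets/nodes; ``decisions`` maps each
    taxon to the number of numbered steps from the entry to (the nearest) lead
    naming it, inclusive; ``leaf_counts`` maps each taxon to the number of
    leads naming it (> 1 = the taxon is duplicated across the key).
    """

    alternatives: int
    decisions: dict[str, int]
    leaf_counts: dict[str, int]

    @property
    def min_decisions(self) -> int:
        return min(self.decisions.values())

    @property
    def max_decisions(self) -> int:
        return max(self.decisions.values())

    @property
    def duplicated_taxa(self) -> list[str]:
        return sorted(t for t, n in self.leaf_counts.items() if n > 1)

    def to_dict(self) -> dict:
        return {
            "alternatives": self.alternatives,
            "decisions": dict(sorted(self.decisions.items())),
            "min_decisions": self.min_decisions,
            "max_decisions": self.max_decisions,
            "duplicated_taxa": self.duplicated_taxa,
            "leaf_counts": dict(sorted(self.leaf_counts.items())),
        }


def key_metrics(key: DichotomousKey | SingleAccessKey) -> KeyMetrics:
    if isinstance(key, SingleAccessKey):
        decisions: dict[str, int] = {}
        leaf_counts: dict[str, int] = {}
        for taxa, depth in key.leaves():
            for tid in taxa:
                decisions[tid] = min(decisions.get(tid, math.inf), depth)  # type: ignore[arg-type]
                leaf_counts[tid] = leaf_counts.get(tid, 0) + 1
        return KeyMetrics(len(key.nodes), {t: int(d) for t, d in decisions.items()},
                          leaf_counts)

    # dichotomous: depth of a couplet = couplets on the path from the entry
    depth: dict[int, int] = {key.entry: 1}
    pending = [key.entry]
    while pending:
        num = pending.pop()
        for lead in key.couplet(num).leads:
            t = lead.target
            if not t.is_terminal and t.couplet not in depth:
                depth[t.couplet] = depth[num] + 1  # type: ignore[index]
                pending.append(t.couplet)  # type: ignore[arg-type]
    decisions = {}
    leaf_counts = {}
    for c in key.couplets:
        for lead in c.leads:
            for tid in lead.target.taxa:
                d = depth.get(c.number)
                if d is not None:
                    decisions[tid] = min(decisions.get(tid, math.inf), d)  # type: ignore[arg-type]
                leaf_counts[tid] = leaf_counts.get(tid, 0) + 1
    return KeyMetrics(len(key.couplets), {t: int(d) for t, d in decisions.items()},
                      leaf_counts)


# ---------------------------------------------------------------------------
# Text rendering and parsing
# ---------------------------------------------------------------------------

def _fmt_num(x: float) -> str:
    return f"{int(x)}" if float(x).is_integer() else repr(float(x))


def _render_pred(p: Predicate) -> str:
    if p.states is not None:
        return f"{p.char_id}={'|'.join(sorted(p.states))}"
    lo, hi = p.interval  # type: ignore[misc]
    return f"{p.char_id}={_fmt_num(lo)}..{_fmt_num(hi)}"


def _render_target(t: LeadTarget) -> str:
    if not t.is_terminal:
        return str(t.couplet)
    names = ", ".join(f"**{tid}**" for tid in t.taxa)
    if len(t.taxa) > 1:
        return f"[{names}] (unresolved)"
    return f"({names})" if t.parenthesized else names


def render_key_text(key: DichotomousKey | SingleAccessKey) -> str:
    """Numbered couplet layout: lead, counter-lead(s) marked with an en dash,
    bracketed machine predicates, and bold-marked taxon targets."""
    lines = []
    if isinstance(key, SingleAccessKey):
        for node in key.nodes:
            for i, (pred, tgt) in enumerate(node.branches):
                marker = str(node.node_id) if i == 0 else "–"
                target = (str(tgt.node_id) if isinstance(tgt, KeyNode)
                          else _render_target(LeadTarget(taxa=tgt)))
                lines.append(f"{marker}\t[{_render_pred(pred)}]\t{target}")
        return "\n".join(lines) + "\n"
    for c in key.couplets:
        for i, lead in enumerate(c.leads):
            marker = str(c.number) if i == 0 else "–"
            preds = "; ".join(_render_pred(p) for p in lead.predicates)
            lines.append(f"{marker}\t{lead.text} [{preds}]\t{_render_target(lead.target)}")
    return "\n".join(lines) + "\n"


_LINE_RE = re.compile(r"^(\d+|–)\t(.*?)\s*\[(.*)\]\t(.+)$")


def _parse_pred(text: str) -> Predicate:
    char_id, _, rhs = text.partition("=")
    m = re.match(r"^(-?\d+(?:\.\d+)?)\.\.(-?\d+(?:\.\d+)?)$", rhs)
    if m:
        return Predicate(char_id, interval=(float(m.group(1)), float(m.group(2))))
    return Predicate(char_id, states=frozenset(rhs.split("|")))


def _parse_target(text: str) -> LeadTarget:
    text = text.strip()
    if text.isdigit():
        return LeadTarget(couplet=int(text))
    if text.startswith("[") and "(unresolved)" in text:
        inner = text[1:text.index("]")]
        taxa = [m.group(1) for m in re.finditer(r"\*\*(.+?)\*\*", inner)]
        return LeadTarget(taxa=tuple(taxa))
    paren = text.startswith("(")
    m = re.search(r"\*\*(.+?)\*\*", text)
    if not m:
        raise KeyError_(f"unparseable lead target {text!r}")
    return LeadTarget(taxa=(m.group(1),), parenthesized=paren)


def parse_key_text(text: str, title: str = "") -> DichotomousKey:
    """Inverse of :func:`render_key_text` for couplet-structured keys."""
    couplets: list[Couplet] = []
    current_num: int | None = None
    current_leads: list[Lead] = []
    for raw in text.splitlines():
        if not raw.strip():
            continue
        m = _LINE_RE.match(raw)
        if not m:
            raise KeyError_(f"unparseable key line {raw!r}")
        marker, lead_text, preds_text, target_text = m.groups()
        preds = tuple(_parse_pred(p.strip()) for p in preds_text.split(";") if p.strip())
        lead = Lead(lead_text, preds, _parse_target(target_text))
        if marker == "–":
            if current_num is None:
                raise KeyError_("counter-lead before any couplet number")
            current_leads.append(lead)
        else:
            if current_num is not None:
                couplets.append(Couplet(current_num, tuple(current_leads)))
            current_num, current_leads = int(marker), [lead]
    if current_num is not None:
        couplets.append(Couplet(current_num, tuple(current_leads)))
    return DichotomousKey(title, tuple(couplets))
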