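"""Reading and writing knowledge bases.

Three formats are supported:

* **JSON** — the native, lossless format (characters with state lists, cells
  with status/value/provenance note).  The schema is documented in
  ``docs/formats.md`` and mirrored by the packaged Platynini base.
* **CSV** — a flat taxa × characters matrix using a compact cell grammar:
  states separated by ``|``, ``?`` = unknown, ``NA`` = inapplicable,
  numerical cells ``lo..hi`` or a single value.  Character kinds and state
  lists are inferred from the cells, so a CSV round trip preserves the matrix
  cell-for-cell but not unused declared states or provenance notes.
* **SDD-flavoured XML** — an export modelled on the Structured Descriptive
  Data interchange standard (one element per character, state and taxon, with
  unknown cells marked); a subset sufficient to round-trip our own exports,
  not a full SDD 1.1 implementation.
"""

from __future__ import annotations

import csv
import json
import re
from pathlib import Path
from typing import Iterable

from lxml import etree

from .core import (
    CharacterDef,
    CharacterKind,
    KBError,
    KnowledgeBase,
    Observation,
    ObservationStatus,
    TaxonDescription,
    validate_kb,
)

__all__ = [
    "load_kb",
    "save_kb",
    "kb_to_dict",
    "kb_from_dict",
    "parse_cell",
    "format_cell",
    "export_sdd_xml",
    "import_sdd_xml",
]

SDD_NS = "http://rs.tdwg.org/UBIF/2006"


def _structural_check(kb: KnowledgeBase, source: str) -> KnowledgeBase:
    report = validate_kb(kb)
    if report.errors:
        raise KBError(f"{source}: " + "; ".join(report.errors))
    return kb


# ---------------------------------------------------------------------------
# Cell grammar (CSV dialect)
# ---------------------------------------------------------------------------

_NUM_RE = re.compile(r"^\s*(-?\d+(?:\.\d+)?)\s*(?:\.\.\s*(-?\d+(?:\.\d+)?))?\s*$")


def parse_cell(text: str, char: CharacterDef) -> Observation:
    """Parse one matrix cell: ``a|b``, ``?``, ``NA``, ``3`` or ``2..4``."""
    text = text.strip()
    if text == "?" or text == "":
        return Observation.unknown()
    if text == "NA":
        return Observation.inapplicable()
    if char.kind is CharacterKind.numerical:
        m = _NUM_RE.match(text)
        if not m:
            raise KBError(f"malformed numerical cell {text!r} for character {char.char_id!r}")
        lo = float(m.group(1))
        hi = float(m.group(2)) if m.group(2) is not None else lo
        return Observation.scored_interval(lo, hi)
    states = [s.strip() for s in text.split("|")]
    if any(not s for s in states):
        raise KBError(f"malformed categorical cell {text!r} for character {char.char_id!r}")
    return Observation.scored_states(states)


def _fmt_num(x: float) -> str:
    return f"{int(x)}" if float(x).is_integer() else repr(float(x))


def format_cell(obs: Observation, char: CharacterDef) -> str:
    if obs.status is ObservationStatus.unknown:
        return "?"
    if obs.status is ObservationStatus.inapplicable:
        return "NA"
    if char.kind is CharacterKind.numerical:
        lo, hi = obs.interval  # type: ignore[misc]
        return _fmt_num(lo) if lo == hi else f"{_fmt_num(lo)}..{_fmt_num(hi)}"
    # keep declaration order for determinism
    return "|".join(s for s in char.state_ids if s in obs.states)


# ---------------------------------------------------------------------------
# JSON
# ---------------------------------------------------------------------------

def _obs_to_dict(obs: Observation, char: CharacterDef) -> dict:
    d: dict = {"status": obs.status.value}
    if obs.is_scored:
        if char.kind is CharacterKind.categorical:
            d["states"] = [s for s in char.state_ids if s in obs.states]
        else:
            d["interval"] = list(obs.interval)  # type: ignore[arg-type]
    if obs.note:
        d["note"] = obs.note
    return d


def _obs_from_dict(d: dict, char: CharacterDef, where: str) -> Observation:
    try:
        status = ObservationStatus(d.get("status", "unknown"))
        if status is not ObservationStatus.scored:
            return Observation(status, note=d.get("note", ""))
        if "states" in d:
            return Observation.scored_states(d["states"], d.get("note", ""))
        lo, hi = d["interval"]
        return Observation.scored_interval(lo, hi, d.get("note", ""))
    except (KeyError, ValueError, TypeError) as exc:
        raise KBError(f"malformed cell at {where}: {exc}") from exc


def kb_to_dict(kb: KnowledgeBase) -> dict:
    chars = []
    for c in kb.characters:
        d: dict = {"id": c.char_id, "name": c.name, "kind": c.kind.value,
                   "weight": c.weight.name}
        if c.group:
            d["group"] = c.group
        if c.kind is CharacterKind.categorical:
            d["states"] = [{"id": s, "label": l} for s, l in c.states]
        else:
            d["units"] = c.units
        chars.append(d)
    taxa = []
    for t in kb.taxa:
        taxa.append({
            "id": t.taxon_id,
            "name": t.name,
            "in_region": t.in_region,
            "notes": t.notes,
            "observations": {
                c.char_id: _obs_to_dict(t.observations[c.char_id], c) for c in kb.characters
            },
        })
    return {"title": kb.title, "notes": kb.notes, "characters": chars, "taxa": taxa}


def kb_from_dict(data: dict, source: str = "<dict>") -> KnowledgeBase:
    try:
        chars = tuple(
            CharacterDef(
                char_id=str(c["id"]),
                name=str(c.get("name", c["id"])),
                kind=CharacterKind(c["kind"]),
                states=tuple((s["id"], s.get("label", s["id"])) for s in c.get("states", [])),
                units=str(c.get("units", "")),
                weight=c.get("weight", "medium"),
                group=str(c.get("group", "")),
            )
            for c in data["characters"]
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise KBError(f"{source}: malformed character definition: {exc}") from exc
    char_map = {c.char_id: c for c in chars}
    taxa = []
    for t in data.get("taxa", []):
        tid = str(t["id"])
        obs = {}
        for cid, cell in t.get("observations", {}).items():
            char = char_map.get(cid)
            if char is None:
                raise KBError(f"{source}: taxon {tid!r} scores undeclared character {cid!r}")
            obs[cid] = _obs_from_dict(cell, char, f"({tid}, {cid})")
        taxa.append(TaxonDescription(tid, str(t.get("name", tid)),
                                     bool(t.get("in_region", True)), obs,
                                     str(t.get("notes", ""))))
    kb = KnowledgeBase(str(data.get("title", "")), chars, tuple(taxa),
                       str(data.get("notes", "")))
    return _structural_check(kb, source)


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

_CSV_META = ("taxon_id", "name", "in_region")


def _kb_to_csv_rows(kb: KnowledgeBase) -> list[list[str]]:
    header = list(_CSV_META) + [
        f"{c.char_id}:{'num' if c.kind is CharacterKind.numerical else 'cat'}"
        for c in kb.characters
    ]
    rows = [header]
    for t in kb.taxa:
        row = [t.taxon_id, t.name, "1" if t.in_region else "0"]
        row += [format_cell(t.observations[c.char_id], c) for c in kb.characters]
        rows.append(row)
    return rows


def _kb_from_csv_rows(rows: list[list[str]], source: str) -> KnowledgeBase:
    if not rows:
        raise KBError(f"{source}: empty CSV")
    header = rows[0]
    if [h.strip() for h in header[:3]] != list(_CSV_META):
        raise KBError(f"{source}: CSV header must start with {', '.join(_CSV_META)}")
    specs = []
    for col in header[3:]:
        cid, _, kind = col.partition(":")
        cid = cid.strip()
        if not cid:
            raise KBError(f"{source}: empty character column name")
        specs.append((cid, CharacterKind.numerical if kind.strip() == "num" else CharacterKind.categorical))

    # first pass: collect observed states per categorical character, in first-appearance order
    observed: dict[str, list[str]] = {cid: [] for cid, k in specs if k is CharacterKind.categorical}
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise KBError(f"{source}: row {r} has {len(row)} cells, expected {len(header)}")
        for (cid, kind), cell in zip(specs, row[3:]):
            if kind is CharacterKind.categorical and cell.strip() not in ("?", "NA", ""):
                for s in cell.split("|"):
                    s = s.strip()
                    if s and s not in observed[cid]:
                        observed[cid].append(s)

    chars = tuple(
        CharacterDef(cid, cid, kind,
                     states=tuple((s, s) for s in observed[cid]) if kind is CharacterKind.categorical else ())
        for cid, kind in specs
    )
    char_map = {c.char_id: c for c in chars}

    taxa = []
    for r, row in enumerate(rows[1:], start=2):
        tid, name, flag = (row[0].strip(), row[1].strip(), row[2].strip())
        obs = {}
        for (cid, _), cell in zip(specs, row[3:]):
            try:
                obs[cid] = parse_cell(cell, char_map[cid])
            except KBError as exc:
                raise KBError(f"{source}: row {r}, column {cid!r}: {exc}") from exc
        taxa.append(TaxonDescription(tid, name or tid, flag not in ("0", "false", "False"), obs))
    kb = KnowledgeBase(Path(source).stem if source != "<csv>" else "", chars, tuple(taxa))
    return _structural_check(kb, source)


# ---------------------------------------------------------------------------
# Entry points
# ---------------------------------------------------------------------------

def load_kb(path: str | Path, format: str | None = None) -> KnowledgeBase:
    """Load a knowledge base from JSON or CSV (format inferred from suffix)."""
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "json")
    if fmt == "json":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        return kb_from_dict(data, str(path))
    if fmt == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            return _kb_from_csv_rows(list(csv.reader(fh)), str(path))
    raise KBError(f"unknown format {fmt!r}")


def save_kb(kb: KnowledgeBase, path: str | Path, format: str | None = None) -> Path:
    """Write a knowledge base; ``load_kb(save_kb(kb))`` is structurally equal."""
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "json")
    if fmt == "json":
        path.write_text(json.dumps(kb_to_dict(kb), indent=2, ensure_ascii=False) + "\n",
                        encoding="utf-8")
    elif fmt == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            csv.writer(fh).writerows(_kb_to_csv_rows(kb))
    else:
        raise KBError(f"unknown format {fmt!r}")
    return path


# ---------------------------------------------------------------------------
# SDD-flavoured XML
# ---------------------------------------------------------------------------

def _E(tag: str, **attrib: str) -> etree._Element:
    return etree.Element(f"{{{SDD_NS}}}{tag}", attrib)


def _sub(parent: etree._Element, tag: str, text: str | None = None, **attrib: str) -> etree._Element:
    el = etree.SubElement(parent, f"{{{SDD_NS}}}{tag}", attrib)
    if text is not None:
        el.text = text
    return el


def export_sdd_xml(kb: KnowledgeBase, path: str | Path) -> Path:
    """Export the knowledge base as SDD-flavoured XML.

    One ``Character`` element per descriptor (with ``StateDefinition`` children
    for categorical ones), one ``CodedDescription`` per taxon; unknown and
    inapplicable cells are marked with an explicit ``Status`` element.
    """
    root = _E("Datasets")
    ds = _sub(root, "Dataset")
    rep = _sub(ds, "Representation")
    _sub(rep, "Label", kb.title)
    if kb.notes:
        _sub(rep, "Detail", kb.notes)

    chars_el = _sub(ds, "Characters")
    for c in kb.characters:
        tag = "CategoricalCharacter" if c.kind is CharacterKind.categorical else "QuantitativeCharacter"
        ch = _sub(chars_el, tag, id=c.char_id, weight=c.weight.name)
        if c.group:
            ch.set("group", c.group)
        crep = _sub(ch, "Representation")
        _sub(crep, "Label", c.name)
        if c.kind is CharacterKind.categorical:
            states = _sub(ch, "States")
            for sid, label in c.states:
                sd = _sub(states, "StateDefinition", id=f"{c.char_id}__{sid}")
                _sub(_sub(sd, "Representation"), "Label", label)
        else:
            _sub(ch, "MeasurementUnit", c.units)

    descs = _sub(ds, "CodedDescriptions")
    for t in kb.taxa:
        cd = _sub(descs, "CodedDescription", id=t.taxon_id,
                  in_region="true" if t.in_region else "false")
        trep = _sub(cd, "Representation")
        _sub(trep, "Label", t.name)
        if t.notes:
            _sub(trep, "Detail", t.notes)
        summary = _sub(cd, "SummaryData")
        for c in kb.characters:
            obs = t.observations[c.char_id]
            if c.kind is CharacterKind.categorical:
                el = _sub(summary, "Categorical", ref=c.char_id)
                if obs.is_scored:
                    for sid in c.state_ids:
                        if sid in obs.states:
                            _sub(el, "State", ref=f"{c.char_id}__{sid}")
                else:
                    _sub(el, "Status", code=obs.status.value)
            else:
                el = _sub(summary, "Quantitative", ref=c.char_id)
                if obs.is_scored:
                    lo, hi = obs.interval  # type: ignore[misc]
                    _sub(el, "Measure", type="Min", value=repr(lo))
                    _sub(el, "Measure", type="Max", value=repr(hi))
                else:
                    _sub(el, "Status", code=obs.status.value)
            if obs.note:
                el.set("note", obs.note)

    path = Path(path)
    etree.ElementTree(root).write(str(path), pretty_print=True,
                                  xml_declaration=True, encoding="UTF-8")
    return path


def _q(tag: str) -> str:
    return f"{{{SDD_NS}}}{tag}"


def _label_of(el: etree._Element) -> str:
    lab = el.find(f"{_q('Representation')}/{_q('Label')}")
    return lab.text or "" if lab is not None else ""


def _detail_of(el: etree._Element) -> str:
    det = el.find(f"{_q('Representation')}/{_q('Detail')}")
    return det.text or "" if det is not None else ""


def import_sdd_xml(path: str | Path) -> KnowledgeBase:
    """Re-import an export produced by :func:`export_sdd_xml` (lossless)."""
    tree = etree.parse(str(path))
    ds = tree.getroot().find(_q("Dataset"))
    if ds is None:
        raise KBError(f"{path}: no Dataset element")

    chars: list[CharacterDef] = []
    chars_el = ds.find(_q("Characters"))
    if chars_el is not None:
        for ch in chars_el:
            cid = ch.get("id", "")
            if ch.tag == _q("CategoricalCharacter"):
                states = []
                for sd in ch.findall(f"{_q('States')}/{_q('StateDefinition')}"):
                    sid = sd.get("id", "")
                    prefix = f"{cid}__"
                    states.append((sid[len(prefix):] if sid.startswith(prefix) else sid,
                                   _label_of(sd)))
                chars.append(CharacterDef(cid, _label_of(ch), CharacterKind.categorical,
                                          tuple(states), "", ch.get("weight", "medium"),
                                          ch.get("group", "")))
            else:
                unit = ch.find(_q("MeasurementUnit"))
                chars.append(CharacterDef(cid, _label_of(ch), CharacterKind.numerical, (),
                                          unit.text or "" if unit is not None else "",
                                          ch.get("weight", "medium"), ch.get("group", "")))

    taxa: list[TaxonDescription] = []
    for cd in ds.findall(f"{_q('CodedDescriptions')}/{_q('CodedDescription')}"):
        obs: dict[str, Observation] = {}
        for el in cd.findall(f"{_q('SummaryData')}/*"):
            cid = el.get("ref", "")
            note = el.get("note", "")
            status_el = el.find(_q("Status"))
            if status_el is not None:
                obs[cid] = Observation(ObservationStatus(status_el.get("code", "unknown")),
                                       note=note)
            elif el.tag == _q("Categorical"):
                prefix = f"{cid}__"
                sids = [s.get("ref", "") for s in el.findall(_q("State"))]
                obs[cid] = Observation.scored_states(
                    [s[len(prefix):] if s.startswith(prefix) else s for s in sids], note)
            else:
                vals = {m.get("type"): float(m.get("value", "nan"))
                        for m in el.findall(_q("Measure"))}
                obs[cid] = Observation.scored_interval(vals["Min"], vals["Max"], note)
        taxa.append(TaxonDescription(cd.get("id", ""), _label_of(cd),
                                     cd.get("in_region", "true") == "true", obs,
                                     _detail_of(cd)))

    kb = KnowledgeBase(_label_of(ds), tuple(chars), tuple(taxa), _detail_of(ds))
    return _structural_check(kb, str(path))
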