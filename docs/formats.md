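# File formats

## JSON knowledge base (native, lossless)

```json
{
  "title": "…",
  "notes": "…",
  "characters": [
    {"id": "c1", "name": "…", "kind": "categorical",
     "weight": "medium", "group": "pronotum",
     "states": [{"id": "s1", "label": "…"}, …]},
    {"id": "c2", "name": "…", "kind": "numerical", "units": "mm"}
  ],
  "taxa": [
    {"id": "t1", "name": "…", "in_region": true, "notes": "…",
     "observations": {
       "c1": {"status": "scored", "states": ["s1", "s2"], "note": "…"},
       "c2": {"status": "scored", "interval": [5.5, 8.0], "note": "…"},
       "c3": {"status": "unknown"},
       "c4": {"status": "inapplicable"}
     }}
  ]
}
```

* `weight` ∈ `weak | medium | strong` (default `medium`).
* A scored cell has exactly one of `states` (non-empty, declared) or
  `interval` (`lo ≤ hi`, closed).
* Every taxon must score every declared character (possibly `unknown`).
* `note` records the cell's provenance (free text, optional).

## CSV matrix

Header: `taxon_id,name,in_region,<char>:cat,<char>:num,…` — one column per
character, suffix `:cat`/`:num` declaring its kind (`:cat` if omitted).
One row per taxon; `in_region` is `1`/`0`.

Cell grammar:

| cell      | meaning                                  |
|-----------|------------------------------------------|
| `s1`      | single state                             |
| `s1\|s3`  | polymorphic (set of states)              |
| `2..4`    | numerical interval                       |
| `3`       | numerical point (`3..3`)                 |
| `?` or `` | unknown                                  |
| `NA`      | inapplicable                             |

State lists are inferred from the cells (first-appearance order), so CSV
round trips preserve the matrix cell-for-cell but drop unused declared
states, labels, weights and notes. `parse ∘ serialize` is the identity on
valid cells.

## Dichotomous key JSON

```json
{
  "title": "…",
  "couplets": [
    {"number": 1,
     "leads": [
       {"text": "…",
        "predicates": [{"char": "c1", "states": ["s1"]}],
        "target": {"couplet": 2}},
       {"text": "…",
        "predicates": [{"char": "c2", "interval": [2, 4]}],
        "target": {"taxon": "t1", "parenthesized": true}}
     ]}
  ]
}
```

A lead matches when **all** its predicates hold (state predicates by
non-empty intersection, interval predicates by closed containment).
Targets are couplet numbers or taxa (`"taxa": [...]` for unresolved
groups; `parenthesized` flags extralimital taxa).

## Rendered key text

One line per lead, tab-separated: marker (couplet number, or `–` for
counter-leads), lead text with bracketed machine predicates, target
(`2`, `**taxon_id**`, `(**taxon_id**)`, or `[**a**, **b**] (unresolved)`).
`parse_key_text` inverts `render_key_text` exactly.

## SDD-flavoured XML

`export_sdd_xml` writes a subset modelled on the TDWG Structured
Descriptive Data vocabulary (namespace `http://rs.tdwg.org/UBIF/2006`):
`Dataset / Characters / {Categorical,Quantitative}Character / States /
StateDefinition` and `CodedDescriptions / CodedDescription / SummaryData /
{Categorical,Quantitative}` with `State ref=`, `Measure type="Min|Max"`,
and explicit `Status code="unknown|inapplicable"` markers for unscored
cells. Weights, groups, region flags and provenance notes ride along as
attributes so that `import_sdd_xml` round-trips our own exports losslessly.
This is an interchange-friendly export, not full SDD 1.1 compliance.
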