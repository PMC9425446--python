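# platykey

Matrix-based taxonomic identification keys: a descriptive knowledge-base
model, a multi-access (interactive) identification engine, a single-access
key generator, and a dichotomous-key interpreter — packaged with a worked
dataset, the ground beetles of tribe Platynini (Coleoptera, Carabidae)
recorded from the southern Levant.

## Who this is for

Taxonomists and biodiversity informaticians who maintain characters × taxa
description matrices (in the tradition of Xper, Lucid and DELTA) and want a
scriptable, offline engine to

* validate a matrix (structural checks, all-unknown characters,
  indistinguishable taxon pairs),
* identify specimens by free-order character elimination,
* generate single-access keys under different character-ranking policies,
* mechanize and regression-check a hand-written dichotomous key, and
* exchange matrices as CSV, JSON or SDD-flavoured XML.

## The model

A knowledge base is a matrix of **characters** (categorical with an ordered
state list, or numerical with units) against **taxa**. A cell is either
*scored* — a non-empty state subset (several states = a polymorphic taxon)
or a closed interval `[lo, hi]` — or *unknown* / *inapplicable*.

Identification is elimination: a specimen answer `A` on character `c` keeps
taxon `t` unless it positively contradicts it, i.e. `t` survives iff its
cell is unscored, or `A ∩ S_t(c) ≠ ∅` (categorical, `S_t` the taxon's state
set), or the measured point lies in `[lo_t, hi_t]` (numerical). Character
usefulness over a remaining set `R` is the pairwise-separation index

    power(c, R) = #{ {s,t} ⊆ R : cells disjoint } / #{ {s,t} ⊆ R : both scored }

where *disjoint* means empty state intersection or non-overlapping
intervals. Ranking policies reorder candidate characters by this power, by
state count (`prefer_fewer_states` / `most_states_first`) and optionally by
a three-level character weight — the same dials matrix key builders expose.

## Worked example

```python
>>> import platykey as pk
>>> kb = pk.platynini_kb()                      # 14 taxa x 16 characters
>>> s = pk.Session(kb).step("hairs_upperside", "present")
>>> [t.taxon_id for t in s.remaining]
['atranus_ruficollis', 'orthotrichus_cymindoides']
>>> s = s.step("pronotum_proportion", "clearly_wider")
>>> [t.taxon_id for t in s.remaining]
['orthotrichus_cymindoides']
```

Two answers — pubescent upper side, pronotum clearly wider than long —
eliminate 13 of the 14 species: the session narrows from the two hairy
genera to *Orthotrichus cymindoides* alone.

The printed 13-couplet key ships in machine-readable form and can be scored
from the command line:

```sh
$ platykey keystats --dichotomous
{
  "alternatives": 13,
  ...
  "min_decisions": 2,
  "max_decisions": 9,
  "duplicated_taxa": []
}
```

13 numbered couplets; the quickest species (the two hairy ones) take 2
steps, the dark *Agonum* species at the end of the key take 9. Other
subcommands: `platykey validate`, `identify --answers answers.json`,
`buildkey --prefer-fewer-states`, `export-sdd --out kb.xml`,
`simulate --seed 1`.

## Layout

* `src/platykey/core.py` — domain model, compatibility, power, ranking,
  validation
* `src/platykey/io.py` — JSON/CSV matrices, SDD-flavoured XML (see
  `docs/formats.md`)
* `src/platykey/engine.py` — identification sessions, decision profiling
* `src/platykey/keygen.py` — dichotomous keys, single-access generation,
  metrics, text rendering
* `src/platykey/synth.py` — random matrices and noisy specimen sampling
* `src/platykey/data/` — the Platynini base and its printed key
* `docs/methods.md` — model, defaults and design decisions in detail
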