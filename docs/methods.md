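# Methods

## The descriptive model

A knowledge base is an ordered list of characters and an ordered list of
taxa, with exactly one observation per (taxon, character) cell. Characters
are categorical (ordered `(state_id, label)` list) or numerical (units; a
taxon's value is a closed interval `[lo, hi]`, a point being `lo == hi`).
Cells are `scored`, `unknown`, or `inapplicable`. Unknown and inapplicable
are stored as distinct statuses — curators mean different things by them —
but both behave identically in every computation: they are compatible with
any specimen answer and excluded from discrimination scoring. Polymorphism
is first-class: a categorical cell may hold several states, and a specimen
answer matches by non-empty intersection, so a two-morph species survives a
question answered with either morph.

Specimen answers are sets of states (a single selection is a singleton) for
categorical characters and measured points for numerical ones. Points are
matched against closed intervals, so boundary measurements match.

## Discriminatory power and ranking

`power(c, R)` is the fraction of scored taxon pairs in the remaining set
`R` that character `c` separates, where a pair is separated iff the two
cells are disjoint (empty state intersection; intervals that merely touch
at an endpoint do **not** separate, consistent with closed-interval
matching). Pairs with an unscored member drop out of both numerator and
denominator; a character with no scored pair has power 0. The index is
deterministic, depends only on the matrix, and reproduces the observed
behaviour of matrix key builders: the many-state coloration character
dominates the full Platynini base, while two-state structural characters
carry less pairwise information.

Ranking composes up to four criteria:

| policy               | sort key (in order)                               |
|----------------------|---------------------------------------------------|
| default              | power ↓, declaration order                        |
| `prefer_fewer_states`| state count ↑, [weight ↓], power ↓, declaration   |
| `most_states_first`  | state count ↓, [weight ↓], power ↓, declaration   |

`use_weights` inserts the declared three-level weight (weak=1 < medium=2 <
strong=3) immediately after the primary criterion. Numerical characters
count as 2 states here, because key generation binarises them at interval
gaps. Already-answered and zero-power characters are excluded from every
ranking.

## The packaged Platynini base

14 taxa × 16 characters, transcribed from the printed 13-couplet key and
the published character overview (15 table rows plus the mentum-tooth
character that the key's third couplet uses). Taxon order follows first
appearance in the key; character order follows the table, mentum tooth
appended last. *Anchomenus bellus*, the parenthesized species expected only
near the region, stays in the matrix with `in_region=false`.

Transcription policy: every scored cell carries a provenance note naming
the couplet lead or table row it came from (an audit test enforces this);
cells with no printed state stay unknown even where the table reports the
character as applicable — the original web database's full state
assignments are unpublished. Three cells could not be copied verbatim and
are marked `inferred` in their notes: the identity of the third species
scored for pronotum punctation (the table says three; the couplets name
only the two *Olisthopus*; we assign *Atranus ruficollis* from the pronotum
plate series), and the setiferous-puncture counts of the six taxa that
leave the key before the couplet that prints the generic (2-)3(-4) range.
The two pubescent genera are the unscored pair for that character, as the
published discussion of detectability implies. The 13 coloration states are
reconstructed from the couplets' color descriptions; one state (uniformly
pale brown) is declared but unassigned, reaching the published count of 13.
All weights ship as medium: a strong/weak assignment existed in the
original database but was never published per character, so reweighting is
exposed as a configuration override rather than guessed into the fixture.

The companion dichotomous key is encoded with one machine predicate per
lead — the character contrast that cleanly discriminates at that couplet —
plus the full diagnostic text. Couplet 10's printed discriminant (extra
hairs on the third antennomere) is not among the 16 matrix characters, so
its predicate uses the coloration contrast the same leads state.

## Interactive sessions and decision counting

A session is an immutable answer log; the remaining taxa are recomputed by
elimination after every step, so the endpoint depends only on the answer
set, never the order. `decision_profile` simulates a noiseless user per
taxon: repeatedly answer the top-ranked suggested character with the
taxon's true value (full state set; interval midpoint for numerical
characters), skipping characters the taxon is unscored for — a user cannot
answer what the specimen does not show. The count is the number of answers
given when the remaining set first collapses to the taxon. On the packaged
base the most-states-first policy resolves every species in 2–4 decisions
and the fewer-states-first policy in 3–9, and the former is never worse per
taxon — the qualitative trade-off reported for the original web key. The
exact published ranges (1–3 and 2–5) depend on that platform's unpublished
ranking metric and state assignments and are deliberately not claimed.

## Single-access key generation

Recursive: at each node ask the top-ranked character, branch per observed
state (numerical: per interval cluster, clusters being maximal runs of
overlapping taxon intervals separated by gaps), copy unscored taxa into
every branch and polymorphic taxa into every branch they exhibit, and
recurse with that character retired on the path. Recursion stops at
singletons or when no remaining character has positive power (an unresolved
multi-taxon leaf, rendered with a warning rather than failing). Branch
predicates are pairwise disjoint by construction; the per-state copy rule
is what makes generated keys list variable species at two or three leaves,
exactly the duplication the polymorphic coloration of the Platynini
produces. Generation is fully deterministic in (base, options).

The shared efficiency metric counts **alternatives** — numbered
couplets/nodes — and per-taxon **decisions**, the numbered steps traversed
from the entry to the lead naming the taxon, inclusive; for duplicated taxa
the minimum over leaves is reported. The encoded printed key scores 13
alternatives with decisions 2–9.

## Synthetic data

`random_kb` draws matrices with configurable shape (taxa, characters,
states per character, optional numerical characters) and noise (defaults:
polymorphism 0.15, unknown 0.1 — moderate values typical of curated
morphological matrices, where most cells are scored and single-state).
`sample_specimen` draws one observation vector from a taxon: one state per
answered categorical character, a uniform point inside the interval for
numerical ones; `unknown_rate` drops answers and `noise_rate` substitutes a
wrong state or an out-of-interval point. A single explicitly seeded NumPy
generator drives each call — no global state, bit-reproducible runs.

What the generator emulates: sparsity, polymorphism and observation error
as independent uniform events. What it does not: correlated characters,
structured observer bias, or abundance-weighted encounter rates — so
passing property suites demonstrate engine correctness (elimination equals
brute force, noiseless containment is exact, accuracy degrades with noise),
not field-performance of any particular key.

## Numerical and procedural choices

* Closed intervals everywhere; touching intervals match and do not
  separate.
* Noiseless numerical answers use the interval midpoint.
* Ties in ranking always fall back to declaration order, making every
  pipeline deterministic.
* Generated numerical branch predicates use the cluster bounds themselves;
  a measurement falling in a gap between clusters satisfies no branch and
  surfaces as an inconsistent-specimen error, which is honest: no taxon in
  the base exhibits such a value.
* Problem sizes in the test and acceptance runs (random bases of 6–8 taxa,
  200 oracle replicates, 20 containment seeds) keep full runs in seconds
  while exercising every code path; the packaged base is always tested in
  full.

## Known limitations

Character dependencies (descriptor applicability rules) are not modelled;
the engine has no probabilistic or fuzzy matching; SDD support is an
export-flavoured subset (lossless for this package's own fields, not a
full implementation of the interchange standard); and foreign Xper/DELTA/
Lucid exports are not imported.
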