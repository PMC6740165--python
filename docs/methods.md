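# Methods

## Problem and model

Categorical laboratory results are free-text renderings of a small
conceptual vocabulary: a urine color is one of ~18 colors, a dipstick
finding one of `negative`/`normal`/`trace`/`+`…`++++`, a serology either
positive/negative or reactive/nonreactive, a blood type one of the ABO/Rh
groups. Local notation, typos, abbreviations and instrument formatting
multiply each concept into many surface strings. `saltc` treats
standardization as nearest-neighbor assignment in a character-count vector
space, after rule-based cleaning and a rule-based decision of *which*
vocabulary (value set) a test draws from.

Core assumptions:

* Each laboratory test reports values from exactly one of the five value
  sets; a test is a single unit of assignment, identified by its test id.
* A test's dominant values are clean enough to reveal its value set: the
  categorizer looks only at *main values*, the top of the per-test frequency
  distribution, where canonical notations concentrate.
* Variant strings of a concept mostly preserve its character multiset
  (swaps are free; drops/inserts/substitutions are small perturbations),
  while different concepts within a value set can be made nearly disjoint in
  characters by abbreviating the canonical comparison strings (`negative` →
  `neg-`, `positive` → `posi`, `nonreactive` → `nonreact`, `trace` → `tr`).
  This is what makes 29 count features sufficient.
* Characters outside the scheme carry no meaning for the category decision:
  digits are concentrations/titers (`250 ++++`, `neg (2.00)`), punctuation
  is formatting. Dropping them at vectorization, not at cleaning, keeps
  preprocessing conservative and auditable.

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| `threshold` (θ) | 0.995 | cumulative relative frequency the main-value prefix must reach (fraction of a test's records) |
| `min_distinct` | 5 | below this many distinct values, all values are main values |
| `measure` | `hybrid` | `cosine`, `euclidean`, or cosine with Euclidean tie-break |
| `min_cosine` | off | optional floor; matches scoring below it go to manual review |
| `coverage_cutoff` | off | optional fraction; only values inside the shortest distribution prefix covering it are mapped, the tail goes to review |
| `blood_type_patterns` | `abo`, `rh` (word-ish), `blood type/group` | test-name regexes enabling the Rh abbreviation correction |
| `group_blood_variants` | off | fold cis-AB into AB on output |

θ = 0.995 keeps enough of the head of each distribution to include every
canonical notation while excluding the typo tail; `min_distinct` = 5 guards
tests whose support is so small that a coverage prefix could starve the
categorizer. Both matter mainly for categorization: mapping itself sees
every value regardless.

Main-value semantics: the shortest descending-frequency prefix whose
cumulative frequency first *reaches* θ (the boundary row is included). Ties
in count are broken lexicographically so the table, and everything
downstream, is a pure function of the input multiset. An alternative
reading — keep values whose individual frequency exceeds 1 − θ — fits some
published frequency patterns better and this prefix reading fits others;
the coverage reading was chosen because it degrades gracefully (it can only
over-include, never drop a dominant canonical) and θ stays interpretable as
coverage. It is exposed as a parameter rather than hard-coded.

Trigger lexicons are deliberately narrow where notations collide across
value sets: `negative`/`neg` trigger only the presence-finding category,
not urine dipstick (where `negative` is nonetheless a canonical value),
because dipstick is evaluated earlier and would otherwise capture every
negative-reporting serology. Dipstick is instead claimed by its graded
values (`tr`, `trace`, `++`, `+++`, `++++` — bare `+` intentionally not a
trigger, since most tests have `+`/`-` data). Token-level trigger matching
skips single-letter alphabetic tokens so the blood-group triggers
`a`/`b`/`o` fire only on whole main values.

## Matching

All candidate scores are computed against comparison-string vectors, never
display labels. For an input vector **x** and candidates **c**ᵢ:

* cosine: argmaxᵢ **x**·**c**ᵢ ⁄ (‖**x**‖‖**c**ᵢ‖), first index on ties;
* euclidean: argminᵢ ‖**x** − **c**ᵢ‖, first index on ties;
* hybrid: the cosine-maximal set, reduced by Euclidean distance; a
  singleton wins, anything still tied is routed to manual review
  (`unmapped`, `tie_after_hybrid`), as is any zero-vector input.

Numerical choices: comparisons run on squared cosine computed as one
division of exact integers (dot², ‖**x**‖²‖**c**‖²) and on integer squared
distances. Count vectors make true ties exactly representable, and a
per-candidate square root would break them — 3/√18 and 1/√2 are equal but
round differently — which an exhaustive cross-check against an
integer-arithmetic brute-force scorer exposed. A 10⁻¹² tolerance remains on
the cosine tie test to absorb any residual float effects; Euclidean ties
compare integers exactly. Reported scores are the rounded square roots.

Occurrence counts (not binary presence) follow from the representation's
definition; a binary mode exists for ablation only. Note the two differ:
cos(`negative`, `neg-`) is 4⁄(2√10) ≈ 0.632 with counts (the `e` counts
twice) but 3⁄(2√7) ≈ 0.567 with presence bits.

No similarity floor applies by default: every value of a classified test is
assigned its nearest canonical, and junk that happens to contain scheme
characters will be assigned *something*. That is the documented cost of
full automation; `min_cosine` and `coverage_cutoff` are the two opt-in
remedies, and zero-vector/fully-tied values always abstain.

## Synthetic corpora and evaluation

The generator emulates the shape of hospital categorical-result data with
known ground truth. Per record it samples a category (default mix dominated
by urinalysis and presence-finding serology, mirroring real corpus
proportions), a test, and a canonical value from heavy-tailed per-test
weights (e.g. urine color ≈ 69/17/12% for the top three values); renders a
realistic surface notation (abbreviations like `neg -`, `non-react`, graded
forms, analyzer concentration prefixes `250 ++++` at `prefix_rate`,
numeric suffixes for serology); then applies at most one typo operation
(adjacent swap, drop, duplicate, substitute, pad — uniform among enabled
ops) at `typo_rate` and case noise at `case_noise_rate`. With probability
`junk_rate` the record is drawn from a junk pool containing no scheme
characters, so junk deterministically vectorizes to zero. Identical specs
(including seed) produce byte-identical corpora.

What the generator does *not* emulate: multi-edit corruption, keyboard- or
phonetically-plausible substitution patterns, embedded test names or free
commentary inside result fields, the enormous unique-value counts of
numeric-suffixed serology (tens of thousands per test), or longitudinal
drift of conventions. Passing recovery tests therefore shows the pipeline
is correct under single-edit, format-style noise on realistic notation
pools — not that real hospital accuracy figures transfer.

`score_mapping` reports accuracy at two granularities: **value-level**
(each distinct (test, raw value) pair once; if corruption collides one
string onto two truths, the majority truth stands in for per-unique-value
adjudication) and **data-level** (per record, so frequent notations weigh
more). Values the mapper abstained on (zero vector, full tie, floor,
unclassified test) are not automatic decisions; they are excluded from the
accuracy denominators and reported as review counts — the convention of
validation protocols that exclude uninterpretable data from interpretation.
Junk scores correct only when left unmapped.

Measured on this generator (20 seeds, n = 1000, typo 0.2, prefix 0.2, junk
0.02 — sizes chosen to keep the full benchmark under a few seconds), mean
value-level accuracy is ≈ 0.97 for hybrid, ≈ 0.87 for cosine-only and
≈ 0.97 for euclidean-only: hybrid's gain over cosine comes entirely from
the collinear dipstick grades, while hybrid and euclidean differ only on
degenerate single-character residues of destroyed short values, where
Euclidean's bias toward short canonicals is accidentally right more often
than cosine's direction match. On such near-ties the ordering of the two
can go either way; the hybrid's advantage over Euclidean in practice comes
from verbose length-variant notations that this generator deliberately
does not fabricate.

## Known limitations

* The shipped SNOMED CT identifiers are curated defaults (several values,
  e.g. urine colors and blood groups, ship without codes); production
  terminology work should supply a reviewed registry config.
* Trigger lexicons and comparison abbreviations are config; a site whose
  dipstick tests report only bare `+` values, for instance, must extend the
  dipstick triggers or those tests will fall through to presence-finding.
* Blood-type context detection is name-based; tests named opaquely (e.g.
  numeric codes) will not get the Rh `-`/`+` correction.
* The categorizer never revisits a decision: a test whose main values mix
  two vocabularies is claimed by the earlier category in the fixed order.
* Matching is per-value and context-free; `pos` under a misclassified test
  maps within the wrong value set with no warning beyond the category
  column.
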