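# saltc

Standardization of free-text **categorical laboratory results** for clinical
data research: urine colors, dipstick grades, blood types,
positive/negative and reactive/nonreactive findings.

EHR laboratory tables record these outcomes as free text, and decades of
local conventions leave the same concept under dozens of notations —
`NEG -`, `neg (2.00)`, `250 4+`, `Starw`, `NON-REACT` — plus junk like
`****`. `saltc` cleans such values, assigns each laboratory test to one of
five predefined value-set categories, and maps every raw value to a
canonical, SNOMED CT–coded value. It is aimed at data curators and
researchers preparing hospital laboratory extracts for analysis or for a
standardized clinical data warehouse.

## Method

The pipeline has five stages:

1. **Preprocessing.** Lowercase, trim and collapse whitespace, normalize dash
   variants; in blood-type test context rewrite bare `-`/`+` to `rh-`/`rh+`;
   reformat digit dipstick grades (`4+` → `++++`, `250 4+` → `250 ++++`).
2. **Distribution profiling.** Per test, rank distinct values by frequency
   and extract the *main values*: the shortest descending-frequency prefix
   whose cumulative relative frequency reaches θ (default 99.5%); tests with
   fewer than 5 distinct values keep all of them.
3. **Test categorization.** Categories are tried in a fixed order — urine
   color, urine dipstick, blood type, presence finding, pathogenesis — and
   the first whose trigger lexicon contains a main value (whole value or
   token, so `250 ++++` fires on `++++`) claims the test. The order matters:
   graded `++`/`+++`/`++++` values claim dipstick tests before the generic
   positive/negative categories ever see their `+` data. Unmatched tests are
   left unclassified.
4. **Character-level vectorization.** Every value maps to a count vector
   **x** ∈ ℕ²⁹ over the scheme `a`–`z`, `-`, `_`, `+`; characters outside
   the scheme (digits, spaces, `*`, parentheses) contribute nothing.
   Canonical values are vectorized from abbreviated *comparison strings*
   (`negative` → `neg-`, `positive` → `posi`) chosen to minimize shared
   characters within a value set.
5. **Similarity mapping.** A value with vector **x** is assigned the
   canonical value **c** of its test's category maximizing the cosine
   similarity cos(**x**, **c**) = **x**·**c** ⁄ (‖**x**‖‖**c**‖); when two
   or more canonicals tie on cosine, the Euclidean distance ‖**x** − **c**‖
   decides among the tied set (the *hybrid* measure). A value still tied
   after both, or with a zero vector, is routed to manual review rather than
   guessed. Pure cosine and pure Euclidean matching are available for
   comparison.

A seeded synthetic-corpus generator with known ground truth (heavy-tailed
value distributions, single-edit typos, case noise, concentration prefixes,
junk) supports accuracy evaluation at two granularities: value-level (over
distinct raw values) and data-level (over records).

## Worked example

```python
>>> from saltc import *
>>> registry = load_registry()
>>> r = match_value(clean_pipeline("+++ 6"), Category.URINE_DIPSTICK, registry)
>>> r.best.label, r.cosine_score, r.euclidean_distance
('+++', 1.0, 0.0)
```

`+++ 6` counts three `+` characters and nothing else, so its vector is
collinear with every grade's vector and cosine ties at 1.0 across
`+`/`++`/`+++`/`++++`; the Euclidean distances 2, 1, 0, 1 break the tie in
favor of `+++`. Running `python examples/worked_examples.py` prints:

```
input '+++ 6' against the urine-dipstick value set:
  +     cosine=1.0000  euclidean=2.0000
  ++    cosine=1.0000  euclidean=1.0000
  +++   cosine=1.0000  euclidean=0.0000
  ++++  cosine=1.0000  euclidean=1.0000
  hybrid pick: +++  (cosine ties at 1.0; distance decides)

input '4+': reformatted to '++++', mapped to '++++' with SNOMED CT concept 260350009
```

The other scripts under `examples/` demonstrate corpus profiling with
main-value extraction and categorization, and a benchmark of the three
similarity measures on a labeled synthetic corpus.

## Command line

```sh
saltc run -i results.csv -o mapped.csv --measure hybrid   # standardize a CSV
saltc profile -i results.csv -o profile.csv               # distributions + main values
saltc synth --n 1000 --seed 42 --out corpus.csv           # labeled synthetic corpus
saltc evaluate --truth corpus.csv --pred mapped.csv       # accuracy report
```

`saltc run` writes one row per input record with the cleaned value, assigned
category, mapped canonical label, SNOMED identifier, similarity scores, and
an unmapped flag with reason. Optional `--min-cosine` and
`--coverage-cutoff` route low-confidence or tail values to manual review;
`--registry` replaces the packaged value sets with a site-specific YAML/JSON
config (the shipped SNOMED identifiers are curated defaults and should be
reviewed before production terminology work).

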