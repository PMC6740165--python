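"""Rule-based assignment of laboratory tests to value-set categories.

A test is categorized by checking whether any of its main values appears in a
category's trigger lexicon, trying the categories in the fixed order urine
color -> urine dipstick -> blood type -> presence finding -> pathogenesis.
The order matters because most tests carry ``+``/``-`` notations: dipstick
tests are claimed first via their graded values (``++``, ``+++``, ``++++``),
blood-type tests via ``rh+``/``rh-`` (after Rh abbreviation correction), and
only then do the generic positive/negative and reactive/nonreactive
categories get to match. A test that fires no lexicon is ``UNCLASSIFIED``.

Matching is exact on preprocessed strings, both on the whole main value and on
its whitespace tokens — ``250 ++++`` triggers through its ``++++`` token.
Single-letter alphabetic tokens are not eligible as tokens (only as whole
values) so that blood-group triggers like ``a``/``b``/``o`` cannot fire from
inside unrelated phrases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from .distribution import MainValueSet
from .preprocess import CleanValue, rh_correct
from .valuesets import CATEGORY_ORDER, Category, ValueSetRegistry

__all__ = ["TestAssignment", "categorize_test"]


@dataclass(frozen=True)
class TestAssignment:
    """The category decision for one laboratory test."""

    test_id: str
    category: Category
    matched_trigger: str | None = None


def _candidates(value: str) -> Iterator[str]:
    yield value
    for token in value.split():
        if token != value and not (len(token) == 1 and token.isalpha()):
            yield token


def categorize_test(
    main_values: MainValueSet,
    registry: ValueSetRegistry,
    blood_type_context: bool = False,
) -> TestAssignment:
    """Assign one test to the first category whose lexicon contains a main value.

    ``blood_type_context`` applies the Rh abbreviation correction (bare
    ``-``/``+`` -> ``rh-``/``rh+``) to the main values before matching; in the
    full pipeline this has normally already happened at preprocessing time.
    Main values are tried in distribution order (most frequent first);
    ``matched_trigger`` records the main value that fired.
    """
    if not main_values.values:
        raise ValueError(f"test '{main_values.test_id}' has no main values")
    values = [
        rh_correct(CleanValue(v), blood_type_context).text for v in main_values.values
    ]
    for category in CATEGORY_ORDER:
        lexicon = registry.triggers_for(category)
        if not lexicon:
            continue
        for value in values:
            if any(candidate in lexicon for candidate in _candidates(value)):
                return TestAssignment(main_values.test_id, category, value)
    return TestAssignment(main_values.test_id, Category.UNCLASSIFIED, None)
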