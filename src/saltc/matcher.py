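"""Character-level vectorization and cosine/Euclidean hybrid value matching.

Every cleaned result value is represented as a 29-dimensional count vector
over the scheme ``a``–``z``, ``-``, ``_``, ``+``; characters outside the
scheme (digits, spaces, parentheses, ``*`` …) contribute nothing. A value is
mapped to the canonical value of its test's category whose *comparison
string* vector is most similar:

* ``cosine``     — argmax of the cosine similarity (direction only, so it is
  insensitive to term length and character order);
* ``euclidean``  — argmin of the Euclidean distance between count vectors;
* ``hybrid``     — cosine first; when two or more canonical values share the
  maximal cosine score, the Euclidean distance decides among the tied set.
  ``+++ 6`` ties at cosine 1.0 with all of ``+``/``++``/``+++``/``++++``
  (the vectors are collinear), and the Euclidean tie-break selects ``+++``.

A value whose vector is zero (junk like ``****``), or that is still tied
after the hybrid tie-break, is left unmapped for manual review rather than
assigned arbitrarily.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._scheme import N_FEATURES, SCHEME, SCHEME_INDEX
from .categorizer import TestAssignment, categorize_test
from .distribution import DistributionTable, build_distribution, extract_main_values
from .preprocess import CleanValue, clean_pipeline
from .valuesets import CanonicalValue, Category, ValueSetRegistry

__all__ = [
    "CharVector",
    "MatchResult",
    "MappedRecord",
    "CorpusResult",
    "DEFAULT_BLOOD_TYPE_PATTERNS",
    "vectorize",
    "cosine_similarity",
    "euclidean_distance",
    "match_value",
    "map_corpus",
]

#: alias for readability: a length-29 nonnegative integer count vector
CharVector = np.ndarray

#: score differences below this are treated as exact ties (count vectors make
#: true ties representable; the tolerance only absorbs float round-off)
TIE_TOL = 1e-12

#: test-name regexes (case-insensitive search) marking blood-type context,
#: which enables the Rh abbreviation correction
DEFAULT_BLOOD_TYPE_PATTERNS: tuple[str, ...] = (
    r"abo",
    r"(?<![a-z])rh(?![a-z])",
    r"blood[ _-]?(type|group)",
)

_METHODS = ("cosine", "euclidean", "hybrid")


def vectorize(value: str | CleanValue, binary: bool = False) -> CharVector:
    """Count vector of a value over the 29-character scheme.

    ``binary=True`` records presence (0/1) instead of counts; occurrence
    counts are the default representation.
    """
    text = value.text if isinstance(value, CleanValue) else value
    counts = np.zeros(N_FEATURES, dtype=np.int64)
    for ch in text:
        idx = SCHEME_INDEX.get(ch)
        if idx is not None:
            counts[idx] += 1
    if binary:
        return (counts > 0).astype(np.int64)
    return counts


def cosine_similarity(u: CharVector, v: CharVector) -> float:
    """Cosine of the angle between two count vectors, in [0, 1].

    The denominator is formed from the exact integer squared norms, so equal
    vectors (and anagrams) score exactly 1.0. Undefined (raises
    ``ValueError``) when either vector is zero; callers mark such values
    unmapped.
    """
    u = np.asarray(u, dtype=np.int64)
    v = np.asarray(v, dtype=np.int64)
    nu2 = int(u @ u)
    nv2 = int(v @ v)
    if nu2 == 0 or nv2 == 0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(np.clip(int(u @ v) / np.sqrt(nu2 * nv2), 0.0, 1.0))


def euclidean_distance(u: CharVector, v: CharVector) -> float:
    """Euclidean distance between two count vectors; 0 iff the vectors are equal."""
    return float(np.linalg.norm(np.asarray(u, dtype=float) - np.asarray(v, dtype=float)))


@dataclass(frozen=True)
class MatchResult:
    """The mapping decision for one cleaned value."""

    input: CleanValue
    category: Category
    best: CanonicalValue | None
    cosine_score: float | None
    euclidean_distance: float | None
    method: str
    tie_after_hybrid: bool = False
    unmapped: bool = False
    reason: str | None = None


def _category_vectors(
    registry: ValueSetRegistry, category: Category
) -> tuple[Sequence[CanonicalValue], np.ndarray, np.ndarray]:
    cache = getattr(registry, "_matcher_cache", None)
    if cache is None:
        cache = {}
        registry._matcher_cache = cache
    if category not in cache:
        values = registry.values_for(category)
        matrix = np.stack([vectorize(v.comparison_string) for v in values])
        norms_sq = (matrix * matrix).sum(axis=1)
        cache[category] = (values, matrix, norms_sq)
    return cache[category]


def match_value(
    value: str | CleanValue,
    category: Category,
    registry: ValueSetRegistry,
    method: str = "hybrid",
    min_cosine: float | None = None,
) -> MatchResult:
    """Map one cleaned value to the most similar canonical value of a category.

    ``min_cosine`` optionally routes matches whose best cosine score falls
    below the floor to manual review (unmapped) instead of accepting them.
    """
    if method not in _METHODS:
        raise ValueError(f"unknown method '{method}'; expected one of {_METHODS}")
    if category is Category.UNCLASSIFIED:
        raise ValueError("cannot match values of an UNCLASSIFIED test")
    clean = value if isinstance(value, CleanValue) else CleanValue(value)
    u = vectorize(clean)
    if not u.any():
        return MatchResult(
            clean, category, None, None, None, method,
            unmapped=True, reason="zero vector: value contains no scheme characters",
        )

    values, matrix, norms_sq = _category_vectors(registry, category)
    nu2 = int(u @ u)
    # comparisons run on squared scores formed by a single division of exact
    # integer quantities, so rationally equal cosines (and equal distances)
    # compare as exact float ties; sqrt enters reported scores only
    dots = matrix @ u
    cos_sq = (dots * dots) / (norms_sq * nu2)
    eu_sq = ((matrix - u) ** 2).sum(axis=1)
    cos = np.sqrt(np.clip(cos_sq, 0.0, 1.0))
    eu = np.sqrt(eu_sq.astype(float))

    tie_after_hybrid = False
    if method == "cosine":
        idx = int(np.argmax(cos_sq))
    elif method == "euclidean":
        idx = int(np.argmin(eu_sq))
    else:
        tied = np.flatnonzero(cos_sq >= cos_sq.max() - TIE_TOL)
        if tied.size == 1:
            idx = int(tied[0])
        else:
            still = tied[np.flatnonzero(eu_sq[tied] == eu_sq[tied].min())]
            if still.size == 1:
                idx = int(still[0])
            else:
                labels = ", ".join(values[i].label for i in still)
                return MatchResult(
                    clean, category, None, float(cos[tied].max()), float(eu[tied].min()),
                    method, tie_after_hybrid=True, unmapped=True,
                    reason=f"fully tied after hybrid tie-break ({labels}); needs manual mapping",
                )

    if min_cosine is not None and cos[idx] < min_cosine:
        return MatchResult(
            clean, category, None, float(cos[idx]), float(eu[idx]), method,
            unmapped=True,
            reason=f"cosine score {cos[idx]:.4f} below floor {min_cosine}",
        )
    return MatchResult(
        clean, category, values[idx], float(cos[idx]), float(eu[idx]), method,
        tie_after_hybrid=tie_after_hybrid,
    )


@dataclass(frozen=True)
class MappedRecord:
    """One input record with its full standardization outcome."""

    test_id: str
    raw_value: str
    clean_value: str
    category: Category
    mapped_label: str | None
    snomed_id: str | None
    cosine_score: float | None
    euclidean_distance: float | None
    method: str
    unmapped: bool
    reason: str | None


@dataclass(frozen=True)
class CorpusResult:
    """All per-record mappings plus per-test assignments and corpus summary."""

    records: tuple[MappedRecord, ...]
    assignments: dict[str, TestAssignment]
    tables: dict[str, DistributionTable]
    summary: dict


def _is_blood_type_test(test_id: str, patterns: Iterable[str]) -> bool:
    return any(re.search(p, test_id, flags=re.IGNORECASE) for p in patterns)


def _normalize_records(records: Iterable) -> list[tuple[str, str]]:
    out = []
    for rec in records:
        if hasattr(rec, "test_id"):
            out.append((str(rec.test_id), str(getattr(rec, "raw_value", getattr(rec, "value", "")))))
        else:
            test_id, value = rec
            out.append((str(test_id), str(value)))
    return out


def map_corpus(
    records: Iterable,
    registry: ValueSetRegistry,
    method: str = "hybrid",
    *,
    threshold: float = 0.995,
    min_distinct: int = 5,
    blood_type_patterns: Iterable[str] = DEFAULT_BLOOD_TYPE_PATTERNS,
    min_cosine: float | None = None,
    coverage_cutoff: float | None = None,
    group_blood_variants: bool = False,
) -> CorpusResult:
    """Run the full standardization pipeline over a corpus.

    Stages, per test: preprocess every raw value (with Rh correction for
    blood-type-context tests), build the frequency distribution, extract main
    values at ``threshold`` coverage, categorize the test, then map every
    distinct value against the assigned category's value set. Records of
    UNCLASSIFIED tests pass through unmapped.

    ``coverage_cutoff`` implements the optional high-frequency restriction:
    only values inside the shortest distribution prefix covering that fraction
    of the test's records are mapped; tail values go to manual review.
    ``group_blood_variants`` folds cis-AB into AB on output (A/B subgroup
    notations such as ``a1``/``ax`` already land on A/B through matching).
    """
    pairs = _normalize_records(records)
    patterns = tuple(blood_type_patterns)
    blood_context = {
        tid: _is_blood_type_test(tid, patterns)
        for tid in dict.fromkeys(tid for tid, _ in pairs)
    }

    cleaned = [clean_pipeline(raw, blood_context[tid]) for tid, raw in pairs]
    tables = build_distribution(
        (tid, cv.text) for (tid, _), cv in zip(pairs, cleaned)
    )

    assignments: dict[str, TestAssignment] = {}
    mappable: dict[str, set[str] | None] = {}
    for tid, table in tables.items():
        main = extract_main_values(table, threshold=threshold, min_distinct=min_distinct)
        assignments[tid] = categorize_test(main, registry)
        if coverage_cutoff is None:
            mappable[tid] = None
        else:
            covered = extract_main_values(table, threshold=coverage_cutoff, min_distinct=0)
            mappable[tid] = set(covered.values)

    match_cache: dict[tuple[str, str], MatchResult] = {}
    out: list[MappedRecord] = []
    for (tid, raw), clean in zip(pairs, cleaned):
        assignment = assignments[tid]
        category = assignment.category
        if category is Category.UNCLASSIFIED:
            out.append(
                MappedRecord(tid, raw, clean.text, category, None, None, None, None,
                             method, True, "unclassified test")
            )
            continue
        allowed = mappable[tid]
        if allowed is not None and clean.text not in allowed:
            out.append(
                MappedRecord(tid, raw, clean.text, category, None, None, None, None,
                             method, True,
                             f"outside coverage cutoff {coverage_cutoff}")
            )
            continue
        key = (tid, clean.text)
        result = match_cache.get(key)
        if result is None:
            result = match_value(clean, category, registry, method, min_cosine=min_cosine)
            match_cache[key] = result
        best = result.best
        if (
            group_blood_variants
            and best is not None
            and category is Category.BLOOD_TYPE
            and best.label == "cis-ab"
        ):
            best = registry.get(Category.BLOOD_TYPE, "ab")
        out.append(
            MappedRecord(
                tid, raw, clean.text, category,
                None if best is None else best.label,
                None if best is None else best.snomed_id,
                result.cosine_score, result.euclidean_distance, method,
                result.unmapped, result.reason,
            )
        )

    by_category: dict[str, dict[str, int]] = {}
    for rec in out:
        stats = by_category.setdefault(
            rec.category.value, {"records": 0, "mapped": 0, "unmapped": 0}
        )
        stats["records"] += 1
        stats["mapped" if not rec.unmapped else "unmapped"] += 1
    summary = {
        "n_records": len(out),
        "n_mapped": sum(1 for r in out if not r.unmapped),
        "n_unmapped": sum(1 for r in out if r.unmapped),
        "n_tests": len(tables),
        "n_unclassified_tests": sum(
            1 for a in assignments.values() if a.category is Category.UNCLASSIFIED
        ),
        "by_category": by_category,
    }
    return CorpusResult(tuple(out), assignments, tables, summary)
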