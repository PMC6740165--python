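"""Seeded synthetic corpora of categorical laboratory results.

Real categorical laboratory data are dominated, per test, by a few canonical
notations with a long tail of typos, case variants, abbreviations, numeric
concentration prefixes (``250 ++++``) and outright junk (``****``). The
generator emulates that shape with known ground truth so mapping accuracy can
be measured: each record samples a category and canonical value from
heavy-tailed weights modeled on the skew of hospital urinalysis/serology
corpora, renders one of the value's common surface notations, then corrupts
it with at most one typo operation at the configured rates.

Junk strings are drawn from a fixed pool containing no scheme characters, so
they deterministically vectorize to zero and should be left unmapped.

``score_mapping`` reports the two validation granularities: value-level
accuracy over distinct (test, raw value) pairs and data-level accuracy over
records, overall and per category.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .matcher import MappedRecord
from .valuesets import Category, ValueSetRegistry

__all__ = [
    "JUNK",
    "NoiseSpec",
    "LabeledRecord",
    "AccuracyReport",
    "generate_corpus",
    "score_mapping",
]

#: ground-truth label of uninterpretable values
JUNK = "JUNK"

ALL_TYPO_OPS = ("swap_adjacent", "drop_char", "duplicate_char", "substitute_char", "pad_spaces")

#: pool of uninterpretable strings; none contains a scheme character
_JUNK_POOL = ("****", "????", "....", "^^", "!!", "##", "(?)", "....;", "*?*")

_DEFAULT_MIX: dict[Category, float] = {
    # modeled on the dominance of urinalysis and serology in hospital corpora
    Category.URINE_COLOR: 0.08,
    Category.URINE_DIPSTICK: 0.56,
    Category.BLOOD_TYPE: 0.06,
    Category.PRESENCE_FINDING: 0.25,
    Category.PATHOGENESIS: 0.05,
}

# per category: test id -> (canonical label -> sampling weight). Test ids for
# blood-type tests intentionally match the default blood-type-context patterns.
_TESTS: dict[Category, dict[str, dict[str, float]]] = {
    Category.URINE_COLOR: {
        "urinalysis: color": {
            "straw": 0.6943, "yellow": 0.1697, "amber": 0.1188, "brown": 0.009,
            "dark yellow": 0.003, "red": 0.002, "colorless": 0.002, "orange": 0.001,
        },
    },
    Category.URINE_DIPSTICK: {
        "urinalysis: blood": {
            "negative": 0.5232, "trace": 0.1373, "+": 0.1173, "++++": 0.0689,
            "++": 0.0660, "+++": 0.0416, "normal": 0.01,
        },
        "urinalysis: protein": {
            "negative": 0.62, "trace": 0.17, "+": 0.10, "++": 0.06,
            "+++": 0.03, "++++": 0.015, "normal": 0.005,
        },
    },
    Category.BLOOD_TYPE: {
        "abo group": {"a": 0.3417, "o": 0.2742, "b": 0.2708, "ab": 0.1115, "cis-ab": 0.0018},
        "rh type": {"rh+": 0.85, "rh-": 0.147, "weak d": 0.003},
    },
    Category.PRESENCE_FINDING: {
        "hepatitis b surface antigen": {"negative": 0.80, "positive": 0.19, "weakly positive": 0.01},
        "hepatitis c antibody": {"negative": 0.93, "positive": 0.069, "weakly positive": 0.001},
    },
    Category.PATHOGENESIS: {
        "vdrl": {"nonreactive": 0.967, "reactive": 0.03, "weakly reactive": 0.003},
    },
}

# canonical label -> (surface notation -> weight); surface forms mirror the
# notation variants observed in practice. Forms are rendered before noise.
_SURFACES: dict[str, dict[str, float]] = {
    "negative": {"neg -": 0.5, "negative": 0.25, "neg": 0.25},
    "normal": {"norm": 0.5, "normal": 0.5},
    "trace": {"tr": 0.6, "trace": 0.4},
    "+": {"+": 0.7, "1+": 0.3},
    "++": {"++": 0.7, "2+": 0.3},
    "+++": {"+++": 0.7, "3+": 0.3},
    "++++": {"++++": 0.7, "4+": 0.3},
    "positive": {"positive": 0.3, "pos": 0.3, "pos (>1000)": 0.2, "posi": 0.2},
    "weakly positive": {"weakly positive": 0.5, "w pos": 0.5},
    "nonreactive": {"non-react": 0.6, "non-reactive": 0.3, "nonreactive": 0.1},
    "reactive": {"reactive": 0.7, "react": 0.3},
    "weakly reactive": {"w-react": 0.5, "weakly-reactive": 0.5},
    "rh+": {"rh+": 0.6, "rh +": 0.2, "+": 0.2},
    "rh-": {"rh-": 0.6, "rh -": 0.2, "-": 0.2},
}

# concentration prefixes by dipstick grade, as commonly printed by analyzers
_CONC_PREFIX: dict[str, tuple[str, ...]] = {
    "trace": ("5", "10", "25"),
    "+": ("25", "30"),
    "++": ("50", "75", "100"),
    "+++": ("150", "300"),
    "++++": ("250", "500"),
}

# presence-finding numeric suffixes (titers/indices printed next to the call)
_PRESENCE_SUFFIX = ("(2.00)", "(0.01)", "(>1000)", "(1.2)")


@dataclass(frozen=True)
class NoiseSpec:
    """Generation parameters; identical specs (incl. seed) yield identical corpora."""

    n_records: int = 1000
    seed: int = 0
    typo_rate: float = 0.0
    case_noise_rate: float = 0.0
    prefix_rate: float = 0.0
    junk_rate: float = 0.0
    category_mix: Mapping[Category, float] = field(
        default_factory=lambda: dict(_DEFAULT_MIX)
    )
    typo_ops: tuple[str, ...] = ALL_TYPO_OPS

    def __post_init__(self) -> None:
        if self.n_records <= 0:
            raise ValueError("n_records must be positive")
        for name in ("typo_rate", "case_noise_rate", "prefix_rate", "junk_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        weights = list(self.category_mix.values())
        if not weights or any(w < 0 for w in weights) or sum(weights) == 0:
            raise ValueError("category_mix weights must be nonnegative and not all zero")
        unknown = set(self.typo_ops) - set(ALL_TYPO_OPS)
        if unknown:
            raise ValueError(f"unknown typo op(s): {sorted(unknown)}")
        if not self.typo_ops:
            raise ValueError("typo_ops must not be empty")


@dataclass(frozen=True)
class LabeledRecord:
    """One synthetic record with its ground truth."""

    test_id: str
    raw_value: str
    true_category: Category
    true_label: str  # canonical label, or JUNK


def _choice(rng: np.random.Generator, table: Mapping[str, float]) -> str:
    keys = list(table)
    w = np.array([table[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=w / w.sum())]


def _apply_typo(rng: np.random.Generator, text: str, ops: Sequence[str]) -> str:
    op = ops[rng.integers(len(ops))]
    n = len(text)
    if op == "pad_spaces":
        return " " * int(rng.integers(1, 3)) + text if rng.random() < 0.5 else text + " " * int(rng.integers(1, 3))
    if n == 0:
        return text
    if op == "swap_adjacent":
        if n < 2:
            return text
        i = int(rng.integers(n - 1))
        return text[:i] + text[i + 1] + text[i] + text[i + 2 :]
    if op == "drop_char":
        if n < 2:  # never corrupt a value into an empty cell
            return text
        i = int(rng.integers(n))
        return text[:i] + text[i + 1 :]
    if op == "duplicate_char":
        i = int(rng.integers(n))
        return text[: i + 1] + text[i] + text[i + 1 :]
    # substitute_char
    i = int(rng.integers(n))
    return text[:i] + "abcdefghijklmnopqrstuvwxyz"[rng.integers(26)] + text[i + 1 :]


def _case_noise(rng: np.random.Generator, text: str) -> str:
    mode = rng.integers(3)
    if mode == 0:
        return text.upper()
    if mode == 1:
        return text.capitalize()
    return "".join(c.upper() if rng.random() < 0.5 else c for c in text)


def generate_corpus(spec: NoiseSpec, registry: ValueSetRegistry) -> list[LabeledRecord]:
    """Draw a labeled corpus under the spec's noise model.

    Per record: sample a category (``category_mix``) and a test of that
    category, then a canonical value from the test's heavy-tailed weights;
    render a surface notation (label, abbreviation, or graded form); attach a
    numeric concentration prefix/suffix with probability ``prefix_rate``
    (urine dipstick and presence-finding forms only); corrupt with one typo at
    ``typo_rate`` and case noise at ``case_noise_rate``. With probability
    ``junk_rate`` the record is an uninterpretable string labeled JUNK.
    """
    rng = np.random.default_rng(spec.seed)
    categories = [c for c, w in spec.category_mix.items() if w > 0]
    cat_w = np.array([spec.category_mix[c] for c in categories], dtype=float)
    cat_w /= cat_w.sum()
    for cat in categories:
        if cat not in _TESTS:
            raise ValueError(f"category_mix names unsupported category {cat}")
        for test_values in _TESTS[cat].values():
            for label in test_values:
                registry.get(cat, label)  # labels must exist in the registry

    records: list[LabeledRecord] = []
    for _ in range(spec.n_records):
        cat = categories[rng.choice(len(categories), p=cat_w)]
        tests = _TESTS[cat]
        test_id = list(tests)[rng.integers(len(tests))]
        if rng.random() < spec.junk_rate:
            raw = _JUNK_POOL[rng.integers(len(_JUNK_POOL))]
            records.append(LabeledRecord(test_id, raw, cat, JUNK))
            continue
        label = _choice(rng, tests[test_id])
        surface = _choice(rng, _SURFACES[label]) if label in _SURFACES else label
        if rng.random() < spec.prefix_rate:
            if cat is Category.URINE_DIPSTICK and label in _CONC_PREFIX:
                pool = _CONC_PREFIX[label]
                surface = f"{pool[rng.integers(len(pool))]} {surface}"
            elif cat is Category.PRESENCE_FINDING:
                surface = f"{surface} {_PRESENCE_SUFFIX[rng.integers(len(_PRESENCE_SUFFIX))]}"
        if rng.random() < spec.typo_rate:
            surface = _apply_typo(rng, surface, spec.typo_ops)
        if rng.random() < spec.case_noise_rate:
            surface = _case_noise(rng, surface)
        records.append(LabeledRecord(test_id, surface, cat, label))
    return records


@dataclass(frozen=True)
class AccuracyReport:
    """Mapping accuracy at the two validation granularities.

    Values the algorithm routed to manual review (unmapped, but not junk) are
    not automatic mapping decisions; they are excluded from the accuracy
    denominators and reported separately as review counts, following the
    validation convention of excluding data the mapper declined to interpret.
    Junk values count as correct when left unmapped and as errors when mapped.
    """

    value_level: float
    data_level: float
    n_values: int
    n_records: int
    n_review_values: int
    n_review_records: int
    by_category: dict[str, dict[str, float]]

    def to_dict(self) -> dict:
        return {
            "value_level": self.value_level,
            "data_level": self.data_level,
            "n_values": self.n_values,
            "n_records": self.n_records,
            "n_review_values": self.n_review_values,
            "n_review_records": self.n_review_records,
            "by_category": self.by_category,
        }


def _outcome(true_label: str, pred: MappedRecord) -> bool | None:
    """True/False for a scored decision, None for a manual-review abstention."""
    if true_label == JUNK:
        return pred.unmapped
    if pred.unmapped:
        return None
    return pred.mapped_label == true_label


def _accuracy(outcomes: Sequence[bool | None]) -> float:
    scored = [o for o in outcomes if o is not None]
    return float(np.mean(scored)) if scored else float("nan")


def score_mapping(
    truth: Sequence[LabeledRecord], predicted: Sequence[MappedRecord]
) -> AccuracyReport:
    """Score predictions against ground truth, per record and per distinct value.

    ``predicted`` must align with ``truth`` record-for-record (same order and
    keys). Data-level accuracy is the fraction of correct records among the
    scored ones. Value-level accuracy is computed over distinct (test, raw
    value) pairs; when corruption makes one surface string arise from
    different canonical values, the value's truth is the majority label of its
    records (first-seen on ties), mirroring per-unique-value human
    adjudication. Non-junk values left unmapped (fully tied, zero vector,
    below a score floor, unclassified test) are abstentions: counted in the
    review totals, excluded from accuracy.
    """
    if len(truth) != len(predicted):
        raise ValueError(
            f"truth has {len(truth)} records but predictions have {len(predicted)}"
        )
    for t, p in zip(truth, predicted):
        if t.test_id != p.test_id or t.raw_value != p.raw_value:
            raise ValueError(
                f"record mismatch: truth ({t.test_id!r}, {t.raw_value!r}) vs "
                f"prediction ({p.test_id!r}, {p.raw_value!r})"
            )

    rec_outcomes: list[bool | None] = []
    by_cat_records: dict[str, list[bool | None]] = defaultdict(list)
    labels: dict[tuple[str, str], Counter] = defaultdict(Counter)
    preds: dict[tuple[str, str], MappedRecord] = {}
    cat_of_value: dict[tuple[str, str], str] = {}
    for t, p in zip(truth, predicted):
        o = _outcome(t.true_label, p)
        rec_outcomes.append(o)
        by_cat_records[t.true_category.value].append(o)
        key = (t.test_id, t.raw_value)
        labels[key][t.true_label] += 1
        preds[key] = p
        cat_of_value.setdefault(key, t.true_category.value)

    val_outcomes: list[bool | None] = []
    by_cat_values: dict[str, list[bool | None]] = defaultdict(list)
    for key, counter in labels.items():
        majority = counter.most_common(1)[0][0]
        o = _outcome(majority, preds[key])
        val_outcomes.append(o)
        by_cat_values[cat_of_value[key]].append(o)

    by_category = {
        cat: {
            "value_level": _accuracy(by_cat_values[cat]),
            "data_level": _accuracy(by_cat_records[cat]),
            "n_values": len(by_cat_values[cat]),
            "n_records": len(by_cat_records[cat]),
            "n_review_values": sum(o is None for o in by_cat_values[cat]),
            "n_review_records": sum(o is None for o in by_cat_records[cat]),
        }
        for cat in by_cat_records
    }
    return AccuracyReport(
        value_level=_accuracy(val_outcomes),
        data_level=_accuracy(rec_outcomes),
        n_values=len(labels),
        n_records=len(truth),
        n_review_values=sum(o is None for o in val_outcomes),
        n_review_records=sum(o is None for o in rec_outcomes),
        by_category=by_category,
    )
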