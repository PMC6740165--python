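"""CSV ingestion/emission and run configuration for the standardization pipeline.

The interchange format is plain UTF-8 comma-separated values with a mandatory
header and minimal quoting. Empty result cells are preserved as empty strings
(they are meaningful: an empty value is unmappable junk, not a missing row).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .distribution import DistributionTable, MainValueSet
from .matcher import DEFAULT_BLOOD_TYPE_PATTERNS, MappedRecord
from .synthetic import LabeledRecord
from .valuesets import Category

__all__ = [
    "RawResult",
    "RunConfig",
    "ColumnError",
    "read_results",
    "write_mapped",
    "read_mapped",
    "write_profile",
    "write_corpus",
    "read_corpus",
]

logger = logging.getLogger("saltc")

MAPPED_COLUMNS = [
    "test_id", "raw_value", "clean_value", "category", "mapped_label",
    "snomed_id", "cosine_score", "euclidean_distance", "method", "unmapped", "reason",
]

CORPUS_COLUMNS = ["test_id", "raw_value", "true_category", "true_label"]


class ColumnError(ValueError):
    """A configured column is missing from the input file."""


@dataclass(frozen=True)
class RawResult:
    """One (test identifier, free-text result value) input record."""

    test_id: str
    value: str
    row: int | None = None  # 1-based data row in the source file, for error context


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one standardization run."""

    input: Path
    output: Path
    test_col: str = "test_id"
    value_col: str = "value"
    measure: str = "hybrid"
    threshold: float = 0.995
    min_distinct: int = 5
    registry_path: Path | None = None
    group_blood_variants: bool = False
    min_cosine: float | None = None
    coverage_cutoff: float | None = None
    blood_type_patterns: tuple[str, ...] = DEFAULT_BLOOD_TYPE_PATTERNS
    log_level: str = "WARNING"
    seed: int | None = None


def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    return pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")


def read_results(
    path: str | Path, test_col: str = "test_id", value_col: str = "value"
) -> list[RawResult]:
    """Read raw results from CSV; empty cells come back as empty strings."""
    df = _read_csv(path)
    for col in (test_col, value_col):
        if col not in df.columns:
            raise ColumnError(
                f"column '{col}' not found in {path} (has: {', '.join(df.columns)})"
            )
    return [
        RawResult(str(t), str(v), row=i + 1)
        for i, (t, v) in enumerate(zip(df[test_col], df[value_col]))
    ]


def write_mapped(results: Sequence[MappedRecord], path: str | Path) -> None:
    """Write per-record mapping output; header always present."""
    rows = [
        {
            "test_id": r.test_id,
            "raw_value": r.raw_value,
            "clean_value": r.clean_value,
            "category": r.category.value,
            "mapped_label": "" if r.mapped_label is None else r.mapped_label,
            "snomed_id": "" if r.snomed_id is None else r.snomed_id,
            "cosine_score": "" if r.cosine_score is None else repr(r.cosine_score),
            "euclidean_distance": ""
            if r.euclidean_distance is None
            else repr(r.euclidean_distance),
            "method": r.method,
            "unmapped": str(r.unmapped).lower(),
            "reason": "" if r.reason is None else r.reason,
        }
        for r in results
    ]
    pd.DataFrame(rows, columns=MAPPED_COLUMNS).to_csv(path, index=False, encoding="utf-8")


def read_mapped(path: str | Path) -> list[MappedRecord]:
    """Read a mapped-output CSV back into records (inverse of ``write_mapped``)."""
    df = _read_csv(path)
    missing = [c for c in MAPPED_COLUMNS if c not in df.columns]
    if missing:
        raise ColumnError(f"{path} is not a mapped-output file; missing {missing}")
    out = []
    for rec in df.to_dict("records"):
        out.append(
            MappedRecord(
                test_id=rec["test_id"],
                raw_value=rec["raw_value"],
                clean_value=rec["clean_value"],
                category=Category(rec["category"]),
                mapped_label=rec["mapped_label"] or None,
                snomed_id=rec["snomed_id"] or None,
                cosine_score=float(rec["cosine_score"]) if rec["cosine_score"] else None,
                euclidean_distance=float(rec["euclidean_distance"])
                if rec["euclidean_distance"]
                else None,
                method=rec["method"],
                unmapped=rec["unmapped"] == "true",
                reason=rec["reason"] or None,
            )
        )
    return out


def write_profile(
    tables: dict[str, DistributionTable],
    main_values: dict[str, MainValueSet],
    path: str | Path,
) -> None:
    """Emit distribution tables with an is_main_value flag."""
    rows = []
    for test_id, table in tables.items():
        main = set(main_values[test_id].values) if test_id in main_values else set()
        for r in table.rows:
            rows.append(
                {
                    "test_id": test_id,
                    "value": r.value,
                    "count": r.count,
                    "rel_freq": r.rel_freq,
                    "cum_freq": r.cum_freq,
                    "is_main_value": str(r.value in main).lower(),
                }
            )
    pd.DataFrame(
        rows, columns=["test_id", "value", "count", "rel_freq", "cum_freq", "is_main_value"]
    ).to_csv(path, index=False, encoding="utf-8")


def write_corpus(records: Sequence[LabeledRecord], path: str | Path) -> None:
    """Write a labeled synthetic corpus."""
    pd.DataFrame(
        [
            {
                "test_id": r.test_id,
                "raw_value": r.raw_value,
                "true_category": r.true_category.value,
                "true_label": r.true_label,
            }
            for r in records
        ],
        columns=CORPUS_COLUMNS,
    ).to_csv(path, index=False, encoding="utf-8")


def read_corpus(path: str | Path) -> list[LabeledRecord]:
    """Read a labeled synthetic corpus written by ``write_corpus``."""
    df = _read_csv(path)
    missing = [c for c in CORPUS_COLUMNS if c not in df.columns]
    if missing:
        raise ColumnError(f"{path} is not a corpus file; missing {missing}")
    return [
        LabeledRecord(
            test_id=rec["test_id"],
            raw_value=rec["raw_value"],
            true_category=Category(rec["true_category"]),
            true_label=rec["true_label"],
        )
        for rec in df.to_dict("records")
    ]
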