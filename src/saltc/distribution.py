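"""Per-test frequency distributions and main-value extraction.

Categorical laboratory results are heavily skewed: each test has a handful of
dominant canonical notations and a long tail of typos and one-off junk. The
categorizer therefore only looks at a test's *main values* — the shortest
descending-frequency prefix of its distribution whose cumulative relative
frequency first reaches the coverage threshold (default 99.5%). Tests with
fewer than ``min_distinct`` (default 5) distinct values keep all of them,
since a too-small main-value set starves the categorizer of evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import pandas as pd

from .preprocess import CleanValue

__all__ = ["DistRow", "DistributionTable", "MainValueSet", "build_distribution", "extract_main_values"]

#: absolute slack when comparing cumulative frequencies with the threshold,
#: guarding against float round-off on count ratios
_EPS = 1e-9


class DistRow(NamedTuple):
    value: str
    count: int
    rel_freq: float
    cum_freq: float


@dataclass(frozen=True)
class DistributionTable:
    """Descending-frequency table of one test's distinct (cleaned) values.

    Rows are sorted by count descending, ties broken lexicographically by
    value so the table is a pure function of the input multiset.
    """

    test_id: str
    rows: tuple[DistRow, ...]

    @property
    def total(self) -> int:
        return sum(r.count for r in self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=DistRow._fields)


@dataclass(frozen=True)
class MainValueSet:
    """The representative values of one test, in distribution order."""

    test_id: str
    values: tuple[str, ...]


def _text(value: str | CleanValue) -> str:
    return value.text if isinstance(value, CleanValue) else value


def build_distribution(
    records: Iterable[tuple[str, str | CleanValue]],
) -> dict[str, DistributionTable]:
    """Count value multiplicities per test and rank them.

    ``records`` is any iterable of ``(test_id, value)`` pairs; an empty input
    yields an empty dict. Output order of rows is deterministic regardless of
    input order.
    """
    pairs = [(test_id, _text(value)) for test_id, value in records]
    if not pairs:
        return {}
    df = pd.DataFrame(pairs, columns=["test_id", "value"])
    tables: dict[str, DistributionTable] = {}
    for test_id, group in df.groupby("test_id", sort=False):
        counts = (
            group.groupby("value", sort=False)
            .size()
            .reset_index(name="count")
            .sort_values(["count", "value"], ascending=[False, True], kind="mergesort")
        )
        total = int(counts["count"].sum())
        rel = counts["count"] / total
        cum = rel.cumsum()
        rows = tuple(
            DistRow(v, int(c), float(r), float(q))
            for v, c, r, q in zip(counts["value"], counts["count"], rel, cum)
        )
        tables[str(test_id)] = DistributionTable(str(test_id), rows)
    return tables


def extract_main_values(
    table: DistributionTable,
    threshold: float = 0.995,
    min_distinct: int = 5,
) -> MainValueSet:
    """Shortest top-frequency prefix covering ``threshold`` of the records.

    If the table has fewer than ``min_distinct`` distinct values, all values
    are returned. ``threshold`` must lie in (0, 1].
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if len(table.rows) < min_distinct:
        return MainValueSet(table.test_id, tuple(r.value for r in table.rows))
    values: list[str] = []
    for row in table.rows:
        values.append(row.value)
        if row.cum_freq >= threshold - _EPS:
            break
    return MainValueSet(table.test_id, tuple(values))
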