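"""Incremental source attribution, prevalence, rounding, and source overlap.

Sources are applied in decreasing order of reliability; each source's
*incremental* contribution is the set of persons it adds beyond every more
reliable source already applied, and the *cumulative* count is the size of
the running union.  Frequency counts are reported rounded to the nearest 5
(the claims-database disclosure convention), but raw counts are carried
everywhere and rounding is applied only at report time: rounded incrementals
may therefore sum a few units away from rounded cumulatives, which is
expected rounding drift, not an error.

Prevalence is the cumulative count over the bundle denominator, as a
percentage rounded half-up to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .selection import SUB_SOURCE_LABELS, SelectionResult

__all__ = [
    "AttributionRow",
    "AttributionResult",
    "VennPartition",
    "attribute_incremental",
    "round_to_nearest_5",
    "prevalence_pct",
    "venn_partition",
    "multi_source_rates",
    "DEFAULT_ORDER",
]

#: default reliability order of the ten sub-sources (report row order)
DEFAULT_ORDER = list(SUB_SOURCE_LABELS)


def round_to_nearest_5(n: int) -> int:
    """The multiple of 5 nearest to ``n`` (remainder 2 rounds down, 3 up)."""
    if n < 0:
        raise ValueError(f"count must be non-negative, got {n}")
    return (int(n) + 2) // 5 * 5


def prevalence_pct(count: int, denominator: int) -> float:
    """``100 * count / denominator`` as a percentage, half-up to 2 decimals."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if count > denominator:
        raise ValueError("count exceeds denominator")
    pct = Decimal(100 * count) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AttributionRow:
    source_label: str
    incremental_ids: frozenset
    incremental_count_raw: int
    incremental_count_rounded: int
    cumulative_count_raw: int
    cumulative_count_rounded: int
    cumulative_prevalence_pct: float


@dataclass(frozen=True)
class AttributionResult:
    rows: tuple[AttributionRow, ...]
    denominator_count: int

    def to_frame(self) -> pd.DataFrame:
        """Report-shaped table (one row per source, raw and rounded counts)."""
        return pd.DataFrame(
            [
                {
                    "source": r.source_label,
                    "incremental_count": r.incremental_count_raw,
                    "incremental_count_rounded": r.incremental_count_rounded,
                    "cumulative_count": r.cumulative_count_raw,
                    "cumulative_count_rounded": r.cumulative_count_rounded,
                    "cumulative_prevalence_pct": r.cumulative_prevalence_pct,
                }
                for r in self.rows
            ]
        )


def attribute_incremental(
    selection: SelectionResult, order: list[str] | None = None
) -> AttributionResult:
    """Incremental/cumulative attribution over sub-sources in the given order.

    ``order`` must be a permutation of a subset of the sub-source labels;
    by default all ten, most reliable first.  The k-th incremental set is the
    k-th source minus the union of all earlier sources, so incremental sets
    are pairwise disjoint and their union is the union of all sources; the
    final cumulative count is invariant under reordering.
    """
    order = list(DEFAULT_ORDER) if order is None else list(order)
    sets = selection.sets()
    unknown = [lab for lab in order if lab not in sets]
    if unknown:
        raise KeyError(f"unknown source label(s): {unknown}")
    if len(set(order)) != len(order):
        raise ValueError("duplicate source label in order")

    denom = selection.denominator_count
    rows = []
    seen: frozenset = frozenset()
    for label in order:
        incremental = sets[label] - seen
        seen = seen | sets[label]
        rows.append(
            AttributionRow(
                source_label=label,
                incremental_ids=incremental,
                incremental_count_raw=len(incremental),
                incremental_count_rounded=round_to_nearest_5(len(incremental)),
                cumulative_count_raw=len(seen),
                cumulative_count_rounded=round_to_nearest_5(len(seen)),
                cumulative_prevalence_pct=(
                    prevalence_pct(len(seen), denom) if denom else float("nan")
                ),
            )
        )
    return AttributionResult(rows=tuple(rows), denominator_count=denom)


@dataclass(frozen=True)
class VennPartition:
    """Exact region counts of a three-set system plus the multi-source fraction."""

    a_only: int
    b_only: int
    c_only: int
    ab_only: int
    ac_only: int
    bc_only: int
    abc: int

    @property
    def union_size(self) -> int:
        return (
            self.a_only + self.b_only + self.c_only
            + self.ab_only + self.ac_only + self.bc_only + self.abc
        )

    @property
    def multi_source_count(self) -> int:
        return self.ab_only + self.ac_only + self.bc_only + self.abc

    @property
    def multi_source_fraction(self) -> float:
        if self.union_size == 0:
            return float("nan")
        return self.multi_source_count / self.union_size

    def to_dict(self) -> dict[str, int]:
        return {
            "A_only": self.a_only,
            "B_only": self.b_only,
            "C_only": self.c_only,
            "A&B_only": self.ab_only,
            "A&C_only": self.ac_only,
            "B&C_only": self.bc_only,
            "A&B&C": self.abc,
        }


def venn_partition(a: frozenset, b: frozenset, c: frozenset) -> VennPartition:
    """Counts of the 7 regions of three sets, by exact set algebra."""
    a, b, c = frozenset(a), frozenset(b), frozenset(c)
    abc = a & b & c
    return VennPartition(
        a_only=len(a - b - c),
        b_only=len(b - a - c),
        c_only=len(c - a - b),
        ab_only=len((a & b) - abc),
        ac_only=len((a & c) - abc),
        bc_only=len((b & c) - abc),
        abc=len(abc),
    )


def multi_source_rates(selection: SelectionResult) -> dict[str, float | None]:
    """Per-method fraction also selected by at least one of the other two
    methods, over the aggregate A / B(2-year) / C(5-year history) sets.
    ``None`` for an empty method set (rate undefined)."""
    m = selection.method_sets()
    sets = {"A": m["A"], "B": m["B"], "C": m["C"]}
    rates: dict[str, float | None] = {}
    for name, s in sets.items():
        others = frozenset().union(*(v for k, v in sets.items() if k != name))
        rates[name] = len(s & others) / len(s) if s else None
    return rates
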