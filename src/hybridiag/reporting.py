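"""Summary tables of classification results.

Aggregates per-sample classifications into per-group (typically
per-institution) category counts and hybrid percentages, plus global
headline percentages (overall hybrid fraction, post-F1 share among
hybrids).  Percentages are kept at full precision internally and rendered
half-up to 2 decimals, with integer-valued percentages rendered without
decimals.  UNRESOLVED samples are counted and shown in their own column but
excluded from hybrid-percentage denominators, never silently merged.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

from .classifier import Category, Classification
from .errors import HybridiagError
from .genotype_io import SampleRecord


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    n_pure: int
    n_f1: int
    n_postf1: int
    n_unresolved: int

    @property
    def n_hybrid(self) -> int:
        return self.n_f1 + self.n_postf1

    @property
    def percent_hybrids(self) -> float | None:
        """100 x hybrids / resolved samples; None when nothing resolved."""
        resolved = self.n - self.n_unresolved
        return 100.0 * self.n_hybrid / resolved if resolved else None


@dataclass(frozen=True)
class SummaryTable:
    """Per-group category counts plus global percentage rows."""

    groups: tuple[GroupSummary, ...]
    group_by: str = "source"

    @property
    def total(self) -> GroupSummary:
        return GroupSummary(
            group="TOTAL",
            n=sum(g.n for g in self.groups),
            n_pure=sum(g.n_pure for g in self.groups),
            n_f1=sum(g.n_f1 for g in self.groups),
            n_postf1=sum(g.n_postf1 for g in self.groups),
            n_unresolved=sum(g.n_unresolved for g in self.groups))

    def _pct(self, count: int) -> float | None:
        t = self.total
        resolved = t.n - t.n_unresolved
        return 100.0 * count / resolved if resolved else None

    @property
    def percent_pure(self) -> float | None:
        return self._pct(self.total.n_pure)

    @property
    def percent_f1(self) -> float | None:
        return self._pct(self.total.n_f1)

    @property
    def percent_postf1(self) -> float | None:
        return self._pct(self.total.n_postf1)

    @property
    def percent_hybrids(self) -> float | None:
        return self._pct(self.total.n_hybrid)

    @property
    def percent_postf1_among_hybrids(self) -> float | None:
        h = self.total.n_hybrid
        return 100.0 * self.total.n_postf1 / h if h else None


def summarize(classified: Sequence[tuple[SampleRecord, Classification]],
              group_by: str = "source") -> SummaryTable:
    """Tabulate classifications per group (any SampleRecord field).

    Groups appear in order of first occurrence; an empty input yields an
    empty table (no percentage rows), not an error.
    """
    pairs = []
    for rec, cls in classified:
        if not hasattr(rec, group_by):
            raise HybridiagError(f"no such grouping field: {group_by!r}")
        value = getattr(rec, group_by)
        pairs.append(("?" if value is None else str(value), cls.category))
    return summarize_pairs(pairs, group_by=group_by)


def summarize_pairs(pairs: Sequence[tuple[str, Category]],
                    group_by: str = "source") -> SummaryTable:
    """Tabulate (group value, category) pairs; backs both API and CLI paths."""
    order: list[str] = []
    counts: dict[str, dict[Category, int]] = {}
    for group, category in pairs:
        if group not in counts:
            order.append(group)
            counts[group] = {c: 0 for c in Category}
        counts[group][category] += 1
    groups = tuple(
        GroupSummary(group=g,
                     n=sum(counts[g].values()),
                     n_pure=counts[g][Category.PURE],
                     n_f1=counts[g][Category.F1_HYBRID],
                     n_postf1=counts[g][Category.POST_F1_HYBRID],
                     n_unresolved=counts[g][Category.UNRESOLVED])
        for g in order)
    return SummaryTable(groups=groups, group_by=group_by)


def format_percent(value: float | None) -> str:
    """Render a percentage half-up to 2 decimals; integers without decimals."""
    if value is None:
        return ""
    q = Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    if q == q.to_integral_value():
        return str(int(q))
    return str(q)


_COLUMNS = ["n", "pure", "f1", "post_f1", "unresolved", "percent_hybrids"]
_GLOBAL_ROWS = [
    ("percent_pure", lambda t: t.percent_pure),
    ("percent_f1", lambda t: t.percent_f1),
    ("percent_postf1", lambda t: t.percent_postf1),
    ("percent_hybrids", lambda t: t.percent_hybrids),
    ("percent_postf1_among_hybrids", lambda t: t.percent_postf1_among_hybrids),
]


def _rows(table: SummaryTable) -> list[list[str]]:
    rows = []
    entries = list(table.groups) + ([table.total] if table.groups else [])
    for g in entries:
        rows.append([g.group, str(g.n), str(g.n_pure), str(g.n_f1),
                     str(g.n_postf1), str(g.n_unresolved),
                     format_percent(g.percent_hybrids)])
    return rows


def render_summary(table: SummaryTable, format: str = "csv") -> str:
    """Render the summary as ``csv`` or ``markdown`` text.

    Both formats carry identical numeric strings: the per-group count table
    (with a TOTAL row), a blank line, then the global percentage rows as
    metric,value pairs.  Byte-stable across runs.
    """
    header = [table.group_by] + _COLUMNS
    rows = _rows(table)
    globals_ = ([(name, format_percent(fn(table))) for name, fn in _GLOBAL_ROWS]
                if table.groups else [])

    if format == "csv":
        import csv as _csv

        buf = io.StringIO()
        w = _csv.writer(buf, lineterminator="\n")
        w.writerow(header)
        w.writerows(rows)
        if globals_:
            buf.write("\n")
            w.writerow(["metric", "value"])
            w.writerows(globals_)
        return buf.getvalue()

    if format == "markdown":
        def md_table(hdr, body):
            lines = ["| " + " | ".join(hdr) + " |",
                     "| " + " | ".join("---" for _ in hdr) + " |"]
            lines += ["| " + " | ".join(r) + " |" for r in body]
            return "\n".join(lines) + "\n"

        out = md_table(header, rows)
        if globals_:
            out += "\n" + md_table(["metric", "value"], list(globals_))
        return out

    raise HybridiagError(f"unknown summary format {format!r}")
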