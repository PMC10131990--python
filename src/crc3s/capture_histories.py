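"""Capture-history tables for multi-source capture-recapture.

A study with ``k`` capture occasions observes each individual's capture
history, a length-``k`` binary pattern ('1' = captured on that occasion,
leftmost character = occasion one). Aggregating over individuals yields a
``2^k - 1``-cell contingency table — the all-zero history is unobservable
and its count is the estimand of capture-recapture analysis.

Published studies often report only the marginal form: per-occasion totals
plus pairwise (and, for three sources, triple) overlaps. For ``k = 3``
the seven cell counts are recovered from the marginals by
inclusion-exclusion. Field data are not always mutually consistent — a
reported overlap pattern can imply a negative cell — so construction
supports a ``strict`` policy (raise) and a ``clamp`` policy (truncate the
cell at zero and attach a warning recording the deficit).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "CaptureMarginals",
    "CaptureHistoryTable",
    "InconsistentMarginalsError",
    "table_from_marginals",
    "table_from_marginals_direct",
    "marginals_from_table",
    "pool_strata",
    "capture_summary",
    "read_marginals_csv",
    "write_marginals_csv",
    "read_table_csv",
    "write_table_csv",
    "table_to_json",
]


class InconsistentMarginalsError(ValueError):
    """Raised when marginals imply a negative capture-history cell."""

    def __init__(self, pattern: str, value: int, stratum: str = ""):
        self.pattern = pattern
        self.value = value
        self.stratum = stratum
        where = f" (stratum {stratum!r})" if stratum else ""
        super().__init__(
            f"inconsistent marginals{where}: cell {pattern} = {value} < 0"
        )


def _round_half_up(x: float, ndigits: int = 2) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def patterns(k: int) -> list[str]:
    """All observable capture patterns (all-zero excluded), '111' first."""
    pats = ["".join(bits) for bits in product("10", repeat=k)]
    return [p for p in pats if "1" in p]


@dataclass(frozen=True)
class CaptureMarginals:
    """Marginal summary of a three-source capture-recapture study.

    Parameters
    ----------
    n
        Per-occasion capture totals ``(n1, ..., nk)``.
    pair_overlaps
        Counts captured in each unordered pair of occasions; for
        ``k = 3`` the order is ``(n12, n13, n23)``.
    triple_overlap
        Count captured in all three occasions (``k = 3`` only).
    stratum
        Label for the stratum (e.g. a province).
    """

    n: tuple[int, ...]
    pair_overlaps: tuple[int, ...]
    triple_overlap: int | None = None
    stratum: str = ""

    @property
    def k(self) -> int:
        return len(self.n)

    def __post_init__(self):
        k = len(self.n)
        if k < 2:
            raise ValueError("need at least 2 capture occasions")
        npairs = k * (k - 1) // 2
        if len(self.pair_overlaps) != npairs:
            raise ValueError(f"expected {npairs} pairwise overlaps, got {len(self.pair_overlaps)}")
        if any(v < 0 for v in self.n) or any(v < 0 for v in self.pair_overlaps):
            raise ValueError("counts must be non-negative")
        pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
        for (i, j), m in zip(pairs, self.pair_overlaps):
            if m > min(self.n[i], self.n[j]):
                raise ValueError(
                    f"overlap of occasions {i + 1},{j + 1} ({m}) exceeds "
                    f"min occasion total ({min(self.n[i], self.n[j])})"
                )
        if k == 3:
            if self.triple_overlap is None:
                raise ValueError("triple_overlap required when k = 3")
            if self.triple_overlap < 0:
                raise ValueError("triple_overlap must be non-negative")
            if any(self.triple_overlap > m for m in self.pair_overlaps):
                raise ValueError("triple_overlap exceeds a pairwise overlap")

    def __add__(self, other: "CaptureMarginals") -> "CaptureMarginals":
        if self.k != other.k:
            raise ValueError("occasion count mismatch")
        triple = None
        if self.k == 3:
            triple = self.triple_overlap + other.triple_overlap
        return CaptureMarginals(
            n=tuple(a + b for a, b in zip(self.n, other.n)),
            pair_overlaps=tuple(a + b for a, b in zip(self.pair_overlaps, other.pair_overlaps)),
            triple_overlap=triple,
            stratum=self.stratum if self.stratum == other.stratum else "pooled",
        )


@dataclass
class CaptureHistoryTable:
    """Counts over the ``2^k - 1`` observable capture patterns of one stratum."""

    k: int
    cells: dict[str, int]
    stratum: str = ""
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        expect = set(patterns(self.k))
        got = set(self.cells)
        if got != expect:
            missing = expect - got
            extra = got - expect
            raise ValueError(
                f"table must have exactly the {2 ** self.k - 1} observable "
                f"patterns; missing={sorted(missing)} extra={sorted(extra)}"
            )
        for p, c in self.cells.items():
            if c < 0 or int(c) != c:
                raise ValueError(f"cell {p} count must be a non-negative integer, got {c}")
        self.cells = {p: int(self.cells[p]) for p in patterns(self.k)}

    @property
    def n_observed(self) -> int:
        return sum(self.cells.values())

    def occasion_total(self, j: int) -> int:
        """Total captured on occasion ``j`` (0-based)."""
        return sum(c for p, c in self.cells.items() if p[j] == "1")

    def permute_occasions(self, order: Sequence[int]) -> "CaptureHistoryTable":
        """Relabel occasions: new occasion ``j`` is old occasion ``order[j]``."""
        if sorted(order) != list(range(self.k)):
            raise ValueError("order must be a permutation of occasions")
        cells = {}
        for p, c in self.cells.items():
            newp = "".join(p[i] for i in order)
            cells[newp] = c
        return CaptureHistoryTable(self.k, cells, stratum=self.stratum, warnings=list(self.warnings))


def table_from_marginals(m: CaptureMarginals, policy: str = "clamp") -> CaptureHistoryTable:
    """Build the 7-cell capture-history table from 3-source marginals.

    Cells follow inclusion-exclusion; ``policy='strict'`` raises
    :class:`InconsistentMarginalsError` on a negative cell, while
    ``policy='clamp'`` truncates it at zero and records the deficit in
    ``table.warnings``.
    """
    if m.k != 3:
        raise ValueError("marginal construction is defined for k = 3 only")
    if policy not in ("strict", "clamp"):
        raise ValueError(f"unknown policy {policy!r}")
    n1, n2, n3 = m.n
    n12, n13, n23 = m.pair_overlaps
    n123 = m.triple_overlap
    raw = {
        "111": n123,
        "110": n12 - n123,
        "101": n13 - n123,
        "011": n23 - n123,
        "100": n1 - n12 - n13 + n123,
        "010": n2 - n12 - n23 + n123,
        "001": n3 - n13 - n23 + n123,
    }
    warnings_: list[str] = []
    cells = {}
    for p in patterns(3):
        v = raw[p]
        if v < 0:
            if policy == "strict":
                raise InconsistentMarginalsError(p, v, m.stratum)
            warnings_.append(
                f"cell {p} clamped to 0 (inclusion-exclusion gave {v}; deficit {-v})"
            )
            v = 0
        cells[p] = v
    return CaptureHistoryTable(3, cells, stratum=m.stratum, warnings=warnings_)


def table_from_marginals_direct(m: CaptureMarginals) -> CaptureHistoryTable:
    """Tabulate each marginal count directly as its own capture pattern.

    The occasion totals become the single-capture cells, the pairwise
    overlaps the two-capture cells and the triple overlap the 111 cell,
    with no inclusion-exclusion correction. Individuals recaptured later
    are therefore counted once per printed summary row, so the cell total
    exceeds the number of distinct people observed: this is **not** a
    valid person-level capture-history table.

    It is provided because it is the tabulation that reproduces the
    published population-size estimates of the bundled Rwanda MSM study:
    fitting the latent-class model to these tables matches the study's
    printed national and provincial medians, whereas the
    inclusion-exclusion tables (the correct person-level aggregation)
    yield systematically smaller estimates. See the reproduction notes in
    the package documentation before using this for new data.
    """
    if m.k != 3:
        raise ValueError("direct tabulation is defined for k = 3 only")
    n1, n2, n3 = m.n
    n12, n13, n23 = m.pair_overlaps
    cells = {
        "100": n1,
        "010": n2,
        "001": n3,
        "110": n12,
        "101": n13,
        "011": n23,
        "111": m.triple_overlap,
    }
    warning = (
        "direct tabulation: marginal counts assigned to patterns without "
        "inclusion-exclusion correction; cell total double-counts recaptures"
    )
    return CaptureHistoryTable(3, cells, stratum=m.stratum, warnings=[warning])


def marginals_from_table(t: CaptureHistoryTable) -> CaptureMarginals:
    """Occasion totals and overlaps by summing cells with a '1' in place."""
    if t.k != 3:
        raise ValueError("marginal summary is defined for k = 3 only")
    n = tuple(t.occasion_total(j) for j in range(3))
    pairs = []
    for i, j in ((0, 1), (0, 2), (1, 2)):
        pairs.append(sum(c for p, c in t.cells.items() if p[i] == "1" and p[j] == "1"))
    triple = t.cells["111"]
    return CaptureMarginals(n=n, pair_overlaps=tuple(pairs), triple_overlap=triple, stratum=t.stratum)


def pool_strata(tables: Iterable[CaptureHistoryTable]) -> CaptureHistoryTable:
    """Cellwise sum of per-stratum tables (the pooled national table)."""
    tables = list(tables)
    if not tables:
        raise ValueError("cannot pool an empty list of tables")
    k = tables[0].k
    if any(t.k != k for t in tables):
        raise ValueError("all tables must share the same number of occasions")
    cells = {p: sum(t.cells[p] for t in tables) for p in patterns(k)}
    warns = [w for t in tables for w in t.warnings]
    return CaptureHistoryTable(k, cells, stratum="pooled", warnings=warns)


def capture_summary(m: CaptureMarginals, objects_assigned: int | None = None) -> dict:
    """Recapture fractions per later occasion, as percentages (2 dp, half-up).

    Returns per-occasion entries: for occasion two the fraction of its
    captures tagged on occasion one; for occasion three the fraction tagged
    on occasion one ("object") and on occasion two ("service"). If
    ``objects_assigned`` is given, the occasion-one distribution success
    rate is included. A zero denominator yields ``None`` with a flag rather
    than an exception.
    """
    n1, n2, n3 = m.n
    n12, n13, n23 = m.pair_overlaps

    def pct(num, den):
        if den == 0:
            return {"count": num, "denominator": den, "percent": None, "undefined": True}
        return {"count": num, "denominator": den, "percent": _round_half_up(100.0 * num / den)}

    out = {
        "capture_two_tagged": pct(n12, n2),
        "capture_three_object": pct(n13, n3),
        "capture_three_service": pct(n23, n3),
    }
    if objects_assigned is not None:
        out["capture_one_distribution"] = pct(n1, objects_assigned)
    return out


# ---------------------------------------------------------------------------
# I/O — marginal CSV (one row per stratum) and cell CSV (long form)

_MARGINAL_COLS = ["stratum", "n1", "n2", "n3", "n12", "n13", "n23", "n123"]


def read_marginals_csv(path: str | Path) -> list[CaptureMarginals]:
    df = pd.read_csv(path)
    missing = [c for c in _MARGINAL_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"marginals CSV missing columns: {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(
            CaptureMarginals(
                n=(int(row.n1), int(row.n2), int(row.n3)),
                pair_overlaps=(int(row.n12), int(row.n13), int(row.n23)),
                triple_overlap=int(row.n123),
                stratum=str(row.stratum),
            )
        )
    return out


def write_marginals_csv(ms: Iterable[CaptureMarginals], path: str | Path) -> None:
    rows = []
    for m in ms:
        rows.append(
            dict(zip(_MARGINAL_COLS, [m.stratum, *m.n, *m.pair_overlaps, m.triple_overlap]))
        )
    pd.DataFrame(rows, columns=_MARGINAL_COLS).to_csv(path, index=False)


def read_table_csv(path: str | Path) -> list[CaptureHistoryTable]:
    """Read cell-form CSV with columns stratum,pattern,count."""
    df = pd.read_csv(path, dtype={"pattern": str})
    for c in ("stratum", "pattern", "count"):
        if c not in df.columns:
            raise ValueError(f"cell CSV missing column {c!r}")
    out = []
    for stratum, grp in df.groupby("stratum", sort=False):
        cells = {str(p): int(c) for p, c in zip(grp["pattern"], grp["count"])}
        k = len(next(iter(cells)))
        out.append(CaptureHistoryTable(k, cells, stratum=str(stratum)))
    return out


def write_table_csv(tables: Iterable[CaptureHistoryTable], path: str | Path) -> None:
    rows = []
    for t in tables:
        for p in patterns(t.k):
            rows.append({"stratum": t.stratum, "pattern": p, "count": t.cells[p]})
    pd.DataFrame(rows).to_csv(path, index=False)


def table_to_json(t: CaptureHistoryTable) -> str:
    return json.dumps(
        {
            "stratum": t.stratum,
            "k": t.k,
            "cells": t.cells,
            "n_observed": t.n_observed,
            "warnings": t.warnings,
        },
        indent=2,
    )
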