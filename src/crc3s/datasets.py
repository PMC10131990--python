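"""Bundled aggregate data from the 2021 Rwanda national MSM 3S-CRC study.

The study tagged men who have sex with men (MSM) in three rounds —
unique-object distribution through community networks (capture one),
MSM-friendly health-service provision (capture two), and a
respondent-driven-sampling survey (capture three) — in five strata: the
four provinces and the city of Kigali. Only the published aggregates are
available: per-stratum occasion totals, pairwise overlaps and the triple
overlap. The Western stratum's printed marginals are mutually
inconsistent (inclusion-exclusion gives a negative cell), which the
clamp policy surfaces as a warning.
"""

from __future__ import annotations

from crc3s.capture_histories import (
    CaptureHistoryTable,
    CaptureMarginals,
    table_from_marginals,
    table_from_marginals_direct,
)
from crc3s.design import DesignSpec

__all__ = [
    "rwanda_marginals",
    "rwanda_national_marginals",
    "rwanda_tables",
    "rwanda_reproduction_tables",
    "rwanda_design_specs",
    "OBJECTS_ASSIGNED",
]

# occasion totals (n1, n2, n3), pairwise overlaps (n12, n13, n23), triple
_STRATA: dict[str, tuple[tuple[int, int, int], tuple[int, int, int], int]] = {
    "Eastern": ((558, 337, 126), (211, 50, 64), 36),
    "Kigali": ((885, 497, 1021), (185, 128, 124), 42),
    "Northern": ((150, 25, 303), (4, 20, 18), 4),
    "Southern": ((515, 291, 152), (195, 42, 54), 28),
    "Western": ((357, 164, 609), (126, 182, 155), 100),
}

#: unique objects assigned for distribution in capture one (2465 succeeded)
OBJECTS_ASSIGNED = 2723

#: anticipated stratum proportions for the RDS survey sample-size formula
_RDS_PREVALENCE = {
    "Kigali": 0.113,
    "Western": 0.064,
    "Southern": 0.014,
    "Northern": 0.031,
    "Eastern": 0.012,
}


def rwanda_marginals() -> list[CaptureMarginals]:
    """Per-stratum capture marginals of the Rwanda study."""
    return [
        CaptureMarginals(n=n, pair_overlaps=pairs, triple_overlap=tri, stratum=name)
        for name, (n, pairs, tri) in _STRATA.items()
    ]


def rwanda_national_marginals() -> CaptureMarginals:
    """Pooled national marginals (2465 / 1314 / 2211; 721 / 422 / 415; 210)."""
    ms = rwanda_marginals()
    total = ms[0]
    for m in ms[1:]:
        total = total + m
    return CaptureMarginals(
        n=total.n,
        pair_overlaps=total.pair_overlaps,
        triple_overlap=total.triple_overlap,
        stratum="national",
    )


def rwanda_tables(policy: str = "clamp") -> tuple[list[CaptureHistoryTable], CaptureHistoryTable]:
    """Per-stratum 7-cell tables plus the pooled national table.

    The Western stratum requires ``policy='clamp'``: its printed marginals
    imply a negative count for the services-only pattern.
    """
    tables = [table_from_marginals(m, policy=policy) for m in rwanda_marginals()]
    # The national table is built from the pooled marginals, not by summing
    # the clamped stratum tables: clamping Western's negative cell breaks
    # the linearity between the two, and the pooled marginals are mutually
    # consistent on their own.
    national = table_from_marginals(rwanda_national_marginals(), policy=policy)
    return tables, national


def rwanda_reproduction_tables() -> tuple[list[CaptureHistoryTable], CaptureHistoryTable]:
    """Tables under the tabulation convention of the original analysis.

    Fitting the latent-class model to the inclusion-exclusion tables does
    not reproduce the study's published estimates; fitting it to tables
    whose cells are the printed marginal counts taken directly (occasion
    totals in the single-capture cells, overlaps in the multi-capture
    cells, uncorrected) reproduces the national and all five stratum
    estimates. These tables exist to reproduce the published numbers and
    to document that finding; use :func:`rwanda_tables` for a correct
    person-level aggregation.
    """
    tables = [table_from_marginals_direct(m) for m in rwanda_marginals()]
    national = table_from_marginals_direct(rwanda_national_marginals())
    return tables, national


def rwanda_design_specs() -> dict[str, DesignSpec]:
    """Per-stratum inputs of the study's RDS sample-size calculation."""
    return {
        name: DesignSpec(p=p, w=0.025, deff=1.5, z=1.96, adjust=0.10)
        for name, p in _RDS_PREVALENCE.items()
    }
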