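"""End-to-end population-size-estimation pipeline.

Marginals CSV -> capture-history tables -> per-stratum and pooled
latent-class fits -> classical diagnostics -> JSON/CSV report. Every
clamped cell, warning and the effective MCMC settings are recorded in
the report; reruns with the same configuration and seed reproduce it
byte-identically apart from the single timestamp field.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from crc3s.capture_histories import (
    CaptureMarginals,
    marginals_from_table,
    read_marginals_csv,
    table_from_marginals,
    table_from_marginals_direct,
    write_table_csv,
)
from crc3s.classical import chapman, independence_mle_3list
from crc3s.lcmcr import LCMCRConfig, PosteriorSummary, draws_to_csv, fit_all_strata, fit_lcmcr
from crc3s.rds_diagnostics import RecruitmentChain, geweke_z, recruitment_homophily

__all__ = ["RunConfig", "run_pse", "proportion_estimate"]

logger = logging.getLogger("crc3s")

EXIT_OK = 0
EXIT_IO = 2
EXIT_SCHEMA = 3
EXIT_INCONSISTENT = 4


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    marginals: list[CaptureMarginals] | str | Path
    policy: str = "clamp"
    tabulation: str = "inclusion_exclusion"  # or "direct" (see table_from_marginals_direct)
    lcmcr: LCMCRConfig = field(default_factory=LCMCRConfig)
    strata: list[str] | None = None  # None = all in input; [] = pooled only
    denominators: dict[str, float] | None = None
    chain_csv: str | Path | None = None
    chain_attribute: str = "attribute"
    out_dir: str | Path | None = None
    write_draws: bool = False

    def load_marginals(self) -> list[CaptureMarginals]:
        if isinstance(self.marginals, (str, Path)):
            return read_marginals_csv(self.marginals)
        return list(self.marginals)


def proportion_estimate(pse: PosteriorSummary, denominator: float) -> dict:
    """Population proportion implied by the PSE and an external denominator.

    Divides the posterior draws of N by the (user-supplied) reference
    population count and summarises as a median percentage with the same
    credible-set construction as the fit.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = 100.0 * pse.draws_N / denominator
    from crc3s.lcmcr import credible_set

    lo, hi = credible_set(pct, pse.cs_level, pse.cs_method)
    return {
        "median_percent": round(float(np.median(pct)), 2),
        "cs_lower_percent": round(lo, 2),
        "cs_upper_percent": round(hi, 2),
        "denominator": denominator,
    }


def _summary_block(s: PosteriorSummary) -> dict:
    return {
        "n_observed": s.n_observed,
        "median": s.median_N,
        "cs_lower": s.cs_lower,
        "cs_upper": s.cs_upper,
        "level": s.cs_level,
        "method": s.cs_method,
    }


def run_pse(cfg: RunConfig) -> dict:
    """Execute the full pipeline and return (and optionally write) the report."""
    marginals = cfg.load_marginals()
    if cfg.strata is not None and cfg.strata != []:
        keep = set(cfg.strata)
        missing = keep - {m.stratum for m in marginals}
        if missing:
            raise ValueError(f"strata not in input: {sorted(missing)}")
        marginals = [m for m in marginals if m.stratum in keep]
    if not marginals:
        raise ValueError("no marginals to analyse")

    if cfg.tabulation == "direct":
        build = lambda m: table_from_marginals_direct(m)  # noqa: E731
    elif cfg.tabulation == "inclusion_exclusion":
        build = lambda m: table_from_marginals(m, policy=cfg.policy)  # noqa: E731
    else:
        raise ValueError(f"unknown tabulation {cfg.tabulation!r}")
    tables = [build(m) for m in marginals]
    for t in tables:
        for w in t.warnings:
            logger.warning("%s: %s", t.stratum, w)

    pooled_m = marginals[0]
    for m in marginals[1:]:
        pooled_m = pooled_m + m
    pooled_table = table_from_marginals(
        CaptureMarginals(
            n=pooled_m.n,
            pair_overlaps=pooled_m.pair_overlaps,
            triple_overlap=pooled_m.triple_overlap,
            stratum="pooled",
        ),
        policy=cfg.policy,
    )

    fit_strata = cfg.strata is None or cfg.strata != []
    per_stratum: dict[str, PosteriorSummary] = {}
    if fit_strata and len(tables) > 1:
        per_stratum = fit_all_strata(tables, cfg.lcmcr)
    pooled_fit = fit_lcmcr(pooled_table, cfg.lcmcr)

    # classical diagnostics on the pooled marginals
    pm = marginals_from_table(pooled_table)
    diagnostics = {
        "chapman": {
            "occasions_1_2": chapman(pm.n[0], pm.n[1], pm.pair_overlaps[0]).estimate,
            "occasions_1_3": chapman(pm.n[0], pm.n[2], pm.pair_overlaps[1]).estimate,
            "occasions_2_3": chapman(pm.n[1], pm.n[2], pm.pair_overlaps[2]).estimate,
        },
        "independence_mle": independence_mle_3list(pooled_table),
        # stationarity check needs a reasonably long kept chain
        "geweke_z_pooled_N": (
            geweke_z(pooled_fit.draws_N) if pooled_fit.draws_N.size >= 200 else None
        ),
    }
    if cfg.chain_csv is not None:
        chain = RecruitmentChain.from_csv(cfg.chain_csv, attribute=cfg.chain_attribute)
        h = recruitment_homophily(chain, cfg.chain_attribute)
        diagnostics["recruitment_homophily"] = {
            "observed": h.observed,
            "expected": h.expected,
            "ratio": h.ratio,
            "n_edges": h.n_edges,
        }

    report = {
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "policy": cfg.policy,
        "mcmc_settings": pooled_fit.settings,
        "tables": {
            t.stratum: {"cells": t.cells, "n_observed": t.n_observed, "warnings": t.warnings}
            for t in [*tables, pooled_table]
        },
        "estimates": {
            "pooled": _summary_block(pooled_fit),
            **{name: _summary_block(s) for name, s in per_stratum.items()},
        },
        "diagnostics": diagnostics,
    }

    if cfg.denominators:
        props = {}
        for name, denom in cfg.denominators.items():
            fit = pooled_fit if name == "pooled" else per_stratum.get(name)
            if fit is None:
                logger.warning("no fit for stratum %r; proportion omitted", name)
                continue
            props[name] = proportion_estimate(fit, denom)
        report["proportions"] = props

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        write_table_csv([*tables, pooled_table], out / "tables.csv")
        if cfg.write_draws:
            draws_to_csv(pooled_fit, out / "draws_pooled.csv")
            for name, s in per_stratum.items():
                draws_to_csv(s, out / f"draws_{name}.csv")
    return report
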