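"""Survey sample-size calculators and a simulation-based CRC power check.

Both capture rounds of a multi-source study and the RDS survey size their
samples with the standard proportion formula

    n = deff * z^2 * p (1 - p) / w^2,

inflated by ``1 / (1 - adjust)`` for anticipated nonresponse or coupon
loss, where ``p`` is the anticipated prevalence/proportion, ``w`` the
absolute precision half-width, and ``deff`` the design effect of the
complex sampling design. The power check simulates full capture studies
from a latent-class scenario, refits the model, and reports bias, RMSE,
mean credible-set width and coverage with Monte-Carlo standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from math import ceil

import numpy as np

from crc3s.lcmcr import LCMCRConfig, fit_lcmcr
from crc3s.synthetic import PopulationScenario, simulate_captures

__all__ = ["DesignSpec", "rds_sample_size", "crc_capture_sample_size", "crc_power_sim"]


@dataclass(frozen=True)
class DesignSpec:
    """Inputs to the proportion-based sample-size formula.

    Attributes
    ----------
    p
        Anticipated proportion (0 < p < 1).
    deff
        Design effect (variance inflation vs. simple random sampling).
    w
        Absolute precision half-width.
    z
        Normal quantile; 1.96 for 95% confidence.
    adjust
        Anticipated nonresponse / loss fraction; the raw size is divided
        by ``1 - adjust``.
    rounding
        'nearest' (half-up) or 'ceiling'.
    """

    p: float
    w: float
    deff: float = 1.0
    z: float = 1.96
    adjust: float = 0.0
    rounding: str = "nearest"

    def __post_init__(self):
        if not 0 < self.p < 1:
            raise ValueError("p must lie in (0, 1)")
        if self.w <= 0:
            raise ValueError("w must be positive")
        if self.deff <= 0 or self.z <= 0:
            raise ValueError("deff and z must be positive")
        if not 0 <= self.adjust < 1:
            raise ValueError("adjust must lie in [0, 1)")
        if self.rounding not in ("nearest", "ceiling"):
            raise ValueError(f"unknown rounding {self.rounding!r}")


def _size(d: DesignSpec) -> int:
    n_raw = d.deff * d.z**2 * d.p * (1.0 - d.p) / d.w**2
    n_raw /= 1.0 - d.adjust
    if d.rounding == "ceiling":
        return int(ceil(n_raw))
    return int(Decimal(repr(n_raw)).quantize(Decimal(1), rounding=ROUND_HALF_UP))


def rds_sample_size(d: DesignSpec) -> int:
    """Required RDS survey size (Salganik-style proportion formula)."""
    return _size(d)


def crc_capture_sample_size(d: DesignSpec) -> int:
    """Required capture-round size; same core formula, loss inflation."""
    return _size(d)


def crc_power_sim(
    true_N: int,
    lam,
    reps: int,
    cfg: LCMCRConfig,
    weights=None,
    seed: int | None = None,
) -> dict:
    """Simulation-based design check for a multi-source CRC study.

    Simulates ``reps`` capture studies from the latent-class scenario
    (``lam`` either per-occasion probabilities or a J x K matrix with
    class ``weights``), fits each with the latent-class sampler, and
    aggregates accuracy of the population-size estimate.

    Returns bias and RMSE of the posterior median, mean credible-set
    width, the coverage of the credible set, and Monte-Carlo standard
    errors for bias and coverage.
    """
    if reps < 10:
        raise ValueError("need at least 10 replicates")
    scenario = PopulationScenario(N=true_N, lam=lam, weights=weights, seed=0)
    lam_arr, w_arr = scenario.arrays()
    p_zero = float(w_arr @ np.prod(1.0 - lam_arr, axis=0))
    if true_N * (1.0 - p_zero) < 10:
        raise ValueError(
            f"degenerate design: expected observed count "
            f"{true_N * (1.0 - p_zero):.1f} < 10"
        )
    ss = np.random.SeedSequence(seed if seed is not None else cfg.seed)
    children = ss.spawn(reps)
    medians, widths, covered = [], [], []
    for child in children:
        s1, s2 = (int(v % (2**31)) for v in child.generate_state(2))
        table, _ = simulate_captures(
            PopulationScenario(N=true_N, lam=lam, weights=weights, seed=s1)
        )
        fit = fit_lcmcr(table, LCMCRConfig(**{**cfg.__dict__, "seed": s2}))
        medians.append(fit.median_N)
        widths.append(fit.cs_upper - fit.cs_lower)
        covered.append(fit.cs_lower <= true_N <= fit.cs_upper)
    medians = np.asarray(medians)
    covered = np.asarray(covered, dtype=float)
    return {
        "true_N": true_N,
        "reps": reps,
        "bias": float(medians.mean() - true_N),
        "bias_mcse": float(medians.std(ddof=1) / np.sqrt(reps)),
        "rmse": float(np.sqrt(np.mean((medians - true_N) ** 2))),
        "mean_cs_width": float(np.mean(widths)),
        "coverage": float(covered.mean()),
        "coverage_mcse": float(covered.std(ddof=1) / np.sqrt(reps)),
    }
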