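"""Bayesian nonparametric latent-class capture-recapture (LCMCR).

The model posits that the closed population of unknown size ``N`` is a
mixture of latent classes; within class ``k`` captures are independent
across occasions with occasion-specific probabilities ``lambda[j, k]``.
Class weights follow a truncated stick-breaking (Dirichlet-process)
prior with concentration ``alpha`` under a Gamma(a, b) hyperprior, so
the effective number of classes adapts to the data. The never-captured
count ``n0`` is treated by negative-binomial data augmentation: given
the probability ``p0`` of an all-zero history,

    P(n0 = m) ∝ Γ(n + m) / (Γ(n) m!) · (1 − p0)^n · p0^m,

which keeps ``N = n + n0 ≥ n`` without an explicit prior on ``N``.

The Gibbs sweep updates, in order: ``n0`` (Gamma–Poisson mixture of the
negative binomial, robust for large counts), the latent-class
allocations (collapsed to multinomials per distinct observed pattern —
identical stationary distribution to per-individual allocation, far
cheaper), the capture probabilities (conjugate Beta), the
stick-breaking fractions (conjugate Beta) and the concentration
(conjugate Gamma).
"""

from __future__ import annotations

import json
import warnings as _warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from crc3s.capture_histories import CaptureHistoryTable, patterns

__all__ = [
    "LCMCRConfig",
    "PosteriorSummary",
    "fit_lcmcr",
    "fit_all_strata",
    "credible_set",
    "draws_to_csv",
    "summary_to_json",
]

_EPS = 1e-12


@dataclass(frozen=True)
class LCMCRConfig:
    """Priors, truncation and MCMC settings for the latent-class sampler.

    Attributes
    ----------
    k_star
        Truncation level of the stick-breaking mixture (max latent classes).
    a_alpha, b_alpha
        Shape and rate of the Gamma hyperprior on the Dirichlet-process
        concentration parameter.
    lambda_a, lambda_b
        Beta prior on every capture probability; (1, 1) is uniform.
    n_samples
        Number of kept posterior draws.
    burn_in
        Iterations discarded before keeping draws.
    thinning
        Iterations between kept draws; total post-burn-in sweeps are
        ``n_samples * thinning``.
    seed
        Seed for the sampler's random generator.
    cs_level, cs_method
        Credible-set probability and construction ('hdi' or 'equal_tail').
    """

    k_star: int = 5
    a_alpha: float = 0.25
    b_alpha: float = 0.25
    lambda_a: float = 1.0
    lambda_b: float = 1.0
    n_samples: int = 10_000
    burn_in: int = 10_000
    thinning: int = 1_000
    seed: int | None = None
    cs_level: float = 0.95
    cs_method: str = "hdi"

    def __post_init__(self):
        if self.k_star < 1:
            raise ValueError("k_star must be >= 1")
        if self.a_alpha <= 0 or self.b_alpha <= 0:
            raise ValueError("a_alpha and b_alpha must be positive")
        if min(self.n_samples, self.burn_in, self.thinning) < 1:
            raise ValueError("n_samples, burn_in and thinning must be >= 1")
        if not 0 < self.cs_level < 1:
            raise ValueError("cs_level must lie in (0, 1)")
        if self.cs_method not in ("hdi", "equal_tail"):
            raise ValueError(f"unknown cs_method {self.cs_method!r}")


@dataclass
class PosteriorSummary:
    """Kept posterior draws of N with median and credible set."""

    draws_N: np.ndarray
    draws_p0: np.ndarray
    draws_alpha: np.ndarray
    median_N: float
    cs_lower: float
    cs_upper: float
    cs_level: float
    cs_method: str
    n_observed: int
    stratum: str = ""
    settings: dict = field(default_factory=dict)


def credible_set(draws, level: float = 0.95, method: str = "hdi") -> tuple[float, float]:
    """Credible interval of posterior draws.

    ``hdi`` returns the shortest contiguous interval containing ``level``
    posterior mass (sliding window over the order statistics; on ties the
    window with the smallest lower bound wins). ``equal_tail`` returns the
    symmetric-tail quantiles.
    """
    x = np.asarray(draws, dtype=float)
    if x.size < 100:
        raise ValueError(f"need at least 100 draws, got {x.size}")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    if method == "equal_tail":
        lo, hi = np.quantile(x, [(1 - level) / 2, 1 - (1 - level) / 2])
        return float(lo), float(hi)
    if method != "hdi":
        raise ValueError(f"unknown method {method!r}")
    xs = np.sort(x)
    n = xs.size
    m = int(np.ceil(level * n))
    widths = xs[m - 1 :] - xs[: n - m + 1]
    i = int(np.argmin(widths))  # first minimum -> smallest lower bound
    return float(xs[i]), float(xs[i + m - 1])


def _stick_break(V: np.ndarray) -> np.ndarray:
    # pi_k = V_k * prod_{l<k} (1 - V_l), with V[K-1] = 1
    pi = np.empty_like(V)
    rest = 1.0
    for k in range(V.size):
        pi[k] = V[k] * rest
        rest *= 1.0 - V[k]
    return pi


def fit_lcmcr(t: CaptureHistoryTable, cfg: LCMCRConfig = LCMCRConfig()) -> PosteriorSummary:
    """Fit the latent-class capture-recapture model by Gibbs sampling.

    Parameters
    ----------
    t
        Observed capture-history table (the all-zero cell absent).
    cfg
        Priors and MCMC settings.

    Returns
    -------
    PosteriorSummary
        Kept draws of ``N = n + n0`` with the median point estimate and
        the credible set requested in ``cfg``.
    """
    n_obs = t.n_observed
    if n_obs < 1:
        raise ValueError("table has no observed individuals")
    pats = patterns(t.k)
    X = np.array([[int(ch) for ch in p] for p in pats], dtype=float)  # P x J
    c = np.array([t.cells[p] for p in pats], dtype=np.int64)
    if not any(c[i] > 0 and X[i].sum() >= 2 for i in range(len(pats))):
        _warnings.warn(
            "no individual was captured on two or more occasions; "
            "the population size is not identifiable from these data",
            UserWarning,
            stacklevel=2,
        )
    J, K = t.k, cfg.k_star
    rng = np.random.default_rng(cfg.seed)

    # initial state drawn from the priors
    lam = rng.beta(cfg.lambda_a, cfg.lambda_b, size=(J, K))
    alpha = cfg.a_alpha / cfg.b_alpha
    V = np.clip(rng.beta(1.0, alpha, size=K), _EPS, 1.0 - _EPS)
    V[K - 1] = 1.0
    pi = _stick_break(V)

    total_iter = cfg.burn_in + cfg.n_samples * cfg.thinning
    keep_N = np.empty(cfg.n_samples, dtype=np.int64)
    keep_p0 = np.empty(cfg.n_samples, dtype=float)
    keep_alpha = np.empty(cfg.n_samples, dtype=float)
    kept = 0

    Xc = 1.0 - X
    for it in range(total_iter):
        lam = np.clip(lam, _EPS, 1.0 - _EPS)
        # per-class probability of an all-zero history, and p0
        q0 = pi * np.prod(1.0 - lam, axis=0)
        p0 = q0.sum()
        if not np.isfinite(p0) or not (0.0 < p0 < 1.0):
            p0 = min(max(p0, _EPS), 1.0 - _EPS)
            if not np.isfinite(p0):
                raise FloatingPointError(f"non-finite state at iteration {it}")
        # 1. n0 | rest  ~  NegBin(n_obs, p0) via Gamma-Poisson mixture
        g = rng.gamma(n_obs, p0 / (1.0 - p0))
        n0 = int(rng.poisson(g))
        # 2. latent-class allocation, collapsed per distinct pattern
        W = pi * np.exp(X @ np.log(lam) + Xc @ np.log1p(-lam))  # P x K
        Z = np.empty((len(pats), K), dtype=np.int64)
        for i in range(len(pats)):
            Z[i] = rng.multinomial(c[i], W[i] / W[i].sum())
        z0 = rng.multinomial(n0, q0 / q0.sum())
        m = Z.sum(axis=0) + z0  # class totals incl. augmented zero-histories
        # 3. capture probabilities (captures vs non-captures per class)
        cap = X.T @ Z  # J x K; zero-history individuals add no captures
        lam = rng.beta(cfg.lambda_a + cap, cfg.lambda_b + (m - cap))
        # 4. stick-breaking fractions
        tail = np.concatenate([np.cumsum(m[::-1])[::-1][1:], [0]])
        V = np.ones(K)
        if K > 1:
            V[: K - 1] = np.clip(
                rng.beta(1.0 + m[: K - 1], alpha + tail[: K - 1]), _EPS, 1.0 - _EPS
            )
        pi = _stick_break(V)
        # 5. concentration parameter
        if K > 1:
            rate = cfg.b_alpha - np.sum(np.log1p(-V[: K - 1]))
            alpha = rng.gamma(cfg.a_alpha + K - 1, 1.0 / rate)
        if not np.all(np.isfinite(lam)) or not np.isfinite(alpha):
            raise FloatingPointError(f"non-finite state at iteration {it}")
        post = it - cfg.burn_in
        if post >= 0 and (post + 1) % cfg.thinning == 0:
            keep_N[kept] = n_obs + n0
            keep_p0[kept] = p0
            keep_alpha[kept] = alpha
            kept += 1

    draws = keep_N[:kept]
    lo, hi = credible_set(draws, cfg.cs_level, cfg.cs_method)
    return PosteriorSummary(
        draws_N=draws,
        draws_p0=keep_p0[:kept],
        draws_alpha=keep_alpha[:kept],
        median_N=float(np.median(draws)),
        cs_lower=lo,
        cs_upper=hi,
        cs_level=cfg.cs_level,
        cs_method=cfg.cs_method,
        n_observed=n_obs,
        stratum=t.stratum,
        settings={
            "k_star": cfg.k_star,
            "a_alpha": cfg.a_alpha,
            "b_alpha": cfg.b_alpha,
            "n_samples": cfg.n_samples,
            "burn_in": cfg.burn_in,
            "thinning": cfg.thinning,
            "seed": cfg.seed,
        },
    )


def fit_all_strata(
    tables: Iterable[CaptureHistoryTable], cfg: LCMCRConfig = LCMCRConfig()
) -> dict[str, PosteriorSummary]:
    """Independent per-stratum fits with deterministic per-stratum seeds."""
    tables = list(tables)
    if not tables:
        return {}
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(len(tables))
    out: dict[str, PosteriorSummary] = {}
    for t, child in zip(tables, children):
        sub = replace(cfg, seed=int(child.generate_state(1)[0] % (2**31)))
        try:
            out[t.stratum] = fit_lcmcr(t, sub)
        except Exception as e:
            raise RuntimeError(f"fit failed for stratum {t.stratum!r}: {e}") from e
    return out


def draws_to_csv(summary: PosteriorSummary, path: str | Path) -> None:
    pd.DataFrame(
        {
            "iteration": np.arange(1, summary.draws_N.size + 1),
            "N": summary.draws_N,
            "p0": summary.draws_p0,
            "alpha": summary.draws_alpha,
        }
    ).to_csv(path, index=False)


def summary_to_json(summaries: Mapping[str, PosteriorSummary] | PosteriorSummary) -> str:
    if isinstance(summaries, PosteriorSummary):
        summaries = {summaries.stratum or "all": summaries}
    out = []
    for name, s in summaries.items():
        out.append(
            {
                "stratum": name,
                "n_observed": s.n_observed,
                "median": s.median_N,
                "cs_lower": s.cs_lower,
                "cs_upper": s.cs_upper,
                "level": s.cs_level,
                "method": s.cs_method,
                "settings": s.settings,
            }
        )
    return json.dumps(out, indent=2)
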