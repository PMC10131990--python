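"""Respondent-driven-sampling dependency checks and MCMC diagnostics.

Capture-recapture assumes the captures are independent. When one capture
round is an RDS survey, dependence would show up as recruitment homophily
on the prior-capture status: recruiters preferentially recruiting peers
with the same capture history. The homophily ratio compares observed
same-attribute recruitments with the expectation under random mixing; a
value near 1 supports independence.

Also provides a Geweke stationarity z-score and plot-ready trace/histogram
exports for assessing convergence of the population-size chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.tsa.ar_model import AutoReg, ar_select_order

__all__ = [
    "RecruitmentChain",
    "HomophilyResult",
    "recruitment_homophily",
    "geweke_z",
    "trace_export",
]


@dataclass
class RecruitmentChain:
    """RDS recruiter->recruit forest with node attributes.

    ``nodes`` maps participant id to a dict of categorical attributes;
    ``edges`` are (recruiter, recruit) pairs; seeds have no recruiter.
    """

    nodes: dict[str, dict[str, object]]
    edges: list[tuple[str, str]]
    seeds: set[str] = field(default_factory=set)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        unknown = [v for e in self.edges for v in e if v not in self.nodes]
        if unknown:
            raise ValueError(f"edge endpoints missing from nodes: {unknown[:5]}")
        if not self.seeds:
            self.seeds = {v for v in self.nodes if g.in_degree(v) == 0}
        for v in self.nodes:
            indeg = g.in_degree(v)
            if v in self.seeds and indeg != 0:
                raise ValueError(f"seed {v!r} has a recruiter")
            if v not in self.seeds and indeg != 1:
                raise ValueError(f"non-seed {v!r} has {indeg} recruiters (expected 1)")
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("recruitment chain contains a cycle")
        self._graph = g

    @classmethod
    def from_csv(cls, path: str | Path, attribute: str = "attribute") -> "RecruitmentChain":
        """Read columns recruit_id, recruiter_id (empty for seeds), <attribute>."""
        df = pd.read_csv(path, dtype=str)
        for c in ("recruit_id", "recruiter_id"):
            if c not in df.columns:
                raise ValueError(f"chain CSV missing column {c!r}")
        if attribute not in df.columns:
            raise ValueError(f"chain CSV missing attribute column {attribute!r}")
        nodes, edges, seeds = {}, [], set()
        for r in df.itertuples():
            rid = str(r.recruit_id)
            nodes[rid] = {attribute: getattr(r, attribute)}
            recruiter = getattr(r, "recruiter_id")
            if pd.isna(recruiter) or str(recruiter) == "":
                seeds.add(rid)
            else:
                edges.append((str(recruiter), rid))
        return cls(nodes=nodes, edges=edges, seeds=seeds)


@dataclass(frozen=True)
class HomophilyResult:
    observed: float
    expected: float
    ratio: float
    n_edges: int


def recruitment_homophily(chain: RecruitmentChain, attribute: str) -> HomophilyResult:
    """Recruitment-homophily ratio for a categorical attribute.

    ``observed`` counts recruiter-recruit edges whose endpoints share the
    attribute value. ``expected`` is the random-mixing expectation: with
    group shares ``s_g`` computed over all recruits, a randomly mixed edge
    matches with probability ``sum_g s_g**2``, so ``expected = n_edges *
    sum_g s_g**2``. A ratio near 1 indicates recruitment independent of
    the attribute; seeds act only as recruiters, never as recruits.
    """
    if not chain.edges:
        raise ValueError("chain has no recruitment edges")
    for v, attrs in chain.nodes.items():
        if attribute not in attrs:
            raise ValueError(f"node {v!r} lacks attribute {attribute!r}")
    recruits = [b for _, b in chain.edges]
    values = pd.Series([chain.nodes[v][attribute] for v in recruits])
    shares = values.value_counts(normalize=True)
    observed = sum(
        1 for a, b in chain.edges if chain.nodes[a][attribute] == chain.nodes[b][attribute]
    )
    expected = float(len(chain.edges) * (shares**2).sum())
    if expected == 0:
        raise ValueError("random-mixing expectation is zero; homophily undefined")
    return HomophilyResult(
        observed=float(observed),
        expected=expected,
        ratio=float(observed) / expected,
        n_edges=len(chain.edges),
    )


def _spectrum0_ar(x: np.ndarray) -> float:
    """Spectral density at frequency zero via an AIC-selected AR fit."""
    x = np.asarray(x, dtype=float)
    maxlag = min(int(10 * np.log10(len(x))), len(x) // 4 - 1)
    if maxlag < 1:
        return float(np.var(x, ddof=1))
    sel = ar_select_order(x, maxlag=maxlag, ic="aic", old_names=False)
    order = sel.ar_lags[-1] if sel.ar_lags else 0
    if order == 0:
        return float(np.var(x, ddof=1))
    fit = AutoReg(x, lags=order, old_names=False).fit()
    resid_var = float(np.var(fit.resid, ddof=0))
    return resid_var / (1.0 - np.sum(fit.params[1:])) ** 2


def geweke_z(draws, frac_a: float = 0.1, frac_b: float = 0.5) -> float:
    """Geweke stationarity z-score between early and late chain segments.

    Compares the mean of the first ``frac_a`` fraction of the chain with
    the mean of the last ``frac_b`` fraction, with variances from
    AR-based spectral density estimates at frequency zero. For a
    stationary chain the score is approximately standard normal.
    """
    x = np.asarray(draws, dtype=float)
    if x.size < 200:
        raise ValueError(f"need at least 200 draws, got {x.size}")
    if not (0 < frac_a < 1 and 0 < frac_b < 1 and frac_a + frac_b <= 1):
        raise ValueError("fractions must be in (0,1) and not overlap")
    if np.ptp(x) == 0:
        raise ValueError("chain is constant; Geweke z is undefined")
    na = int(np.floor(frac_a * x.size))
    nb = int(np.floor(frac_b * x.size))
    a, b = x[:na], x[-nb:]
    sa, sb = _spectrum0_ar(a), _spectrum0_ar(b)
    denom = np.sqrt(sa / na + sb / nb)
    if denom == 0:
        raise ValueError("zero spectral variance; Geweke z is undefined")
    return float((a.mean() - b.mean()) / denom)


def trace_export(draws) -> dict:
    """Plot-ready trace series and histogram (Freedman-Diaconis bins)."""
    x = np.asarray(draws, dtype=float)
    if x.size == 0:
        raise ValueError("no draws")
    if np.ptp(x) == 0:
        edges = np.array([x[0] - 0.5, x[0] + 0.5])
        counts = np.array([x.size])
    else:
        counts, edges = np.histogram(x, bins="fd")
    return {
        "iteration": np.arange(1, x.size + 1),
        "value": x,
        "hist_counts": counts,
        "hist_edges": edges,
    }
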