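"""Synthetic capture-recapture data and RDS recruitment chains.

Generative twins of the structures the analysis assumes: a closed
population partitioned into latent classes with class-specific,
occasion-independent capture probabilities (product-Bernoulli within
class), and a coupon-based branching recruitment process with a tunable
assortativity (homophily) parameter. Every stage of the pipeline is
testable against these generators without external data.
"""

from __future__ import annotations

import warnings as _warnings
from collections import deque
from dataclasses import dataclass

import numpy as np

from crc3s.capture_histories import CaptureHistoryTable, patterns
from crc3s.rds_diagnostics import RecruitmentChain

__all__ = [
    "PopulationScenario",
    "ChainScenario",
    "simulate_captures",
    "simulate_chain",
    "load_scenario_yaml",
]


@dataclass(frozen=True)
class PopulationScenario:
    """Closed heterogeneous population with latent-class capture structure.

    ``lam[j][k]`` is the probability that a class-``k`` member is captured
    on occasion ``j``; ``weights`` are the class membership probabilities.
    """

    N: int
    lam: tuple  # J x K nested tuples, or length-J for a single class
    weights: tuple | None = None
    seed: int | None = None

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lam = np.asarray(self.lam, dtype=float)
        if lam.ndim == 1:  # flat vector: J occasions, one class
            lam = lam.reshape(-1, 1)
        w = np.asarray(self.weights, dtype=float) if self.weights is not None else np.ones(lam.shape[1])
        w = w / w.sum()
        if lam.shape[1] != w.size:
            raise ValueError("lambda columns must match number of class weights")
        if np.any((lam < 0) | (lam > 1)):
            raise ValueError("capture probabilities must lie in [0, 1]")
        return lam, w

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("N must be positive")
        self.arrays()


def simulate_captures(s: PopulationScenario) -> tuple[CaptureHistoryTable, dict]:
    """Simulate one realisation of the capture study.

    Each of the ``N`` members draws a latent class, then an independent
    Bernoulli capture per occasion; all-zero histories are dropped (they
    are unobservable in the field). Returns the observable table plus the
    true latent bookkeeping for recovery tests.
    """
    lam, w = s.arrays()
    J, K = lam.shape
    rng = np.random.default_rng(s.seed)
    class_counts = rng.multinomial(s.N, w)
    pats = patterns(J)
    X = np.array([[int(ch) for ch in p] for p in pats], dtype=float)
    cells = {p: 0 for p in pats}
    n_unobserved = 0
    for k in range(K):
        lk = lam[:, k]
        probs = np.prod(np.where(X == 1, lk, 1.0 - lk), axis=1)
        p_zero = float(np.prod(1.0 - lk))
        full = np.concatenate([probs, [p_zero]])
        full = full / full.sum()
        draw = rng.multinomial(class_counts[k], full)
        for p, d in zip(pats, draw[:-1]):
            cells[p] += int(d)
        n_unobserved += int(draw[-1])
    table = CaptureHistoryTable(J, cells, stratum="simulated")
    truth = {
        "N": s.N,
        "n_observed": table.n_observed,
        "n_unobserved": n_unobserved,
        "class_counts": class_counts.tolist(),
    }
    return table, truth


def load_scenario_yaml(path) -> "PopulationScenario | ChainScenario":
    """Load a scenario from YAML; `kind: population` or `kind: chain`."""
    import yaml

    raw = yaml.safe_load(open(path))
    kind = raw.pop("kind", "population")
    if kind == "population":
        if "lam" in raw:
            lam = raw.pop("lam")
            raw["lam"] = tuple(tuple(r) for r in lam) if isinstance(lam[0], list) else tuple(lam)
        if raw.get("weights") is not None:
            raw["weights"] = tuple(raw["weights"])
        return PopulationScenario(**raw)
    if kind == "chain":
        if raw.get("group_props") is not None:
            raw["group_props"] = tuple(raw["group_props"])
        return ChainScenario(**raw)
    raise ValueError(f"unknown scenario kind {kind!r}")


@dataclass(frozen=True)
class ChainScenario:
    """Coupon-based RDS recruitment with tunable attribute assortativity.

    With probability ``h`` a recruit copies the recruiter's group; with
    probability ``1 - h`` the group is drawn from the population shares,
    so ``h = 0`` gives random mixing and ``h = 1`` perfect assortativity.
    """

    n_seeds: int = 24
    coupons: int = 3
    target_size: int = 500
    group_props: tuple = (0.5, 0.5)
    h: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if not 0 <= self.h <= 1:
            raise ValueError("h must lie in [0, 1]")
        p = np.asarray(self.group_props, dtype=float)
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("group proportions must be a probability vector")
        if self.n_seeds < 1 or self.coupons < 0 or self.target_size < self.n_seeds:
            raise ValueError("invalid chain scenario sizes")


def simulate_chain(c: ChainScenario, attribute: str = "group") -> RecruitmentChain:
    """Simulate a recruitment forest by breadth-first coupon redemption.

    Recruitment stops at ``target_size`` participants (seeds included);
    if every coupon is spent first, a partial chain is returned with a
    warning attached.
    """
    rng = np.random.default_rng(c.seed)
    props = np.asarray(c.group_props, dtype=float)
    groups = [f"g{i + 1}" for i in range(props.size)]
    nodes: dict[str, dict[str, object]] = {}
    edges: list[tuple[str, str]] = []
    seeds: set[str] = set()
    queue: deque[str] = deque()
    for i in range(c.n_seeds):
        sid = f"S{i + 1}"
        nodes[sid] = {attribute: groups[rng.choice(props.size, p=props)]}
        seeds.add(sid)
        queue.append(sid)
    nxt = 1
    warnings_: list[str] = []
    while len(nodes) < c.target_size and queue:
        recruiter = queue.popleft()
        for _ in range(c.coupons):
            if len(nodes) >= c.target_size:
                break
            rid = f"R{nxt}"
            nxt += 1
            if rng.random() < c.h:
                grp = nodes[recruiter][attribute]
            else:
                grp = groups[rng.choice(props.size, p=props)]
            nodes[rid] = {attribute: grp}
            edges.append((recruiter, rid))
            queue.append(rid)
    if len(nodes) < c.target_size:
        msg = f"coupons exhausted at {len(nodes)} of {c.target_size} participants"
        _warnings.warn(msg, UserWarning, stacklevel=2)
        warnings_.append(msg)
    return RecruitmentChain(nodes=nodes, edges=edges, seeds=seeds, warnings=warnings_)
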