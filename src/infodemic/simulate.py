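"""Independent-cascade spread simulation and node-removal interventions.

The spread model is the standard independent cascade: each newly activated
node gets exactly one chance to activate each currently inactive
out-neighbour, succeeding with the edge's transmission probability (a uniform
p, or min(1, p * weight) in weighted mode); the process runs to quiescence
and the spread is the number of activated nodes including the seeds.

Monte-Carlo runs use the live-edge coupling: each run draws one uniform
threshold per edge of the *full* network, an edge is "live" iff its threshold
falls below its transmission probability, and the spread is the set of nodes
reachable from the (surviving) seeds through live edges.  Because baseline
and post-removal arms share the same per-run thresholds (common random
numbers), removing nodes can never increase a run's spread, p = 1 reduces
exactly to reachability, and reduction estimates have low variance.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping

import numpy as np

from .network import InteractionNetwork, ScoreVector


@dataclasses.dataclass(frozen=True)
class CascadeConfig:
    """Transmission probability, Monte-Carlo runs, seed nodes and RNG seed."""

    seed_nodes: frozenset
    p: float = 0.1
    runs: int = 1000
    seed: int = 7
    weighted: bool = False

    def __post_init__(self):
        object.__setattr__(self, "seed_nodes", frozenset(self.seed_nodes))
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"transmission probability must lie in [0, 1], got {self.p}")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")
        if not self.seed_nodes:
            raise ValueError("seed_nodes must be non-empty")


@dataclasses.dataclass
class SpreadDistribution:
    mean: float
    se: float
    counts: tuple

    @property
    def runs(self) -> int:
        return len(self.counts)


@dataclasses.dataclass
class InterventionOutcome:
    """Baseline vs post-removal cascade spread under common random numbers."""

    strategy_label: str
    removal_set: frozenset
    baseline_spread: float
    baseline_se: float
    post_removal_spread: float
    post_removal_se: float
    reduction_percent: float
    all_seeds_removed: bool
    params: dict

    def __str__(self) -> str:
        return (
            f"{self.strategy_label}: baseline {self.baseline_spread:.2f} "
            f"± {self.baseline_se:.2f} -> {self.post_removal_spread:.2f} "
            f"± {self.post_removal_se:.2f} ({self.reduction_percent:.2f}% reduction, "
            f"|removal|={len(self.removal_set)})"
        )


def _edge_probabilities(net: InteractionNetwork, cfg: CascadeConfig) -> tuple[list, np.ndarray]:
    edges = net.edges()
    if cfg.weighted:
        probs = np.minimum(1.0, cfg.p * np.array([w for _, _, w in edges]))
    else:
        probs = np.full(len(edges), cfg.p)
    return edges, probs


def _live_spread(
    adjacency: Mapping,
    live: np.ndarray,
    seeds: Iterable,
    excluded: frozenset = frozenset(),
) -> int:
    """Nodes reachable from surviving seeds through live edges (BFS)."""
    active = {s for s in seeds if s not in excluded}
    frontier = list(active)
    while frontier:
        nxt = []
        for u in frontier:
            for eidx, v in adjacency.get(u, ()):
                if live[eidx] and v not in active and v not in excluded:
                    active.add(v)
                    nxt.append(v)
        frontier = nxt
    return len(active)


def _summary(counts: np.ndarray) -> SpreadDistribution:
    mean = float(counts.mean())
    se = float(counts.std(ddof=1) / np.sqrt(len(counts))) if len(counts) > 1 else 0.0
    return SpreadDistribution(mean=mean, se=se, counts=tuple(int(c) for c in counts))


def simulate_cascade(net: InteractionNetwork, cfg: CascadeConfig) -> SpreadDistribution:
    """Monte-Carlo spread distribution of cfg.seed_nodes on the intact network."""
    unknown = cfg.seed_nodes - net.node_set
    if unknown:
        raise KeyError(f"seed nodes not in network: {sorted(unknown)}")
    edges, probs = _edge_probabilities(net, cfg)
    adjacency: dict = {}
    for eidx, (u, v, _) in enumerate(edges):
        adjacency.setdefault(u, []).append((eidx, v))
    rng = np.random.default_rng(cfg.seed)
    counts = np.empty(cfg.runs, dtype=np.int64)
    seeds = sorted(cfg.seed_nodes)
    for r in range(cfg.runs):
        live = rng.random(len(edges)) < probs
        counts[r] = _live_spread(adjacency, live, seeds)
    return _summary(counts)


def evaluate_intervention(
    net: InteractionNetwork,
    cfg: CascadeConfig,
    removal: Iterable,
    strategy_label: str = "removal",
) -> InterventionOutcome:
    """Baseline vs post-removal spread with shared per-run edge thresholds.

    Removed nodes are neutralised: they cannot activate (removed seeds are
    dropped) and cannot be activated.  If every seed is removed the
    post-removal spread is 0 and the reduction 100% (flagged, not an error).
    """
    removal = frozenset(removal)
    unknown = removal - net.node_set
    if unknown:
        raise KeyError(f"removal nodes not in network: {sorted(unknown)}")
    unknown = cfg.seed_nodes - net.node_set
    if unknown:
        raise KeyError(f"seed nodes not in network: {sorted(unknown)}")
    edges, probs = _edge_probabilities(net, cfg)
    adjacency: dict = {}
    for eidx, (u, v, _) in enumerate(edges):
        adjacency.setdefault(u, []).append((eidx, v))
    rng = np.random.default_rng(cfg.seed)
    seeds = sorted(cfg.seed_nodes)
    base = np.empty(cfg.runs, dtype=np.int64)
    post = np.empty(cfg.runs, dtype=np.int64)
    for r in range(cfg.runs):
        live = rng.random(len(edges)) < probs  # one draw, both arms
        base[r] = _live_spread(adjacency, live, seeds)
        post[r] = _live_spread(adjacency, live, seeds, excluded=removal)
    base_s, post_s = _summary(base), _summary(post)
    all_removed = cfg.seed_nodes <= removal
    reduction = 100.0 * (1.0 - post_s.mean / base_s.mean) if base_s.mean > 0 else 0.0
    return InterventionOutcome(
        strategy_label=strategy_label,
        removal_set=removal,
        baseline_spread=base_s.mean,
        baseline_se=base_s.se,
        post_removal_spread=post_s.mean,
        post_removal_se=post_s.se,
        reduction_percent=reduction,
        all_seeds_removed=all_removed,
        params={"p": cfg.p, "runs": cfg.runs, "seed": cfg.seed, "weighted": cfg.weighted},
    )


def removal_set_from_ranking(
    rankings: ScoreVector | Iterable[ScoreVector],
    k: int = 10,
    strategy: str | None = None,
) -> frozenset:
    """Top-k of one metric, or the union of top-k lists across several.

    ``strategy`` may be 'single-metric' or 'union-of-metrics'; when omitted
    it is inferred from whether one or several score vectors are given.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(rankings, ScoreVector):
        vectors = [rankings]
    else:
        vectors = list(rankings)
    if strategy == "single-metric" and len(vectors) != 1:
        raise ValueError("single-metric strategy expects exactly one score vector")
    out: set = set()
    for sv in vectors:
        out.update(sv.ranking()[:k])
    return frozenset(out)


def strategy_comparison(
    net: InteractionNetwork,
    cfg: CascadeConfig,
    strategies,
) -> list[InterventionOutcome]:
    """One intervention outcome per labelled removal set, sorted by reduction.

    All strategies share the same cascade configuration (hence the same
    per-run thresholds).  ``strategies`` is a mapping label -> node set or an
    iterable of (label, set) pairs; duplicate labels are an error.
    """
    if isinstance(strategies, Mapping):
        pairs = list(strategies.items())
    else:
        pairs = [(label, set(nodes)) for label, nodes in strategies]
        labels = [label for label, _ in pairs]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate strategy labels")
    if len(pairs) < 2:
        raise ValueError("strategy_comparison needs at least two strategies")
    outcomes = [
        evaluate_intervention(net, cfg, nodes, strategy_label=label)
        for label, nodes in pairs
    ]
    return sorted(outcomes, key=lambda o: (-o.reduction_percent, o.strategy_label))
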