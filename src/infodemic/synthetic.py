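"""Seeded generators for retweet-style directed networks with planted truth.

The generator emulates the qualitative features of a health-misinformation
retweet graph: heavy-tailed in-degrees from directed preferential attachment
(each arriving user "retweets" a few existing users chosen proportional to
in-degree + 1), a handful of planted hubs with boosted incoming reach,
planted high-vulnerability amplifiers, planted persistent spreaders wired
into reciprocal feedback motifs, misinformation-seed flags, and node
attributes (retweet counts rank-matched to in-degree, emotion-word counts
rank-matched to vulnerability).

Planted structure design: hubs are hosted on the earliest (already rich)
nodes and receive extra in-edges from many ordinary, low-out-degree users,
so they dominate both raw connectivity among organic accounts and the damped
propagation ranking.  Vulnerable amplifiers receive *more* raw in-edges, but
from dedicated bot-like amplifier accounts with no standing of their own
(teleport-level scores, diluted by their own out-degree), so the amplifiers
top the exposure-times-susceptibility ranking without displacing hubs from
the propagation top ranks.  Persistent spreaders sit in small reciprocal
cliques whose cumulative influence grows geometrically, primed by a few
ordinary feeders.  All outputs are reproducible bit-for-bit from
(spec, seed).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .network import InteractionNetwork, NodeAttributeTable, write_edge_list


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters; the defaults are the package's study conditions."""

    n: int = 500
    attachment_out: int = 3
    planted_hubs: int = 5
    hub_boost: int = 150            # extra in-edges per hub, ordinary sources
    planted_vulnerable: int = 5
    vulnerable_floor: float = 0.9   # planted vul0 drawn from [floor, 1]
    vulnerable_boost: int = 300     # in-edges per vulnerable node from amplifier accounts
    background_vul0_max: float = 0.5
    planted_persistent: int = 3
    persistent_clique: int = 3      # reciprocal partners per persistent spreader
    persistent_feeders: int = 15    # ordinary in-edges priming each spreader
    misinfo_seed_fraction: float = 0.05
    islands: int = 0                # disconnected reciprocal pairs (fragmentation)
    seed: int = 0

    def __post_init__(self):
        if self.attachment_out < 1 or self.attachment_out >= self.n:
            raise ValueError("attachment_out must satisfy 1 <= attachment_out < n")
        if self.planted_hubs > self.n // 3:
            raise ValueError("planted_hubs must not exceed n // 3")
        if self.n // 3 + self.planted_vulnerable + self.planted_persistent > self.n:
            raise ValueError("n too small for the requested planted structure")
        if not 0.0 <= self.misinfo_seed_fraction <= 1.0:
            raise ValueError("misinfo_seed_fraction must lie in [0, 1]")
        if not 0.0 < self.vulnerable_floor <= 1.0:
            raise ValueError("vulnerable_floor must lie in (0, 1]")
        if not 0.0 <= self.background_vul0_max <= self.vulnerable_floor:
            raise ValueError("background_vul0_max must lie in [0, vulnerable_floor]")


def _node_id(i: int) -> str:
    return f"u{i:05d}"


def generate_network(
    spec: SyntheticSpec,
) -> tuple[InteractionNetwork, NodeAttributeTable, dict]:
    """Generate (network, attributes, manifest) from a seeded spec.

    The manifest records every planted identity so recovery experiments can
    score themselves against the generator's ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    n, m_out = spec.n, spec.attachment_out
    core = [_node_id(i) for i in range(n)]
    edges: dict[tuple[str, str], float] = {}

    def add_edge(u: str, v: str, w: float = 1.0) -> None:
        if u == v:
            return
        edges[(u, v)] = edges.get((u, v), 0.0) + w

    # -- preferential attachment growth (new user retweets existing users) --
    indeg = np.zeros(n)
    m0 = m_out + 1
    for i in range(1, m0):
        for j in range(i):
            add_edge(core[i], core[j])
            indeg[j] += 1
    for i in range(m0, n):
        weights = indeg[:i] + 1.0
        targets = rng.choice(i, size=m_out, replace=False, p=weights / weights.sum())
        for j in sorted(targets):
            add_edge(core[i], core[j])
            indeg[j] += 1

    # -- planted identities --------------------------------------------------
    # hubs sit on the earliest (organically richest) nodes; vulnerable and
    # persistent hosts are mid-growth accounts
    start = n // 3
    hubs = core[: spec.planted_hubs]
    vulnerable = core[start : start + spec.planted_vulnerable]
    persistent = core[
        start + spec.planted_vulnerable :
        start + spec.planted_vulnerable + spec.planted_persistent
    ]
    planted = set(hubs) | set(vulnerable) | set(persistent)
    pool = np.array([v for v in core if v not in planted])

    if spec.planted_hubs and len(pool) < spec.hub_boost:
        raise ValueError("n too small for hub_boost distinct sources")

    # hubs: many ordinary low-out-degree sources -> strong propagation pull
    for hub in hubs:
        sources = rng.choice(pool, size=spec.hub_boost, replace=False)
        for s in sorted(sources):
            add_edge(s, hub)

    # vulnerable amplifiers: dedicated bot-like amplifier accounts pointing
    # at every amplifier; highest raw exposure, but each amplifier account
    # has no incoming standing and its contribution is diluted 1/out-degree
    extra = n
    amplifier_sources: list[str] = []
    if vulnerable:
        for _ in range(spec.vulnerable_boost):
            src = _node_id(extra)
            extra += 1
            amplifier_sources.append(src)
            for v in vulnerable:
                add_edge(src, v)

    # persistent spreaders: reciprocal cliques (geometric influence growth),
    # plus ordinary feeders so the planted node is prominent from the first
    # step and outranks its dedicated partners throughout
    partners: dict[str, list[str]] = {}
    feeder_count = min(spec.persistent_feeders, len(pool))
    for p in persistent:
        group = [p]
        for _ in range(spec.persistent_clique):
            pid = _node_id(extra)
            extra += 1
            group.append(pid)
        partners[p] = group[1:]
        for a in group:
            for b in group:
                if a != b:
                    add_edge(a, b)
        feeders = rng.choice(pool, size=feeder_count, replace=False)
        for s in sorted(feeders):
            add_edge(s, p)

    # islands: disconnected reciprocal pairs for fragmentation scenarios
    island_nodes: list[str] = []
    for _ in range(spec.islands):
        a, b = _node_id(extra), _node_id(extra + 1)
        extra += 2
        add_edge(a, b)
        add_edge(b, a)
        island_nodes.extend([a, b])

    all_nodes = sorted(
        core
        + amplifier_sources
        + [v for vs in partners.values() for v in vs]
        + island_nodes
    )
    net = InteractionNetwork.from_edges(
        [(u, v, w) for (u, v), w in sorted(edges.items())], nodes=all_nodes
    )

    # -- node attributes ----------------------------------------------------
    nodes = net.nodes
    size = len(nodes)
    vul_set = set(vulnerable)
    vul0 = np.empty(size)
    for i, v in enumerate(nodes):  # draws consumed in ascending node-id order
        if v in vul_set:
            vul0[i] = rng.uniform(spec.vulnerable_floor, 1.0)
        else:
            vul0[i] = rng.uniform(0.0, spec.background_vul0_max)

    in_degrees = np.array([net.degree_of(v, "in") for v in nodes])
    # retweet counts: heavy-tailed draws rank-matched to in-degree, then
    # bounded multiplicative noise (correlation without an exact copy)
    draws = np.sort(rng.lognormal(mean=3.0, sigma=1.0, size=size))[::-1] * 10.0
    order = sorted(range(size), key=lambda i: (-in_degrees[i], nodes[i]))
    retweet = np.zeros(size)
    for rank, i in enumerate(order):
        retweet[i] = draws[rank]
    retweet = np.maximum(0, np.round(retweet * rng.uniform(0.9, 1.1, size=size))).astype(int)

    # emotion-word counts: rank-matched to vul0 (vulnerability proxy)
    emo_draws = np.sort(rng.poisson(lam=12.0, size=size))[::-1]
    order = sorted(range(size), key=lambda i: (-vul0[i], nodes[i]))
    emotion = np.zeros(size, dtype=int)
    for rank, i in enumerate(order):
        emotion[i] = emo_draws[rank]

    misinfo = rng.random(size) < spec.misinfo_seed_fraction

    frame = pd.DataFrame(
        {
            "vul0": vul0,
            "retweet_count": retweet,
            "emotion_word_count": emotion,
            "misinfo_seed": misinfo,
        },
        index=pd.Index(nodes, name="node_id"),
    )
    attrs = NodeAttributeTable(frame)

    manifest = {
        "spec": dataclasses.asdict(spec),
        "n_nodes": net.n,
        "n_edges": net.m,
        "planted_hubs": list(hubs),
        "planted_vulnerable": list(vulnerable),
        "planted_persistent": list(persistent),
        "persistent_partners": {p: list(ps) for p, ps in partners.items()},
        "amplifier_sources": amplifier_sources,
        "island_nodes": island_nodes,
        "misinfo_seeds": [v for i, v in enumerate(nodes) if misinfo[i]],
    }
    return net, attrs, manifest


def write_bundle(
    net: InteractionNetwork,
    attrs: NodeAttributeTable,
    manifest: dict,
    out_dir,
) -> dict:
    """Write edges.tsv, attributes.tsv, manifest.json and a README; return paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "edges": out / "edges.tsv",
        "attributes": out / "attributes.tsv",
        "manifest": out / "manifest.json",
        "readme": out / "README.txt",
    }
    write_edge_list(net, paths["edges"])
    attrs.write(paths["attributes"])
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    paths["readme"].write_text(
        "Synthetic retweet-style misinformation network\n"
        f"nodes: {net.n}, edges: {net.m}\n"
        f"planted hubs: {', '.join(manifest['planted_hubs']) or '(none)'}\n"
        f"planted vulnerable: {', '.join(manifest['planted_vulnerable']) or '(none)'}\n"
        f"planted persistent: {', '.join(manifest['planted_persistent']) or '(none)'}\n"
        "See manifest.json for the full planted ground truth.\n"
    )
    return {k: str(v) for k, v in paths.items()}
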