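"""End-to-end validation pipeline: all seven metrics on one dataset.

This is the generic "run the whole framework on a (second) dataset"
workflow: compute the four traditional and three novel centralities, compare
their top-k lists (overlap partition, coverage gain of the combined pool over
the traditional union), align the novel metrics with observable proxies when
the attribute table carries them, and contrast node-removal interventions
built from the traditional union versus the traditional + novel union.
"""

from __future__ import annotations

import json
from pathlib import Path

from . import advanced, classical, compare, simulate
from ._util import fork_seed, write_provenance
from .network import InteractionNetwork, NodeAttributeTable, write_scores

TRADITIONAL_METRICS = ("degree", "closeness", "betweenness", "eigenvector")
NOVEL_METRICS = ("pc", "mvc", "dic")


def compute_all_metrics(
    net: InteractionNetwork,
    attrs: NodeAttributeTable | None = None,
    seed: int = 0,
) -> dict:
    """All seven score vectors keyed by metric name."""
    vectors = {
        "degree": classical.degree_centrality(net, mode="total"),
        "closeness": classical.closeness_centrality(net, formulation="auto"),
        "betweenness": classical.betweenness_centrality(net),
    }
    vectors["eigenvector"], _ = classical.eigenvector_centrality(net)
    vectors["pc"], _ = advanced.propagation_centrality(net)
    init = advanced.initialise_vulnerability(
        net, attrs=attrs, seed=fork_seed(seed, "mvc-init")
    )
    vectors["mvc"], _ = advanced.misinformation_vulnerability_centrality(net, init)
    vectors["dic"], _ = advanced.dynamic_influence_centrality(net)
    return vectors


def pipeline_all(
    net: InteractionNetwork,
    attrs: NodeAttributeTable | None = None,
    k: int = 10,
    p: float = 0.1,
    runs: int = 200,
    seed: int = 0,
    out_dir=None,
) -> dict:
    """Run the full framework; return (and optionally write) a report bundle."""
    vectors = compute_all_metrics(net, attrs=attrs, seed=seed)
    tops = {name: compare.top_k(sv, k) for name, sv in vectors.items()}

    trad_lists = {name: tops[name] for name in TRADITIONAL_METRICS}
    all_lists = {name: tops[name] for name in TRADITIONAL_METRICS + NOVEL_METRICS}
    trad_cmp = compare.overlap_partition(trad_lists)
    full_cmp = compare.overlap_partition(all_lists)
    base_union = set(trad_cmp.union)
    combined_union = set(full_cmp.union)
    gain = compare.coverage_gain(base_union, combined_union)
    full_cmp.coverage_gain_percent = gain

    report: dict = {
        "k": k,
        "metrics": sorted(vectors),
        "top_k": {name: list(lst) for name, lst in tops.items()},
        "traditional_union_size": len(base_union),
        "combined_union_size": len(combined_union),
        "coverage_gain_percent": gain,
        "traditional_partition": {
            compare.TopKComparison.label(s): sorted(nodes)
            for s, nodes in trad_cmp.partition.items()
        },
        "novel_exclusivity": {
            name: compare.exclusivity_fraction(tops[name], trad_lists).exclusivity
            for name in NOVEL_METRICS
        },
    }

    # proxy alignment, when the attribute table carries the proxy columns
    proxies = {}
    if attrs is not None and attrs.has_column("retweet_count"):
        retweets = attrs.column("retweet_count")
        for name in ("pc", "dic"):
            if set(vectors[name].scores) <= set(retweets):
                al = compare.proxy_alignment(
                    vectors[name], retweets, k=k, proxy_name="retweet_count"
                )
                proxies[f"{name}_vs_retweets"] = {
                    "overlap_at_k": al.overlap_at_k,
                    "rank_correlation": al.rank_correlation,
                }
    if attrs is not None and attrs.has_column("emotion_word_count"):
        emotion = attrs.column("emotion_word_count")
        if set(vectors["mvc"].scores) <= set(emotion):
            al = compare.proxy_alignment(
                vectors["mvc"], emotion, k=k, proxy_name="emotion_word_count"
            )
            proxies["mvc_vs_emotion"] = {
                "overlap_at_k": al.overlap_at_k,
                "rank_correlation": al.rank_correlation,
            }
    report["proxy_alignment"] = proxies if proxies else {"status": "skipped"}

    # intervention contrast: traditional union vs traditional + novel union
    seeds = _choose_seed_nodes(net, attrs)
    cfg = simulate.CascadeConfig(
        seed_nodes=frozenset(seeds), p=p, runs=runs, seed=fork_seed(seed, "cascade")
    )
    strategies = {
        "traditional-union": base_union,
        "traditional+novel-union": combined_union,
    }
    outcomes = simulate.strategy_comparison(net, cfg, strategies)
    report["intervention"] = {
        o.strategy_label: {
            "baseline_spread": o.baseline_spread,
            "post_removal_spread": o.post_removal_spread,
            "reduction_percent": o.reduction_percent,
            "removal_size": len(o.removal_set),
        }
        for o in outcomes
    }
    report["cascade"] = {"p": p, "runs": runs, "seed_nodes": sorted(seeds)}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, sv in vectors.items():
            write_scores(sv, out / f"scores_{name}.csv")
        (out / "partition_report.txt").write_text(full_cmp.report() + "\n")
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        write_provenance(out / "provenance.json", {"k": k, "p": p, "runs": runs, "seed": seed})
        report["artifacts"] = sorted(str(p.name) for p in out.iterdir())
    return report


def _choose_seed_nodes(net: InteractionNetwork, attrs: NodeAttributeTable | None) -> set:
    """Misinformation originators: flagged nodes, else the top-retweet node."""
    if attrs is not None and attrs.has_column("misinfo_seed"):
        flagged = {
            v for v, flag in attrs.column("misinfo_seed").items()
            if flag and net.has_node(v)
        }
        if flagged:
            return flagged
    if attrs is not None and attrs.has_column("retweet_count"):
        counts = {
            v: c for v, c in attrs.column("retweet_count").items() if net.has_node(v)
        }
        if counts:
            return {max(sorted(counts), key=lambda v: counts[v])}
    return {net.nodes[0]}
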