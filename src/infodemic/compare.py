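"""Top-k influencer extraction, overlap partitioning and proxy validation.

The comparison framework mirrors how competing centrality rankings are
usually summarised: take each metric's top-k list, partition the union of
lists by exactly which metrics contain each node ("exclusive" vs shared
blocks), quantify how much a new family of metrics extends the covered
influencer pool, and check rankings against observable proxies (retweet
counts for influence, emotion-word counts for vulnerability).
"""

from __future__ import annotations

import dataclasses
import re
import warnings
from collections.abc import Iterable, Mapping
from pathlib import Path

from scipy import stats

from .network import ScoreVector

#: Default emotion lexicon covering fear / outrage / conspiracy vocabulary.
#: A convenience word list for building the vulnerability proxy column from
#: post text; not a canonical psycholinguistic resource.
DEFAULT_EMOTION_LEXICON = frozenset(
    {
        "fear", "afraid", "scared", "terrified", "panic", "dread", "horror",
        "alarming", "outrage", "outraged", "anger", "angry", "furious",
        "disgust", "shocking", "scandal", "conspiracy", "coverup", "hoax",
        "fraud", "lie", "lies", "liar", "deceit", "corrupt", "sinister",
        "plot", "evil", "threat", "danger",
    }
)

_TOKEN = re.compile(r"[a-z0-9']+")


def load_lexicon(path) -> frozenset:
    """One term per line; '#' comments and blank lines ignored."""
    terms = set()
    for line in Path(path).read_text().splitlines():
        term = line.strip().lower()
        if term and not term.startswith("#"):
            terms.add(term)
    if not terms:
        raise ValueError(f"lexicon file {path} contains no terms")
    return frozenset(terms)


def count_emotion_terms(text: str, lexicon: Iterable[str] = DEFAULT_EMOTION_LEXICON) -> int:
    """Case-insensitive count of whole-token lexicon matches in ``text``.

    Tokenisation splits on whitespace/punctuation, so 'fearless' does not
    match 'fear'.
    """
    lex = {t.lower() for t in lexicon}
    if not lex:
        raise ValueError("lexicon must be non-empty")
    return sum(1 for tok in _TOKEN.findall(text.lower()) if tok in lex)


# -- top-k and overlap partitions ------------------------------------------


def top_k(sv: ScoreVector, k: int = 10) -> list:
    """The k highest-scoring nodes; ties break by ascending node id.

    If the network has fewer than k nodes the full (shorter) ranking is
    returned with a warning — a flagged success, not an error.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ranking = sv.ranking()
    if len(ranking) < k:
        warnings.warn(
            f"top_k: only {len(ranking)} nodes available for k={k}; "
            "returning the full ranking",
            stacklevel=2,
        )
    return ranking[:k]


@dataclasses.dataclass
class TopKComparison:
    """Per-metric top-k lists plus their exclusive/shared partition.

    ``partition`` maps the exact subset of list names containing a node
    (tuple in input order) to the node set of that block; blocks are pairwise
    disjoint and union to the union of all lists.
    """

    lists: dict
    partition: dict
    union: frozenset
    coverage_gain_percent: float | None = None

    @property
    def union_size(self) -> int:
        return len(self.union)

    @staticmethod
    def label(subset: tuple) -> str:
        if len(subset) == 1:
            return f"{subset[0]}-exclusive"
        return " & ".join(subset)

    def block_counts(self) -> dict:
        return {self.label(s): len(nodes) for s, nodes in self.partition.items()}

    def block(self, *names) -> frozenset:
        return self.partition.get(tuple(names), frozenset())

    def report(self) -> str:
        lines = [
            f"{'Category':<44} {'Count':>5}  Node IDs",
            "-" * 78,
        ]
        for subset, nodes in self.partition.items():
            ids = ", ".join(sorted(nodes))
            lines.append(f"{self.label(subset):<44} {len(nodes):>5}  {ids}")
        lines.append("-" * 78)
        lines.append(f"{'union':<44} {self.union_size:>5}")
        return "\n".join(lines)


def overlap_partition(lists) -> TopKComparison:
    """Partition the union of named top-k lists by exact membership subset.

    ``lists`` is a mapping name -> ordered node list, or an iterable of
    (name, list) pairs (duplicate names are an error).
    """
    if isinstance(lists, Mapping):
        pairs = list(lists.items())
    else:
        pairs = [(name, list(members)) for name, members in lists]
        names = [name for name, _ in pairs]
        if len(names) != len(set(names)):
            raise ValueError("duplicate list names in overlap_partition input")
    if len(pairs) < 2:
        raise ValueError("overlap_partition needs at least two named lists")
    names = [name for name, _ in pairs]
    sets = {name: set(members) for name, members in pairs}
    union = set().union(*sets.values())
    partition: dict = {}
    for node in union:
        subset = tuple(name for name in names if node in sets[name])
        partition.setdefault(subset, set()).add(node)
    # deterministic block order: by subset size desc then input order
    ordered = dict(
        sorted(
            ((s, frozenset(nodes)) for s, nodes in partition.items()),
            key=lambda item: (-len(item[0]), [names.index(n) for n in item[0]]),
        )
    )
    return TopKComparison(
        lists={name: tuple(members) for name, members in pairs},
        partition=ordered,
        union=frozenset(union),
    )


# -- coverage / exclusivity arithmetic -------------------------------------


def coverage_gain_from_counts(base_count: int, extended_count: int) -> float:
    """100 * (extended - base) / base, to 2 decimals (e.g. 29 -> 42: 44.83)."""
    if base_count <= 0:
        raise ValueError("base count must be positive")
    if extended_count < base_count:
        raise ValueError("extended count must be >= base count")
    return round(100.0 * (extended_count - base_count) / base_count, 2)


def coverage_gain(base_union: Iterable, extended_union: Iterable) -> float:
    """Percentage growth of the influencer pool from base to extended union."""
    base, ext = set(base_union), set(extended_union)
    if not base:
        raise ValueError("base union must be non-empty")
    if not base <= ext:
        raise ValueError("base union must be a subset of the extended union")
    return coverage_gain_from_counts(len(base), len(ext))


def relative_improvement(base_percent: float, new_percent: float) -> float:
    """Relative change of an outcome rate, e.g. 50% -> 62.5% gives 25.0."""
    if base_percent == 0:
        raise ValueError("base percentage must be non-zero")
    return round(100.0 * (new_percent - base_percent) / base_percent, 2)


@dataclasses.dataclass
class ExclusivityResult:
    exclusivity: float  # fraction of candidate absent from every reference list
    overlap: float      # complement: present in at least one reference list
    exclusive_nodes: frozenset
    shared_nodes: frozenset


def exclusivity_fraction(candidate: Iterable, reference_lists) -> ExclusivityResult:
    """Fraction of a candidate top-k list unseen by the reference lists."""
    cand = list(candidate)
    if not cand:
        raise ValueError("candidate list must be non-empty")
    if isinstance(reference_lists, Mapping):
        reference = set().union(*(set(v) for v in reference_lists.values()))
    else:
        reference = set(reference_lists)
    exclusive = frozenset(v for v in cand if v not in reference)
    shared = frozenset(v for v in cand if v in reference)
    return ExclusivityResult(
        exclusivity=len(exclusive) / len(cand),
        overlap=len(shared) / len(cand),
        exclusive_nodes=exclusive,
        shared_nodes=shared,
    )


# -- proxy ground-truth alignment ------------------------------------------


@dataclasses.dataclass
class ProxyAlignment:
    """Agreement between a metric ranking and an observable proxy ranking."""

    proxy_name: str
    k: int
    overlap_at_k: float       # |top-k(metric) ∩ top-k(proxy)| / k
    rank_correlation: float   # Spearman with midrank ties, in [-1, 1]
    n: int


def proxy_alignment(
    sv: ScoreVector, proxy: Mapping, k: int = 10, proxy_name: str = "proxy"
) -> ProxyAlignment:
    """Compare a metric against a higher-is-better proxy value mapping.

    The rank correlation is Spearman's rho (1 - 6*sum(d^2)/(n(n^2-1)) with
    midranks for ties) over the full rankings; overlap@k compares the two
    top-k sets.  Every scored node must have a proxy value.
    """
    nodes = sorted(sv.scores)
    missing = [v for v in nodes if v not in proxy]
    if missing:
        raise ValueError(f"proxy values missing for nodes: {missing}")
    if len(nodes) < 2:
        raise ValueError("proxy alignment needs at least two nodes")
    metric_vals = [sv.scores[v] for v in nodes]
    proxy_vals = [float(proxy[v]) for v in nodes]
    rho = float(stats.spearmanr(metric_vals, proxy_vals).statistic)
    k_eff = min(k, len(nodes))
    metric_top = set(sv.ranking()[:k_eff])
    proxy_top = set(
        sorted(nodes, key=lambda v: (-float(proxy[v]), v))[:k_eff]
    )
    return ProxyAlignment(
        proxy_name=proxy_name,
        k=k_eff,
        overlap_at_k=len(metric_top & proxy_top) / k_eff,
        rank_correlation=rho,
        n=len(nodes),
    )
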