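"""Directed weighted interaction networks and their delimited on-disk formats.

The central container is :class:`InteractionNetwork`: a directed graph whose
nodes are opaque string identifiers (users) and whose edges carry a strictly
positive weight representing interaction strength or frequency (e.g. number of
retweets).  Edge lists, node attribute tables and score files are plain
delimited text; no binary formats are read or written.
"""

from __future__ import annotations

import dataclasses
import json
import re
from collections.abc import Iterable, Mapping
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp


class ParseError(ValueError):
    """Malformed input file (message names the offending line or node)."""


_WS = re.compile(r"\s+")


def _clean_id(raw: str) -> str:
    """Normalise a node identifier: strip and remove internal whitespace.

    Dataset exports sometimes print grouping spaces inside numeric IDs
    (e.g. ``"11 019"``); those collapse to ``"11019"``.
    """
    return _WS.sub("", raw.strip())


@dataclasses.dataclass
class LoadReport:
    rows_read: int = 0
    edges_kept: int = 0
    self_loops_dropped: int = 0
    duplicates_merged: int = 0
    nodes: int = 0


class InteractionNetwork:
    """Directed weighted graph G = (V, E) with adjacency entries a_ij = w_ij.

    Invariants: every edge endpoint is a node; weights are strictly positive;
    duplicate (source, target) pairs have been weight-summed; self-loops are
    absent unless explicitly permitted at load time.
    """

    def __init__(self, graph: nx.DiGraph | None = None):
        self._g = graph if graph is not None else nx.DiGraph()
        self._order: tuple[str, ...] | None = None
        self.load_report: LoadReport | None = None

    # -- construction -----------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str] | tuple[str, str, float]],
        nodes: Iterable[str] = (),
        allow_self_loops: bool = False,
    ) -> "InteractionNetwork":
        """Build a network from (source, target[, weight]) tuples.

        Duplicate pairs are weight-summed; self-loops are dropped (and counted
        in the load report) unless ``allow_self_loops``.
        """
        report = LoadReport()
        g = nx.DiGraph()
        for nid in nodes:
            g.add_node(str(nid))
        for row in edges:
            u, v = str(row[0]), str(row[1])
            w = float(row[2]) if len(row) > 2 else 1.0
            report.rows_read += 1
            if w <= 0 or not np.isfinite(w):
                raise ParseError(f"edge ({u}, {v}): non-positive weight {w!r}")
            if u == v and not allow_self_loops:
                report.self_loops_dropped += 1
                g.add_node(u)
                continue
            if g.has_edge(u, v):
                g[u][v]["weight"] += w
                report.duplicates_merged += 1
            else:
                g.add_edge(u, v, weight=w)
        report.edges_kept = g.number_of_edges()
        report.nodes = g.number_of_nodes()
        net = cls(g)
        net.load_report = report
        return net

    # -- basic views ------------------------------------------------------

    @property
    def nodes(self) -> tuple[str, ...]:
        """Node identifiers in ascending (lexicographic) order."""
        if self._order is None:
            self._order = tuple(sorted(self._g.nodes))
        return self._order

    @property
    def node_set(self) -> frozenset:
        return frozenset(self._g.nodes)

    @property
    def n(self) -> int:
        return self._g.number_of_nodes()

    @property
    def m(self) -> int:
        return self._g.number_of_edges()

    def has_node(self, v: str) -> bool:
        return self._g.has_node(v)

    def edges(self) -> list[tuple[str, str, float]]:
        """Edges as (source, target, weight), sorted for determinism."""
        return sorted((u, v, d["weight"]) for u, v, d in self._g.edges(data=True))

    def weight(self, u: str, v: str) -> float:
        return self._g[u][v]["weight"]

    def _require(self, v: str) -> None:
        if not self._g.has_node(v):
            raise KeyError(f"unknown node {v!r}")

    def in_neighbours(self, v: str) -> set:
        """N_in(v) = {u : (u, v) in E}."""
        self._require(v)
        return set(self._g.predecessors(v))

    def out_neighbours(self, v: str) -> set:
        self._require(v)
        return set(self._g.successors(v))

    def degree_of(self, v: str, mode: str = "total") -> int:
        """Count of distinct edges at v by direction; total = in + out."""
        self._require(v)
        if mode == "in":
            return self._g.in_degree(v)
        if mode == "out":
            return self._g.out_degree(v)
        if mode == "total":
            return self._g.in_degree(v) + self._g.out_degree(v)
        raise ValueError(f"mode must be 'in', 'out' or 'total', got {mode!r}")

    def remove_nodes(self, removal: Iterable[str]) -> "InteractionNetwork":
        """Induced subgraph on the remaining nodes; the input is unmodified."""
        removal = set(removal)
        unknown = removal - self.node_set
        if unknown:
            raise KeyError(f"unknown nodes in removal set: {sorted(unknown)}")
        g = self._g.copy()
        g.remove_nodes_from(removal)
        return InteractionNetwork(g)

    def adjacency_matrix(self, binary: bool = False) -> sp.csr_array:
        """A[i, j] = w_ij for edge nodes[i] -> nodes[j] (binary: 1)."""
        order = self.nodes
        idx = {v: i for i, v in enumerate(order)}
        rows, cols, vals = [], [], []
        for u, v, w in self.edges():
            rows.append(idx[u])
            cols.append(idx[v])
            vals.append(1.0 if binary else w)
        return sp.csr_array(
            (vals, (rows, cols)), shape=(self.n, self.n), dtype=float
        )

    def to_networkx(self) -> nx.DiGraph:
        return self._g.copy()

    @property
    def graph(self) -> nx.DiGraph:
        """Read-only access to the underlying networkx digraph."""
        return self._g

    def __eq__(self, other) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return self.node_set == other.node_set and self.edges() == other.edges()

    def __repr__(self) -> str:
        return f"InteractionNetwork(n={self.n}, m={self.m})"


# -- spec-level functional wrappers ---------------------------------------


def in_neighbours(net: InteractionNetwork, v: str) -> set:
    return net.in_neighbours(v)


def degree_of(net: InteractionNetwork, v: str, mode: str = "total") -> int:
    return net.degree_of(v, mode)


def remove_nodes(net: InteractionNetwork, removal: Iterable[str]) -> InteractionNetwork:
    return net.remove_nodes(removal)


# -- edge-list reader ------------------------------------------------------


def _detect_delimiter(line: str) -> str | None:
    if "\t" in line:
        return "\t"
    if "," in line:
        return ","
    return None  # any-whitespace split


def _is_float(text: str) -> bool:
    try:
        float(text)
    except ValueError:
        return False
    return True


def read_edge_list(
    path,
    delimiter: str | None = None,
    has_header: bool | None = None,
    allow_self_loops: bool = False,
) -> InteractionNetwork:
    """Read a delimited edge list: ``source, target[, weight]`` per row.

    Lines starting with ``#`` and blank lines are ignored; the delimiter is
    auto-detected (tab, then comma, else whitespace) from the first data row
    when not given; missing weights default to 1.0.  ``has_header=None``
    auto-detects a header row (a non-numeric weight field, or leading fields
    named source/target).  Duplicate rows are weight-summed; self-loops are
    dropped and counted unless permitted.  The load report is attached as
    ``net.load_report``.
    """
    path = Path(path)
    rows: list[tuple[str, str, float]] = []
    first_data_line = True
    header_skipped = has_header is not True
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if not header_skipped:
                header_skipped = True
                continue
            if delimiter is None:
                delimiter = _detect_delimiter(line)
            fields = line.split(delimiter) if delimiter else line.split()
            fields = [f.strip() for f in fields]
            if first_data_line:
                first_data_line = False
                if has_header is None and len(fields) in (2, 3):
                    looks_named = tuple(f.lower() for f in fields[:2]) == ("source", "target")
                    looks_nonnumeric_weight = len(fields) == 3 and not _is_float(fields[2])
                    if looks_named or looks_nonnumeric_weight:
                        continue
            if len(fields) not in (2, 3):
                raise ParseError(
                    f"{path.name} line {lineno}: expected 2 or 3 fields, got {len(fields)}"
                )
            u, v = _clean_id(fields[0]), _clean_id(fields[1])
            if not u or not v:
                raise ParseError(f"{path.name} line {lineno}: empty node identifier")
            if len(fields) == 3:
                try:
                    w = float(fields[2])
                except ValueError:
                    raise ParseError(
                        f"{path.name} line {lineno}: non-numeric weight {fields[2]!r}"
                    ) from None
                if w <= 0 or not np.isfinite(w):
                    raise ParseError(
                        f"{path.name} line {lineno}: non-positive weight {fields[2]}"
                    )
            else:
                w = 1.0
            rows.append((u, v, w))
    if not rows:
        raise ParseError(f"{path.name}: no edge rows found")
    return InteractionNetwork.from_edges(rows, allow_self_loops=allow_self_loops)


def write_edge_list(net: InteractionNetwork, path, delimiter: str = "\t") -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# infodemic edge list: {net.n} nodes, {net.m} edges\n")
        fh.write(delimiter.join(("source", "target", "weight")) + "\n")
        for u, v, w in net.edges():
            fh.write(delimiter.join((u, v, f"{w:.12g}")) + "\n")
        for v in net.nodes:  # keep isolated nodes round-trippable
            if net.degree_of(v, "total") == 0:
                fh.write(delimiter.join((v, v, "1")) + "\n")


# -- node attribute tables -------------------------------------------------

RECOGNISED_COLUMNS = ("vul0", "retweet_count", "emotion_word_count", "misinfo_seed")

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}


class NodeAttributeTable:
    """Per-node attributes keyed by node_id.

    Recognised columns: ``vul0`` (initial vulnerability in [0, 1]),
    ``retweet_count``, ``emotion_word_count`` (non-negative integers) and
    ``misinfo_seed`` (boolean misinformation-originator flag).  Unrecognised
    columns are preserved as opaque extras; absent values stay explicit (NaN).
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.index.has_duplicates:
            dup = sorted(frame.index[frame.index.duplicated()].unique())
            raise ParseError(f"duplicate node_id entries: {dup}")
        self._df = frame
        self._validate()

    def _validate(self) -> None:
        if "vul0" in self._df.columns:
            col = self._df["vul0"]
            bad = col[(col.notna()) & ((col < 0) | (col > 1))]
            if len(bad):
                node = bad.index[0]
                raise ParseError(
                    f"vul0 out of [0, 1] for node {node!r}: {bad.iloc[0]}"
                )
        for name in ("retweet_count", "emotion_word_count"):
            if name in self._df.columns:
                col = self._df[name]
                bad = col[(col.notna()) & (col < 0)]
                if len(bad):
                    raise ParseError(
                        f"{name} negative for node {bad.index[0]!r}: {bad.iloc[0]}"
                    )

    @classmethod
    def from_mapping(cls, columns: Mapping[str, Mapping[str, object]]) -> "NodeAttributeTable":
        frame = pd.DataFrame({k: pd.Series(dict(v)) for k, v in columns.items()})
        frame.index = frame.index.astype(str)
        frame.index.name = "node_id"
        return cls(frame)

    @property
    def frame(self) -> pd.DataFrame:
        return self._df

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(sorted(self._df.index))

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(self._df.columns)

    def has_column(self, name: str) -> bool:
        return name in self._df.columns

    def column(self, name: str, nodes: Iterable[str] | None = None) -> dict:
        """Values of a column (restricted to ``nodes`` if given); NaN dropped."""
        series = self._df[name]
        if nodes is not None:
            series = series.reindex(list(nodes))
        return {str(k): v for k, v in series.items() if pd.notna(v)}

    def get(self, node: str, name: str, default=None):
        if node in self._df.index and name in self._df.columns:
            v = self._df.at[node, name]
            if pd.notna(v):
                return v.item() if hasattr(v, "item") else v
        return default

    def write(self, path, delimiter: str = "\t") -> None:
        df = self._df.copy()
        if "misinfo_seed" in df.columns:
            df["misinfo_seed"] = df["misinfo_seed"].map(
                lambda b: "" if pd.isna(b) else ("true" if b else "false")
            )
        df.sort_index().to_csv(path, sep=delimiter)

    def __len__(self) -> int:
        return len(self._df)


def read_node_attributes(path, delimiter: str | None = None) -> NodeAttributeTable:
    """Read a delimited attribute table with a header naming ``node_id``."""
    path = Path(path)
    df = pd.read_csv(
        path,
        sep=delimiter,
        engine="python",
        comment="#",
        dtype={"node_id": str},
        skipinitialspace=True,
    )
    if "node_id" not in df.columns:
        raise ParseError(f"{path.name}: header must name a node_id column")
    df["node_id"] = df["node_id"].map(_clean_id)
    if df["node_id"].duplicated().any():
        dup = sorted(df.loc[df["node_id"].duplicated(), "node_id"].unique())
        raise ParseError(f"{path.name}: duplicate node_id entries: {dup}")
    df = df.set_index("node_id")
    if "misinfo_seed" in df.columns:
        def _to_bool(v):
            if pd.isna(v):
                return np.nan
            s = str(v).strip().lower()
            if s in _TRUE:
                return True
            if s in _FALSE:
                return False
            raise ParseError(f"{path.name}: unparseable misinfo_seed value {v!r}")
        df["misinfo_seed"] = df["misinfo_seed"].map(_to_bool)
    for name in ("vul0",):
        if name in df.columns:
            df[name] = pd.to_numeric(df[name], errors="raise")
    return NodeAttributeTable(df)


# -- score vectors ---------------------------------------------------------


@dataclasses.dataclass
class ScoreVector:
    """A node -> score mapping tagged with the producing metric and params.

    ``normalised`` is None for raw scores, ``"minmax"`` when min maps to 0 and
    max to 1, or ``"max"`` when the vector was divided by its maximum.
    """

    metric_name: str
    scores: dict
    params: dict = dataclasses.field(default_factory=dict)
    normalised: str | None = None

    def ranking(self) -> list[str]:
        """Nodes from best to worst; ties broken by ascending node id."""
        return sorted(self.scores, key=lambda v: (-self.scores[v], v))

    def ranks(self) -> dict:
        """Rank 1 = highest score (competition order after the tie-break)."""
        return {v: i + 1 for i, v in enumerate(self.ranking())}

    def series(self) -> pd.Series:
        return pd.Series(self.scores, name=self.metric_name).sort_index()

    def covers(self, net: InteractionNetwork) -> bool:
        return set(self.scores) == net.node_set

    def __len__(self) -> int:
        return len(self.scores)


def write_scores(sv: ScoreVector, path, delimiter: str = ",") -> None:
    """Write ``node_id,score,rank`` with a ``#`` provenance header.

    Rank 1 is the highest score; ties break by ascending node id.  Scores are
    printed with 12 significant digits so a round-trip read agrees to that
    precision.
    """
    path = Path(path)
    ranks = sv.ranks()
    with path.open("w") as fh:
        fh.write("# infodemic scores\n")
        fh.write(f"# metric: {sv.metric_name}\n")
        fh.write(f"# params: {json.dumps(sv.params, sort_keys=True, default=str)}\n")
        fh.write(f"# normalised: {sv.normalised or 'none'}\n")
        fh.write(delimiter.join(("node_id", "score", "rank")) + "\n")
        for v in sv.ranking():
            fh.write(delimiter.join((v, f"{sv.scores[v]:.12g}", str(ranks[v]))) + "\n")


def read_scores(path) -> ScoreVector:
    """Read a score file produced by :func:`write_scores`."""
    path = Path(path)
    metric, params, normalised = "unknown", {}, None
    scores: dict = {}
    header_seen = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("metric:"):
                    metric = body.split(":", 1)[1].strip()
                elif body.startswith("params:"):
                    params = json.loads(body.split(":", 1)[1].strip())
                elif body.startswith("normalised:"):
                    val = body.split(":", 1)[1].strip()
                    normalised = None if val == "none" else val
                continue
            fields = [f.strip() for f in line.split(",")]
            if not header_seen:
                if fields[:2] != ["node_id", "score"]:
                    raise ParseError(f"{path.name} line {lineno}: bad score header")
                header_seen = True
                continue
            if len(fields) < 2:
                raise ParseError(f"{path.name} line {lineno}: expected node_id,score[,rank]")
            scores[_clean_id(fields[0])] = float(fields[1])
    if not header_seen:
        raise ParseError(f"{path.name}: missing score header")
    return ScoreVector(metric_name=metric, scores=scores, params=params, normalised=normalised)
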