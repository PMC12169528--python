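"""The four traditional baselines: degree, closeness, betweenness, eigenvector.

Degree and betweenness are the raw (unnormalised) counts and path-fraction
sums; closeness offers the standard reciprocal-of-distance-sum form with a
harmonic fallback for fragmented graphs; eigenvector centrality runs power
iteration on the (transposed) binary adjacency with a small uniform teleport
perturbation so the Perron-Frobenius preconditions (positivity,
irreducibility) hold even on disconnected graphs.

Shortest-path work is delegated to networkx (breadth-first search on hop
counts, Dijkstra on weighted distances, Brandes accumulation for
betweenness); the weighted distance of an edge is 1/weight, since weights are
interaction strengths, not costs.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

from .base import CentralityModel, NonConvergenceError, SpectralSummary
from .network import InteractionNetwork, ScoreVector


class DegreeCentrality(CentralityModel):
    """C_D(v) = deg(v) under the chosen direction; unnormalised counts."""

    metric_name = "degree"

    def __init__(self, network: InteractionNetwork, mode: str = "total"):
        super().__init__(network)
        if mode not in ("in", "out", "total"):
            raise ValueError(f"mode must be 'in', 'out' or 'total', got {mode!r}")
        self.mode = mode

    @property
    def params(self) -> dict:
        return {"mode": self.mode}

    def _compute(self):
        scores = {
            v: float(self.network.degree_of(v, self.mode)) for v in self.network.nodes
        }
        return scores, None, None, None


class ClosenessCentrality(CentralityModel):
    """Reciprocal distance-sum closeness with a harmonic fallback.

    standard:  C_C(v) = 1 / sum_{u != v} d(v, u), defined only when every
               other node is reachable;
    harmonic:  H(v) = sum_{u != v} 1 / d(v, u), unreachable terms contribute
               zero (well defined on fragmented graphs);
    auto:      standard when every ordered pair is reachable, else harmonic
               (the choice is recorded in the result params).

    ``direction='outgoing'`` uses distances from v; ``'incoming'`` distances
    to v.  Distances are hop counts.
    """

    metric_name = "closeness"

    def __init__(
        self,
        network: InteractionNetwork,
        formulation: str = "auto",
        direction: str = "outgoing",
    ):
        super().__init__(network)
        if formulation not in ("standard", "harmonic", "auto"):
            raise ValueError(f"unknown formulation {formulation!r}")
        if direction not in ("outgoing", "incoming"):
            raise ValueError(f"unknown direction {direction!r}")
        self.formulation = formulation
        self.direction = direction
        self._used: str | None = None

    @property
    def params(self) -> dict:
        return {
            "formulation": self.formulation,
            "formulation_used": self._used or self.formulation,
            "direction": self.direction,
        }

    def _distances(self, g: nx.DiGraph) -> dict:
        return {v: nx.single_source_shortest_path_length(g, v) for v in g.nodes}

    def _compute(self):
        g = self.network.graph
        if self.direction == "incoming":
            g = g.reverse(copy=False)
        dist = self._distances(g)
        n = self.network.n
        all_reachable = all(len(d) == n for d in dist.values())
        used = self.formulation
        if used == "auto":
            used = "standard" if all_reachable else "harmonic"
        if used == "standard" and not all_reachable:
            raise ValueError(
                "standard closeness undefined: some nodes cannot reach all others; "
                "use formulation='harmonic' or 'auto'"
            )
        scores = {}
        for v in self.network.nodes:
            d = dist[v]
            if used == "standard":
                total = sum(x for u, x in d.items() if u != v)
                scores[v] = 1.0 / total if total > 0 else 0.0
            else:
                scores[v] = float(sum(1.0 / x for u, x in d.items() if x > 0))
        self._used = used
        return scores, None, None, None


class BetweennessCentrality(CentralityModel):
    """C_B(v) = sum over ordered pairs s != t (both != v) of sigma_st(v)/sigma_st.

    Endpoints are excluded and no normalisation is applied (raw sums).
    Unweighted mode uses hop counts; weighted mode uses distance = 1/weight.
    Computed with the Brandes accumulation as implemented in networkx.
    """

    metric_name = "betweenness"

    def __init__(self, network: InteractionNetwork, weighted: bool = False):
        super().__init__(network)
        self.weighted = weighted

    @property
    def params(self) -> dict:
        return {"weighted": self.weighted}

    def _compute(self):
        g = self.network.graph
        if self.weighted:
            g = g.copy()
            for u, v, data in g.edges(data=True):
                g[u][v]["dist"] = 1.0 / data["weight"]
            raw = nx.betweenness_centrality(g, normalized=False, weight="dist")
        else:
            raw = nx.betweenness_centrality(g, normalized=False)
        return {v: float(raw[v]) for v in self.network.nodes}, None, None, None


class EigenvectorCentrality(CentralityModel):
    """Power iteration for the dominant eigenvector of the perturbed adjacency.

    The iteration matrix is M = B + (epsilon/n) * 1 1^T where B is the binary
    adjacency transposed for ``orientation='in'`` (incoming links confer
    status, matching the in-neighbour orientation of the propagation metric)
    or untransposed for ``orientation='out'``.  The epsilon teleport term
    makes M strictly positive, so the Perron-Frobenius theorem guarantees a
    unique positive dominant eigenvector; the returned scores are that vector,
    L2-normalised.  Convergence: successive-iterate L1 difference <= tol.
    """

    metric_name = "eigenvector"
    requires_edges = True

    def __init__(
        self,
        network: InteractionNetwork,
        tol: float = 1e-10,
        max_iter: int = 1000,
        epsilon_teleport: float = 1e-6,
        orientation: str = "in",
    ):
        super().__init__(network)
        if orientation not in ("in", "out"):
            raise ValueError(f"unknown orientation {orientation!r}")
        if epsilon_teleport <= 0:
            raise ValueError("epsilon_teleport must be positive")
        self.tol = tol
        self.max_iter = max_iter
        self.epsilon_teleport = epsilon_teleport
        self.orientation = orientation

    @property
    def params(self) -> dict:
        return {
            "tol": self.tol,
            "max_iter": self.max_iter,
            "epsilon_teleport": self.epsilon_teleport,
            "orientation": self.orientation,
        }

    def _compute(self):
        net = self.network
        n = net.n
        A = net.adjacency_matrix(binary=True)
        B = A.T if self.orientation == "in" else A
        eps_n = self.epsilon_teleport / n

        def op(x: np.ndarray) -> np.ndarray:
            return B @ x + eps_n * x.sum()

        x = np.full(n, 1.0 / np.sqrt(n))
        lam = 1.0
        delta = np.inf
        iters = 0
        for iters in range(1, self.max_iter + 1):
            y = op(x)
            lam = float(np.linalg.norm(y))
            x_new = y / lam
            delta = float(np.abs(x_new - x).sum())
            x = x_new
            if delta <= self.tol:
                break
        residual = float(np.linalg.norm(op(x) - lam * x))
        if delta > self.tol:
            raise NonConvergenceError(
                f"eigenvector power iteration did not converge in {self.max_iter} "
                f"iterations (last L1 change {delta:.3g})",
                residual=delta,
            )
        summary = SpectralSummary(
            dominant_eigenvalue=lam, iterations_used=iters, residual=residual
        )
        scores = {v: float(x[i]) for i, v in enumerate(net.nodes)}
        return scores, None, summary, None


# -- functional wrappers ---------------------------------------------------


def degree_centrality(net: InteractionNetwork, mode: str = "total") -> ScoreVector:
    return DegreeCentrality(net, mode=mode).fit().score_vector


def closeness_centrality(
    net: InteractionNetwork, formulation: str = "auto", direction: str = "outgoing"
) -> ScoreVector:
    return ClosenessCentrality(net, formulation, direction).fit().score_vector


def betweenness_centrality(net: InteractionNetwork, weighted: bool = False) -> ScoreVector:
    return BetweennessCentrality(net, weighted=weighted).fit().score_vector


def eigenvector_centrality(
    net: InteractionNetwork,
    tol: float = 1e-10,
    max_iter: int = 1000,
    epsilon_teleport: float = 1e-6,
    orientation: str = "in",
) -> tuple[ScoreVector, SpectralSummary]:
    res = EigenvectorCentrality(net, tol, max_iter, epsilon_teleport, orientation).fit()
    return res.score_vector, res.diagnostics
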