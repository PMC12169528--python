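"""The three purpose-built misinformation centralities: PC, MVC and DIC.

Propagation Centrality (PC) is a damped, in-neighbour propagation ranking:
the fixed point of

    x(v) = (1 - d)/n + d * sum_{u in N_in(v)} x(u) / d_out(u)

with damping d (default 0.85).  It captures steady-state influence: a node is
influential when influential nodes point at it.

Misinformation Vulnerability Centrality (MVC) couples a node's exposure with
its innate susceptibility.  Starting from vul_0 in [0, 1] (from attribute
data, from susceptibility feature columns, or drawn U(0, 1) from a seeded
generator), the vulnerability recurrence

    vul_{t+1}(v) = degree(v) * vul_t(v)

is iterated a small number of steps (default 5) with degree fixed on the
static snapshot, so the raw score has the closed form degree(v)^steps *
vul_0(v); the final vector is min-max normalised to [0, 1].

Dynamic Influence Centrality (DIC) accumulates influence over discrete
timesteps from an all-ones start:

    DIC_{t+1}(v) = DIC_t(v) + sum_{u in N_in(v)} DIC_t(u)

equivalently DIC_t = (I + B^T)^t 1 with B the binary adjacency; after a
bounded number of steps (default 10) the vector is normalised.  The whole
trajectory is kept so that persistence (being repeatedly in the per-step
top-k) can be profiled.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np

from .base import CentralityModel, SpectralSummary
from .network import InteractionNetwork, NodeAttributeTable, ScoreVector

#: attribute columns accepted as susceptibility features for vul_0
#: (credibility proxy, unchecked retweets, misinformation engagement)
VULNERABILITY_FEATURES = ("low_credibility", "retweet_count", "emotion_word_count")

# raw values beyond this cannot be represented exactly / meaningfully in
# float64 integer arithmetic; the DIC guard refuses to cross it
_FLOAT_EXACT_LIMIT = 2.0**53


def _minmax(values: np.ndarray, degenerate: float = 0.5) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        return np.full_like(values, degenerate, dtype=float)
    return (values - lo) / (hi - lo)


# -- Propagation Centrality ------------------------------------------------


@dataclasses.dataclass
class PCParams:
    """Parameters of the damped propagation ranking.

    dangling_mode='literal' applies the printed update exactly (nodes without
    out-edges contribute nothing, so total mass leaks); 'redistribute' adds
    the dangling mass back uniformly, matching conventional damped ranking.
    weighted=False divides by the out-degree (edge count); the weighted
    variant divides each contribution w_uv / out-strength(u).
    """

    damping: float = 0.85
    max_iter: int = 100
    tol: float = 1e-9
    dangling_mode: str = "literal"
    weighted: bool = False

    def __post_init__(self):
        if not 0 < self.damping < 1:
            raise ValueError(f"damping must lie in (0, 1), got {self.damping}")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.dangling_mode not in ("literal", "redistribute"):
            raise ValueError(f"unknown dangling_mode {self.dangling_mode!r}")


class PropagationCentrality(CentralityModel):
    """Fixed point of the damped in-neighbour propagation equation."""

    metric_name = "pc"

    def __init__(self, network: InteractionNetwork, params: PCParams | None = None, **kw):
        super().__init__(network)
        self.pc_params = params if params is not None else PCParams(**kw)

    @property
    def params(self) -> dict:
        return dataclasses.asdict(self.pc_params)

    def _compute(self):
        p = self.pc_params
        net = self.network
        n = net.n
        A = net.adjacency_matrix(binary=not p.weighted)  # rows = sources
        out = np.asarray(A.sum(axis=1)).ravel()  # out-degree or out-strength
        dangling = out == 0.0
        inv_out = np.where(dangling, 0.0, 1.0 / np.where(dangling, 1.0, out))
        # M x propagates source scores along edges: (M x)_v = sum_u x_u/out_u
        M = (A * inv_out[:, None]).T.tocsr()

        d = p.damping
        teleport = (1.0 - d) / n
        x = np.full(n, 1.0 / n)  # uniform initialisation
        delta = np.inf
        iters = 0
        for iters in range(1, p.max_iter + 1):
            y = teleport + d * (M @ x)
            if p.dangling_mode == "redistribute":
                y += d * x[dangling].sum() / n
            delta = float(np.abs(y - x).sum())
            x = y
            if delta <= p.tol:
                break
        converged = delta <= p.tol
        if not converged:
            warnings.warn(
                f"propagation centrality stopped at max_iter={p.max_iter} with "
                f"L1 change {delta:.3g} > tol {p.tol:.3g}",
                RuntimeWarning,
                stacklevel=3,
            )
        # Perron-root estimate of the full (affine folded to linear) operator
        gx = d * (M @ x) + teleport * x.sum()
        if p.dangling_mode == "redistribute":
            gx += d * x[dangling].sum() / n
        lam = float(gx.sum() / x.sum())
        summary = SpectralSummary(
            dominant_eigenvalue=lam,
            iterations_used=iters,
            residual=delta,
            converged=converged,
        )
        scores = {v: float(x[i]) for i, v in enumerate(net.nodes)}
        return scores, None, summary, None


def propagation_centrality(
    net: InteractionNetwork, params: PCParams | None = None, **kw
) -> tuple[ScoreVector, SpectralSummary]:
    res = PropagationCentrality(net, params=params, **kw).fit()
    return res.score_vector, res.diagnostics


# -- Misinformation Vulnerability Centrality -------------------------------


@dataclasses.dataclass
class VulnerabilityState:
    """Per-node vulnerability trajectory vul_t across MVC timesteps.

    ``values`` has shape (t + 1, n) with row 0 the initial state (in [0, 1]);
    nodes are in ascending id order.  ``source`` records where vul_0 came
    from: 'attributes', 'features(...)' or 'seeded_uniform(seed)'.
    """

    nodes: tuple
    values: np.ndarray
    source: str
    degree_mode: str | None = None

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.nodes):
            raise ValueError("trajectory width must equal the node count")
        v0 = self.values[0]
        if ((v0 < 0) | (v0 > 1)).any():
            raise ValueError("vul_0 must lie in [0, 1] for every node")

    @property
    def t(self) -> int:
        return self.values.shape[0] - 1

    def vul0(self) -> dict:
        return {v: float(self.values[0, i]) for i, v in enumerate(self.nodes)}

    def trajectory_of(self, node) -> np.ndarray:
        return self.values[:, self.nodes.index(node)]


def initialise_vulnerability(
    net: InteractionNetwork,
    attrs: NodeAttributeTable | None = None,
    seed: int | None = None,
) -> VulnerabilityState:
    """Build the t = 0 vulnerability state.

    Priority: an explicit ``vul0`` attribute column covering every node; else
    the equal-weight mean of whichever susceptibility feature columns are
    present (min-max rescaled to [0, 1]); else U(0, 1) draws from a seeded
    generator, consumed in ascending node-id order for reproducibility.
    Partial attribute coverage is an error (no silent mixing of sources).
    """
    nodes = net.nodes
    if attrs is not None and attrs.has_column("vul0") and len(attrs.column("vul0")):
        col = attrs.column("vul0", nodes)
        missing = [v for v in nodes if v not in col]
        if missing:
            raise ValueError(
                f"attribute vul0 does not cover all nodes (missing e.g. {missing[:5]})"
            )
        v0 = np.array([float(col[v]) for v in nodes])
        source = "attributes"
    elif attrs is not None and any(attrs.has_column(c) for c in VULNERABILITY_FEATURES):
        present = [c for c in VULNERABILITY_FEATURES if attrs.has_column(c)]
        mat = []
        for c in present:
            col = attrs.column(c, nodes)
            missing = [v for v in nodes if v not in col]
            if missing:
                raise ValueError(
                    f"feature column {c!r} does not cover all nodes "
                    f"(missing e.g. {missing[:5]})"
                )
            mat.append([float(col[v]) for v in nodes])
        mean = np.asarray(mat, dtype=float).mean(axis=0)
        v0 = _minmax(mean)
        source = f"features({','.join(present)})"
    else:
        if seed is None:
            raise ValueError(
                "no vulnerability source: provide attrs with vul0/feature columns "
                "or a seed for the U(0,1) initialisation"
            )
        rng = np.random.default_rng(seed)
        v0 = rng.random(len(nodes))  # draws consumed in ascending node-id order
        source = f"seeded_uniform({seed})"
    return VulnerabilityState(nodes=nodes, values=v0[None, :], source=source)


class VulnerabilityCentrality(CentralityModel):
    """MVC: iterate vul_{t+1} = degree * vul_t, then min-max normalise.

    Degenerate min-max (all raw scores equal) maps every node to 0.5.  When
    degree^steps would overflow float64, the normalised scores are computed
    from the closed form in log space; overflowing trajectory entries are
    reported as inf.
    """

    metric_name = "mvc"

    def __init__(
        self,
        network: InteractionNetwork,
        init: VulnerabilityState,
        steps: int = 5,
        degree_mode: str = "in",
        max_steps: int = 10,
    ):
        super().__init__(network)
        if steps < 1:
            raise ValueError("steps must be >= 1")
        if steps > max_steps:
            raise ValueError(f"steps={steps} exceeds the configured ceiling {max_steps}")
        if degree_mode not in ("in", "out", "total"):
            raise ValueError(f"unknown degree_mode {degree_mode!r}")
        if tuple(init.nodes) != network.nodes:
            raise ValueError("vulnerability state does not match the network's nodes")
        self.init = init
        self.steps = steps
        self.degree_mode = degree_mode

    @property
    def params(self) -> dict:
        return {
            "steps": self.steps,
            "degree_mode": self.degree_mode,
            "vul0_source": self.init.source,
        }

    def _compute(self):
        net = self.network
        nodes = net.nodes
        deg = np.array([net.degree_of(v, self.degree_mode) for v in nodes], dtype=float)
        v0 = self.init.values[0].copy()
        traj = np.empty((self.steps + 1, len(nodes)))
        traj[0] = v0
        with np.errstate(over="ignore"):
            for t in range(1, self.steps + 1):
                traj[t] = deg * traj[t - 1]
        raw = traj[-1]
        if np.isinf(raw).any():
            norm = self._normalise_logspace(deg, v0)
        else:
            norm = _minmax(raw)
        state = VulnerabilityState(
            nodes=nodes, values=traj, source=self.init.source, degree_mode=self.degree_mode
        )
        scores = {v: float(norm[i]) for i, v in enumerate(nodes)}
        return scores, "minmax", None, {"trajectory": state}

    def _normalise_logspace(self, deg: np.ndarray, v0: np.ndarray) -> np.ndarray:
        # raw_i = deg_i^steps * v0_i; work with L_i = log raw_i, shifting by
        # the maximum so exp() stays finite: minmax(raw) =
        # (exp(L - Lmax) - exp(Lmin - Lmax)) / (1 - exp(Lmin - Lmax)).
        pos = (deg > 0) & (v0 > 0)
        L = np.full(len(deg), -np.inf)
        L[pos] = self.steps * np.log(deg[pos]) + np.log(v0[pos])
        lmax = L.max()
        if not np.isfinite(lmax):  # all raw zero
            return np.full(len(deg), 0.5)
        shifted = np.exp(L - lmax)  # zero raw values map to exp(-inf) = 0
        lo = shifted.min()
        if lo == 1.0:
            return np.full(len(deg), 0.5)
        return (shifted - lo) / (1.0 - lo)


def misinformation_vulnerability_centrality(
    net: InteractionNetwork,
    init: VulnerabilityState,
    steps: int = 5,
    degree_mode: str = "in",
) -> tuple[ScoreVector, VulnerabilityState]:
    res = VulnerabilityCentrality(net, init, steps=steps, degree_mode=degree_mode).fit()
    return res.score_vector, res.extras["trajectory"]


# -- Dynamic Influence Centrality ------------------------------------------


@dataclasses.dataclass
class InfluenceTrajectory:
    """Per-node cumulative influence DIC_t across timesteps (all-ones start)."""

    nodes: tuple
    values: np.ndarray  # shape (steps + 1, n), non-decreasing along axis 0
    steps: int

    def final(self) -> np.ndarray:
        return self.values[-1]

    def trajectory_of(self, node) -> np.ndarray:
        return self.values[:, self.nodes.index(node)]


class DynamicInfluence(CentralityModel):
    """DIC: cumulative in-neighbour influence over a bounded number of steps."""

    metric_name = "dic"

    def __init__(
        self,
        network: InteractionNetwork,
        steps: int = 10,
        normalisation: str = "max",
        weighted: bool = False,
    ):
        super().__init__(network)
        if steps < 1:
            raise ValueError("steps must be >= 1")
        if normalisation not in ("max", "minmax"):
            raise ValueError(f"unknown normalisation {normalisation!r}")
        self.steps = steps
        self.normalisation = normalisation
        self.weighted = weighted

    @property
    def params(self) -> dict:
        return {
            "steps": self.steps,
            "normalisation": self.normalisation,
            "weighted": self.weighted,
        }

    def _compute(self):
        net = self.network
        n = net.n
        A = net.adjacency_matrix(binary=not self.weighted)
        BT = A.T.tocsr()
        in_weight = np.asarray(BT.sum(axis=1)).ravel()  # in-degree / in-strength
        growth = 1.0 + (in_weight.max() if n else 0.0)
        if self.weighted:
            vals = np.ones(n, dtype=float)
        else:
            vals = np.ones(n, dtype=np.int64)
        traj = np.empty((self.steps + 1, n), dtype=vals.dtype)
        traj[0] = vals
        for t in range(1, self.steps + 1):
            # one growth step multiplies the max by at most (1 + max in-degree)
            if float(vals.max()) * growth > _FLOAT_EXACT_LIMIT:
                raise ValueError(
                    f"dynamic influence values would exceed the exact float64 "
                    f"range at step {t}; rerun with fewer steps"
                )
            vals = vals + BT @ vals
            traj[t] = vals
        final = traj[-1].astype(float)
        if self.normalisation == "max":
            norm = final / final.max()
        else:
            norm = _minmax(final)
        trajectory = InfluenceTrajectory(nodes=net.nodes, values=traj, steps=self.steps)
        scores = {v: float(norm[i]) for i, v in enumerate(net.nodes)}
        return scores, self.normalisation, None, {"trajectory": trajectory}


def dynamic_influence_centrality(
    net: InteractionNetwork,
    steps: int = 10,
    normalisation: str = "max",
    weighted: bool = False,
) -> tuple[ScoreVector, InfluenceTrajectory]:
    res = DynamicInfluence(net, steps=steps, normalisation=normalisation, weighted=weighted).fit()
    return res.score_vector, res.extras["trajectory"]


def persistence_profile(traj: InfluenceTrajectory, k: int) -> list:
    """Rank nodes by how many timesteps they spend in the per-step top-k.

    Each step's influence vector is max-normalised before the top-k cut (the
    cut is scale-invariant, so this matches ranking the raw vectors).  A node
    is "in the top-k" of a step when its value is at least the k-th largest,
    so boundary ties all count (at t = 0 every node ties and every node
    counts).  The final ordering breaks count ties by final influence, then
    ascending node id, and surfaces 'long-tail' persistent spreaders that
    stay prominent across snapshots rather than peaking once.
    """
    nodes = traj.nodes
    n = len(nodes)
    if traj.values.shape[0] < 2:
        raise ValueError("trajectory must contain at least two timesteps")
    if k > n:
        raise ValueError(f"k={k} exceeds the node count {n}")
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = dict.fromkeys(nodes, 0)
    for row in traj.values:
        step_scores = row / row.max()
        cutoff = np.partition(step_scores, n - k)[n - k]  # k-th largest value
        for i in range(n):
            if step_scores[i] >= cutoff:
                counts[nodes[i]] += 1
    final = {v: float(traj.values[-1, i]) for i, v in enumerate(nodes)}
    return sorted(nodes, key=lambda v: (-counts[v], -final[v], v))
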