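"""Model/Results base classes shared by all centrality metrics.

Each metric is a model object built from an :class:`InteractionNetwork`;
calling :meth:`CentralityModel.fit` runs the (possibly iterative) computation
and returns a :class:`CentralityResults` carrying the per-node scores, the
run's parameters, convergence diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import dataclasses

from .network import InteractionNetwork, ScoreVector, write_scores


class NonConvergenceError(RuntimeError):
    """Iterative scheme failed to converge within max_iter."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclasses.dataclass
class SpectralSummary:
    """Diagnostics of a power-iteration / fixed-point computation."""

    dominant_eigenvalue: float
    iterations_used: int
    residual: float
    converged: bool = True


class CentralityModel:
    """Base class: a centrality metric over a fixed interaction network."""

    metric_name = "centrality"
    requires_edges = False

    def __init__(self, network: InteractionNetwork):
        if network.n == 0:
            raise ValueError(f"{self.metric_name}: network has no nodes")
        if self.requires_edges and network.m == 0:
            raise ValueError(f"{self.metric_name}: network has no edges")
        self.network = network

    @property
    def params(self) -> dict:
        return {}

    def _compute(self):
        """Return (scores: dict, normalised: str|None, diagnostics, extras)."""
        raise NotImplementedError

    def fit(self) -> "CentralityResults":
        scores, normalised, diagnostics, extras = self._compute()
        sv = ScoreVector(
            metric_name=self.metric_name,
            scores=scores,
            params=dict(self.params),
            normalised=normalised,
        )
        assert sv.covers(self.network), "scores must cover exactly the network's nodes"
        return CentralityResults(self, sv, diagnostics=diagnostics, extras=extras)


class CentralityResults:
    """Fitted scores plus diagnostics for one metric on one network."""

    def __init__(self, model, score_vector, diagnostics=None, extras=None):
        self.model = model
        self.score_vector = score_vector
        self.diagnostics = diagnostics
        self.extras = extras if extras is not None else {}

    @property
    def scores(self) -> dict:
        return self.score_vector.scores

    @property
    def params(self) -> dict:
        return self.score_vector.params

    def ranking(self) -> list[str]:
        return self.score_vector.ranking()

    def top(self, k: int = 10) -> list[str]:
        return self.ranking()[: max(k, 0)]

    def save(self, path) -> None:
        write_scores(self.score_vector, path)

    def summary(self, top: int = 10) -> str:
        net = self.model.network
        lines = [
            f"{self.score_vector.metric_name} centrality results",
            "=" * 46,
            f"nodes: {net.n}    edges: {net.m}",
        ]
        if self.params:
            lines.append(
                "params: " + ", ".join(f"{k}={v}" for k, v in sorted(self.params.items()))
            )
        if self.score_vector.normalised:
            lines.append(f"normalisation: {self.score_vector.normalised}")
        if isinstance(self.diagnostics, SpectralSummary):
            d = self.diagnostics
            lines.append(
                f"dominant eigenvalue: {d.dominant_eigenvalue:.6g}   "
                f"iterations: {d.iterations_used}   residual: {d.residual:.3g}   "
                f"converged: {d.converged}"
            )
        lines.append("-" * 46)
        lines.append(f"{'rank':>4}  {'node':<16}  score")
        for i, v in enumerate(self.top(top), start=1):
            lines.append(f"{i:>4}  {v:<16}  {self.scores[v]:.6g}")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<CentralityResults {self.score_vector.metric_name!r} "
            f"n={len(self.score_vector)}>"
        )
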