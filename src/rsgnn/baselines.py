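"""Classical centrality baselines: degree, K-shell, betweenness, PageRank."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from rsgnn.netio import Network

__all__ = [
    "CentralityResult",
    "degree_centrality",
    "k_shell",
    "betweenness",
    "pagerank",
    "ranking_to_csv",
    "BASELINES",
]


@dataclass(frozen=True)
class CentralityResult:
    method: str
    scores: np.ndarray = field(repr=False)  # internal-index order

    def ranking(self, g: Network):
        """Descending score order, ties broken by internal index."""
        order = np.lexsort((np.arange(len(self.scores)), -self.scores))
        return [(g.node_ids[i], float(self.scores[i])) for i in order]


def degree_centrality(g: Network) -> CentralityResult:
    """DC(u) = k(u) / (n - 1)."""
    if g.n < 2:
        raise ValueError("degree centrality needs n >= 2")
    return CentralityResult("dc", g.degrees() / (g.n - 1))


def k_shell(g: Network) -> CentralityResult:
    """Iterative peeling: remove all nodes of degree <= s, assign shell s."""
    core = nx.core_number(g.to_networkx())
    return CentralityResult("ks", np.array([core[i] for i in range(g.n)], dtype=float))


def betweenness(g: Network) -> CentralityResult:
    """Unnormalized betweenness over unordered pairs (Brandes accumulation)."""
    nxg = g.to_networkx()
    if g.n > 1 and not nx.is_connected(nxg):
        raise ValueError("betweenness requires a connected graph; extract the LCC first")
    bc = nx.betweenness_centrality(nxg, normalized=False)
    return CentralityResult("bc", np.array([bc[i] for i in range(g.n)]))


def pagerank(g: Network, damping: float = 0.85, tol: float = 1e-9) -> CentralityResult:
    """Power-iteration PageRank; scores sum to 1.

    Undirected edges are treated as a pair of opposite directed edges.
    """
    nxg = g.to_networkx()
    if g.n > 1 and not nx.is_connected(nxg):
        raise ValueError("pagerank requires a connected graph; extract the LCC first")
    try:
        pr = nx.pagerank(nxg, alpha=damping, tol=tol, max_iter=500)
    except nx.PowerIterationFailedConvergence as exc:
        raise RuntimeError(f"pagerank failed to converge: {exc}") from exc
    return CentralityResult("pr", np.array([pr[i] for i in range(g.n)]))


BASELINES = {
    "dc": degree_centrality,
    "ks": k_shell,
    "bc": betweenness,
    "pr": pagerank,
}


def ranking_to_csv(g: Network, result: CentralityResult, path) -> None:
    """Same node,score,rank format as the model's ranking export."""
    lines = ["node,score,rank"]
    for pos, (label, score) in enumerate(result.ranking(g), start=1):
        lines.append(f"{label},{score:.10g},{pos}")
    Path(path).write_text("\n".join(lines) + "\n")
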