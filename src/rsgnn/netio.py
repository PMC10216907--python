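"""Graph ingestion, synthetic generators, and descriptive statistics.

Graphs are undirected and simple.  Every :class:`Network` carries a
deterministic internal indexing: original labels are sorted (numerically
when every label parses as an integer, lexicographically otherwise) and
mapped to ``0..n-1``.  All matrices produced elsewhere in the package are
addressed by these internal indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "NetworkStats",
    "read_edgelist",
    "write_edgelist",
    "read_gml",
    "largest_connected_component",
    "generate_ba",
    "generate_lfr",
    "network_stats",
    "stats_to_csv",
]


def _sort_labels(labels: Iterable) -> list:
    labels = list(labels)
    try:
        return sorted(labels, key=lambda x: (0, int(x)))
    except (TypeError, ValueError):
        return sorted(labels, key=str)


@dataclass(frozen=True)
class Network:
    """An undirected simple graph with a stable internal indexing.

    Attributes
    ----------
    node_ids : list
        Original labels, in internal-index order (sorted).
    edges : frozenset of (int, int)
        Unordered edges as internal-index pairs ``(i, j)`` with ``i < j``.
    """

    node_ids: list
    edges: frozenset = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.node_ids)

    @property
    def m_edges(self) -> int:
        return len(self.edges)

    def __post_init__(self):
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop at internal index {i}")
            if not (0 <= i < self.n and 0 <= j < self.n):
                raise ValueError(f"edge ({i},{j}) out of range for n={self.n}")
            if i > j:
                raise ValueError("edges must be stored as (i, j) with i < j")

    @classmethod
    def from_edges(cls, labeled_edges: Iterable[tuple], nodes: Optional[Iterable] = None) -> "Network":
        """Build from original-label edges, collapsing duplicates and self-loops."""
        label_set = set(nodes) if nodes is not None else set()
        pairs = []
        dropped = 0
        for u, v in labeled_edges:
            label_set.add(u)
            label_set.add(v)
            if u == v:
                dropped += 1
                continue
            pairs.append((u, v))
        node_ids = _sort_labels(label_set)
        index = {lab: i for i, lab in enumerate(node_ids)}
        edge_set = set()
        for u, v in pairs:
            i, j = index[u], index[v]
            key = (i, j) if i < j else (j, i)
            if key in edge_set:
                dropped += 1
            else:
                edge_set.add(key)
        if dropped:
            logger.info("dropped %d self-loop/duplicate edge records", dropped)
        return cls(node_ids=node_ids, edges=frozenset(edge_set))

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Network":
        return cls.from_edges(g.edges(), nodes=g.nodes())

    def to_networkx(self) -> nx.Graph:
        """NetworkX view on internal indices (0..n-1)."""
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edges)
        return g

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric 0/1 CSR adjacency addressed by internal indices."""
        if not self.edges:
            return sp.csr_matrix((self.n, self.n), dtype=np.int64)
        rows, cols = [], []
        for i, j in self.edges:
            rows += [i, j]
            cols += [j, i]
        data = np.ones(len(rows), dtype=np.int64)
        return sp.csr_matrix((data, (rows, cols)), shape=(self.n, self.n))

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=np.int64)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def neighbors(self, i: int) -> np.ndarray:
        """Sorted internal indices of the neighbors of node ``i``."""
        adj = self.adjacency()
        return adj.indices[adj.indptr[i]:adj.indptr[i + 1]].copy()


@dataclass(frozen=True)
class NetworkStats:
    """The six catalog-style statistics: n, |E|, <k>, max degree, C, r."""

    n: int
    m_edges: int
    avg_degree: float
    max_degree: int
    clustering: float
    assortativity: Optional[float]  # None when endpoint degrees have zero variance


def read_edgelist(path, delimiter: Optional[str] = None) -> Network:
    """Read a whitespace/comma-delimited edge list.

    Lines starting with ``#`` are ignored.  The delimiter is auto-detected
    among space, tab and comma unless given.  Self-loops and duplicate
    (including reversed-duplicate) edges are collapsed silently; the count
    of dropped records is logged.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise IOError(f"cannot read edge list {path}: {exc}") from exc
    edges = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if delimiter is not None:
            tokens = [t for t in line.split(delimiter) if t]
        elif "," in line:
            tokens = [t.strip() for t in line.split(",") if t.strip()]
        else:
            tokens = line.split()
        if len(tokens) < 2:
            raise ValueError(f"{path}:{lineno}: expected >= 2 tokens, got {len(tokens)}")
        edges.append((tokens[0], tokens[1]))
    return Network.from_edges(edges)


def write_edgelist(g: Network, path, delimiter: str = " ") -> None:
    """Write one edge per line using original labels."""
    path = Path(path)
    lines = []
    for i, j in sorted(g.edges):
        lines.append(f"{g.node_ids[i]}{delimiter}{g.node_ids[j]}")
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def read_gml(path) -> Network:
    """Optional GML reader (delegates to networkx)."""
    return Network.from_networkx(nx.read_gml(Path(path), label="id"))


def largest_connected_component(g: Network) -> Network:
    """Induced subgraph on the largest component, original labels preserved.

    Ties between equally sized components are broken in favor of the one
    containing the smallest minimum original label (i.e., the smallest
    internal index).
    """
    if g.n == 0:
        raise ValueError("empty graph has no connected component")
    comps = sorted(
        nx.connected_components(g.to_networkx()),
        key=lambda c: (-len(c), min(c)),
    )
    keep = comps[0]
    labels = {g.node_ids[i] for i in keep}
    edges = [
        (g.node_ids[i], g.node_ids[j]) for i, j in g.edges if i in keep and j in keep
    ]
    return Network.from_edges(edges, nodes=labels)


def generate_ba(n: int, m_attach: int, seed: int) -> Network:
    """Barabási–Albert preferential-attachment graph.

    Starts from ``m_attach`` initially unconnected nodes (the standard
    construction), so the edge count is ``m_attach * (n - m_attach)``.
    """
    if not (1 <= m_attach < n):
        raise ValueError(f"require 1 <= m_attach < n, got m_attach={m_attach}, n={n}")
    return Network.from_networkx(nx.barabasi_albert_graph(n, m_attach, seed=seed))


def generate_lfr(
    n: int,
    tau1: float = 3.0,
    tau2: float = 1.5,
    mu: float = 0.1,
    avg_deg: float = 8.0,
    max_deg: int = 50,
    seed: int = 0,
    min_community: int = 50,
    max_community: int = 200,
) -> Network:
    """LFR community benchmark graph, reduced to its largest component.

    Delegates to the networkx benchmark implementation; infeasible
    parameter combinations raise with the generator's message.
    ``min_community`` must be at least the largest degree for community
    assignment to succeed, and ``max_community`` must exceed it: leaving
    the window degenerate makes the community-size sampler pathologically
    slow.
    """
    try:
        g = nx.LFR_benchmark_graph(
            n,
            tau1,
            tau2,
            mu,
            average_degree=avg_deg,
            max_degree=max_deg,
            min_community=min_community,
            max_community=max_community,
            seed=seed,
        )
    except Exception as exc:  # generator raises several exception types
        raise ValueError(f"LFR generation failed: {exc}") from exc
    g.remove_edges_from(nx.selfloop_edges(g))
    return largest_connected_component(Network.from_networkx(g))


def network_stats(g: Network) -> NetworkStats:
    """Compute n, |E|, <k>, max degree, average local clustering and
    degree assortativity.

    Clustering is the mean of local clustering coefficients with 0 assigned
    to nodes of degree < 2.  Assortativity is the Pearson correlation of
    degrees over edge endpoints; it is None when either endpoint-degree
    sequence is constant (0/0).
    """
    if g.n < 1:
        raise ValueError("need at least one node")
    deg = g.degrees()
    nxg = g.to_networkx()
    clustering = nx.average_clustering(nxg) if g.n > 0 else 0.0
    assort: Optional[float] = None
    if g.m_edges > 0:
        # explicit Pearson over the 2m (i, j) endpoint pairs
        pairs = np.array([(deg[i], deg[j]) for i, j in g.edges], dtype=float)
        x = np.concatenate([pairs[:, 0], pairs[:, 1]])
        y = np.concatenate([pairs[:, 1], pairs[:, 0]])
        sx, sy = x.std(), y.std()
        if sx > 0 and sy > 0:
            assort = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    return NetworkStats(
        n=g.n,
        m_edges=g.m_edges,
        avg_degree=2.0 * g.m_edges / g.n,
        max_degree=int(deg.max()) if g.n else 0,
        clustering=float(clustering),
        assortativity=assort,
    )


def stats_to_csv(named_stats: Sequence[tuple], path) -> None:
    """Export stats rows as CSV with the documented column set."""
    header = "network,n,edges,avg_degree,max_degree,clustering,assortativity"
    lines = [header]
    for name, s in named_stats:
        r = "" if s.assortativity is None else f"{s.assortativity:.6g}"
        lines.append(
            f"{name},{s.n},{s.m_edges},{s.avg_degree:.6g},{s.max_degree},"
            f"{s.clustering:.6g},{r}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
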