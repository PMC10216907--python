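"""Entropy-weighted node features.

Two per-node indicators — the degree ``k(u)`` and the neighbor average
degree ``kbar(u)`` — are fused into one basic feature ``B(u)`` with weights
derived from the entropy-weight method: an indicator whose distribution
over nodes is closer to uniform (high entropy) is less informative and
receives less weight.  Each node's input feature row stacks its own
``B`` value with those of its highest-degree neighbors, padded with zeros
to a fixed width (24 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from rsgnn.netio import Network

__all__ = [
    "EntropyWeights",
    "FeatureBundle",
    "neighbor_avg_degree",
    "entropy_weights",
    "basic_feature",
    "input_features",
    "build_features",
    "DEFAULT_WIDTH",
]

DEFAULT_WIDTH = 24


@dataclass(frozen=True)
class EntropyWeights:
    """Entropy values and the resulting indicator weights (omega1+omega2=1)."""

    H_k: float
    H_kbar: float
    omega1: float
    omega2: float


@dataclass(frozen=True)
class FeatureBundle:
    weights: EntropyWeights
    basic: np.ndarray  # (n,) B(u)
    features: np.ndarray  # (n, width) F


def neighbor_avg_degree(g: Network, u: int = None) -> np.ndarray | float:
    """Mean degree over first-order neighbors.

    With ``u`` given, returns the scalar for that node; otherwise the full
    per-node vector.  Isolated nodes are rejected (cannot occur after LCC
    extraction on graphs with >= 2 nodes).
    """
    deg = g.degrees().astype(float)
    if u is not None:
        nbrs = g.neighbors(u)
        if len(nbrs) == 0:
            raise ValueError(f"node {u} is isolated: neighbor average degree undefined")
        return float(deg[nbrs].mean())
    if (deg == 0).any():
        bad = int(np.argmax(deg == 0))
        raise ValueError(f"node {bad} is isolated: neighbor average degree undefined")
    adj = g.adjacency()
    return np.asarray(adj @ deg) / deg


def _indicator_entropy(values: np.ndarray, n: int) -> float:
    """Entropy of a min-max-normalized indicator, on a 0..1 scale.

    Shares are taken against the sum of normalized values; 0*ln(0) := 0.
    A constant indicator (min == max) degenerates to entropy 1: maximally
    uniform, hence non-informative.
    """
    vmin, vmax = values.min(), values.max()
    if vmax == vmin:
        return 1.0
    norm = (values - vmin) / (vmax - vmin)
    total = norm.sum()
    p = norm / total
    nz = p > 0
    return float(-np.sum(p[nz] * np.log(p[nz])) / np.log(n))


def entropy_weights(g: Network) -> EntropyWeights:
    """Entropy-weight fusion of degree and neighbor average degree."""
    if g.n < 3:
        raise ValueError("entropy weights need n >= 3")
    deg = g.degrees().astype(float)
    kbar = neighbor_avg_degree(g)
    H_k = _indicator_entropy(deg, g.n)
    H_kbar = _indicator_entropy(kbar, g.n)
    denom = 2.0 - H_k - H_kbar
    if denom <= 0:  # both indicators degenerate (e.g. regular graph)
        omega1 = omega2 = 0.5
    else:
        omega1 = (1.0 - H_k) / denom
        omega2 = (1.0 - H_kbar) / denom
    return EntropyWeights(H_k=H_k, H_kbar=H_kbar, omega1=omega1, omega2=omega2)


def basic_feature(g: Network, w: EntropyWeights) -> np.ndarray:
    """B(u) = omega1 * k(u) + omega2 * kbar(u), on raw degree scales."""
    deg = g.degrees().astype(float)
    kbar = neighbor_avg_degree(g)
    return w.omega1 * deg + w.omega2 * kbar


def input_features(g: Network, B: np.ndarray, width: int = DEFAULT_WIDTH) -> np.ndarray:
    """Per-node input rows ``[B(u), B(u1), ..., B(u_{width-1})]``.

    Neighbors are ordered by degree descending (ties broken by internal
    index ascending), truncated to the first ``width - 1`` and zero-padded.
    """
    if width < 2:
        raise ValueError(f"feature width must be >= 2, got {width}")
    B = np.asarray(B, dtype=float)
    if B.shape != (g.n,):
        raise ValueError(f"B has shape {B.shape}, expected ({g.n},)")
    deg = g.degrees()
    F = np.zeros((g.n, width))
    F[:, 0] = B
    for u in range(g.n):
        nbrs = g.neighbors(u)
        order = nbrs[np.lexsort((nbrs, -deg[nbrs]))][: width - 1]
        F[u, 1 : 1 + len(order)] = B[order]
    return F


def build_features(
    g: Network, width: int = DEFAULT_WIDTH, basic_rule: str = "entropy"
) -> FeatureBundle:
    """Full feature pipeline.

    ``basic_rule`` selects the per-node scalar stacked into the rows:
    ``"entropy"`` (the weighted fusion, default), ``"degree"`` (k(u) only)
    or ``"neighbor_degree"`` (kbar(u) only) — the latter two exist for the
    feature ablation.
    """
    w = entropy_weights(g)
    if basic_rule == "entropy":
        B = basic_feature(g, w)
    elif basic_rule == "degree":
        B = g.degrees().astype(float)
    elif basic_rule == "neighbor_degree":
        B = np.asarray(neighbor_avg_degree(g), dtype=float)
    else:
        raise ValueError(f"unknown basic_rule {basic_rule!r}")
    return FeatureBundle(weights=w, basic=B, features=input_features(g, B, width))


def features_to_csv(g: Network, bundle: FeatureBundle, path) -> None:
    """CSV export: original label then f0..f{width-1} per row."""
    width = bundle.features.shape[1]
    lines = ["node," + ",".join(f"f{i}" for i in range(width))]
    for u in range(g.n):
        row = ",".join(f"{v:.10g}" for v in bundle.features[u])
        lines.append(f"{g.node_ids[u]},{row}")
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
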