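"""Relationship-strength matrix R = (A + I)^2 and its normalized form.

Entrywise, R_ii = k(i) + 1, R_ij = C_ij + 2 on edges and R_ij = C_ij
otherwise, where C_ij counts common neighbors.  The propagation operator
is L = D^{-1/2} R D^{-1/2} with D_ii the row sum of R.  Both are kept
sparse: the fill of R is each node's closed 2-hop neighborhood, so dense
storage is prohibitive at power-grid scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from rsgnn.netio import Network

__all__ = ["StrengthOperator", "strength_matrix", "common_neighbors", "strength_to_triplets"]


@dataclass(frozen=True)
class StrengthOperator:
    """R (integer, sparse), its row sums S, and L = D^{-1/2} R D^{-1/2}."""

    R: sp.csr_matrix
    S: np.ndarray
    L: sp.csr_matrix


def strength_matrix(g: Network) -> StrengthOperator:
    if g.n < 2:
        raise ValueError("need at least two nodes")
    A = g.adjacency()
    AI = (A + sp.identity(g.n, dtype=np.int64, format="csr")).tocsr()
    R = (AI @ AI).tocsr()
    R.eliminate_zeros()
    S = np.asarray(R.sum(axis=1)).ravel().astype(float)
    if (S <= 0).any():
        raise ValueError("zero row sum in relationship strength matrix")
    d_inv_sqrt = 1.0 / np.sqrt(S)
    Dhalf = sp.diags(d_inv_sqrt)
    L = (Dhalf @ R.astype(float) @ Dhalf).tocsr()
    return StrengthOperator(R=R, S=S, L=L)


def common_neighbors(g: Network, i: int, j: int) -> int:
    """|N(i) ∩ N(j)| — the inner product of adjacency row i and column j."""
    if i == j:
        raise ValueError("common_neighbors requires i != j")
    return int(np.intersect1d(g.neighbors(i), g.neighbors(j)).size)


def strength_to_triplets(g: Network, op: StrengthOperator, path) -> None:
    """Export R as an (i, j, value) triplet file using original labels."""
    coo = op.R.tocoo()
    lines = ["# i j strength"]
    for i, j, v in zip(coo.row, coo.col, coo.data):
        lines.append(f"{g.node_ids[i]} {g.node_ids[j]} {int(v)}")
    Path(path).write_text("\n".join(lines) + "\n")
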