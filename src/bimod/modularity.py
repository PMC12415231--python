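"""Directed modularity matrix and the bimodularity index.

For a directed graph with weight matrix ``A``, out-strengths ``k_out``
(row sums), in-strengths ``k_in`` (column sums) and total weight
``m = sum(A)``, the directed modularity matrix under the configuration-model
null is

    B[i, j] = A[i, j] - k_out[i] * k_in[j] / m .

Every row and column of ``B`` sums to zero, so the whole-graph community
always scores zero.

The *bimodularity* index generalizes modularity to a pair of partitions:
K sending communities C_out and K receiving communities C_in, where
community k sends to community k,

    Qbi = (1/m) * sum_k sum_{i in C_k^out, j in C_k^in} B[i, j] .

For two communities encoded as +/-1 indicator vectors s_out, s_in this
collapses to the bilinear form Qbi = (1/2m) s_out^T B s_in, which is what
the spectral optimizer relaxes.  On an undirected (symmetric) graph with
s_out = s_in the index falls back to classical Newman modularity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import DirectedGraph

__all__ = [
    "ModularityMatrix",
    "PartitionPair",
    "degrees",
    "modularity_matrix",
    "bimodularity",
    "bimodularity_vectors",
    "brute_force_best_bipartition",
]

#: relative tolerance for floating-point identities, scaled by m
RTOL = 1e-9


@dataclass
class ModularityMatrix:
    """Dense directed modularity matrix with its degree data attached."""

    B: np.ndarray
    k_out: np.ndarray
    k_in: np.ndarray
    m: float

    @property
    def n(self) -> int:
        return self.B.shape[0]

    @property
    def null_term(self) -> np.ndarray:
        """Configuration-model expectation E(A_ij | H0) = k_out_i k_in_j / m."""
        return np.outer(self.k_out, self.k_in) / self.m


@dataclass
class PartitionPair:
    """Paired sending/receiving node partitions with the identity mapping.

    ``assign_out[i]`` is node i's sending community and ``assign_in[i]`` its
    receiving community, labels in ``{1..K}``; community k sends to
    community k.  The two-community case corresponds to +/-1 sign vectors.
    """

    assign_out: np.ndarray
    assign_in: np.ndarray
    n_communities: int = field(init=False)

    def __post_init__(self) -> None:
        self.assign_out = np.asarray(self.assign_out, dtype=int)
        self.assign_in = np.asarray(self.assign_in, dtype=int)
        if self.assign_out.shape != self.assign_in.shape or self.assign_out.ndim != 1:
            raise ValueError("assign_out and assign_in must be 1-D and equal length")
        labels = np.union1d(self.assign_out, self.assign_in)
        K = int(labels.max(initial=0))
        if labels.min(initial=1) < 1 or K < 1:
            raise ValueError("labels must be drawn from {1..K}")
        self.n_communities = K

    @classmethod
    def from_signs(cls, s_out, s_in) -> "PartitionPair":
        """Build the two-community pair from +/-1 sign vectors (+1 -> label 1)."""
        s_out = np.asarray(s_out)
        s_in = np.asarray(s_in)
        _check_signs(s_out, s_in)
        return cls(np.where(s_out > 0, 1, 2), np.where(s_in > 0, 1, 2))


def degrees(g: DirectedGraph) -> tuple[np.ndarray, np.ndarray]:
    """Out-strengths (row sums) and in-strengths (column sums) of ``A``."""
    return g.A.sum(axis=1), g.A.sum(axis=0)


def modularity_matrix(g: DirectedGraph) -> ModularityMatrix:
    """Build B = A - k_out k_in^T / m; requires a nonempty graph (m > 0)."""
    k_out, k_in = degrees(g)
    m = g.m
    if m <= 0:
        raise ValueError("empty graph: total edge weight m must be positive")
    B = g.A - np.outer(k_out, k_in) / m
    return ModularityMatrix(B=B, k_out=k_out, k_in=k_in, m=m)


def _as_matrix(g) -> ModularityMatrix:
    return g if isinstance(g, ModularityMatrix) else modularity_matrix(g)


def bimodularity(g: DirectedGraph | ModularityMatrix, p: PartitionPair) -> float:
    """Bimodularity index of a K-community sending/receiving partition pair.

    Returns ``(1/m) * sum_k sum_{out==k, in==k} B[i, j]`` for any K >= 1.
    """
    mm = _as_matrix(g)
    if len(p.assign_out) != mm.n:
        raise ValueError(
            f"partition covers {len(p.assign_out)} nodes, graph has {mm.n}"
        )
    total = 0.0
    for k in range(1, p.n_communities + 1):
        rows = p.assign_out == k
        cols = p.assign_in == k
        if rows.any() and cols.any():
            total += mm.B[np.ix_(rows, cols)].sum()
    return total / mm.m


def _check_signs(*vecs) -> None:
    for s in vecs:
        if not np.all(np.isin(s, (-1, 1))):
            raise ValueError("sign vectors must contain only -1 and +1")


def bimodularity_vectors(mm: ModularityMatrix, s_out, s_in) -> float:
    """Two-community bimodularity from +/-1 sign vectors: (1/2m) s_out^T B s_in."""
    s_out = np.asarray(s_out)
    s_in = np.asarray(s_in)
    if s_out.shape != (mm.n,) or s_in.shape != (mm.n,):
        raise ValueError("sign vectors must have one entry per node")
    _check_signs(s_out, s_in)
    return float(s_out @ mm.B @ s_in) / (2.0 * mm.m)


def _sign_matrix(n: int) -> np.ndarray:
    """All 2^n sign vectors as rows, lexicographic with +1 sorting before -1."""
    bits = (np.arange(2**n)[:, None] >> np.arange(n - 1, -1, -1)) & 1
    return 1 - 2 * bits.astype(np.int8)


def brute_force_best_bipartition(
    mm: ModularityMatrix, max_n: int = 12
) -> tuple[np.ndarray, np.ndarray, float]:
    """Exhaustive maximizer of the two-community bimodularity (testing oracle).

    Enumerates every (s_out, s_in) pair of +/-1 vectors, up to the global
    sign symmetry Qbi(-s_out, -s_in) = Qbi(s_out, s_in), and returns the
    lexicographically smallest maximizer (+1 sorting before -1, s_out[0]
    fixed to +1).  Exponential in n; refuses n > ``max_n``.
    """
    n = mm.n
    if n > max_n:
        raise ValueError(f"n={n} exceeds brute-force limit max_n={max_n}")
    S = _sign_matrix(n)
    S_out = S[: 2 ** (n - 1)] if n > 0 else S  # first entry +1: global sign fixed
    vals = (S_out @ mm.B @ S.T) / (2.0 * mm.m)
    flat = int(np.argmax(vals))  # first occurrence = lexicographically smallest
    io_, ii = divmod(flat, S.shape[0])
    return (
        S_out[io_].astype(int).copy(),
        S[ii].astype(int).copy(),
        float(vals[io_, ii]),
    )
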