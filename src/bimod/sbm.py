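"""Directed stochastic-block-model generators for validation.

The generator draws *undirected* candidate edges block-pair by block-pair
and then assigns each drawn edge a single direction, so the result never
contains a bidirectional node pair or a self-loop and its symmetrization
``A + A^T`` is a binary undirected SBM with the requested densities.

Within a block, an unordered pair gets an edge with probability
``p_within`` and points from the lower- to the higher-index node with
probability ``p_dir`` (0.5 by default, in which case the convention is
immaterial).  Between blocks a and b, the unordered pair gets an edge
with probability ``P[a, b] + P[b, a]`` and points a -> b with probability
``P[a, b] / (P[a, b] + P[b, a])`` — for the usual case where only one of
the two entries is nonzero this is exactly "draw with p_con, orient along
the prescribed direction".

The *block cycle* is the canonical benchmark: ``n_blocks`` equal blocks,
each a conventional community, additionally projecting onto the next
block around a cycle.  Its ground truth has ``2 * n_blocks`` edge classes
(one per within-block group and one per consecutive block pair).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import DirectedGraph

__all__ = ["SBMSpec", "generate_sbm", "generate_block_cycle"]


@dataclass
class SBMSpec:
    """Specification of a directed stochastic block graph.

    Parameters
    ----------
    block_sizes : list of int
        Number of nodes per block; positive.
    p_within : float
        Undirected edge probability inside each block (the density gamma).
    between : ndarray of shape (n_blocks, n_blocks)
        ``between[a, b]`` is the probability of a directed edge a -> b for
        each cross-block node pair; the diagonal is ignored.  For each
        unordered block pair the two entries must sum to at most 1.
    p_dir : float, default=0.5
        Probability that a within-block edge points from the lower- to
        the higher-index node.
    seed : int, default=0
    """

    block_sizes: list
    p_within: float
    between: np.ndarray
    p_dir: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.block_sizes = [int(s) for s in self.block_sizes]
        if any(s <= 0 for s in self.block_sizes):
            raise ValueError("block sizes must be positive")
        nb = len(self.block_sizes)
        self.between = np.asarray(self.between, dtype=float)
        if self.between.shape != (nb, nb):
            raise ValueError(
                f"between must be {nb}x{nb}, got {self.between.shape}"
            )
        for p, name in ((self.p_within, "p_within"), (self.p_dir, "p_dir")):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} is not a probability")
        if np.any(self.between < 0) or np.any(self.between > 1):
            raise ValueError("between entries must be probabilities")
        tot = self.between + self.between.T
        iu = np.triu_indices(nb, k=1)
        if np.any(tot[iu] > 1.0 + 1e-12):
            raise ValueError(
                "between[a,b] + between[b,a] must not exceed 1 for any pair"
            )

    @property
    def n_blocks(self) -> int:
        return len(self.block_sizes)

    @property
    def n_nodes(self) -> int:
        return sum(self.block_sizes)


def generate_sbm(spec: SBMSpec) -> tuple[DirectedGraph, np.ndarray, np.ndarray]:
    """Draw one directed stochastic block graph.

    Returns
    -------
    graph : DirectedGraph
        Binary directed graph with integer node ids 0..n-1, blocks
        contiguous in id order.  No self-loops, no bidirectional pairs.
    node_blocks : ndarray of shape (n,)
        Ground-truth block index per node.
    edge_labels : ndarray of shape (n_edges,)
        Ground-truth class per structural edge, aligned with the graph's
        row-major edge ordering; the class of edge (i, j) encodes the
        ordered block pair (block[i], block[j]).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    nb = spec.n_blocks
    starts = np.concatenate([[0], np.cumsum(spec.block_sizes)])
    node_blocks = np.repeat(np.arange(nb), spec.block_sizes)
    A = np.zeros((n, n))

    for a in range(nb):
        # within-block: unordered pairs i < j, then orient
        lo, hi = starts[a], starts[a + 1]
        iu, ju = np.triu_indices(hi - lo, k=1)
        iu, ju = iu + lo, ju + lo
        drawn = rng.random(iu.size) < spec.p_within
        fwd = rng.random(iu.size) < spec.p_dir
        src = np.where(fwd, iu, ju)[drawn]
        tgt = np.where(fwd, ju, iu)[drawn]
        A[src, tgt] = 1.0
        for b in range(a + 1, nb):
            p_ab = spec.between[a, b]
            p_ba = spec.between[b, a]
            p_tot = p_ab + p_ba
            if p_tot == 0:
                continue
            ia = np.repeat(np.arange(starts[a], starts[a + 1]),
                           spec.block_sizes[b])
            jb = np.tile(np.arange(starts[b], starts[b + 1]),
                         spec.block_sizes[a])
            drawn = rng.random(ia.size) < p_tot
            fwd = rng.random(ia.size) < (p_ab / p_tot)
            src = np.where(fwd, ia, jb)[drawn]
            tgt = np.where(fwd, jb, ia)[drawn]
            A[src, tgt] = 1.0

    g = DirectedGraph(list(range(n)), A)
    edges = g.edge_index_pairs()
    edge_labels = node_blocks[edges[:, 0]] * nb + node_blocks[edges[:, 1]]
    return g, node_blocks, edge_labels


def generate_block_cycle(
    n_blocks: int = 4,
    block_size: int = 50,
    p_self: float = 0.3,
    p_con: float = 0.3,
    p_dir: float = 0.5,
    seed: int = 0,
) -> tuple[DirectedGraph, np.ndarray, np.ndarray]:
    """Block-cycle graph: dense blocks projecting onto the next block.

    The benchmark configuration is 4 blocks of 50 nodes with
    ``p_self = p_con = 0.3``: four conventional communities whose
    between-block edges all run around the cycle (block k -> block k+1
    mod ``n_blocks``).
    """
    if n_blocks < 2:
        raise ValueError("a block cycle needs at least 2 blocks")
    between = np.zeros((n_blocks, n_blocks))
    for k in range(n_blocks):
        between[k, (k + 1) % n_blocks] = p_con
    spec = SBMSpec(
        block_sizes=[block_size] * n_blocks,
        p_within=p_self,
        between=between,
        p_dir=p_dir,
        seed=seed,
    )
    return generate_sbm(spec)
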