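"""Directed-graph container and plain-text I/O.

The package works on a single in-memory representation, :class:`DirectedGraph`:
an ordered node list plus a dense nonnegative weight matrix ``A`` where
``A[i, j]`` is the weight of the edge running *from* node ``i`` (source,
row) *to* node ``j`` (target, column).  Edge lists and dense adjacency
matrices in delimited text are the supported external formats; parallel
edges in an edge list are aggregated by summing their weights.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DirectedGraph",
    "GraphSummary",
    "read_edge_list",
    "read_adjacency",
    "write_edge_list",
    "summarize",
]


@dataclass
class DirectedGraph:
    """A directed, weighted graph.

    Parameters
    ----------
    node_ids : list
        Ordered, unique node identifiers (strings or integers).  The order
        fixes the row/column indexing of ``A`` and is preserved by every
        operation, so embeddings are reproducible run to run.
    A : ndarray of shape (n, n)
        Nonnegative weight matrix; ``A[i, j]`` is the weight of edge i -> j.
    metadata : pandas.DataFrame, optional
        Per-node annotation table indexed by node id (e.g. neuron type,
        body position).
    """

    node_ids: list
    A: np.ndarray
    metadata: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ValueError(f"adjacency must be square, got shape {self.A.shape}")
        self.node_ids = list(self.node_ids)
        if len(self.node_ids) != self.A.shape[0]:
            raise ValueError(
                f"{len(self.node_ids)} node ids for a "
                f"{self.A.shape[0]}x{self.A.shape[1]} matrix"
            )
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("node ids must be unique")
        if np.any(self.A < 0):
            raise ValueError("edge weights must be nonnegative")
        if np.any(np.diag(self.A) > 0):
            warnings.warn(
                "graph has self-loops; they are included in degrees and m",
                stacklevel=2,
            )

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def m(self) -> float:
        """Total directed edge weight (sum of all entries of ``A``)."""
        return float(self.A.sum())

    def index_of(self, node) -> int:
        return self.node_ids.index(node)

    def edge_index_pairs(self) -> np.ndarray:
        """Structural edges as (source, target) index pairs, row-major order.

        This ordering is the canonical edge ordering used everywhere
        downstream (edge features, cluster labels, ground-truth labels).
        """
        return np.argwhere(self.A > 0)

    def binarized(self) -> "DirectedGraph":
        """Copy with every positive weight replaced by 1."""
        return DirectedGraph(self.node_ids, (self.A > 0).astype(float), self.metadata)


@dataclass(frozen=True)
class GraphSummary:
    """Structural edge counts of a directed graph.

    ``n_edges = n_unidirectional + 2 * n_bidirectional + n_self_loops``:
    a reciprocated pair contributes two directed edges.  Symmetry
    classification uses the structural nonzero pattern, not the weights.
    """

    n_nodes: int
    n_edges: int
    total_weight: float
    n_unidirectional: int
    n_bidirectional: int
    n_self_loops: int


def summarize(g: DirectedGraph) -> GraphSummary:
    """Count nodes, directed edges, and uni-/bidirectional connections."""
    S = g.A > 0
    off = S.copy()
    np.fill_diagonal(off, False)
    both = off & off.T
    n_bi = int(both.sum()) // 2
    n_uni = int((off & ~off.T).sum())
    return GraphSummary(
        n_nodes=g.n_nodes,
        n_edges=int(S.sum()),
        total_weight=g.m,
        n_unidirectional=n_uni,
        n_bidirectional=n_bi,
        n_self_loops=int(np.diag(S).sum()),
    )


def _sniff_sep(path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return "\t" if "\t" in line else ","
    return "\t"


_HEADER_NAMES = {"source", "target", "src", "dst", "from", "to"}


def _has_header(first_row) -> bool:
    # A header is assumed only when the first row's source/target tokens are
    # non-numeric *column names* (source/target and common aliases); plain
    # string node ids in a headerless file are therefore kept as data.
    toks = [str(t).strip().lower() for t in first_row[:2]]
    return toks[0] in _HEADER_NAMES and toks[1] in _HEADER_NAMES


def read_edge_list(
    path,
    weight_column: str | None = "weight",
    header: str = "auto",
    binarize: bool = False,
    node_ids: list | None = None,
) -> DirectedGraph:
    """Read a delimited ``source, target[, weight]`` edge list.

    Parameters
    ----------
    path : str or path-like
        TSV or CSV file; comment lines start with ``#``.
    weight_column : str or None
        Name of the weight column when the file has a header.  Headerless
        files use the third column if present.  Missing weights mean 1.
    header : {"auto", "yes", "no"}
        ``"auto"`` assumes a header when the first row's source/target
        tokens are non-numeric.
    binarize : bool
        Replace every positive weight by 1 after aggregation.
    node_ids : list, optional
        Explicit node ordering; otherwise nodes appear in first-occurrence
        order (sources before targets within a row).

    Duplicate (source, target) rows are aggregated by summing weights.
    """
    sep = _sniff_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, comment="#", header=None, dtype=str,
                         skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise ValueError(f"no edges in {path}") from None
    if df.empty:
        raise ValueError(f"no edges in {path}")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: line 1: expected at least 2 columns")

    first = [str(x) for x in df.iloc[0, :2]]
    use_header = {"auto": _has_header(first), "yes": True, "no": False}[header]
    if use_header:
        df.columns = [str(c).strip() for c in df.iloc[0]]
        df = df.iloc[1:].reset_index(drop=True)
        if "source" in df.columns and "target" in df.columns:
            src, tgt = df["source"], df["target"]
        else:
            src, tgt = df.iloc[:, 0], df.iloc[:, 1]
        if weight_column is not None and weight_column in df.columns:
            wcol = df[weight_column]
        elif df.shape[1] >= 3 and "source" not in df.columns:
            wcol = df.iloc[:, 2]
        else:
            wcol = None
    else:
        src, tgt = df.iloc[:, 0], df.iloc[:, 1]
        wcol = df.iloc[:, 2] if df.shape[1] >= 3 else None

    if len(src) == 0:
        raise ValueError(f"no edges in {path}")

    src = src.astype(str).str.strip()
    tgt = tgt.astype(str).str.strip()
    bad = src.eq("") | tgt.eq("") | src.isna() | tgt.isna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 1 + int(use_header)
        raise ValueError(f"{path}: malformed row at line {line}")

    if wcol is None:
        w = np.ones(len(src))
    else:
        w = pd.to_numeric(wcol, errors="coerce").to_numpy(dtype=float)
        w = np.where(np.isnan(w) & wcol.isna().to_numpy(), 1.0, w)
        if np.any(np.isnan(w)):
            line = int(np.flatnonzero(np.isnan(w))[0]) + 1 + int(use_header)
            raise ValueError(f"{path}: malformed weight at line {line}")
        if np.any(w < 0):
            raise ValueError(f"{path}: negative edge weight")

    if node_ids is None:
        order: dict = {}
        for s, t in zip(src, tgt):
            order.setdefault(s, len(order))
            order.setdefault(t, len(order))
        node_ids = list(order)
    else:
        node_ids = [str(x) for x in node_ids]
        order = {v: i for i, v in enumerate(node_ids)}
        missing = (set(src) | set(tgt)) - set(order)
        if missing:
            raise ValueError(f"edge references unknown node(s): {sorted(missing)[:5]}")

    n = len(node_ids)
    A = np.zeros((n, n))
    si = src.map(order).to_numpy(dtype=int)
    ti = tgt.map(order).to_numpy(dtype=int)
    np.add.at(A, (si, ti), w)

    # Integer-looking ids are kept as strings for round-trip fidelity only
    # when mixed; otherwise convert back to int for convenience.
    if all(s.lstrip("-").isdigit() for s in node_ids):
        node_ids = [int(s) for s in node_ids]

    g = DirectedGraph(node_ids, A)
    return g.binarized() if binarize else g


def write_edge_list(g: DirectedGraph, path, sep: str = "\t") -> None:
    """Write the graph as a ``source<sep>target<sep>weight`` file with header."""
    idx = g.edge_index_pairs()
    with open(path, "w") as fh:
        fh.write(sep.join(["source", "target", "weight"]) + "\n")
        for i, j in idx:
            w = float(g.A[i, j])
            wtxt = str(int(w)) if w == int(w) else repr(w)
            fh.write(sep.join([str(g.node_ids[i]), str(g.node_ids[j]), wtxt]) + "\n")


def read_adjacency(path, node_ids: list | None = None) -> DirectedGraph:
    """Read a dense delimited numeric matrix as a directed graph (row = source)."""
    with open(path) as fh:
        text = [ln for ln in fh if ln.strip() and not ln.startswith("#")]
    if not text:
        raise ValueError(f"no data in {path}")
    sep = "\t" if "\t" in text[0] else ","
    try:
        A = np.loadtxt(io.StringIO("".join(text)), delimiter=sep, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"{path}: could not parse numeric matrix: {exc}") from None
    if A.shape[0] != A.shape[1]:
        raise ValueError(f"{path}: matrix is {A.shape[0]}x{A.shape[1]}, not square")
    if np.any(A < 0):
        raise ValueError(f"{path}: negative entries are not valid edge weights")
    if node_ids is None:
        node_ids = list(range(A.shape[0]))
    return DirectedGraph(node_ids, A)


def read_node_metadata(path) -> pd.DataFrame:
    """Read a per-node CSV with a ``node`` column plus arbitrary annotations."""
    df = pd.read_csv(path, comment="#")
    if "node" not in df.columns:
        raise ValueError(f"{path}: metadata file needs a 'node' column")
    return df.set_index("node")
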