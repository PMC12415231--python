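"""Spectral maximization of bimodularity via SVD of the modularity matrix.

Relaxing the +/-1 sending/receiving indicator vectors to unit norm turns
the bimodularity maximization into a bilinear problem whose stationary
points are the singular vector pairs of B:  with ``B = U S V^T``, the
pair (u_k, v_k) attains Qbi(u_k, v_k) = u_k^T B v_k / (2m) = sigma_k / (2m).
The left singular vectors embed nodes by their *sending* behaviour, the
right ones by their *receiving* behaviour.

Sign convention: an SVD is only defined up to a joint sign flip of
(u_k, v_k).  Orientation is fixed deterministically (largest-magnitude
entry of u_k made positive), and the *reported* sign of a component is
taken from the dot product u_k . v_k: positive means assortative
structure (the paired node sets overlap: edges concentrate within a set),
negative disassortative (edges run between disjoint sets).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .graph import DirectedGraph
from .modularity import ModularityMatrix, modularity_matrix

__all__ = [
    "BimodularComponent",
    "BimodularEmbedding",
    "svd_components",
    "component_bimodularity",
    "node_embedding",
]

#: below this |u.v| the component's sign is reported as positive
_COS_TOL = 1e-10

#: above this size the dense SVD is replaced by a truncated iterative one
_DENSE_SVD_MAX_N = 2000


@dataclass
class BimodularComponent:
    """One singular triple of B, interpreted as a bimodular component.

    Attributes
    ----------
    index : int
        1-based rank by decreasing singular value.
    u, v : ndarray
        Unit-norm left (sending) and right (receiving) singular vectors.
    sigma : float
        Singular value, >= 0.
    cos_uv : float
        ``u . v``, cosine of the angle between the pair.
    signed_mu : float
        ``sign(cos_uv) * sigma`` — the signed value mu_k used for
        reporting; positive = assortative, negative = disassortative.
    qbi : float
        The component's bimodularity, sigma / (2m).
    """

    index: int
    u: np.ndarray
    v: np.ndarray
    sigma: float
    cos_uv: float
    signed_mu: float
    qbi: float


def _oriented(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # joint flip so the largest-|.| entry of u is positive (ties -> lowest
    # index, which is what argmax returns); preserves u^T B v = sigma >= 0
    if u[int(np.argmax(np.abs(u)))] < 0:
        return -u, -v
    return u, v


def svd_components(
    mm: ModularityMatrix, n_components: int, random_state: int | None = 0
) -> list[BimodularComponent]:
    """Leading ``n_components`` singular triples of B, orientation fixed.

    Uses a full dense SVD for n <= 2000 and a seeded truncated solver
    (``scipy.sparse.linalg.svds``) above that.
    """
    n = mm.n
    if not 1 <= n_components <= n:
        raise ValueError(f"n_components must be in [1, {n}], got {n_components}")
    if n <= _DENSE_SVD_MAX_N:
        U, s, Vt = np.linalg.svd(mm.B)
    else:
        from scipy.sparse.linalg import svds

        rng = np.random.default_rng(random_state)
        v0 = rng.standard_normal(min(mm.B.shape))
        U, s, Vt = svds(mm.B, k=n_components, v0=v0)
        order = np.argsort(s)[::-1]
        U, s, Vt = U[:, order], s[order], Vt[order]

    comps = []
    for k in range(n_components):
        u, v = _oriented(U[:, k], Vt[k])
        sigma = float(s[k])
        cos_uv = float(u @ v)
        sign = 1.0 if abs(cos_uv) < _COS_TOL else float(np.sign(cos_uv))
        comps.append(
            BimodularComponent(
                index=k + 1,
                u=u,
                v=v,
                sigma=sigma,
                cos_uv=cos_uv,
                signed_mu=sign * sigma,
                qbi=sigma / (2.0 * mm.m),
            )
        )
    return comps


def component_bimodularity(c: BimodularComponent, m: float) -> float:
    """Bimodularity attained by one relaxed component: sigma / (2m)."""
    return c.sigma / (2.0 * m)


def node_embedding(components: list[BimodularComponent], node_ids) -> pd.DataFrame:
    """Per-node sending/receiving coordinates (u_1, v_1, ..., u_N, v_N).

    Returns a DataFrame with a ``node`` column followed by interleaved
    ``u1, v1, u2, v2, ...`` columns (unscaled singular-vector entries).
    """
    if not components:
        raise ValueError("need at least one component")
    data = {"node": list(node_ids)}
    for c in components:
        data[f"u{c.index}"] = c.u
        data[f"v{c.index}"] = c.v
    return pd.DataFrame(data)


def spectrum_table(components: list[BimodularComponent]) -> pd.DataFrame:
    """Spectrum as a table with columns ``k, sigma, signed_mu, qbi``."""
    return pd.DataFrame(
        {
            "k": [c.index for c in components],
            "sigma": [c.sigma for c in components],
            "signed_mu": [c.signed_mu for c in components],
            "qbi": [c.qbi for c in components],
        }
    )


class BimodularEmbedding(BaseEstimator):
    """Node embedding by the leading bimodular components of a directed graph.

    Computes the directed modularity matrix B = A - k_out k_in^T / m and
    its truncated SVD; nodes are embedded by the left (sending) and right
    (receiving) singular vectors.  Analogous to
    :class:`sklearn.manifold.SpectralEmbedding`, but for directed graphs
    under the configuration-model null.

    Parameters
    ----------
    n_components : int, default=2
        Number of singular triples N to retain.
    random_state : int or None, default=0
        Seed for the truncated SVD solver (only used for n > 2000).

    Attributes
    ----------
    components_ : list of BimodularComponent
        Singular triples by decreasing sigma, orientation fixed.
    singular_values_ : ndarray of shape (n_components,)
    signed_mu_ : ndarray of shape (n_components,)
        Signed singular values (dot-product sign convention).
    qbi_ : ndarray of shape (n_components,)
        Per-component bimodularity sigma_k / (2m).
    embedding_ : ndarray of shape (n_nodes, 2 * n_components)
        Interleaved (u_1, v_1, ..., u_N, v_N) node coordinates.
    modularity_matrix_ : ModularityMatrix
    node_ids_ : list

    Examples
    --------
    >>> import numpy as np
    >>> A = np.zeros((4, 4)); A[0, 2] = A[1, 3] = 1
    >>> emb = BimodularEmbedding(n_components=1).fit(A)
    >>> float(emb.singular_values_[0])
    1.0
    """

    def __init__(self, n_components: int = 2, random_state: int | None = 0):
        self.n_components = n_components
        self.random_state = random_state

    def _validate_graph(self, X) -> DirectedGraph:
        if isinstance(X, DirectedGraph):
            return X
        X = np.asarray(X, dtype=float)
        return DirectedGraph(list(range(X.shape[0])), X)

    def fit(self, X, y=None) -> "BimodularEmbedding":
        """Fit on a DirectedGraph or an (n, n) nonnegative weight matrix."""
        g = self._validate_graph(X)
        mm = modularity_matrix(g)
        comps = svd_components(mm, self.n_components, self.random_state)
        self.graph_ = g
        self.node_ids_ = list(g.node_ids)
        self.modularity_matrix_ = mm
        self.components_ = comps
        self.singular_values_ = np.array([c.sigma for c in comps])
        self.signed_mu_ = np.array([c.signed_mu for c in comps])
        self.qbi_ = np.array([c.qbi for c in comps])
        self.embedding_ = np.column_stack(
            [x for c in comps for x in (c.u, c.v)]
        )
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        """Fit and return the (n_nodes, 2N) node embedding."""
        return self.fit(X).embedding_

    def embedding_frame(self) -> pd.DataFrame:
        """The fitted node embedding as a labelled DataFrame."""
        check_is_fitted(self, "components_")
        return node_embedding(self.components_, self.node_ids_)

    def spectrum_frame(self) -> pd.DataFrame:
        check_is_fitted(self, "components_")
        return spectrum_table(self.components_)
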