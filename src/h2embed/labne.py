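"""Laplacian-based network embedding (LaBNE).

The network is treated as the neighbourhood mesh of samples lying on the
hyperbolic plane; minimising ``tr(Y^T L Y)`` subject to ``Y^T D Y = I`` maps
connected nodes close together in the Euclidean plane.  Because the native
disc model is conformal, the Euclidean angles of the two nontrivial
generalized eigenvectors of ``L y = lambda D y`` are read off as hyperbolic
angular coordinates; radii come from the degree ranking, and the angles are
finally re-spread uniformly on the circle, preserving their circular order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, sparse

from .geometry import radial_from_rank
from .network import Network
from .result import EmbeddingResult

logger = logging.getLogger(__name__)

__all__ = [
    "SpectralEmbedding",
    "graph_laplacian",
    "spectral_embed",
    "angles_from_embedding",
    "respread_angles",
    "labne_embed",
]

# relative threshold separating the trivial (constant) eigenvector
_NULL_TOL = 1e-10


@dataclass
class SpectralEmbedding:
    """Two-column spectral coordinates and their generalized eigenvalues."""

    Y: np.ndarray
    eigenvalues: np.ndarray = field(default_factory=lambda: np.zeros(2))


def graph_laplacian(net: Network):
    """Combinatorial Laplacian ``L = D - A`` and degree matrix ``D`` (CSR)."""
    A = net.sparse_adjacency()
    D = sparse.diags(net.degrees.astype(float), format="csr")
    return (D - A).tocsr(), D


def _fix_signs(Y: np.ndarray, anchor_order: np.ndarray) -> np.ndarray:
    """Resolve per-column sign ambiguity: walking nodes in degree-rank order,
    the first with a nonzero entry in a column gets a non-negative value.

    Anchoring at the degree ranking (not raw indices) makes the fixed signs
    follow node relabelings whenever degrees are untied.
    """
    Y = Y.copy()
    for c in range(Y.shape[1]):
        col = Y[anchor_order, c]
        nz = np.flatnonzero(np.abs(col) > 0)
        if len(nz) and col[nz[0]] < 0:
            Y[:, c] = -Y[:, c]
    return Y


def spectral_embed(net: Network, n_components: int = 2) -> SpectralEmbedding:
    """Solve ``L Y = lambda D Y`` for the eigenvectors with the smallest
    nonzero eigenvalues.

    Dense solver for moderate networks; shift-inverted Lanczos for large
    ones, with a dense retry on non-convergence (N <= 2000).  Columns are
    D-orthonormal (``Y^T D Y = I``) and sign-fixed for reproducibility.
    """
    if net.N < 4:
        raise ValueError("spectral embedding needs at least 4 nodes")
    L, D = graph_laplacian(net)
    k = n_components + 1  # account for the trivial null vector
    tol = _NULL_TOL * net.degrees.max()
    if net.N <= 2000:
        vals, vecs = linalg.eigh(L.toarray(), D.toarray(),
                                 subset_by_index=[0, min(k + 2, net.N - 1)])
    else:
        try:
            vals, vecs = sparse.linalg.eigsh(L, k=k + 2, M=D, sigma=-1e-3,
                                             which="LM")
        except Exception as exc:  # non-convergence
            raise RuntimeError(
                "sparse generalized eigensolver failed to converge") from exc
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]
    keep = np.flatnonzero(vals > tol)[:n_components]
    if len(keep) < n_components:
        raise RuntimeError("could not find enough nonzero eigenvalues")
    Y = _fix_signs(vecs[:, keep], net.rank_order)
    return SpectralEmbedding(Y=Y, eigenvalues=vals[keep])


def angles_from_embedding(emb: SpectralEmbedding) -> np.ndarray:
    """Angular coordinates ``theta_i = atan2(y2_i, y1_i)`` mapped to [0, 2pi).

    Nodes exactly at the origin (both components zero) get theta = 0.
    """
    y1, y2 = emb.Y[:, 0], emb.Y[:, 1]
    at_origin = (y1 == 0) & (y2 == 0)
    if at_origin.any():
        logger.warning("%d node(s) at the spectral origin; assigning theta=0",
                       int(at_origin.sum()))
    theta = np.arctan2(y2, y1) % (2.0 * np.pi)
    theta[at_origin] = 0.0
    return theta


def respread_angles(theta: np.ndarray) -> np.ndarray:
    """Spread angles uniformly on [0, 2pi) preserving their circular order.

    The node with angular rank k (ties broken by node index) receives
    ``2 pi k / N``.
    """
    theta = np.asarray(theta, dtype=float)
    n = len(theta)
    order = np.lexsort((np.arange(n), theta))
    out = np.empty(n)
    out[order] = 2.0 * np.pi * np.arange(n) / n
    return out


def labne_embed(net: Network, gamma: float, respread: bool = True) -> EmbeddingResult:
    """Full LaBNE: spectral angles (optionally re-spread) + degree-rank radii."""
    emb = spectral_embed(net)
    theta = angles_from_embedding(emb)
    if respread:
        theta = respread_angles(theta)
    r = radial_from_rank(net.degree_rank, net.N, gamma)
    return EmbeddingResult(method="labne", r=r, theta=theta,
                           params={"gamma": gamma, "respread": respread})
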