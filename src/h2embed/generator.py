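"""Popularity-similarity (PS) network simulator.

Growth rules on the hyperbolic disc: node ``t`` is born at radius
``r_t = 2 ln t`` and a uniform angle; every older node ``s`` fades outward to
``beta r_s + (1 - beta) r_t``; node ``t`` then links to ``m_t`` distinct older
nodes.  At temperature ``T > 0`` partners are drawn by rejection sampling with
the Fermi-Dirac acceptance ``p(x_st)``; at ``T = 0`` the step-function limit
makes the new node connect to its ``m_t`` hyperbolically nearest predecessors.
Networks built this way are scale-free with exponent ``gamma = 1 + 1/beta``
and their clustering falls roughly linearly in ``T``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import PSParams, angular_separation, _approx_distance_arrays, disc_radius
from .network import Network

__all__ = ["GeneratedNetwork", "generate", "mean_clustering"]


@dataclass
class GeneratedNetwork:
    """A simulated PS network with its ground-truth coordinates.

    ``r`` and ``theta`` are indexed by birth order ``t = 1..N`` (array index
    ``t - 1``); ``r`` holds the final, post-fading radii
    ``beta * 2 ln t + (1 - beta) * 2 ln N``.
    """

    params: PSParams
    r: np.ndarray
    theta: np.ndarray
    edges: np.ndarray

    def network(self) -> Network:
        """View as a :class:`Network` with labels '1'..'N' (birth ranks)."""
        return Network(
            [(int(u), int(v)) for u, v in self.edges],
            [str(t) for t in range(1, self.params.N + 1)],
        )


def _links_per_node(m: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Integer link counts with mean m: floor(m) + Bernoulli(frac(m))."""
    base = int(math.floor(m))
    frac = m - base
    extra = (rng.random(n) < frac).astype(np.int64) if frac > 0 else np.zeros(n, np.int64)
    return base + extra


def generate(params: PSParams) -> GeneratedNetwork:
    """Simulate a PS network of ``params.N`` nodes with known coordinates.

    Determinism: identical parameters (including seed) produce identical
    networks.  Early nodes with fewer predecessors than their link budget
    connect to all existing nodes.
    """
    N, m, beta, T = params.N, params.m, params.beta, params.T
    rng = np.random.default_rng(params.seed)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=N)
    m_t = _links_per_node(m, N, rng)
    births = np.arange(1, N + 1, dtype=float)
    r_birth = 2.0 * np.log(births)

    edges: list[tuple[int, int]] = []
    for t in range(2, N + 1):
        idx = t - 1  # 0-based index of the newborn
        n_links = int(m_t[idx])
        if n_links == 0:
            n_links = 1  # keep the graph connected
        if t - 1 <= n_links:
            edges.extend((s, idx) for s in range(idx))
            continue
        # radii of older nodes faded to time t (closed form)
        r_old = beta * r_birth[:idx] + (1.0 - beta) * r_birth[idx]
        dth = angular_separation(theta[:idx], theta[idx])
        dist = _approx_distance_arrays(r_old, r_birth[idx], dth)
        if T == 0.0:
            # step-probability limit: the m_t hyperbolically nearest nodes
            order = np.lexsort((np.arange(idx), dist))
            chosen = order[:n_links]
        else:
            chosen = _sample_partners(dist, disc_radius(t, m, beta, T), T,
                                      n_links, rng)
        edges.extend((int(s), idx) for s in chosen)

    r_final = beta * r_birth + (1.0 - beta) * r_birth[-1]
    return GeneratedNetwork(params=params, r=r_final, theta=theta,
                            edges=np.array(edges, dtype=np.int64))


def _sample_partners(dist: np.ndarray, R_t: float, T: float, n_links: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample ``n_links`` distinct partners with acceptance p(x).

    Mirrors the growth rule: pick a uniformly random not-yet-connected older
    node, accept with the Fermi-Dirac probability, repeat.  Attempts are
    capped at ``100 * t`` per link; on exhaustion the remaining partners are
    drawn by weighted sampling without replacement so runtime stays bounded.
    """
    from scipy.special import expit

    n_old = len(dist)
    p = expit(-(dist - R_t) / (2.0 * T))
    connected = np.zeros(n_old, dtype=bool)
    need = n_links
    budget = 100 * (n_old + 1) * n_links
    batch = max(4 * n_links, 64)
    while need > 0 and budget > 0:
        cand = rng.integers(0, n_old, size=batch)
        acc = rng.random(batch) < p[cand]
        for s, ok in zip(cand, acc):
            budget -= 1
            if ok and not connected[s]:
                connected[s] = True
                need -= 1
                if need == 0:
                    break
            if budget <= 0:
                break
    if need > 0:
        # Efraimidis-Spirakis weighted sampling without replacement
        w = np.where(connected, 0.0, p)
        w = np.maximum(w, 1e-300)
        keys = rng.random(n_old) ** (1.0 / w)
        keys[connected] = -1.0
        extra = np.argsort(keys)[::-1][:need]
        connected[extra] = True
    return np.flatnonzero(connected)


def mean_clustering(net) -> float:
    """Average local clustering coefficient.

    Per node: ``2 * triangles / (k (k - 1))``; nodes of degree < 2 contribute
    0.  Accepts a :class:`Network` or :class:`GeneratedNetwork`.
    """
    if isinstance(net, GeneratedNetwork):
        net = net.network()
    if net.N == 0:
        raise ValueError("empty network")
    g = net.to_igraph()
    cc = g.transitivity_local_undirected(mode="zero")
    return float(np.mean(cc))
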