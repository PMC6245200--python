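"""Embedding quality metrics: greedy routing, connection-probability curves,
temperature estimation and power-law exponent fitting.

Greedy routing treats inferred coordinates as addresses: each node forwards a
packet to its neighbour hyperbolically closest to the target; if the packet
is ever sent back to the node it just came from, it is dropped.  The success
rate over random source-target pairs and the hop stretch (greedy path length
over shortest path length) measure how navigable the embedded network is.

The temperature of a real network is estimated from the near-linear decay of
clustering with temperature: PS replicas with the same (N, m, gamma) are
generated at T = 0, their mean clustering is the y-intercept of a line that
reaches zero clustering at T = 1, and the observed clustering is inverted
through that line.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .generator import generate, mean_clustering
from .geometry import PSParams, angular_separation, _approx_distance_arrays, \
    _exact_distance_arrays
from .network import Network

__all__ = [
    "RoutingReport",
    "TemperatureFit",
    "greedy_route",
    "routing_report",
    "connection_probability_curve",
    "estimate_temperature",
    "fit_power_law_exponent",
]


@dataclass
class RoutingReport:
    """Aggregate outcome of greedy routing over sampled source-target pairs."""

    n_pairs: int
    successes: int
    hop_stretches: list[float] = field(default_factory=list)

    @property
    def success_rate(self) -> float:
        return self.successes / self.n_pairs

    @property
    def mean_stretch(self) -> float:
        return float(np.mean(self.hop_stretches)) if self.hop_stretches else float("nan")


@dataclass
class TemperatureFit:
    """Clustering-based temperature estimate ``T = 1 - cbar / cbar_zero``."""

    cbar_real: float
    cbar_zero: float
    T_est: float
    n_replicas: int


def _routing_distances(r: np.ndarray, theta: np.ndarray, nodes: np.ndarray,
                       target: int) -> np.ndarray:
    """Distances from ``nodes`` to ``target``: approximate formula with the
    exact law of cosines as fallback wherever the approximation falls below
    the co-angular bound |r_a - r_b| (tiny angular separations)."""
    dth = angular_separation(theta[nodes], theta[target])
    d = _approx_distance_arrays(r[nodes], r[target], dth)
    lo = np.abs(r[nodes] - r[target])
    bad = d < lo
    if bad.any():
        d[bad] = _exact_distance_arrays(r[nodes][bad], r[target], dth[bad])
    return d


def greedy_route(coords, net: Network, source: int, target: int):
    """Route one packet greedily from ``source`` to ``target``.

    ``coords`` is an (N, 2) array of (r, theta) rows or an object with ``r``
    and ``theta`` attributes.  Returns ``(delivered, path)`` where ``path``
    includes the source and the last node reached.  The packet is dropped as
    soon as a node forwards it back to the previous hop; a cap of N hops
    guards against longer cycles.  Next-hop ties break to the smaller index.
    """
    if source == target:
        raise ValueError("source and target must differ")
    r, theta = _coord_arrays(coords)
    path = [source]
    prev = -1
    current = source
    for _ in range(net.N):
        nbrs = net.adjacency[current]
        d = _routing_distances(r, theta, nbrs, target)
        nxt = int(nbrs[np.argmin(d)])  # ties -> smallest index (adjacency sorted)
        path.append(nxt)
        if nxt == target:
            return True, path
        if nxt == prev:
            return False, path
        prev, current = current, nxt
    return False, path


def _coord_arrays(coords):
    if hasattr(coords, "r") and hasattr(coords, "theta"):
        return np.asarray(coords.r, float), np.asarray(coords.theta, float)
    arr = np.asarray(coords, dtype=float)
    return arr[:, 0], arr[:, 1]


def _bfs_distance(net: Network, source: int, target: int) -> int:
    seen = {source}
    q = deque([(source, 0)])
    while q:
        u, d = q.popleft()
        if u == target:
            return d
        for v in net.adjacency[u]:
            if v not in seen:
                seen.add(int(v))
                q.append((int(v), d + 1))
    raise RuntimeError("network not connected")


def routing_report(coords, net: Network, n_pairs: int = 1000,
                   seed: int = 0) -> RoutingReport:
    """Greedy-route ``n_pairs`` seeded random ordered source-target pairs.

    Pairs are sampled uniformly with replacement.  Hop stretch (greedy hops
    over BFS shortest-path hops) is recorded for delivered packets only.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    successes = 0
    stretches: list[float] = []
    for _ in range(n_pairs):
        s = int(rng.integers(net.N))
        t = int(rng.integers(net.N))
        while t == s:
            t = int(rng.integers(net.N))
        ok, path = greedy_route(coords, net, s, t)
        if ok:
            successes += 1
            stretches.append((len(path) - 1) / _bfs_distance(net, s, t))
    return RoutingReport(n_pairs=n_pairs, successes=successes,
                         hop_stretches=stretches)


def connection_probability_curve(coords, net: Network, bin_width: float = 1.0):
    """Fraction of connected node pairs per hyperbolic-distance bin.

    All N(N-1)/2 pairs are binned by their (approximate) hyperbolic distance;
    each populated bin yields ``(bin_center, fraction_connected, pair_count)``.
    Empty bins are omitted.
    """
    if net.N < 2:
        raise ValueError("need at least two nodes")
    r, theta = _coord_arrays(coords)
    iu, ju = np.triu_indices(net.N, k=1)
    dth = angular_separation(theta[iu], theta[ju])
    d = _approx_distance_arrays(r[iu], r[ju], dth)
    d = np.maximum(d, 0.0)
    A = net.adjacency_matrix()
    connected = A[iu, ju] > 0
    k = np.floor(d / bin_width).astype(np.int64)
    out = []
    for b in np.unique(k):
        mask = k == b
        out.append(((b + 0.5) * bin_width,
                    float(connected[mask].mean()),
                    int(mask.sum())))
    return out


def estimate_temperature(net: Network | None = None, gamma: float = 2.5,
                         m: float | None = None, n_replicas: int = 10,
                         seed: int = 0, *, n_nodes: int | None = None,
                         cbar_real: float | None = None) -> TemperatureFit:
    """Estimate a network's temperature from its clustering coefficient.

    PS replicas with matching ``(N, m, gamma)`` are generated at T = 0 and
    their mean clustering averaged into ``cbar_zero``; the line through
    ``(T=0, cbar_zero)`` and ``(T=1, 0)`` is then inverted at the observed
    clustering:  ``T_est = 1 - cbar_real / cbar_zero``, clamped to [0, 1).

    Either pass a :class:`Network` (N, m and clustering are measured from
    it) or the summary statistics ``n_nodes``/``cbar_real``/``m`` directly.
    """
    if net is not None:
        n_nodes = net.N
        if m is None:
            m = net.mean_degree / 2.0
        if cbar_real is None:
            cbar_real = mean_clustering(net)
    if n_nodes is None or cbar_real is None or m is None:
        raise ValueError("need a network or explicit n_nodes, cbar_real and m")
    if n_replicas < 1:
        raise ValueError("n_replicas must be >= 1")
    seeds = np.random.SeedSequence(seed).generate_state(n_replicas) % (2 ** 31)
    cbars = [
        mean_clustering(generate(PSParams(N=n_nodes, m=m, gamma=gamma,
                                          T=0.0, seed=int(s))))
        for s in seeds
    ]
    cbar_zero = float(np.mean(cbars))
    if cbar_zero <= 0.0:
        raise ValueError("replica clustering is zero; degenerate parameters")
    T_est = min(max(1.0 - cbar_real / cbar_zero, 0.0), np.nextafter(1.0, 0.0))
    return TemperatureFit(cbar_real=float(cbar_real), cbar_zero=cbar_zero,
                          T_est=float(T_est), n_replicas=n_replicas)


def fit_power_law_exponent(degrees, k_min: int | None = None,
                           min_tail: int = 50) -> float:
    """Continuous maximum-likelihood (Hill) estimate of the degree exponent.

    ``gamma_hat = 1 + n / sum ln(k_i / (k_min - 0.5))`` over degrees
    >= k_min.  When ``k_min`` is not given it is chosen by minimising the
    Kolmogorov-Smirnov distance between the empirical tail and the fitted
    continuous power law, among values leaving at least ``min_tail`` points.
    """
    k = np.asarray(degrees, dtype=float)
    k = k[k > 0]
    if k.size < min_tail:
        raise ValueError(f"need at least {min_tail} positive degrees")
    if np.all(k == k[0]):
        raise ValueError("degenerate degree sequence (all degrees equal)")

    def hill(tail: np.ndarray, kmin: float) -> float:
        s = np.log(tail / (kmin - 0.5)).sum()
        if s <= 0:
            raise ValueError("degenerate tail for Hill estimator")
        return 1.0 + tail.size / s

    if k_min is not None:
        tail = k[k >= k_min]
        if tail.size < min_tail:
            raise ValueError("too few tail points at the requested k_min")
        return hill(tail, k_min)

    best = None
    for km in np.unique(k)[:-1]:
        tail = np.sort(k[k >= km])
        if tail.size < min_tail:
            break
        try:
            g = hill(tail, km)
        except ValueError:
            continue
        # KS distance between empirical and fitted tail CDFs
        x0 = km - 0.5
        cdf = 1.0 - (tail / x0) ** (1.0 - g)
        emp_hi = np.arange(1, tail.size + 1) / tail.size
        emp_lo = np.arange(0, tail.size) / tail.size
        ks = max(np.abs(emp_hi - cdf).max(), np.abs(emp_lo - cdf).max())
        if best is None or ks < best[0]:
            best = (ks, g)
    if best is None:
        raise ValueError("no viable k_min with enough tail points")
    return best[1]
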