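"""HyperMap: maximum-likelihood inference of hyperbolic node coordinates.

The method replays the popularity-similarity growth of the observed network:
nodes are sorted decreasingly by degree and re-born one at a time at radius
``r_i = 2 ln i`` (older nodes fading outward), and each newborn receives the
angular coordinate that maximises the likelihood that the PS model produced
the observed adjacency.  Two likelihoods are used, following the fast hybrid
scheme: high-degree nodes (degree >= ``k_speedup``) maximise a Gaussian
log-likelihood of their observed final common-neighbour counts; low-degree
nodes maximise the Bernoulli link likelihood over a small region around a
neighbour-based initial estimate.  The angular search is a grid of spacing
``1/i`` radians, either over the full circle or — in refinement mode, used
by LaBNE+HM — over a window around externally supplied draft angles.

The common-neighbour mean and variance are modelled as moments of a sum of
independent Bernoulli indicators: ``mu = sum_k p(x_ik) p(x_jk)`` and
``sigma^2 = sum_k p(x_ik) p(x_jk) (1 - p(x_ik) p(x_jk))`` over the nodes
``k`` already present, ``k != i, j``.  The observed counts ``n_ij`` are
taken over the same population: common neighbours of ranks i and j within
the subgraph induced by the first i ranked nodes, so that the observed and
modelled scales agree while node i is being placed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .geometry import (
    angular_separation,
    _approx_distance_arrays,
    disc_radius,
    radial_from_rank,
)
from .network import Network
from .result import EmbeddingResult

__all__ = [
    "LikelihoodContext",
    "link_loglikelihood",
    "cn_loglikelihood",
    "candidate_angles",
    "hypermap_embed",
]

DEFAULT_K_SPEEDUP = 10
# half-width pi/6 around the neighbour-based estimate for low-degree nodes
DEFAULT_LOCAL_WINDOW = math.pi / 3.0
_P_CLAMP = 1e-12
_SIGMA2_FLOOR = 1e-6
_LOG_INV_SQRT_2PI = -0.5 * math.log(2.0 * math.pi)


@dataclass
class LikelihoodContext:
    """Precomputed, rank-ordered quantities shared by all likelihood calls.

    ``alpha`` is indexed by degree rank minus one (rank 1 = highest degree):
    ``alpha[i-1, j-1]`` is 1 iff ranks i and j are adjacent in the observed
    network.
    """

    alpha: np.ndarray
    degrees: np.ndarray
    m: float
    beta: float
    T: float
    k_speedup: int = DEFAULT_K_SPEEDUP
    sigma2_floor: float = _SIGMA2_FLOOR

    @classmethod
    def from_network(cls, net: Network, gamma: float, T: float,
                     k_speedup: int = DEFAULT_K_SPEEDUP) -> "LikelihoodContext":
        order = net.rank_order
        A = net.adjacency_matrix()[np.ix_(order, order)]
        return cls(
            alpha=A,
            degrees=net.degrees[order].astype(float),
            m=net.L / net.N,
            beta=1.0 / (gamma - 1.0),
            T=T,
            k_speedup=k_speedup,
        )

    def common_neighbors_at(self, i: int) -> np.ndarray:
        """Observed common-neighbour counts ``n_ij`` between rank ``i`` and
        every rank ``j < i``, counted within the subgraph induced by the
        first ``i`` ranked nodes (the population the model moments cover)."""
        return self.alpha[: i - 1, : i - 1] @ self.alpha[i - 1, : i - 1]


def _replay_radii(i: int, beta: float) -> tuple[np.ndarray, float]:
    """Radii at replay time i: previously born ranks 1..i-1 (faded) and r_i."""
    j = np.arange(1, i, dtype=float)
    r_i = 2.0 * math.log(i)
    r_prev = beta * 2.0 * np.log(j) + (1.0 - beta) * r_i
    return r_prev, r_i


def _pair_probs(theta_cand: np.ndarray, theta_prev: np.ndarray,
                r_prev: np.ndarray, r_i: float, R_i: float,
                T: float) -> np.ndarray:
    """(C, i-1) matrix of clamped connection probabilities between each
    candidate position of the newborn and every placed node."""
    dth = angular_separation(theta_cand[:, None], theta_prev[None, :])
    x = _approx_distance_arrays(r_i, r_prev[None, :], dth)
    return np.clip(expit(-(x - R_i) / (2.0 * T)), _P_CLAMP, 1.0 - _P_CLAMP)


def _link_ll_many(i: int, theta_cand: np.ndarray, theta_prev: np.ndarray,
                  ctx: LikelihoodContext, r_prev: np.ndarray | None = None,
                  R_i: float | None = None) -> np.ndarray:
    if r_prev is None:
        r_prev, _ = _replay_radii(i, ctx.beta)
    r_i = 2.0 * math.log(i)
    if R_i is None:
        R_i = disc_radius(i, ctx.m, ctx.beta, ctx.T)
    p = _pair_probs(np.asarray(theta_cand, float), theta_prev, r_prev, r_i,
                    R_i, ctx.T)
    a = ctx.alpha[i - 1, : i - 1]
    return np.log(p) @ a + np.log1p(-p) @ (1.0 - a)


def _placed_pair_probs(i: int, theta_prev: np.ndarray, r_prev: np.ndarray,
                       R_i: float, T: float) -> np.ndarray:
    """(i-1, i-1) connection probabilities among the already placed nodes at
    replay time i, with a zero diagonal (a node is never its own neighbour)."""
    dth = angular_separation(theta_prev[:, None], theta_prev[None, :])
    x = _approx_distance_arrays(r_prev[:, None], r_prev[None, :], dth)
    P = np.clip(expit(-(x - R_i) / (2.0 * T)), _P_CLAMP, 1.0 - _P_CLAMP)
    np.fill_diagonal(P, 0.0)
    return P


def _cn_ll_many(i: int, theta_cand: np.ndarray, theta_prev: np.ndarray,
                ctx: LikelihoodContext, r_prev: np.ndarray | None = None,
                R_i: float | None = None) -> np.ndarray:
    if r_prev is None:
        r_prev, _ = _replay_radii(i, ctx.beta)
    r_i = 2.0 * math.log(i)
    if R_i is None:
        R_i = disc_radius(i, ctx.m, ctx.beta, ctx.T)
    P_c = _pair_probs(np.asarray(theta_cand, float), theta_prev, r_prev, r_i,
                      R_i, ctx.T)
    P_prev = _placed_pair_probs(i, theta_prev, r_prev, R_i, ctx.T)
    mu = P_c @ P_prev
    sigma2 = np.maximum(mu - (P_c ** 2) @ (P_prev ** 2), ctx.sigma2_floor)
    n = ctx.common_neighbors_at(i)
    return ((i - 1) * _LOG_INV_SQRT_2PI
            - 0.5 * np.log(sigma2).sum(axis=1)
            - (((n - mu) ** 2) / (2.0 * sigma2)).sum(axis=1))


def link_loglikelihood(i: int, theta_i: float, theta_prev: np.ndarray,
                       ctx: LikelihoodContext) -> float:
    """Log of the Bernoulli link likelihood
    ``prod_{j<i} p(x_ij)^alpha_ij (1 - p(x_ij))^(1 - alpha_ij)`` for the
    newborn of rank ``i`` placed at angle ``theta_i``.

    Probabilities are clamped to ``[1e-12, 1 - 1e-12]`` so the result is
    always finite; ``i = 1`` returns 0 (empty product).
    """
    if i == 1:
        return 0.0
    return float(_link_ll_many(i, np.array([theta_i]), np.asarray(theta_prev, float), ctx)[0])


def cn_loglikelihood(i: int, theta_i: float, theta_prev: np.ndarray,
                     ctx: LikelihoodContext) -> float:
    """Gaussian log-likelihood of the observed common-neighbour counts
    ``n_ij`` of rank ``i`` against the model moments mu and sigma^2:

        (i-1) ln(1/sqrt(2 pi)) - sum_j ln sigma - sum_j (n_ij - mu)^2 / (2 sigma^2)

    sigma^2 is floored at 1e-6; ``i = 1`` returns 0.
    """
    if i == 1:
        return 0.0
    return float(_cn_ll_many(i, np.array([theta_i]), np.asarray(theta_prev, float), ctx)[0])


def candidate_angles(i: int, window: float | None = None,
                     center: float | None = None) -> np.ndarray:
    """Grid of candidate angles of spacing ``1/i`` radians.

    Full-space mode (no window): ``{0, 1/i, 2/i, ...}`` covering [0, 2 pi).
    Refinement mode: a grid covering ``[center - window/2, center + window/2]``
    (wrapped mod 2 pi) that always contains ``center``.
    """
    step = 1.0 / i
    if window is None:
        return np.arange(0.0, 2.0 * np.pi, step)
    if window <= 0:
        raise ValueError(f"window must be positive, got {window}")
    if center is None:
        raise ValueError("refinement mode requires a center angle")
    if window >= 2.0 * np.pi:
        return (center + np.arange(0.0, 2.0 * np.pi, step)) % (2.0 * np.pi)
    offs = np.arange(step, window / 2.0 + 1e-12, step)
    return np.concatenate([(center - offs[::-1]), [center], center + offs]) % (2.0 * np.pi)


def _pick_angle(cands: np.ndarray, ll: np.ndarray,
                center: float | None) -> float:
    """Argmax with deterministic tie-breaking: nearest to center, then
    smallest angle."""
    best = ll.max()
    tied = np.flatnonzero(ll == best)
    if len(tied) == 1:
        return float(cands[tied[0]])
    tc = cands[tied]
    if center is not None:
        sep = angular_separation(tc, center)
        order = np.lexsort((tc, sep))
    else:
        order = np.argsort(tc)
    return float(tc[order[0]])


def _circular_mean(angles: np.ndarray, weights: np.ndarray) -> float:
    s = float(np.sum(weights * np.sin(angles)))
    c = float(np.sum(weights * np.cos(angles)))
    return math.atan2(s, c) % (2.0 * math.pi)


def hypermap_embed(net: Network, gamma: float, T: float,
                   init_angles: np.ndarray | None = None,
                   window: float | None = None,
                   k_speedup: int = DEFAULT_K_SPEEDUP,
                   seed: int = 0) -> EmbeddingResult:
    """Embed a network by maximum-likelihood replay of PS growth.

    Parameters
    ----------
    net : Network
        Connected simple graph.
    gamma, T : float
        Assumed scaling exponent (in [2, 3]) and temperature (in (0, 1)).
    init_angles, window : optional
        Refinement mode: per-node draft angles (internal node-index order)
        and a window width in radians; every angular search is then
        restricted to ``window/2`` around the draft angle.  Omit both for
        full HyperMap.
    k_speedup : int
        Degree threshold of the fast hybrid scheme (default 10).
    seed : int
        Seeds the random angle of the first (highest-degree) node in
        full-space mode.
    """
    if not 0.0 < T < 1.0:
        raise ValueError("HyperMap requires temperature T in (0, 1); "
                         "embed cold networks with a small positive T")
    if window is not None and init_angles is None:
        raise ValueError("refinement mode requires init_angles")
    refine = window is not None
    ctx = LikelihoodContext.from_network(net, gamma, T, k_speedup)
    N = net.N
    order = net.rank_order
    init_rank = None
    if init_angles is not None:
        init_angles = np.asarray(init_angles, dtype=float)
        if len(init_angles) != N:
            raise ValueError("init_angles must have one angle per node")
        init_rank = init_angles[order]

    rng = np.random.default_rng(seed)
    theta_rank = np.empty(N)
    theta_rank[0] = init_rank[0] if refine else rng.uniform(0.0, 2.0 * np.pi)

    for i in range(2, N + 1):
        theta_prev = theta_rank[: i - 1]
        r_prev, _ = _replay_radii(i, ctx.beta)
        R_i = disc_radius(i, ctx.m, ctx.beta, ctx.T)
        use_cn = ctx.degrees[i - 1] >= k_speedup
        if refine:
            center = float(init_rank[i - 1])
            cands = candidate_angles(i, window, center)
        elif use_cn:
            center = None
            cands = candidate_angles(i)
        else:
            # speed-up heuristic: local search around the weighted circular
            # mean of already-placed neighbours
            nb = np.flatnonzero(ctx.alpha[i - 1, : i - 1] > 0)
            if len(nb):
                center = _circular_mean(theta_prev[nb], np.exp(-r_prev[nb]))
                cands = candidate_angles(i, DEFAULT_LOCAL_WINDOW, center)
            else:
                center = None
                cands = candidate_angles(i)
        if use_cn:
            ll = _cn_ll_many(i, cands, theta_prev, ctx, r_prev, R_i)
        else:
            ll = _link_ll_many(i, cands, theta_prev, ctx, r_prev, R_i)
        theta_rank[i - 1] = _pick_angle(cands, ll, center)

    theta = np.empty(N)
    theta[order] = theta_rank
    r = radial_from_rank(net.degree_rank, N, gamma)
    return EmbeddingResult(
        method="hypermap" if not refine else "hypermap-refine",
        r=r, theta=theta,
        params={"gamma": gamma, "T": T, "window": window,
                "k_speedup": k_speedup, "seed": seed},
        draft_theta=init_angles.copy() if init_angles is not None else None,
    )


def total_loglikelihood(net: Network, theta: np.ndarray, gamma: float, T: float,
                        k_speedup: int = DEFAULT_K_SPEEDUP) -> float:
    """Total replay log-likelihood of a fixed set of angles.

    Sums, over every rank i, the same per-node objective HyperMap maximises
    (common-neighbour likelihood for high-degree nodes, link likelihood
    otherwise) evaluated at the given angles.  Used to compare a draft
    embedding with its refinement.
    """
    ctx = LikelihoodContext.from_network(net, gamma, T, k_speedup)
    theta_rank = np.asarray(theta, dtype=float)[net.rank_order]
    total = 0.0
    for i in range(2, net.N + 1):
        fn = cn_loglikelihood if ctx.degrees[i - 1] >= k_speedup else link_loglikelihood
        total += fn(i, float(theta_rank[i - 1]), theta_rank[: i - 1], ctx)
    return total
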