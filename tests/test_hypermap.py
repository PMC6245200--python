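import math
import time

import numpy as np
import pytest

from h2embed import (
    LikelihoodContext,
    PSParams,
    candidate_angles,
    cn_loglikelihood,
    connection_probability,
    disc_radius,
    generate,
    hypermap_embed,
    link_loglikelihood,
)
from h2embed.geometry import angular_separation
from conftest import random_connected_network


def replay_radii(i, beta):
    """Radii at replay time i (independent re-derivation)."""
    r_i = 2 * math.log(i)
    r_prev = [beta * 2 * math.log(j) + (1 - beta) * r_i for j in range(1, i)]
    return r_prev, r_i


def pair_prob(r_a, r_b, th_a, th_b, R, T):
    """Scalar Fermi probability with the clamping used by the likelihoods."""
    dth = math.pi - abs(math.pi - abs(th_a - th_b) % (2 * math.pi))
    if dth == 0.0:
        x = abs(r_a - r_b)
    else:
        x = r_a + r_b + 2 * math.log(dth / 2)
    p = 1.0 / (1.0 + math.exp(min((x - R) / (2 * T), 700)))
    return min(max(p, 1e-12), 1 - 1e-12)


def brute_link_ll(i, theta_i, theta_prev, ctx):
    """Term-by-term product-form oracle for the link likelihood."""
    r_prev, r_i = replay_radii(i, ctx.beta)
    R = disc_radius(i, ctx.m, ctx.beta, ctx.T)
    total = 0.0
    for j in range(i - 1):
        p = pair_prob(r_i, r_prev[j], theta_i, theta_prev[j], R, ctx.T)
        total += math.log(p) if ctx.alpha[i - 1, j] else math.log(1 - p)
    return total


def brute_cn_ll(i, theta_i, theta_prev, ctx):
    """Exhaustive-sum oracle for the common-neighbour likelihood."""
    r_prev, r_i = replay_radii(i, ctx.beta)
    R = disc_radius(i, ctx.m, ctx.beta, ctx.T)
    total = (i - 1) * math.log(1 / math.sqrt(2 * math.pi))
    for j in range(i - 1):
        mu = sig2 = 0.0
        for k in range(i - 1):
            if k == j:
                continue
            q = (pair_prob(r_i, r_prev[k], theta_i, theta_prev[k], R, ctx.T)
                 * pair_prob(r_prev[j], r_prev[k], theta_prev[j], theta_prev[k], R, ctx.T))
            mu += q
            sig2 += q * (1 - q)
        sig2 = max(sig2, 1e-6)
        n_ij = sum(1 for k in range(i - 1)
                   if ctx.alpha[i - 1, k] and ctx.alpha[j, k])
        total += -0.5 * math.log(sig2) - (n_ij - mu) ** 2 / (2 * sig2)
    return total


class TestCandidateAngles:
    def test_full_space_count(self):
        assert len(candidate_angles(4)) == 26  # ceil(2 pi / 0.25)

    def test_window_grid(self):
        c = candidate_angles(100, window=math.pi / 6, center=1.0)
        assert np.isclose(c, 1.0).any()
        sep = angular_separation(c, 1.0)
        assert (sep <= math.pi / 12 + 1e-9).all()
        gaps = np.diff(np.sort(c))
        assert np.allclose(gaps, 0.01, atol=1e-12)

    def test_full_window_equals_full_space_up_to_rotation(self):
        full = candidate_angles(10)
        windowed = candidate_angles(10, window=2 * math.pi, center=0.7)
        assert len(full) == len(windowed)
        assert np.allclose(np.sort((windowed - 0.7) % (2 * math.pi)), np.sort(full))

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            candidate_angles(5, window=-1.0, center=0.0)


@pytest.fixture(scope="module")
def toy_ctx():
    net = random_connected_network(6, 0.5, seed=2)
    return LikelihoodContext.from_network(net, gamma=2.5, T=0.4)


class TestLikelihoods:
    def test_first_node_empty_product(self, toy_ctx):
        assert link_loglikelihood(1, 0.3, np.array([]), toy_ctx) == 0.0
        assert cn_loglikelihood(1, 0.3, np.array([]), toy_ctx) == 0.0

    def test_single_prior_half_probability(self):
        # place the candidate at the angular separation where x = R_2 exactly,
        # so the single-term product is ln p = ln 0.5 whether or not the pair
        # is linked (1 - p = p at the midpoint)
        from conftest import path_network
        ctx = LikelihoodContext.from_network(path_network(8), gamma=2.5, T=0.4)
        r_prev, r_i = replay_radii(2, ctx.beta)
        R = disc_radius(2, ctx.m, ctx.beta, ctx.T)
        dth = 2 * math.exp((R - r_i - r_prev[0]) / 2)
        assert 0 < dth < math.pi
        ll = link_loglikelihood(2, dth, np.array([0.0]), ctx)
        assert ll == pytest.approx(math.log(0.5), abs=1e-9)

    def test_link_likelihood_matches_bruteforce(self, toy_ctx):
        rng = np.random.default_rng(4)
        for i in (2, 3, 4, 5, 6):
            theta_prev = rng.uniform(0, 2 * np.pi, i - 1)
            theta_i = rng.uniform(0, 2 * np.pi)
            assert link_loglikelihood(i, theta_i, theta_prev, toy_ctx) == \
                pytest.approx(brute_link_ll(i, theta_i, theta_prev, toy_ctx), rel=1e-10)

    def test_cn_likelihood_matches_bruteforce(self, toy_ctx):
        rng = np.random.default_rng(5)
        for i in (2, 3, 4, 5, 6):
            theta_prev = rng.uniform(0, 2 * np.pi, i - 1)
            theta_i = rng.uniform(0, 2 * np.pi)
            assert cn_loglikelihood(i, theta_i, theta_prev, toy_ctx) == \
                pytest.approx(brute_cn_ll(i, theta_i, theta_prev, toy_ctx), rel=1e-10)

    def test_isolated_pairs_hit_variance_floor(self):
        # two far-apart prior nodes sharing nothing: each summand reduces to
        # the floored -ln sigma term
        net = random_connected_network(8, 0.4, seed=3)
        ctx = LikelihoodContext.from_network(net, gamma=2.5, T=0.01)
        i = 3
        theta_prev = np.array([0.0, math.pi])
        ll = cn_loglikelihood(i, math.pi / 2, theta_prev, ctx)
        assert np.isfinite(ll)


class TestHypermapEmbed:
    def test_matches_exhaustive_replay(self):
        """The embedding IS a grid search: an unoptimized per-candidate loop
        over the same grids must select identical angles."""
        net = random_connected_network(10, 0.45, seed=6)
        gamma, T, k_speedup = 2.5, 0.4, 3
        emb = hypermap_embed(net, gamma, T, k_speedup=k_speedup, seed=9)
        ctx = LikelihoodContext.from_network(net, gamma, T, k_speedup)
        order = net.rank_order
        got = emb.theta[order]
        theta = [got[0]]  # rank 1: seeded random angle, shared
        for i in range(2, net.N + 1):
            theta_prev = np.array(theta)
            use_cn = ctx.degrees[i - 1] >= k_speedup
            if use_cn:
                cands, center = candidate_angles(i), None
            else:
                nb = np.flatnonzero(ctx.alpha[i - 1, : i - 1] > 0)
                if len(nb):
                    r_prev, _ = replay_radii(i, ctx.beta)
                    w = np.exp(-np.array(r_prev)[nb])
                    center = math.atan2((w * np.sin(theta_prev[nb])).sum(),
                                        (w * np.cos(theta_prev[nb])).sum()) % (2 * math.pi)
                    cands = candidate_angles(i, math.pi / 3, center)
                else:
                    cands, center = candidate_angles(i), None
            fn = brute_cn_ll if use_cn else brute_link_ll
            lls = np.array([fn(i, float(c), theta_prev, ctx) for c in cands])
            best = lls.max()
            tied = np.flatnonzero(np.isclose(lls, best, rtol=0, atol=1e-12))
            tc = cands[tied]
            if center is not None:
                pick = tc[np.lexsort((tc, angular_separation(tc, center)))[0]]
            else:
                pick = tc.min()
            theta.append(float(pick))
        assert np.allclose(got, theta, atol=1e-9)

    def test_refinement_respects_window(self, warm_ps_net):
        rng = np.random.default_rng(11)
        init = rng.uniform(0, 2 * np.pi, warm_ps_net.N)
        w = math.pi / 6
        emb = hypermap_embed(warm_ps_net, 2.5, 0.3, init_angles=init, window=w)
        sep = angular_separation(emb.theta, init)
        assert (sep <= w / 2 + 1e-9).all()

    def test_refinement_never_decreases_per_node_likelihood(self, warm_ps_net):
        """The window always contains its center, so the chosen angle's
        objective is >= the draft's, node by node."""
        from h2embed import labne_embed
        net = warm_ps_net
        draft = labne_embed(net, 2.5).theta
        emb = hypermap_embed(net, 2.5, 0.3, init_angles=draft, window=math.pi / 6)
        ctx = LikelihoodContext.from_network(net, 2.5, 0.3)
        order = net.rank_order
        ref_rank, draft_rank = emb.theta[order], draft[order]
        for i in range(2, net.N + 1):
            fn = cn_loglikelihood if ctx.degrees[i - 1] >= 10 else link_loglikelihood
            prev = ref_rank[: i - 1]
            assert fn(i, float(ref_rank[i - 1]), prev, ctx) >= \
                fn(i, float(draft_rank[i - 1]), prev, ctx) - 1e-9

    def test_rotational_equivariance_in_refinement(self):
        net = random_connected_network(20, 0.3, seed=12)
        rng = np.random.default_rng(13)
        init = rng.uniform(0, 2 * np.pi, net.N)
        delta = 1.2345
        e1 = hypermap_embed(net, 2.5, 0.4, init_angles=init, window=math.pi / 4)
        e2 = hypermap_embed(net, 2.5, 0.4, init_angles=(init + delta) % (2 * np.pi),
                            window=math.pi / 4)
        dth = angular_separation(e2.theta, (e1.theta + delta) % (2 * np.pi))
        assert dth.max() < 1e-9

    def test_connected_pairs_concentrate_below_disc_radius(self):
        """Full HyperMap recovers the distance-dependence of connections:
        pairs inside the final disc radius are connected far more often."""
        gen = generate(PSParams(N=300, m=5, gamma=2.5, T=0.3, seed=17))
        net = gen.network()
        emb = hypermap_embed(net, 2.5, 0.3, seed=18)
        from h2embed.geometry import _approx_distance_arrays
        iu, ju = np.triu_indices(net.N, 1)
        dth = angular_separation(emb.theta[iu], emb.theta[ju])
        d = _approx_distance_arrays(emb.r[iu], emb.r[ju], dth)
        R_N = disc_radius(net.N, net.L / net.N, 1 / 1.5, 0.3)
        A = net.adjacency_matrix()
        conn = A[iu, ju] > 0
        near, far = d < R_N, d > R_N
        assert conn[near].mean() > conn[far].mean()

    def test_window_narrows_runtime(self):
        gen = generate(PSParams(N=250, m=5, gamma=2.5, T=0.3, seed=19))
        net = gen.network()
        init = np.zeros(net.N)
        t0 = time.perf_counter()
        hypermap_embed(net, 2.5, 0.3, init_angles=init, window=math.pi / 36)
        narrow = time.perf_counter() - t0
        t0 = time.perf_counter()
        hypermap_embed(net, 2.5, 0.3, init_angles=init, window=2 * math.pi)
        wide = time.perf_counter() - t0
        assert narrow < wide

    def test_cold_temperature_rejected(self, warm_ps_net):
        with pytest.raises(ValueError, match="T"):
            hypermap_embed(warm_ps_net, 2.5, 0.0)

    def test_window_without_init_rejected(self, warm_ps_net):
        with pytest.raises(ValueError, match="init"):
            hypermap_embed(warm_ps_net, 2.5, 0.3, window=math.pi / 6)
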