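import math

import numpy as np
import pytest

from h2embed import Network, PSParams, generate


def circular_correlation(a, b):
    """Fisher-Lee circular correlation: rotation-invariant angular agreement.

    Reflection flips the sign, so tests score ``max(|rho|)`` over reflection
    implicitly by taking the absolute value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ii, jj = np.triu_indices(len(a), 1)
    sa = np.sin(a[ii] - a[jj])
    sb = np.sin(b[ii] - b[jj])
    denom = math.sqrt(float((sa ** 2).sum()) * float((sb ** 2).sum()))
    return float((sa * sb).sum()) / denom


def true_coords(gen):
    """(N, 2) ground-truth coordinate array of a GeneratedNetwork."""
    return np.column_stack([gen.r, gen.theta % (2.0 * np.pi)])


def path_network(n):
    return Network([(i, i + 1) for i in range(n - 1)], [str(i) for i in range(n)])


def complete_network(n):
    return Network([(i, j) for i in range(n) for j in range(i + 1, n)],
                   [str(i) for i in range(n)])


def cycle_network(n):
    return Network([(i, (i + 1) % n) for i in range(n)],
                   [str(i) for i in range(n)])


def star_network(n_leaves):
    return Network([(0, i) for i in range(1, n_leaves + 1)],
                   [str(i) for i in range(n_leaves + 1)])


def random_connected_network(n, p, seed):
    """Erdos-Renyi G(n, p) conditioned on connectivity (resampled)."""
    rng = np.random.default_rng(seed)
    for _ in range(200):
        iu, ju = np.triu_indices(n, 1)
        mask = rng.random(len(iu)) < p
        edges = list(zip(iu[mask].tolist(), ju[mask].tolist()))
        try:
            return Network(edges, [str(i) for i in range(n)])
        except ValueError:
            continue
    raise RuntimeError("failed to draw a connected graph")


@pytest.fixture(scope="session")
def cold_ps_small():
    """PS network N=200, 2m=10, gamma=2.5, T=0 with ground truth."""
    return generate(PSParams(N=200, m=5, gamma=2.5, T=0.0, seed=42))


@pytest.fixture(scope="session")
def warm_ps_small():
    """PS network N=200, 2m=10, gamma=2.5, T=0.3 with ground truth."""
    return generate(PSParams(N=200, m=5, gamma=2.5, T=0.3, seed=42))


@pytest.fixture(scope="session")
def cold_ps_net(cold_ps_small):
    return cold_ps_small.network()


@pytest.fixture(scope="session")
def warm_ps_net(warm_ps_small):
    return warm_ps_small.network()
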