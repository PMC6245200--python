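"""Native-disc hyperbolic geometry shared by the generator and all embedders.

The native representation of the hyperbolic plane H^2 (curvature K = -1)
places a node at polar coordinates ``(r, theta)`` where ``r`` is both the
Euclidean and the hyperbolic distance from the disc origin and angular
separations are conformal.  All coordinate formulas of the
popularity-similarity (PS) model live here: the hyperbolic distance (exact
law of cosines and the standard large-distance approximation), the
Fermi-Dirac connection probability, the growing disc radius ``R_t``, the
popularity-fading radial update and the degree-rank radial formula used by
every embedding method.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PolarCoordinate",
    "PSParams",
    "angular_separation",
    "hyperbolic_distance",
    "connection_probability",
    "disc_radius",
    "radial_update",
    "radial_from_rank",
]


class PolarCoordinate(tuple):
    """A node position ``(r, theta)`` in the native hyperbolic disc.

    ``r >= 0``; ``theta`` is normalized to ``[0, 2*pi)`` on construction.
    """

    __slots__ = ()

    def __new__(cls, r: float, theta: float) -> "PolarCoordinate":
        if r < 0:
            raise ValueError(f"radial coordinate must be non-negative, got {r}")
        return super().__new__(cls, (float(r), float(theta) % (2.0 * math.pi)))

    @property
    def r(self) -> float:
        return self[0]

    @property
    def theta(self) -> float:
        return self[1]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PolarCoordinate(r={self.r!r}, theta={self.theta!r})"


@dataclass(frozen=True)
class PSParams:
    """Parameters of the popularity-similarity growth model.

    Attributes
    ----------
    N : int
        Final number of nodes.
    m : float
        Links added per new node (half the target average degree).  May be
        fractional; the generator then draws ``floor(m) + Bernoulli(frac(m))``
        links per node so the mean is preserved.
    gamma : float
        Scaling exponent of the power-law degree distribution, in ``[2, 3]``.
    T : float
        Network temperature in ``[0, 1)``; controls clustering.  ``T = 0``
        is the cold regime (deterministic nearest-neighbour attachment,
        maximal clustering).
    seed : int
        RNG seed for reproducible simulation.
    """

    N: int
    m: float
    gamma: float
    T: float = 0.0
    seed: int = 0
    beta: float = field(init=False)

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError(f"N must be >= 2, got {self.N}")
        if self.m <= 0:
            raise ValueError(f"m must be positive, got {self.m}")
        if not 2.0 <= self.gamma <= 3.0:
            raise ValueError(f"gamma must lie in [2, 3], got {self.gamma}")
        if not 0.0 <= self.T < 1.0:
            raise ValueError(f"T must lie in [0, 1), got {self.T}")
        object.__setattr__(self, "beta", 1.0 / (self.gamma - 1.0))


def angular_separation(theta_a, theta_b):
    """Shorter-arc angular distance, elementwise, in ``[0, pi]``."""
    d = np.abs(np.asarray(theta_a) - np.asarray(theta_b))
    return np.pi - np.abs(np.pi - d % (2.0 * np.pi))


def _approx_distance_arrays(r_a, r_b, dtheta):
    """Vectorized approximate distance with the co-angular singularity removed.

    ``r_a + r_b + 2 ln(dtheta/2)`` diverges to -inf as dtheta -> 0 while the
    true distance tends to ``|r_a - r_b|``; co-angular pairs therefore get
    ``|r_a - r_b|`` instead.
    """
    r_a = np.asarray(r_a, dtype=float)
    r_b = np.asarray(r_b, dtype=float)
    dtheta = np.asarray(dtheta, dtype=float)
    with np.errstate(divide="ignore"):
        x = r_a + r_b + 2.0 * np.log(dtheta / 2.0)
    return np.where(dtheta > 0.0, x, np.abs(r_a - r_b))


def _exact_distance_arrays(r_a, r_b, dtheta):
    """Vectorized K=-1 hyperbolic law of cosines, clamped to be >= 0.

    Evaluated as ``cosh d = cosh(r_a - r_b) + 2 sinh r_a sinh r_b
    sin^2(dtheta/2)`` — algebraically identical to the textbook
    ``cosh r_a cosh r_b - sinh r_a sinh r_b cos dtheta`` but free of the
    catastrophic cancellation that form suffers at small angular
    separations (it is exact for coincident points).
    """
    r_a = np.asarray(r_a, dtype=float)
    r_b = np.asarray(r_b, dtype=float)
    arg = (np.cosh(r_a - r_b)
           + 2.0 * np.sinh(r_a) * np.sinh(r_b) * np.sin(dtheta / 2.0) ** 2)
    return np.arccosh(np.maximum(arg, 1.0))


def hyperbolic_distance(
    a: PolarCoordinate,
    b: PolarCoordinate,
    mode: Literal["approximate", "exact"] = "approximate",
) -> float:
    """Hyperbolic distance between two points of the native disc.

    ``approximate`` returns ``r_a + r_b + 2 ln(dtheta/2)`` (the standard
    large-distance form used throughout the PS model); ``exact`` evaluates
    the curvature ``K = -1`` law of cosines
    ``arccosh(cosh r_a cosh r_b - sinh r_a sinh r_b cos dtheta)``.
    The angular separation is always the shorter arc.  For co-angular points
    the approximate form is undefined and ``|r_a - r_b|`` (the true distance)
    is returned with a warning.
    """
    dtheta = float(angular_separation(a.theta, b.theta))
    if mode == "exact":
        return float(_exact_distance_arrays(a.r, b.r, dtheta))
    if mode != "approximate":
        raise ValueError(f"unknown mode {mode!r}")
    if dtheta == 0.0:
        logger.warning(
            "approximate hyperbolic distance undefined at zero angular "
            "separation; returning |r_a - r_b|"
        )
        return abs(a.r - b.r)
    return float(_approx_distance_arrays(a.r, b.r, dtheta))


def connection_probability(x, R_t: float, T: float):
    """Fermi-Dirac link probability ``p(x) = 1 / (1 + exp((x - R_t)/(2T)))``.

    At ``T = 0`` the pointwise limit is the step function ``1{x <= R_t}``.
    Accepts scalar or array ``x``.
    """
    if T < 0:
        raise ValueError("temperature must be non-negative")
    x = np.asarray(x, dtype=float)
    if T == 0.0:
        p = np.where(x <= R_t, 1.0, 0.0)
    else:
        # expit form is overflow-safe for large |x - R_t|
        from scipy.special import expit

        p = expit(-(x - R_t) / (2.0 * T))
    return float(p) if p.ndim == 0 else p


def disc_radius(t: float, m: float, beta: float, T: float) -> float:
    """Radius ``R_t`` of the hyperbolic disc containing the network at time t.

    ``R_t`` is where the connection probability crosses 1/2.  The general
    expression for ``T > 0`` and ``beta < 1`` is

        R_t = r_t - 2 ln[ 2T (1 - e^{-(1-beta) r_t / 2}) / (m (1-beta) sin(pi T)) ]

    with ``r_t = 2 ln t``.  The ``T -> 0`` and ``beta = 1`` limits replace the
    bracket by its limiting value.  ``t = 1`` (the first node, alone in the
    disc) returns 0 by convention; negative values are clamped to 0.
    """
    if t < 1:
        raise ValueError(f"birth rank must be >= 1, got {t}")
    if t == 1:
        return 0.0
    r_t = 2.0 * math.log(t)
    if beta == 1.0:
        if T == 0.0:
            # limit of T r_t / (m sin(pi T)) as T -> 0
            bracket = r_t / (math.pi * m)
        else:
            bracket = T * r_t / (m * math.sin(math.pi * T))
    else:
        decay = 1.0 - math.exp(-(1.0 - beta) * r_t / 2.0)
        if T == 0.0:
            bracket = 2.0 * decay / (math.pi * m * (1.0 - beta))
        else:
            bracket = 2.0 * T * decay / (m * (1.0 - beta) * math.sin(math.pi * T))
    return max(r_t - 2.0 * math.log(bracket), 0.0)


def radial_update(r_s: float, r_t: float, beta: float) -> float:
    """Popularity fading: node born at radius ``r_s`` drifts to
    ``beta * r_s + (1 - beta) * r_t`` when the disc has grown to ``r_t``.

    With ``beta = 1`` radii never change; with ``beta = 0`` all nodes collapse
    onto the rim ``r_t``.
    """
    return beta * r_s + (1.0 - beta) * r_t


def radial_from_rank(i, N: int, gamma: float):
    """Radial coordinate assigned to degree rank ``i`` (1 = highest degree):
    ``r_i = 2 beta ln i + 2 (1 - beta) ln N`` with ``beta = 1/(gamma - 1)``.

    This is the final (post-fading) radius a node born at time ``i`` would
    occupy in a PS network of ``N`` nodes; it is shared by every embedding
    method.  Accepts scalar or array ``i``.
    """
    beta = 1.0 / (gamma - 1.0)
    i = np.asarray(i, dtype=float)
    r = 2.0 * beta * np.log(i) + 2.0 * (1.0 - beta) * math.log(N)
    return float(r) if r.ndim == 0 else r
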