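"""LaBNE+HM: spectral draft embedding refined by windowed HyperMap.

LaBNE drafts the angular configuration in milliseconds; HyperMap then
searches for each node's maximum-likelihood angle only inside a window ``w``
around the draft, instead of the full circle.  The window trades the two
methods off: ``w -> 0`` reproduces LaBNE, ``w -> 2 pi`` reproduces full
HyperMap.  Well-clustered (cold) networks need narrow windows because the
draft is already accurate; sparse, hot networks need wider ones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .hypermap import DEFAULT_K_SPEEDUP, hypermap_embed
from .labne import labne_embed
from .network import Network
from .result import EmbeddingResult

logger = logging.getLogger(__name__)

__all__ = ["WindowPolicy", "choose_window", "labne_hm_embed"]

# narrowest window ever probed; also the working temperature substituted for
# the refinement stage when the input network is cold (the likelihood needs
# T > 0)
MIN_WINDOW = math.pi / 36.0
COLD_REFINE_T = 0.1


@dataclass(frozen=True)
class WindowPolicy:
    """How to map an (estimated) temperature to a refinement window.

    ``linear``: w = 2 pi T; ``quadratic``: w = 2 pi T^2 (both floored at
    pi/36); ``manual``: a fixed width in radians.
    """

    mode: str = "manual"
    manual_w: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("manual", "linear", "quadratic"):
            raise ValueError(f"unknown window policy {self.mode!r}")
        if self.mode == "manual":
            if self.manual_w is None:
                raise ValueError("manual window policy requires manual_w")
            if not 0.0 < self.manual_w <= 2.0 * math.pi:
                raise ValueError("manual window must lie in (0, 2 pi]")


def choose_window(T: float, policy: WindowPolicy) -> float:
    """Refinement window width in radians for temperature ``T``."""
    if not 0.0 <= T < 1.0:
        raise ValueError(f"T must lie in [0, 1), got {T}")
    if policy.mode == "manual":
        return float(policy.manual_w)
    w = 2.0 * math.pi * (T if policy.mode == "linear" else T * T)
    return max(w, MIN_WINDOW)


def labne_hm_embed(net: Network, gamma: float, T: float,
                   policy: WindowPolicy,
                   k_speedup: int = DEFAULT_K_SPEEDUP,
                   seed: int = 0) -> EmbeddingResult:
    """Two-stage embedding: LaBNE draft, then windowed HyperMap refinement.

    The draft angles are kept in ``draft_theta``.  Cold inputs (T = 0) are
    refined at the working temperature 0.1 — the likelihood degenerates at
    exactly zero — while the window is still chosen from the stated T.
    """
    w = choose_window(T, policy)
    draft = labne_embed(net, gamma)
    T_eff = T
    if T_eff <= 0.0:
        logger.info("cold network: refining at working temperature %s",
                    COLD_REFINE_T)
        T_eff = COLD_REFINE_T
    refined = hypermap_embed(net, gamma, T_eff, init_angles=draft.theta,
                             window=w, k_speedup=k_speedup, seed=seed)
    return EmbeddingResult(
        method="labne+hm",
        r=refined.r,
        theta=refined.theta,
        params={"gamma": gamma, "T": T, "T_refine": T_eff, "window": w,
                "policy": policy.mode, "k_speedup": k_speedup, "seed": seed},
        draft_theta=draft.theta,
    )
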