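"""Embedding result container shared by all methods."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EmbeddingResult"]


@dataclass
class EmbeddingResult:
    """Per-node inferred hyperbolic coordinates plus provenance.

    ``r`` and ``theta`` are indexed by the network's internal node indices.
    ``draft_theta`` holds the pre-refinement angles when a two-stage method
    (LaBNE+HM) produced the result.
    """

    method: str
    r: np.ndarray
    theta: np.ndarray
    params: dict = field(default_factory=dict)
    draft_theta: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float) % (2.0 * np.pi)
        if self.r.shape != self.theta.shape:
            raise ValueError("r and theta must have matching shapes")
        if (self.r < 0).any():
            raise ValueError("radial coordinates must be non-negative")

    @property
    def n_nodes(self) -> int:
        return len(self.r)

    def coords(self) -> np.ndarray:
        """(N, 2) array of (r, theta) rows."""
        return np.column_stack([self.r, self.theta])
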