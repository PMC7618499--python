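"""Shared containers and small numeric helpers.

The central container is :class:`FrameSequence`, a T x H x W integer-grayscale
movie with the physical metadata (pixel pitch in microns, frame period in
seconds) needed to express results in absolute units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def round_half_up(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer with ties going up.

    Integer ADCs conventionally quantize half-levels upward; ``np.round``
    rounds half to even, which would split tied grayscale levels.
    """
    return np.floor(np.asarray(x, dtype=float) + 0.5)


@dataclass
class FrameSequence:
    """A grayscale movie: ``data`` has shape (T, H, W).

    Parameters
    ----------
    data
        Integer grayscale values (stored as provided; analyses promote to
        float internally).
    dx, dy
        Pixel pitch in microns along x (columns) and y (rows). Optional:
        only required when results in physical units are requested.
    dt
        Frame period in seconds.
    """

    data: np.ndarray
    dx: float | None = None
    dy: float | None = None
    dt: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected (T, H, W) data, got shape {self.data.shape}")
        for name in ("dx", "dy", "dt"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def require_physical_units(self) -> None:
        if self.dx is None or self.dy is None or self.dt is None:
            raise ValueError(
                "physical units requested but dx/dy/dt metadata is missing"
            )
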