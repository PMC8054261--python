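"""Shared lightweight containers for images, masks and growth curves."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["FieldImage", "LightProfile", "GrowthCurve"]


def as_array(image: "FieldImage | np.ndarray") -> np.ndarray:
    """Accept either a FieldImage-like object or a bare 2-D array."""
    data = getattr(image, "data", image)
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D intensity grid, got ndim={arr.ndim}")
    return arr


@dataclass
class FieldImage:
    """A single-channel well-scan intensity grid.

    Parameters
    ----------
    data : 2-D float array, arbitrary intensity units (16-bit range on disk).
    pixel_size_um : physical pixel pitch in micrometres per pixel.
    """

    data: np.ndarray
    pixel_size_um: float = 20.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class LightProfile(FieldImage):
    """Empty-well illumination reference on the same grid as the well scan."""


@dataclass
class GrowthCurve:
    """A live-cell count time series for one condition.

    times are hours, strictly increasing; counts are nonnegative live-cell
    counts. ``condition`` carries the experimental key (cell line, O2 %,
    substrate, dose, experiment date) plus any bookkeeping flags.
    """

    times: np.ndarray
    counts: np.ndarray
    condition: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times.shape != self.counts.shape:
            raise ValueError("times and counts must have equal length")
        if np.any(np.diff(self.times) <= 0):
            i = int(np.flatnonzero(np.diff(self.times) <= 0)[0]) + 1
            raise ValueError(f"times must be strictly increasing: offending index {i}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    def __len__(self) -> int:
        return len(self.times)
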