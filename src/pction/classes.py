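"""Fixed-width partition of the HU scale into CT-number classes.

The classifier's targets are not tissues but narrow CT-number intervals:
the HU axis is split into ``count`` half-open sections ``[edge, edge+width)``
of ``width`` HU each (default 128 sections of 32 HU covering [-1024, 3072)).
A voxel's class is the section containing its reference-CT value;
out-of-range values clamp to the first/last section so outliers never abort
training.  The reconstruction step later maps posterior probabilities back
through each section's mean HU measured on the learning set, so the best
achievable per-class mean error is bounded by the half-width (16 HU by
default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ClassBinning", "bin_hu", "class_stats"]


@dataclass(frozen=True)
class ClassBinning:
    lower: float = -1024.0
    width: float = 32.0
    count: int = 128

    def __post_init__(self) -> None:
        if self.width <= 0 or self.count < 1:
            raise ValueError("class width must be > 0 and count >= 1")

    @property
    def upper(self) -> float:
        return self.lower + self.width * self.count

    def midpoints(self) -> np.ndarray:
        return self.lower + (np.arange(self.count) + 0.5) * self.width

    def edges(self) -> np.ndarray:
        return self.lower + np.arange(self.count + 1) * self.width


def bin_hu(hu: float | np.ndarray, binning: ClassBinning) -> np.ndarray:
    """Class index of each HU value; out-of-range values clamp to the ends."""
    idx = np.floor((np.asarray(hu, dtype=float) - binning.lower) / binning.width)
    return np.clip(idx, 0, binning.count - 1).astype(np.int64)


def class_stats(
    hu: np.ndarray, binning: ClassBinning
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class member count and mean HU from learning-set values.

    Returns ``(counts, means)`` of length ``binning.count``; empty classes
    carry NaN means and are excluded from any classifier built on them.
    """
    hu = np.asarray(hu, dtype=float).ravel()
    if hu.size == 0:
        raise ValueError("class_stats requires a non-empty sample")
    labels = bin_hu(hu, binning)
    counts = np.bincount(labels, minlength=binning.count)
    sums = np.bincount(labels, weights=hu, minlength=binning.count)
    means = np.full(binning.count, np.nan)
    nonzero = counts > 0
    means[nonzero] = sums[nonzero] / counts[nonzero]
    return counts, means
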