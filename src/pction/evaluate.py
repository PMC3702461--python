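"""Quantitative pseudo-CT vs reference-CT comparison.

MAE = (1/n) sum_i |pCT_i - rCT_i| over mask voxels; per-class mean error
ME_cl = (1/n_cl) sum_i (pCT_i - rCT_i) where class membership is taken from
the *reference* CT, so systematic biases (e.g. bone underestimation) show up
against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classes import ClassBinning, bin_hu
from .volio import Volume

__all__ = ["MetricReport", "mae", "me_per_class", "difference_map"]


@dataclass
class MetricReport:
    mae: float
    sd_abs_error: float
    n: int
    me_per_class: dict[int, float] = field(default_factory=dict)
    n_per_class: dict[int, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mae": self.mae,
            "sd_abs_error": self.sd_abs_error,
            "n": self.n,
            "me_per_class": {str(k): v for k, v in self.me_per_class.items()},
            "n_per_class": {str(k): v for k, v in self.n_per_class.items()},
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _masked_pair(pct: Volume, rct: Volume, mask: Volume) -> tuple[np.ndarray, np.ndarray]:
    if not (pct.same_grid(rct) and pct.same_grid(mask)):
        raise ValueError("pCT, rCT and mask must share one grid")
    sel = mask.values > 0
    if not sel.any():
        raise ValueError("mask is empty")
    return pct.values[sel].astype(float), rct.values[sel].astype(float)


def mae(pct: Volume, rct: Volume, mask: Volume) -> tuple[float, float]:
    """Mean and sd of the absolute pCT-rCT error over mask voxels (HU)."""
    p, r = _masked_pair(pct, rct, mask)
    abs_err = np.abs(p - r)
    return float(abs_err.mean()), float(abs_err.std())


def me_per_class(
    pct: Volume, rct: Volume, mask: Volume, binning: ClassBinning
) -> tuple[dict[int, float], dict[int, int]]:
    """Signed mean error per CT class; classes keyed by reference-CT bin.

    Returns ``(me, counts)`` over non-empty classes only.
    """
    p, r = _masked_pair(pct, rct, mask)
    labels = bin_hu(r, binning)
    err = p - r
    counts = np.bincount(labels, minlength=binning.count)
    sums = np.bincount(labels, weights=err, minlength=binning.count)
    me = {int(k): float(sums[k] / counts[k]) for k in np.nonzero(counts)[0]}
    n = {int(k): int(counts[k]) for k in np.nonzero(counts)[0]}
    return me, n


def report(pct: Volume, rct: Volume, mask: Volume, binning: ClassBinning) -> MetricReport:
    m, sd = mae(pct, rct, mask)
    me, n_cl = me_per_class(pct, rct, mask, binning)
    return MetricReport(
        mae=m, sd_abs_error=sd, n=int((mask.values > 0).sum()),
        me_per_class=me, n_per_class=n_cl,
    )


def difference_map(pct: Volume, rct: Volume) -> Volume:
    """Signed voxelwise pCT - rCT volume (display hint: symmetric log scale)."""
    if not pct.same_grid(rct):
        raise ValueError("pCT and rCT must share one grid")
    return Volume(pct.values.astype(float) - rct.values.astype(float),
                  spacing=pct.spacing, origin=pct.origin, role="pct")
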