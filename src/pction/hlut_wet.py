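"""HU -> water-equivalent path length conversion and range-error analysis.

An empirical Hounsfield lookup table (HLUT) maps CT numbers to relative
water-equivalent path length (WEPL) by piecewise-linear interpolation with
linear extrapolation beyond the outer control points, floored at zero.  The
water-equivalent thickness (WET) of a beam path is the integral of WEPL
along it; a systematic pseudo-CT error ME in a tissue propagates to

    dWET_tissue = dWEPL_tissue * d

for a thickness d of that tissue, with dWEPL evaluated from the HLUT at a
representative HU of the tissue interval.  A simplified axis-aligned ray
tracer quantifies per-ray distal WET discrepancies over a planning target
volume (PTV), including a target-shift adaptation proxy.  This is a
transparent range-error model, not a dose engine: no lateral scattering,
beam optimization or biological weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .volio import Volume

__all__ = [
    "Hlut",
    "TissueGrouping",
    "WetReport",
    "DEFAULT_HLUT",
    "DEFAULT_GROUPING",
    "hu_to_wepl",
    "wepl_volume",
    "me_per_tissue_group",
    "delta_wet",
    "trace_wet",
    "range_error_map",
    "shift_experiment",
]


@dataclass(frozen=True)
class Hlut:
    """Ordered (HU, relative WEPL) control points."""

    hu: tuple[float, ...]
    wepl: tuple[float, ...]

    def __post_init__(self) -> None:
        hu = np.asarray(self.hu, dtype=float)
        w = np.asarray(self.wepl, dtype=float)
        if hu.size < 2 or hu.size != w.size:
            raise ValueError("an HLUT needs >= 2 (hu, wepl) control points")
        if not np.all(np.diff(hu) > 0):
            raise ValueError("HLUT HU control points must be strictly increasing")
        if np.any(w < 0):
            raise ValueError("HLUT WEPL values must be non-negative")

    @classmethod
    def from_csv(cls, path: str | Path) -> "Hlut":
        tab = pd.read_csv(path)
        return cls(hu=tuple(tab.iloc[:, 0]), wepl=tuple(tab.iloc[:, 1]))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"hu": self.hu, "wepl": self.wepl}).to_csv(path, index=False)


# Default empirical-style table for a 140 kVp scale; strictly configuration —
# all WET statements are relative to the table in use.
DEFAULT_HLUT = Hlut(
    hu=(-1000.0, -100.0, 0.0, 100.0, 1200.0, 3000.0),
    wepl=(0.0, 0.95, 1.00, 1.07, 1.65, 2.40),
)


def hu_to_wepl(hu: float | np.ndarray, hlut: Hlut = DEFAULT_HLUT) -> np.ndarray | float:
    """Piecewise-linear conversion with linear end extrapolation, floored at 0."""
    h = np.asarray(hlut.hu)
    w = np.asarray(hlut.wepl)
    x = np.asarray(hu, dtype=float)
    out = np.interp(x, h, w)
    lo = x < h[0]
    if np.any(lo):
        s = (w[1] - w[0]) / (h[1] - h[0])
        out = np.where(lo, w[0] + s * (x - h[0]), out)
    hi = x > h[-1]
    if np.any(hi):
        s = (w[-1] - w[-2]) / (h[-1] - h[-2])
        out = np.where(hi, w[-1] + s * (x - h[-1]), out)
    out = np.maximum(out, 0.0)
    return float(out) if np.isscalar(hu) else out


def wepl_volume(ct: Volume, hlut: Hlut = DEFAULT_HLUT) -> Volume:
    return Volume(hu_to_wepl(ct.values, hlut), spacing=ct.spacing,
                  origin=ct.origin, role="wepl")


@dataclass(frozen=True)
class TissueGrouping:
    """Named, ordered, disjoint HU intervals covering the scale.

    ``intervals`` maps name -> (lo, hi) half-open [lo, hi); consecutive
    intervals must tile the full range.
    """

    intervals: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        items = list(self.intervals.items())
        for (_, (lo, hi)) in items:
            if not lo < hi:
                raise ValueError("each interval needs lo < hi")
        for (_, (_, hi)), (_, (lo2, _)) in zip(items, items[1:]):
            if hi != lo2:
                raise ValueError("intervals must be ordered, disjoint and gap-free")

    def representative_hu(self, name: str) -> float:
        lo, hi = self.intervals[name]
        return 0.5 * (lo + hi)

    def assign(self, hu: np.ndarray) -> dict[str, np.ndarray]:
        """Boolean membership per tissue name."""
        out = {}
        items = list(self.intervals.items())
        for i, (name, (lo, hi)) in enumerate(items):
            sel = (hu >= lo) & (hu < hi)
            if i == len(items) - 1:
                sel |= hu >= hi  # top interval absorbs the upper edge
            if i == 0:
                sel |= hu < lo
            out[name] = sel
        return out


DEFAULT_GROUPING = TissueGrouping(
    {
        "air": (-1024.0, -800.0),
        "partial_volume": (-800.0, -150.0),
        "soft_tissue": (-150.0, 150.0),
        "soft_bone": (150.0, 700.0),
        "bone": (700.0, 3072.0),
    }
)


def me_per_tissue_group(
    pct: Volume,
    rct: Volume,
    mask: Volume,
    grouping: TissueGrouping = DEFAULT_GROUPING,
    hlut: Hlut = DEFAULT_HLUT,
) -> pd.DataFrame:
    """Signed mean pCT error and per-voxel WEPL-error sd per tissue group.

    Group membership is decided by the reference CT.  Returns a table with
    one row per non-empty group: n, me_hu, sd_voxel_wepl.
    """
    sel = mask.values > 0
    if not sel.any():
        raise ValueError("mask is empty")
    p = pct.values[sel].astype(float)
    r = rct.values[sel].astype(float)
    dw = np.asarray(hu_to_wepl(p, hlut)) - np.asarray(hu_to_wepl(r, hlut))
    rows = []
    for name, member in grouping.assign(r).items():
        if not member.any():
            continue
        rows.append(
            {
                "tissue": name,
                "n": int(member.sum()),
                "me_hu": float((p[member] - r[member]).mean()),
                "sd_voxel_wepl": float(dw[member].std()),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class WetReport:
    """Per-tissue WET deviation table (thicknesses in cm, WET in mm)."""

    table: pd.DataFrame
    se_mode: str
    voxel_size_mm: float

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def delta_wet(
    me_per_tissue: Mapping[str, float],
    hlut: Hlut = DEFAULT_HLUT,
    thicknesses_cm: Sequence[float] = (1.0, 5.0, 10.0),
    error_sd_per_voxel: Mapping[str, float] | float = 0.0,
    voxel_size_mm: float = 0.5,
    se_mode: str = "sqrt",
    grouping: TissueGrouping = DEFAULT_GROUPING,
) -> WetReport:
    """Propagate per-tissue mean pCT errors to WET deviations.

    dWEPL is evaluated as wepl(HU_rep + ME) - wepl(HU_rep) at the interval's
    representative HU; dWET(d) = dWEPL * d, reported in mm.  Standard errors
    accumulate per beam voxel of ``voxel_size_mm``: under ``"sqrt"``
    independent per-voxel WEPL errors add in quadrature,
    SE = sd * voxel * sqrt(d / voxel); under ``"linear"`` they are treated as
    fully correlated, SE = sd * d.
    """
    if se_mode not in ("sqrt", "linear"):
        raise ValueError("se_mode must be 'sqrt' or 'linear'")
    if any(d <= 0 for d in thicknesses_cm):
        raise ValueError("thicknesses must be positive")
    rows = []
    for tissue, me in me_per_tissue.items():
        hu0 = grouping.representative_hu(tissue)
        dwepl = float(hu_to_wepl(hu0 + me, hlut)) - float(hu_to_wepl(hu0, hlut))
        sd = (
            float(error_sd_per_voxel.get(tissue, 0.0))
            if isinstance(error_sd_per_voxel, Mapping)
            else float(error_sd_per_voxel)
        )
        row = {"tissue": tissue, "me_hu": float(me), "dwepl": dwepl}
        for d_cm in thicknesses_cm:
            d_mm = d_cm * 10.0
            if se_mode == "sqrt":
                se = sd * voxel_size_mm * np.sqrt(d_mm / voxel_size_mm)
            else:
                se = sd * d_mm
            row[f"dwet_{d_cm:g}cm_mm"] = dwepl * d_mm
            row[f"se_{d_cm:g}cm_mm"] = se
        rows.append(row)
    return WetReport(table=pd.DataFrame(rows), se_mode=se_mode,
                     voxel_size_mm=voxel_size_mm)


def trace_wet(
    wepl: Volume,
    entry: Sequence[int],
    axis: int,
    direction: int = 1,
    stop_depth_mm: float | None = None,
    wet_target_mm: float | None = None,
) -> dict:
    """Accumulate WET along an axis-aligned ray.

    Starts at voxel ``entry`` and walks along ``axis`` in ``direction``
    (+1/-1).  Returns depths (mm, at voxel exits), the cumulative WET
    profile (mm), and — when ``wet_target_mm`` is given — the geometric
    crossing depth where cumulative WET first reaches the target (linear
    sub-voxel interpolation), or ``crossed=False`` if the ray exits first.
    """
    if direction not in (1, -1):
        raise ValueError("direction must be +1 or -1")
    entry = tuple(int(e) for e in entry)
    for a in range(3):
        if not 0 <= entry[a] < wepl.shape[a]:
            raise ValueError(f"entry voxel {entry} outside grid {wepl.shape}")
    step = wepl.spacing[axis]
    idx = [slice(e, e + 1) for e in entry]
    idx[axis] = slice(entry[axis], None) if direction == 1 else slice(entry[axis], None, -1)
    line = wepl.values[tuple(idx)].ravel().astype(float)
    depths = np.arange(1, len(line) + 1) * step  # voxel exit depths
    wet = np.cumsum(line) * step
    if stop_depth_mm is not None and stop_depth_mm < depths[-1]:
        n_full = int(np.sum(depths < stop_depth_mm))  # whole voxels traversed
        partial = stop_depth_mm - n_full * step
        wet_stop = (wet[n_full - 1] if n_full else 0.0) + line[n_full] * partial
        depths = np.append(depths[:n_full], stop_depth_mm)
        wet = np.append(wet[:n_full], wet_stop)
    result = {"depths_mm": depths, "wet_mm": wet, "crossed": None, "crossing_depth_mm": None}
    if wet_target_mm is not None:
        if wet.size and wet[-1] >= wet_target_mm:
            i = int(np.searchsorted(wet, wet_target_mm))
            prev_wet = wet[i - 1] if i > 0 else 0.0
            prev_depth = depths[i - 1] if i > 0 else 0.0
            seg = wet[i] - prev_wet
            frac = 0.0 if seg == 0 else (wet_target_mm - prev_wet) / seg
            result["crossed"] = True
            result["crossing_depth_mm"] = float(prev_depth + frac * (depths[i] - prev_depth))
        else:
            result["crossed"] = False
    return result


def _distal_index(col: np.ndarray, direction: int) -> int | None:
    """Index of the last PTV voxel along the beam direction, or None."""
    hits = np.nonzero(col)[0]
    if hits.size == 0:
        return None
    return int(hits[-1]) if direction == 1 else int(hits[0])


def _wet_to_distal(wepl_vals: np.ndarray, axis: int, distal: np.ndarray,
                   direction: int, step: float) -> np.ndarray:
    """WET (mm) from the entry face to the distal face of index per ray."""
    if direction == -1:
        cum = np.cumsum(np.flip(wepl_vals, axis=axis), axis=axis) * step
        distal = wepl_vals.shape[axis] - 1 - distal
    else:
        cum = np.cumsum(wepl_vals, axis=axis) * step
    return np.take_along_axis(cum, np.expand_dims(distal, axis), axis=axis).squeeze(axis)


def range_error_map(
    pct: Volume,
    rct: Volume,
    hlut: Hlut,
    axis: int,
    ptv: Volume,
    direction: int = 1,
) -> dict:
    """Per-ray distal WET discrepancy between pCT- and rCT-derived WEPL.

    For every axis-aligned ray intersecting the PTV, accumulates WET from the
    volume entry face to the distal PTV surface under both CTs and reports
    the difference (mm, pCT minus rCT).  Returns the per-ray difference map
    (NaN off-PTV) and summary statistics.
    """
    if not (pct.same_grid(rct) and pct.same_grid(ptv)):
        raise ValueError("pCT, rCT and PTV must share one grid")
    ptv_mask = ptv.values > 0
    if not ptv_mask.any():
        raise ValueError("PTV mask is empty")
    step = pct.spacing[axis]
    wp = np.asarray(hu_to_wepl(pct.values.astype(float), hlut))
    wr = np.asarray(hu_to_wepl(rct.values.astype(float), hlut))

    hit = ptv_mask.any(axis=axis)
    # distal index per transverse position
    n_axis = ptv_mask.shape[axis]
    arange = np.arange(n_axis)
    shape = [1, 1, 1]
    shape[axis] = n_axis
    ar = arange.reshape(shape)
    if direction == 1:
        distal = np.where(ptv_mask, ar, -1).max(axis=axis)
    else:
        distal = np.where(ptv_mask, ar, n_axis).min(axis=axis)
    wet_p = _wet_to_distal(wp, axis, np.maximum(distal, 0), direction, step)
    wet_r = _wet_to_distal(wr, axis, np.maximum(distal, 0), direction, step)
    diff = np.where(hit, wet_p - wet_r, np.nan)
    vals = diff[hit]
    return {
        "diff_map_mm": diff,
        "n_rays": int(hit.sum()),
        "mean_mm": float(vals.mean()),
        "mean_abs_mm": float(np.abs(vals).mean()),
        "max_abs_mm": float(np.abs(vals).max()),
    }


def shift_experiment(
    pct: Volume,
    rct: Volume,
    hlut: Hlut,
    ptv: Volume,
    shift_mm: Sequence[float],
    axis: int,
    direction: int = 1,
) -> dict:
    """Compare pCT-based plan adaptation against ignoring a target shift.

    The PTV is translated by ``shift_mm`` (interpolated mask shift).  Two
    distal-WET error maps are evaluated against the *shifted* target:

    * ``adapted``: a plan re-targeted on the pseudo CT — per-ray WET to the
      shifted PTV's distal surface under pCT minus under rCT (classifier
      error only);
    * ``non_adapted``: the original reference-CT plan left in place — per-ray
      WET under rCT to the *unshifted* distal surface minus to the shifted
      one (pure geometric-miss error).  Rays of the shifted PTV with no
      unshifted counterpart are counted separately as uncovered.

    With zero shift the non-adapted error vanishes identically and the
    adapted error reduces to the plain pCT range error.
    """
    shift_vox = np.asarray(shift_mm, dtype=float) / np.asarray(ptv.spacing)
    shifted = ndimage.shift(ptv.values.astype(float), shift_vox, order=1,
                            mode="constant", cval=0.0) > 0.5
    if shifted.sum() == 0 or (ptv.values > 0).sum() * 0.5 > shifted.sum():
        raise ValueError("shifted PTV leaves the grid (or nearly so)")
    shifted_ptv = ptv.with_values(shifted.astype(np.uint8))

    adapted = range_error_map(pct, rct, hlut, axis, shifted_ptv, direction)

    step = rct.spacing[axis]
    wr = np.asarray(hu_to_wepl(rct.values.astype(float), hlut))
    old_mask = ptv.values > 0
    new_mask = shifted
    n_axis = old_mask.shape[axis]
    shape = [1, 1, 1]
    shape[axis] = n_axis
    ar = np.arange(n_axis).reshape(shape)
    if direction == 1:
        distal_old = np.where(old_mask, ar, -1).max(axis=axis)
        distal_new = np.where(new_mask, ar, -1).max(axis=axis)
    else:
        distal_old = np.where(old_mask, ar, n_axis).min(axis=axis)
        distal_new = np.where(new_mask, ar, n_axis).min(axis=axis)
    hit_new = new_mask.any(axis=axis)
    hit_old = old_mask.any(axis=axis)
    both = hit_new & hit_old
    wet_old = _wet_to_distal(wr, axis, np.maximum(distal_old, 0), direction, step)
    wet_new = _wet_to_distal(wr, axis, np.maximum(distal_new, 0), direction, step)
    diff_b = np.where(both, wet_old - wet_new, np.nan)
    vals_b = diff_b[both]
    non_adapted = {
        "diff_map_mm": diff_b,
        "n_rays": int(both.sum()),
        "n_uncovered_rays": int((hit_new & ~hit_old).sum()),
        "mean_mm": float(vals_b.mean()) if vals_b.size else 0.0,
        "mean_abs_mm": float(np.abs(vals_b).mean()) if vals_b.size else 0.0,
        "max_abs_mm": float(np.abs(vals_b).max()) if vals_b.size else 0.0,
    }
    return {
        "adapted": adapted,
        "non_adapted": non_adapted,
        "shift_mm": tuple(float(s) for s in shift_mm),
    }
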