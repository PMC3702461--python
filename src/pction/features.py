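"""Per-voxel observation vectors: contrast intensities, box statistics,
coordinate distances, and global feature scaling.

The observation vector of voxel j is X_j = (x_1, ..., x_p) with

    p = n_images * (1 + box_mean + box_sd) + 3 * dist_xyz + dist_center

where n_images counts rendered echo images over the selected contrasts
(an ultrashort-echo contrast contributes two echo images).  Column order is
all intensities, then all box means, then all box sds, then dist features.

Box features use the (2h+1)^3 neighborhood including the central voxel
(26 surrounding voxels for the default half-width h = 1); boxes at volume
borders are truncated to the available voxels.  ``box_sd`` is, by its
original definition, the population standard deviation of the box
*multiplied by the central voxel's intensity*; a plain-sd variant exists
behind a toggle.  Distance features are computed in mm after translating
coordinates so the mask centroid sits at the origin: ``dist_xyz`` are the
three absolute voxel-center offsets, ``dist_center`` the in-plane (axial)
radial distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .volio import Volume

__all__ = [
    "FeatureSpec",
    "ObservationMatrix",
    "ScalingParams",
    "box_mean",
    "box_sd",
    "box_mean_volume",
    "box_sd_volume",
    "dist_features",
    "assemble",
    "scale",
    "apply_scale",
]


@dataclass(frozen=True)
class FeatureSpec:
    """Which contrasts and derived features enter the observation vector."""

    contrasts: tuple[str, ...]
    box_mean: bool = False
    box_sd: bool = False
    dist_xyz: bool = False
    dist_center: bool = False
    box_half_width: int = 1
    plain_sd: bool = False  # drop the central-intensity weighting of box_sd

    def __post_init__(self) -> None:
        object.__setattr__(self, "contrasts", tuple(self.contrasts))
        if len(self.contrasts) == 0:
            raise ValueError("at least one contrast must be selected")
        if self.box_half_width < 1:
            raise ValueError("box half-width must be >= 1")

    def dimensionality(self, n_images: int) -> int:
        return (
            n_images * (1 + int(self.box_mean) + int(self.box_sd))
            + 3 * int(self.dist_xyz)
            + int(self.dist_center)
        )


@dataclass(frozen=True)
class ScalingParams:
    mean: np.ndarray  # (p,)
    sd: np.ndarray  # (p,)
    columns: tuple[str, ...]


@dataclass
class ObservationMatrix:
    """n x p feature matrix over mask voxels with the voxel -> grid map."""

    X: np.ndarray
    columns: tuple[str, ...]
    voxel_indices: np.ndarray  # (n, 3) int
    labels: np.ndarray | None = None
    scaling: ScalingParams | None = None

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def _box_sums(values: np.ndarray, half_width: int) -> tuple[np.ndarray, np.ndarray]:
    """Truncated-box sums and voxel counts for every voxel."""
    size = 2 * half_width + 1
    vol = float(size**3)
    s = ndimage.uniform_filter(values.astype(float), size, mode="constant", cval=0.0) * vol
    c = ndimage.uniform_filter(np.ones_like(values, dtype=float), size,
                               mode="constant", cval=0.0) * vol
    return s, np.rint(c)


def box_mean_volume(vol: Volume, half_width: int = 1) -> np.ndarray:
    """Box mean of every voxel (borders truncated)."""
    s, c = _box_sums(vol.values, half_width)
    return s / c


def box_sd_volume(vol: Volume, half_width: int = 1, plain: bool = False) -> np.ndarray:
    """Population box sd of every voxel, weighted by the central intensity.

    ``plain=True`` returns the unweighted standard deviation.
    """
    v = vol.values.astype(float)
    s, c = _box_sums(v, half_width)
    s2, _ = _box_sums(v * v, half_width)
    var = np.maximum(s2 / c - (s / c) ** 2, 0.0)
    sd = np.sqrt(var)
    return sd if plain else sd * v


def box_mean(vol: Volume, voxel: Sequence[int], half_width: int = 1) -> float:
    """Box mean at a single voxel (reference scalar API)."""
    return float(box_mean_volume(vol, half_width)[tuple(voxel)])


def box_sd(vol: Volume, voxel: Sequence[int], half_width: int = 1,
           plain: bool = False) -> float:
    return float(box_sd_volume(vol, half_width, plain)[tuple(voxel)])


def _mask_centroid(mask: Volume) -> np.ndarray:
    idx = np.argwhere(mask.values > 0)
    if idx.size == 0:
        raise ValueError("mask is empty")
    centers = (idx + 0.5) * np.asarray(mask.spacing) + np.asarray(mask.origin)
    return centers.mean(axis=0)


def dist_features(
    voxels: np.ndarray, mask: Volume, slice_axis: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Absolute mm offsets from the mask centroid and the in-plane distance.

    Parameters
    ----------
    voxels : (n, 3) integer voxel indices (or a single index triple)
    slice_axis : axis perpendicular to the 2D slice plane (axial by default)

    Returns ``(dist_xyz, dist_center)`` with shapes (n, 3) and (n,).
    """
    voxels = np.atleast_2d(np.asarray(voxels))
    centroid = _mask_centroid(mask)
    centers = (voxels + 0.5) * np.asarray(mask.spacing) + np.asarray(mask.origin)
    offsets = centers - centroid
    dist_xyz = np.abs(offsets)
    in_plane = [a for a in range(3) if a != slice_axis]
    dist_center = np.sqrt((offsets[:, in_plane] ** 2).sum(axis=1))
    return dist_xyz, dist_center


def assemble(
    images: Mapping[str, Sequence[Volume]],
    spec: FeatureSpec,
    mask: Volume,
    labels: np.ndarray | None = None,
) -> ObservationMatrix:
    """Build the observation matrix over mask voxels.

    ``images`` maps contrast name to its echo volumes; only contrasts listed
    in the spec are used, in spec order.  All volumes must share the mask
    grid.  ``labels``, if given, is a full-grid integer array sampled at the
    mask voxels.
    """
    selected: list[tuple[str, Volume]] = []
    for contrast in spec.contrasts:
        if contrast not in images:
            raise ValueError(f"contrast {contrast!r} not among provided images")
        for e, vol in enumerate(images[contrast]):
            if not vol.same_grid(mask):
                raise ValueError(f"{contrast} echo {e}: grid differs from mask grid")
            selected.append((f"{contrast}.e{e}" if len(images[contrast]) > 1 else contrast, vol))

    idx = np.argwhere(mask.values > 0)
    flat = tuple(idx.T)
    cols: list[np.ndarray] = []
    names: list[str] = []
    for name, vol in selected:
        cols.append(vol.values[flat].astype(float))
        names.append(name)
    if spec.box_mean:
        for name, vol in selected:
            cols.append(box_mean_volume(vol, spec.box_half_width)[flat])
            names.append(f"{name}.box_mean")
    if spec.box_sd:
        for name, vol in selected:
            cols.append(box_sd_volume(vol, spec.box_half_width, spec.plain_sd)[flat])
            names.append(f"{name}.box_sd")
    if spec.dist_xyz or spec.dist_center:
        dxyz, dc = dist_features(idx, mask)
        if spec.dist_xyz:
            for a, ax in enumerate("xyz"):
                cols.append(dxyz[:, a])
                names.append(f"dist_{ax}")
        if spec.dist_center:
            cols.append(dc)
            names.append("dist_center")

    X = np.column_stack(cols)
    n_images = len(selected)
    assert X.shape[1] == spec.dimensionality(n_images)
    lab = labels[flat] if labels is not None else None
    return ObservationMatrix(X=X, columns=tuple(names), voxel_indices=idx, labels=lab)


def scale(obs: ObservationMatrix) -> tuple[ObservationMatrix, ScalingParams]:
    """Standardize each column to mean 0, sd 1 on this (learning) set."""
    if obs.n < 2:
        raise ValueError("scaling requires at least 2 observations")
    mean = obs.X.mean(axis=0)
    sd = obs.X.std(axis=0)
    dead = np.nonzero(sd == 0)[0]
    if dead.size:
        raise ValueError(
            "zero-variance feature column(s) on the learning set: "
            + ", ".join(obs.columns[i] for i in dead)
        )
    params = ScalingParams(mean=mean, sd=sd, columns=obs.columns)
    return apply_scale(obs, params), params


def apply_scale(obs: ObservationMatrix, params: ScalingParams) -> ObservationMatrix:
    """Transform with previously learned scaling parameters."""
    if params.columns != obs.columns:
        raise ValueError("scaling parameters were learned on different columns")
    X = (obs.X - params.mean) / params.sd
    return replace(obs, X=X, scaling=params)
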