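"""Volume container, NIfTI/MetaImage I/O, grid resampling and air masking.

Conventions
-----------
Arrays are indexed ``[i, j, k]`` with ``k`` the slice (axial) axis.  Voxel
indices are 0-based and the world coordinate of a voxel *center* is

    world = origin + (index + 0.5) * spacing          [mm]

so ``origin`` is the corner of the first voxel.  All resampling assumes the
source and target already share a world frame (volumes are generated or
registered co-aligned upstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import SimpleITK as sitk
from scipy import ndimage

__all__ = [
    "Volume",
    "read_volume",
    "write_volume",
    "resample_to",
    "air_mask",
    "inject_shift",
]

#: default padding intensity by role for out-of-extent samples
_PAD_BY_ROLE = {"ct": -1000.0, "pct": -1000.0, "mr": 0.0, "label": 0.0,
                "mask": 0.0, "wepl": 0.0}

_ROLES = tuple(_PAD_BY_ROLE)


@dataclass
class Volume:
    """A 3D scalar grid with spacing/origin metadata.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
    spacing : mm per axis, all > 0
    origin : mm, corner of voxel (0, 0, 0)
    role : one of {"ct", "mr", "label", "mask", "pct", "wepl"}
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    role: str = "mr"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.role not in _ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {_ROLES}")
        if self.role == "mask":
            u = np.unique(self.values)
            if not np.isin(u, (0, 1)).all():
                raise ValueError("mask volumes may contain only {0, 1}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def voxel_centers(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def extent(self) -> list[tuple[float, float]]:
        """World bounding box [(lo, hi)] per axis (outer voxel faces)."""
        return [
            (self.origin[a], self.origin[a] + self.shape[a] * self.spacing[a])
            for a in range(3)
        ]

    def same_grid(self, other: "Volume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def with_values(self, values: np.ndarray, role: str | None = None) -> "Volume":
        return replace(self, values=values, role=role or self.role)


def _affine(vol: Volume) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(vol.spacing)
    # nibabel affines map indices to voxel centers
    aff[:3, 3] = np.asarray(vol.origin) + 0.5 * np.asarray(vol.spacing)
    return aff


def write_volume(vol: Volume, path: str | Path) -> None:
    """Write to NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) by extension.

    Masks and labels are stored as uint8/int16; everything else as float32.
    """
    path = Path(path)
    if vol.role == "mask":
        data = vol.values.astype(np.uint8)
    elif vol.role == "label":
        data = vol.values.astype(np.int16)
    else:
        data = vol.values.astype(np.float32)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        img = nib.Nifti1Image(data, _affine(vol))
        img.header.set_xyzt_units("mm")
        nib.save(img, str(path))
    elif name.endswith((".mha", ".mhd")):
        img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
        img.SetSpacing(vol.spacing)
        img.SetOrigin(tuple(np.asarray(vol.origin) + 0.5 * np.asarray(vol.spacing)))
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unsupported volume format: {path.name}")


def read_volume(path: str | Path, role: str = "mr") -> Volume:
    """Read a NIfTI or MetaImage file; only axis-aligned grids are supported."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        aff = img.affine
        offdiag = aff[:3, :3] - np.diag(np.diag(aff[:3, :3]))
        if not np.allclose(offdiag, 0, atol=1e-6):
            raise ValueError(f"{path.name}: only axis-aligned (diagonal) affines supported")
        spacing = np.abs(np.diag(aff[:3, :3]))
        origin = aff[:3, 3] - 0.5 * spacing
        values = np.asarray(img.dataobj)
    elif name.endswith((".mha", ".mhd")):
        img = sitk.ReadImage(str(path))
        spacing = np.asarray(img.GetSpacing())
        origin = np.asarray(img.GetOrigin()) - 0.5 * spacing
        values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    return Volume(values=values, spacing=tuple(spacing), origin=tuple(origin), role=role)


def resample_to(vol: Volume, target: Volume, pad_value: float | None = None) -> Volume:
    """Trilinear resampling of ``vol`` onto the grid of ``target``.

    Both volumes must share a world frame.  Target voxel centers outside the
    source extent take ``pad_value`` (default: air-equivalent by role, 0 for
    MR and -1000 for CT).  Raises if the two extents do not overlap at all.
    """
    if pad_value is None:
        pad_value = _PAD_BY_ROLE[vol.role]
    se, te = vol.extent(), target.extent()
    for a in range(3):
        if se[a][1] <= te[a][0] or te[a][1] <= se[a][0]:
            raise ValueError(
                f"source and target extents do not overlap on axis {a}: "
                f"{se[a]} vs {te[a]}"
            )
    # fractional source indices of the target voxel centers
    coords = np.meshgrid(
        *[
            (target.voxel_centers(a) - vol.origin[a]) / vol.spacing[a] - 0.5
            for a in range(3)
        ],
        indexing="ij",
    )
    out = ndimage.map_coordinates(
        vol.values.astype(float),
        np.stack(coords),
        order=1,
        mode="constant",
        cval=pad_value,
    )
    return Volume(out, spacing=target.spacing, origin=target.origin, role=vol.role)


def air_mask(
    ct: Volume,
    threshold: float = -800.0,
    min_component: int = 27,
    closing_radius: int = 1,
    fill_holes: bool = True,
) -> Volume:
    """Threshold mask excluding the *surrounding* air from downstream steps.

    mask = 1 where CT > ``threshold`` (HU), after binary closing with a ball
    of ``closing_radius`` voxels and removal of connected components smaller
    than ``min_component`` voxels.  Enclosed air (internal cavities) is kept
    by hole filling — only the air reaching the image edges is excluded, so
    cavity voxels remain part of the classified population.
    """
    if ct.role != "ct":
        raise ValueError(f"air_mask expects a CT volume, got role={ct.role!r}")
    mask = ct.values > threshold
    if closing_radius > 0 and mask.any():
        struct = _ball(closing_radius)
        mask = ndimage.binary_closing(mask, structure=struct)
    if min_component > 1 and mask.any():
        labels, n = ndimage.label(mask)
        sizes = np.bincount(labels.ravel())
        keep = sizes >= min_component
        keep[0] = False
        mask = keep[labels]
    if fill_holes and mask.any():
        mask = ndimage.binary_fill_holes(mask)
    return Volume(mask.astype(np.uint8), spacing=ct.spacing, origin=ct.origin, role="mask")


def _ball(radius: int) -> np.ndarray:
    r = int(radius)
    ax = np.arange(-r, r + 1)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    return (x * x + y * y + z * z) <= r * r


def inject_shift(vol: Volume, shift_voxels: Sequence[int]) -> Volume:
    """Shift a volume by whole voxels, padding with the role's air value.

    A deliberate misalignment injector for studying sensitivity of the
    classifier to residual registration error; not part of the main pipeline.
    """
    pad = _PAD_BY_ROLE[vol.role]
    out = np.full_like(vol.values, pad, dtype=float)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for a, s in enumerate(int(v) for v in shift_voxels):
        n = vol.shape[a]
        if abs(s) >= n:
            return vol.with_values(out)
        if s >= 0:
            dst[a], src[a] = slice(s, n), slice(0, n - s)
        else:
            dst[a], src[a] = slice(0, n + s), slice(-s, n)
    out[tuple(dst)] = vol.values[tuple(src)]
    return vol.with_values(out)
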