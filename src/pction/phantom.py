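"""Seeded digital phantom: co-registered multi-contrast MR + CT volumes.

Emulates meat-sample acquisitions used to develop MR-to-pseudo-CT
classification: piecewise-homogeneous tissue regions (fat, muscle, marrow,
cartilage, cortical bone, air), closed-form MR signal per sequence, partial
volume mixing by supersample-then-block-average, a smooth multiplicative
bias field on MR, Rician noise on MR magnitudes and Gaussian noise on CT.

MR signal models (steady-state closed forms; arbitrary units):

* spin echo               ``S = PD (1 - e^{-TR/T1}) e^{-TE/T2}``
* spoiled gradient echo   ``S = PD sin(a) (1 - E1) / (1 - cos(a) E1) e^{-TE/T2}``
  with ``E1 = e^{-TR/T1}``; used for the ultrashort-echo (UTE) readout,
  where the tissue ``t2`` is interpreted as T2*
* inversion-prepared GRE  ``S = PD |1 - 2 e^{-TI/T1} + e^{-TR/T1}| e^{-TE/T2}``

The point of the UTE readout is bone/air separation: cortical bone
(T2* ~ 0.45 ms) retains signal at TE = 0.05 ms but is indistinguishable
from air at conventional echo times (TE >= a few ms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .volio import Volume

__all__ = [
    "TissueSpec",
    "SequenceParams",
    "Region",
    "PhantomScene",
    "PhantomSample",
    "DEFAULT_TISSUES",
    "DEFAULT_SEQUENCES",
    "mr_signal",
    "build_labels",
    "render_volumes",
    "default_scene",
]


@dataclass(frozen=True)
class TissueSpec:
    """MR- and CT-relevant bulk parameters of one tissue.

    ``t2`` is used as T2* when rendering ultrashort-echo readouts.
    ``fat_class`` marks lipid-dominated tissues nulled by fat saturation.
    """

    name: str
    t1: float  # ms
    t2: float  # ms
    proton_density: float  # relative, >= 0
    electron_density: float  # relative to water
    nominal_hu: float
    fat_class: bool = False

    def __post_init__(self) -> None:
        if self.proton_density < 0:
            raise ValueError(f"{self.name}: proton density must be >= 0")
        if self.proton_density > 0 and (self.t1 <= 0 or self.t2 <= 0):
            raise ValueError(f"{self.name}: relaxation times must be positive")
        if self.proton_density > 0 and self.t2 > self.t1:
            raise ValueError(f"{self.name}: requires t2 <= t1")


# Literature-seeded table.  T1/T2 in ms; proton densities are relative
# plausible values (air carries none); nominal HU chosen consistent with a
# 140 kVp clinical scale and configurable per scene.
DEFAULT_TISSUES: dict[str, TissueSpec] = {
    t.name: t
    for t in [
        TissueSpec("air", t1=1.0, t2=1.0, proton_density=0.0,
                   electron_density=0.001, nominal_hu=-1000.0),
        TissueSpec("fat", t1=371.0, t2=133.0, proton_density=1.00,
                   electron_density=0.951, nominal_hu=-100.0, fat_class=True),
        TissueSpec("marrow", t1=365.0, t2=133.0, proton_density=0.95,
                   electron_density=0.982, nominal_hu=-80.0, fat_class=True),
        TissueSpec("muscle", t1=1412.0, t2=40.0, proton_density=0.70,
                   electron_density=1.040, nominal_hu=40.0),
        TissueSpec("cartilage", t1=1156.0, t2=35.0, proton_density=0.80,
                   electron_density=1.083, nominal_hu=120.0),
        TissueSpec("cortical_bone", t1=200.0, t2=0.45, proton_density=0.20,
                   electron_density=1.781, nominal_hu=1200.0),
    ]
}

_KINDS = ("spin_echo", "inversion_recovery_gre", "ute_gre")


@dataclass(frozen=True)
class SequenceParams:
    """Acquisition parameters of one rendered echo image."""

    kind: str
    te: float  # ms
    tr: float  # ms
    flip_angle: float = 90.0  # degrees
    ti: float | None = None  # ms, inversion_recovery_gre only
    fat_saturation: bool = False

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown sequence kind {self.kind!r}")
        if not self.te < self.tr:
            raise ValueError("requires te < tr")
        if not 0 < self.flip_angle <= 90:
            raise ValueError("flip angle must lie in (0, 90] degrees")
        if self.kind == "inversion_recovery_gre" and self.ti is None:
            raise ValueError("inversion_recovery_gre requires ti")


# The acquisition protocol emulated by default: two UTE echoes per UTE
# contrast, turbo-spin-echo contrasts, and an inversion-prepared GRE.
DEFAULT_SEQUENCES: dict[str, list[SequenceParams]] = {
    "TSE1": [SequenceParams("spin_echo", te=8.3, tr=7500, flip_angle=90)],
    "TSE2": [SequenceParams("spin_echo", te=8.3, tr=7500, flip_angle=90,
                            fat_saturation=True)],
    "TSE3": [SequenceParams("spin_echo", te=75.0, tr=7500, flip_angle=90)],
    "MPRAGE": [SequenceParams("inversion_recovery_gre", te=2.38, tr=2000,
                              flip_angle=12, ti=700)],
    "UTE1": [SequenceParams("ute_gre", te=0.05, tr=7.25, flip_angle=12),
             SequenceParams("ute_gre", te=4.91, tr=7.25, flip_angle=12)],
    "UTE2": [SequenceParams("ute_gre", te=0.05, tr=7.25, flip_angle=60),
             SequenceParams("ute_gre", te=4.91, tr=7.25, flip_angle=60)],
}


def mr_signal(tissue: TissueSpec, seq: SequenceParams) -> float:
    """Noiseless MR magnitude signal of a pure tissue under one sequence."""
    if tissue.proton_density == 0.0:
        return 0.0
    if seq.fat_saturation and tissue.fat_class:
        return 0.0
    pd, t1, t2 = tissue.proton_density, tissue.t1, tissue.t2
    decay = math.exp(-seq.te / t2)
    if seq.kind == "spin_echo":
        return pd * (1.0 - math.exp(-seq.tr / t1)) * decay
    if seq.kind == "ute_gre":
        e1 = math.exp(-seq.tr / t1)
        a = math.radians(seq.flip_angle)
        return pd * math.sin(a) * (1.0 - e1) / (1.0 - math.cos(a) * e1) * decay
    # inversion-prepared GRE
    assert seq.ti is not None
    mz = abs(1.0 - 2.0 * math.exp(-seq.ti / t1) + math.exp(-seq.tr / t1))
    return pd * mz * decay


@dataclass(frozen=True)
class Region:
    """A geometric primitive bound to a tissue; later regions overwrite earlier.

    Kinds and required params (all lengths in mm, world coordinates):

    * ``ellipsoid``: center (3,), radii (3,)
    * ``cylinder``: center (3,), radius, half_length, axis in {0,1,2}
    * ``cylinder_shell``: center (3,), r_inner, r_outer, half_length, axis
    * ``box``: center (3,), half_sizes (3,)
    """

    kind: str
    tissue: str
    params: Mapping[str, object]

    def contains(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        p = self.params
        c = np.asarray(p["center"], dtype=float)
        dx, dy, dz = x - c[0], y - c[1], z - c[2]
        if self.kind == "ellipsoid":
            rx, ry, rz = np.asarray(p["radii"], dtype=float)
            return (dx / rx) ** 2 + (dy / ry) ** 2 + (dz / rz) ** 2 <= 1.0
        if self.kind in ("cylinder", "cylinder_shell"):
            axis = int(p.get("axis", 2))
            d = [dx, dy, dz]
            along = d.pop(axis)
            r2 = d[0] ** 2 + d[1] ** 2
            inside_len = np.abs(along) <= float(p["half_length"])
            if self.kind == "cylinder":
                return inside_len & (r2 <= float(p["radius"]) ** 2)
            ri, ro = float(p["r_inner"]), float(p["r_outer"])
            return inside_len & (r2 <= ro * ro) & (r2 > ri * ri)
        if self.kind == "box":
            hx, hy, hz = np.asarray(p["half_sizes"], dtype=float)
            return (np.abs(dx) <= hx) & (np.abs(dy) <= hy) & (np.abs(dz) <= hz)
        raise ValueError(f"unknown region kind {self.kind!r}")


@dataclass
class PhantomScene:
    """Full description of one synthetic sample; everything needed to render.

    Noise and bias amplitudes are free parameters of the generator (the
    emulated protocol does not pin them); defaults are documented in
    docs/methods.md.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    regions: list[Region] = field(default_factory=list)
    tissues: Mapping[str, TissueSpec] = field(default_factory=lambda: dict(DEFAULT_TISSUES))
    supersampling: int = 2
    bias_amplitude: float = 0.0  # relative amplitude of the MR bias field
    mr_sigma: float = 0.0  # Rician channel sigma, signal units
    ct_sigma: float = 0.0  # additive Gaussian sigma, HU
    seed: int = 0

    def __post_init__(self) -> None:
        if self.supersampling < 1:
            raise ValueError("supersampling factor must be >= 1")
        if not 0 <= self.bias_amplitude < 0.9:
            raise ValueError("bias amplitude must lie in [0, 0.9)")
        for r in self.regions:
            if r.tissue not in self.tissues:
                raise ValueError(f"region references unknown tissue {r.tissue!r}")
        if "air" not in self.tissues:
            raise ValueError("scene tissue table must define 'air' (background)")

    def tissue_order(self) -> list[str]:
        """Label id -> tissue name; air is always label 0."""
        order = ["air"]
        for r in self.regions:
            if r.tissue not in order:
                order.append(r.tissue)
        return order


@dataclass
class PhantomSample:
    """Rendered output: co-registered MR contrasts, CT and ground-truth labels."""

    mr: dict[str, list[Volume]]
    ct: Volume
    labels: Volume
    tissue_names: list[str]


def build_labels(scene: PhantomScene) -> Volume:
    """Rasterize regions onto the supersampled fine grid.

    Returns an integer label volume (0 = air background); labels index
    ``scene.tissue_order()``.  Deterministic for a fixed scene.
    """
    ss = scene.supersampling
    fine_shape = tuple(n * ss for n in scene.shape)
    fine_spacing = tuple(s / ss for s in scene.spacing)
    centers = [
        scene.origin[a] + (np.arange(fine_shape[a]) + 0.5) * fine_spacing[a]
        for a in range(3)
    ]
    x, y, z = np.meshgrid(*centers, indexing="ij", sparse=True)
    labels = np.zeros(fine_shape, dtype=np.int16)
    order = scene.tissue_order()
    for region in scene.regions:
        labels[region.contains(x, y, z)] = order.index(region.tissue)
    return Volume(labels, spacing=fine_spacing, origin=scene.origin, role="label")


def _block_average(fine: np.ndarray, ss: int) -> np.ndarray:
    if ss == 1:
        return fine.astype(float)
    nx, ny, nz = (n // ss for n in fine.shape)
    return (
        fine.astype(float)
        .reshape(nx, ss, ny, ss, nz, ss)
        .mean(axis=(1, 3, 5))
    )


def _bias_field(scene: PhantomScene, rng: np.random.Generator) -> np.ndarray:
    """Strictly positive smooth multiplicative field: 1 + amp * P(x, y, z).

    P is a random quadratic polynomial in coordinates normalized to [-1, 1],
    scaled to max |P| = 1.  Stands in for inhomogeneous coil illumination.
    """
    if scene.bias_amplitude == 0.0:
        return np.ones(scene.shape)
    coords = [np.linspace(-1.0, 1.0, n) for n in scene.shape]
    x, y, z = np.meshgrid(*coords, indexing="ij", sparse=True)
    terms = [x, y, z, x * y, x * z, y * z, x * x, y * y, z * z]
    coef = rng.standard_normal(len(terms))
    p = sum(c * t for c, t in zip(coef, terms))
    p = p / np.max(np.abs(p))
    return 1.0 + scene.bias_amplitude * p


def render_volumes(
    scene: PhantomScene,
    sequences: Mapping[str, Sequence[SequenceParams]] | None = None,
) -> PhantomSample:
    """Render the scene into co-registered MR contrasts, a CT and labels.

    Pipeline per volume: noiseless fine-grid rendering from the label map,
    block average to the target grid (partial-volume mixing at boundaries),
    then for MR a multiplicative bias field and Rician noise, for CT additive
    Gaussian noise.  Bit-identical output for a fixed scene (seed included).

    The returned label volume is the majority (modal) fine label per target
    voxel; the noiseless CT of a pure voxel equals the tissue's nominal HU.
    """
    if sequences is None:
        sequences = DEFAULT_SEQUENCES
    ss = scene.supersampling
    fine = build_labels(scene)
    order = scene.tissue_order()
    n_tissues = len(order)

    # CT: nominal HU per label, averaged down, plus Gaussian noise
    hu_lut = np.array([scene.tissues[t].nominal_hu for t in order])
    ct_vals = _block_average(hu_lut[fine.values], ss)
    rng_ct = np.random.default_rng([scene.seed, 3])
    if scene.ct_sigma > 0:
        ct_vals = ct_vals + rng_ct.normal(0.0, scene.ct_sigma, ct_vals.shape)
    ct = Volume(ct_vals, spacing=scene.spacing, origin=scene.origin, role="ct")

    rng_bias = np.random.default_rng([scene.seed, 1])
    bias = _bias_field(scene, rng_bias)

    mr: dict[str, list[Volume]] = {}
    image_index = 0
    for contrast, echoes in sequences.items():
        vols: list[Volume] = []
        for seq in echoes:
            lut = np.array([mr_signal(scene.tissues[t], seq) for t in order])
            vals = _block_average(lut[fine.values], ss) * bias
            if scene.mr_sigma > 0:
                rng_mr = np.random.default_rng([scene.seed, 2, image_index])
                g1 = rng_mr.normal(0.0, scene.mr_sigma, vals.shape)
                g2 = rng_mr.normal(0.0, scene.mr_sigma, vals.shape)
                vals = np.sqrt((vals + g1) ** 2 + g2 ** 2)
            vols.append(Volume(vals, spacing=scene.spacing, origin=scene.origin, role="mr"))
            image_index += 1
        mr[contrast] = vols

    # modal fine label per target voxel as ground truth
    if ss == 1:
        maj = fine.values.astype(np.int16)
    else:
        nx, ny, nz = scene.shape
        blocks = fine.values.reshape(nx, ss, ny, ss, nz, ss)
        counts = np.stack(
            [(blocks == t).sum(axis=(1, 3, 5)) for t in range(n_tissues)]
        )
        maj = counts.argmax(axis=0).astype(np.int16)
    labels = Volume(maj, spacing=scene.spacing, origin=scene.origin, role="label")
    return PhantomSample(mr=mr, ct=ct, labels=labels, tissue_names=order)


def default_scene(
    seed: int,
    shape: tuple[int, int, int] = (44, 44, 24),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    mr_sigma: float = 0.0,
    ct_sigma: float = 0.0,
    bias_amplitude: float = 0.0,
    supersampling: int = 2,
    air_cavity: bool = True,
) -> PhantomScene:
    """A meat-sample-like scene with seeded geometry jitter.

    Fat shell around a muscle bulk, a cortical-bone cylinder shell with a
    marrow core, a cartilage band and an optional internal air cavity.
    Different seeds move and rescale the structures so that several scenes
    form a small cross-validation family of distinct but similar samples.
    """
    rng = np.random.default_rng([seed, 0])
    ext = np.array(shape) * np.array(spacing)
    c = ext / 2.0 + rng.uniform(-1.0, 1.0, 3)  # sample center, mm

    fat_radii = ext * np.array([0.42, 0.40, 0.44]) * rng.uniform(0.95, 1.05, 3)
    muscle_radii = fat_radii * rng.uniform(0.78, 0.84, 3)

    bone_c = c + np.array([rng.uniform(-4, 4), rng.uniform(-4, 4), 0.0])
    bone_router = 7.0 * rng.uniform(0.92, 1.08)
    bone_rinner = bone_router - 3.2  # ~3 mm cortical shell, pork-femur-like
    bone_hl = ext[2] * 0.38

    cart_c = bone_c + np.array([bone_router + 2.5, 0.0, 0.0])
    regions = [
        Region("ellipsoid", "fat", {"center": c, "radii": fat_radii}),
        Region("ellipsoid", "muscle", {"center": c, "radii": muscle_radii}),
        Region("cylinder", "cartilage",
               {"center": cart_c, "radius": 2.8, "half_length": bone_hl, "axis": 2}),
        Region("cylinder_shell", "cortical_bone",
               {"center": bone_c, "r_inner": bone_rinner, "r_outer": bone_router,
                "half_length": bone_hl, "axis": 2}),
        Region("cylinder", "marrow",
               {"center": bone_c, "radius": bone_rinner, "half_length": bone_hl,
                "axis": 2}),
    ]
    if air_cavity:
        cav_c = c + np.array([-muscle_radii[0] * 0.45, muscle_radii[1] * 0.4, 0.0])
        regions.append(Region("ellipsoid", "air",
                              {"center": cav_c, "radii": (2.5, 2.2, 3.0)}))
    return PhantomScene(
        shape=shape,
        spacing=spacing,
        regions=regions,
        supersampling=supersampling,
        bias_amplitude=bias_amplitude,
        mr_sigma=mr_sigma,
        ct_sigma=ct_sigma,
        seed=seed,
    )
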