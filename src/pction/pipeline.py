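"""End-to-end training, pseudo-CT prediction, cross-validation and
contrast/feature combination search.

Training pools voxel observations over the learning samples, standardizes
features, labels each voxel with its reference-CT class, fits the subspace
discriminant model and stores each class's mean HU.  Prediction maps the
posterior simplex back to a CT number per voxel:

    pCT_j = sum_k P(C_k | X_j) * meanHU_k

so a pseudo CT is always a convex combination of learned class means —
soft reconstruction rather than hard assignment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import evaluate, hdda
from .classes import ClassBinning, bin_hu
from .features import (FeatureSpec, ObservationMatrix, ScalingParams,
                       apply_scale, assemble, scale)
from .volio import Volume

__all__ = [
    "Sample",
    "PipelineConfig",
    "TrainedPredictor",
    "train",
    "predict_pct",
    "crossval",
    "combination_search",
]

_AIR_HU = -1000.0


@dataclass
class Sample:
    """One co-registered acquisition: MR contrasts, reference CT and mask."""

    mr: Mapping[str, Sequence[Volume]]
    ct: Volume
    mask: Volume
    name: str = ""


@dataclass(frozen=True)
class PipelineConfig:
    binning: ClassBinning = field(default_factory=ClassBinning)
    dim_threshold: float = 0.2  # scree gap threshold for subspace dimension
    var_floor: float = 1e-6  # eigenvalue regularization, scaled units
    class_floor: int | None = None  # min learning voxels per class; default 5*p
    max_learn_voxels: int | None = None  # stratified subsampling cap
    seed: int = 0
    chunk_size: int = 200_000


@dataclass
class TrainedPredictor:
    """Everything needed to turn new MR volumes into a pseudo CT."""

    spec: FeatureSpec
    scaling: ScalingParams
    binning: ClassBinning
    model: hdda.HddaModel
    class_mean_hu: dict[int, float]

    def to_dict(self) -> dict:
        return {
            "spec": {
                "contrasts": list(self.spec.contrasts),
                "box_mean": self.spec.box_mean,
                "box_sd": self.spec.box_sd,
                "dist_xyz": self.spec.dist_xyz,
                "dist_center": self.spec.dist_center,
                "box_half_width": self.spec.box_half_width,
                "plain_sd": self.spec.plain_sd,
            },
            "scaling": {
                "mean": self.scaling.mean.tolist(),
                "sd": self.scaling.sd.tolist(),
                "columns": list(self.scaling.columns),
            },
            "binning": {
                "lower": self.binning.lower,
                "width": self.binning.width,
                "count": self.binning.count,
            },
            "model": self.model.to_dict(),
            "class_mean_hu": {str(k): v for k, v in self.class_mean_hu.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedPredictor":
        return cls(
            spec=FeatureSpec(**d["spec"]),
            scaling=ScalingParams(
                mean=np.asarray(d["scaling"]["mean"]),
                sd=np.asarray(d["scaling"]["sd"]),
                columns=tuple(d["scaling"]["columns"]),
            ),
            binning=ClassBinning(**d["binning"]),
            model=hdda.HddaModel.from_dict(d["model"]),
            class_mean_hu={int(k): float(v) for k, v in d["class_mean_hu"].items()},
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedPredictor":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _reassign_to_retained(labels: np.ndarray, retained: np.ndarray,
                          binning: ClassBinning) -> np.ndarray:
    """Map dropped-class voxels to the retained class with the nearest midpoint."""
    mid = binning.midpoints()
    lut = np.empty(binning.count, dtype=np.int64)
    for k in range(binning.count):
        # ties toward the lower class index (argmin picks the first)
        lut[k] = retained[np.argmin(np.abs(mid[retained] - mid[k]))]
    out = labels.copy()
    keep = np.isin(labels, retained)
    out[~keep] = lut[labels[~keep]]
    return out


def _stratified_cap(labels: np.ndarray, cap: int, rng: np.random.Generator) -> np.ndarray:
    """Row subset of size ~cap, proportional per class, at least 1 per class."""
    n = labels.shape[0]
    if n <= cap:
        return np.arange(n)
    frac = cap / n
    keep: list[np.ndarray] = []
    for k in np.unique(labels):
        rows = np.nonzero(labels == k)[0]
        m = max(1, int(round(rows.size * frac)))
        keep.append(rng.choice(rows, size=m, replace=False))
    return np.sort(np.concatenate(keep))


def train(
    samples: Sequence[Sample],
    spec: FeatureSpec,
    config: PipelineConfig | None = None,
) -> TrainedPredictor:
    """Learn the decision rule from one or more labeled samples.

    Observations from all samples are pooled; classes with fewer learning
    voxels than the class floor (default 5 p) are dropped and their voxels
    relabeled to the nearest retained class.  Raises if fewer than two
    classes survive.
    """
    if config is None:
        config = PipelineConfig()
    if len(samples) == 0:
        raise ValueError("training requires at least one sample")

    xs, hus = [], []
    columns: tuple[str, ...] = ()
    for s in samples:
        obs = assemble(s.mr, spec, s.mask)
        if not s.ct.same_grid(s.mask):
            raise ValueError(f"sample {s.name!r}: CT grid differs from mask grid")
        xs.append(obs.X)
        columns = obs.columns
        sel = tuple(obs.voxel_indices.T)
        hus.append(s.ct.values[sel].astype(float))
    X = np.vstack(xs)
    hu = np.concatenate(hus)
    p = X.shape[1]

    labels = bin_hu(hu, config.binning)
    floor = config.class_floor if config.class_floor is not None else 5 * p
    counts = np.bincount(labels, minlength=config.binning.count)
    retained = np.nonzero(counts >= floor)[0]
    if retained.size < 2:
        raise ValueError(
            f"only {retained.size} class(es) retained (floor={floor}); "
            "the learning set does not support a discriminant model"
        )
    labels = _reassign_to_retained(labels, retained, config.binning)

    if config.max_learn_voxels is not None:
        rng = np.random.default_rng([config.seed, 101])
        rows = _stratified_cap(labels, config.max_learn_voxels, rng)
        X, labels, hu = X[rows], labels[rows], hu[rows]

    obs_pool = ObservationMatrix(
        X=X, columns=columns,
        voxel_indices=np.zeros((X.shape[0], 3), dtype=int), labels=labels,
    )
    scaled, params = scale(obs_pool)
    model = hdda.fit(scaled.X, labels, threshold=config.dim_threshold,
                     var_floor=config.var_floor)
    mean_hu = {
        int(k): float(hu[labels == k].mean()) for k in np.unique(labels)
    }
    return TrainedPredictor(spec=spec, scaling=params, binning=config.binning,
                            model=model, class_mean_hu=mean_hu)


def predict_pct(
    pred: TrainedPredictor,
    mr: Mapping[str, Sequence[Volume]],
    mask: Volume,
    chunk_size: int = 200_000,
) -> Volume:
    """Predict a pseudo-CT volume; voxels outside the mask are set to air.

    Prediction runs in voxel chunks; results are independent of chunk size.
    """
    obs = assemble(mr, pred.spec, mask)
    obs = apply_scale(obs, pred.scaling)
    means = np.array([pred.class_mean_hu[k] for k in pred.model.class_labels])
    out_vals = np.full(mask.shape, _AIR_HU, dtype=float)
    sel = tuple(obs.voxel_indices.T)
    pct_rows = np.empty(obs.n)
    for start in range(0, obs.n, chunk_size):
        chunk = obs.X[start:start + chunk_size]
        post, _ = hdda.posteriors(pred.model, chunk)
        pct_rows[start:start + chunk_size] = post @ means
    out_vals[sel] = pct_rows
    return Volume(out_vals, spacing=mask.spacing, origin=mask.origin, role="pct")


def crossval(
    samples: Sequence[Sample],
    spec: FeatureSpec,
    config: PipelineConfig | None = None,
) -> list[dict]:
    """Leave-one-sample-out cross-validation.

    Each fold trains on all other samples and predicts the held-out one;
    returns one record per fold with the pseudo CT and its metric report.
    """
    if len(samples) < 2:
        raise ValueError("cross-validation requires at least 2 samples")
    if config is None:
        config = PipelineConfig()
    folds = []
    for i, held_out in enumerate(samples):
        learn = [s for j, s in enumerate(samples) if j != i]
        pred = train(learn, spec, config)
        pct = predict_pct(pred, held_out.mr, held_out.mask,
                          chunk_size=config.chunk_size)
        rep = evaluate.report(pct, held_out.ct, held_out.mask, config.binning)
        folds.append({
            "fold": i,
            "sample": held_out.name or str(i),
            "pct": pct,
            "report": rep,
            "predictor": pred,
        })
    return folds


def _spec_label(spec: FeatureSpec) -> tuple[str, str]:
    feats = [f for f, on in [("box_mean", spec.box_mean), ("box_sd", spec.box_sd),
                             ("dist_xyz", spec.dist_xyz),
                             ("dist_center", spec.dist_center)] if on]
    return ", ".join(spec.contrasts), ", ".join(feats) or "none"


def combination_search(
    samples: Sequence[Sample],
    specs: Sequence[FeatureSpec],
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Cross-validate every candidate spec; table sorted by mean MAE ascending."""
    rows = []
    for spec in specs:
        folds = crossval(samples, spec, config)
        maes = [f["report"].mae for f in folds]
        contrasts, feats = _spec_label(spec)
        rows.append({
            "contrasts": contrasts,
            "features": feats,
            "mean_mae_hu": float(np.mean(maes)),
            **{f"mae_fold{f['fold']}_hu": f["report"].mae for f in folds},
        })
    return (pd.DataFrame(rows)
            .sort_values("mean_mae_hu", kind="stable")
            .reset_index(drop=True))
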