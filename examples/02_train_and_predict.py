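"""Train the pseudo-CT predictor on two scenes and predict a third.

The observation vector per voxel is (TSE1, UTE2 echo 1, UTE2 echo 2,
their box-sd features, in-plane distance to the sample centroid) — the
7-dimensional combination that performed best in cross-validation.  The
pseudo CT of a voxel is the posterior-weighted mean of the 32-HU-class
mean CT numbers.
"""

from pction import FeatureSpec, predict_pct, train
from pction.evaluate import mae, me_per_class
from pction.classes import ClassBinning
from pction.phantom import default_scene, render_volumes
from pction.pipeline import Sample
from pction.volio import air_mask


def make_sample(seed):
    rendered = render_volumes(default_scene(seed))
    return Sample(mr=rendered.mr, ct=rendered.ct,
                  mask=air_mask(rendered.ct), name=f"scene{seed}")


spec = FeatureSpec(contrasts=("TSE1", "UTE2"), box_sd=True, dist_center=True)
learn = [make_sample(1), make_sample(3)]
held = make_sample(2)

pred = train(learn, spec)
print(f"feature dimension p = {len(pred.scaling.columns)}; "
      f"{len(pred.model.class_labels)} retained HU classes")

pct = predict_pct(pred, held.mr, held.mask)
value, sd = mae(pct, held.ct, held.mask)
print(f"held-out sample: MAE = {value:.1f} HU (sd of |error| {sd:.1f} HU)")

binning = ClassBinning()
me, n = me_per_class(pct, held.ct, held.mask, binning)
mids = binning.midpoints()
print("mean error per class for the pure-tissue bins "
      "(|ME| <= 16 HU is the class-quantization bound):")
for hu, name in [(-1000, "air"), (-100, "fat"), (-80, "marrow"),
                 (40, "muscle"), (120, "cartilage"), (1200, "bone")]:
    k = int((hu - binning.lower) // binning.width)
    if k in me:
        print(f"  {name:10s} class mid {mids[k]:7.0f} HU: "
              f"ME {me[k]:+7.1f} HU over {n[k]} voxels")
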