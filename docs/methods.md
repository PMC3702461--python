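# Methods

## The estimation problem

The package predicts a CT-number volume (pseudo CT, pCT) from co-registered
multi-contrast MR volumes, then converts CT numbers to relative
water-equivalent path length (WEPL) for ion-range analysis.  The mapping is
treated as pure pattern recognition: no physical model links MR signal to
attenuation.  The CT scale is discretized into K = 128 half-open classes of
32 HU anchored at −1024 HU (covering [−1024, 3072); the anchor is a
configuration choice — the class count and width are the method's
constants, the anchor is not).  A learning set of voxels with known CT
provides labeled observations; prediction reconstructs a continuous value
as the posterior-weighted mean of class mean HU.  The discretization bounds
the best attainable per-class mean error by the half-width, 16 HU.

## Observation vectors

Per voxel: the selected contrast intensities (an ultrashort-echo contrast
contributes its two echo images), optionally per-image *box.mean* and
*box.sd* over the 3×3×3 neighborhood (26 surrounding voxels; truncated at
volume borders rather than zero-padded, so no synthetic air context leaks
into the sample), and optionally coordinate features *dist.xyz* (three
absolute mm offsets) and *dist.center* (in-plane axial radius), both taken
after translating coordinates to the mask centroid so they are invariant to
where the sample sits in the scanner frame.  *box.sd* is the population
standard deviation of the box **multiplied by the central voxel's
intensity** — an unconventional but deliberate definition: the weighting
couples edge evidence with brightness, so dark-voxel boxes contribute
little; `plain_sd=True` switches to the conventional unweighted version.  Distances are computed in mm (not voxel
units) on the volume-level centroid; the slice plane for *dist.center* is
the stored axial plane.  All features are standardized to mean 0 / sd 1 on
the learning set; prediction data reuse the learning-set parameters.

## The subspace discriminant (HDDA)

Each class k is Gaussian with covariance constrained to a dₖ-dimensional
signal subspace plus isotropic residual noise:

    Σₖ = Qₖ diag(aₖ₁ … aₖ_dₖ) Qₖᵀ + bₖ (I − Qₖ Qₖᵀ)

Fitting is closed-form per class: prior nₖ/n, empirical mean, eigenvalue
decomposition of the empirical covariance; aₖⱼ are the top dₖ eigenvalues,
bₖ the mean of the rest, dₖ is picked by Cattell's scree rule — the largest
index whose eigenvalue gap is at least `threshold × max gap`, with the
threshold default 0.2.  Ambiguity note: the scree rule is applied to
eigenvalue *gaps* (not cumulative variance); the rule lives behind
`hdda.select_dimension` so an alternative can be substituted in isolation.
Ties at the threshold resolve to the larger dimension; a flat spectrum
falls back to dₖ = 1.  Eigenvector signs are fixed (first non-negligible
component positive) so fits are bit-deterministic.  Variances are floored
at 1e−6 (scaled units) so nearly-empty or constant classes cannot produce a
singular model.  Classification evaluates

    Kₖ(x) = ‖proj‖²-weighted Mahalanobis in the subspace
          + residual ‖x − Pₖx‖² / bₖ
          + Σⱼ log aₖⱼ + (p − dₖ) log bₖ − 2 log πₖ

which equals −2 log(πₖ 𝒩(x; μₖ, Σₖ)) up to the class-independent constant
p log 2π; posteriors are softmax(−Kₖ/2) with max-subtraction.  Correctness
is pinned by an oracle: posteriors computed through the cost must agree
with posteriors from dense multivariate-normal densities on the
reconstructed Σₖ to 1e−8 (and with unconstrained QDA in the dₖ = p−1
limit).  Classes with fewer than 5p learning voxels are dropped and their
voxels relabeled to the retained class with the nearest midpoint; dropped
classes simply receive no posterior mass at prediction, keeping the
posterior a simplex over retained classes.

## Synthetic phantom

The generator emulates a meat-sample acquisition so the whole pipeline is
testable without the original scans.  A scene is a list of geometric
primitives (ellipsoids, cylinders, shells, boxes) bound to tissues with
literature-seeded T1/T2 (T2* for the UTE readout), relative proton and
electron density and a nominal HU.  Rendering: rasterize labels on a
supersampled grid (factor 2 by default), map tissues to noiseless MR
signals via standard steady-state closed forms (spin echo, spoiled GRE for
UTE, inversion-prepared GRE) and to nominal HU, block-average to the target
grid — which *is* the partial-volume model: boundary voxels become convex
mixtures — then apply a strictly positive low-order-polynomial
multiplicative bias field to MR, Rician noise to MR magnitudes (two-channel
Gaussian construction) and additive Gaussian noise to CT.  All randomness
derives from one scene seed through fixed substreams; output is
bit-reproducible.

Default study conditions (chosen once as a desk-scale stand-in for the
three-sample protocol): grid 44×44×24 at 1 mm isotropic, supersampling 2; a
fat shell around a muscle bulk, a cortical-bone cylinder shell (~3 mm
cortex, pork-femur-like) around a marrow core, a thin cartilage cylinder
and an enclosed air cavity; three scenes differ by seeded geometry jitter
(positions and radii).  Noise and bias amplitudes are free parameters the
emulated protocol does not pin down; the cross-validation study conditions
are noiseless and bias-free (`mr_sigma = ct_sigma = bias_amplitude = 0`),
noisy values (mr_sigma 0.01, ct_sigma 10 HU, bias 0.1) appear only in
examples.  The sequence closed forms are contrast-plausible, not
quantitative MR — no Bloch simulation, k-space sampling, distortion or
coil model; fat saturation is modeled as label-based nulling of fat-class
tissues (fat, yellow marrow).

What the phantom does *not* emulate, hence what passing tests do not show
about real data: registration error between MR and CT (an integer-shift
injector exists for sensitivity studies but synthetic volumes are generated
aligned), scanner-specific intensity filters, anatomical texture within
tissues, and continuous partial-volume fractions (supersampling quantizes
mixtures to multiples of 1/8).  Real-data MAEs are dominated by exactly
these terms, so synthetic MAEs (≈10–20 HU noiseless, ≈50–100 HU at the
example noise levels) are not comparable to scanner results in absolute
value — only the structure (soft tissue accurate, transitions and bone
hard, UTE indispensable for bone/air) carries over.

On noiseless scenes a known, reproducible limitation appears: sparse
boundary-mixture classes (e.g. muscle–cartilage partial-volume bins) are
absorbed by their dominant neighbor class.  With the scree threshold 0.2
the big class keeps dₖ ≈ 1–2 and pools its tight intensity variance with
its broad spatial/box-feature variance into the isotropic bₖ, so its
density remains high at the mixture location and its larger prior wins;
this persists under resubstitution and in the QDA limit, i.e. it is a
property of the model family, not of the fit.  Consequently the per-class
|ME| ≤ 16 HU quantization bound holds for the well-populated tissue classes
and for the voxel-weighted soft-tissue group (|ME| < 1 HU), but individual
partial-volume classes (≈0.5–4 % of soft-tissue voxels) can exceed it by a
factor of 2–5.

## Volume handling

Arrays are indexed (x, y, z) with z the slice axis; world coordinates are
voxel-centered: world = origin + (index + 0.5)·spacing, documented once and
used everywhere (I/O, resampling, distances, ray tracing).  NIfTI I/O goes
through nibabel, MetaImage through SimpleITK; only axis-aligned grids are
supported.  MR-to-CT grid resampling is trilinear with role-dependent
padding (0 for MR, −1000 HU for CT) and errors on disjoint extents.  Rigid
registration itself is out of scope — inputs are assumed co-registered.
The air-exclusion mask thresholds CT at −800 HU (value not dictated by the
protocol; configurable), closes with a 1-voxel ball, removes components
under 27 voxels and **fills holes**, so only air connected to the image
edge is excluded and internal cavities stay part of the classified
population.

## HLUT, WET and the shift experiment

The HLUT is strictly configuration: ordered (HU, WEPL) control points,
piecewise-linear with linear end extrapolation floored at 0.  The shipped
default table spans (−1000, 0.00) … (3000, 2.40) on a 140 kVp-like scale;
all WET statements are relative to the configured table.  Tissue groups
(air < −800, partial volume [−800, −150), soft tissue [−150, 150), soft
bone [150, 700), bone ≥ 700 HU) are interval conventions, with ΔWEPL
evaluated at the interval midpoint (configurable): ΔWET = ΔWEPL · d for
thickness d, reported at 1/5/10 cm.  Standard errors accumulate per
0.5 mm beam voxel either as a random walk (`"sqrt"`, default:
SE = σ·√(voxel·d)) or fully correlated (`"linear"`: SE = σ·d); both modes
exist because either convention is defensible and neither is claimed to
reproduce any particular published table.

The range proxy is an axis-aligned ray tracer: WET(depth) accumulates
wepl·step along the beam axis; per-ray distal error is the WET difference
from the entry face to the PTV's distal surface under pCT vs reference CT.
It is deliberately *not* a dose engine — no lateral scatter, spot
optimization, ripple filter or biological weighting — so its outputs are
range discrepancies in mm, not dose statistics.  The adaptation experiment
shifts the PTV by an interpolated mask translation (2 mm x + 2 mm y in the
default setup) and compares (A) re-planning on the pCT against the shifted
target — classifier error only — with (B) keeping the reference-CT plan —
pure geometric miss.  Zero shift makes B vanish identically and reduces A
to the plain pCT range error, which is asserted in tests.  On the default
scenes A ≈ 0.05–0.4 mm vs B ≈ 1.8–2.1 mm: re-planning on the pseudo CT
beats ignoring a 2 mm shift whenever the classifier's WET error is below
the geometric miss.

## Numerical and scale choices

Cross-validation is leave-one-sample-out over the three scenes; learning
voxels may be capped by stratified proportional subsampling (preserving
class priors) to bound fit time, though at the default scene size
(~15 000 mask voxels/scene) the full pipeline runs in seconds on one core
— the problem sizes above were chosen as the package's desk-scale study
conditions.  Prediction runs in voxel chunks with results independent of
chunk size.  Out-of-range HU clamps to the first/last class rather than
erroring so noisy outliers cannot abort training.  Determinism: fixed
scene seed + config ⇒ bit-identical volumes, models and predictions.

Known limitations, summarized: single-Gaussian-per-class cannot represent
bimodal partial-volume classes (see above); absolute MR noise sigmas weight
low-amplitude contrasts (UTE steady-state signal ~0.01–0.03) much more
heavily than high-amplitude ones, so per-contrast noise should be scaled if
realistic SNR ratios matter; the combination ranking on noiseless data
favors raw intensities (features add nothing when classes are
near-deterministic), while the noisy-example conditions reproduce the
expected ordering in which neighborhood and coordinate features help
substantially.
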