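# Methods

`lamikit` re-implements, end to end on synthetic phantoms, a learned
adaptive-illumination stack for multiphoton microscopy: a forward model of
two-photon excitation under tissue scattering, surface-shape featurization, a
small neural network that predicts per-point excitation power from shape, a
software model of the fast EOM-based illumination patterner, a three-stage
registration/stitching pipeline, cell-candidate identification with active
learning, and track motility statistics. This note records the models, the
defaults and the reasoning behind the genuinely open choices.

## Forward model (phantom)

A sample is a closed convex shape (sphere, ellipsoid, flat slab, or a union
of two spherical lobes) with a homogeneous scattering mean free path `ls`
(um). For a focal point inside the sample, every excitation ray in the
objective's numerical aperture is attenuated independently by
`exp(-d/ls)`, where `d` is that ray's in-tissue path length (computed
analytically from the sample geometry). The pupil carries a Gaussian
amplitude with zero phase; per-ray power weights are the Gaussian intensity
times the annulus area, normalized to one. The attenuation factor is the
pupil-weighted mean

    A = sum_k w_k exp(-d_k / ls),  A in (0, 1],

and the noiseless expected brightness of a standard candle is

    E = gain * b * vignette(x, y) * (P0 * A)^2,

the two-photon square law applied to the unscattered power. `b` is the
candle's intrinsic labeling factor (lognormal, population mean 1, CV
configurable, default 0.2 — labeling noise is independent of position);
`vignette` is a cos^4-like radial sensitivity profile over the 220 um field
of view (default falloff 10% at the corner), included so that field position
carries a learnable effect. Shot noise is Poisson on `E` when enabled;
Gaussian read noise is available but off by default.

Deliberately not modeled: wave-optical effects, heterogeneous scattering,
photobleaching, and a separate emission-reabsorption term — excitation
scattering and emission absorption are lumped into the single attenuation
term, since the learner cannot distinguish them anyway.

Choice of `ls`: scattering mean free paths for lymphoid tissue near 800 nm
are not well tabulated; 100 um is a realistic mid-range value and is shared
between the phantom and the ray-optics model everywhere in the test suite.
With `ls = 100` um the required power at 300 um depth is roughly an order of
magnitude above the surface value, matching practical experience with
deep-tissue two-photon imaging.

Coordinates are right-handed with z increasing into the tissue, units um,
voxel centers at half-integer positions.

## Surface map and shape features

The sample surface is a single-valued height map `z(x, y)`: picked 3D surface
points are Delaunay-triangulated in XY and interpolated piecewise linearly;
outside the convex hull of the picked points the height is undefined (NaN).
Points that would create a vertical overhang (duplicate XY, distinct z) are
rejected. A cached regular-grid evaluation (2 um spacing, bilinear) speeds up
the millions of height queries made during featurization; near-hull cache
cells read as undefined, which is conservative (undefined counts as
"above the surface" during ray searches).

Shape features for a focal point are the in-tissue propagation distances of
12 rays, all inclined 20 degrees to the optical axis with equally spaced
azimuths (ray 0 along +x; by the rotational symmetry encoded below the phase
is immaterial for symmetric surfaces). Each distance is found by binary
search for the smallest `t` at which `point + t*dir` is above the surface or
undefined, starting from 2000 um and halving to a 1 um tolerance (11 steps).
The tolerance is our choice: well below the 4 um plane spacing, and cheap.
Distances are binned into a 12-bin histogram with nonlinear edges
`(k/12)^1.5 * 350` um for `k = 0..12` — short propagation distances matter
exponentially more than long ones, and 350 um is the depth beyond which no
excitation is expected. Distances beyond 350 um clamp into the last bin so
the counts always sum to 12. The final feature vector is
`[brightness, field_x, field_y, counts_0..counts_11]` (15 elements).

## Ray-optics comparison model

`relative_power = 1/A` on an ideal sphere, with analytic sphere-line path
lengths, is the physics-only baseline. Because marginal rays cut shorter
chords through a convex sample than through a flat slab, log relative power
is concave in depth (sub-exponential), whereas the flat-slab paraxial limit
is exactly exponential (`1/A = exp(z/ls)`). For real-time use the model is
precomputed into a bilinear lookup table over (vertical depth to surface,
surface normal angle), which parameterizes the sphere model completely.

When this baseline is deployed on a non-spherical sample (the generalization
experiment below), it assumes the sample *is* a sphere: a least-squares
sphere is fitted to the picked surface points and depth/normal angle are
taken from that sphere. Giving it the true per-point surface depth would
erase exactly the model mismatch the comparison is about.

Imageable-volume accounting uses spherical-shell arithmetic with the default
parameters: constant illumination images a 25 um shell of a 510 um sphere,
quartered for shadowing (~1.94e7 um^3); the learned method images the full
shell from the surface to the 300 um power-limited depth (~5.17e8 um^3),
a ~27x increase. The intermediate strategies (exponential-with-depth valid to
h = 140 um, arbitrary profile to h = 300 um, surface-offset profiles) are
modeled as cylinders `pi r^2 h`; their exact geometry is under-determined,
so they sit behind a config switch and are not used in any headline number.

## Power predictor

A single-hidden-layer fully connected network (15 -> 200 -> 1, ReLU) maps
standardized features to an EOM voltage. The EOM's voltage-to-power curve is
a fitted sinusoid `p(V) = a sin(wV + phi) + c` constrained to `p(0) = 0` and
to a strictly increasing branch on [0, 1.2] V; its inverse is evaluated on a
dense grid. The training loss is squared error *in power space*:
`(p(V_pred) - p(V_true))^2`, which makes the loss invariant to how the
voltage axis is parameterized.

Training data come from the simulated calibration protocol: candles seeded
through the phantom to 300 um depth, each tile imaged with the spherical-
model reference power multiplied by one uniform factor in [0.5, 2] per tile,
so observed brightness spans too-dim to unnecessarily bright at every depth.
Defaults: batch size 1000, Adam (lr 3e-3), dropout 0.5 on the hidden layer,
early stopping when the validation loss (10% split) fails to improve for 10
epochs; each plateau restores the best weights and halves the learning rate
(3 times) before stopping.

Two numerical details matter. First, the sinusoid is flat at both voltage
rails, so gradients vanish for out-of-range outputs: the output layer is
initialized small and biased at the mean-power voltage, and the loss path
clamps voltages just inside the rails (straight-through gradient). Second,
dropout noise on the hidden layer passes through the *curved* sinusoid, so
the dropout-trained weights are systematically biased for deterministic
(dropout-off) inference — by up to tens of percent at low powers where the
curve is most convex. A short dropout-free fine-tune phase (same loss,
lr/6, same early stopping) closes that train/test gap; without it the
predictor under-powers shallow focal points.

At inference the brightness feature is supplied directly as a z-score of the
training brightness distribution (0 requests the training-mean brightness),
the output voltage is clipped to [0, 1.2] V, and an 8x8 grid of predictions
per field of view feeds the patterner. Grid nodes outside the surface hull
take the nearest in-hull node's value. One predictor is trained per
excitation laser and tagged accordingly.

What the synthetic experiment does and does not show: training on a sphere
phantom and testing on an eccentric ellipsoid exercises generalization
across surface shape, vignetting compensation, and labeling/shot noise, with
an exact forward-model oracle. It does not probe heterogeneous scattering,
surface-mapping errors from hand-picking, sample drift, or wave-optical
effects; passing it says the learner recovers the attenuation physics it was
shown, not that every real sample is in reach.

## TR-SLM model

An 8x8 pattern in [0, 1] (fraction of full-scale voltage) is bilinearly
interpolated across the field. The resonant X mirror imposes
`x(t) = (1 - cos(pi t / T_line)) / 2` within each line (so dwell time per
unit x is highest at the edges); Y advances linearly per line. The line-sync
interrupt restarts the update timer every line; between update ticks the
commanded voltage is held, smearing sharp transitions along the fast axis
only. Voltages are quantized to 12 bits of the 1.2 V full scale (rounding,
then clamped to the pattern's own ceiling so applied power never exceeds the
commanded maximum). The default update interval of 0.5 us (~126 updates per
line) reproduces smooth gradient patterns — the realistic case — within 1%
RMS while a checkerboard still blurs horizontally; the real device's update
rate is not documented, so it is configurable.

## Registration

Stage 1 (within-stack breathing jitter) minimizes the sum of squared
differences between consecutive resampled planes, normalized by the stack's
total squared intensity, plus `lambda (||x||^2 + ||y||^2)` with
`lambda = 8e-3`, by Adam at learning rate 1 with patience 10; each plateau
restores the best iterate and halves the rate until below 1/16. All
channels except the SHG fiducial drive the loss; a 5% border is masked.
Planes are resampled by *Fourier phase-ramp translation* rather than
bilinear interpolation: bilinear resampling attenuates high spatial
frequencies at fractional shifts, so on sharp data the loss can be lowered
by blurring a plane instead of aligning it (we observed spurious global
minima); the Fourier shift is energy-preserving and eliminates that failure
mode. Gradients use exact spectral derivatives of each plane.

A property of the normalized loss worth knowing: the data term's gain from
correcting one plane is bounded by ~4/N of the normalized scale (N planes),
while the penalty grows as `lambda s^2`. At `lambda = 8e-3` this supports
sub-0.5-pixel recovery for shifts up to ~2 px confined to a few planes —
which is the artifact regime this correction targets (breathing motion
confined to single planes) — and shrinks larger or denser corrections by
roughly `2 lambda / (k + 2 lambda)`. The tests stay inside the supported
regime deliberately.

Stage 2 (time) is the argmax of the mean-removed 3D circular
cross-correlation between consecutive time points, accumulated over the
series; it is exact on integer shifts. Stage 3 (stitching) maximizes the
mean correlation coefficient over the overlap regions of adjacent stacks
(correlation, not cross-correlation, so brightness rescaling is harmless),
three translation parameters per stack with the first stack pinned, using a
trust-region optimizer with finite-difference gradients; inputs are
time-averaged, and a min-over-channels pseudo-channel is available as an
autofluorescence fiducial. Zero-variance overlaps are skipped with a
warning.

The online Z-drift estimator reduces the 3D cross-correlation of the
(SHG-like) fiducial channel to a curve of per-Z-lag maxima, fits a cubic
spline, and takes its continuous argmax for sub-plane accuracy; an
exponential moving average (weight 0.5, configurable — the value is not
documented) tracks the drift rate so the next step can be pre-compensated.

## Cell identification

Candidates come from a deterministic pipeline: Gaussian smoothing, local
background subtraction by grey opening (the estimator is our choice — the
original used a commercial package's internals), global thresholding,
connected components, and a watershed split from distance-transform seed
maxima of a configurable size. Engineered features per candidate:
background-subtracted unit-norm spectrum (zero vectors flagged), the
pre-normalization magnitude, pairwise distances between per-channel
intensity-weighted centers of mass and their distances to the plain
centroid, inter-channel correlations, per-channel basic statistics, and
morphology. Six channels by default.

The NC-ROI extractor clusters a candidate's voxels by normalized-cut
spectral clustering on `w_ij = exp(-d_ij)` with
`d_ij = alpha ||r_i - r_j||^2 + beta (1 - s_i . s_j)` (alpha in 1/um^2,
beta dimensionless), returning the cluster whose mean unit spectrum best
matches a reference (ties to the larger side). The spectral term is written
as a *dissimilarity*: the formulation this is based on adds the raw dot
product, which would make spectrally similar voxels less adjacent,
contradicting its purpose; `literal_formula=True` preserves that raw form
for comparison. The partition is invariant to global intensity rescaling
because only unit spectra enter.

The classifier is an averaged ensemble of 12-hidden-unit networks trained on
the logistic loss (3 members while labels are being collected, ~100 for a
final prediction pass). Uncertainty sampling labels, at each round, the
unlabeled candidate whose ensemble score is closest to 0.5 (ties to the
lowest index). The labeling-efficiency simulator starts from one random
positive and one random negative, then iterates select/label/retrain,
scoring accuracy and balanced accuracy on the remaining unlabeled pool;
balanced accuracy is the headline metric because the pools of interest are
heavily imbalanced (~0.5% positive, mirroring hundreds of target cells among
tens of thousands of candidates). The synthetic pool emulates the engineered
feature geometry: positives carry a reference spectral signature, negatives
mix broad autofluorescence, a distinct second fluorophore, and bleed-through
composites near the decision boundary.

## Motility statistics

The motility coefficient of a track is the slope of its time-averaged MSD
over the first third of lags, divided by 6 — for a 3D random walk with
diffusivity D, MSD = 6 D t, so the estimator recovers D. The definition is
ours (the quantity is conventional but rarely written down); a log-log MSD
slope serves as the diffusive-exponent diagnostic (~1 diffusive, ~2
ballistic, <1 confined). Tracks shorter than 5 minutes are excluded by
default (3-minute variant available).

Displacement-versus-sqrt(time) curves pool per-timepoint displacements from
track start over all tracks and fit a locally linear (LOWESS-style)
smoother with tricubic or Gaussian weights on a fixed grid; the bandwidth is
manual. 95% confidence bands come from 500 bootstrap resamples of whole
tracks (not points), respecting within-track correlation. Cluster density
counts, for each cell, the other cells within 100 um, divides by the number
of cells at that time point, and averages over cells (the aggregation is our
choice; the per-cell quantity is the defined one).

## Problem sizes

The test suite runs the full calibration experiment at 10^4 candles with
2x10^3 held-out probes, registration on 64x64 stacks of 10-12 planes,
active learning on 4x10^3-candidate pools over 10 seeds with a 100-label
budget, and motility on 100-200 simulated tracks — sizes chosen so the whole
suite completes in a few minutes on one CPU while every pipeline still runs
end to end at realistic signal-to-noise.
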