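# Methods

## Problem setting

Attenuation correction (AC) turns a raw PET reconstruction into a
quantitative image: without it, annihilation photon pairs absorbed or
scattered in tissue suppress counts, most strongly deep in the body.  The
usual correction divides out a survival factor derived from a CT
attenuation map, but the CT-corrected reference itself can be corrupted —
by photopenic *halo* shells around intensely hot organs (failed scatter
correction under the extreme organ-to-background contrast of renally
excreted tracers), by respiratory *motion* misalignment between the PET and
CT volumes, and by transaxial *truncation* of the CT field of view.  A
network trained to map non-AC images to CT-AC images inherits these
corruptions through its training targets.

This package implements the two-stage defense: train once on everything
with a robust L1 loss, let the model score its own training set
(self-inference), exclude the cases whose references the consensus mapping
cannot explain, and retrain on the purified set with an L2 loss.  Because
clinical cohorts cannot be redistributed, the package ships a synthetic
cohort generator that reproduces the *structure* of the problem — paired
volumes whose reference arm carries controlled, labelled artifacts — so
every stage of the pipeline is testable end to end.

## Synthetic cohort

Each subject is a whole-body-like phantom on a 48 x 48 x 64 grid at
4.07 x 4.07 x 3.0 mm voxels (configurable): an elliptic-cylinder torso of
soft tissue (mu = 0.096 cm^-1 at 511 keV), two ellipsoidal lungs
(0.03 cm^-1), an optional cortical bone rim (0.15 cm^-1), two kidneys and a
bladder.  Activity is SUV-like: soft tissue 1, lungs 0.3, kidneys 15,
bladder 20 — an organ-to-background ratio above 10, the regime in which
halo artifacts arise.  Organ positions, sizes and intensities are jittered
by +/-10% per subject (seeded), emulating cohort variability.

**Attenuation physics.**  Both photons of a coincidence must escape, so a
voxel's detection probability is the angle average of
`exp(-integral mu dl)` along the *entire* line of response.  We restrict
LORs to transaxial planes (36 angles by default) and march each line at a
fixed step (half the smallest voxel pitch) with bilinear interpolation.
Because every subject in a cohort shares one grid geometry, the sampling
pattern is precomputed once into a sparse operator (ray x voxel); applying
it to a new attenuation map costs two sparse-dense products, which makes
cohort generation interactive.  A direct rotate-resample implementation is
retained as an internal reference and the two agree to float precision.

**Pairing and noise.**  `non_ac = Poisson(A.S/s)*s` (mean-preserving scaled
Poisson; the single knob `s` controls variance, default 0.05 — at soft
tissue activity 1 this corresponds to roughly 20 effective counts per
voxel, a realistic whole-body noise level).  `clean_ref = non_ac / S` is
the ideal correction; `ct_ac` divides by a survival factor computed from a
*corrupted* attenuation map instead:

* halo — suppression shells (default 80–100% suppression, 10–18 mm thick)
  around bladder *and* both kidneys, applied in image space on the
  corrected image.  Halos are judged clinically by their image-space
  zero-voxel signature, so the injection realizes that signature directly
  rather than modelling the scatter estimation failure that causes it;
* motion — the correction's map is translated axially by 2–4 voxels plus
  one voxel anteriorly (respiratory displacement of the thoracoabdominal
  interface and abdominal wall);
* truncation — the correction's map is zeroed outside a transaxial
  cylinder of 60–80% of the body radius.

The corrupted survival factor is floored at 1e-3, trading unbounded
division blow-up for a bounded, documented bias in truncated regions.
Artifact-free, noiseless pairs reproduce the activity map to float
rounding — the simulator's self-consistency check.

What the generator does **not** emulate: reconstruction point-spread and
inter-voxel noise correlation (OSEM), scatter physics, anatomical texture,
axial LOR obliquity, metal artifacts.  Passing tests therefore demonstrate
the *pipeline's* correctness and the purification mechanism under
controlled contamination, not clinical performance.

## Network

A 20-layer 3D residual CNN maps the non-AC volume to the corrected volume
at unchanged resolution: layers 1–7 use 3^3 kernels (dilation 1), layers
8–14 dilation 2, layers 15–20 dilation 4; identity residual connections
join every two layers; batch normalization and ReLU interleave throughout;
16 feature channels (configurable).  Layer 20 is the linear output head —
a regression task takes no squashing output nonlinearity (a softmax head
remains selectable but is not meaningful for intensity regression).  The
input is added back onto the head output (a global skip), so the trunk
learns the additive correction; with in-plane survival factors in the
0.2–0.7 range this shortens training substantially.  Inputs are normalized
per volume by the 99th-percentile intensity and the scale inverted on
output.

The network, backpropagation and the Adam optimizer are implemented
directly in NumPy: convolutions gather the 27 dilated kernel offsets into
an im2col matrix evaluated as a single BLAS GEMM, activations are
channel-first float32, and all randomness flows from explicit seeds, which
makes training bit-reproducible on CPU — a property the purification
reproducibility guarantees rely on.

**Training patches are full-transaxial axial slabs** (default 6–8 planes).
The survival factor of a voxel depends only on its own transaxial slice,
so a slab patch carries the complete attenuation context of every voxel it
contains; compact cubic patches would hide the body outline that determines
the correction.  Inference tiles the volume with the same slabs (no
overlap) so the network always sees the context it was trained on.

## Two-stage protocol

1. **Stage 1**: L1 loss on all training pairs.  The per-voxel gradient of
   L1 is bounded by 1, so artifact-corrupted reference voxels cannot
   dominate the fit.
2. **Self-inference**: the stage-1 model predicts every training case;
   each case is scored against its own CT-AC reference with MAE, RMSE, and
   ARE% in two floor conventions (below).
3. **Outlier exclusion**: per metric, a robust z-score
   `(x - median) / (1.4826 * MAD)`; a case is excluded when its maximum z
   across the metrics exceeds k (default 2.5).  The MAD is computed from
   the deviations *below* the median: corrupted cases push every metric
   upward, so the left half of the distribution is the uncontaminated
   estimate of clean-case spread, and a two-sided MAD would be inflated by
   the very outliers being hunted (the classical masking effect).
4. **Stage 2**: L2 loss, trained from scratch on the purified set —
   "retrained", not fine-tuned, so no stage-1 artifact memory survives.
   L2 models fine intensity relationships best once heavy tails are gone.

**Relative-metric floors.**  RE%/ARE% divide by the reference, which is
near zero in air, in low-count lung voxels — and inside photopenic halos.
For *evaluation* the package follows the conventional choice: voxels with
reference below a floor (1% of the in-mask 99th-percentile value) are
excluded from the relative sums.  For *purification* that convention has a
blind spot: a fully photopenic halo zeroes its own reference and silently
drops out of the score.  Self-inference therefore also computes a
clamp-floor ARE% (denominator clamped at the floor, every mask voxel kept),
in which a void contributes prediction/floor — a large, reliable signal.
Misalignment errors in mid-intensity tissue, conversely, show best in the
exclude-floor ARE%.  Both enter the outlier rule.  Both conventions are
exposed as configuration on the metric suite.

**Evaluation masks** default to an automatic body mask derived from the
non-AC image (threshold at 5% of the 99th-percentile intensity, interior
holes filled).  The non-AC image is unaffected by reference artifacts, so
the mask is stable across clean and corrupted cases; whole-grid evaluation
is available but dilutes every average with empty air.

**Hyperparameters.**  Adam with momentum (beta1) 0.9, beta2 0.999.  The
grid-search harness scans learning rates 1e-5..1e-3, batch sizes {2, 4, 8}
and momenta {0.9, 0.99}, scoring each combination by validation MAE on a
seeded 20% split; divergent combinations score +inf and the search
continues; ties break toward the smaller learning rate, then batch.  Tests
and the acceptance script run desk-scale budgets (4–8 epochs, learning
rate 1e-3, batch 2) chosen once for this cohort scale; the library defaults
(learning rate 1e-4, batch 4) reflect the configuration such a search
favors at full scale.

**Statistics.**  The with/without-purification comparison uses Welch's
two-sided independent-samples t-test on per-case MAE (the variant that does
not assume equal variances; the equal-variance form is a special case).
Degenerate zero-variance inputs return p = 1 (equal means) or p = 0 by
convention.

## Metric suite

Over an evaluation mask M (float64 accumulation): ME (signed mean error),
MAE, RMSE; RE% and ARE% over the floored voxel set; the VOI-level relative
error of mean uptake for an optional volume of interest; SSIM with a
Gaussian window (sigma 1.5, 11^3 support, weighted non-sample covariances,
C1=(0.01 L)^2, C2=(0.03 L)^2, L = in-mask reference range) computed in 3D
and averaged over M; PSNR = 10 log10(L^2/MSE) with an infinite value
serialized as null plus a flag.  SSIM windows are truncated and
renormalized at volume borders rather than padded, so border voxels are
compared over their real neighborhood; every kernel is verified against an
independent brute-force loop implementation to 1e-10 relative.

The chain |ME| <= MAE <= RMSE and ARE% >= |RE%| hold on every case by
construction and are asserted as invariants.

## Halo QA

A halo is operationally a connected volume of (near-)zero voxels wrapped
around a hot organ.  The detector takes 26-connected components of voxels
at or below a zero threshold (default 2% of the volume's 99th-percentile
intensity; a strict-zero mode exists) inside the body mask, keeps those
touching a one-voxel dilation of the hot-organ mask and at least 20 voxels
large, and reports voxel count and millilitre volume per segment.  The
relaxed threshold exists because noisy simulation and network outputs are
rarely exactly zero.  Detection is validated against the simulator's
recorded shell voxel counts (within +/-10%) and against clean cases (no
segment); detected volume is non-decreasing in injected suppression.
Intensity profiles (trilinear samples along an arbitrary segment, positions
in mm) and relative voxel-wise difference maps
((a-b)/max(b, floor) x 100 with a validity mask) complete the reporting.

## Numerical and degenerate-input policy

* Volumes are float32 on disk and in the network; metric accumulation and
  line integrals run in float64.
* Survival factors are exact 1 where mu = 0; sparse and dense ray marchers
  agree bit-for-bit in float32.
* Division guards: corrupted survival floored at 1e-3; relative metrics
  floored as above; PSNR of identical images reported as infinite via a
  sentinel, never as an exception.
* Degenerate outlier tables (zero MAD) skip the degenerate metric with a
  warning; a purification that would exclude more than half the training
  set aborts — a threshold that aggressive indicates misconfiguration.
* Empty VOIs, empty masks, non-finite volumes, shells outside the grid,
  and unknown config keys are explicit errors, not warnings.

## Problem sizes used by tests and the acceptance script

Cohort-scale checks run 50-subject training sets (40 clean + 10
artifact-corrupted) at the default 48 x 48 x 64 grid with the 16-feature
network: stage 1 trains six epochs on 4-plane slabs and self-inference
scores every second axial slab (a systematic half-volume sample; every
artifact class spans multiple slabs, so detection power is preserved —
verified against full-volume scoring during development).  Three seeded
cohorts enter the purification sensitivity/specificity check.

The purification-benefit comparison runs three replicates on compact
24 x 24 x 32 cohorts (15 clean + 5 artifact training subjects) with an
8-feature stage-2/baseline pair trained for 100 epochs: deep enough that a
model trained on corrupted references absorbs their bias — the regime the
purification protocol exists for.  At materially shorter budgets the
contaminated model can even win, because epoch-based budgets hand the
larger training set more optimizer steps while the artifact bias is not
yet expressed; the methods choice here is therefore a convergence floor,
not a tuning knob.  The grid search runs its full 18-combination grid at
toy scale (tiny subjects, one epoch).  These sizes are the package's
desk-scale study conditions: large enough for the purification statistics
to be meaningful, small enough to run on one CPU core.

## Known limitations

* The simulator's artifacts are geometric idealizations; real halos are
  asymmetric and scatter-model dependent, real motion is non-rigid.
* In-plane-only LORs overstate axial uniformity of attenuation.
* The network is deliberately narrow (16 features); it demonstrates the
  protocol rather than chasing image quality.
* Self-inference scores whole cases; a reference corrupted only in a small
  sub-volume scales the case score with the corrupted fraction, so very
  local artifacts need a lower threshold k or regional scoring.
* Clinical headline numbers from the source cohort (828 scans) are not
  reproducible here and are not targeted by any test.
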