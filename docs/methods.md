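# Methods

`protoplan` re-creates, at desk scale and on fully synthetic data, an
automated treatment-planning workflow for proton pencil-beam scanning
(PBS): a 3D U-Net predicts a dose distribution from ROI masks, the
prediction is touched up by DVH histogram matching, and a robust
dose-mimicking optimizer converts it into a deliverable spot plan, which is
then scored against clinical goals, perturbation scenarios, and a gamma
comparison.  This note records the models, the defaults and why they were
chosen, and what the synthetic setting can and cannot show.

## Voxel model and conventions

All volumes live on one regular lattice with array axes `(i, j, k)` mapped
to patient axes x (right→left), y (posterior→anterior), z
(inferior→superior); the origin is the center of voxel (0,0,0).  The
single treatment beam is fixed en face along +y, so array axis 1 is the
depth axis.  The default desk-scale lattice is 32 × 32 × 48 voxels at 5 mm
(the full-scale clinical lattice of 200 × 160 × 224 at 2.5 mm is supported
by the same code paths but is not a CPU-scale training target).
Prescription dose is 50.4 Gy(RBE) in 28 fractions; fractionation is
metadata only.

Centered crop/pad puts the odd voxel of any asymmetric margin on the
high-index side — an arbitrary but fixed and tested convention.

## Synthetic thorax phantom

The phantom emulates post-mastectomy chest-wall anatomy: a body ellipsoid
(water density 1.0 g/cc), two lung ellipsoids (0.26 g/cc), a spherical
heart, an esophagus tube, a chest-wall shell target spanning a band of the
body-normalized radius on the treated side, and a nodal target volume
superior-medial to it.  Densities are water-equivalent surrogates, not CT
values.  Cohort variation is Gaussian jitter of organ centers (σ = 3 mm)
and semi-axes (σ = 4%), truncated at ±2σ so the default anatomy always
fits the grid; every case is reproducible from one integer seed.

What the phantom does **not** emulate: CT texture and heterogeneity inside
soft tissue, breathing motion, realistic nodal topology (axilla/SCV/IMC
are one convex blob), or inter-patient variation beyond affine jitter.
Consequences: the prediction task is much easier than on clinical data, so
passing tests demonstrate that the pipeline's machinery is correct and
self-consistent — not that the network would predict clinical dose
accurately.

## Analytic spot dose engine

Dose is linear in spot weights, `dose = A @ w`, with one sparse influence
column per spot.  Each spot kernel is separable:

* depth factor in water-equivalent depth (WED): an entry plateau (default
  0.35 of peak) plus a Gaussian Bragg peak (σ = 6 mm) centered at the
  spot's nominal range.  The plateau applies proximally only — it is
  rolled off by a sigmoid centered two Bragg widths beyond the peak so the
  distal falloff is carried by the peak Gaussian (protons stop).  An early
  symmetric variant that let the plateau continue past the peak made
  superficial target coverage flood every downstream organ and was
  rejected as unphysical.
* lateral factor: 2D Gaussian in beam's-eye-view distance, with σ growing
  linearly in geometric depth (6 mm + 0.02/mm), a crude stand-in for
  multiple Coulomb scattering.

WED is the cumulative density × path-length integral along +y evaluated at
voxel centers.  No nuclear halo, no Monte Carlo noise, no deliverability
constraints (minimum spot weight defaults to 0).

Uncertainty scenarios follow the standard robustness recipe: setup shifts
of ±5 mm along each axis and density (range) scaling of ±3%.  Shifts are
rendered as nearest-voxel translations of the patient relative to the beam
(5 mm is an exact multiple of both default spacings, so no interpolation
is involved); the dose is shifted back onto the patient lattice.  The
*optimization* set is {no shift, ±each axis} × {0.97, 1.00, 1.03} = 21
scenarios; the *evaluation* set is {±each axis} × {0.97, 1.03} = 12; both
always contain the stated combinations exactly.

Spot placement is deterministic: a regular lateral lattice (7.5 mm) over
the target's beam's-eye-view projection dilated by a 12 mm margin, and
range layers every 7.5 mm water covering each column's target WED span.
The 12 mm lateral margin deliberately exceeds the 5 mm setup shift plus
the lateral penumbra, so robust coverage is geometrically possible.
Influence entries below 1e-4 of their column maximum are dropped.

## Reference (training) doses

Training pairs need a "clinically approved plan" stand-in.  Each phantom's
reference dose is produced by the package's own chain: spots are placed as
above, and their weights are optimized by *robust* mimicking (the full
21-scenario set, targets robust) of an idealized prescription — a plateau
of 1.03 × Rx over the targets dilated by the 5 mm setup margin, with a
10 mm Gaussian falloff, zero outside the body.  Aiming slightly above Rx
with a margin mirrors how clinical plans are driven so coverage holds
under perturbation; making the reference optimization robust mirrors the
fact that the plans a clinical prediction model learns from are themselves
robustly optimized.  Both choices were fixed during design bring-up of the
pipeline and are deliberate study conditions, not fitted values.

## Dose prediction network

Inputs are four binary channels — target union, lungs, heart ∪ esophagus,
external — assembled from a configurable ROI→channel map; the output is
one Rx-normalized dose volume (doses are scaled so prescription voxels
read 1.0).  The architecture is the classic 3D U-Net: two 3×3×3 "same"
convolutions per level with ReLU, 2× max pooling, stride-2 transposed
convolution upsampling, concatenation skips, and a final 1×1×1 projection
without activation.  Negative predicted dose is clamped to zero at
inference (the head is unconstrained; the clamping convention is ours).

Two configurations are named:

* **full-scale**: channel widths (21, 37, 167), depth 2 — exactly
  1,194,857 trainable parameters.  The reference design fixes the
  structure and the exact total count but not the per-level widths, so the
  widths were found by exhaustive search (`scripts/calibrate_unet.py`)
  under the canonical structure; no standard doubling progression matches
  the count exactly, and this is the match that keeps every structural
  convention.
* **desk-scale**: widths (8, 16, 32) for the 5 mm lattice; CPU-trainable
  in minutes.

The network is implemented on a compact numpy layer engine
(`protoplan.nn`), keeping the dependency surface small and every gradient
inspectable: im2col-based 3D convolution, max pooling with recorded
argmax, transposed convolution, Adam (β = 0.9/0.999, ε = 1e-7), and
mean-L1 loss, all with hand-written reverse-mode gradients verified by
adjoint identities in the test suite.  Training uses batch size 1, Adam at
1e-3, a seeded shuffle per epoch, and keeps the parameter snapshot at the
epoch with the lowest validation loss.  Everything is float32 and
deterministic for a fixed seed on a fixed BLAS configuration.

At desk scale, with cohorts of a handful of phantoms, the network operates
in the memorization regime; the end-to-end check therefore plans a case
the model has seen, which is the intended smoke-test reading (does the
whole chain cohere?), not a generalization claim.

## DVH postprocessing

A rule edits one ROI's DVH and the voxel doses are resampled to the edited
DVH by rank-preserving histogram matching (value at average rank r among n
becomes the target quantile at r/(n−1); ties share a rank, so the remap is
monotone).  `max_dose_clamp` compresses doses above the level onto the
level — the minimal monotone change; `min_coverage` raises the coldest
voxels of the covered fraction up to the level, leaving hotter voxels
untouched.  Rules apply in list order; overlapping ruled ROIs take the
last transform and the conflict is logged.  Voxels outside all ruled ROIs
are bit-identical before and after — whether a vendor implementation also
renormalizes globally is unknown to us, and restricting the edit to ruled
ROIs is the conservative reading.  The default rule set clamps the
esophagus max point dose to 35 Gy and requires 100% of the chest-wall
target to receive 98% of prescription.

## Robust dose mimicking

The objective is a one-sided voxel-wise quadratic: overdose (d > d_ref)
costs `w+ (d − d_ref)²`, underdose costs `w− (d − d_ref)²`, summed over
voxels.  Per-voxel weights come from per-ROI pairs by elementwise maximum
over the ROIs containing the voxel; voxels in an OAR with no target
overlap get `w− = 0` (dose below the reference there is never penalized);
voxels inside the body but in no configured ROI get a default pair.
Two default weight sets ship with the package, and both are calibration
choices (any vendor's clinical values are proprietary and unknown):
reference-dose *generation* uses targets (30, 100), OARs (5, 1),
elsewhere (1.0, 0.1); the *plan-stage* model settings use targets
(30, 100), OARs (8, 1), elsewhere (2.0, 0.2).  The plan-stage pair leans
harder against overdose outside the targets because its reference is a
network prediction rather than an idealized prescription: the predicted
dose already contains the robust margins, so extra dose beyond it is
purely tracking error.  This split mirrors commissioning practice — the
mimicking weights are tuned so delivered plans track the model's
predictions.  The optional dependence of the weights on the predicted dose
level is exposed as a hook but off by default, since its functional form
is not public.

For robust ROIs (the two targets by default) the objective term is the
arithmetic mean over all 21 scenario doses, with the single predicted dose
as the reference in every scenario; all other voxels are scored on the
nominal dose only.  The mean (rather than worst-case) keeps the problem
smooth and matches the composite-objective lineage the workflow descends
from.  The objective is evaluated on Rx-normalized dose so the weights are
dimensionless.

Optimization is projected gradient descent: cold start at zero weights,
Armijo backtracking line search with optimistic step growth, projection
onto w ≥ 0 after each step.  The objective is C¹ (the one-sided quadratics
meet with zero slope), so gradient descent is well behaved; the returned
trace is non-increasing by construction.  The iteration budget is a
configuration value (clinical default 200); the parameter-recovery check
runs longer because projected gradient has a slow linear tail, and
iterations are cheap at that problem size.

## Evaluation

* **DVH metrics**: V-metrics count voxels at or above the level (boundary
  inclusive, matching the ≥ phrasing of the goal definitions); D0.03cc
  interpolates linearly across the partial hottest voxel; ROIs smaller
  than the hotspot volume fall back to the ROI minimum with a warning.
* **Clinical goals**: the standard chest-wall set (V95%(Rx) ≥ 95% for both
  targets, esophagus D0.03cc ≤ 40 Gy, heart mean ≤ 1.25 Gy, lung V20 ≤
  20%, lung mean ≤ 10 Gy, lung V5 ≤ 25%).  The phantom has a single
  combined lung mask, so the ipsilateral and total lung goals both map to
  it by explicit configuration — laterality is anatomical and is never
  inferred from mask geometry.
* **Robustness pass rate**: percent of the 12 evaluation scenarios in
  which each goal is met.
* **Gamma**: 3% local dose difference, 3 mm distance-to-agreement, 10%
  low-dose threshold relative to the reference grid's maximum.  The fast
  implementation visits candidate offsets (lattice step = DTA/10, radius
  capped at 3 × DTA) nearest first and retires a voxel when the distance
  term alone exceeds its current best γ²; an independent brute-force
  implementation with hand-rolled trilinear interpolation scans the full
  lattice and serves as the oracle.  Gamma is asymmetric in
  (reference, evaluated); the reference is always the first argument, and
  in the planning report the postprocessed prediction is the reference and
  the mimicked dose is evaluated.
* **Paired statistics**: two-sided Wilcoxon signed-rank on per-case goal
  values, zero differences dropped; an all-tied comparison is flagged
  degenerate with p = 1.

## Numerical choices and degenerate inputs

Nearest-voxel scenario shifts avoid interpolation ambiguity and are exact
on the default grids.  The influence sparsity cutoff (1e-4 of column max)
bounds memory and is recorded in configuration.  Histogram matching of a
single-voxel sample uses the median rank.  The gamma boundary test γ ≤ 1
carries a 1e-9 absolute tolerance so exact-boundary cases (a uniform 3%
local offset) count as passing.  Empty targets, missing ROIs, all-zero
influence matrices, and missing validation splits raise immediately with
named errors rather than degrading.

## Problem sizes used by the shipped checks

The test suite and the acceptance script run everything at desk scale,
chosen as the natural sizes for the 5 mm phantom lattice: recovery on a
20³ water box with ~64 spots; gamma oracle agreement on twenty random 20³
pairs; single-phantom overfit at 32³; and an end-to-end cohort of three
phantoms (two training, one validation) with the planned case drawn from
the training split.  The full-scale network configuration is built and
counted but never trained.

## Known limitations

* The engine is analytic and noise-free; nothing about Monte Carlo
  statistics, nuclear interactions, or machine deliverability constraints
  transfers from these tests to a clinical system.
* The robust-mimicking scenario aggregation is the mean; worst-case
  composites would change the coverage/conformality trade-off.
* Histogram matching restricted to ruled ROIs may diverge from vendor
  behavior on overlap or global renormalization.
* Desk-scale training shows pipeline coherence, not predictive accuracy;
  headline clinical numbers from the motivating study (patient-cohort
  means, measured QA pass rates) are not reproducible here and are not
  claimed.
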