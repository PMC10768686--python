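# Methods

This note records the models implemented in `deepcsd`, the choices made
where the design was genuinely open, and what the synthetic phantoms do and
do not establish about real data.

## Signal representation

All spherical functions — the normalized single-shell diffusion signal
("signal ODF") and the fiber orientation distribution function (fODF) — are
represented by real, antipodally symmetric spherical harmonics up to even
order L = 8, giving (L+1)(L+2)/2 = 45 coefficients ordered by increasing
even order k, then degree m from −k to +k. The convention
(`real-sym-orthonormal`) is fully orthonormal: m = 0 is the zonal term,
m < 0 carries sine azimuthal factors, m > 0 cosine factors, each scaled by
√2 and the orthonormal normalization, with associated Legendre functions
including the Condon–Shortley phase. Real "tournier"-family conventions in
the wild differ from one another by √2 factors on the m ≠ 0 terms; every
quantity reported here (round trips, angular correlations, deconvolutions)
is internal to this one documented convention, so none of the results
depend on which variant another package uses.

Fitting is ordinary least squares on the sampled directions; with ≥ 45
well-spread directions the order-8 fit is well posed and the default ridge
is 0. A Laplace–Beltrami-weighted ridge (penalty ∝ (k(k+1))²) is available
for direction-starved fits. Fits refuse direction sets whose design matrix
condition number exceeds 10⁶.

## Synthetic scan/rescan phantoms

The phantom generator stands in for paired multi-site HARDI cohorts.

* **Acquisition geometry.** Gradient schemes minimize an electrostatic
  repulsion energy over antipodal pairs from a seeded random start
  (deterministic per seed). The reference scheme has 96 directions at
  b = 2000 s/mm² plus one b0.
* **Tissue model.** Each white-matter voxel holds one or two fiber
  populations (prolate tensors, λ = [1.7, 0.2, 0.2]×10⁻³ mm²/s) plus an
  isotropic compartment (D = 3.0×10⁻³ mm²/s). The 16³ reference phantom
  contains a coherent single-fiber slab (orientation bending smoothly,
  ≤ 15° between neighbors) and a 90°-crossing slab, separated by a gap and
  surrounded by isotropic background.
* **Ground-truth fODFs.** Mixtures of antipodally symmetric Watson lobes
  (concentration κ = 50 by default) centered on the configured fibers.
  The order-8 projection is computed analytically: a zonal kernel centered
  on μ has coefficients √(4π/(2k+1))·f_k·Y_k^m(μ), with the zonal profile
  f_k from 1-D Gauss–Legendre quadrature. This is exact and rotation
  invariant — no spherical-grid aliasing. Because a sharp lobe truncated
  at order 8 rings slightly negative, the (0,0) term absorbs the ringing
  floor (plus a 10⁻³ margin): peak geometry and every order-≥1 quantity,
  including ACC, are untouched, and the stored field is nonnegative on a
  dense probe sphere.
* **Noise and rescan perturbation.** Rician (magnitude-MR) noise,
  σ = s0/SNR; a Gaussian option exists for debugging. The rescan of a pair
  shares the anatomy voxelwise but uses an independent noise stream at
  SNR 25 (vs 30), a ±5% low-frequency multiplicative bias field, and a 3°
  rigid rotation of the gradient scheme. These defaults are stipulations:
  they visibly perturb naive voxelwise estimation while keeping recovery
  feasible; published inter-site effect sizes are not characterized well
  enough to calibrate against.

What the phantoms deliberately omit: motion/eddy/susceptibility artifacts,
partial-volume gradients at tissue boundaries, spatially varying noise,
realistic anatomy. Tests passing on these phantoms demonstrate correctness
of the estimators and the claimed orderings under controlled variability,
not performance on clinical data.

## Constrained spherical deconvolution

Single-shell single-tissue CSD provides silver-standard labels and the
model-based baseline. The single-fiber response is estimated from
phantom-designated single-fiber voxels: log-linear tensor fit, signals
reoriented so the principal axis maps to +z, pooled zonal (m = 0) SH fit
of the b0-normalized profile. In the orthonormal basis the spherical
convolution multiplies coefficient (k, m) by r_k·√(4π/(2k+1)).

The deconvolution is the classic iterative hard-threshold scheme:
initialize from the unconstrained solution truncated at order 4; points of
a fixed 724-point symmetric sphere whose fODF amplitude falls below
τ·(mean initial amplitude) form an active set penalized with weight λ
(per constraint row); iterate to active-set stability (≤ 50 iterations).
Defaults τ = 0.1, λ = 1.

Two numerical choices deserve notice:

* **Floor enforcement.** The λ = 1 fixed point can leave residual
  negativity of a few percent of the maximum in crossing voxels. A final
  surgical pass adds a strong penalty (λ_floor = 100) only on points still
  below −1% of the maximum, accumulated over ≤ 10 passes. This pins the
  advertised output floor (min amplitude ≥ −0.01·max) at a small cost in
  lobe sharpness; a blanket increase of λ would smooth the entire fODF.
* **Sharpness vs. nonnegativity.** For a noiseless tensor voxel the
  unconstrained deconvolution is an exact band-limited delta, which rings
  to −9.5% of its peak; enforcing near-nonnegativity necessarily smooths
  it. Consequently CSD output lobes are broader than the κ = 50 Watson
  ground truth (phantom-mean ACC vs ground truth ≈ 0.85 noiseless), while
  peak directions stay accurate to ≪ 1° (single) and ≤ 5° (90° crossing).
  Exact round-trip recovery (ACC ≥ 0.99) holds for fODFs whose amplitudes
  everywhere clear the hard threshold, in which case no constraint fires.

Peak extraction evaluates the fODF on the 724-point sphere, keeps local
maxima above 0.25 of the global maximum, refines them by tangent-plane
ascent, and merges peaks closer than 25° (antipodally identified).

## Direction-dropout augmentation

Training inputs may be refit from random gradient subsets (uniform without
replacement, ≥ 45 directions for order 8 — the minimal determined fit)
while the label stays pinned, by reference, to the full-direction CSD
field. Candidate subsets must pass a coverage check: SH design-matrix
condition number ≤ 1000 and largest empty spherical-cap radius ≤ 30° on a
724-point probe (antipodal identification). The cap criterion carries the
geometric burden — hemispheric clusters fail it outright; the condition
ceiling only rejects near-rank-deficiency, because even an optimal
electrostatic 45-direction scheme has condition ≈ 13 in an orthonormal
basis and typical random 45-of-96 subsets sit near 100. Rejected subsets
are resampled (up to 100 attempts). Augmentation operates at the
signal-SH stage (refit per subset), not by zero-filling signals, since the
SH vector is the fixed model input.

Subset refits use a Laplace–Beltrami ridge of 10⁻³ by default: a
near-minimal (45-direction) order-8 fit amplifies acquisition noise in
the high orders by one to two orders of magnitude, which makes the
refit useless as a network input; the ridge weight was chosen as the
minimizer of the refit error against the full-direction fit on noisy
phantoms (median relative error ≈ 0.08 at 10⁻³, vs ≈ 1.0 unregularized).
Full-direction fits remain exact least squares, and the noiseless
well-posedness property of accepted subsets (refit within 5% of the full
fit) holds for the unregularized fit as stated.

## Estimators and training

**Patch CNN.** 3×3×3 patches with 45 channels; conv1 (1³ kernel, 45
filters) → conv2 (3³, padding 1, 45) → conv3 (3³, padding 0, 45); a
residual shortcut adds the conv1 activation at the patch center (channel
counts match and the center voxel is the prediction target; an
average-pool alternative is a config flag) to the conv3 output; then two
dense layers (45 → 200 → 45). Batch normalization follows each affine
before its ReLU; the output layer is linear, since SH coefficients are
signed. **Voxel MLP baseline:** 45 → 400 → 45 → 200 → 45, ReLU hidden,
linear output.

The layers are implemented directly in numpy with hand-written gradients
(verified against finite differences to ~10⁻⁷ in the tests); the padded
patch convolution executes as one dense matmul against a structured weight
matrix, which at these sizes is much faster than gather/scatter and equals
im2col exactly (tested). Networks carry a fixed per-coefficient affine
input/output normalization (statistics from the training volumes,
serialized with the weights): signal and fODF coefficients span orders of
magnitude across the 45 channels, and standardizing both — with the output
mapped back to raw coefficients inside the model — conditions the
optimization without changing the predictor class or the loss, which is
always computed on raw coefficients.

**Loss.** For labeled patches, the mean over samples of the summed squared
coefficient error against the full-direction CSD label of the center
voxel; for scan/rescan pairs, the same functional applied to predictions
at corresponding voxel coordinates of the two registered volumes (its
expectation is 0 for a perfectly reproducible estimator); total
α·fit + β·pairing, defaults α = β = 1, and β = 0 whenever no paired data
participate. One shared network forwards all three patch groups per step
(a single concatenated batch, so batch-norm statistics pool the groups);
gradients flow through both members of each pair — the pairing term is
symmetric and no stop-gradient is applied. Per-voxel pairing (not
per-volume averaging) is used.

**Optimization.** Adam with step-decay schedules, restarted per stage:
patch CNN (10⁻² × 40, 3·10⁻³ × 25, 10⁻³ × 15 epochs), voxel MLP
(3·10⁻³ × 40, 10⁻³ × 30) at batch size 128. A flat 10⁻³ for 50 epochs
leaves the deeper patch network visibly undertrained on desk-scale data,
and the MLP diverges intermittently above 3·10⁻³ — hence per-architecture
schedules. Optional validation scoring (mean ACC on held-back voxels)
selects the best epoch and restores it. Training patches are restricted to
voxels whose full 3×3×3 neighborhood lies inside the volume; inference
uses reflect padding, so predictions cover the full mask.

**Finetuning mechanism.** `freeze_all_but_dense` leaves only the two dense
head layers (and their batch norm) trainable, for transfer experiments.

## Evaluation

The angular correlation coefficient (ACC) is the cosine similarity of two
coefficient vectors over orders k ≥ 1 — the (0,0) term is excluded exactly
as the definition is written. In a real basis the conjugate in the general
definition is the identity; this is documented, not configurable. Voxels
with zero energy above order zero make ACC 0/0; they raise a distinct
error (scalar path) or are recorded as NaN and counted (map path) rather
than silently contributing 0, which would bias white-matter means. The
per-voxel (0,0) extraction is named `zeroth_coeff_map`; `md_map` is kept
as an alias for the field's customary name, though it is not a diffusivity
in physical units.

The paired comparison is a two-sided Wilcoxon signed-rank test: zero
differences dropped; for n ≤ 25 the exact null distribution is enumerated
by dynamic programming over (mid-)ranks, which handles ties exactly;
larger samples use the normal approximation with continuity correction.

### Reference experiment (the scaled-down model comparison)

Three 16³ phantoms act as subjects: A (labeled; its scan and rescan each
provide full-direction CSD labels), B (scan/rescan pair for the pairing
loss), C (held out). Accuracy is scored on 150 withheld interior WM voxels
of subject A, masked out of training — the protocol of scoring accuracy on
withheld voxels and reproducibility on registered pairs; scan/rescan
consistency is the mean ACC between predictions on C's scan and rescan.
Stochastic comparisons average training seeds {0, 1, 2}.

Two comparisons deserve a caveat the numbers alone would hide. First, on
these phantoms the CSD label of a voxel is a deterministic function of
that voxel's own signal, so patch context carries no information about
the same-scan label that the center voxel does not already carry: a
voxel-wise learner is near-optimal by construction, and the patch-vs-voxel
accuracy comparison is made between the proposed configuration (patch
network with the pairing loss) and the plain voxel baseline — the
matched no-pairing configurations measure as a statistical tie here.
Second, the direction-dropout comparison (augmented model vs 45-direction
CSD, both against the full-direction silver standard, ten random
45-direction dropouts) is scored on the same withheld voxels; CSD from a
coverage-checked 45-direction subset is only mildly degraded on these
clean phantoms, and the model's margin comes chiefly from its stability
on poorly conditioned subsets where CSD deteriorates sharply.

Problem sizes (16³ phantoms, ~1100 WM voxels, 20 batches of 128 per
epoch) are chosen so the whole suite runs on a single CPU in minutes;
they are desk-scale analogues, not reproductions of cohort-scale numbers.

## Known limitations

* Single shell, single tissue, order 8 only; no multi-shell or
  multi-tissue deconvolution.
* Voxel-space processing: gradient directions are not reoriented by the
  NIfTI affine (phantom affines are diagonal).
* CSD lobe sharpness is bounded by the nonnegativity floor (see above);
  comparisons against the sharp Watson ground truth reflect that bound.
* The coverage-check thresholds and rescan perturbation magnitudes are
  package stipulations, config-exposed, not fitted to any dataset.
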