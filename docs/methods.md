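# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind `slmcompare`. Symbols follow the README: data
`d = L s + n`, inverse operator `G`, estimate `ŝ = G d`.

## Forward model

**Conductor.** Three nested concentric spherical shells with homogeneous
isotropic conductivities; defaults radii (83, 88, 94) mm and conductivities
(0.33, 0.0042, 0.33) S/m for brain, skull and scalp. The potential of a
current dipole in the innermost shell is computed per spherical-harmonic
degree n by solving the small linear system of interface conditions
(potential and radial current continuity, insulating outer boundary) for
the two radial coefficients of every layer. A single layer reproduces the
classical homogeneous-sphere factor (2n+1)/n, and with equal conductivities
the series matches the closed-form homogeneous-sphere solution to better
than 1e-6 relative (tested); the closed form was derived independently by
summing the Legendre generating functions and lives in the test suite as an
oracle, not in the implementation.

**Series truncation.** Default 120 terms. The truncation rule flags any
evaluation whose last term contributes more than 1e-8 of the accumulated
total. With the mesh-fitting rule below, sources sit at 0.95 of the brain
radius, where 120 terms satisfy the bound; shallower truncations (60–100)
do not. The per-degree transfer coefficients are cached per head model.

**Mesh fitting.** Surface source models and spherical conductors disagree
about scale, so source meshes are affinely rescaled so the outermost vertex
sits at 0.95 × brain radius before lead-field computation (configurable;
`fit_to_sphere=False` instead raises on out-of-shell vertices).

**Referencing.** The lead field is average-referenced by default (each
column sums to zero across electrodes), and `apply_inverse` re-references
data the same way before applying an operator built from an
average-referenced lead field. Recording hardware references (e.g., FCz)
and reference-free source models otherwise disagree; the flag is exposed.

**Units.** Positions mm, conductivities S/m, dipole moments nA·m,
potentials µV.

**Montage.** `.sfp`-style files (label x y z) are supported; positions are
normalized and projected to the scalp radius. A deterministic generated cap
(Fibonacci spiral over the upper ~120° of the sphere, E001…) stands in for
an extended 10-20 high-density layout so nothing needs to be downloaded.

## Inverse methods

All three methods share `G = C_s Lᵀ (L C_s Lᵀ + α C_n)⁻¹`, solved through a
symmetric eigendecomposition with an eigenvalue floor of 1e-12 × the largest
eigenvalue (flagged, not silent).

**Depth weighting.** w_p = (Σ_{i∈I_p} ‖l_i‖²)^(−γ), γ = 0.5, with weights
above 10 × min(w) clipped so the dynamic range never exceeds the limit of
10. The weights enter as the source prior variance, C_s = diag(w_p) per
component triple — deep sources (weak columns) get larger prior variance,
which is what compensates the superficial bias of the plain minimum norm
and is equivalent to approximately normalizing the effective lead-field
columns. (Writing the same quantity as a penalty matrix W with
C_s = (WᵀW)⁻¹ requires W = diag(w_p^(−1/2)); texts differ on which symbol
carries the exponent, so the package fixes the convention here.) Depth
weighting applies to wMNE and dSPM; sLORETA standardizes the *unweighted*
MNE operator.

**Noise covariance.** Population sample covariance of concatenated
resting-condition data, then scale-aware Tikhonov loading
C ← C + ε·(tr C / N_e)·I with ε = 0.1. The trace-relative form keeps the
loading invariant under unit changes.

**Regularization parameter.** α is selected per method and per training
fold by generalized cross-validation on the whitened, prior-weighted
system: with K = C_n^(−1/2) L C_s^(1/2) and H(α) = K Kᵀ(K Kᵀ + α I)⁻¹,
GCV(α) = ‖(I − H) d̃‖²_F / tr(I − H)², evaluated exactly through one SVD of
K over a default grid of 40 log-spaced points in [1e-6, 1e2]. The data d̃
are the training movement-preparation samples at −0.05 s. If the grid
minimizer falls below 0.01 (which happens for noiseless, consistent data,
where GCV keeps decreasing), the fixed default α = 1/3 is used instead.

**dSPM.** s_p = (Σ_{i∈I_p} g_i C_n g_iᵀ)^(−1/2) applied as a diagonal
scaling of the base (w)MNE operator — after it, the estimated noise
variance at every source point is exactly 1, and row directions are
unchanged (both tested).

**sLORETA.** Each 3×3 diagonal block of A = G L is symmetrized, checked
positive definite (eigenvalues above 1e-12 × the mean block trace, else an
error naming the vertex) and inverted through its eigendecomposition square
root. The defining property — zero localization error for a noiseless
single dipole — is verified over 60 random source vertices in the
acceptance suite.

## Cluster-based plausibility metric

**Selection.** round(0.05 · N_s) vertices of largest amplitude norm
(‖(x,y,z)‖ per vertex), ties at the cutoff resolved toward lower vertex
indices.

**Clustering.** DBSCAN on the 3-D vertex coordinates, Euclidean metric, run
independently per hemisphere so midline-adjacent activity never merges
across hemispheres. eps is the 95 %-quantile of mesh edge lengths and the
core threshold the 95 %-quantile of vertex degrees (linear-interpolation
quantiles; the threshold rounded half-up) — i.e., adjacent vertices should
cluster together. Euclidean rather than geodesic distance is used because
eps derives from Euclidean edge lengths. Cluster centers are
activation-weighted centers of mass.

**Distance.** A COM scores 0 if the mesh vertex nearest to it belongs to
the reference region (so slightly off-surface COMs above the region count
as hits, and exact-hit results are representable); otherwise the minimum
Euclidean distance to any region vertex. The smallest COM distance over all
clusters is reported together with N_c.

**Random baseline and normalization.** For each N_c, surrogate COMs are
drawn uniformly without replacement from the source-space vertices
(20 000 draws per N_c by default, seeded and recorded; max N_c = 15) and
the mean minimum distance recorded; d_r(N_c) = a·N_c^b is fitted by OLS on
the log-log means and extrapolates beyond the fitted range. The surrogate
scheme — vertices standing in for COMs — is the simplest one consistent
with treating the baseline as a function of cluster count alone; it is a
modeling choice. The cluster variant of the metric normalizes by the
*fitted* d_r(N_c); the maximum-activity variant normalizes by the
*empirical* one-cluster mean, mirroring the two different constants such
analyses print.

A calibration property follows by construction: random source
distributions scored through the normalization have mean d_n = 1 per N_c.
Two caveats documented deliberately: (i) the power law is an approximation
— on every mesh we fitted, log-log residuals are 2–5 %, so the *fitted*
denominator deviates from the *empirical* mean by more than the sampling
error of large draws (visible in the coexistence of a fitted one-cluster
value and a slightly different empirical one-cluster mean); the
self-consistency test therefore compares mean d_n to 1 within three
standard errors that propagate both the sampling error of the numerator
and the OLS prediction uncertainty of the fitted denominator
(`BaselineFit.prediction_se`). With sampling-only errors the check would
fail on any mesh, for the model-misfit reason above, not for an
implementation reason. (ii) Trials whose selection yields no cluster at all
(all points noise) are reported as missing and counted, never imputed.

**Statistics.** Pairwise Wilcoxon signed-rank tests on paired per-trial
distances, Holm step-down correction across the three method pairs;
all-zero difference vectors are reported as p = 1 with a degenerate flag.

## Classification pipeline

**Preprocessing.** Two-stage FIR anti-alias decimation (recording rate →
100 Hz → 20 Hz), the second stage low-passing at 4 Hz — the slow
pre-movement negativity lives below that — followed by a second-order
zero-phase Butterworth high-pass at 0.2 Hz to remove drift and offsets.
Measured on tones: 1 Hz passes within 5 %, 8 Hz is attenuated by more than
20 dB, a DC offset is removed to below 1 %. The 0.2 Hz corner was chosen
over a lower one because zero-phase filtering at 0.05–0.1 Hz has settling
transients longer than any desk-scale recording; 0.2 Hz leaves the
0.25–4 Hz band of the target potential essentially untouched.

**Movement onset.** Motion-tracking speed per sampling interval, scanned
backwards from the switch-release event; onset is the earliest sample of
the contiguous bout strictly exceeding 0.075 mm/ms (a speed exactly at the
threshold does not count as moving).

**Segmentation.** Per trial: five 0.2 s (4-sample) resting segments tiling
[−3, −2] s before onset and one movement-preparation segment ending at
−0.05 s — a fixed 1:5 class ratio. Trials with onsets earlier than 3 s into
a recording are skipped with a logged warning.

**Features.** The inverse operator of the fold is applied to all training
movement segments; vertices are ranked by mean amplitude norm (mean over
segments and time points — the ranking statistic had to be fixed here, and
the mean is the least trial-dominated choice) and the top
round(0.05 · N_s) kept. Features are the raw source components, vertex-
major × component × time (750 × 3 × 4 = 9 000 on a 15 002-vertex space),
standardized per feature on training data; columns with standard deviation
below 1e-12 are zeroed after centering.

**Classifier.** Linear soft-margin SVM (LIBSVM-style cost parameter), the
under-represented movement class weighted 2. The cost λ is selected from
{1e-6 … 1e0} (seven log-spaced values) by a seeded, stratified 2×5-fold
inner cross-validation maximizing balanced accuracy; the decision threshold
is then tuned on training data by sweeping midpoints of sorted decision
values (ties toward the smallest threshold). Outer evaluation is 3-fold by
experimental run; nothing fitted ever sees the held-out run (verified by a
scramble-the-test-run invariance test).

## Synthetic data

The generator produces the statistical structure the analysis assumes, not
a biophysical MRCP model: a half-cosine negative ramp from 0 at −2 s to
−peak at onset (held briefly through execution) at configured vertices;
per-trial background sources at uniformly random vertices with 1/f-shaped
unit-RMS time courses; white Gaussian sensor noise. Defaults: 40 trials per
run × 3 runs (a typical session's 120 trials), 20 Hz analysis rate
(recordings can be generated at 5 kHz to exercise the decimation chain, but
pipeline tests generate directly at 20 Hz for speed), peak 60 nA·m,
3 background sources at 10 nA·m RMS, 1 µV sensor noise — amplitudes sized
so the single-trial scalp signal is a few µV against µV-scale noise, i.e.,
detectable but not trivial. Kinematics: stationary, then a straight ~200 mm
reach with a trapezoidal speed profile whose 10 ms ramp makes the
interval-averaged speed cross the 0.075 mm/ms detection threshold within
one 2 ms tracking sample of the nominal onset.

What passing tests on these data do **not** show: robustness to real-EEG
nuisance structure (eye blinks, EMG, electrode drift, spatially correlated
noise beyond the optional mixing), realistic cortical folding (fixture
spaces are spheres; depth weighting is exercised only mildly because all
fixture vertices are equidistant from the sensors), or template-specific
constants that depend on a particular cortical tessellation.

## Problem sizes and numerical conventions

Tests and the acceptance script run on icosphere fixtures (162 or 642
vertices, 32 electrodes, 6–40 trials per run) — sizes chosen so the full
suite completes in about a minute while every code path, including nested
CV and GCV, is the real one. Nearest-vertex and top-k ties break toward the
lowest vertex index everywhere. Quantiles interpolate linearly; the DBSCAN
core threshold rounds half-up. All matrix inversions go through symmetric
eigendecompositions with a relative floor of 1e-12. Every stochastic
component takes an explicit seed and records it in its output.

## Known limitations

- Spherical conductor only; no BEM/FEM, no MEG.
- Geodesic distances are not implemented; all metric distances are
  Euclidean in 3-D.
- The random-baseline surrogate (vertices as COMs) is one of several
  defensible schemes; the normalization constant changes by a few percent
  under alternatives (e.g., clustering random activations first).
- `N_c = 0` trials are excluded from distance averages (with a count);
  under extreme settings this can bias method comparisons.
- The classifier grid and inner-CV layout are fixed, not adaptive; at very
  small trial counts the threshold tuning adds variance (visible as ±0.05
  spread of the null balanced accuracy).
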