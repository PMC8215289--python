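# Methods

This note documents the statistical model behind `permconnect`, the
assumptions each stage makes, the defaults and why they were chosen, and what
the synthetic cohort generator does and does not emulate.

## Data model

A cohort contains three groups — controls, TIA (no MRI-confirmed infarct) and
minor stroke (confirmed infarct) — with default sizes 20/25/17. Each subject
carries a 4D BOLD volume (default 160 volumes at TR = 3.12 s), T×6 motion
parameters (translations in mm, rotations in radians), an ICA-like component
set (spatial z-maps, time courses, motion flags), a phenotype record (age,
vascular-risk-factor count, cognitive scores), and — for stroke subjects
only — a binary lesion mask. Volumes, masks and atlas maps are NIfTI-1 with a
RAS+ affine; tables are TSV.

## Quality control

Framewise displacement follows the Power convention:
FD₁ = 0, FD_t = Σ|Δtranslation| + 50 mm × Σ|Δrotation|, with rotations
converted to arc length at a 50 mm head radius. A run is excluded when its
**mean** FD strictly exceeds 0.5 mm. The mean (rather than maximum) summary
matches common preprocessing reports; the maximum is recorded in the QC table
alongside it so either rule can be audited. The boundary is exclusive: a run
at exactly 0.5 mm is kept.

## Cleaning chain

The order is fixed and logged: nuisance OLS regression → per-voxel z-scoring
→ Gaussian smoothing → probabilistic parcellation.

* **Nuisance design.** Motion-component time courses, the CSF series,
  lesion-flagged component time courses (see below) and a discrete-cosine
  high-pass basis, plus an explicit intercept. DCT-II component k has
  frequency k/(2·T·TR); all components strictly below 1/128 s⁻¹
  (0.0078 Hz) are included — 7 regressors at T = 160, TR = 3.12 s. Columns
  are unit-normalized and the constant term handled by the intercept, which
  keeps the design well-conditioned. Exactly collinear columns are pruned
  greedily in input order (deterministic and order-stable) with a logged
  warning. Lesion-flagged component series enter this single one-pass OLS
  design together with all other regressors.
* **z-scoring** uses the population (divide-by-T) standard deviation; the
  convention is fixed so exact-value tests are well-defined. Zero-variance
  series map to zeros with a warning instead of NaN.
* **Smoothing** is a separable Gaussian per frame with
  σ = FWHM/(2√(2 ln 2)) — 2.548 mm at the default 6 mm FWHM. Outside-mask
  values are zero-padded and the result renormalized by the smoothed mask, so
  signal does not bleed across the brain boundary.
* **Parcellation** takes the probabilistic-map-weighted mean of voxel series,
  weights normalized to sum to one within the brain mask, node order fixed by
  the atlas label table. An atlas map with no in-mask weight is an error
  naming the node.

## Lesion-artifact flagging

Component spatial z-maps are binarized at the two-sided Normal quantile
(|z| ≥ 1.95996 for α = 0.05; ICA maps are signed, hence two-sided by default,
with a one-sided mode available). A component is lesion-flagged when the
Jaccard index between its binary map and the lesion mask is ≥ 0.05 — the
boundary is inclusive — and its time course is added to the nuisance design
unless the component is already motion-flagged (motion components are in the
design regardless and are not re-added). TIA subjects and controls have no
mask; flagging is then a warned no-op.

## Connectivity

Partial correlations come from the inverse sample covariance,
ρ̂ᵢⱼ = −Ωᵢⱼ/√(Ωᵢᵢ Ωⱼⱼ). With T = 160 ≫ N = 11 the empirical covariance is
comfortably invertible, so plain inversion is the default; a Ledoit–Wolf
shrinkage mode exists for ill-conditioned inputs (T ≤ N is rejected with
instructions to enable it). Edges are vectorized in a single canonical order
— upper triangle, row-major over the atlas node order — and labelled
DMN↔DMN (6 edges), FPN↔FPN (21) or FPN↔DMN (28). The parcellation has 11
nodes: 4 DMN (frontal, medial, left, right) and 7 FPN (left/right
dorsolateral prefrontal, left/right parietal, left/right frontal pole, right
posterior temporal); the node list is configuration, not hard-coded into the
estimator.

## Inference

**Group contrasts.** The edge statistic is the pooled-variance two-sample t
(sign = mean A − mean B). The choice between pooled and Welch variants is
calibration-neutral here because inference is by permutation
under exchangeability; pooled is used for its exact F = t² relationship with
the ANOVA. maxT correction applies the *same* label permutation to all edges
(enforced by construction: one permutation matrix drives the whole edge
matrix) and records max|t| per permutation in a single null; corrected
p-values use the add-one convention (1 + count)/(B + 1), so p ∈ [1/(B+1), 1]
and never 0. When C(n, n_A) ≤ B all label splits are enumerated exactly and
the p-value is the exact proportion (the identity split makes it positive).
Exceedance comparisons carry a 10⁻⁸ relative tolerance so floating-point ties
(e.g. the complementary split, whose |t| is identical in real arithmetic) are
counted.

**Huber regression.** Confound residualization and the interaction model use
robust M-estimation with the Huber loss (quadratic within ε·σ, linear
beyond; ε = 1.35), a ridge penalty α = 10⁻³ on non-intercept coefficients,
convergence tolerance 10⁻⁵, and jointly estimated scale σ via the
concomitant-scale fixed point σ² = mean(min(r², (εσ)²)). The solver is
iteratively reweighted least squares, implemented natively and vectorized
across response columns: one batched (p+1)×(p+1) solve per iteration refits
thousands of permuted responses at once, which is what makes
permutation-based regression inference affordable (~10⁵ refits per
calibration run). Late iterations average consecutive steps to break
two-cycles between weight assignments; fits that still fail the tolerance
return with a convergence flag and a warning. Unit tests pin the solver to
scikit-learn's `HuberRegressor` (same parameterization) on clean and
outlier-contaminated data.

**Manly permutation.** Interaction inference permutes the *raw response
vector* wholesale (unrestricted sampling) and refits the full model per
permutation — not Freedman–Lane residual permutation — and each coefficient
is referred to its own two-sided permutation null with the add-one
convention. No multiple-comparison correction is applied to these
regressions by design. The optional 95% CI on the interaction coefficient is
a percentile bootstrap and is an extension, not part of the permutation test.

**Corrected model.** Both the cognitive score and the edge values are
Huber-residualized on age and vascular-risk-factor count before testing; the
group term itself is never residualized.

## Synthetic cohort generator

The generator emulates the *structure* of the study data, with every
generative parameter known:

* Node signals are i.i.d. rows from N(0, Ω_g⁻¹) per group, so true partial
  correlations are known in closed form. Default group precisions plant
  modest within-network coupling (partial ρ = 0.12), weak between-network
  coupling (0.03), and three group effects of +0.20: one FPN↔DMN edge
  (patients vs controls) and one intra-DMN plus one intra-FPN edge (stroke
  vs TIA) — the contrast pattern the inference stage is meant to detect.
* Volumes mix node signals through Gaussian-blob probabilistic atlas maps at
  fixed lattice centers, plus nuisance mixtures and white noise. Nuisance
  spatial loadings are structured (axis gradients for motion, a corner blob
  for CSF, uniform for drift) to mimic real ICA maps; after per-map
  z-scoring the uniform map is inert and gradients rarely cross the
  threshold, so only lesion-supported components can overlap a mask.
* Stroke subjects get a compact ~20-voxel lesion at a random interior site
  and an injected artifact component whose binary support is a subset of the
  mask with a configurable Jaccard overlap (default 0.30), recorded as
  ground truth.
* Ages are Normal(70, 9) truncated to [45, 90]; vascular-risk-factor counts
  are Poisson with group-dependent means 0.6/1.0/1.8 (control/TIA/stroke)
  plus a mild age slope — reproducing the confounding the corrected model
  must remove.
* Cognitive scores follow
  b₀ + b₁·edge + b₂·group + b₃·edge·group + slopes·(age, VRF) + noise, where
  "edge" is the subject's *realized* partial correlation on a designated node
  pair. The default executive-speed score carries a moderate interaction
  that is realistically underpowered at n = 42; power experiments use
  explicit stronger configurations.

Determinism: one master seed drives a `SeedSequence` tree; identical
(spec, seed) reproduces every array bit-exactly.

What the generator does **not** emulate: anatomical images, registration,
slice timing, physiological noise spectra, spatial autocorrelation of real
BOLD, hemodynamic lag, or lesion-induced signal delay. Passing tests
demonstrate correctness of the statistical machinery under the generative
model, not robustness to those real-data complications.

## Numerical choices and problem sizes

* Recovery benchmark: estimator-recovery checks use a dense sign-mixed
  precision Ω = 0.3 I + 0.7 ssᵀ (alternating signs s), which puts |partial
  ρ| = 0.7 on every edge. At T = 2000 each estimate's sampling sd is then
  ≈ (1 − ρ²)/√T ≈ 0.011, so a 0.05 max-error bound over 55 edges probes
  implementation correctness. With a mostly-null matrix the same bound would
  sit *below* the noise floor (per-edge sd ≈ 0.022, expected max ≈ 0.056)
  and would fail for a correct estimator; dense signal is therefore the
  appropriate benchmark condition.
* Familywise-error calibration uses 500 global-null replicates of a
  20-vs-42 cohort at B = 1000; Manly calibration uses 200 null replicates at
  B = 500 and power uses 200 replicates (the Monte-Carlo sd at the measured
  power ≈ 0.87 is 0.023, keeping the estimate well clear of the 0.8
  detection-rate threshold for a calibrated implementation).
* Huber/OLS agreement is asymptotic; it is asserted at n = 20,000 where the
  O(1/√n) coefficient gap is safely below the 1% residual-RMS bound.
* Degenerate inputs: zero pooled variance gives t = 0 with a warning;
  constant series z-score to zeros; an empty lesion mask is a warned no-op;
  a constant edge vector makes the interaction model ill-posed and is
  rejected; both-empty masks have Jaccard 0 by convention.

## Known limitations

* The ANCOVA uses a single-factor Type-III-style comparison (full vs
  group-dropped model); it does not implement factorial designs.
* The bootstrap CI on interaction coefficients is percentile-only.
* No parametric multiple-testing alternatives (FDR/Bonferroni), no
  graph-theory metrics, no voxelwise inference — edge-level statistics only.
* Real acquisitions deviate from the generator's assumptions (see above);
  calibration results transfer only insofar as exchangeability holds.
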