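# Methods

`voxdose` implements a voxel-based (VB) dose–morbidity analysis for
radiotherapy cohorts, together with a synthetic head-and-neck cohort
generator that provides known ground truth for every stage. This note
records the models, the parameters that matter, and the numerical choices
behind the implementation.

## The analysis model

The clinical question is whether patients who develop a toxicity (here: a
severe radiation-induced acute dysphagia-like binary outcome) received
systematically more dose in some *subregion* of the swallowing apparatus,
without committing in advance to an organ-based partition.

1. **Inter-patient normalisation.** Each patient's planning image is
   registered to a reference anatomy (common coordinate system, CCS) with a
   masked, multi-resolution log-diffeomorphic demons algorithm. The
   transform is the exponential of a stationary velocity field `v`, computed
   by scaling and squaring, so the inverse `exp(-v)` always exists — the
   property needed to push regions back into a new patient's planning space.
   The registration mask is the body contour intersected with a 30 mm
   spherical dilation of the union of oral cavity, larynx and esophagus.
   Dose maps are pulled into the CCS through `exp(v)` with trilinear
   interpolation (masks through the same warp, thresholded at 0.5).
2. **Registration quality.** Pre/post scores per patient and structure:
   Dice `2|A∩B|/(|A|+|B|)`, modified Hausdorff distance (the maximum of the
   two mean directed distances between 6-connectivity boundary voxels, in
   mm), and dose–organ overlap (DOO), a dose-weighted Dice
   `2·Σ_{A∩B} d / (Σ_A d + Σ_B d)` computed with the warped patient dose as
   the single weighting volume. Paired pre/post changes are tested with a
   Wilcoxon signed-rank test (exact enumeration with mid-ranked ties up to
   n = 15 non-zero differences, tie-corrected normal approximation with
   continuity beyond).
3. **Gatekeeping test.** Per ROI voxel, the normalized dose difference is
   the two-sample pooled-variance t statistic between outcome groups
   (zero-variance voxels are assigned 0; they carry no evidence). The
   global test statistic `T_max` is its maximum over the ROI; its null
   distribution comes from relabeling patients (group sizes preserved),
   with exhaustive enumeration whenever the number of distinct relabelings
   does not exceed the requested permutation count. One-sided alternative:
   more dose in the toxicity group.
4. **TFCE significance mapping.** The statistic map is transformed by
   threshold-free cluster enhancement, `TFCE(v) = ∫ e(h,v)^E h^H dh`, where
   `e(h,v)` is the extent (physical volume by default) of the connected
   component of `{t ≥ h}` containing `v` (26-connectivity). Familywise
   corrected p-values compare each voxel's observed TFCE value with the
   permutation distribution of the ROI-wide TFCE maximum.
5. **Subregions and their readout.** `S_p = {v : p(v) ≤ p}` forms a nested
   family over a logarithmic grid of levels (0.001–1, 30 points, 0.05 always
   included). Per-patient mean doses on `S_0.05` feed a Mann–Whitney U test
   and a ROC analysis (AUC via the rank identity, ties ½; 95% CI by
   stratified percentile bootstrap over patients); the Mann–Whitney p-value
   as a function of the level p is the `p_U(p)` curve, whose minimum
   indicates the most discriminative level.
6. **Planning constraint.** If a Kolmogorov–Smirnov test against a normal
   fitted to the toxicity-group mean doses does not reject (p > 0.05), the
   mean-dose bound is the parametric first percentile
   `mean + sd · probit(0.01)` (sample sd, n−1); otherwise the empirical
   percentile is used with a warning. The significant region is back-warped
   into a patient's planning space with `exp(-v)` of that patient's
   registration velocity, and plans are evaluated by the region's mean dose
   and cumulative DVH `V(d)` (bin width 0.1 Gy).

## The synthetic cohort

The generator emulates the statistical structure the analysis assumes, not
clinical imaging realism.

* **Template anatomy** on a 96×96×120 grid at 2 mm (any grid ≥ 32³ scales
  the same normalised geometry): elliptical body, vertebral column with
  periodic bone/disc alternation, oral cavity, larynx and esophagus with
  air lumina, three pharyngeal constrictors, cricopharyngeus and cervical
  esophagus along the posterior pharyngeal wall. Intensities are three
  HU-like levels (air −1000, soft tissue 40, bone 700) blurred by 1.5 mm.
  The vertebral periodicity matters: without inferior–superior contrast the
  z-component of any deformation would be unobservable inside the mask
  (aperture problem) and registration recovery could not be tested.
* **Ground-truth effect region**: the intersection of a ~13 mm sphere at the
  cricopharyngeus / cervical-esophagus junction with those two structures
  (≈ 7.6 cm³ at the default grid).
* **Per-patient deformations**: white Gaussian vector noise smoothed with a
  12 mm kernel and scaled to a 15 mm maximum displacement (≈ 2.5–3.5 mm mean
  displacement in the swallowing ROI, giving pre-registration organ Dice
  ≈ 0.8, a realistic inter-patient mismatch). Fields whose exponential
  folds (min Jacobian determinant ≤ 0.05) are resampled up to 5 times.
  Patient = template pulled back through `exp(v_true)`; the velocity is
  retained so tests and validation runs can warp doses with the truth.
* **Dose model**: a broad Gaussian bell centred near the pharynx with peak
  ≈ 70 Gy (the prescription scale), per-patient jitter of centre (6 mm sd),
  widths (10% lognormal) and output (3%), plus smooth zero-mean noise
  (8 mm correlation, 3 Gy sd), clipped at 0. Toxicity cases additionally
  receive a uniform `effect_size` inside the patient-space image of the
  sensitive region. The default effect of 6 Gy was chosen once so that the
  mean dose over the sensitive region discriminates cases at AUC ≈ 0.75–0.87
  — informative but not trivial; recovery experiments use a stronger 12 Gy
  planted effect. Outcomes are either deterministic (exactly `n_cases`
  cases receive the effect) or logistic in the sensitive-region mean dose
  (no planted effect; used for calibration studies).
* **What the phantom does not model**: realistic beam/arc physics, CT
  texture and artefacts, contouring variability, or anatomy-correlated dose
  shaping. Passing the recovery tests therefore shows the *pipeline* is
  correct and calibrated under its own assumptions, not that the clinical
  effect sizes or score values would be reproduced on real cohorts.

## Numerical choices

* **Velocity exponential**: scaling and squaring with the number of
  squarings chosen so the scaled field's maximum displacement is ≤ 0.5
  voxel; composition uses trilinear, edge-clamped lookups. The inverse
  consistency `exp(v) ∘ exp(-v)` is held under 0.1 voxel mean displacement
  for all generated fields.
* **Demons defaults**: 3 levels (×4, ×2, ×1), 50/50/30 iterations, fluid
  smoothing 2 mm, diffusion smoothing 1.5 mm, symmetric (average-gradient)
  force with denominator floored at 10⁻⁶ of the squared intensity range,
  per-iteration step capped at 0.5 voxel. Two deliberate deviations from
  textbook settings: smoothing kernels are floored at one voxel at each
  pyramid level (a mm-specified sigma is sub-voxel at coarse levels and
  regularises nothing), and the 0.5-voxel step cap replaces a 1-voxel cap
  that made coarse levels overshoot and oscillate. Intensities are jointly
  rescaled to [0, 1] over the 1st–99th percentile range before iteration.
  The first-order log-composition (`v ← v + u`) is a documented
  approximation, adequate at these step sizes.
* **TFCE integration**: the default integrates *exactly* over the sublevel
  structure of the map — voxels are processed in descending order with a
  union-find over components, and each interval between consecutive values
  contributes `e^E · Δ(h^{H+1})/(H+1)` in closed form. This removes the
  O(dh) bias of stepped integration (≈ 1.5% at the map maximum for H = 2
  with 100 steps) and is fast enough to run inside the permutation loop
  (numba kernel). A stepped mode (`n_steps`, midpoint extent evaluation,
  exact truncation of the h-integral at each voxel's value) is retained for
  step-size studies; with 100 steps it agrees with fine integration to a
  few percent. Exponents default to E = 0.5, H = 2 (the neuroimaging
  convention), extent in mm³, 26-connectivity.
* **Permutation p-values**: add-one estimator `(1 + #{null ≥ obs})/(1 + N)`
  for Monte Carlo nulls (so p is never 0 and never below `1/(N+1)`), plain
  counting for exhaustive enumeration. The TFCE null and observed maps use
  the same exact transform, so the corrected p-values are internally
  consistent.
* **Mann–Whitney / Wilcoxon**: exact enumeration only in the regimes where
  it is both feasible and well-defined (Mann–Whitney: n₁+n₂ ≤ 12 without
  ties; Wilcoxon: ≤ 15 non-zero differences, mid-ranked ties enumerated
  explicitly); otherwise tie-corrected normal approximations with
  continuity. Fully tied degenerate samples return p = 1.
* **KS Gaussianity gate**: the plain one-sample KS test against the normal
  fitted to the sample, as the constraint derivation prescribes. With
  estimated parameters this is anti-conservative (it under-rejects; a
  Lilliefors correction would be stricter) — acceptable here because the
  gate's failure mode is falling back to the empirical percentile.
* **Degenerate inputs**: empty masks, empty outcome groups, zero variance
  and non-finite fields raise; empty subregion family members are skipped
  and recorded; a registration level whose masked SSD rises monotonically
  emits a divergence warning and keeps the best iterate.

## Problem sizes used in the validation suite

Chosen as the package's own desk-scale study sizes: type-I calibration uses
500 undeformed null cohorts of 16 patients at 32³ with 500 permutations
(deformations do not affect permutation exchangeability, so omitting them
isolates the inference machinery); planted-region recovery uses one
40-patient cohort at the default 96×96×120 @ 2 mm grid with a 12 Gy effect,
doses mapped to the CCS by the retained ground-truth deformations (the
registration stage has its own dedicated recovery experiment of 10 deformed
patients plus pure-translation cases at 48×48×64). The acceptance script
runs the complete pipeline — including real registration of all 42 patients
— on a 48×48×64 grid spanning the template's full 192×192×240 mm extent.

## Known limitations

* Axis-aligned NIfTI grids only; no DICOM RT-STRUCT/RT-PLAN handling.
* First-order log-domain composition (no BCH correction).
* One-sided (dose higher in cases) voxel statistics by default.
* The DOO weighting uses a single dose volume for both masks; a two-volume
  variant would need a second convention for the unwarped mask.
* No covariate adjustment of the voxel model, and no FDR-style alternatives
  to the max-statistic familywise correction.
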