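# Methods

This note records the measurement conventions, the generative model behind
the synthetic cohorts, the statistical machinery, and the design decisions
taken where the underlying study protocol left the choice open. It states
no empirical result beyond what the test suite and `scripts/acceptance.py`
themselves compute.

## Per-scan SN measurements

A scan is a 3-D NM-sensitive image (slice axis inferior → superior, slice 0
most caudal; voxels 0.4 × 0.4 × 3 mm³ by default) with two disjoint ROI
masks: the SN (both sides pooled into one voxel set, matching single
per-subject reporting) and a background region covering the tegmentum,
required to be nonempty on every SN-bearing slice.

* **Slice selection.** The SN is "visible" on a slice when the mask has at
  least `min_voxels` voxels there (default 1; the protocol does not define
  visibility). The measurement window is the most inferior run of 3
  contiguous visible slices; if none exists the scan is excluded with an
  error naming the longest available run. Selection is repeated
  independently per visit and per rater.
* **Vol** = voxel count on those 3 slices × voxel volume (mm³).
* **C_vol** = Vol / TIV with TIV in cm³. Units are mm³/cm³ deliberately:
  with Vol ≈ 273 mm³ and TIV ≈ 1.44 L this gives the conventional ≈ 0.19
  scale rather than the dimensionless ≈ 1.9 × 10⁻⁴.
* **SNR** = mean over the 3 slices of (mean SN intensity / mean background
  intensity) × 100. **CNR** = mean over slices of (SN − background mean) /
  background SD. The background SD uses the sample (n−1) estimator by
  default (`ddof` configurable). CNR is refused on a noiseless background.
* **Percent differences.** Vol, C_vol and CNR changes are ratios to the
  reference value. SNR changes are referenced to the contrast above the
  background pedestal, (a − b)/(b − 100) × 100, because SNR = 100 carries
  no NM signal at all; a raw-ratio change of a quantity pinned near 100
  would understate contrast loss by an order of magnitude. The same
  referencing is used for SNR annual rates (a raw-ratio option is exposed
  via the measure-kind argument).
* **Annual rates.** Per subject: percent change between visits divided by
  the inter-visit delay in years; the cohort value is the mean of
  per-subject rates (not a ratio of group means). Subjects missing a visit
  are excluded and counted.

## Synthetic phantoms

Each phantom is Gaussian background noise N(bnd_mean, bnd_sd²) on a
scaled-down grid (default 96 × 96 × 12 at the native voxel size — the full
clinical field of view would only add empty voxels and test time), with two
ellipsoidal SN blobs whose mean intensity is bnd_mean × SNR_target/100, and
a fixed rectangular background ROI dorsal to them, disjoint by
construction. Blob voxels are chosen by ranking candidates on the
ellipsoidal quadratic form and keeping exactly round(V_target/voxel volume)
per side, so the noiseless volume is correct within one voxel volume by
construction and the mask spans exactly `n_sn_slices` contiguous slices.
Gaussian (not Rician) intensity noise is used: at background SNR ≈ 13 the
magnitude-MRI Rician distribution is indistinguishable from Gaussian for
these purposes, and Gaussianity keeps every estimator analytic. The single
noise knob `bnd_sd` also sets the rendered CNR
(= bnd_mean·(SNR−100)/100 / bnd_sd).

Simulated raters toggle boundary voxels of the SN mask with probability
`boundary_shift_prob`. The boundary is restricted to the in-plane contour
of each slice: raters trace slice by slice, so disagreement is about the
contour, not about conjuring SN on new slices (a 3-D dilation would shift
the 3-lowest-slice window and is not a plausible rater error). The default
probability 0.5 makes the expected Dice ≈ 0.84, inside the 0.82–0.85 range
reported for trained human raters.

## Synthetic cohorts

`CohortDesign` encodes one study cohort; the defaults are the early-PD
cohort, with a `progressing_pd()` preset for the advanced cohort. Per
subject:

* Sex (PD ≈ 2:1 male, HV majority female), age ≈ N(61, 9²) yr, TIV ≈
  N(1438, 120²) cm³ with a ±55 cm³ sex offset (men larger).
* Baseline Vol ~ N(273.2, 48.4²) mm³ for HV, shifted down by the group
  deficit fraction for PD (11.2% early, 38.4% progressing). SNR deficits
  act on (SNR − 100) (17.4% / 21.4%); CNR deficits on the CNR itself.
  C_vol is *derived* as Vol/TIV, so the female C_vol advantage and the
  amplified C_vol group deficit emerge from the TIV sex offset and the sex
  imbalance rather than being drawn independently of Vol.
* Follow-up after ≈ N(2.0, 0.2²) yr (2.4 ± 0.5 progressing). Each subject
  carries a personal annualized rate N(programmed mean, rate_sd²) per
  measure; programmed means are −5.8 (Vol), +1.5 (SNR contrast), +1.9
  (CNR) %/yr for early PD, −10.2/−3.7/−3.0 for progressing PD, and
  +0.4/+0.8/+3.9 for healthy volunteers. C_vol shares Vol's rate (TIV held
  fixed across visits). The per-subject rate SDs (4.1, 2.2, 2.6 %/yr for
  Vol, SNR, CNR; 4.0 for C_vol-scale analyses) are back-calculated from the
  published trial-size grid by inverting the two-arm normal formula at the
  printed n — the only route available, since per-subject change SDs are
  not reported.
* MDS-UPDRS-III OFF is drawn by the bivariate-normal construction so its
  within-group correlation with baseline C_vol equals `clinical_corr_rho`
  (default −0.4); it progresses by ≈ 1.65 points/yr. Disease duration, H&Y
  and LEDD are drawn at their cohort means; LEDD is independent of all
  imaging measures (no correlation was observed) and held constant across
  visits, as nothing downstream consumes it.
* Dropout removes each subject's V2 row with probability `dropout_frac`
  (0.20 early ≈ 79/99 retained; 0.268 progressing); the progressing
  cohort's healthy volunteers have no V2 at all.

Every subject-visit row has a matching phantom parameterization (per-side
target volume = Vol/2, target SNR, background SD chosen to render the
target CNR, child seed), so images can be rendered and re-measured; the
table values are the noise-free generative truth and rendering adds
measurement noise on top.

What the generator does **not** emulate: partial-volume effects at 3-mm
slices, rater bias fields, Rician tails, scanner drift between visits,
non-Gaussian clinical score distributions, or informative dropout. Passing
tests therefore demonstrate correctness of the estimators and statistics
under the programmed model, not robustness to those real-data effects.

## Statistics

All tests are two-sided at α = 0.05 unless configured. Demographics use
pooled-variance t tests and Pearson χ² (1 df, no continuity correction);
normality is gated by Shapiro–Wilk.

* **Cross-sectional:** per-measure OLS of measure ~ group × sex + age
  (age centered), Type-III sums of squares with sum-to-zero factor coding —
  the conventional reporting scheme for unbalanced factorial designs with a
  covariate. The "multivariate" GLM of the original analysis is realized as
  per-measure univariate models, since only per-measure F values are
  reported anywhere.
* **Longitudinal:** a mixed (split-plot) design with visit (V1, V2) as the
  within-subject factor. For a 2-level within factor the classical
  decomposition is exact and handles covariates and unbalanced cells:
  between-subject terms are Type-III F tests on per-subject visit means,
  the visit main effect is the Type-III intercept test on the V2 − V1
  differences, and each visit × X interaction is the X term of that
  difference model. This reproduces REML-based mixed-model F tests for this
  design and is cross-checked against an independent mixed-ANOVA
  implementation in the tests. Identical visits (all differences zero)
  return F = 0, p = 1 rather than 0/0.
* **Scanner effect:** one-way ANOVA across scanners on healthy-volunteer
  baselines.
* **ROC:** empirical AUC (ties 0.5); since PD lowers SN measures, the score
  sign is flipped when needed so AUC ≥ 0.5 and the flip is disclosed.
* **Correlations:** Pearson r between each SN measure and each clinical
  variable. Family-wise correction permutes the clinical variable jointly
  across the 4-measure family and compares each observed |r| to the
  permutation distribution of the family maximum |r|; the corrected p uses
  the add-one estimator (1 + hits)/(1 + B), or the exact proportion over
  all n! permutations when n! ≤ B. The family boundary (measures × one
  clinical variable) is a choice; per-pair permutation would be less
  conservative.

## Sample-size estimation

For a two-arm trial comparing 1-year changes, n per arm =
⌈2σ²(z₁₋α/₂ + z_power)²/Δ²⌉ (rounded up — conservative), with σ the SD of
the per-subject annualized change estimated from a (synthetic or supplied)
PD cohort and Δ = effect fraction × the reference decline. The reference
defaults to the PD − HV rate difference; referencing to the PD decline
alone is exposed (`delta_reference="pd"`), and the acceptance grid uses it
because the healthy-volunteer rates are small and noisy enough to make the
difference reference unstable in small simulated cohorts. The Monte-Carlo
counterpart binary-searches the smallest n whose simulated two-sample
t-test rejection rate reaches the target power; the two routes agree within
a few percent and serve as each other's check. No dropout inflation or
interim-analysis adjustment is applied.

## Numerical and reproducibility choices

* Every stochastic operation takes an explicit integer seed; fixed seeds
  give bit-identical images, tables and CSV outputs. Pipeline outputs embed
  a hash of the scientific configuration (output paths excluded) plus the
  seed, and `report.json` records per-file SHA-256 hashes and exclusion
  accounting.
* Degenerate inputs fail loudly and specifically: empty masks, missing
  background on an SN slice, SNR reference at the 100 background level,
  zero pooled variance, single-level factors, rank-deficient designs
  (naming the aliased term), infeasible correlation targets.
* Monte-Carlo problem sizes in the tests (e.g. 200 replicates for type-I
  calibration, 100 for interaction detection, 800 simulation replicates
  per power cell) are chosen so binomial error is small against the bands
  being asserted while the whole suite stays interactive.

## Known limitations

* TIV is an input (or generated) quantity; no tissue segmentation is
  performed, and C_vol inherits Vol's annual rate because TIV is held
  fixed across visits.
* The mixed ANOVA covers exactly the two study designs (visit × group ×
  sex + age, and visit × sex + age); it is not a general mixed-model
  engine, and no random-slope extensions are offered.
* Whether published SNR annual rates used raw or background-referenced
  changes cannot be determined from the printed values; background-
  referenced is the default here and both are available.
* Sample-size results depend on which decline reference and σ the original
  grid used, neither of which is stated; all inputs are echoed in the
  output so any convention can be reproduced.
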