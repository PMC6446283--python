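# Methods

This note documents the models, defaults and design choices behind
`natsc`: what is computed, under which assumptions, and what the synthetic
cohort does and does not establish about real data.

## Quantification model

Tissue sodium concentration is obtained from the tissue/reference signal
ratio with two multiplicative relaxation corrections:

* **T1 saturation** `1 − exp(−TR/T1)` per compartment.  At TR = 120 ms the
  factors are 0.984 (brain, T1 = 29 ms), 0.873 (CSF, T1 = 58.1 ms) and
  0.968 (reference, T1 = 35 ms).
* **Transverse decay at TE** `α·exp(−TE/T2f) + β·exp(−TE/T2s)`.  Sodium in
  tissue decays biexponentially because of residual quadrupolar
  interactions; free fluids (CSF, saline) are effectively
  monoexponential (α = 0).

Compartment constants (ms; α/β dimensionless):

| compartment | T1   | T2f  | T2s  | α/β     |
|-------------|------|------|------|---------|
| brain       | 29   | 4    | 29   | 0.6/0.4 |
| CSF         | 58.1 | 55   | 55   | 0.0/1.0 |
| reference   | 35*  | 7.15 | 33.7 | 0.6/0.4*|

`*` The reference-tube T1 is **not a measured value**: 35 ms is a typical
order of magnitude for aqueous/agarose NaCl phantoms at 3 T and is a
documented assumption, exposed as a required config field.  Likewise the
reference α/β = 0.6/0.4 reflects that the two quoted reference T2
components imply a biexponential (agarose-doped) phantom; both are
overridable.  The reference concentration 102.7 mmol/L is derived from
0.6 % NaCl (6 g/L ÷ 58.44 g/mol).

The brain T1 of 29 ms equals the brain T2s; the source constants list them
identically and no alternative value is available, so 29 ms is used as
given.

### Weight conventions

The compact printed form of the calibration equation uses a single α/β
pair in both the reference (numerator) and tissue (denominator) decay
terms.  Taken literally, that assigns the *same physical reference tube*
two different decay factors depending on which tissue class is being
quantified (brain 0.6/0.4 vs CSF 0/1 weights applied to the reference
T2s), an internal inconsistency of about 1.3 % at TE = 0.2 ms.  `natsc`
therefore defaults to `weight_convention="per-compartment"` — every
compartment decays by its own α/β, which makes quantification the exact
inverse of the forward signal model — and offers
`weight_convention="tissue"` (the literal shared-pair form) for
sensitivity analysis.  Flip-angle/steady-state effects are assumed to
cancel in the tissue/reference ratio and are not modeled.

## Synthetic cohort

The generator emulates a 12-subject, 3-visit (V1/V2 same day, V3 later),
2-reader test–retest study:

* **Geometry.** A schematic head on a 144×168×132 voxel, 1 mm anatomical
  grid: GM ellipsoid shell, WM core, bilateral caudate-head spheres,
  midline pons, bilateral cerebellum blobs, bilateral ventricular CSF,
  plus an external reference cylinder (r = 10 mm) outside the head.
  Region sizes are chosen so each region keeps a blur-free core large
  enough for the 0.508 cm² ROI protocol; no anatomical realism is
  intended.  The phantom is mirror-symmetric about the grid's left/right
  axis, so bilateral ROIs rasterize identically in the absence of a
  configured laterality effect.
* **Truth.** Per-subject region concentrations ~ Normal(mean, SD) with
  defaults GM 51.5 ± 4.5, WM 40.9 ± 3.8, HCN 60.9 ± 8.1, pons 39.8 ± 5.3,
  cerebellum 40.1 ± 4.9, CSF 102.1 ± 21.6 mmol/kg WW (clipped at 20 % of
  the mean to stay positive).  The caudate head carries a +4.4 mmol/kg
  left-minus-right offset by default, the one laterality effect the
  analysis is meant to resolve; all offsets are configurable.
* **Forward signal.** Per anatomical voxel,
  `gain × concentration × saturation × decay` (per-compartment weights),
  blurred with a Gaussian PSF of FWHM one sodium voxel (3.6 mm) as the
  partial-volume model, rigidly displaced by the session transform and
  trilinearly sampled at the sodium-grid voxel centers (the sodium grid
  is centered on the anatomical field of view).  k-space simulation of
  the radial readout is deliberately out of scope: the analysis operates
  on reconstructed images.
* **Session effects.** Gain ~ Normal(1, 0.02), translations/rotations
  uniform within ±2 mm / ±2°, Rician noise sigma 1.5 signal units
  (SNR ≈ 25 in white matter; source studies report no SNR, so this is a
  simulator choice).  Per-session seeds derive from a master seed by
  stable hashing of (subject, visit), so enlarging a cohort never
  reshuffles existing subjects.
* **Readers.** ROI placement jitter: in-plane Gaussian displacement of
  SD 1 mm per axis, deterministic per (reader, subject, visit, region,
  side, seed).  Systematic reader bias (one reader consistently reading
  higher) is *not* modeled.

Because sessions are corrected with the *known* rigid transform
(registration estimation is out of scope) and ROIs sit in region cores,
the synthetic cohort validates the quantification chain, not registration
accuracy or landmark-finding.  Passing tests show the pipeline recovers
known truth under controlled degradations; they cannot show robustness to
real anatomy, B0/B1 inhomogeneity, or the coarse-voxel partial-volume
biases of small structures — the known failure modes flagged for ROI work
near CSF.

## Statistics

* **Visit comparisons.** Subject-paired sign-flip permutation tests,
  statistic |Σ dᵢ|, exhaustively enumerating all 2ⁿ sign patterns for
  n ≤ 12 (exact p, granularity 1/2ⁿ) and 10⁴ seeded flips otherwise.  A
  repeated-measures "each visit vs baseline" family is additionally
  summarized by a max-t permutation over the contrasts (shared subject
  flips), honoring the contrast-vs-control structure of a Dunnett-style
  procedure without parametric multivariate-t quantiles.  Paired
  differences below 10⁻⁹ of the data scale count as exact ties, so
  numerically identical measurements yield p = 1.
* **Laterality.** The same paired sign-flip test on left−right
  differences.  (A chi-squared test is sometimes quoted for such
  continuous paired comparisons; that is statistically implausible and a
  paired permutation test is used instead.)
* **Fluctuation.** `100 × (max − min)/max` per region.  The denominator
  convention was selected because it reproduces all five reported
  percentage values from their printed max/min pairs within 0.2
  percentage points; a fixture test pins this reproduction.
* **Agreement.** Pooled Pearson r² over (subject, region) pairs per visit
  pair; Spearman rho (midranks) per region between readers; Bland–Altman
  on the reader-ratio scale with mean ± 1.96 SD limits.
* **Normality.** KS distance to a normal with estimated mean/SD,
  referenced to a Monte-Carlo null (2000 simulated normal samples,
  seeded) — the Lilliefors correction, since the naive KS distribution is
  invalid with fitted parameters.
* **Aggregation.** Readers are averaged within (subject, visit, region,
  side) first, then sides, before any across-subject statistic; the
  pooled "Mean" row aggregates over (subject, region) values.  No
  multiple-testing correction is applied across regions in the per-region
  tables.  Rendered reports round to one decimal; CSV output keeps full
  precision.

## Problem sizes and determinism

Default validation sizes, chosen to keep the full suite and the acceptance
script fast on a single CPU while leaving Monte-Carlo margins of ≥ 3
standard errors: 12 subjects × 3 visits for noiseless recovery and cohort
summaries, 50 subjects × 1 visit for noisy recovery, 1000 measurement-level
null cohorts of n = 12 for permutation-test calibration (image rendering
adds nothing to that check), 10⁵ voxels for the noise-model moments, and
200 truth-only subjects for variance calibration.  Every random draw
descends from one master seed; identical configuration and seed reproduce
all CSV/JSON outputs byte-for-byte.

## Known limitations

* Axis-aligned grids only; oblique acquisitions are rejected rather than
  resampled.
* The printed-form ("tissue") weight convention and the per-compartment
  default differ by ~1.3 % for CSF; users comparing against literature
  values computed with the shared-pair form should select it explicitly.
* The phantom's laterality and reader models are deliberately minimal
  (symmetric jitter, no reader bias, no day-level physiological drift).
* Concentration units mix mmol/kg wet weight (tissue) and mmol/L
  (reference); they are treated as numerically interchangeable in the
  calibration, as is standard practice for aqueous references.
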