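# Methods

This note documents the models, numerical choices and validation design of
`metmorph`. It is the package's own account of what it computes and why;
every number quoted here is produced by the test suite or the demo.

## Lesion phantoms

A phantom is a star-shaped solid with radial boundary
`r(θ, φ) = R0 (1 + Σ a_lm Y_lm(θ, φ))`, where the `Y_lm` are **orthonormal
real spherical harmonics without the Condon–Shortley phase** (m = 0 zonal,
m > 0 cosine-type, m < 0 sine-type, each tesseral term carrying the √2
orthonormalization). The convention is stated so amplitude values are
portable; a quadrature test verifies orthonormality directly. An optional
concentric spherical core of radius `core_radius_fraction · R0` stands in
for central necrosis. Validity requires `r > 0` on a dense angular grid and
the core strictly inside the surface.

Reference volume and area come from angular quadrature — Gauss–Legendre in
cos θ crossed with a uniform azimuth grid, 256 × 512 by default:

- `V = (1/3) ∮ r³ dΩ`,
- `S = ∮ r √(r² + r_θ² + r_φ²/sin²θ) dΩ` (first fundamental form), with
  harmonic derivatives evaluated analytically.

At the default resolution both reduce to the closed sphere forms within
1 × 10⁻⁴ relative error, the area self-converges to better than 0.1% between
64² and 256² grids for amplitudes ≤ 0.3, and the volume agrees with an
independent 10⁷-sample Monte-Carlo rejection oracle within 0.5%.

**Voxelization** uses the voxel-center rule: a voxel belongs to the lesion
iff its center lies inside the radial surface (necrotic iff also inside the
core). This makes the noiseless segmentation round trip *exact*, which the
tests exploit: thresholding midway between the background (20) and enhancing
(100) intensity levels recovers the ground-truth voxel sets bit for bit.
Intensities mimic CE-T1w contrast (necrotic level 45, between background and
rim); Gaussian noise is seeded and reproducible. The field of view is
auto-sized with a two-voxel margin so isosurface extraction always has a
background shell. Deliberately absent: MR physics (bias fields, contrast
kinetics, artifacts) and any anatomical background — the phantoms validate
geometry and statistics, not scanner realism, so passing tests say nothing
about robustness to real MRI artifacts or to inter-rater segmentation
variability.

**Longitudinal series** scale the base radius by `factor^(1/3)` per
timepoint so volume scales by `factor`; harmonic amplitudes can be rescaled
per timepoint to mimic the increase in surface irregularity after
irradiation. The baseline (typically at a negative, pre-treatment time)
comes first; times must be strictly increasing.

## Segmentation and necrosis

`segment_ce` thresholds at an explicit gray level (≥ threshold), keeps
26-connected components per policy (`largest` by default), and never chooses
a threshold silently — an Otsu helper exists but must be invoked
deliberately, since in the clinical workflow an expert picks the level.
Lesions touching the image boundary raise a warning rather than an error
(their treatment in clinical practice is ambiguous).

`detect_necrosis` implements enclosure topologically: necrosis is the 3D
hole fill of the CE label minus the CE label, with **6-connectivity for the
background complement**. A single-voxel perforation of the rim therefore
disqualifies the core — it is no longer enclosed — which the tests check
against an independent boundary flood-fill oracle. Filling in full 3D
(rather than slice-wise) avoids artifacts at thick slices. The operation is
idempotent.

## Morphometry

Volumes are voxel counts × voxel volume (mm³ → cm³). The surface entering
the regularity index is the **outer total-tumor isosurface** (CE plus filled
necrosis), because the index's volume is the total volume; using the inner
CE interface would mismatch numerator and denominator. The original clinical
definition does not state this explicitly; the choice is recorded in each
mask's provenance string.

Marching cubes on a raw binary mask overestimates a sphere's area by ~8–9%
(staircase bias; measured during development at 0.5–1 mm spacing). The
binary indicator is therefore smoothed with a **1-voxel Gaussian** before
extraction at iso-level 0.5, which brings the error to −0.2% at 0.5 mm and
−1.5% at 1.0 mm on a 1-cm-radius sphere. Consequences worth knowing:
the residual bias is negative (areas slightly underestimated, SR slightly
inflated, noticeably so for lesions under ~10 voxels across — a single-voxel
lesion triggers an explicit warning, and the smoothing falls back to the raw
indicator if it would erase the lesion entirely); anisotropic spacing is
applied to mesh vertices per axis.

The constants 10.63 and 0.62 are used exactly as printed in the feature
definitions — not recomputed at higher precision — so outputs are comparable
with published values; the analytic forms 6√π and (3/4π)^(1/3) appear only
in tests, which check that the printed constants are their two-decimal
roundings and that an ideal sphere scores SR = 1.00.

Necrotic volume at or below a configurable floor (default: one voxel) is
treated as absent and counted as enhancing. The floor exists because hole
filling on discretized masks can produce isolated enclosed background voxels
that are artifacts, not necrotic cores (the solid-sphere fixture exposed
exactly this), and because the binary necrosis flag needs a stated rule.

## Survival analysis

Kaplan–Meier, log-rank and Cox machinery is delegated to `lifelines`
(product-limit estimator; Efron tie handling; Wald CIs); the package owns
the screening logic around it. Tests keep an independent route throughout:
a hand product-limit computation, a hand O−E/V log-rank on a six-subject
fixture (statistic 0.48488), a brute-force 1-D partial-likelihood scan for
a small Cox fixture, and a 2⁸ sign-enumeration oracle for the exact Wilcoxon
p-value.

**Progression events.** A follow-up counts as progression when total volume
exceeds the running *post-treatment nadir* by ≥ 20% relative **and** ≥ 0.1 cm³
absolute (both configurable, always logged). The nadir initializes at the
first follow-up, so the earliest possible event is the second follow-up.
This is a stated stand-in for volumetric response criteria used clinically;
any analysis report records the criterion applied.

**Threshold sweep.** Candidates are the unique observed values (or an even
grid); splits leaving either group under 10% of the cohort are excluded.
A candidate is significant at p < 0.05 and *non-isolated* if an adjacent
candidate is also significant; the lowest-p non-isolated significant
candidate wins. "Non-isolated" is interpreted minimally — one significant
neighbor — as the smallest reading that discards isolated spikes. The
selected p is reported uncorrected (the procedure is deliberately
optimistic, mirroring how such cutpoints are chosen in the clinical
literature), but the full p-profile is always emitted so users can apply
multiplicity corrections; on null covariates occasional selections are
expected and observed (one pre-treatment variable in the committed demo
seed), which is why the demo's planted-null check is made on the designed
null covariate.

**Cox screening.** Univariate hazard ratios are reported per dichotomized
group when a threshold was selected, per unit of the covariate otherwise.
Backward stepwise-Wald elimination drops the largest-p covariate until all
remaining have p ≤ 0.10 (configurable); an empty model is a legitimate
outcome. Exactly collinear dichotomized covariates (e.g. "necrotic volume
> 0" versus the necrosis flag) are deduplicated before the multivariate fit,
with the drop logged.

**Auxiliary tests.** Wilcoxon signed-rank is exact for ≤ 25 untied non-zero
differences, normal-approximated with tie correction otherwise. The KS
normality check estimates mean/SD from the sample and therefore reports the
Lilliefors-corrected p-value, flagged as such in the output; a calibration
test confirms a ~5% rejection rate on normal samples at n = 200.

## Cohort simulation and recovery validation

`simulate_cohort` draws event times from a proportional-hazards exponential
model `λ_i = λ0 exp(Σ β_j x_ij)` with independent exponential censoring and
an administrative horizon — the standard design for validating survival
estimators, with every generating parameter known. Recovery results (from
`tests/test_acceptance.py`, replicate seeds spawned from one master
generator):

- Cox on a binary covariate with true HR 2, n = 500, 100 replicates:
  mean log-HR bias 0.023, 95% Wald CI coverage 95/100.
- Threshold sweep on a step hazard (HR 3 at x = 5, x ~ U(0, 10)), n = 400,
  41-point grid, 50 replicates: selected cutpoint within ±10% of the range
  in 50/50.
- Stepwise elimination of a pure-noise covariate alongside a true HR-2
  signal, n = 500, 50 replicates: eliminated in 46/50 (the expected rate is
  ~90% by construction, since a null covariate clears α = 0.10 about 10% of
  the time).

The exponential hazard is a simplification: real progression hazards are
non-constant and per-patient correlated (several lesions per patient).
Per-lesion analysis without clustering adjustment mirrors the clinical
screening design and is a known limitation, not a claim of independence.

## The demo's study conditions

`run_demo` fixes a 100-lesion cohort, one pre-treatment scan (t = −0.5
months) and one first follow-up (t = +3 months) per lesion; voxel spacing
(0.75, 0.75, 1.25) mm, in the clinical CE-T1w regime; median pre-treatment
radius 0.8 cm (lognormal, σ = 0.3, clipped to 0.4–1.8 cm); harmonic
irregularity drawn per lesion (degrees 2–4); necrosis prevalence 35% pre /
55% post; median post/pre volume ratio 0.55 (lognormal, σ = 0.55); post
amplitudes ×1.25 (irradiation roughens surfaces). The progression hazard is
0.05/month × exp(0.9·1[ratio > 0.5] + 0.8·necrosis_post), with 0.02/month
censoring and a 24-month horizon, plus a standard-normal null covariate.
These sizes keep a full demo run around half a minute on one CPU while
giving the planted effects clear power; all of them are ordinary function
arguments and can be changed without touching the analysis code. Outputs
(feature, cohort, survival and report CSVs, the JSON sweep profiles, KM and
correlation figures) are byte-deterministic per seed, which the tests assert
by comparing files from two runs.

## Known limitations

- Surface area (hence SR) carries a small spacing-dependent negative bias;
  comparisons should hold voxel spacing fixed across a cohort.
- The sweep's selected p-values are optimistic by design; treat the report
  as screening, not confirmation.
- No DICOM ingestion, no registration across timepoints, no per-patient
  random effects, no MR artifact modeling.
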