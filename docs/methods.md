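# Methods

## The quantification model

`thoraxcomp` quantifies six tissues — skeletal muscle (SM), bone, and
subcutaneous (SAT), intermuscular (IMAT), visceral (VAT) and epicardial
(EAT) adipose tissue — from a thoracic CT attenuation volume plus
upstream organ masks (lungs, heart, epicardial fat, vertebrae). The
chain is deliberately rule-based, so every step is auditable:

**Body extraction.** Voxels ≥ −500 HU form candidate tissue; the
largest 26-connected component is kept and holes are filled slice-wise
(8-neighbourhood), re-including lung parenchyma and gas. The −500 HU
default sits midway between lung parenchyma (≈ −800 HU) and soft
tissue and is configurable.

**Compartmentalisation.** On every axial slice the filled 2-D convex
hull of the union of lungs, heart and the epicardial fat mask defines
the intrathoracic space; bone-density voxels are removed from it
(bones always count as extrathoracic), and the rest of the body is
extrathoracic. The hull is 2-D per slice rather than 3-D because the
stack-of-slices geometry of attenuation-correction CT makes per-slice
hulls robust to cranio-caudal truncation; both the hull dimensionality
(per-slice is the only implemented variant) and the organ set seeding
the hull are exposed in configuration. Hull membership is defined
exactly: a voxel centre belongs to the hull iff it is a convex
combination of organ voxel centres (facet inequalities with 1e-9
slack; degenerate point/segment inputs use exact integer arithmetic).
An independent Delaunay-triangulation membership oracle is used in
tests to pin this definition.

**Slab standardisation.** Quantification is limited to the inclusive
z-range spanned by the T5–T11 vertebra masks (full voxel extent, not
centroids). Scans missing any of T5–T11 are rejected outright — the
same rule the study population applies — rather than extrapolated.

**Tissue attribution.** Density classes use closed HU intervals:
adipose [−190, −30], muscle [−29, +150], bone [+151, +1200]. Values
outside all intervals (including the open gaps between the printed
integer bounds, e.g. −29.5) are unassigned. Intrathoracic adipose is
VAT unless inside the EAT mask; extrathoracic muscle is SM;
bone-density is bone anywhere; extrathoracic adipose components
touching the body-surface shell (1-voxel erosion difference,
26-connected components) are SAT in their entirety, all others IMAT.
EAT is density-gated by default (only adipose-density voxels of the
EAT mask count), so EAT mean density is computed over fat voxels like
the other adipose depots; a flag disables the gate because the
original pipeline's convention is not documented.

**Metrics.** Volume = voxel count × voxel volume; mean density =
arithmetic mean HU over the entire tissue volume; indexed volume =
volume / BSA with BSA from DuBois–DuBois
(0.007184 · weight^0.425 · height^0.725, kg and cm). The
sensitivity-analysis variant expresses volume as a percentage of total
thoracic volume, operationalised as the union of the intrathoracic
compartment and the lungs within the slab (the union rather than a
sum, since hole-filled body extraction already places the lungs inside
the compartment). Note that extrathoracic tissues can exceed 100% of
this quantity — the fraction is an indexing variant, not a proportion
of a containing volume. Undefined values (empty tissue, missing
height/weight) are explicit nulls.

## The phantom generator

The generator builds the anatomy the rules above assume: an elliptical
body with a SAT rim (6 voxels) and muscle wall (10 voxels), a convex
elliptical cavity holding two lung ellipsoids, a heart ellipsoid with
a 3-voxel EAT shell, VAT pockets placed between the lungs (provably
inside the organ hull — the generator verifies containment with its
Delaunay oracle and aborts otherwise), IMAT pockets buried in the
muscle wall, a 12-level vertebral column and rib blocks. Default grid
160×160×120 at 2.5×2.5×3.0 mm, default means: fat −100, muscle +40,
bone +400, lung −800, air −1000 HU — each safely interior to its
classification interval. Boundary-stress variants put fat/muscle means
at −30/−29 HU and muscle/bone at +150/+151 HU to pin the closed-interval
reading.

The mediastinal background is painted at −250 HU, outside every
classification interval. This is the one deliberately non-physiologic
choice: it makes zero-noise recovery of all six tissues *exact by
construction*, because intrathoracic non-organ tissue otherwise lands
in SM or VAT depending on how much of the cavity the organ hull
covers, which cannot be known without running the pipeline under test.
Consequently the phantom validates the attribution logic, interval
edges, hull geometry, skin-contact rule and bookkeeping — it does not
emulate CT texture, partial-volume effects, beam hardening or realistic
mediastinal anatomy, and exact recovery on it says nothing about
segmentation accuracy on real scans. Additive Gaussian HU noise
(`degrade_phantom`) probes robustness of the interval rules; at SD 15
the per-tissue volume error on the default phantom is ≈ 1%
(regression-bounded at 3%), dominated by the small IMAT/VAT pockets.

## The cohort simulator

The simulator emulates the statistical structure of a PET-MPI referral
cohort of 10 085 patients: 57.2% male; age ≈ N(67.5, 12.6²) years; BMI
≈ N(30.3, 7²) with 0.3% missing (median-imputed downstream);
comorbidity prevalences from the population table (hypertension 0.790,
diabetes 0.388, dyslipidaemia 0.690, heart failure 0.195, cancer
0.192, prior MI 0.206, prior revascularisation 0.289); early (90-day)
revascularisation prevalence is not reported and defaults to 0.08.
PET markers: stress TPD and MFR are log-normal with parameters matched
to the published medians/IQRs, LVEF near-normal. CAC is ordinal
(0 / 1–99 / 100–399 / ≥400) with a point mass at zero; the probability
vector (0.30, 0.15, 0.20, 0.35) respects the published zero 25th
percentile and a median in the 100–399 band (the true boundaries are
not printed).

Composition metrics are drawn per tissue as a bivariate normal on the
z-scale with the published volume–density correlations (SM +0.46,
SAT −0.68, EAT −0.46, VAT −0.23, IMAT −0.52; bone unreported, 0) and
mapped linearly to plausible units, so Pearson correlations are
preserved exactly in the population; values are not truncated, so
extreme tails can be physiologically implausible. Event times use the
latent cause-specific-hazards construction: independent Weibull
proportional-hazards times for death (shape 1.1, scale 11 y) and MI
(shape 1.0, scale 40 y) with per-SD log-hazard vectors applied to the
z-scale covariates, independent U(1, 11) y censoring, observed time =
the minimum. This yields closed-form truth for cause-specific Cox
models; subdistribution-hazard coefficients under competing risks are
*not* equal to the cause-specific ones except when the competing
hazard vanishes, which is exactly the degenerate case the acceptance
check exercises.

## Statistical stages

*Youden cut-points* are found by exhaustive search over observed
values in both orientations per sex stratum; ties are broken toward
higher sensitivity, then the lower cut-point, then the abnormal-above
orientation, and a flag marks non-unique maxima. The search is tested
for exact agreement with an independent brute-force implementation.

*Cox models* use lifelines (Efron tie handling). Continuous covariates
are standardised to sample SD 1 — after any natural-log transform, the
convention adopted where the order is not documented — so hazard
ratios are per SD; categorical CAC enters as dummies against the zero
category. The null-model Efron partial likelihood is computed in
closed form so likelihood-ratio increments against the null flow
through the same nested-model interface; increments are gated at
α = 0.001, the only multiplicity adjustment applied. An optional ridge
penalizer (default 0) regularises deliberately degenerate designs;
singular fits otherwise fail loudly.

*Competing risks* default to a Fine–Gray subdistribution-hazard model,
implemented via the Geskus risk-set expansion: subjects failing from
the competing cause remain at risk after their failure, weighted by
the censoring Kaplan–Meier ratio G(t−)/G(T−), and the expanded
start–stop data are fitted as a weighted time-varying Cox model. The
implementation agrees with R's `cmprsk::crr` to ~1e-5 on shared data
(tested). A `cause-specific` flavour (censor competing events) is one
flag away, since the original analysis does not say which was used.

*Proportional hazards* are checked with scaled Schoenfeld residuals
against rank-transformed event time (per covariate); the global
statistic sums the per-covariate chi-squares on k df, a standard
approximation to the joint score test.

## Numerical and design notes

- Axis convention is fixed: arrays are (x, y, z), z ascending toward
  the head; NIfTI inputs are reoriented to closest-canonical on read.
  Inputs must be pre-aligned — no resampling is performed.
- Hull facet tests use 1e-9 slack on integer-coordinate geometry where
  the nearest off-facet grid point is ≥ 1/500 away, so membership is
  effectively exact; collinear slices fall back to integer arithmetic.
- Volumes and mean densities on constant-valued regions are exact in
  double precision (sums of identical representable values), which is
  what makes the zero-noise equality tests legitimate as *exact*
  comparisons.
- Problem sizes used by the acceptance script (default phantom ~3.1M
  voxels; 200 Cox replicates at n = 2000; 500 LR-null replicates at
  n = 300; 1000 Youden datasets at n ≤ 200; cohorts of 5000–10000 for
  the competing-risk and correlation checks) were chosen so the whole
  script runs in about a minute on one CPU while keeping Monte-Carlo
  error well inside the tolerances tested.

## Known limitations

- The phantom's convexity-by-construction means the hull logic is
  never stressed by organs whose true cavity is concave in-slice.
- EAT gating, hull organ set, thoracic-volume definition and
  competing-risk flavour are configurable precisely because the source
  method leaves them under-specified; defaults are documented above.
- The cohort simulator draws covariates independently except for the
  within-tissue volume–density pairs; real cohorts have richer
  cross-correlations (age–composition, BMI–SAT), so recovery results
  here do not certify behaviour under strong covariate confounding.
- The global Schoenfeld statistic is an approximation, not the exact
  joint score test.
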