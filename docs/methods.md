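# Methods

## The grading model

`gbmgrade` implements a five-feature pre-operative MRI complexity score
for adult supratentorial glioblastoma. Each feature contributes one point
when present, all features weighted equally:

| feature | present when | threshold default |
|---|---|---|
| periventricular / deep location | distance from enhancing tumour to ventricles **< 10 mm** (strict) | 10 mm |
| corpus callosum or bilateral location | enhancing tumour extends into the corpus callosum **or** crosses the midsagittal plane | — |
| eloquent location | enhancing tumour extends into motor/sensory cortex, language cortex, insula or basal ganglia | — |
| size | maximal tumour diameter **≥ 40 mm** (inclusive) | 40 mm |
| associated oedema | oedema extends **≥ 10 mm** beyond the enhancing margin (inclusive) | 10 mm |

The total (0–5) maps to complexity classes: low (0–1), moderate (2–3),
high (4–5). The boundary semantics (strict for the ventricle distance,
inclusive for size and oedema) are intrinsic to the scale and pinned by
tests. Thresholds are configurable; non-default values are recorded in
output metadata. A record with any missing measurement is ungradable and
reported as such — no imputation.

## Geometry on voxel masks

All inputs are co-registered binary masks (NIfTI-1) with orthogonal
direction axes. Measurements are between **voxel centres**:

* *Ventricle distance* — minimum over tumour voxels of the exact Euclidean
  distance transform of the ventricle mask, with anisotropic spacing; 0 on
  overlap.
* *Oedema extension* — maximum over oedema voxels of the distance to the
  nearest tumour voxel; 0 for empty or fully contained oedema.
* *Diameter* — exact maximal pairwise voxel-centre distance (3D Feret
  diameter). For large masks the search is restricted to convex-hull
  vertices, which is exact; degenerate (flat/collinear) masks fall back to
  the full pairwise scan. An optional `axial` mode takes the maximum
  in-plane diameter over constant-k slices, mirroring how radiologists
  often measure on a single slice; the scale does not specify which read
  was used, so both are offered and `3d` (the well-defined choice) is the
  default.
* *Involvement* — voxel-overlap count at a configurable minimum (default
  1 voxel, the conservative reading of "extends into").
* *Bilaterality* — tumour voxel centres strictly on both sides of the
  midsagittal plane; centres exactly on the plane count for neither side.
  The midline defaults to the x = 0 plane of the RAS scanner frame; an
  explicit plane (point + normal) may be supplied.

Because distances ignore sub-voxel surface offsets, every length carries a
discretisation error bounded by one voxel space diagonal (√3 mm at 1 mm
isotropic). Multifocal tumours are treated as one point set (distances and
diameter over the union). Voxel indices are 0-based and voxel (0,0,0)'s
centre sits at the affine's translation, matching NIfTI affine semantics.

## Cohort statistics

* *Major complication* — Clavien-Dindo strictly above 3a, i.e. {3b, 4a,
  4b, 5}.
* *Chi-square* — plain Pearson statistic on the grade × outcome table, no
  continuity correction, no exact test; expected counts below 5 raise a
  warning flag but do not block the test (the complications table has
  expected counts below 1, and the validation analysis ran it regardless —
  the flag documents the caveat). Degenerate 1×c tables are rejected;
  all-zero rows/columns are dropped with a warning.
* *Cohen's kappa* — computed on the 3-level complexity classes by default
  (a 6-level raw-score option exists); the default standard error is the
  large-sample non-null estimator of Fleiss, Cohen & Everitt, as major
  statistics packages report, with the simple
  `sqrt(p_o(1−p_o)/(n(1−p_e)²))` formula available by option. Tables whose
  margins concentrate in one category make kappa undefined and are
  rejected.
* Percentages round half-up to one decimal, computed from exact rationals,
  matching clinical table style. p-values print to 4 decimals; machine
  outputs keep full precision.

In tests, the chi-square p-value is cross-checked against a Monte-Carlo
permutation null with fixed margins using the **mid-p** convention
(half-weighting the atom at the observed statistic): the asymptotic
chi-square tail approximates the discrete conditional distribution in the
mid-p sense, and the fixture sits at n = 600 where that approximation is
comfortably inside Monte-Carlo error. Kappa and its asymptotic SE are
cross-checked against an independent implementation (statsmodels) and a
10,000-replicate multinomial bootstrap.

## Synthetic data

**Phantoms** stand in for patient imaging. Each phantom is an axis-aligned
ellipsoid tumour, an oedema shell of commanded thickness (built from the
same distance transform the measurement uses, but on the complement side),
a ventricle slab whose face sits at a commanded gap from the tumour
surface (snapped to the voxel lattice so the commanded gap is realised
between centres to within half a voxel), and 8 mm boxes for the corpus
callosum and eloquent regions that either overlap the tumour or sit 5 mm
clear of it. The grid auto-sizes to contain everything with a 3 mm margin,
and voxel centres are laid on half-spacing offsets so none falls exactly
on the midline. Every commanded quantity is the analytic ground truth:
gap (clamped at 0), shell thickness, 2×(largest semi-axis), and the three
booleans. The randomised recovery suite draws semi-axes of 5–24 mm, gaps
of −5–18 mm and thicknesses of 0–16 mm at 1 mm isotropic spacing — sizes
representative of surgical-series glioblastomas — and requires recovery
within one voxel diagonal. Phantoms do not emulate MRI intensities,
irregular margins, infiltrative non-enhancing tumour, or registration
error; passing tests therefore validate the geometry pipeline, not a
segmentation algorithm.

**Simulated cohorts** stand in for the 88-patient validation records. Five
binary flags are drawn per patient — independent Bernoulli at the
validation cohort's prevalences (68/88, 29/88, 38/88, 62/88, 61/88) by
default; the published tables give only marginals, so any joint structure
is explicitly synthetic and available as an optional Gaussian copula with
a user-supplied latent correlation matrix. Score and class come from the
grading module; complete resection and major complication are Bernoulli
conditional on class (7/14, 7/45, 1/29 and 0/14, 1/45, 2/29). A fired
complication is assigned a Clavien-Dindo grade uniformly from {3b, 4a,
4b, 5}, since only the >3a dichotomy is analysed; patients without a major
complication are recorded as 'none' (minor complications are not
modelled). Each call uses a single seeded generator and records the seed
in provenance metadata.

**Second rater.** Rater noise acts at the feature level: each flag flips
independently with probability ε ∈ [0, 0.5], and the second rater's score
and class are recomputed. Raters disagree on reading features, class
disagreement is induced — and this makes chance-corrected agreement a
monotone one-parameter family, so a bisection on ε calibrates simulated
kappa to any achievable target. The published agreement (κ = 0.625,
SE 0.066) cannot be re-derived because the rater cross-table was not
printed; the calibration demonstrates that the simulator spans it, it does
not reproduce it. Published prose also does not state whether agreement
was computed on 3 classes or 6 score levels; the class scale is the
default here.

## Numerical and design choices

* Distance transforms: `scipy.ndimage.distance_transform_edt` with
  per-axis sampling — exact Euclidean, anisotropy-aware.
* Chi-square: `scipy.stats.chi2_contingency(correction=False)`; kappa and
  both SE formulas are implemented in-package.
* Connectivity conventions, where components matter, are 26-neighbour 3D.
* CSV dialect is fixed (UTF-8, comma, '.' decimal, booleans 0/1) for
  byte-exact round-trips; provenance travels as `#` comment lines.
* CLI flags override config-file values; every run logs its config digest
  and seed to stderr, never mixing logs into machine output.
* Problem sizes in the test-suite: 50 random phantoms (grids ≈ 60–110
  voxels per axis), cohort recovery at n = 100,000, kappa calibration at
  n = 10,000 per bisection step — large enough for the stated statistical
  bands at three standard errors.

## Known limitations

* The "deep location" clause of the periventricular feature is collapsed
  to the 10 mm ventricle-distance rule, as the operational definition
  does; tumours deep in white matter but far from ventricles score 0 on
  this feature.
* Surface-to-surface sub-voxel distances are not modelled; all lengths are
  voxel-centre quantities with the one-diagonal error bound.
* The oedema measurement trusts whatever oedema mask it is given (T1
  hypo-intensity vs FLAIR is a segmentation question outside scope).
* Simulated cohorts have no demographic covariates and, by default, no
  feature dependence; they validate the statistical machinery, not
  clinical effect sizes.
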