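# Methods

This note documents the models, numerical choices and known limitations of
`fetalfold`. It is the companion to the test suite: every claim here about
behaviour is something the tests or `scripts/acceptance.py` actually
compute.

## Phantom model

The synthetic brain is a parametric label volume standing in for the
outputs of an MRI segmentation/parcellation pipeline. The white-matter
core boundary is a radially perturbed sphere,

    r(θ, φ) = R · (1 + a · sin(f·θ) · sin(f·φ)),

with polar angle θ, azimuth φ, base radius `wm_radius` R, folding
amplitude `a ≥ 0` and integer angular wavenumber `f` (default 8). A
cortical shell of constant radial thickness (`cgm_thickness`, default
3 mm) wraps the core. Deep gray matter and two ventricles are ellipsoids
carved out of the core; cerebellum, brainstem and two hippocampi are
ellipsoids placed below the cerebrum with validated clearance, so at
`a = 0` every structure volume has a closed form (`analytic_volumes`).
Voxel centres sit at `index × spacing` with no rotational affine — phantom
and mesh share one frame, keeping geometric oracles exact.

The parcellation divides the cortical sheet into eight angular sectors
around the left–right axis (four wide lobar sectors plus narrow cingulate,
insula and corpus-callosum sectors), mirrored in both hemispheres; DGM and
ventricle labels complete the ten regions. The mid-sagittal plane is the
grid's x-centre; anything exactly on it belongs to the left hemisphere by
convention.

`f = 8` with 1 mm rasterization is the default operating point of the
folding model: at lower wavenumbers the gyrification index's genuine
response between amplitudes 0 and 0.05 falls below the mesh-discretization
resolution (the geodesic-patch area is close to an intrinsic surface
quantity, so shallow extrinsic folding moves it only weakly), whereas at
this operating point the amplitude sweep {0, 0.05, 0.15} is resolved with
clear margins.

## Surface extraction

The gray–white junction is the 0.5-level isosurface of the inside
indicator of {WM, DGM, ventricles}. The binary indicator is anti-aliased
with a Gaussian (σ = 1 voxel, configurable; 0 disables) before marching
cubes: contouring the raw binary mask yields a staircase surface whose
area is biased ≈ +9 % and does not converge with resolution, while the
anti-aliased isosurface tracks the true boundary (sphere area error
≈ 0.5 % at 1 mm, shrinking at 0.5 mm). Mesh cleanup merges duplicate
vertices and drops degenerate triangles; optional Taubin smoothing is off
by default. Per hemisphere, the largest connected component is kept and
discarded area is logged; an open surface is an error.

Vertices get the label of the nearest non-background parcellation voxel
(Euclidean distance between vertex and voxel centres; ties to the smallest
label). Convex hulls are built per hemisphere or for the whole surface;
qhull is run strictly first so degenerate (coplanar) input fails loudly
rather than being joggled.

## Folding metrics

**Associated vertex area** is one third of each incident triangle's area;
associated areas sum exactly to the mesh area.

**Lobar surface area** credits each triangle to the majority region of its
three vertices (tie → region of the lowest vertex index) and sums the four
lobar regions.

**Local gyrification index.** Numerator: summed associated areas of
vertices within geodesic distance `patch_radius` (default 15 mm) of the
vertex. Geodesic distances are shortest paths on a chord-augmented graph:
every vertex pair within `chord_hops` (default 4) mesh edges is joined by
its straight-line chord. Pure edge-path Dijkstra on marching-cubes meshes
overestimates geodesics by 10–15 % (paths zigzag along grid-aligned
edges), which would bias LGI low by ≈ 20 %; 3–4 mm chords cut the
distortion below ~1.5 % and are far too short to tunnel across folds at
the wavelengths modelled here. Denominator: the hull area inside a
Euclidean ball of the same radius centred at the vertex's nearest hull
point, computed from hull faces subdivided to the surface-mesh edge scale
(large flat hull facets otherwise quantize the ball intersection). Both
sides use a half-edge-wide linear partial-coverage ramp at the patch
boundary, suppressing the ±5 % per-vertex jitter of a hard cutoff. On a
convex phantom all vertex LGIs fall in ≈ [0.96, 0.98]; the residual
deficit below 1 is the intrinsic geodesic-disc deficit of a sphere
(2R²(1−cos(r/R))/r²) plus ≤ 1.5 % metric distortion.

LGI uses the **whole-surface hull**: a per-hemisphere hull has an
artificial flat wall at the mid-sagittal plane that would roughly double
the denominator for vertices within a patch radius of the midline. Sulcal
depth uses **per-hemisphere hulls**, as depth is defined against the
hemisphere's own envelope. Consequently the hemisphere-independence
property (perturbing one hemisphere leaves the other's values bit-identical)
holds for depth and area but not for LGI, whose reference envelope is
global.

**Sulcal depth** is the exact point-to-triangle minimum distance to the
hull, with KD-tree pruning on face centroids and a certified re-check so
the true minimiser is never missed; a Monte-Carlo sampled-hull oracle
bounds it in tests.

**Aggregation**: lobar means weight vertices by associated area; the
global value combines the four lobes area-weighted; a lobe without
vertices is reported missing (NaN), never zero.

## Cohort simulator

Two epochs ("pre", "pandemic") with, by default, 137 + 65 mothers, about a
third scanned twice (second scan 6–12 weeks later), gestational ages from
a truncated normal on [16.7, 39.1] weeks (mean 30.5, sd 6.5), 52 % male
fetuses, maternal age truncated normal 34 ± 4.5 on [17, 51], and parental
education/employment codes drawn identically in both epochs. Distress
totals (SSAI/STAI 20–80, PSS 0–40, EPDS 0–30) are truncated normals with
epoch-shifted means concentrated on stress and depression (published
pregnancy-screening spreads: anxiety sd ≈ 10, PSS ≈ 6.5, EPDS ≈ 5),
correlated within mother, rounded to integers; a configurable fraction of
mothers has no distress data (complete-case handling downstream).

Outcomes follow closed-form growth curves plus a subject-level random
intercept (inducing the within-mother correlation the GEE must absorb) and
scan noise. Tissue volumes are exponential in GA, anchored so GA-30 values
sit at (CGM 60, WM 98.5, DGM 15.5, cerebellum 8.8, brainstem 3.95,
hippocampus 1.15) cm³ with term values inside the physiologic envelope.
Folding amplitude is linear in GA (0.10 at GA 30, +0.004/week); surface
area, LGI and sulcal depth derive from amplitude and GA through documented
linear sensitivities (area 1.5·10⁵ mm², LGI 8.0, depth 16 mm per unit
amplitude), then split into lobes by fixed shares/offsets plus noise.
Configured cohort effects add to tissue volumes (default: WM −5.8,
cerebellum −0.5, hippocampus −0.1 cm³) and to folding amplitude (−0.01),
and each scan records its generating parameters (`true_wm_radius`,
`true_fold_amplitude`) plus a rasterizable `PhantomSpec`.

What the simulator does **not** emulate: MRI intensities and motion,
segmentation errors, non-Gaussian outcome tails, distress-score item
structure and between-scale correlation as observed in real screening
instruments (the simulated union prevalence of "any elevated measure" is
therefore higher than in typical cohorts), or secular GA-at-enrollment
trends. Passing tests demonstrate the correctness of the measurement and
inference machinery under these study conditions, not properties of any
particular real cohort.

A methodological note discovered while validating the simulator: with
epoch-specific repeat-scan fractions, the GA distribution differs by
cohort, and the exponential growth that a linear GA term cannot absorb
shifts the cohort-effect estimand by a few tenths of a cm³ (identically
for OLS and exchangeable GEE). The parameter-recovery studies therefore
use equal repeat fractions across epochs — a calibration design that
isolates the injected effect — while the realistic unequal-fraction
defaults remain for study-emulation runs.

## Statistics

Demographics: Shapiro–Wilk normality screen (3 ≤ n ≤ 5000, constant
samples rejected), Wilcoxon–Mann–Whitney (exact enumeration for tie-free
samples with n ≤ 8 per group, otherwise tie-corrected normal approximation
with continuity correction), Pearson chi-square without continuity
correction (positive expected counts required).

GEE: Gaussian family, identity link, exchangeable working correlation,
cluster = mother, coefficients iterated to 1e-8 (max 100 iterations),
robust sandwich covariance, two-sided Wald tests. Singleton clusters
reduce exactly to OLS. When the jointly iterated exchangeable correlation
two-cycles (its moment update is unstable when scan pairs are scarce, and
statsmodels does not constrain it to the feasible range), the correlation
is frozen at the stable one-step moment estimate from OLS residuals,
clipped strictly inside (−1/(max cluster − 1), 1), and the coefficients
are solved under that fixed structure; the fit records which path was
taken. A constant outcome yields the degenerate exact fit (intercept =
constant, zero slopes, no sampling variability).

Least-squares means are model predictions at cohort 0/1 with all other
covariates at their fitted-sample means (sex at its sample proportion);
with the identity link the LS-mean difference equals the cohort
coefficient to machine precision. BH-FDR q-values (step-up with the
monotonicity pass) are computed within declared outcome families — 6
tissues, each feature's 4 lobes, or the 3 global features. Inter-rater
agreement uses ICC(2,1) (two-way random, absolute agreement, single
measure) from the ANOVA mean squares. Growth curves are least squares:
exponential fits are log-linearized (`y = exp(a + b·GA)`, requiring
positive outcomes), feature fits are linear.

The battery enumerator is deterministic and order-stable; Step 3's measure
list is an explicit input (default `{PSS, EPDS}`) rather than re-derived
from Step-1 results, so enumeration counts are stable. The sensitivity
scenarios are GA ≥ 28 weeks and maternal age ≤ 40 years (applied to
mothers; maternal age is constant within mother so the row filter is
equivalent). Sex is coded female 0 / male 1.

## Numerical and design choices

* `patch_radius` default 15 mm: fetal brains are small; the adult-scale
  convention is scaled down. It must exceed three mean edge lengths.
* Anti-alias σ = 1 voxel; smoothing iterations default 0.
* Region-assignment ties (exact equal distances) go to the smallest label.
* Volumes are integer label counts — no partial-volume modelling.
* Problem sizes in the test and acceptance runs: geometry oracles on
  20–30 mm phantoms at 1 and 0.5 mm; recovery and null-calibration studies
  use 200 mothers × 200 replicates and 202-mother null cohorts × 200
  replicates respectively.

## Limitations

* The folding model is a smooth global perturbation, not developmental
  sulcation; its LGI/depth responses are qualitative knobs, not fetal
  gyrification trajectories.
* Graph geodesics (even chord-augmented) slightly overestimate true
  surface geodesics; the residual ≤ 1.5 % distortion biases LGI low by
  ≤ 3 % relative, uniformly across conditions.
* The hull-ball correspondence for the LGI denominator is one reading of
  "the corresponding hull area"; monotonicity results do not depend on it,
  absolute LGI values do.
* Exchangeable-correlation estimates in very small strata are frozen
  one-step estimates rather than fully iterated solutions.
* No mixed-effects alternative, no imputation of missing distress scores,
  no small-sample GEE corrections.
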