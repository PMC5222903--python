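# Methods

`vfinterp` benchmarks nine nonparametric scattered-data interpolators for
static visual-field (perimetry) data. This note records the models,
conventions, and numerical choices the package commits to, and what its
synthetic cohorts can and cannot establish.

## Data model

A perimetry examination is a point cloud {(xᵢ, yᵢ, zᵢ)}, i = 1…N, of retinal
locations in visual-field degrees (x positive toward the subject's right, y
positive superior) with differential luminance sensitivities zᵢ in dB
(0 = blind, ~32–35 = healthy fixation). The default test grid has N = 164
locations on radial spokes over concentric elliptical rings, spanning 135°
horizontally and 125° vertically, binocularly symmetric (negating x maps an
OD grid onto the OS grid) and centrally condensed. Exact clinical grid
coordinates are not public; the ring layout here is frozen so that the point
count, extents, symmetry, condensation, and a mean pairwise separation of
49.5° (reported: 48.3°) all hold. "Mean separation" is the mean over all
N(N−1)/2 unordered pairs — a nearest-neighbor mean would be an order of
magnitude below the reported figure on a ±67.5° domain.

The physiologic blind spot is handled positionally: points within 6.0° of
(+15.0°, −1.5°) for OD (mirrored for OS) are excluded from *metric
evaluation only*; they remain interpolation inputs. A sensitivity-driven
detection rule could be substituted by changing the radius/center.

## Interpolators

All nine methods share a `fit`/`predict` contract and are pure interpolators
(training sites reproduced to 1e−6 dB):

| method | construction | notes |
|---|---|---|
| NN | nearest neighbor | ties → lowest training index |
| Lin | barycentric linear on Delaunay | undefined outside hull |
| Cub | Clough–Tocher C¹ cubic on Delaunay | gradient estimation as in scipy |
| NatN | Sibson natural neighbor | own implementation, see below |
| IDW | Shepard, weights d^(−2), all points | value at a datum = the datum |
| IDW2 | IDW restricted to a cutoff radius | radius = mean grid separation |
| RBFlin | φ(r) = r, unaugmented | interpolation matrix invertible as-is |
| RBFtps | φ(r) = r² log r + affine term | side conditions Pᵀw = 0 |
| Krig | ordinary Kriging, exponential model | variogram fitted per exam |

Out-of-hull queries for Lin/Cub/NatN are resolved by a configurable fallback
(default: nearest training value, flagged and counted). This matters for
leave-one-out folds at hull vertices, where the reduced hull cannot contain
the held-out location; the per-exam fallback count is reported so its
influence is auditable.

The thin-plate spline is augmented with an affine polynomial (it is
conditionally positive definite of order 2; augmentation also gives it exact
linear precision). The linear kernel is used unaugmented. Both choices are
toggleable (`rbf_augment`).

### Natural neighbor

Sibson weights are computed per query from the Bowyer–Watson cavity of the
precomputed Delaunay triangulation: inserting q destroys every triangle
whose circumcircle contains q, and within a destroyed triangle (a, b, c)
with circumcenter x the area stolen from a is the signed area of
(circumcenter(q,a,b), x, circumcenter(q,a,c)); summing over the cavity gives
the exact area-stealing decomposition (verified against a half-plane Voronoi
construction in the tests). Two degeneracies are handled: a query collinear
with a data-point pair sends a circumcenter to infinity (retried under a
deterministic sub-1e−6° perturbation), and a query near a Delaunay edge
produces circumcenters of magnitude R ≈ L²/8h whose areas cancel
catastrophically in double precision (R² ε ≈ 1e−3 dB at h = 5e−7°); such
queries are recomputed in extended precision, keeping the interpolant
continuous to <1e−3 dB across 1e−6° steps.

### Kriging

The empirical semivariogram uses 12 equal-width lag bins over
(0, max distance/2], γ = half the mean squared value difference, fitted by
pair-count-weighted least squares to γ(h) = nugget + (sill −
nugget)(1 − e^(−h/range)). The *predictor*, however, pins the nugget at
zero by default: an exponential covariance has no nugget term, and a
nugget-ful Kriging predictor is a smoother, not a pure interpolator, which
would break the exactness contract shared by all nine methods and hand
Kriging a noise-filtering advantage none of its competitors get. Nugget
estimation remains available (`krig_nugget="fit"`), and the standalone
variogram fit keeps its general nugget parameter. On optimizer failure the
fit falls back (flagged) to nugget 0, sill = sample variance,
range = mean lag/3. The ordinary-Kriging system carries the unbiasedness
constraint (weights sum to 1); singular systems get one 1e−10 diagonal
jitter retry, which also covers the constant-field case (sill = 0).

## Accuracy evaluation

Truth for an eye is the per-location mean over its replicate exams. For each
exam and method, location k is predicted from the other N−1 measured points
and the modified residual e_k = ẑ_k − z̃_k is taken against the truth value,
not the held-out measurement — the quantity of interest is recovery of the
underlying sensitivity. Metrics over the N_b kept (non-blind-spot)
locations: MAE, RMSE, and Willmott's modified index of agreement
d₁ = 1 − Σ|e_k| / Σ(|z̃_k − z̄| + |ẑ_k − z̄|) ∈ [0, 1], with z̄ the kept-set
truth mean; a zero denominator (constant, perfectly predicted field) returns
1 by convention. Parameters defined per examination — the IDW2 radius and
the Kriging variogram — are resolved once on the full exam and shared by all
folds. The specialized leave-one-out paths (vectorized Shepard/NN, submatrix
solves for RBF/Kriging) are tested fold-for-fold against literal refitting.

## Surfaces and smoothness

Hill-of-vision surfaces are built by interpolating an exam, augmented with
72 zero-dB boundary points on a 120° circle (equal 5° spacing, first point
at angle 0; a boundary point colliding with a datum is shifted by half a
step), onto a 501×501 lattice spanning ±90° (spacing 0.36°). Matrix axis 0
indexes x ascending, axis 1 indexes y ascending. Smoothness is
TV₁ = √(mean over Ω of |∇x h|² + |∇y h|²) and TV₂ with second differences,
where the first differences are forward with wrap-around at the last index
and the second differences central with wrap at both ends — implemented
exactly as specified even though wrapping a visual field is physically odd,
because the mask Ω (lattice points inside the convex hull of the
*non-augmented* test grid, closed hull, on-edge points inside) never touches
the wrap-affected rows/columns for the default geometry (hull half-width
67.5° < 90°). Both conventions are covered by tests with and without masks.

## Synthetic cohort

The generator emulates the study cohort structure exactly: 10 normal
subjects (46 exams) and 10 RP patients (83 exams), both eyes, with the
published per-eye replicate schedule frozen as the default; other subject
counts draw replicates uniformly from a configurable range. Hills of vision
are parametric: normals are radial cones (peak 32 dB at fixation, slope
0.25 dB/°, values clamped to [0, 35] dB — the realistic span of size-V
static perimetry) with a 0-dB blind-spot disc of radius 4°; RP phenotypes
are a mid-peripheral ring scotoma (Gaussian annulus subtracted in dB, which
is multiplicative suppression of linear sensitivity) or concentric
constriction (preserved central island with a 5° linear ramp to the 0-dB
floor). Test–retest noise is homoscedastic Gaussian, SD 2.5 dB, clamped to
the dB range; the reliability flag is a Bernoulli pass/fail with default
fail rate 0 (the emulated counts are *admitted* exams).

What the generator does not emulate: fixation instability, fatigue and
learning effects, sensitivity-dependent (heteroscedastic) noise, staircase
quantization, and the non-stationary spatial error structure of real
patient fields. Consequences are visible in the benchmark: the synthetic
fields are second-order stationary with Gaussian noise — the regime in which
an exponential-model Kriging predictor is near-optimal by construction — so
Kriging's mean MAE lands within a few hundredths of a dB of the linear RBF
and frequently takes a top-three slot, whereas clinical data (with exactly
the pathologies listed above) ranked it mid-pack. A green accuracy test here
therefore establishes the correctness of the pipeline and the qualitative
ordering of the non-Kriging methods, not the clinical ranking of Kriging.

## Statistics

Interpolators are compared pairwise with one-tailed Wilcoxon signed-rank
tests (pairing unit: the examination; zero differences dropped; exact null
for ≤25 untied differences, otherwise tie-corrected normal approximation
with continuity correction), only in the direction where the reference
method had the better mean ("better" is metric-specific: smaller for
MAE/RMSE/TV, larger for d₁). The significance level is Bonferroni-corrected
across the nine methods to 0.05/9 ≈ 0.0055. Normal-vs-patient contrasts use
two-tailed rank-sum tests at 0.05. Eye-level clustering is ignored (no
clustering adjustment is defined for the emulated analysis); Pratt's
zero-handling is not implemented, only the drop-zeros convention.

## Numerical conventions

- Geometric degeneracy tolerance 1e−9 (degrees² scale); coincident-query
  tolerance 1e−9°.
- Linear systems: dense LU/solve with one 1e−10 diagonal-jitter retry;
  solutions validated to a residual norm < 1e−6 relative.
- Canonical point order: lexicographic by (x, y) rounded to 1e−6°, matching
  the 6-decimal CSV format so ordering survives file round trips.
- All randomness flows from a single integer seed through
  `numpy.random.default_rng`; cohort generation, the pipeline, and the CLI
  are bit-for-bit reproducible given (config, seed).

## Known limitations

- The Clough–Tocher construction is a stand-in for whichever proprietary
  "cubic" gridding the original analysis used; agreement is structural, not
  numeric.
- Natural-neighbor evaluation is ~0.3 ms/query; dense 501² surfaces take
  minutes per exam on one CPU.
- The comparison tables treat every exam as independent; replicate exams of
  one eye share a truth field and are therefore positively correlated,
  which makes the signed-rank p-values anti-conservative at cohort scale.
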