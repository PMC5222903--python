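# vfinterp

Benchmarking scattered-data interpolators for static visual-field
(perimetry) data.

Standard automated perimetry measures differential light sensitivity (in dB)
at a sparse, irregular set of retinal locations — a sampled "hill of vision"
(HOV). Clinicians and researchers interpolate these point clouds to
visualize fields, unify disparate test grids, and compute volumetric or
contour-based endpoints, so the choice of interpolator matters. `vfinterp`
implements nine widely used nonparametric scattered-data interpolators
behind one `fit`/`predict` contract and the machinery to compare them on
accuracy and surface smoothness:

- **NN / Lin / Cub / NatN** — nearest-neighbor, barycentric linear,
  Clough–Tocher C¹ cubic, and Sibson natural-neighbor interpolation on the
  Delaunay triangulation of the test grid;
- **IDW / IDW2** — Shepard inverse-distance weighting with power 2, global
  and radius-localized (cutoff = mean pairwise grid separation);
- **RBFlin / RBFtps** — radial basis functions with kernels φ(r) = r and
  φ(r) = r² log r (affine-augmented);
- **Krig** — ordinary Kriging with an exponential semivariogram fitted per
  examination.

Accuracy is assessed by leave-one-out cross-validation against
replicate-averaged truth: with z̃ the per-location mean over an eye's
repeated exams, each location k is predicted from the other N−1 points of
one exam and scored by the modified residual e_k = ẑ_k − z̃_k. Blind-spot
locations are excluded from the metrics (MAE, RMSE, and Willmott's modified
index of agreement d₁ ∈ [0, 1]). Smoothness is assessed on dense 501×501
HOV surfaces spanning ±90° (built after augmenting each exam with 72
zero-dB boundary points on a 120° circle) via first- and second-order
isotropic total variation over the convex hull of the test grid:

    TV₁(h) = sqrt( mean_Ω |∇x h|² + |∇y h|² ),
    TV₂(h) = sqrt( mean_Ω |∇xx h|² + |∇yy h|² ).

Method differences are tested with one-tailed Wilcoxon signed-rank tests at
a Bonferroni-corrected level 0.05/9 ≈ 0.0055, and normal-vs-patient
differences with two-tailed rank-sum tests.

Because clinical perimetry data are not redistributable, the package ships a
synthetic cohort generator (parametric normal and retinitis-pigmentosa
hills of vision, 164-point radial test grid, replicate exams with Gaussian
test–retest noise) so the whole pipeline runs end to end from a single seed.
See `docs/methods.md` for the models and their limitations.

## Worked example

```python
import vfinterp as vf
from vfinterp.io import evaluate_examinations
from vfinterp.stats import records_to_frame

cfg = vf.CohortConfig(n_normals=1, n_patients=1, exams_per_eye=(2, 2), seed=42)
exams = vf.simulate_cohort(cfg)                       # 8 exams, 164 points each
records = evaluate_examinations(exams, vf.METHODS, vf.BlindSpotSpec(),
                                surface_n=101)        # LOOCV + smoothness
df = records_to_frame(records)
print(df.groupby("method")[["mae", "rmse", "d1", "tv1", "tv2"]]
        .mean().sort_values("mae").round(3))
```

prints

```
          mae   rmse     d1    tv1    tv2
method
Krig    1.862  2.754  0.829  1.230  0.794
RBFlin  1.901  2.766  0.828  1.277  0.770
NatN    2.053  3.218  0.807  1.295  0.859
RBFtps  2.217  3.051  0.804  1.479  0.857
Lin     2.223  3.555  0.798  1.409  1.056
Cub     2.586  3.641  0.771  1.611  1.027
NN      3.032  5.229  0.745  3.236  4.676
IDW2    3.203  3.965  0.686  1.317  1.512
IDW     3.642  4.308  0.614  1.297  1.500
```

Reading the table: MAE/RMSE are mean LOOCV errors in dB against the
replicate-averaged truth (lower is better); d₁ is bounded agreement (higher
is better); TV₁/TV₂ are surface roughness in dB per cell and per cell²
(lower is smoother). The RBF, natural-neighbor and Kriging interpolators
recover the underlying field to ~2 dB; piecewise-constant NN surfaces are
roughest by an order of magnitude in TV₂, and global Shepard weighting (IDW)
trades smooth-looking TV₁ for the worst point accuracy — the same
qualitative structure seen on clinical data. (On synthetic stationary
fields Kriging also scores near the top; see `docs/methods.md` for why that
flatters it relative to clinical practice.)

The same pipeline is scriptable from the shell:

```sh
vfinterp simulate-cohort --out cohort.csv --seed 7
vfinterp evaluate-loocv --exams cohort.csv --out metrics.csv --surface-n 101
vfinterp compare --metrics metrics.csv --out tables/ --reference RBFlin
# or in one shot, from a flat YAML config:
vfinterp run --config run.yaml --out results/ --seed 7
```

`run` writes the cohort CSV, per-exam metric records, optional dense-surface
files, comparison tables (method means, one-tailed p-values with Bonferroni
flags, and normal-vs-patient rank-sum p-values), and a manifest capturing
the config, seed, and package version; reruns with the same seed are
bit-for-bit identical.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch — synthetic cohort generation,
leave-one-out accuracy for all nine interpolators, dense-surface smoothness,
and the nonparametric comparison — on a seeded, scaled-down cohort, and
writes the machine-readable result file.
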