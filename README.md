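# leafspec

Hyperspectral inversion of leaf nitrogen content for apple orchards:
a tested, reusable implementation of the full chain from leaf reflectance
spectra (400–2500 nm) to an interpretable nitrogen prediction.

Leaf nitrogen (% dry mass) drives photosynthesis, yield and fruit quality,
but the reference measurement (Kjeldahl digestion) is destructive and slow.
Reflectance spectroscopy offers a non-destructive alternative: pigment
absorption in the visible, the red-edge rise near 700 nm, water bands at
1450/1940 nm, protein (amide/C–H) bands near 2045–2215 nm and
structural-carbohydrate bands near 2324–2394 nm all shift with nitrogen
status.  `leafspec` implements the complete inversion workflow used in
recent orchard phenotyping studies:

1. **Synthetic data** — ASD FieldSpec-style leaf spectra with a
   nitrogen-dependent absorption model and stage-specific (NSS/ASS)
   nitrogen distributions, standing in for undeposited field data;
2. **Preprocessing** — Savitzky–Golay smoothing, SG second derivative,
   multiplicative scatter correction (MSC), standard normal variate (SNV),
   per-wavelength Pearson screening;
3. **Sampling** — Mahalanobis-distance outlier removal in PCA score space
   and SPXY (joint X–Y Kennard–Stone) train/test partitioning;
4. **Wavelength selection** — CARS (competitive adaptive reweighted
   sampling, PLS-based Monte-Carlo elimination with an exponentially
   decreasing retention schedule) followed by SPA (successive projections,
   minimal-collinearity forward selection);
5. **Models** — random forest, RBF-SVM with grid-search CV, a 1-D
   convolutional network (two conv/ReLU/max-pool blocks, dropout, dense
   head — implemented in numpy with verified gradients), and a PSO-CNN
   whose learning rate, batch size and L2 coefficient are tuned by
   global-best particle swarm optimization;
6. **Evaluation** — R², RMSE, both RPD conventions, residual diagnostics
   (±1 sd coverage, histogram, normal Q–Q), and cross-stage validation on
   an independent phenological stage;
7. **Interpretation** — exact (coalition-enumeration) and sampled Shapley
   values with rankings and beeswarm-ready exports.

The core quantities: R² = 1 − Σ(yᵢ−ŷᵢ)²/Σ(yᵢ−ȳ)², RMSE = √(Σ(yᵢ−ŷᵢ)²/n),
RPD = sd(y)/RMSE (values > 2 indicate strong models, 1.4–2.0 moderate),
and Shapley values φᵢ = Σ_S |S|!(p−|S|−1)!/p! · [f(S∪{i}) − f(S)] with
out-of-coalition features at training means.  See `docs/methods.md` for
the full model description, defaults, and limitations.

## Worked example

```python
from leafspec.model import NitrogenInversion

inv = NitrogenInversion.from_synthetic("NSS", seed=42)   # n=125 leaves
res = inv.fit(models=("rf", "svm"), seed=42)
print(res.summary())
```

```
Leaf nitrogen inversion results
================================================================
samples: 121 (train 73, test 48; 4 outlier(s) removed)
selected wavelengths (20): 400, 411, 427, 463, 467, 476, 536, 699, 705, 1359, 2184, 2344, 2357, 2362, 2379, 2401, 2429, 2456, 2485, 2491 nm
selection RMSE: 0.0714
----------------------------------------------------------------
model    set          R2    RMSE     RPD    RPD*
rf       train     0.957   0.043   4.835   4.413
rf       test      0.740   0.074   1.983   1.695
svm      train     0.979   0.030   7.017   6.794
svm      test      0.703   0.079   1.856   1.884
----------------------------------------------------------------
RPD = sd(observed)/RMSE; RPD* uses predicted deviations
```

Four spectral outliers were screened out, SPXY kept 73 training and 48
test leaves, and CARS–SPA reduced 2101 bands to 20 — pigment/blue bands,
the red edge (699/705 nm), a water band (1359 nm), a protein band
(2184 nm) and a structural-carbohydrate cluster.  On the held-out test
set the random forest explains 74 % of nitrogen variance with an RMSE of
0.074 % N; RPD ≈ 2.0 grades it at the strong/moderate boundary.

Shapley attribution of the forest (`res.explain(kind="rf")`) ranks the
red-edge and protein bands first, and the sign column shows the expected
physiology — higher reflectance at red-edge/protein bands means *less*
absorption, hence lower predicted nitrogen (negative correlation), while
structural-carbohydrate bands act in the opposite direction:

```
 rank  wavelength_nm  mean_abs_shap  value_shap_correlation
    1          699.0       0.077444               -0.844633
    2          705.0       0.044292               -0.839684
    3         2184.0       0.019243               -0.821542
    4         2362.0       0.007073                0.632965
    5         2344.0       0.005201                0.408640
```

The CNN and PSO-CNN train the same way (`models=("cnn", "pso-cnn")`);
`leafspec.pipeline.run_all` executes all four models plus cross-stage
validation and SHAP in one call with a provenance manifest, and the
`leafspec` command line exposes the stages individually:

```bash
leafspec simulate --stage NSS --n 125 --seed 42 --out nss.csv
leafspec preprocess --method sg-sd nss.csv nss_sd.csv
leafspec split --method spxy nss.csv split.json
leafspec run --seed 42 --out run_dir/     # full pipeline, all models
```

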