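# Methods

This note records the modelling choices behind `gbmprog`: the generative
model of the synthetic cohorts, the definitions of the image-derived
features, the survival-statistics conventions, the two search algorithms,
and the places where a genuinely open design decision had to be made.

## Synthetic cohorts

The generator (`gbmprog.synth`) emulates a pretreatment-GBM imaging cohort
at the level of its summary statistics, not its images.

**Feature marginals.** Age is truncated normal (center 63 y, SD 12 y,
support 19–86 y). Contrast-enhancing (CE) volume, CE rim width, and
necrotic volume are log-normal with means 19.64 cm³, 0.57 cm, 13.50 cm³
and log-scale SDs 0.9, 0.45, 1.2 — means match the published cohort table
and the SDs were chosen once so the implied ranges bracket the published
ranges. Surface regularity is a scaled Beta(4, 3.9) on (0.24, 0.99), mean
≈0.62. Total volume is CE + necrotic *by construction*. Maximum diameter is
1.52× the CE equivalent-sphere diameter times multiplicative log-normal
noise whose SD is set analytically from the target Spearman correlation
(default 0.916): on the log scale the correlation between
log V and log V/3 + ε is s/√(s² + 9σ²_ε) with s = SD(log V), so
σ_ε = (s/3)·√(1/ρ² − 1). Total surface follows the sphericity relation
S = (36π V²)^⅓ / regularity times independent log-normal noise (σ = 0.35),
because a measured surface is not a deterministic function of volume.
Noise columns are independent standard normals; the default table is
4 informative + 4 derived + 36 noise = 44 columns.

**Survival.** A Weibull-baseline proportional-hazards law: subject i with
prognostic score PSᵢ = Σ β_f x_{if} (the default β are the published
linear-model weights: +0.030/y age, −0.340/cm rim width, −1.100
regularity, +0.012/cm³ CE volume) draws

T = λ · (−log U / exp(PSᵢ − mean PS))^{1/k},  U ~ Uniform(0,1),

with shape k = 1.2 (realistically increasing hazard for GBM) and scale λ
calibrated so the median at the mean score equals 12.8 months. The PH form
was chosen because the analysis pipeline fits Cox models, making parameter
recovery well-posed. Censoring is administrative: C = c_max·V with
V ~ Uniform(0,1) and c_max found by bisection so the realized censored
fraction matches the target (~9%); observed time is min(T, C). Setting
`deterministic_survival=True` collapses U to ½, making survival a strictly
monotone function of the score (used to verify that the true model then
achieves concordance 1).

Three independent seeded streams drive features, survival, and noise
columns, so changing the noise-column count perturbs nothing else.

**What the generator does not emulate.** The 40 noise features are
mutually independent — real radiomic attributes are strongly collinear and
weakly informative. Consequences: (i) correlation-based deduplication is
exercised only through the deliberately constructed volume–diameter pair,
and (ii) the regression tree does not reproduce the discovery-side
overfitting seen with real texture features, because greedy variance
splits on independent noise isolate outliers without gaining ranking
power (see Limitations). Feature–survival links are exactly log-linear PH;
no non-proportional hazards, no informative censoring, no site effects.
Passing tests therefore demonstrate algorithmic correctness and the broad
overfitting phenomenology, not performance on real MRI cohorts.

**Tumor masks.** A radially perturbed sphere: the boundary is
r(direction) = R·(1 + a·f), where f is a Gaussian-smoothed random field on
a 64×64 latitude–longitude grid (wrap-smoothed across the seam, normalized
to max |f| = 1) and a is the irregularity amplitude. The necrotic core is
the same star-shaped region scaled by fraction^⅓, so its volume is exactly
that fraction of the total in the continuum and it is strictly interior.
R is found by bisection on the rasterized CE voxel count; at ≤1 mm
isotropic spacing the CE volume lands within 2% of target.

## Morphology (16 measures)

Voxel centers sit at integer indices scaled by the (possibly anisotropic)
spacing; internal units are mm, reported units cm/cm²/cm³.

* **Volumes** are label counts × voxel volume; total = CE + necrotic holds
  exactly because the labels partition the tumor.
* **Total surface** is the area of a marching-cubes mesh of the
  whole-tumor region. The binary volume is smoothed with a 1-voxel
  Gaussian before meshing: the level-0.5 isosurface of the raw binary
  field carries a rasterization staircase that inflates the area of a
  20 mm ball by ~9%, while the smoothed field reproduces the analytic
  sphere area to <1%. Regions too small to survive smoothing fall back to
  the raw interface.
* **Surface regularity** is the sphericity-style index
  (36π V²)^⅓ / S — equal to 1 for a perfect ball, decreasing with surface
  irregularity; the published range (0.24–0.99) fixes this orientation.
* **Maximum diameter** is the largest pairwise Euclidean distance between
  boundary-voxel centers in physical units, computed exactly via the
  convex hull (verified against the O(m²) scan).
* **CE rim width** uses Euclidean distance transforms with the physical
  spacing: with necrosis present, the mean over CE voxels of (distance to
  the outer boundary + distance to the necrotic core), which equals the
  analytic shell thickness for concentric shells; without necrosis it
  degenerates to twice the mean distance to the boundary — a
  diameter-like thickness of the solid lesion. The construction of the
  published rim width is not documented; this one is fully specified and
  scale-covariant.
* Nine auxiliary measures complete the set of 16: necrotic surface and its
  regularity, rim-width SD, equivalent spherical diameters (total, CE),
  necrotic and CE volume fractions, surface-to-volume ratio, necrotic
  maximum diameter. They are clearly named, tested for internal
  consistency, and deliberately excluded from the headline pipeline.

## Texture (28 measures)

Intensities are quantized to G equal-width bins (default G = 16, the
common radiomics default) over the in-mask range, making all co-occurrence
and run-length features invariant to affine intensity shifts. Both
matrices use the 13 unique offsets of the 3D 26-neighborhood at distance
1; co-occurrence matrices are symmetrized and normalized per direction,
features averaged over directions. Runs are maximal same-level voxel
sequences along a direction, bounded by the mask. The feature families are
the canonical ones: 12 Haralick-type co-occurrence statistics, 11
Galloway-type run-length statistics, and 5 moments of the 3D gradient
magnitude (central differences in physical spacing). All features agree
with independent brute-force pair/run enumeration to 1e-9 on random small
volumes. The exact published 28-feature list is not public; the names are
config-addressable so the set can be edited without code changes.

## Survival statistics

* **Kaplan-Meier** estimation and **Cox** fits delegate to `lifelines`
  (Efron tie handling; two-tailed Wald p-values and 95% CIs).
* The **Breslow test** is the Gehan-Breslow generalized Wilcoxon (at-risk
  weights), the standard test of that name in survival software; the
  log-rank test uses unit weights.
* The **concordance index** follows the non-censored convention: censored
  subjects are removed, all event pairs with distinct survival times are
  compared, score ties count ½, time-tied pairs are excluded. This is
  deliberately *not* Harrell's censoring-aware pair rule; it matches the
  convention under which the published c-indexes were computed. It is
  verified to equal exhaustive pair enumeration exactly.

## Cutpoint search

Candidate thresholds are midpoints of consecutive distinct sorted values
whose two arms each hold ≥10% of the cohort (the floor prevents
1-vs-(n−1) splits; the published work is silent here). The weighted
observed-minus-expected statistics for *all* candidate splits are computed
in one vectorized pass over (event time × subject rank) membership
matrices, which equals the per-split test exactly and makes exhaustive
scans cheap. A significant threshold (p < 0.05) is *non-isolated* when all
candidates within a window of 1 position on each side are significant too
(the published rule names the concept but not the window; it is
configurable). The best non-isolated significant threshold by log-rank p
is returned with its Gehan-Breslow p, the hazard ratio with Wald 95% CI
from a Cox fit on the binary indicator, and the dichotomized concordance
index; if none qualifies, the overall best-p split is returned flagged
not-significant.

## Coefficient grid search

The per-coefficient grid is an inclusive evenly spaced `linspace` with
`subintervals` points over (B − f·B, B + f·B), f = 0.25 — endpoint
handling is unstated in the source description, and the inclusive choice
contains the seed-adjacent points. A zero seed coefficient collapses its
grid to {0} (±25% of zero is zero); `subintervals = 1` or `f = 0`
reproduces the seed exactly (identity limit). For each candidate
coefficient vector, the best dichotomizing threshold of the score is found
by maximizing the dichotomized concordance index — a deliberately
different inner criterion from the univariate screen's minimum p-value,
mirroring the study design. The sweep is O(n²) per candidate: with event
subjects sorted by score, concordant cross-group pair counts for every
threshold come from a 2-D prefix sum of the pairwise "died earlier"
matrix, whose time-comparison part is fixed across candidates. Ties in
the achieved c-index break toward the first candidate in lexicographic
grid order. The full 30⁴ grid at n = 311 completes in ~25 minutes on one
CPU; tests and the orchestrated study default to 7 points per coefficient
(tests of the oracle equivalence use 5), with grids above 10⁶ candidates
refused unless forced.

## ML comparators

All models regress *observed survival months* on features, restricted to
subjects whose death was observed — the study's target and censoring
handling are undocumented, and this choice matches its non-censored
concordance convention. Features are min-max normalized to [0, 1] with
statistics learned on training rows only (so ε = 0.01 "with respect to
normalized data" is concrete); z-scoring is available by config.

* **ANN** — one hidden layer of ⌊(n_features+1)/2⌋ sigmoid units, linear
  output, weights initialized uniform in ±1/√fan-in from the seed,
  trained by full-batch gradient descent on MSE with momentum 0.5,
  learning rate 0.01, 200 iterations. "Simple SGD" is ambiguous between
  full-batch and per-sample; full-batch is deterministic given the seed
  and is the choice here (configurable).
* **SVR (RBF)** — `sklearn.svm.SVR`, ε = 0.01, γ = 1.0, C = 0.001.
* **RFF kernel regression** — the Gaussian kernel is linearized by 200
  random Fourier components (frequencies ~ N(0, 2γI), phases ~ U(0, 2π),
  z(x) = √(2/D)·cos(xW + b)); the linear head is SGD with squared-ε loss
  (ε = 0.01) and the trade-off parameter mapped to the ridge weight
  (α = 0.01).
* **Regression tree** — exact greedy variance-reduction splitting, depth
  ≤5, minimal decrease 0.1 in weighted-impurity units (months²; the
  alternative reading — 10% of root SSE — collapses every tree on
  weak-signal survival data to a single leaf). 50–50 pruning: the tree is
  grown on a random half of the training rows and pruned bottom-up on the
  held-out half, collapsing a subtree only when its leaf has strictly
  lower held-out SSE; nodes no validation row reaches are left as grown.
* **Forest attribute filter** — repeated random train/test splits; an
  extremely randomized forest (10 estimators, depth 5, min leaf 20, min
  split 40, min impurity decrease 0.1) qualifies when its test RMSE beats
  the baseline by ≥5%, the baseline being the constant
  train-mean predictor (undefined in the source; this is the natural
  null model). Scores are the summed importances of qualifying forests;
  zero qualifying iterations is a valid outcome on pure noise. The full
  design uses 10 000 iterations; the orchestrated study scales this down
  (default 300) since the ranking stabilizes far earlier on synthetic
  cohorts.
* **CV attribute search** — candidate subsets from the top-ranked
  features; per subset, 20 random folds each holding out 50 subjects;
  winner = best mean RMSE among subsets within 0.005 of the best mean
  c-index. The threshold carried to validation is the best-c-index fold's
  optimal cutpoint of its test predictions (the source rule "best obtained
  during CV" does not pin this down).

## Orchestrated study

`run_study` wires the stages together with seeds derived deterministically
from the study seed, so a rerun from the persisted JSON config is
bit-identical. Only clinical + morphological columns enter the
linear-model screen — the noise columns stand in for textural attributes,
which feed the ML comparators only (using the best-split p of a pure-noise
feature in a marginal screen would otherwise admit almost everything,
because the scan minimum is multiplicity-biased). Correlation
deduplication is greedy, best p first: a feature is dropped only in
favour of a feature that is itself kept. The study defaults
(`subintervals = 7`, `rf_iterations = 300`) keep a complete run in the
minutes range; the full-design values (30, 10 000) are plain config
settings.

## Known limitations

* The screen's per-feature p-values are scan minima and carry no
  multiple-testing correction — faithful to the study design, which
  applies none; they should be read as ranking scores, not calibrated
  error rates.
* Under the synthetic conditions (independent Gaussian noise features,
  heavy-tailed survival), the regression tree does not show the
  discovery-side overfitting direction that flexible global models (ANN,
  kernel regressions) show clearly; see the generator section for the
  mechanism.
* The dichotomized concordance index is structurally capped below 1
  (same-group pairs count ½), so dichotomized and continuous c-indexes
  are not directly comparable; the pipeline reports continuous c for Cox
  and the ML models and dichotomized c for the threshold-frozen linear
  model, matching each method's usage.
* NIfTI-1 stores voxel spacing in float32; round-trips are exact at that
  precision.
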