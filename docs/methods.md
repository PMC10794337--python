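# Methods

## Cell shape model

A cell boundary is an ellipse with a sinusoidal radial perturbation,

    r(θ) = r_ellipse(θ) · (1 + ε · sin(kθ + φ)),

with semi-axes a ≥ b, irregularity amplitude ε, protrusion count k and
phase φ. The perturbation drives solidity below 1 in a controlled way
(k ≥ 3), which is what the descriptor panel's boundary-sensitivity
claims rest on. All ground-truth descriptor values are computed from a
dense polygonal sampling of this boundary (360 vertices): area and
perimeter by the shoelace/arc-length formulas, axes from the polygon's
central second moments (Green's theorem closed forms, axes = 4·√eigenvalue
of the region covariance — the moment-equivalent-ellipse convention),
convex hull area via Qhull. Generator and pixel measurements therefore
share one geometric definition, and the scene→segment→measure round
trip can be scored against analytic truth.

## Class geometry sampling

Each phenotype class samples three independent factors per cell: area
A (lognormal), aspect ratio q (lognormal, ≥ 1) and irregularity ε
(normal, clipped to [0, 0.45]); protrusion count k is uniform on
{3..8}. Semi-axes follow as a = √(Aq / (π(1+ε²/2))), b = a/q, so
minor ≤ major always holds and the enclosed area matches the sampled A.
Size and elongation are deliberately independent generative factors:
spreading area and polarization vary separately in cultured
macrophages, and sampling the two axes instead would make area a
deterministic function of (major, aspect), collapsing the panel's
effective rank — with the side effect that no attribution method could
distinguish the coupled features (exact functional duplicates receive
equal Shapley values by symmetry).

The same reasoning sets the within-class spreads. Roundness equals
1/(q·g) where g = (π/4·major·minor)/A ≈ 1 + c·ε² is the moment-inflation
factor of the boundary perturbation; with a wide within-class aspect
spread, roundness is a functional duplicate of aspect ratio. The
defaults (aspect sd = 0.15·mean, ε sd = 0.12, giving sd(log g) ≈ 0.06
and pooled corr(aspect, roundness) ≈ −0.93) keep the duplication broken
so that models must engage the true factors.

Default class parameters (area µm² / aspect / ε means):
M0 330/1.30/0.05, GM-CSF-M1 520/1.40/0.10, GM-CSF/TNFα/IFNγ-M1
600/1.75/0.18, M-CSF-M2 450/1.26/0.07, M-CSF/IL-4-M2a 760/1.70/0.22,
M-CSF/IL-10-M2c 700/1.38/0.12; area sd = 0.45·mean throughout. These
were calibrated once so that the six-class single-cell problem is
genuinely hard (stratified 70/30 random-forest test accuracy ≈ 0.40,
i.e. ≤ 0.50) while class means remain distinct enough for tile-level
separation — the operating point in which balanced aggregation is the
mechanism of interest — and frozen. Class sizes default to the study's
counts (353/3078/1891/1321/1077/1584; 9304 cells). Donor structure is a
per-donor multiplicative size shift (unit-mean, sd 0.03, 3 donors); no
further batch effects are modelled.

## Marker couplings

Marker intensity is a deterministic function of true shape plus
additive Gaussian noise floored at 0. Couplings are linear, log-linear
or constant in the descriptor panel. Noise is specified either as an
absolute sd or as a noise share (fraction of realized cohort-wide
signal variance); the default intracellular IL-10 coupling is linear in
area (0.004/µm²), major axis (0.10/µm) and aspect ratio (2.0), identical
across classes, at a 5% noise share — so a perfect regressor tops out
near R² = 0.95, and each of the three coupled features contributes
comparable variance on its natural scale. CD80/CD163 get class-dependent
intercepts (high in M1-like vs M2-like classes) with a mild area
coupling, emulating marker panels that corroborate but do not determine
the phenotype.

## Scenes and imaging model

Scenes render each cell's body at a constant F-actin level (140), a
nuclear disk (radius 0.35·b, level 180) and marker channels filled at
the cell's true per-pixel marker level, over constant backgrounds
(8/10/6) with Gaussian read noise (sd 2) floored at 0. Default sampling
is 0.65 µm/px (typical 10× objective with a standard camera sensor) on
1024×1024 scenes. Placement is rejection sampling of bounding circles
with configurable overlap tolerance (default 0 = non-overlapping) and a
per-cell retry budget; exceeding it raises a layout error. No optics
(PSF, vignetting, photobleaching) are simulated: passing recovery tests
shows the measurement chain is unbiased on resolution-limited
discretization, not that segmentation would survive real haze, debris
or dense cell contact.

## Segmentation

The Fiji-style recipe: Otsu binarization of the actin channel
(foreground strictly above threshold; constant images raise a
degenerate-input error), nucleus detection by Otsu + size filter
(≥ 10 px) with single-linkage merging of seeds closer than 5 px,
watershed of the negated Euclidean distance transform of the body mask
flooded from the nucleus seeds, then removal of cells < 50 px and
(by default) border-touching cells, with survivors re-labelled from 1.
Foreground components containing no seed keep a connected-component
label so the watershed output partitions the mask exhaustively.
Whether the original distance map is mask-based or inter-nucleus
Voronoi is ambiguous; both coincide on well-separated convex-ish cells,
which the fixtures use.

## Morphometry

Area, moment axes and solidity come from scikit-image regionprops
(pixelized convex hull — the ImageJ-family convention). The perimeter
estimator is the 4-direction Crofton formula: naive or √2-weighted
boundary-step counting overestimates a digitized disk's circumference
by ~5%, pushing circularity to 0.91 where the analytic value is 1,
while Crofton is within 1.6% at r ≥ 20 px; since circularity of a disk
must approach 1, Crofton is the right estimator and its value is frozen
by test (10×10 square → 36.8117). Circularity and solidity are clamped
to ≤ 1 against discretization overshoot. Background for intensity
measurements is the per-channel median of non-cell pixels. Bead
calibration is an OLS line intensity ~ exposure (≥ 2 distinct
exposures); normalized intensity = raw / predicted bead intensity,
which is exposure-invariant by construction and errors on nonpositive
predictions.

## SuperTiles

Within a tile, t rows are drawn uniformly *without* replacement (a
subset of the class); tiles are drawn independently, so s > 1
bootstraps the class with replacement across tiles. Per-class tile
count is floor(n_minority·s/t) — flooring never exceeds the balance
budget. Aggregation is the arithmetic mean of every numeric feature;
donor ids are dropped (tiles average across donors) while provenance
keeps source row indices, which is what the leakage check in mixed
training uses. Without-replacement sampling contracts tile variance by
(σ²/t)·(N−t)/(N−1); the finite-population factor is ~0.89 for the
minority class at t = 40 and negligible elsewhere, well inside the 20%
band the variance-contraction test allows. The printed per-class tile
counts of the study's sweep cannot be reconstructed from the balance
formula with any single (t, s), so the sweep API exposes the (t, s)
grid explicitly and tags each block instead of guessing an
accumulation scheme.

## Models and metrics

Random forests (100 trees) on z-scored predictors; the scaler is fit on
the training split only. Splits are stratified 70/30; training uses
10-fold cross-validation (per-fold metric table reported), and
repeated-seed sweeps may skip the fold loop. Classifiers use
scikit-learn's sqrt(p) feature subsampling. Regressors default to
max_features = 0.5 (3 of 7 candidates per split): the shape panel is
strongly collinear, and a regression forest that considers every
feature at every split funnels all importance into one member of each
correlated group, so moderate subsampling is required for attribution
to reflect the true couplings (it also matches the p/3 regression
folklore). Feature attribution is permutation importance (10 repeats)
computed on the held-out split and flagged as such in the output;
full-cohort attribution was measured to systematically favor proxy
features and is not used.

Metric panel: accuracy, one-vs-rest macro AUC, macro recall/precision,
F1 as the per-class harmonic mean 2PR/(P+R) macro-averaged, Cohen's
kappa and multiclass MCC (both higher-is-better), validated against
direct confusion-matrix formulas to 1e-12. AUC with a single observed
class is reported as NaN, never fabricated. Regression reports R²
(NaN for a constant target), MAE, MSE, RMSE, RMSLE (values shifted to
nonnegative if needed, logged) and MAPE.

Because it is ambiguous whether headline tile accuracies should be
measured on a held-out split of the tiles or on held-out original
cells, both evaluation modes exist: `eval_on="synthetic_split"` (70/30
on the tile set) and `eval_on="original_holdout"` (tiles built from the
70% original training rows only; evaluation on the held-out 30% of
original cells, leakage-free by construction). The accuracy-lift
experiments use the synthetic split; the holdout mode is reported
separately where run.

## Group statistics

Kruskal–Wallis (scipy, tie-corrected, chi-square reference with k−1 df)
with Dunn's pairwise z-tests computed from pooled mean ranks,
σ²ᵢⱼ = (N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/nᵢ+1/nⱼ); two-sided normal
p-values are reported both unadjusted and Holm-adjusted, since the
original analysis names no multiplicity handling. All-identical values
across groups return H = 0, p = 1 rather than an error. The class-average
map z-scales class means per feature with the population (n-denominator)
sd and clusters rows and columns by complete-linkage Euclidean
hierarchical clustering; features with zero variance across class means
are excluded and logged.

## Problem sizes and determinism

Every generator and model consumes a single seeded NumPy generator; a
(config, seed) pair reproduces tables byte-for-byte and scenes
pixel-for-pixel. The test suite and acceptance script run the full
9304-cell cohort, 10-seed model sweeps, and 12–20 scenes of 50 cells at
1024² px — sizes chosen so each experiment's sampling error is well
inside its acceptance band while a complete run stays in the
single-digit minutes on one CPU.

## Known limitations

Synthetic cells are star-convex single objects: no touching-cell
clumps beyond what the overlap parameter allows, no texture inside the
cell, no nucleus shape variation, no intensity gradients. Passing the
recovery tests validates the measurement chain and the augmentation/
modeling mechanism, not real-microscopy robustness. The IL-10 coupling
is linear; real morphology–cytokine relationships need not be. Donor
effects are a mean size shift only, so donor-level confounding of
classifiers is not probed.
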