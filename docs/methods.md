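# Methods

This note documents the statistical models implemented in `burnhab`, the
design choices made where conventions genuinely diverge, what the synthetic
data generator does and does not emulate, and the numerical settings that
matter for reproducing results.

## Covariate engine

Covariates follow the two-scale logic of nest-site selection in burned
forest: birds select locally burned or open sites (nest substrate, predator
refuge) inside home ranges that retain live, closed-canopy forest (foraging).

* **Burned-or-open mask.** A pixel qualifies when ΔNBR > 270 (moderate-to-
  severe burn) or pre-fire canopy cover < 10%. Both thresholds are strict;
  ties (ΔNBR = 270, canopy = 10%) fall outside the mask. Non-forest pixels
  must carry canopy 0 in the input layer and are therefore open.
* **Neighbourhoods.** Local scale is the 3×3 window (0.81 ha at 30 m).
  Landscape scale is a disc whose radius is the whole-pixel floor of the
  metric radius: at 1 km and 30 m this is a 33-cell disc of exactly 3,409
  pixels (about 307 ha), the neighbourhood size conventional for this
  covariate set. A "centres within 1,000 m" rule would give 3,505 pixels;
  the floor convention is deliberate and tested. At raster edges the
  denominator is the intersected neighbourhood, so percentages stay in
  [0, 100] without boundary bias. Focal sums use FFT convolution and are
  verified against a brute-force loop in the tests.
* **Aspect.** Casp = cos(aspect°) with aspect clockwise from north (+1
  north-facing, −1 south-facing), forced to 0 where slope ≤ 2% because
  aspect is meaningless on near-flat ground.
* **Year handling.** Nests take covariates from the raster of the year they
  were found; non-nests average across surveyed years (they represent
  average availability); available sites use one stated year.

## Maximum-entropy model

The model is the standard presence–background Gibbs form. Features are
linear, quadratic and pairwise products of base covariates, min–max scaled
to [0, 1] over the training background; prediction clamps covariates to the
training bounds (clamped values are logged). The penalised objective

  ℓ(λ) = λ·f̄_presence − log Σ_background exp(λ·f) − Σⱼ βⱼ|λⱼ|

is concave; it is solved by splitting λ into non-negative parts and running
L-BFGS-B with the analytic gradient (ftol 1e-12, gtol 1e-10, cap 10,000
iterations), so refits from permuted data agree to ~1e-6. At β = 0 the
first-order conditions are exact moment matching, E_q[fⱼ] = f̄_presence,ⱼ,
satisfied to 1e-6 in the tests.

* **Regularisation.** The per-feature penalty is
  βⱼ = β · sd_background(fⱼ) / √(n_presence) with a single dimensionless
  multiplier β (default 1.0, configurable). Scaling by feature spread and
  presence sample size is the conventional calibration for this model
  family; a fixed absolute penalty of 1.0 on [0, 1]-scaled features would
  shrink all coefficients to zero at realistic sample sizes.
* **Logistic output.** HSI = e^H q / (1 + e^H q), where H is the entropy of
  the fitted background distribution; a site with the typical probability
  mass q = e^(−H) scores exactly 0.5.
* **Variable contributions.** Contribution of a variable is the loss of
  penalised training gain when all features involving it are removed and the
  model refitted, floored at zero and normalised to sum to 100. This
  leave-variable-out definition is deterministic and well defined, unlike
  the path-dependent per-iteration attribution of the original maximum-
  entropy software; it is a deliberate deviation. Variables below 5% are
  dropped in a single pass and the model refitted.
* **Pooling.** For pooled fits the background is subsampled (seeded) so each
  location's share of background sites matches its share of nests.

## Weighted logistic regression and model selection

Weights w₁ = 1, w₀ = n₁/n₀ make the weighted prevalence exactly 0.5 — the
class ratio is a sampling artifact, and the fitted response is a relative
suitability index. Fitting is IRLS via statsmodels GLM (binomial family,
frequency weights); standard errors are model-based (weighted Fisher
information), not sandwich. The weighted log-likelihood is
Σ wᵢ [yᵢ log pᵢ + (1−yᵢ) log(1−pᵢ)].

* **AICc.** n in the small-sample correction is the number of observations,
  matching the default of the GLM framework the method is normally run in.
  An alternative convention (effective n = 2 n₁) can be passed explicitly
  via the `aicc` helper since it only needs (logL, K, n).
* **Enumeration.** All subsets of size 0..⌈n_nests/10⌉, size-major then
  lexicographic, including the intercept-only model. First-order linear
  terms only; no quadratics or interactions.
* **Ranking.** Ascending AICc; ties broken by smaller K then lexicographic
  subset. Akaike weights are computed over all successful candidates.
  Candidates with perfect separation (non-convergence, |coefficient| >
  1,000, or exploding/non-finite SEs) are excluded from the ranking and
  counted in the log rather than penalised.
* **Within-2-units rule.** Inclusive (ΔAICc ≤ 2.0). This matters: with the
  published per-location rankings, the boundary model at exactly Δ = 2.0
  contributes the sixth pooled candidate covariate, giving 2⁶ = 64 pooled
  candidate subsets; an exclusive rule would give 32.
* **Pooled weighting.** Observations of the location with the larger weight
  sum are multiplied by one scalar so per-location weight sums are equal.
* **VIF.** 1/(1−R²ⱼ) from unweighted OLS of each covariate on the others;
  exact collinearity reports ∞.

## Transferability evaluation

AUC is the Mann–Whitney estimator with ties counting ½ (HSIs can tie on
coarse rasters). CIs are stratified percentile bootstrap, resampling sites
within class (2,000 replicates default, seeded); percentile intervals are
widened, if necessary, to contain the point estimate so the invariant
ci_low ≤ AUC ≤ ci_high always holds. The transferability rule is strict:
lower 95% limit > 0.5. The logistic model is scored nest vs. non-nest, the
maximum-entropy model nest vs. available, mirroring each model's reference-
site definition. Site-level (not cell-level) resampling is used for AUC
CIs; cell-level resampling is reserved for the density CIs, where the
spatial unit is explicit.

## Density calibration

Reference sites are assumed to represent surveyed area, so the share of
reference sites in an HSI stratum estimates the share of area there. Only
hatched nests (≥ 1 nestling) enter this module; the filter is applied here,
not upstream, so AUC evaluation keeps all nests.

* **Moving windows.** Windows cover contiguous `window_frac` (default 0.1)
  shares of the sorted reference HSIs, advanced by `step_frac` (default
  0.01); both are configuration, not doctrine, since the originating
  description of the technique does not fix them. A window's HSI span runs
  from its first reference value (inclusive) to the first value beyond it
  (exclusive), with the outermost windows extended to ±∞ — so when step
  equals window width the windows tile the axis and window densities
  integrate exactly back to the total nest count (tested).
* **Classes.** Two thresholds, lower-inclusive: low < t₁ ≤ moderate < t₂ ≤
  high. Class area = reference share × total surveyed area; density =
  hatched nests / area; percent nests = 100 · density_c / Σ density (the
  expected split under equal-area sampling). A class with no reference
  sites has zero area and NaN density, flagged with a warning.
* **Natural breaks.** The advisory threshold finder returns the midpoints
  flanking the two largest density increases of the curve; a flat curve
  falls back to tertiles with a warning. User thresholds always override.
* **Block bootstrap.** 600-m grid cells (anchored at the raster origin,
  lower-left inclusive) are the sampling unit; cells are resampled with
  replacement preserving the cell count, class densities and percents are
  recomputed per resample (5,000 default), and CI endpoints are
  median-unbiased (type-8) quantiles, verified against the hand plotting-
  position formula (k − ⅓)/(n + ⅓). A single cell degenerates to the point
  estimate with a warning.

## Synthetic data generator

The generator exists so the whole pipeline is exercisable and testable
end-to-end. Layers are Gaussian random fields (kernel-smoothed white noise,
wrap boundary, empirically re-standardised) transformed marginally:
Gaussian ΔNBR (mean 330, SD 230, ≈ 60% of pixels above 270); canopy cover
with a 15% point mass at 0 (pre-fire openings) and a scaled Beta(2, 2.5)
body; a pine mask at probability 0.65; gamma slope (mean 15%, SD 10%,
capped at 60%); uniform aspect; zero-inflated gamma snag and tree densities
at the 50-m plot scale (medium snags mean 60/ha, large snags 10/ha, live
trees 35/ha). These marginals sit inside the ranges reported for burned
dry-conifer study areas. The burn/canopy correlation range default (600 m)
was set, once, so the local vs. landscape burned-open correlation lands
near 0.46, the value this covariate pair exhibits in real burned
landscapes; a sweep gave ≈ 0.36/0.48/0.62 at 450/600/800 m.

Nests are a weighted draw without replacement with log-weight
η = b·(LocBrnOpn, LandBrnOpn, TreeDens, PIPO_pct); the default coefficients
(+0.015, −0.037, −0.009, +0.012) carry the field-typical sign structure
and magnitudes. Exponential (log-linear) selection is what makes logistic
regression of use vs. availability consistent for the slope coefficients —
the intercept is not identified, which is why recovery checks cover slopes
only. Non-nests are uniform over pixels ≥ 35 m from every nest that hold at
least one medium-or-large snag in their plot (snag layers are generated
independently of the selection covariates, so the filter does not bias
slope recovery). Available sites are uniform random pixels. Hatch outcomes
are i.i.d. Bernoulli(0.94), independent of covariates by default — the
calibration module estimates density, not survival. Nest-per-pixel
uniqueness is enforced. The generator emits single-year values; multi-year
extraction is supported by the covariate engine but the generator does not
model between-year variance.

What passing tests therefore show: the estimators are correct on data
satisfying their assumptions (log-linear selection, representative
reference sites, independent hatching). What they do not show: robustness
to fire-physics spatial structure, territoriality/home-range clustering of
nests, observer effects, or selection–survival confounding — none of which
the generator attempts to emulate.

## Problem sizes and runtime choices

Simulation-based checks use 220×220-pixel landscapes (≈ 4,356 ha at 30 m,
the size of a large surveyed fire), 200 nests and 200 non-nests per
replicate, 100 replicates for coefficient recovery (50 in the acceptance
script), 50 replicate data sets at 500 bootstrap draws for null-AUC
coverage, and reduced bootstrap counts in pipeline smoke tests. Defaults in
the library itself remain at field scale (10,000 background sites, 2,000
AUC and 5,000 density bootstrap resamples).

## Known limitations

* The maximum-entropy implementation supports linear/quadratic/product
  features only (no hinge or threshold features) and a single β multiplier
  per fit; published variable-contribution percentages from the original
  software are therefore matched in rank order, not digit for digit.
* AUC bootstrap resamples sites, not spatial cells; spatial autocorrelation
  may make those CIs slightly anti-conservative.
* The generator's hatch flag is covariate-independent; an HSI-linked hatch
  mechanism would be needed to study selection–fitness coupling.
* No CRS handling or reprojection: all rasters must already share one grid.
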