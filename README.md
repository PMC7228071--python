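# burnhab

Habitat-suitability modelling for cavity-nesting birds in burned conifer
forest.

After a wildfire, land managers must decide quickly which stands to salvage-log
and which to retain as habitat for fire-associated species such as the
white-headed woodpecker (*Dryobates albolarvatus*), which nests in snags within
burned or open-canopy patches embedded in less-burned home ranges. `burnhab`
implements, as a tested and reusable pipeline, the statistical workflow used to
build, evaluate and calibrate habitat suitability index (HSI) models for this
setting — and ships a synthetic burned-landscape generator so every stage runs
and is testable without any proprietary field data.

## What the package computes

**Covariates** (30-m raster grid). From burn severity (ΔNBR), pre-fire canopy
cover, a ponderosa-pine mask and topography, the engine derives the standard
two-scale covariates: percent of the 3×3-pixel (0.81 ha) neighbourhood that is
moderately-to-severely burned (ΔNBR > 270) or open (< 10% canopy)
(`LocBrnOpn`), the same percentage over a 1-km disc (3,409 pixels)
(`LandBrnOpn`), percent pine-dominated forest over the disc (`LandPIPO`),
slope, and cosine aspect (zeroed where slope ≤ 2%).

**Maximum-entropy model** (presence–background). Nests vs. 10,000 random
available pixels; the Gibbs density q(x) ∝ exp(Σⱼ λⱼ fⱼ(x)) over the background
is fitted by maximising the L1-penalised presence log-likelihood

  ℓ(λ) = λ·f̄_presence − log Z(λ) − Σⱼ βⱼ|λⱼ|,

with linear, quadratic and pairwise-product features scaled to [0, 1].
HSI = e^H q / (1 + e^H q), with H the entropy of the fitted background
distribution. Variables contributing < 5% of training gain (leave-variable-out)
are dropped and the model refitted.

**Weighted logistic regression** (use–non-use). Nests (w₁ = 1) vs. field-
verified non-nest sites (w₀ = n₁/n₀, making the weighted prevalence exactly
0.5 so the fitted response is a relative HSI). All covariate subsets up to one
covariate per 10 nests (rounded up) are fitted and ranked by
AICc = −2 log L + 2K + 2K(K+1)/(n−K−1), with Akaike weights and a
variance-inflation-factor screen.

**Transferability.** Mann–Whitney AUC with stratified percentile-bootstrap
CIs; a model transfers to a location when the lower 95% CI limit for AUC
exceeds 0.5. Data from mutually transferable locations are pooled (per-location
weight sums equalised; background proportions matched to nest proportions) for
a final model.

**Density calibration.** Hatched-nest densities along the HSI gradient in
equal-area moving windows; two thresholds at natural breaks define low /
moderate / high suitability classes; per-class density, expected percent of
nests and surveyed area, with spatial block-bootstrap CIs (600-m grid cells
resampled with replacement, 5,000 resamples, median-unbiased quantiles).

## Worked example

```python
import burnhab
from burnhab import (LandscapeParams, SelectionParams, generate_landscape,
                     simulate_sites, fit_wlr, enumerate_candidates,
                     rank_models, cross_apply, transferable)

landscape = generate_landscape(LandscapeParams(seed=1))
sites = simulate_sites(landscape, SelectionParams(seed=2), location="fireA")
data = sites[sites["role"].isin(["nest", "non-nest"])].copy()
data["y"] = (data["role"] == "nest").astype(float)

subsets = enumerate_candidates(burnhab.ALL_COVARIATES, n_nests=47)   # 638
ranking = rank_models([fit_wlr(data, s) for s in subsets])
print(ranking.table().head(3).round(3).to_string(index=False))
res = cross_apply(ranking.best, sites, n_boot=2000, seed=3, development=True)
print(f"AUC {res.auc:.2f} ({res.ci_low:.2f}, {res.ci_high:.2f}) "
      f"transferable={transferable(res)}")
```

Output:

```
                                  covariates  K    logL    AICc  dAICc  weight
           LocBrnOpn + LandBrnOpn + PIPO_pct  4 -55.132 118.447  0.000   0.088
LocBrnOpn + LandBrnOpn + LandPIPO + PIPO_pct  5 -54.879 120.035  1.588   0.040
LocBrnOpn + LandBrnOpn + TreeDens + PIPO_pct  5 -54.896 120.068  1.621   0.039
AUC 0.76 (0.68, 0.84) transferable=True
```

With 47 simulated nests the cap is ⌈47/10⌉ = 5 covariates, giving 638 candidate
subsets. The top-ranked model carries the expected selection signs (positive
local burned/open, negative landscape burned/open, positive percent pine), its
Akaike weight (0.088) reflects genuine model-selection uncertainty among
closely ranked subsets, and the in-sample AUC of 0.76 with a lower CI limit
above 0.5 indicates useful discrimination of nest from non-nest sites.

The same workflow is available from the shell:

```bash
burnhab simulate --seed 1 --outdir out/
burnhab fit-wlr out/sites_locA.csv --out out/ranking.csv
burnhab run --seed 7 --outdir out/full   # full two-location pipeline
```

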