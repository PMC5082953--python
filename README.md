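# sagersf

Seasonal resource selection functions (RSFs) for telemetry studies of
sagebrush-obligate wildlife, built as a complete, testable pipeline: from raw
relocations and landscape layers to model-averaged habitat maps, with a
two-scale test of energy-development effects. A synthetic landscape and
telemetry generator with known selection truth makes every stage verifiable
without any field data.

## Who this is for

Quantitative wildlife ecologists fitting used-available habitat selection
models — the design popularized for greater sage-grouse and similar species —
who want the full chain in one place:

1. **Study design** — assign relocations to biological seasons (breeding
   1 Apr–15 Jul, summer 16 Jul–1 Sep, winter 1 Oct–1 Mar), derive each
   season's movement-buffer radius as mean step distance ÷ mean step interval
   (m/day), and draw a uniform availability sample over the study extent with
   a coefficient-convergence sensitivity analysis for its size.
2. **Covariates** — summarize every variable over each buffered observation:
   vegetation-class proportions by exact cell–disc overlap, area-weighted
   elevation/NDVI means, distances to habitat classes and water (zero when the
   feature lies inside the buffer), stream density, and energy covariates
   (distance to oil/gas roads and active well pads, and a development index
   combining rescaled well and oil-road densities over a 1 km² window).
3. **Fitting** — Pearson screen (|r| > 0.65 drops the lower-priority
   variable), then all-subsets used-available logistic regression with a
   per-animal Gaussian random intercept, the marginal likelihood integrated by
   adaptive Gauss–Hermite quadrature. Models are ranked by AICc; Akaike
   weights define the 95% confidence set.
4. **Maps** — each confidence-set model becomes a raster of relative
   probability of presence (moving-window covariates, logistic link, random
   intercept at 0); surfaces are averaged with renormalized weights.
5. **Validation** — k-fold cross-validation withholding whole birds,
   area-adjusted bin frequencies, Spearman rank correlation r_s, and
   rank-based AUC.
6. **Energy scales** — add energy covariates to the seasonal base model at
   the landscape scale and on the subset of observations within 2 km of
   active wells, comparing AICc — including a constructed experiment showing
   how the same road avoidance can flip coefficient sign between scales when
   development sits inside preferred habitat.

## The model

For used (y=1) and available (y=0) buffered observations with covariates x
and animal i, the package fits

    logit P(y = 1 | x, b_i) = β₀ + x'β + b_i,    b_i ~ Normal(0, σ_b²)

maximizing the marginal likelihood (adaptive Gauss–Hermite, 21 nodes). The
shared seasonal availability sample is apportioned at random among the
season's animals so σ_b stays identifiable. exp(βⱼ) is the odds ratio of use
per unit of covariate j; the map value is exp(η)/(1+exp(η)) with η = β₀+x'β,
read as a *relative* (ordinal) probability of presence. For a candidate set
of p screened covariates, all 2^p subsets are fitted and compared by

    AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1),   w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2),

and prediction surfaces (not coefficients) are model-averaged over the
smallest weight-ordered set with cumulative weight ≥ 0.95.

## Worked example

`python examples/03_fit_rsf.py` simulates a breeding-season campaign on a
2.5 km synthetic basin (18 birds, weekly fixes, 1,200 available points),
screens covariates and fits all subsets:

```
collinearity screen dropped: ['dist_water (r=+0.73 with dist_agriculture)',
                              'ndvi (r=-0.70 with dist_agriculture)']
retained: ['sagebrush', 'grassland', 'sagebrush_grassland',
           'dist_agriculture', 'agriculture']

                                            formula  k     aicc  delta  weight ...
sagebrush + sagebrush_grassland + dist_agriculture   5 1702.118  0.000   0.291
                   sagebrush + sagebrush_grassland   4 1702.654  0.536   0.222
...
32 models; the 95% confidence set holds 7 of them

top model (sagebrush + sagebrush_grassland + dist_agriculture), sigma_b = 0.00:
                     beta_std  se_std ...   beta     se     odds_ratio
sagebrush               1.131   0.093 ...  3.137  0.258        23.025
sagebrush_grassland     0.382   0.070 ...  3.195  0.585        24.408
dist_agriculture       -0.109   0.069 ... -0.559  0.352         0.572
```

The simulation truth put a sagebrush coefficient of 3.161 into the selection
model; the fitted 3.137 (odds ratio ≈ 23) recovers it, and the standardized
column ranks sagebrush as the dominant effect. The other examples cover
landscape simulation, study design, habitat mapping (`04`), cross-validation
(`05`, average r_s ≈ 0.92, AUC ≈ 0.73 on a well-specified simulation), the
two-scale energy comparison with the sign-reversal experiment (`06`), and the
seasonal-workbook entry point (`07`). A thin CLI mirrors the pipeline:
`rsf run`, `rsf simulate`, `rsf fit`, `rsf validate`, `rsf ingest-s1`.

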