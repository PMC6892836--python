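# Methods

This note documents the statistical models, algorithms, defaults, and design
choices behind `spectrait`, and what the synthetic-trial tests do and do not
demonstrate about real field data.

## Problem setting

Breeding programs screening wheat lines for drought tolerance need fast,
non-destructive proxies for three destructive agronomic measurements taken
around anthesis: shoot dry weight per land area (DW, kg m⁻²), water content
of the aboveground biomass (WC, %, fresh basis), and final grain yield (GY,
t ha⁻¹ at ~14% seed moisture). Canopy reflectance between 350 and 2500 nm
carries pigment, structure, biomass, and water-status information, so the
package implements the full analysis chain from plot-level spectra to
breeding-relevant statistics: spectral index evaluation and discovery,
quantitative-genetic screening, full-spectrum multivariate calibration,
parsimonious wavelength models, and genotype clustering.

## Trait conventions

WC defaults to the fresh basis, `100·(FW − DW)/FW`, which is the only
convention under which typical biomass water contents fall in the observed
58–79% range; the dry basis `100·(FW − DW)/DW` is available via
`water_content(..., basis="dry")` for comparison with sources that use it.

## Spectra

All operations consume spectra canonicalized to the integer 1-nm grid
350–2500 nm (2151 bands). Raw instrument grids (e.g. 1.4 nm VNIR / 2.2 nm
SWIR sampling) are linearly interpolated; canonicalization is idempotent and
no extrapolation is permitted. Replicate scans of a plot are averaged
pointwise *before* any index is computed (index of the mean spectrum, not
mean of indices); the two orders differ only at second order in the
within-plot scatter, and averaging first matches how field spectra are
usually exported. Index formulas address bands by exact integer nanometre —
the canonical grid guarantees presence, eliminating silent nearest-neighbour
band substitutions.

## Spectral reflectance indices

The default registry holds 23 indices in six wavelength-region groups
(VIS/VIS, NIR/VIS, NIR/NIR, SWIR/VIS, SWIR/SWIR, SWIR/NIR): sixteen
constructed two-band indices in normalized-difference form
`(Ra − Rb)/(Ra + Rb)`, and seven published forms (NDVI, OSAVI, MTVI, EVI,
NWI-2, a three-band product ratio R1100/(R351·R1392), NDMI). Three registry
choices deserve note, all overridable through the YAML registry file:

* MTVI is labelled by its (750, 550) bands but requires a red band; the
  registry uses (NIR, red, green) = (750, 670, 550).
* EVI is labelled (800, 660) but requires a blue band; 480 nm is used.
* NDMI(2200, 1100) is oriented `(R1100 − R2200)/(R1100 + R2200)` so the
  index increases with canopy wetness.
* SRI(1250, 590) is stored in the SWIR/VIS group, preserving the
  conventional grouping of its source even though 1250 nm is NIR by the
  region definitions used here.

Per-index univariate performance is the OLS coefficient of determination
against a trait, which for simple regression equals the squared Pearson
correlation.

## Contour maps

Index discovery scans every two-band normalized-difference index on a
stepped wavelength grid (default 5 nm; 1 nm available) against a trait and
records the R² matrix. Pairs closer than 5 nm are masked (the index
degenerates to a noise ratio). Hot spots are connected components
(8-neighbourhood) of cells at or above a threshold — by default the 95th
percentile of the map, since no standard numeric rule exists; each region
reports its peak pair, and the shortlist operation unions peak wavelengths
over whatever maps are supplied.

## Variance components, heritability, genetic correlation

Estimation is method-of-moments from the balanced genotype × environment
ANOVA with r replicates, environments being treatment × year cells:

```
MS_G   = σ²e + r·σ²GE + r·e·σ²G
MS_GE  = σ²e + r·σ²GE
MS_err = σ²e
σ²P    = σ²G + σ²GE/e + σ²e/(r·e)      H² = σ²G/σ²P
```

Genetic covariance applies the same decomposition to mean cross-products,
and rg = Cov_G/√(Var_G,x · Var_G,y). Negative moment estimates are truncated
to zero and flagged; rg outside [−1, 1] (possible for moment estimators) is
clipped and flagged. Within a single treatment e = number of years (2 by
default); pooled FL+LM analyses use e = 4. The split-plot error strata of
the field layout are deliberately collapsed into one residual, matching the
single-residual σ²P formula; REML/mixed-model estimation and standard errors
are out of scope.

## PLSR, LOOCV, VIP, band intervals

PLS1 is fitted by sequential NIPALS-style extraction: each latent variable's
unit-norm weight vector maximizes covariance between its X-score and the
current response residual. Predictors are autoscaled (centre, unit variance)
— the chemometrics default for reflectance matrices, recorded in model
metadata; weight-vector signs are fixed (largest-magnitude element positive)
so fits are backend-reproducible. Leave-one-out cross-validation accumulates
PRESS per LV count into `Q²cum = 1 − PRESS/SS_total`. The optimal number of
latent variables (ONLV) is the smallest count whose Q²cum lies within 1%
(relative) of the curve maximum — an explicit parsimony tie-break — and a
model is flagged acceptable when Q²cum > 0.5.

VIP over the ONLV latent variables is
`VIP_j = √(p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a)`; mean squared VIP is
exactly 1. Sensitive band intervals keep wavelengths with VIP > 1 whose
absolute loading weight reaches the 75th percentile (configurable) on at
least one LV, merging runs and bridging gaps up to 5 nm. Calibration /
validation reporting uses a seeded random 75/25 split, ONLV chosen by LOOCV
on the calibration set only, and per-set R² (squared Pearson of observed vs
predicted), RMSE, and RE = 100·RMSE/mean(observed in that set) — the
respective set's own mean, not a pooled mean.

## Stepwise MLR

The selector is classic forward selection with backward elimination: enter
the candidate with the smallest partial-F p-value when below α_enter = 0.05,
then drop any entered term whose p-value exceeds α_remove = 0.10; ties break
by lower p-value then lower column position, so traces are deterministic.
The forward step computes exact partial-F statistics for all candidates at
once by QR-orthogonalizing them against the current model. Final models are
always refit by OLS so reported coefficients, R², and RMSE (√(SSE/n)) are
recomputable from the data.

Wavelength models built from PLSR band intervals use every 1-nm wavelength
inside the intervals as candidates (uniformly thinned above 300) and cap the
model at 4 terms by default: with hundreds of strongly collinear reflectance
candidates, an uncapped stepwise run keeps absorbing noise terms, and short
equations are the point of this modelling style. Index-group models default
to `all_terms` (OLS on every index in the group, dropping collinear columns
with a warning), with `stepwise` available.

## Clustering

Genotypes are profiled by their mean DW, WC, GY over all plots in scope,
z-scored by default because the traits live on incommensurate scales (a
raw-scale option exists; with raw units GY dominates the distances), then
clustered by UPGMA (average linkage, Euclidean distance) and cut at k = 3.
Clusters are renumbered by descending mean GY so cluster 1 is always the
best-performing group; contrasts are reported as relative decreases
`100·(mean_ref − mean_cmp)/mean_ref`, rounded to one decimal for display
with the unrounded value retained. Trees export to Newick with branch
lengths derived from merge heights.

## Synthetic trial generator

The generator realizes a 32-genotype (30 inbred lines + 2 parents) × 2
irrigation treatments (FL/LM) × 2 years × 3 replicates split-plot trial —
384 plots. Traits follow `value = treatment mean + genotype + G×E +
residual` with genotype effects multivariate normal across traits
(covariance diag(σ_G)·C·diag(σ_G)), independent G×E effects per
treatment-year environment, and i.i.d. plot residuals. Defaults: treatment
means (2.0 kg m⁻², 74%, 6.4 t ha⁻¹) under FL and (1.3, 64, 3.5) under LM;
variance components (σ²G, σ²GE, σ²e) of (0.04, 0.008, 0.01) for DW,
(9, 1.8, 2.5) for WC, (0.5, 0.1, 0.15) for GY — heritabilities near 0.85 at
e = 2, r = 3, typical of well-replicated trials; genetic correlations 0.8
(DW–GY), 0.6 (DW–WC and WC–GY). Rare draws outside physical ranges
(negative yields at ~4σ) are truncated and the truncation absorbed into the
stored residual so the additive identity stays exact. All randomness derives
from one master seed through named substreams (genotype, G×E, residual,
sensor noise), so each stage is independently replayable.

Spectra come from a phenomenological forward model, not a radiative-transfer
code: a VIS level with pigment absorption wells at 490/670 nm deepening with
GY; a red-edge sigmoid whose amplitude grows with DW and whose inflection
(722 nm at reference traits) shifts 25 nm per unit scaled DW — the shift
dominates near the inflection, making 700–740 nm the most DW-sensitive
region, as the red-edge shift does in real canopies; an NIR plateau rising
with DW; Gaussian water wells at 970/1200/1450/1900 nm deepening with WC
(the 970 nm well carries the strongest coupling so the canonical NIR water
feature stands clear of sensor noise); and a SWIR dry-matter slope tied to
DW. Coupling is multiplied by a per-treatment gain (FL 0.35, LM 1.0): a
closed, saturated full-irrigation canopy expresses genotypic differences
only weakly in reflectance, which is the regime contrast the pipeline must
resolve. Additive homoscedastic sensor noise (sd 0.01 reflectance — chosen
as a plausible plot-level repeatability; no instrument value is asserted)
is applied before clipping to [0.001, 0.999].

What the generator does *not* emulate: radiative transfer and
soil/illumination geometry, heteroscedastic or spectrally correlated sensor
noise, detector-junction artefacts, growth-stage dynamics, unbalanced or
missing plots, and any nonlinearity between traits and spectra beyond the
sigmoid shift. Passing tests therefore demonstrate that the estimators
recover known structure under the stated statistical model at field-realistic
sizes — not that real canopies satisfy that model.

## Problem sizes and numerical choices

The default test-suite and acceptance computations use: the full 384-plot
trial for end-to-end runs; 200 genotypes × 2 environments × 3 replicates for
parameter recovery (components within 15% relative, H² within 0.05, rg
within 0.1); 20 generator seeds for band-localization rates; contour scans
at a 5-nm step (the 1-nm scan is available but 5 nm preserves region
detection at a fraction of the cost); LOOCV to 10 latent variables. In the
seed-loop localization checks the ONLV is selected on a 5-nm-decimated
spectrum — the Q² curve is insensitive to decimation for these smooth
spectra — and VIP/intervals are then computed at full 1-nm resolution.
Collinearity guards: stepwise skips candidates whose residual variance after
projection is below 1e-12 of their scale; group models drop collinear
columns greedily (keeping the earliest) before the full OLS fit. Variance
truncation at zero and rg clipping are always flagged in the output rather
than silent.

## Known limitations

* Moment-based components are inefficient relative to REML for unbalanced
  data, and the package refuses unbalanced layouts rather than guessing.
* No inference is provided for H² or rg (no standard errors), and no
  selection-aware inference for stepwise models.
* The 4-term stepwise cap and the 1%-of-maximum ONLV rule are sensible
  defaults, not estimated quantities; both are parameters.
* Hot-spot extraction depends on the threshold rule; the default 95th
  percentile is arbitrary and should be varied in real analyses.
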