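# Methods

This note documents the models, numerical choices and assumptions behind
`drydiv`, and what the synthetic-data validation does and does not
demonstrate.

## Drought indexing

**SPEI.** The monthly climatic water balance D = P − PET is aggregated over
k months (k = 12 ending December for annual conditions; k = 6 over
April–September for the growing season). A three-parameter log-logistic
distribution is fitted to the reference-period aggregates (inclusive
1991–2021, 31 values; at least 25 required) by unbiased probability-weighted
moments, and SPEI is the standard-normal quantile of the fitted CDF, clipped
to ±3.5. We parametrize the family as the generalized logistic
(κ, α, ξ) via Hosking's L-moment estimators (κ = −τ₃,
α = λ₂ sin(κπ)/(κπ), ξ = λ₁ − α(1/κ − π/sin(κπ))). For κ < 0 this is
exactly the classical log-logistic with shape −1/κ; the extension to κ > 0
covers left-skewed aggregate samples — which arise routinely when a scripted
multiyear drought sits inside the reference window — where a strict
log-logistic fit has no valid shape parameter. This matches the behaviour
of the standard L-moment software stack used for SPEI in practice. The fit
is cross-checked in the tests against an independently coded
plotting-position PWM implementation and against parameter recovery from
large samples of scipy's `fisk` (log-logistic) distribution.

**Severity classification.** Severe: SPEI12 < −1.28, strict, so a value of
exactly −1.28 is not severe (−1.28 is the 10% quantile of the standardized
scale); moderate: −1.28 ≤ SPEI12 < −0.5; otherwise normal/wet.

**REW bucket.** Full plant-hydraulics process models resolve organ-level
water potentials; this package instead uses a deliberately simple daily
single-bucket balance, and every REW value it produces is flagged as coming
from it. Storage W is bounded by a residual floor and field capacity;
REW = (W − W_wp)/(W_fc − W_wp); evapotranspiration is PET throttled by a
factor rising linearly from 0 at REW = 0 to 1 at REW ≥ 0.4; overflow leaves
as runoff; extraction never draws below the residual. Because the residual
may sit below the wilting point, REW can go slightly negative, down to
(residual − wilting)/(1 − wilting) — real sites do report small negative
REW quartiles. The ledger W(d+1) − W(d) = P − E − runoff closes to
numerical precision by construction. Monthly climate is disaggregated to
daily by uniform spreading within each month — the minimal assumption when
no daily data exist. Default soil: 150 mm capacity, wilting at 15% and
residual at 12% of capacity; these are free configuration, since no
site-specific soil retention data are bundled.

**Summaries and calendar.** REWmin is the minimum over April–September of
monthly mean REW; drought days count days with REW < 0.4 over the calendar
year and over the growing season (fixed as April 1 – September 30).
The calendar takes the first severe year in the focus span as Resp_yr 1,
continues through consecutive drought years (SPEI12 < −0.5), retains the
first following non-drought year as the final post-drought label (at most
four labels), and picks up to the two most recent consecutive preceding
years with SPEI12 ≥ −0.5 as the pre-drought reference. No severe year
yields an empty calendar with an explanatory status; no qualifying
reference year is an error — the response ratio is undefined without one.

## Ring processing

BAI is computed from pith to bark assuming concentric rings:
r_t = pith_offset + Σ TRW, BAI_t = π(r_t² − r_{t−1}²); the sum telescopes
to πr² exactly, which the tests exploit as an identity. The pith offset
defaults to 0 (cores assumed to reach the pith) and is configurable per
tree. BIOMinc = BAI × 10⁻⁶ × ring density (kg m⁻¹ yr⁻¹). Series are used
raw and undetrended — there is deliberately no detrending API, because age
trends in short juvenile series cannot be separated from drought signals
without distorting them; tree age is instead controlled in the models.

The Lloret response divides growth in each labeled response year by the
unweighted arithmetic mean of growth over the reference year(s) and is
log-transformed for modeling. Response years with zero growth are flagged
and excluded from the log-scale analysis rather than offset by a constant
(offsets distort ratios); the exclusion count is reported. A zero reference
mean is an error for that tree. The quality filter removes series flagged
doubtful upstream and removes a whole species-by-site group when its
doubtful proportion strictly exceeds 40% (so exactly 40% is retained);
crossdating itself is upstream of this package and input years are trusted.

Tucson (.rwl) files are written in the 0.01 mm dialect with the 999
end-of-series marker and read in both the 0.01 mm/999 and 0.001 mm/−9999
dialects.

## Neighborhood metrics

HSM_TLP = TLP − P50 must be positive (P50 < TLP < 0). Neighborhoods are
all living trees within a fixed radius of the focal tree (1.5 m for
narrow-spacing designs, 2.9 m for wide), searched within the focal tree's
plot; the first/second-order neighbor distinction is collapsed into the
radius, which already encodes it. Hegyi's index is Σⱼ (BAⱼ/BAᵢ)/dᵢⱼ.
Realized neighborhood species richness counts the focal species (the
interacting community includes the focal tree; a config switch exposes the
alternative). FDis pools basal area by species into relative abundances
a_k (Σa_k = 1) and takes the abundance-weighted mean absolute distance of
species trait values to the weighted centroid — the standard functional-
dispersion definition. A formula variant circulating in print divides by
Σd_k instead of normalizing abundances; we follow the canonical definition.
Standardizations: basal area z-scored within site × species (relative
intraspecific size), Hegyi z-scored within site (relative interspecific
competition; site × species available as a switch), FDis min-max
normalized across all sites (identically 0 when the dataset is all
monocultures). Standard deviations use the n−1 denominator; zero-variance
groups are flagged and set to 0.

## Mixed models

Both model families are linear mixed models on log response ratios, fitted
with statsmodels' MixedLM by REML.

*Single-year (cross-site)*: log response ~ diversity × HSM_TLP × drought
covariate + BA_z + Hegyi_z + age + preceding-year drought covariate, with
random intercepts for site and plot-within-site (variance component). The
diversity moderator is nSR or normalized FDis (separate models); the
drought covariate is one of SPEI12, SPEI6, REWmin, or the drought-day
counts, and the preceding-year control is always matched in kind to it.

*Consecutive-year (site-specific)*: log response ~ 0 + Resp_yr +
Resp_yr:diversity + Resp_yr:HSM + diversity:HSM + BA_z + Hegyi_z with a
tree random intercept for the repeated measures. The suppressed intercept
makes each year coefficient the mean log response relative to pre-drought
growth. Drought covariates are excluded by construction: they would be
confounded with the categorical year effect.

Numerical and inferential choices:

- **Trait centering.** HSM_TLP (and the drought covariate in single-year
  models) enters through a stateful centering transform. With raw
  all-positive trait values the diversity × trait interaction is nearly a
  linear combination of the diversity-by-year terms and inflates their
  variance several-fold; centering removes the collinearity without
  changing slope interpretations, and predictions still accept raw-scale
  trait values. Diversity is left uncentered so that 0 anchors at
  monocultures.
- **AIC on ML refits.** REML likelihoods are not comparable across
  different fixed-effect sets, so `compare_models` always uses a
  maximum-likelihood refit (k counts fixed effects plus variance
  parameters). Reported estimates stay REML. The refit can be skipped
  (`ml_refit=False`) when AIC is not needed, halving fit cost in
  replication studies.
- **p-values** use Wald t with residual-based denominator degrees of
  freedom (n_obs − fixed-effect rank − number of groups), recorded in the
  fit metadata. Satterthwaite approximations are not implemented; at the
  package's typical group counts the residual-df t is near-normal anyway.
- **R²** follows the variance-partition definition for mixed models:
  marginal = var(fixed predictions)/(var(fixed) + Σ random variances +
  residual); conditional adds the random variances to the numerator, so
  conditional ≥ marginal always.
- **Degenerate inputs.** A response vector with (near-)zero variance
  raises before fitting; a rank-deficient fixed-effect design raises with
  the names of the inestimable columns (e.g. trait terms in a
  single-species dataset); missing year levels per tree raise listing the
  trees. A fit whose smallest relative variance component falls below 1e-6
  is flagged singular but retained.
- **Marginal effects** are fixed-effect predictions over a grid of focus
  predictors (defaults: diversity at 0/0.3/0.6, HSM_TLP at 0.8/1.5 MPa,
  drought covariates at observed quantiles) with all other numeric
  covariates at 0 (their standardized center) and categoricals at the
  reference level; Wald bands; grid points outside the observed predictor
  range are flagged as extrapolation.

## Synthetic experiment generator

The generator emulates a TreeDivNet-style planted experiment: a species
pool whose hydraulic safety margins span a configurable range (default
0.8–1.5 MPa, evenly spaced with endpoints assigned), monocultures plus
systematic mixtures on a 1–6 richness gradient, square planting grids
(default 8 × 8 at 1.5 m) with two replicate plots per composition, random
(not drought-linked) mortality, and focal-tree selection mimicking field
criteria: living interior trees (more than one planting distance from the
plot edge, avoiding truncated neighborhoods) with all four first-order
neighbors alive, nearest the plot center first, up to 10 per species ×
composition.

Climate is seasonal monthly precipitation (gamma noise) and PET (July
peak); scripted drought/wet years are realized by rescaling the year's
precipitation so its annual water balance lands at a target anomaly inside
the intended SPEI12 band (severe forced below every unscripted year, so a
single scripted severe year is the driest by construction). The default
script is 2017 wet (guaranteeing a qualifying reference year, as the field
designs require), 2018 severe, 2019–2020 moderate, 2021 wet — a
three-year drought plus post-drought year. Unscripted years are left
random, so the standardization property (≈10% of reference years severe)
remains testable.

Ground-truth growth: log G_it = μ_s + α·log(age) + γ_BA·z(BA) +
(θ0 + θH·HSM_s)·S_t + β_FD(yr)·FD_i + u_site + u_plot + u_tree + ε, with
stress index S_t = max(0, (0.4 − REWmin_t)/0.4) and β_FD zero before the
drought. Ring density is drawn per ring as species mean ± noise floored at
50 kg m⁻³ (no within-tree density model exists to copy); ring width is
recovered from the simulated biomass increment through the basal-area
geometry, so TRW → BAI → BIOMinc round-trips exactly through the ring
module. This growth-generating process is an explicit artifact assumption
— field studies measure growth, they do not specify its generator — chosen
to match the response structure the inference layer assumes, which is
precisely what makes parameter recovery a meaningful validation of the
fitting code rather than of nature.

Default effect sizes and variances (log scale): α = 0.3, γ_BA = 0.1,
θ0 = −0.4, θH = 0.2, β_FD = −0.3 in the third drought year (zero
elsewhere), residual sd 0.12 (within-tree interannual noise), tree sd 0.1,
plot sd ≈ 0.07, site sd 0.1 — magnitudes typical of young, evenly aged
plantations. The default drought calendar keeps a single reference year:
the log response ratio is then an exact difference of log growths, the
random site/plot/tree intercepts cancel, and the generator's parameters
map one-to-one onto the consecutive-model coefficients (year intercepts
absorb the age trend and mean-trait drought term; trait-by-year terms are
θH·(S_y − S_ref); diversity-by-year terms are β_FD(y); size, competition
and diversity × trait are exactly zero). With two reference years the
mapping would acquire a small Jensen bias in the intercepts.

**What passing tests show — and don't.** The recovery studies (200
replicates at ~300 focal trees: |bias| < 0.02 per coefficient, ~95% CI
coverage, ≥80% detection of the −0.3 diversity effect, nominal type-I
rate under the null; 100 replicates per theoretical pathway reproducing
sign and strengthening of diversity-effect trajectories) validate the
whole chain — climate to calendar to rings to neighborhoods to mixed
model — under a data-generating process that satisfies the model's
assumptions. Real tree-ring data violate them in ways the generator
deliberately omits: drought-linked and spatially clustered mortality,
within-species trait plasticity, crossdating error, non-random focal
sampling, carry-over growth physiology, and site heterogeneity beyond
random intercepts. Passing here demonstrates correctness of the
implementation, not robustness of the design to those violations.

Problem sizes throughout (replicate counts, tree numbers, series lengths)
are the package's chosen validation scale: large enough for the Monte-Carlo
error of each check to sit well inside its tolerance, small enough to keep
the full suite comfortably interactive.

## Pipeline

`drydiv run` executes simulate → drought → neigh → rings → fit → report
per site from one YAML config, logging record counts in/out at each stage
(so the quality filter and focal selection are auditable), writing all
intermediates as tab-delimited text for diffability, and emitting a
manifest with SHA-256 hashes of every output plus the resolved config;
identical configs reproduce identical hashes. Single-year cross-site
models require at least two sites and are skipped (with a warning)
otherwise; consecutive-year models are fitted per site, as they are
site-specific by design.

## Known limitations

- The bucket model is a one-reservoir caricature of soil–plant hydraulics;
  its parameters are configuration, not calibrated physics, and REW-based
  covariates inherit that.
- Uniform monthly-to-daily disaggregation flattens within-month rainfall
  structure, smoothing drought-day counts.
- Satterthwaite/Kenward-Roger small-sample inference is not implemented;
  with few sites the single-year model's site-level covariates (e.g.
  REWmin) have optimistic SEs.
- Single-trait FDis only; the multi-trait form and height/crown-based
  competition indices are out of scope.
- Mortality in the generator is random; drought-induced mortality and its
  feedback on neighborhoods is a non-goal.
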