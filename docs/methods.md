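# Methods

`gestwin` re-implements, as a tested and reusable pipeline, an analysis
chain linking weekly prenatal ambient air pollution to placental epigenetic
gestational age acceleration (GAA) or deceleration (GAD) at birth. Because
cohort data of this kind are typically not public, the package ships a
synthetic-data generator with a complete ground-truth record, so every
stage can be validated against planted truth.

## The unified week axis

All weekly quantities live on a unified axis: weeks 1–13 are the 13
complete 7-day preconception weeks (three months before conception), and
week 14 is pregnancy week 1. The distributed-lag axis ends at unified week
48 = pregnancy week 35; pregnancy weeks 36–39 are excluded structurally so
that term and near-term pregnancies contribute a complete lag history
(births before pregnancy week 35 still leave missing lag weeks and are
dropped from lag models, with the count reported).

## Exposure assignment

Weekly pollutant concentrations are interpolated from monitoring stations
to each residence by inverse-distance-squared weighting,

  x̂ = Σᵢ vᵢ/dᵢ² / Σᵢ 1/dᵢ²,

with great-circle (haversine) distances on a sphere of radius 6371.0088 km
and a 1 m distance floor so a collocated station dominates without a
division by zero. Station eligibility: if any station lies within 5 km of
the residence, all and only the stations within 5 km are used; otherwise
the up-to-four nearest stations within 50 km; otherwise the week is
missing. A station missing one week drops out of that week's interpolation
only.

Period averages (preconception; pregnancy; trimesters defined by pregnancy
days 1–90, 91–180, 181–birth, mapped to weeks by the majority-day rule so
boundary weeks 13 and 26 belong to trimesters 1 and 2) are arithmetic means
of weekly values, reported only when at most 10% of the period's weeks are
missing (strictly more than 10% invalidates the period).

## Methylation QC

Fixed order: probe filters → sample filters → twin dedup → batch
adjustment → gold-standard normalization → PC outlier flagging.

* Probes are dropped when detection p > 0.01 in strictly more than 10% of
  samples, or when on a user-supplied cross-reactive list.
* Samples are dropped for >10% failing probes, median log2 intensity < 11,
  missing reported sex, or sex discordance. Sex is predicted from
  X-chromosome probes by exact 1-D two-means clustering of the per-sample
  mean beta; the lower-mean cluster is male (X inactivation leaves females
  with intermediate methylation). One twin per pair is kept at random
  (seeded).
* Batch adjustment is the parametric empirical Bayes location/scale model
  (ComBat): per-feature per-batch means and variances are shrunk toward
  pooled estimates under a normal prior (locations) and inverse-gamma prior
  (scales, hyperparameters by method of moments) via the standard iterative
  conditional solution, then removed, with covariates (sex) protected. It
  operates on logit(beta) with ε = 1e-6 clipping, where the Gaussian model
  is defensible; after adjustment each feature is recentred to its original
  logit-scale grand mean, making the grand-mean preservation exact rather
  than approximate. A single batch is a no-op by definition.
* Gold-standard normalization maps each sample's values through their
  empirical quantiles (average ranks, plotting positions rank/(n−1)) onto a
  reference distribution, by default the sorted mean array. This implements
  the rescale-to-reference contract with a monotone, rank-preserving map; it
  is deliberately not a probe-type (Infinium I/II) mixture model, which
  would require probe-design annotation the pipeline does not consume.
* Visual PC inspection is replaced by an automated rule: samples whose
  first two PC scores deviate from their sex subgroup's median by more than
  k = 3 robust SDs (1.4826 × MAD) in either PC are flagged. At k = 3 and
  n = 100 the expected false-flag count is ≈ 0.5 (100 samples × 2 PCs at
  the two-sided 3σ rate).

## Cell-type deconvolution

Six placental cell types (syncytiotrophoblast, trophoblasts, Hofbauer,
endothelial, stromal, nucleated red blood cells) are estimated per sample
by constrained projection: minimize ‖b − Rw‖² subject to w ≥ 0 and
Σw ≤ 1, solved by SLSQP (6 variables; verified against an exhaustive
grid-search oracle). Weights are reported unnormalized, with an optional
renormalization to the unit simplex for covariate use; the underlying
question of whether proportions should be renormalized before entering
regressions is left configurable because either convention is defensible.

## Epigenetic gestational age and acceleration

A clock is a linear predictor EGA = intercept + Σⱼ wⱼ βⱼ over its CpG set;
all clock CpGs must be present (no imputation). Clocks may be loaded from a
coefficient file or trained by elastic net (chronologic GA on beta values,
10-fold cross-validated penalty over a log-spaced grid, l1 ratio 0.5,
seeded folds; only nonzero coefficients are kept).

Extrinsic GAA/GAD is the residual of EGA on chronologic GA (OLS with
intercept); intrinsic GAA/GAD additionally adjusts for estimated cell
proportions, dropping the largest compartment (syncytiotrophoblast, by
default, configurable) to avoid the simplex collinearity. Positive
residual = acceleration. Both residual vectors sum to zero by construction.

## Association models

Period-average models are OLS of a GAA residual on the period-average
exposure plus the covariate roster (maternal age; race, ethnicity,
education, income, pre-pregnancy BMI class, child sex, birth season
warm Apr–Sep / cold Oct–Mar, study site; fixed reference levels, dummy
coding), complete cases only, with the exposure coefficient rescaled
post-fit to a per-10-unit increment and normal-theory (t) 95% CIs.
Mutually adjusted models enter all period averages of one pollutant
simultaneously. No multiple-testing adjustment is applied across the
analysis grid; raw two-sided p-values are reported.

## Distributed-lag models

The outcome is regressed on the full 48-week exposure history with the
weekly-coefficient curve θ constrained to a basis B (θ = Bη): polynomials
of degree 0–6 in the centered/scaled lag index, or natural cubic splines
(df 2–8, boundary knots at lags 1 and 48, internal knots at equally spaced
quantiles, classic truncated-power ns() construction). The fit is OLS on
[1 | covariates | XB]; weekly effects are reported per 10-unit increment
with pointwise t CIs (pointwise, not simultaneous, matching the usual
weekly effect-curve presentation). The basis is selected by minimum
RSS-based AIC, n·log(RSS/n) + 2(p+1) — equivalent in ranking to the
Gaussian likelihood form — with ties going to the smaller order. Critical
windows are maximal runs of consecutive weeks whose CI excludes zero, each
annotated with sign and peak week (argmax |θ| within the run).

## The synthetic generator

What it emulates: spatially structured seasonal weekly pollutant fields
(baseline + linear spatial gradient + annual sinusoid + AR(1) anomalies,
floored at 0) sampled at stations; pregnancy calendars with conception
dates uniform over a year and GA at birth truncated-normal on [28, 42]
weeks (default mean 39.2, SD 1.4); beta values in [0,1] in which a clock
CpG set drifts with biological GA on the logit scale; cell-type mixing
from a reference panel with Dirichlet proportions centered on placental
composition; plate location/scale batch effects on the logit scale;
detection-p failures; planted low-intensity, sex-discordant and twin
samples; and a planted exposure effect confined to a configurable window:

  bioGA = cGA + γ · (mean windowed exposure)/10 + N(0, σ_bio).

The latent "true" exposure at a residence is the generative field (its
deterministic part plus a shared regional AR(1) anomaly) evaluated at the
residence coordinates — not the IDW interpolation — so exposure-assignment
error is realistically nonzero and can be studied separately from model
error. Station observations add station-local AR(1) noise on top; the
regional and local components are 0.6 and 0.8 of the pollutant's nominal
anomaly SD (quadrature sum = 1).

RNG design: one stream per component (stations, participants,
methylation), derived from the master seed by fixed offsets, so changing
the cohort size never perturbs the station series. Probe-level "biology" —
clock CpG coefficients, background and X-probe profiles, the reference
panel — is drawn from a separate `biology_seed` stream, so clocks trained
on one synthetic cohort transfer to another, as an externally trained
clock assumes shared CpG–GA biology across real cohorts.

What it does not emulate: raw intensity (.idat) artefacts, probe-type
chemistry, genomic CpG annotation, residential mobility, cohort
ascertainment, or non-linear clock biology. Passing tests therefore show
the pipeline recovers planted effects under these idealized conditions,
not that equally sized effects are detectable in any particular real
cohort.

### Calibration benchmarks and problem sizes

Large Monte-Carlo calibration studies (type-I error, CI coverage,
omitted-variable-bias resolution, window recovery) run at the regression
level via lightweight outcome-cohort generators that plant the same
per-10-unit effect structure without the methylation layer; the full chain
is exercised end-to-end in the pipeline smoke test and the acceptance
script. Default benchmark sizes: 1,000 null cohorts and 500 effect cohorts
of n = 100 for the period-average calibration; 200 cohorts of n = 150 for
mutual adjustment and for window recovery; 200 six-type mixtures for
deconvolution; a 400-sample cohort with 558 causal CpGs among 5,000 for
the clock benchmark (300 train / 100 held out).

The window-recovery benchmark plants a triangular weekly-effect profile
peaking at the center of pregnancy weeks 21–31 with γ = −1.5 weeks per
sustained 10-unit increase. The magnitude was set by a power analysis:
effects in the −0.7 per-10-unit class are strongly detected cumulatively
(windowed-mean t ≈ 6 at n = 150) but pointwise weekly CIs — the quantity
window extraction consumes — carry roughly threefold larger standard
errors under seasonally correlated exposure histories, so reliable
pointwise recovery needs the larger planted effect. The triangular profile
makes the planted peak well defined; a flat window has no unique peak and
lets low-order polynomial fits park the argmax at an axis boundary. The
default full-cohort generator effect remains γ = −1.0 over unified weeks
34–44.

### Numerical choices

* Logit transforms clip beta to [1e-6, 1 − 1e-6].
* Methylation noise is specified on the beta scale and applied on the
  logit scale as 4 × beta_noise_sd (delta method at β = 0.5).
* Station-selection distance ties break by station id; quantile mapping
  uses average ranks so ties stay tied; a single non-missing value maps
  through quantile 0.5.
* SLSQP runs with ftol = 1e-14 and weights clipped at 0; degenerate
  (rank-deficient) panels and designs raise rather than warn.
* Lag indices are centered and scaled before powering; θ is always
  reported on the raw weekly scale.
* Exact (saturated) OLS residualizations are legal and return zero
  residuals (the two-point extrinsic case).

### Known limitations

* The EB batch model assumes approximate Gaussianity on the logit scale;
  probes pinned near 0 or 1 violate it and are only protected by clipping.
* Sex prediction assumes both sexes are present; a single-sex batch would
  split one sex into two clusters.
* The DLM drops participants with any missing lag week rather than
  imputing; with sparse station networks this can cost substantial n.
* Pointwise window extraction has no familywise error control across the
  48 weeks; isolated one-week runs should be interpreted accordingly.
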