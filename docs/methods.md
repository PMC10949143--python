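# Methods

This note documents the models, conventions and design choices behind
`leadwater`, in the spirit of a statistical-software methods appendix.

## Setting and estimands

The data-generating setting is a city offering free household lead
self-test kits. Each test yields three draws (stagnant first draw, 2-min
flush, 5-min flush) with a 1 ppb limit of detection; results are
aggregated to census blocks nested in block groups, tracts and community
areas. Because testing is voluntary, tested blocks are a biased sample of
the city. The estimands are (i) the block-level prevalence of
lead-contaminated water, (ii) per-group disparities in screening and
exposure odds, and (iii) the number of children younger than 6 exposed and
their relative blood-lead-level (BLL) increase attributable to drinking
water.

## Block labelling

A block is labelled contaminated when at least 50% of its tests have a
second-draw concentration ≥ 1 ppb. The 1 ppb cutoff is the assay's
detection limit (and no lead level is considered safe); the second draw is
used because it has the highest median concentration. Ties at exactly 50%
count as contaminated ("at least half"). Values reported as 0 with a
below-detection flag count as < 1 ppb. First- and third-draw labels are
available as a robustness path. Percentages in draw summaries are rounded
half-up to 2 decimals.

## Synthetic-city generator

The generator exists so every downstream stage is testable with known
ground truth. It emulates:

- **Geography.** A balanced hierarchy (default 4 blocks/block group,
  3 block groups/tract, 8 tracts/community area); labels only, no
  coordinates.
- **Population and housing.** Block population is log-normal (median 58,
  σ = 0.75, matching a typical residential-block distribution); buildings
  per block Poisson(16, min 1); building age Normal(97, 15) truncated at 0.
- **Race composition.** City-level proportions (Asian 0.07, Black 0.29,
  Hispanic 0.30, White 0.34) are perturbed by a low-concentration Dirichlet
  per community area (α = 2 × proportions) and a high-concentration
  Dirichlet per block (α = 30 × area mix), producing realistic residential
  segregation: areas differ strongly, blocks within an area are similar.
- **Latent contamination.** logit p = 0.9 + 1.2·(Black+Hispanic share)
  + 0.5·z(building age) − 0.4·z(log population) + 0.3·z(buildings)
  + N(0, 1.5²) community-area effect; the block state is Bernoulli(p).
  Defaults give ≈ 73% prevalence and make geography the dominant predictor,
  both features of the motivating setting. Per-group coefficients
  (`b_race`) are available for correctly specified recovery experiments.
- **Screening selection.** logit(propensity) = −1.5 + 2.2·(White share);
  ≈ 36% of blocks tested, tested blocks whiter than untested — the
  selection bias the disparity analysis is about. Tested blocks receive
  1 + Poisson(2.2) tests (mean ≈ 3.2, mirroring ~38 k tests over ~12 k
  blocks).
- **Concentrations.** A two-component log-normal mixture per draw:
  contaminated blocks (3.4, 4.2, 2.0) ppb medians with σ_log = 1.0; clean
  blocks (0.30, 0.35, 0.20) with σ_log = 0.8. The 2-min flush is highest,
  reproducing the observed ordering of draw medians (2.6 > 2.3 > 1.5 among
  the published results). Draws < 1 ppb are stored as 0 ppb with a
  below-detection flag.
- **Water-source survey.** Per-race unfiltered-tap proportions (Asian
  0.18, Black 0.14, Hispanic 0.12, White 0.32) chosen to match reported
  weighted percentages; the population-weighted citywide share is ≈ 20%.
  The Asian value is not separately published and was set so the citywide
  aggregate holds. Community-area rows are population-weighted mixtures
  with mild Dirichlet noise (concentration 300) emulating survey error.

What the generator does **not** emulate: spatial adjacency (no
coordinates, so no spatial autocorrelation beyond the hierarchy), address-
or household-level heterogeneity within a block, temporal drift over the
collection window, and measurement error beyond left-censoring. Passing
tests therefore demonstrate correctness of the estimation machinery under
the assumed structure, not performance on real municipal data; in
particular the published AUROC (0.81) and citywide exposure figures depend
on the real data and are structural references only.

Seeding: one master seed; each stage derives its own seed as
`(master·100003 + offset) mod (2³¹−1)` so stages are independently
reproducible; all stage seeds are logged in `manifest.json`.

## Risk model

LightGBM gradient-boosted trees (default), geography encoded as raw
categorical levels — not target-encoded, which would leak the outcome.
80/20 stratified train/held-out split; a small learning-rate × num-leaves
grid is tuned by stratified 5-fold cross-validation *inside the training
split*; AUROC, PPV and NPV at the fixed threshold (default 0.5; the
classification threshold is a config value) are computed only on the
untouched held-out rows, whose confusion counts are retained for
uncertainty propagation. Determinism is enforced
(`deterministic=true`, single thread, fixed seed). A penalized logistic
regression (one-hot geography) is a pluggable fallback; any
fit/predict-proba estimator satisfies the interface. Attributions are
LightGBM's native TreeSHAP (`pred_contrib`), which is exactly additive on
the margin scale; global importance is the mean absolute contribution.
A unit-of-analysis switch refits with household tests as observations
(per-test detection outcome) as a robustness path.

## Disparity regressions

Regressions are fit separately per group (avoiding the compositional
collinearity a joint model would have): screening (outcome: tested flag;
covariates: group proportion, predicted risk — the risk-adjusted design
that distinguishes "tested less given risk" from "tested less because less
at risk"; the unadjusted variant is a robustness switch) and exposure
(outcome: block label; covariates: group proportion, block population).
SEs are model-based by default with an HC1 robust option. p-values are
two-sided Wald.

Reporting conventions:

- **Per-10pp increase** = 100·(e^b − 1)/10, i.e. the full-range (0 → 1)
  percentage odds change divided by ten. The alternative reading,
  100·(e^{b/10} − 1), is the model's exact per-10pp odds change but is not
  the convention used in the published tables this package follows; the
  implementation uses the former. CIs transform b ± 1.96·SE through the
  same map.
- **E-value** uses the common-outcome odds-ratio approximation on the
  full-range OR: RR\* = √OR (inverting protective ORs), E = RR\* +
  √(RR\*(RR\*−1)); E(1) = 1. The E-value is computed from e^b, not from
  the per-10pp OR — this is the convention that reproduces the published
  E-values.

Degenerate designs (constant regressor, single-valued outcome, perfect
separation) raise a dedicated error rather than returning silent NaNs;
convergence/separation warnings are carried on the result.

## Microsimulation

Per replicate (default 10,000):

1. **Exposure status.** Tested blocks keep their observed labels
   (authoritative, never resampled — the original analysis is ambiguous
   here and this is our documented choice). Untested blocks start from the
   predicted label; predicted positives stay exposed with probability PPV,
   predicted negatives become exposed with probability 1 − NPV, making the
   expected exposed count unbiased under transportable predictive values.
2. **Children.** n\_{<6} = n\_{<5} + n\_{5–9}/5 (uniform ages within the
   bin; mean age ≈ 42 months). Child counts are fixed across replicates
   (not resampled); race allocation is proportional to block composition;
   water-source allocation applies per-race survey proportions (the finest
   survey geography available in the synthetic data).
3. **Dose.** One concentration per exposed block per replicate (tests
   measure block/household water, not children), resampled with
   replacement from the nonzero second-draw results of the block's region —
   fallback chain block group → tract → community area → citywide,
   config-selectable — and top-coded at 10 ppb because the
   exposure–response association is unsupported above that. One slope per
   exposed block, Uniform(CI_low, CI_high).
4. **Outcomes.** Affected-children relative BLL increase = child-weighted
   mean of slope × concentration over exposed blocks; overall-population
   increase = affected increase × (exposed children on unfiltered tap) /
   (all children), per stratum. Summaries are replicate means with
   5th–95th percentile uncertainty intervals (numpy linear interpolation
   between order statistics).

**Exposure–response slope.** The % BLL increase per ppb (150-day horizon,
children 1–5) comes from external epidemiology; the package deliberately
ships *no* default and refuses to run until `slope_point`/`slope_ci_low`/
`slope_ci_high` are set. Examples and tests use an illustrative 0.25
(0.10–0.40) %/ppb, which is **not** an authoritative value. Estimates must
not be extrapolated beyond 150 days or to children under 12 months.

**PPV/NPV uncertainty propagation.** With PPV/NPV treated as known
constants, the replicate interval reflects only binomial misclassification
noise; when the predictive values are themselves held-out *estimates*,
their sampling error shifts the whole distribution and the nominal 90%
interval under-covers the true exposed count (in our calibration
experiments, roughly 60–75% coverage, versus near-nominal coverage when
the true predictive values are supplied). `run_microsim` therefore accepts
the held-out confusion counts (tp, fp, tn, fn) and, when given, draws
PPV ~ Beta(tp+½, fp+½) and NPV ~ Beta(tn+½, fn+½) (Jeffreys) per
replicate before the binomial adjustment. The fixed-constant path remains
the default for fidelity to the original procedure; the propagation path
restores approximately nominal coverage and is what the coverage tests
exercise.

## Numerical choices and degenerate inputs

- Percent rounding half-up (decimal arithmetic), 2 decimals.
- Percentiles: linear interpolation (so values 1..100 give a 5.95–95.05
  interval).
- A zero-width slope CI returns the constant; an empty regional pool falls
  back up the chain; an empty citywide pool is an error.
- A replicate with no exposed blocks reports a BLL increase of 0.
- Hyperparameter grid ties break toward the first grid entry.
- CSV everywhere, UTF-8, header row; `truth_` columns are synthetic ground
  truth and must never be fed to inference.

## Problem sizes in tests

The test and calibration experiments use cities of 300–4,000 blocks,
microsimulations of 200–10,000 replicates and 50-seed replication loops —
sizes chosen so each experiment's Monte Carlo error is small relative to
the tolerance it asserts (e.g. 2-SE parameter-recovery checks across 50
seeds, 3-SE binomial concentration checks at n = 10,000).

## Known limitations

- Relative BLL increases only; no absolute BLLs and no downstream health
  outcomes (IQ, preterm birth) are modelled.
- The misclassification adjustment assumes held-out PPV/NPV transport to
  untested blocks; under strong selection this is an approximation, and
  the Beta propagation widens intervals but does not remove transport
  bias.
- The per-block test-count distribution (Poisson, min 1) is a modelling
  choice; real programs may be more dispersed.
- Survey water-source data are joined at race level in the synthetic
  setting; finer survey geography would change the stratified (not the
  total) exposure counts.
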