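# Methods

## Energy-expenditure model

All energy arithmetic follows the Japanese per-body-surface-area
convention.  BSA (cm²) = weight^0.444 × height^0.663 × 88.83 with weight
in kg and height in cm; BMR (kcal/day) = standard value (kcal/m²/h) ×
BSA × 24 / 10⁴.  The standard values are a (sex, age-band) table; the
authoritative printed source for the original analysis is not publicly
reproduced, so the shipped `src/metcal/data/bmr_reference.csv` is a
stand-in approximating the classic Japanese standard table (female
values 34.3 → 29.9 kcal/m²/h from ages 18–29 to 70–79).  Any CSV with
columns `sex, age_min, age_max, kcal_per_m2_per_h` (contiguous,
non-overlapping bands, positive values) can be substituted; all
downstream numbers scale accordingly.

Activity energy for one bout is MET × hours × weight × 1.05 kcal.  The
questionnaire reports weekly hours; the TEE sum divides them by 7 so
that all TEEs are kcal/day.  Off-duty light time PA₈ is the residual
168 − 7·sleep − ΣPA₁..₇ and must be non-negative; a negative residual
raises an error by default, with an opt-in clip-to-zero mode for messy
survey data.  The thermic effect of food is defined as TEE/10, which we
implement by the exact algebraic closure TEE = S/0.9 (S = sleep term +
activity sum) rather than fixed-point iteration — the two are
mathematically identical and the closure is exact to machine precision
(the test suite checks TEF ≡ 0.1·TEE at 1e−9 relative tolerance).

The 7-day accelerometer TEE adds to the daily device output an imputed
energy for non-wear episodes (bathing fixed at 1.5 METs; other known
activities at a caller-supplied compendium intensity) plus BMR ×
sleep/24 for sleep, and averages the 7 days.  Device output is treated
as the complete waking worn-time EE; whether it embeds a BMR component
is not externally specified, and the additive assembly here is the
plainest reading of the measurement description.

MVPA is the weekly sum of reported category hours whose MET is ≥ 3.0
(inclusive threshold, so a 3.0-MET category qualifies); sleep (1.0 MET)
and residual light time never count.  Exercise volume Ex = Σ MET ×
hours over the same categories.

Two tabulated "light physical activity (min/week)" survey items exist in
the source tables but conflict with the residual-time definition of
PA₈; the TEE computation always uses the residual definition and any
reported light-activity column is ignored for TEE.

## Bayesian MET calibration

The observation model is the minimal one consistent with the design:
accelerometer TEE_j ~ Normal(questionnaire TEE_j(MET₁..₈), σ²),
independent across participants.  Given anthropometry, sleep and
reported hours, the questionnaire TEE is linear in the METs
(Q = offset + X·met with X_ji = w_j·1.05·PA_ji/(7·0.9)), which the
sampler exploits; a reference `log_posterior` recomputes the density
through the full TEE routine and the two paths are tested for equality.

Priors: independent gammas per MET with mean equal to the midrange
value and shape 4 (coefficient of variation 0.5) — right-skewed,
strictly positive, weak relative to the likelihood for any category
with appreciable reported time.  The questionnaire's printed anchor
ranges are available as *optional* hard truncation but are **off by
default**: the calibrated reference values for walking (1.8), moderate
(2.4) and vigorous (4.4) lie outside their anchor ranges (2.0–4.0,
3.0–5.0, 5.0–8.0), so a truncated model cannot produce them; the ranges
act as soft prior centring instead.  σ has a half-normal prior with
scale 300 kcal/day; `sigma_fixed` freezes it instead (whether the
original analysis estimated or fixed σ is unstated, and the fixed mode
also enables an exact chain-vs-grid validation).  The phrase "gamma
distributions as the posterior distributions" in the source is read as
gamma *priors*, since posteriors are not chosen.

Sampler: componentwise random-walk Metropolis on the log scale over the
nine parameters, with batch adaptation of the proposal scales toward a
0.44 acceptance rate during burn-in only (step ±min(0.1, b^−1/2) per
50-iteration batch); the kept chain uses frozen scales and is therefore
Markov.  Defaults are 1,000 burn-in and 10,000 kept iterations,
initialised at the midrange METs and σ₀ = 200 kcal.  Identical seed,
config and data give bitwise-identical chains.  Categories with no
reported time in any record trigger a prior-dominated warning rather
than an error.  Summaries report the posterior mean, SD, empirical
2.5/97.5 percentiles, an effective sample size from the
initial-positive-pair autocorrelation sum, and a Geweke z comparing the
first 10% with the last 50% of the chain.

## Agreement statistics

Mean difference and SD are over questionnaire − accelerometer pairs.
The percentage difference is computed on cohort means,
(mean Q − mean A)/mean A × 100, the convention consistent with the
reported summary statistics; a per-pair mode is provided.  Bland–Altman
bias is the mean difference and the 95% limits of agreement are bias ±
1.96·SD, with the per-pair (mean, difference) table emitted for
plotting.  The ICC is fixed as ICC(2,1) — two-way, absolute agreement,
single measurement — computed from the paired-ANOVA mean squares with
the McGraw–Wong F-based 95% CI; the variant used originally is
unspecified, and ICC(2,1) is the standard choice for method agreement
on single measurements.  Perfectly agreeing columns return ICC 1 with a
degenerate interval; near-zero between-subject variance triggers a
warning rather than an error.

## Cohort pipeline

Exclusion is sequential in the stated order (pregnancy, missing
anthropometry, missing activity responses), attributing each record to
the first criterion it trips; the published counts sum exactly to input
minus retained, implying this mutually exclusive attribution.  Age
groups are 25–29 and then inclusive decades to 60–69; out-of-range ages
are binning errors.  The Jonckheere–Terpstra statistic is the sum of
Mann–Whitney counts (ties ½) over ordered group pairs, tested two-sided
against a tie-corrected normal approximation, with exhaustive
permutation enumeration for total n ≤ 12 (sidedness is not externally
specified; two-sided is the conservative choice).  ANOVA + Tukey HSD
run through scipy (`f_oneway`, `tukey_hsd`), and pairwise Mann–Whitney
uses scipy's tie-corrected implementation with p multiplied by C(k,2)
and capped at 1.  ANOVA is applied to TEE and the nonparametric battery
to MVPA by default; both are callable on either outcome.

## Synthetic cohorts

The generators reproduce the published marginal structure, not real
survey microdata.  Every variable is a truncated normal (activity times
truncated at zero, matching reported means/SDs of non-negative
variables), with a point mass at zero for the off-duty exercise
categories whose published medians are zero (moderate p₀ = 0.5 in the
validation sample, 0.6 in the baseline strata; vigorous 0.8/0.9; very
vigorous absent from the tables, so its occurrence defaults to zero and
is configurable).  The nonzero component's location is scaled by
1/(1 − p₀) to preserve the published overall mean before truncation.
`MarginalSpec.implied_mean/implied_sd` give the analytic moments of the
resulting mixture, and distribution-fidelity tests compare samples
against those implied moments (4 SE at n = 5,000).

Height is Normal(158, 5.5) cm truncated to [140, 180] — the adult
Japanese female reference, as the tables report BMI but not height —
and weight is derived as BMI·(height/100)² to honour the BMI
statistics.  Weekly feasibility (7·sleep + ΣPA ≤ 168) is enforced by
proportional shrinkage of the activity row, a <0.1% event under the
default marginals.  Within-person correlations between activity
categories are not modelled beyond the budget constraint.  Baseline
records are allocated to the five age strata proportionally to the
published stratum sizes (490 / 13,553 / 11,547 / 5,093 / 254), each
stratum with its own published activity marginals; exclusion flags are
independent Bernoulli draws at the published rates, or exact
mutually-exclusive counts in fixture mode for deterministic accounting
tests.

The validation generator sets accelerometer TEE = questionnaire TEE
under the configured *true* MET set (default: the calibrated reference
set) plus additive Gaussian noise, σ default 150 kcal/day (the reported
SD of the questionnaire-vs-accelerometer difference under the
calibrated METs); 9/31 of participants are two-season by default and
receive the average of two noise draws.  A constant device bias is
available and defaults to 0.  What passing tests show is therefore
internal validity — recovery of known METs from data generated by the
stated model — not agreement with any real cohort: real questionnaire
error is not additive Gaussian, activity reports are heaped at round
numbers, and categories correlate within person.

## Experiment sizes and numerical choices

The recovery experiment uses 20 replicates of n = 200 with σ = 100
kcal/day: coverage is assessed per replicate (≥ 6 of 8 METs inside the
95% credible interval) and bias on the replicate-averaged posterior
means of the well-identified categories (implied mean reported time
> 1 h/week — the four work categories and residual light time), since a
single replicate's sampling error in the sparse heavy-work category is
itself a sizeable fraction of the 15% bias budget.  The consistency
experiment uses one n = 5,000, σ = 10 cohort (2% budget).  Trend-test
calibration uses 2,000 replicates of five exchangeable Normal groups of
20.  The MVPA age-trend contrast uses 20 rosters of n = 2,000; the
calibrated-MET trend must reach p < 0.05 in ≥ 95% of seeds and its mean
|z| must exceed the midrange one (the midrange trend is diluted because
moderate activity, which rises with age, then counts as MVPA).
p-values at these effect sizes can underflow, so the contrast is stated
on |z|.

Degenerate inputs: all-tied trend data give z = 0, p = 1; zero
within-group variance everywhere is an ANOVA error; an empty age group
is omitted from summaries with a warning; ICC ties are handled by
midranks inside scipy.  All randomness flows from explicit integer
seeds through `numpy.random.default_rng`; no routine consults ambient
entropy.

## Known limitations

* The BMR standard table is a documented stand-in; absolute TEE levels
  (not the calibration logic) depend on it.
* The likelihood treats two-season (noise-averaged) records as having
  the same residual variance as single-season ones.
* The ICC confidence interval assumes the two-way ANOVA normality
  conditions; with n = 31-scale samples it is approximate.
* The exact Jonckheere–Terpstra option enumerates multinomial
  assignments and is limited to total n ≤ 14.
* Figure rendering is out of scope; the package emits plot-ready tables
  (Bland–Altman pairs, group summaries) instead.
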