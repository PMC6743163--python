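# metcal

Calibration of the MET intensity values behind a short self-administered
physical-activity questionnaire for midlife working women, validated
against accelerometer-measured energy expenditure, plus the downstream
cohort analyses (total energy expenditure and MVPA by age group).

## The problem

Short questionnaires for large epidemiological surveys ask for weekly
hours in a handful of intensity categories — here four on-duty
categories (sitting, standing, walking, heavy work) and three off-duty
exercise categories (moderate, vigorous, very vigorous), with off-duty
*light* activity defined as the residual of the 168-hour week after
sleep.  Turning those hours into energy expenditure requires a MET value
per category.  Conventionally one assigns the midpoint of each
category's anchor range ("midrange" METs: 1.3, 1.5, 2.5, 6.0 at work;
3.0, 6.0, 10.0 off duty; 1.5 for light).  This package instead
*estimates* the eight reference METs by Bayesian calibration against
7-day accelerometer TEE in a small paired validation sample, and then
propagates either MET set through a large baseline cohort.

## The model

Questionnaire TEE (kcal/day) for a person with weight *w* (kg), daily
sleep *s* (h) and weekly category hours PA₁..PA₈ (PA₈ the residual):

    TEE = BMR·(s/24) + TEF + Σᵢ w · 1.05 · (PAᵢ/7) · METᵢ
    TEF = TEE/10            (thermic effect of food)
    BMR = standard value (kcal/m²/h) · BSA (cm²) · 24 / 10⁴
    BSA = w^0.444 · h^0.663 · 88.83      (h = height in cm)

The TEF definition closes algebraically: TEE = S/0.9 where S is the
sleep term plus the activity sum.  For calibration, each validation
participant's accelerometer TEE is modelled as
Normal(questionnaire TEE(MET₁..₈), σ²) — linear in the unknown METs —
with right-skewed gamma priors centred on the midrange values (the
anchor ranges are available as optional hard truncation) and a
half-normal prior on σ.  An adaptive Metropolis-within-Gibbs sampler
(1,000 burn-in, 10,000 kept draws) yields posterior means and 95%
credible intervals for the eight METs.

Downstream, the package computes method agreement (mean and percentage
difference, Bland–Altman limits of agreement, ICC(2,1) with an F-based
95% CI) and the cohort battery: sequential exclusion filtering, age
groups (25–29, 30–39, …, 60–69), per-group TEE and MVPA (hours/week at
≥ 3 METs), one-way ANOVA + Tukey HSD, the Jonckheere–Terpstra ordered
trend test (tie-corrected, with an exact small-sample option) and
pairwise Mann–Whitney with Bonferroni adjustment.

Because no individual-level data are deposited, the package ships
seeded generators that emulate the two cohorts' published marginal
structure — a 31-person validation sample and a 30,937-person baseline
sample in five age strata — with known true METs and additive
accelerometer noise, so every claim is testable end to end.

## Worked example

```python
from metcal import (ActivityProfile, MetSet, Participant,
                    questionnaire_tee, mvpa_hours)

p = Participant(id="demo", age=45, weight=53.0, height=158.0)
profile = ActivityProfile(
    sleep_hours_per_day=7.2,
    work_hours=(13.9, 12.1, 11.4, 1.1),        # h/week
    offduty_hours=(0.6, 7.4 / 60.0, 0.0),      # h/week
)
for mets in (MetSet.midrange(), MetSet.estimated()):
    print(mets.label, round(questionnaire_tee(p, profile, mets), 1),
          "kcal/day, MVPA", round(mvpa_hours(profile, mets), 2), "h/wk")
```

prints

```
midrange 2079.5 kcal/day, MVPA 1.82 h/wk
estimated 1711.0 kcal/day, MVPA 1.22 h/wk
```

The midrange METs give a ~370 kcal/day higher TEE for the same
answers, and the moderate-activity 0.6 h/week counts toward MVPA only
under the midrange value (3.0 ≥ 3) — not under the calibrated 2.4.

The full two-study workflow lives in `analysis/`:

```bash
python analysis/01_simulate_cohorts.py --seed 1   # both synthetic cohorts
python analysis/02_calibrate_mets.py   --seed 1   # MCMC calibration + agreement
python analysis/03_age_trends.py       --seed 1   # exclusions, age groups, tests
```

On the seed-1 cohorts this prints, among other things, posterior MET
estimates with 95% credible intervals, an agreement panel in which the
calibrated METs track the accelerometer far more closely than the
midrange ones (mean difference +4 ± 110 kcal/day, +0.2%, ICC 0.94
versus +397 ± 129 kcal/day, +20.9%, ICC 0.55), exclusion accounting
(48,618 − 998 − 1,416 − 15,267 = 30,937 retained) and a
Jonckheere–Terpstra MVPA age trend that is steeper under the calibrated
METs (z = −24.7) than under the midrange METs (z = −19.2).  Summary
tables land in `results/`; bulky intermediates (raw chains, the full
roster) go to `scratch/`.

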