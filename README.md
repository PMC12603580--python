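# gravida

Spline-GEE modelling of wearable biobehavioral trajectories across
pregnancy, with a gestational-age-matched pre-loss divergence analysis
and a seeded synthetic-cohort generator.

## The problem

Consumer ring wearables record sleep durations and stages, nocturnal
skin temperature, sleep heart rate (HR), heart-rate variability (HRV),
respiratory rate and daily steps every day for months. Across a
pregnancy these signals shift in characteristic, strongly nonlinear
ways: sleep and temperature peak in the first trimester, HR climbs
toward the third trimester while HRV mirrors it downward, activity dips
early and again before birth. Quantifying these population trajectories
— and asking whether they diverge in the weeks before an early
pregnancy loss — requires longitudinal models that respect within-person
correlation and between-person baseline differences.

`gravida` is aimed at biostatisticians and digital-health researchers
who want a tested, reusable implementation of that analysis pipeline.
Real cohorts of this kind are privacy-protected, so the package ships a
first-class synthetic generator that emulates the data structure
(64-week windows spanning 8 prepregnancy weeks through 56 weeks after
the last menstrual period, term/preterm/loss outcome mix, missing days,
self-reported dates) with trajectory templates anchored at published
landmark deviations.

## The model

Each metric is normalised per individual as a z-score against their
prepregnancy baseline — the mean and SD over the 28 days before the
estimated pregnancy start (expected due date − 280 days when a due date
is reported, otherwise the reported LMP date). Weekly means of the
z-scores are modelled with generalized estimating equations (GEE),
identity link, clustering on participant with an exchangeable working
correlation α and dispersion φ:

```
E[z_it] = β₀ + B(week_it)ᵀ β,          V_i = φ[(1−α)I + α 11ᵀ]
```

where `B` is a cubic B-spline basis with 8 degrees of freedom (quantile
interior knots, clamped boundary). Coefficient covariances use the
robust sandwich `B⁻¹MB⁻¹`, valid even when the working correlation is
wrong, and effects are assessed with joint Wald χ² tests on coefficient
blocks. Maternal-age and BMI moderation enters through covariate
B-splines plus tensor-product interactions with the gestational-age
spline.

For pregnancies ending before 20 weeks, the 28 days up to and including
the end day are extracted as gap-filled daily z-scores, paired with a
randomly sampled term pregnancy observed over the same gestational-day
window, and modelled with a 3-df spline of day-relative-to-end plus a
linear outcome term and an outcome-by-day interaction. Effect sizes are
the mean modelled term-minus-loss differences over the 28-day and final
7-day windows; a divergence-onset estimator reports the earliest day
from which the fitted loss curve stays below the term curve by more
than a threshold (default 0.25 z).

The GEE solver is implemented in this package (vectorised
Sherman–Morrison inversion of the exchangeable structure; moment
updates of α and φ) and is cross-checked against statsmodels in the
test suite to 1e-4 relative agreement.

## Worked example

Simulate a 200-pregnancy cohort, fit the temperature trajectory, and
run the matched pre-loss analysis for time in bed:

```
$ gravida simulate --n 200 --seed 1 --out demo/cohort
wrote demo/cohort/profiles.csv (200 pregnancies), demo/cohort/daily.csv (61079 records)

$ gravida term --daily demo/cohort/daily.csv --profiles demo/cohort/profiles.csv \
    --metric temp_peak --out demo/results
temp_peak: GA Wald chi2=4404.6 (df=8, p=0.00e+00); extremum +0.295 native units at week 8.3

$ gravida loss --daily demo/cohort/daily.csv --profiles demo/cohort/profiles.csv \
    --metric time_in_bed --seed 1 --out demo/results
time_in_bed: outcome Wald p=2.58e-21; delta_28d=+0.323 z, delta_7d=+0.748 z; onset -15 days (89 pairs)
```

Reading the output: the gestational-age spline block is overwhelmingly
significant (χ²=4404.6 on 8 df), and the fitted temperature curve peaks
+0.295 °C above the individual baselines near week 8–9 — recovering the
+0.3 °C landmark the generator encodes. In the loss analysis the joint
Wald test on {outcome, outcome×day} rejects strongly; time in bed in
the loss group runs 0.32 baseline-SDs below the matched term group over
the final 28 days (0.75 SDs over the final week), with the fitted
divergence onset 15 days before the end — close to the generator's
14-day truth even at 89 pairs.

`gravida run --seed 42 --out results/` executes the whole pipeline
(simulate → preprocess → per-metric trajectory models → per-metric loss
models) and writes curves, test summaries and a reproducibility
manifest; `gravida report results/` assembles summary tables.

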