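# Methods

## Timeline conventions

Gestational age is anchored at the first day of the last menstrual
period (LMP): day 0. When an expected due date is reported, pregnancy
start is the due date minus 280 days (40 weeks) and takes precedence
over a reported LMP date; conception is approximated as LMP + 14 days.
Trimesters are the inclusive day ranges 0–97 (0w0d–13w6d), 98–195
(14w0d–27w6d) and 196–286 (28w0d–40w6d). The analysis window covers
day offsets −56…391 (8 prepregnancy weeks + 56 weeks). Gestational
week *w* is the half-open 7-day bin of days 7w…7w+6, so "week 9" means
days 63–69; negative offsets bin the same way. The model's weekly time
axis is the integer bin label, which places the fitted curve roughly
half a week early relative to continuous time — immaterial at the
resolution of the reported landmarks, but worth knowing when reading
peak weeks off fitted curves.

Outcome labels are validated against the gestational age implied by
the dates (loss < 140 days, preterm < 259, term 259–294); mismatches
are logged as warnings rather than raised, because self-reported dates
carry recall noise.

## Preprocessing

Order of operations: (1) deduplicate to one record per
participant-day, keeping the last-seen row; (2) blank sleep-period
metrics (sleep durations and stages, nocturnal temperature, HR, HRV,
respiratory rate) on rows not flagged as main sleep, keeping daily
steps; (3) exclude pregnancies with under 40% of days observed in the
prepregnancy window or in any trimester the pregnancy overlaps —
a trimester is assessed over its intersection with [0, end day], and
trimesters never reached (e.g. T2 for a week-10 loss) are not
assessed; (4) average observed days into gestational-week bins, with
no weekly-level imputation; (5) z-score weekly values against the
individual's baseline mean and sample SD (n−1) over days −28…−1.

A baseline is valid when it has at least 7 observed days and SD ≥ 1e-6
native units; participants with an invalid baseline are dropped from
that metric's analyses. These validity floors are package choices:
they keep z-scores well defined without discarding sparse but usable
participants.

The daily-resolution path used by the pre-loss analysis linearly
interpolates interior gaps of at most 7 days (configurable); longer
runs and leading/trailing gaps stay missing. The cap prevents bridging
multi-week gaps inside the 28-day window.

## The GEE engine

Identity-link Gaussian GEE with exchangeable working correlation.
Each iteration recomputes moment estimates — dispersion
φ = Σe²/(N−p) and correlation
α = Σᵢ Σ_{j<k} e_ij e_ik / (φ(Σᵢ nᵢ(nᵢ−1)/2 − p)) — from the current
residuals, then solves the weighted normal equations with
Vᵢ = φ[(1−α)I + α11ᵀ]. The exchangeable inverse is applied through
the Sherman–Morrison identity, so the solver is a handful of matrix
products over cluster-summed statistics with no per-cluster Python
loop. Convergence: max |Δβ| < 1e-8, at most 100 iterations, with at
least one α refinement before convergence is declared;
non-convergence is flagged on the result, never silent. α is clamped
to its valid range (−1/(max nᵢ − 1), 1); a perfect fit (φ = 0)
degenerates to zero covariances. The robust covariance is the
sandwich B⁻¹MB⁻¹.

B-spline bases are cubic with interior knots at quantiles of the
observed predictor and clamped boundary knots at its min/max;
evaluation uses the de Boor recursion (via scipy's B-spline design
matrix), verified in tests against an independent textbook Cox–de Boor
implementation. The first basis column is dropped (absorbed by the
intercept) and `df` counts retained columns, so df=8 means 5 interior
knots. Prediction outside the training boundary raises rather than
extrapolates. Tensor-product interactions are all pairwise column
products, A-major.

Joint Wald tests use the robust covariance: W = β_Sᵀ V_SS⁻¹ β_S with
df = |S|. A singular sub-covariance raises an error naming the block —
no generalized inverse, because singularity indicates a design problem
that should be fixed, not papered over.

For models with age/BMI moderation the default test per covariate is
the joint Wald over the main-effect spline block and the
tensor-interaction block together (the interaction-only test is
available via a flag). A known caveat, visible in the test suite: with
many tested degrees of freedom (12 df for a 3-df covariate spline plus
its 3×3 tensor block) the sandwich-based Wald is mildly liberal at
hundreds of clusters — simulated type-I error runs around 0.07–0.11 at
nominal 0.05 — and approaches nominal only at cohort sizes in the
thousands. The engine-level test with 4 tested df at 100 clusters is
calibrated within [0.03, 0.08].

## Analysis 1: term trajectories

Per metric, weekly z-values of term pregnancies are regressed on an
intercept plus an 8-df spline of gestational week (clusters =
participants), with the gestational-age effect tested jointly on the
spline block. The spline domain is the full observed week range,
prepregnancy weeks included. Fitted z-curves convert to native units
through the cohort-median baseline SD (per-participant conversion then
averaging is the obvious alternative; the median is robust to
heavy-tailed SD estimates). Summaries report the mean fitted deviation
per trimester, plus a postpartum segment (weeks 41–56) added for
completeness. The covariate model adds 3-df age and BMI splines and
their tensor products with the gestational-age spline; 3 df keeps the
covariate curves monotone-ish and the parameter count proportionate to
typical cohort sizes.

## Analysis 2: pre-loss divergence

Pregnancies ending before 20 weeks contribute the 28 days up to and
including the end day (a case ending at 7w1d spans 3w2d–7w1d); cases
ending before gestational day 28 cannot host the window and are
dropped. Each case is matched to a term pregnancy sampled uniformly —
without replacement while the pool lasts, then with replacement — and
required to observe at least 40% of the same gestational-day window
(up to 50 redraws). The GEE models daily z on a 3-df spline of
day-relative-to-end (−27…0), an outcome indicator and an
outcome-by-day linear interaction, clustering by pregnancy; the
outcome effect is the joint Wald on {outcome, outcome×day}. Effect
sizes are mean modelled term−loss differences over the 28-day and
7-day windows, computed from fitted curves, not raw means.

The divergence onset is the most negative day d* such that the fitted
loss−term difference stays below −q for every day in [d*, 0], with
q = 0.25 z by default. Both q and the sustained-through-end
requirement are package choices (published accounts describe onset
only qualitatively); q is exposed in configuration. Because the fitted
between-group difference in this model is linear in day, the onset
estimator effectively locates where that line crosses −q, which tracks
a ramp-shaped truth well but cannot represent multi-phase divergence.

## The synthetic cohort generator

The generator is the package's study bed: real cohorts of this kind
are not public. Per pregnancy it draws age ~ N(32.2, 4.5²) years and
BMI ~ N(25.3, 5.4²) kg/m² (clipped to plausible ranges), an outcome
from the configured mix (defaults 48.8% term / 3.1% preterm / 48.0%
loss), an end day uniform within the outcome's gestational range
(loss weeks 4–20, preterm 28–36, term 37–42), an LMP date, and a due
date recorded for 49.3% of pregnancies (due = LMP + 280, so both
self-report routes agree exactly; date-noise between the two routes is
not simulated). Daily metric values are
`baseline constant + template deviation(week) + subject intercept +
daily Gaussian noise`, days dropped independently at 15%, and 3% of
retained days marked as nap nights. Steps are rounded and floored at
zero; all metrics are floored at physical zero, and sleep-stage
percentages are kept inside a feasible simplex. `time_in_bed` is
generated as `time_asleep + time_awake` and `rem_pct` as
`100 − light − deep`, so the structural identities hold exactly.

Noise magnitudes are free parameters with no published values to
anchor them: daily
residual SDs default to 0.45 h asleep, 0.30 h awake, 0.15 °C
temperature, 2.5 bpm HR, 8 ms HRV, 0.6 breaths/min, 2500 steps, with
between-subject intercept SDs of similar order — values a ring-wear
dataset would plausibly show. The random-intercept construction makes
within-subject correlation exchangeable by design (ICC = s²/(s²+r²)),
which is exactly the working assumption of the estimator; passing
recovery tests therefore validate the pipeline's correctness, not its
robustness to correlation misspecification (the sandwich covariance
addresses that analytically, and the robust-vs-naive test exercises
it only under exchangeability).

Template anchors are weekly samples of smooth curves constructed to
lie in the same 8-df spline space the estimator uses, constrained to
hit each published landmark exactly — value and zero slope at the
landmark week, measured relative to the 4-week baseline-window mean,
with the prepregnancy segment pinned near zero. The published curves
are themselves 8-df spline fits, so a landmark riding on structure the
basis cannot represent would not be the estimand of the stated model;
spline-representable truths keep the printed landmark identifiable.
A cost of the pinned baseline and limited basis resolution is that the
first-trimester biphasic HR/HRV wiggle (an early peak near week 5 and
dip near week 9) is flattened into a monotone rise in the default
templates; the headline landmarks are unaffected.

Loss pregnancies follow the term template until a per-metric
divergence onset before the end day, then ramp linearly to a
per-metric end deviation (defaults: asleep −0.50 h from 14 days out;
awake −0.10 h, temperature −0.22 °C, respiratory rate −0.45 /min from
7 days; HR −2.5 bpm from 4 days; steps and HRV no divergence), with a
14-day linear recovery after the end. The implied time-in-bed
divergence starts 14 days out (through the sleep component) and
reaches ≈ −0.6 h (~−1.1 z) at the end.

Age/BMI modifiers on a template act only inside a gestational-week
window (default weeks 0–40): a modifier active during the baseline
window would be absorbed by the individual z-scoring and be
unestimable by construction.

Everything is a deterministic function of the configuration seed; the
pipeline seed feeds named substreams (cohort generation, control
matching) so stages are independently reproducible.

## Problem sizes

The bundled recovery checks run at 500 term pregnancies for the
trajectory landmarks and 300 matched pairs for the divergence
analysis; engine calibration uses 500 replicates of 100 clusters × 8
observations (4 tested df) and 250 replicates of 400 clusters × 20
weeks for the covariate-model null. These sizes give Monte-Carlo noise
comfortably inside the stated tolerances (e.g. the fitted temperature
peak varies by ~0.005 °C across seeds at n=500).

## Known limitations

* Gaussian daily noise and a single random intercept per metric: no
  heteroscedasticity over gestation, no autocorrelated wear gaps, no
  weekday/weekend activity structure, no device or firmware effects.
* Missingness is completely at random; real non-wear correlates with
  the physiology being measured.
* The loss generator diverges linearly and recovers linearly;
  etiology-specific signatures are out of scope.
* Preterm pregnancies are generated (for outcome-mix realism) but not
  modelled separately.
* The onset estimator assumes a sustained, monotone-through-threshold
  divergence; it returns nothing when the end-day difference does not
  clear the threshold.
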