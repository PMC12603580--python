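"""Seeded synthetic cohorts of daily ring-wearable data across pregnancy.

The real study cohort is privacy-protected, so this module generates
cohorts with the statistical structure the downstream analyses assume:
per-pregnancy metadata (age, BMI, self-reported LMP and/or due date,
outcome, pregnancy end) and one wearable record per participant-day over
an 8-weeks-prepregnancy .. 56-weeks window, with

* per-metric nonlinear mean trajectories over gestational age, encoded as
  piecewise-linear :class:`TrajectoryTemplate` anchors whose landmark
  values are the published cohort-level deviations (e.g. nocturnal skin
  temperature peaking +0.3 °C above baseline at week 9, heart rate
  +10 bpm at week 32, a ≈2000-step deficit near week 8);
* a subject-level random intercept plus independent Gaussian daily noise,
  which induces an exchangeable within-subject correlation of
  s²/(s²+r²);
* missing days, occasional nap (non-main-sleep) nights, and two sources
  of pregnancy-start self-report (expected due date vs LMP date);
* for pregnancies ending in early loss, trajectories that track the term
  template until a divergence onset (default 14 days before the end) and
  then ramp linearly to a per-metric end deviation, with signs matching
  the published pre-loss decreases.

Structural identities are enforced by construction: ``time_in_bed`` is
generated as ``time_asleep + time_awake`` (their default templates sum to
the published +30 = +15 + 15 minute week-9 landmarks) and ``rem_pct`` as
``100 − light_pct − deep_pct``.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .timeline import (
    OUTCOME_LOSS,
    OUTCOME_PRETERM,
    OUTCOME_TERM,
    TERM_DURATION_DAYS,
    WINDOW_END_DAY,
)

#: All wearable metrics carried by a daily record.
METRICS = [
    "time_in_bed",
    "time_asleep",
    "time_awake",
    "light_pct",
    "deep_pct",
    "rem_pct",
    "temp_peak",
    "hr",
    "hrv",
    "rr",
    "steps",
]

#: Metrics measured during the main (nocturnal) sleep period; daily steps
#: are accumulated over the whole day and are not sleep-gated.
SLEEP_GATED_METRICS = [m for m in METRICS if m != "steps"]

#: Metrics simulated directly; the rest are structural sums/complements.
_GENERATED_METRICS = [
    "time_asleep",
    "time_awake",
    "light_pct",
    "deep_pct",
    "temp_peak",
    "hr",
    "hrv",
    "rr",
    "steps",
]

#: Cohort centre used to anchor age/BMI modifier terms (published means).
REFERENCE_AGE = 32.2
REFERENCE_BMI = 25.3

#: Postpartum follow-up simulated after pregnancy end.
POSTPARTUM_SPAN_DAYS = 112

PROFILE_COLUMNS = [
    "participant_id",
    "age",
    "height_m",
    "weight_kg",
    "lmp_date",
    "due_date",
    "end_date",
    "outcome",
]

DAILY_COLUMNS = ["participant_id", "date"] + METRICS + ["is_main_sleep"]


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrajectoryTemplate:
    """Piecewise-linear mean deviation from prepregnancy baseline.

    ``anchors`` are (gestational week, deviation in native units) pairs
    with strictly increasing weeks; the earliest (prepregnancy) anchor
    must sit at deviation 0 so the baseline is identifiable.  Optional
    age/BMI modifiers add ``slope × (covariate − cohort reference)`` to
    the deviation, but only inside their gestational-week window —
    a covariate shift active during the baseline window would be absorbed
    by the per-individual z-scoring and be unestimable by design.
    """

    metric: str
    anchors: Tuple[Tuple[float, float], ...]
    age_modifier: float = 0.0
    bmi_modifier: float = 0.0
    age_window: Tuple[float, float] = (0.0, 40.0)
    bmi_window: Tuple[float, float] = (0.0, 40.0)

    def __post_init__(self) -> None:
        weeks = [w for w, _ in self.anchors]
        if len(weeks) < 2:
            raise ValueError("template needs at least two anchors")
        if not all(b > a for a, b in zip(weeks, weeks[1:])):
            raise ValueError("anchor weeks must be strictly increasing")
        if abs(self.anchors[0][1]) > 1e-12:
            raise ValueError("deviation at the earliest anchor must be 0")

    @property
    def week_range(self) -> Tuple[float, float]:
        return self.anchors[0][0], self.anchors[-1][0]


def evaluate_template(
    template: TrajectoryTemplate,
    week,
    age: float = REFERENCE_AGE,
    bmi: float = REFERENCE_BMI,
):
    """Native-unit mean deviation at gestational ``week`` (scalar or array).

    Piecewise-linear interpolation of the anchors plus the windowed
    age/BMI modifier terms.  Weeks outside the anchor range raise.
    """
    w = np.asarray(week, dtype=float)
    lo, hi = template.week_range
    if np.any(w < lo) or np.any(w > hi):
        raise ValueError(f"week outside template range [{lo}, {hi}]")
    xs = np.array([a[0] for a in template.anchors])
    ys = np.array([a[1] for a in template.anchors])
    dev = np.interp(w, xs, ys)
    if template.age_modifier != 0.0:
        in_win = (w >= template.age_window[0]) & (w <= template.age_window[1])
        dev = dev + np.where(in_win, template.age_modifier * (age - REFERENCE_AGE), 0.0)
    if template.bmi_modifier != 0.0:
        in_win = (w >= template.bmi_window[0]) & (w <= template.bmi_window[1])
        dev = dev + np.where(in_win, template.bmi_modifier * (bmi - REFERENCE_BMI), 0.0)
    return float(dev) if np.isscalar(week) else dev


def _sum_templates(
    metric: str, a: TrajectoryTemplate, b: TrajectoryTemplate
) -> TrajectoryTemplate:
    """Anchor-wise sum of two templates on the union week grid."""
    weeks = sorted({w for w, _ in a.anchors} | {w for w, _ in b.anchors})
    anchors = tuple(
        (w, evaluate_template(a, w) + evaluate_template(b, w)) for w in weeks
    )
    return TrajectoryTemplate(metric=metric, anchors=anchors)


#: Frozen anchor tables of the default templates (weekly samples of smooth
#: landmark-constrained curves; see ``default_templates``).
_DEFAULT_ANCHORS = {
    "temp_peak": (
            (-8, 0), (-7, -0.032606), (-6, -0.048716), (-5, -0.050467), (-4, -0.039996),
            (-3, -0.019439), (-2, 0.009067), (-1, 0.043386), (0, 0.08138), (1, 0.120914),
            (2, 0.159851), (3, 0.196129), (4, 0.228552), (5, 0.256485), (6, 0.279301),
            (7, 0.296374), (8, 0.307078), (9, 0.310785), (10, 0.306869), (11, 0.294704),
            (12, 0.273663), (13, 0.243137), (14, 0.2036), (15, 0.157201), (16, 0.106233),
            (17, 0.05299), (18, -0.000235), (19, -0.051149), (20, -0.097458), (21, -0.136868),
            (22, -0.167086), (23, -0.18582), (24, -0.191523), (25, -0.185647), (26, -0.170391),
            (27, -0.147954), (28, -0.120535), (29, -0.090333), (30, -0.059548), (31, -0.030379),
            (32, -0.005026), (33, 0.014314), (34, 0.025613), (35, 0.028867), (36, 0.025374),
            (37, 0.016452), (38, 0.003423), (39, -0.012396), (40, -0.029684), (41, -0.047122),
            (42, -0.06339), (43, -0.07717), (44, -0.087156), (45, -0.093004), (46, -0.095852),
            (47, -0.096968), (48, -0.097617), (49, -0.099066), (50, -0.102583), (51, -0.109433),
            (52, -0.120884), (53, -0.138201), (54, -0.162652), (55, -0.162652), (56, -0.162652),
    ),
    "hr": (
            (-8, 0), (-7, 0.119559), (-6, 0.251804), (-5, 0.397504), (-4, 0.557427),
            (-3, 0.732339), (-2, 0.923011), (-1, 1.13021), (0, 1.3547), (1, 1.59726),
            (2, 1.85865), (3, 2.13924), (4, 2.43477), (5, 2.73801), (6, 3.04167),
            (7, 3.33846), (8, 3.62108), (9, 3.88225), (10, 4.11468), (11, 4.31109),
            (12, 4.46417), (13, 4.5668), (14, 4.62146), (15, 4.6455), (16, 4.65758),
            (17, 4.67634), (18, 4.72041), (19, 4.80845), (20, 4.95909), (21, 5.19098),
            (22, 5.52277), (23, 5.97309), (24, 6.55028), (25, 7.22142), (26, 7.94331),
            (27, 8.67272), (28, 9.36642), (29, 9.9812), (30, 10.4738), (31, 10.8011),
            (32, 10.9198), (33, 10.7867), (34, 10.3634), (35, 9.6675), (36, 8.75274),
            (37, 7.67346), (38, 6.484), (39, 5.23872), (40, 3.99195), (41, 2.79803),
            (42, 1.71131), (43, 0.786124), (44, 0.076258), (45, -0.398329), (46, -0.670094),
            (47, -0.776004), (48, -0.753025), (49, -0.638124), (50, -0.468265), (51, -0.280416),
            (52, -0.111542), (53, 0.001391), (54, 0.021415), (55, 0.021415), (56, 0.021415),
    ),
    "hrv": (
            (-8, 0), (-7, -0.124677), (-6, -0.271963), (-5, -0.450412), (-4, -0.668575),
            (-3, -0.935005), (-2, -1.25825), (-1, -1.64688), (0, -2.10942), (1, -2.65445),
            (2, -3.2905), (3, -4.0243), (4, -4.8412), (5, -5.71278), (6, -6.61039),
            (7, -7.50537), (8, -8.36907), (9, -9.17285), (10, -9.88804), (11, -10.486),
            (12, -10.9381), (13, -11.216), (14, -11.318), (15, -11.2828), (16, -11.1527),
            (17, -10.9701), (18, -10.7774), (19, -10.6169), (20, -10.5309), (21, -10.5619),
            (22, -10.752), (23, -11.1437), (24, -11.7611), (25, -12.5558), (26, -13.4609),
            (27, -14.4099), (28, -15.3359), (29, -16.1722), (30, -16.8522), (31, -17.3091),
            (32, -17.4762), (33, -17.2869), (34, -16.6812), (35, -15.6803), (36, -14.3571),
            (37, -12.7855), (38, -11.0395), (39, -9.19302), (40, -7.31987), (41, -5.49401),
            (42, -3.78934), (43, -2.27979), (44, -1.0386), (45, -0.100256), (46, 0.560895),
            (47, 0.975678), (48, 1.17491), (49, 1.18943), (50, 1.05004), (51, 0.787574),
            (52, 0.432856), (53, 0.016707), (54, -0.43005), (55, -0.43005), (56, -0.43005),
    ),
    "steps": (
            (-8, 0), (-7, 187.44), (-6, 250.383), (-5, 206.835), (-4, 74.8022),
            (-3, -127.71), (-2, -382.696), (-1, -672.149), (0, -978.064), (1, -1282.43),
            (2, -1567.25), (3, -1815.38), (4, -2019.69), (5, -2179.55), (6, -2294.4),
            (7, -2363.71), (8, -2386.93), (9, -2363.53), (10, -2292.96), (11, -2174.68),
            (12, -2008.14), (13, -1792.91), (14, -1534.26), (15, -1246.32), (16, -943.988),
            (17, -642.169), (18, -355.759), (19, -99.6592), (20, 111.232), (21, 262.016),
            (22, 337.792), (23, 323.662), (24, 210.041), (25, 8.60511), (26, -263.654),
            (27, -589.746), (28, -952.678), (29, -1335.46), (30, -1721.1), (31, -2092.61),
            (32, -2433), (33, -2725.27), (34, -2953.42), (35, -3112.87), (36, -3206.4),
            (37, -3236.93), (38, -3207.37), (39, -3120.64), (40, -2979.64), (41, -2787.29),
            (42, -2546.5), (43, -2260.19), (44, -1931.39), (45, -1570.37), (46, -1198.64),
            (47, -838.68), (48, -512.955), (49, -243.938), (50, -54.1016), (51, 34.0824),
            (52, -1.85821), (53, -184.395), (54, -536.001), (55, -536.001), (56, -536.001),
    ),
    "rr": (
            (-8, 0), (-7, -0.051848), (-6, -0.063149), (-5, -0.039124), (-4, 0.015009),
            (-3, 0.09403), (-2, 0.192721), (-1, 0.305863), (0, 0.428236), (1, 0.554622),
            (2, 0.6798), (3, 0.798665), (4, 0.907398), (5, 1.00302), (6, 1.08256),
            (7, 1.14305), (8, 1.18152), (9, 1.195), (10, 1.18053), (11, 1.13513),
            (12, 1.05584), (13, 0.939766), (14, 0.788556), (15, 0.610905), (16, 0.416112),
            (17, 0.213478), (18, 0.012301), (19, -0.178118), (20, -0.348481), (21, -0.489486),
            (22, -0.591836), (23, -0.646231), (24, -0.646622), (25, -0.599974), (26, -0.516502),
            (27, -0.406421), (28, -0.279946), (29, -0.147293), (30, -0.018678), (31, 0.095684),
            (32, 0.185578), (33, 0.240789), (34, 0.252011), (35, 0.220525), (36, 0.154442),
            (37, 0.061987), (38, -0.048617), (39, -0.169145), (40, -0.291373), (41, -0.407077),
            (42, -0.508031), (43, -0.586012), (44, -0.632893), (45, -0.646367), (46, -0.633148),
            (47, -0.600729), (48, -0.556599), (49, -0.508251), (50, -0.463175), (51, -0.428863),
            (52, -0.412806), (53, -0.422494), (54, -0.46542), (55, -0.46542), (56, -0.46542),
    ),
    "time_asleep": (
            (-8, 0), (-7, -0.005498), (-6, -0.003535), (-5, 0.005009), (-4, 0.019256),
            (-3, 0.038325), (-2, 0.061337), (-1, 0.087413), (0, 0.115673), (1, 0.145237),
            (2, 0.175226), (3, 0.20475), (4, 0.232782), (5, 0.258212), (6, 0.279928),
            (7, 0.296817), (8, 0.307766), (9, 0.311663), (10, 0.307395), (11, 0.29385),
            (12, 0.269915), (13, 0.234503), (14, 0.18801), (15, 0.13314), (16, 0.07279),
            (17, 0.009859), (18, -0.052752), (19, -0.112145), (20, -0.165421), (21, -0.209681),
            (22, -0.242024), (23, -0.259554), (24, -0.260566), (25, -0.248151), (26, -0.226594),
            (27, -0.200181), (28, -0.173198), (29, -0.149931), (30, -0.134666), (31, -0.131689),
            (32, -0.145287), (33, -0.179745), (34, -0.238869), (35, -0.320888), (36, -0.420431),
            (37, -0.532068), (38, -0.650369), (39, -0.769902), (40, -0.885238), (41, -0.990946),
            (42, -1.0816), (43, -1.15176), (44, -1.19607), (45, -1.21327), (46, -1.20845),
            (47, -1.18727), (48, -1.15535), (49, -1.11836), (50, -1.08192), (51, -1.05169),
            (52, -1.0333), (53, -1.0324), (54, -1.05464), (55, -1.05464), (56, -1.05464),
    ),
    "time_awake": (
            (-8, 0), (-7, -0.015053), (-6, -0.018395), (-5, -0.011635), (-4, 0.003618),
            (-3, 0.025753), (-2, 0.053161), (-1, 0.084233), (0, 0.117357), (1, 0.150926),
            (2, 0.183328), (3, 0.213015), (4, 0.239153), (5, 0.261364), (6, 0.27928),
            (7, 0.292534), (8, 0.300756), (9, 0.303579), (10, 0.300633), (11, 0.291552),
            (12, 0.275965), (13, 0.25352), (14, 0.224662), (15, 0.191087), (16, 0.154594),
            (17, 0.116983), (18, 0.080055), (19, 0.04561), (20, 0.015449), (21, -0.008629),
            (22, -0.024824), (23, -0.031334), (24, -0.0266), (25, -0.010025), (26, 0.01875),
            (27, 0.060082), (28, 0.114329), (29, 0.181848), (30, 0.262996), (31, 0.358132),
            (32, 0.467612), (33, 0.591795), (34, 0.730738), (35, 0.881023), (36, 1.03698),
            (37, 1.19292), (38, 1.34313), (39, 1.48192), (40, 1.60358), (41, 1.70241),
            (42, 1.77271), (43, 1.80878), (44, 1.80502), (45, 1.76214), (46, 1.6906),
            (47, 1.60171), (48, 1.50676), (49, 1.41708), (50, 1.34396), (51, 1.2987),
            (52, 1.29262), (53, 1.33702), (54, 1.4432), (55, 1.4432), (56, 1.4432),
    ),
}


def default_templates() -> Dict[str, TrajectoryTemplate]:
    """Ground-truth mean curves anchored at the published landmarks.

    Landmarks encoded (term pregnancies, native units, deviation from the
    individual 4-week prepregnancy baseline mean):

    * time asleep +15 min and time awake +15 min at week 9 (hence time in
      bed +30 min); second-trimester settling; wake climbing steeply in
      late gestation so that nightly wake at birth exceeds 3 baseline SDs,
      with postpartum wake ≈ +90 min and sleep ≈ −70 min;
    * nocturnal skin temperature rising through the first weeks to a
      +0.3 °C peak at week 9, declining below baseline mid-pregnancy,
      with a small positive bump near birth;
    * heart rate climbing to +10 bpm at week 32 then dropping sharply at
      birth; HRV the mirrored pattern with a > 15 ms nadir;
    * respiratory rate ≈ +1 breath/min peak near week 9, settling back
      and dropping below baseline post partum;
    * steps ≈ −2000 trough near week 8, partial mid-pregnancy rebound,
      > 2500 below baseline near birth.

    The anchor tables are weekly samples of smooth curves that lie in the
    same 8-df B-spline space the trajectory estimator uses, constrained to
    hit each landmark exactly (value and zero slope at the landmark week,
    measured relative to the baseline-window mean).  The published curves
    are themselves 8-df spline fits, so a landmark that the spline basis
    cannot represent would not be the estimand of the stated model; using
    spline-representable truths keeps the printed landmark identifiable.
    Sleep-stage percentages are flat (no published stage landmarks).
    """
    templates: Dict[str, TrajectoryTemplate] = {
        metric: TrajectoryTemplate(metric, anchors=anchors)
        for metric, anchors in _DEFAULT_ANCHORS.items()
    }
    for stage in ("light_pct", "deep_pct", "rem_pct"):
        templates[stage] = TrajectoryTemplate(
            stage, anchors=((-8, 0.0), (0, 0.0), (56, 0.0))
        )
    templates["time_in_bed"] = _sum_templates(
        "time_in_bed", templates["time_asleep"], templates["time_awake"]
    )
    return templates


@dataclass(frozen=True)
class LossDivergence:
    """Pre-loss deviation of a metric from the term trajectory.

    The loss-group mean tracks the term template until ``onset_days``
    before the pregnancy end, then ramps linearly to ``end_deviation``
    (native units, added to the term curve) on the end day.  After the
    end the deviation decays back to the term curve over
    ``recovery_days``.
    """

    metric: str
    onset_days: int
    end_deviation: float
    recovery_days: int = 14


def default_loss_divergences() -> Dict[str, LossDivergence]:
    """Published pre-loss signature: time in bed starts decreasing about
    two weeks before the end (the sleep component carries the earlier
    onset), sleep duration / temperature / respiratory rate about one
    week before, HR a few days before; steps and HRV show no reliable
    effect.  ``time_in_bed`` is structural (asleep + awake), so its
    divergence is induced through the two components."""
    return {
        "time_asleep": LossDivergence("time_asleep", onset_days=14, end_deviation=-0.50),
        "time_awake": LossDivergence("time_awake", onset_days=7, end_deviation=-0.10),
        "temp_peak": LossDivergence("temp_peak", onset_days=7, end_deviation=-0.22),
        "rr": LossDivergence("rr", onset_days=7, end_deviation=-0.45),
        "hr": LossDivergence("hr", onset_days=4, end_deviation=-2.5),
    }


# ---------------------------------------------------------------------------
# Cohort configuration
# ---------------------------------------------------------------------------

#: Daily residual noise SD per simulated metric, native units.
DEFAULT_RESIDUAL_SD = {
    "time_asleep": 0.45,
    "time_awake": 0.30,
    "light_pct": 4.0,
    "deep_pct": 3.0,
    "temp_peak": 0.15,
    "hr": 2.5,
    "hrv": 8.0,
    "rr": 0.6,
    "steps": 2500.0,
}

#: Between-subject random-intercept SD per simulated metric, native units.
DEFAULT_INTERCEPT_SD = {
    "time_asleep": 0.50,
    "time_awake": 0.20,
    "light_pct": 5.0,
    "deep_pct": 4.0,
    "temp_peak": 0.25,
    "hr": 5.0,
    "hrv": 10.0,
    "rr": 1.0,
    "steps": 2000.0,
}

#: Cohort-level prepregnancy baseline constants, native units.
DEFAULT_BASELINE = {
    "time_asleep": 7.1,
    "time_awake": 1.0,
    "light_pct": 55.0,
    "deep_pct": 20.0,
    "temp_peak": 36.8,
    "hr": 62.0,
    "hrv": 55.0,
    "rr": 14.5,
    "steps": 9500.0,
}

#: Published outcome mix: 5039 term / 324 preterm / 4955 loss of 10,318.
DEFAULT_OUTCOME_PROPORTIONS = {
    OUTCOME_TERM: 5039 / 10318,
    OUTCOME_PRETERM: 324 / 10318,
    OUTCOME_LOSS: 4955 / 10318,
}


@dataclass(frozen=True)
class CohortConfig:
    """Knobs of the synthetic cohort generator.

    Defaults reproduce the published cohort structure where stated (mean
    age 32.2 ± 4.5 y, BMI 25.3 ± 5.4 kg/m², outcome mix, 49.3% of starts
    derived from a due date); noise and missingness magnitudes are free
    parameters of the generator, chosen as plausible ring-wear values and
    documented as such.
    """

    n_pregnancies: int = 100
    outcome_proportions: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_PROPORTIONS)
    )
    age_mean: float = 32.2
    age_sd: float = 4.5
    bmi_mean: float = 25.3
    bmi_sd: float = 5.4
    missing_day_rate: float = 0.15
    nap_rate: float = 0.03
    random_intercept_sd: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INTERCEPT_SD)
    )
    residual_sd: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RESIDUAL_SD)
    )
    due_date_known_fraction: float = 0.493
    divergence: Dict[str, LossDivergence] = field(
        default_factory=default_loss_divergences
    )
    first_lmp_date: dt.date = dt.date(2023, 6, 1)
    lmp_spread_days: int = 365
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.outcome_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"outcome proportions sum to {total}, expected 1")
        if any(v < 0 for v in self.outcome_proportions.values()):
            raise ValueError("outcome proportions must be nonnegative")
        for name in ("missing_day_rate", "nap_rate", "due_date_known_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_pregnancies < 1:
            raise ValueError("n_pregnancies must be >= 1")


@dataclass(frozen=True)
class PregnancyProfile:
    """Per-pregnancy metadata as self-reported in the app."""

    participant_id: str
    age: float
    height: float
    weight_prepregnancy: float
    lmp_date: Optional[dt.date]
    due_date: Optional[dt.date]
    end_date: dt.date
    outcome: str


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

_END_DAY_RANGES = {
    # gestational-day ranges for pregnancy end, inclusive
    OUTCOME_LOSS: (28, 139),  # weeks 4–20 (ends before 20w0d)
    OUTCOME_PRETERM: (196, 258),  # weeks 28–36
    OUTCOME_TERM: (259, 294),  # weeks 37–42
}


def _loss_offset(
    div: LossDivergence, day: np.ndarray, end_day: int
) -> np.ndarray:
    """Additional mean deviation of a loss pregnancy around its end."""
    rel = day - end_day  # 0 on the end day
    ramp = np.clip((rel + div.onset_days) / div.onset_days, 0.0, None)
    pre = np.where(rel <= 0, np.minimum(ramp, 1.0), 0.0)
    post = np.where(
        rel > 0, np.clip(1.0 - rel / div.recovery_days, 0.0, 1.0), 0.0
    )
    return div.end_deviation * (pre + post)


def generate_cohort(
    config: CohortConfig,
    templates: Optional[Dict[str, TrajectoryTemplate]] = None,
) -> tuple[List[PregnancyProfile], pd.DataFrame]:
    """Generate a seeded cohort of profiles and daily wearable records.

    Per pregnancy: the outcome is drawn from the configured proportions
    and the end day uniformly within the outcome's gestational range;
    each simulated metric follows ``baseline + template deviation +
    subject intercept + daily Gaussian noise``; days are dropped
    independently at ``missing_day_rate``; a small share of retained days
    are nap nights (``is_main_sleep = False``).  ``time_in_bed`` and
    ``rem_pct`` are derived from the structural identities.  The whole
    cohort is a deterministic function of (config, templates).

    Returns the profile list and a tidy daily-record DataFrame.
    """
    if templates is None:
        templates = default_templates()
    missing = [m for m in METRICS if m not in templates]
    if missing:
        raise ValueError(f"templates missing for metrics: {missing}")

    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    outcomes = list(config.outcome_proportions)
    probs = np.array([config.outcome_proportions[o] for o in outcomes])

    profiles: List[PregnancyProfile] = []
    frames: List[pd.DataFrame] = []
    for i in range(config.n_pregnancies):
        pid = f"P{i:05d}"
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 18.0, 51.0))
        bmi = float(np.clip(rng.normal(config.bmi_mean, config.bmi_sd), 16.0, 55.0))
        height = float(np.clip(rng.normal(1.65, 0.07), 1.45, 1.90))
        weight = bmi * height**2
        outcome = outcomes[int(rng.choice(len(outcomes), p=probs))]
        lo, hi = _END_DAY_RANGES[outcome]
        end_day = int(rng.integers(lo, hi + 1))
        start = config.first_lmp_date + dt.timedelta(
            days=int(rng.integers(0, config.lmp_spread_days + 1))
        )
        due = (
            start + dt.timedelta(days=TERM_DURATION_DAYS)
            if rng.random() < config.due_date_known_fraction
            else None
        )
        profiles.append(
            PregnancyProfile(
                participant_id=pid,
                age=age,
                height=height,
                weight_prepregnancy=weight,
                lmp_date=start,
                due_date=due,
                end_date=start + dt.timedelta(days=end_day),
                outcome=outcome,
            )
        )

        last_day = min(end_day + POSTPARTUM_SPAN_DAYS, WINDOW_END_DAY)
        days = np.arange(-56, last_day + 1)
        keep = rng.random(len(days)) >= config.missing_day_rate
        days = days[keep]
        if len(days) == 0:
            continue
        weeks = days / 7.0

        values: Dict[str, np.ndarray] = {}
        for metric in _GENERATED_METRICS:
            tmpl = templates[metric]
            dev = evaluate_template(tmpl, weeks, age=age, bmi=bmi)
            if outcome == OUTCOME_LOSS and metric in config.divergence:
                dev = dev + _loss_offset(config.divergence[metric], days, end_day)
            intercept = rng.normal(0.0, config.random_intercept_sd.get(metric, 0.0))
            noise = rng.normal(0.0, config.residual_sd.get(metric, 0.0), len(days))
            values[metric] = DEFAULT_BASELINE[metric] + dev + intercept + noise

        # Structural identities and physical floors.
        for metric in _GENERATED_METRICS:
            values[metric] = np.maximum(values[metric], 0.0)
        values["light_pct"] = np.clip(values["light_pct"], 20.0, 75.0)
        values["deep_pct"] = np.clip(values["deep_pct"], 3.0, 35.0)
        over = values["light_pct"] + values["deep_pct"]
        scale = np.where(over > 95.0, 95.0 / over, 1.0)
        values["light_pct"] *= scale
        values["deep_pct"] *= scale
        values["rem_pct"] = 100.0 - values["light_pct"] - values["deep_pct"]
        values["time_in_bed"] = values["time_asleep"] + values["time_awake"]
        values["steps"] = np.maximum(np.round(values["steps"]), 0.0)

        frames.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "date": [start + dt.timedelta(days=int(d)) for d in days],
                    **{m: values[m] for m in METRICS},
                    "is_main_sleep": rng.random(len(days)) >= config.nap_rate,
                }
            )
        )

    if frames:
        daily = pd.concat(frames, ignore_index=True)[DAILY_COLUMNS]
    else:
        daily = pd.DataFrame(columns=DAILY_COLUMNS)
    return profiles, daily


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def profiles_to_frame(profiles: Sequence[PregnancyProfile]) -> pd.DataFrame:
    rows = [
        {
            "participant_id": p.participant_id,
            "age": p.age,
            "height_m": p.height,
            "weight_kg": p.weight_prepregnancy,
            "lmp_date": p.lmp_date,
            "due_date": p.due_date,
            "end_date": p.end_date,
            "outcome": p.outcome,
        }
        for p in profiles
    ]
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def frame_to_profiles(frame: pd.DataFrame) -> List[PregnancyProfile]:
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            PregnancyProfile(
                participant_id=row.participant_id,
                age=float(row.age),
                height=float(row.height_m),
                weight_prepregnancy=float(row.weight_kg),
                lmp_date=_parse_date(row.lmp_date),
                due_date=_parse_date(row.due_date),
                end_date=_parse_date(row.end_date),
                outcome=row.outcome,
            )
        )
    return out


def _parse_date(value) -> Optional[dt.date]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, dt.date):
        return value
    if isinstance(value, str):
        return dt.date.fromisoformat(value) if value else None
    if pd.isna(value):
        return None
    return pd.Timestamp(value).date()


def write_cohort(
    profiles: Sequence[PregnancyProfile],
    daily: pd.DataFrame,
    directory: str | Path,
) -> tuple[Path, Path]:
    """Write ``profiles.csv`` and ``daily.csv`` (ISO dates, full-precision
    floats); round-trip reading reproduces every field exactly."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ppath = directory / "profiles.csv"
    dpath = directory / "daily.csv"
    pframe = profiles_to_frame(list(profiles))
    pframe.to_csv(ppath, index=False, float_format="%.17g")
    daily.to_csv(dpath, index=False, float_format="%.17g")
    return ppath, dpath


def read_cohort(directory: str | Path) -> tuple[List[PregnancyProfile], pd.DataFrame]:
    """Read a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    pframe = pd.read_csv(
        directory / "profiles.csv",
        dtype={"participant_id": str},
        float_precision="round_trip",
    )
    daily = pd.read_csv(
        directory / "daily.csv",
        dtype={"participant_id": str},
        float_precision="round_trip",
    )
    if len(daily):
        daily["date"] = pd.to_datetime(daily["date"]).dt.date
        daily["is_main_sleep"] = daily["is_main_sleep"].astype(bool)
    return frame_to_profiles(pframe), daily


def term_only(config: CohortConfig) -> CohortConfig:
    """A copy of ``config`` restricted to term pregnancies."""
    return replace(
        config,
        outcome_proportions={OUTCOME_TERM: 1.0, OUTCOME_PRETERM: 0.0, OUTCOME_LOSS: 0.0},
    )
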