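"""Matched pre-loss divergence analysis.

Analysis 2: for each pregnancy that ended in early loss (before 20
weeks), the 28 days ending on the pregnancy-end day are extracted as
gap-filled daily z-scores, and a gestational-age-matched term pregnancy
is sampled as control (the same gestational-day window: a loss at
7 weeks 1 day contributes days 3w2d .. 7w1d for both members).  A
Gaussian GEE models the daily z-value on a 3-df B-spline of the day
relative to the end (−27 .. 0), a linear outcome (loss) indicator and a
linear outcome-by-day interaction, clustering by pregnancy.  The outcome
effect is the joint Wald test of {outcome, outcome × day}; effect sizes
are the mean modelled term-minus-loss differences over the whole 28-day
window and over the final 7 days; the divergence onset is the earliest
day from which the fitted loss-minus-term difference stays below a
threshold through the end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .preprocess import daily_zscores, start_dates
from .spline_gee import (
    GEEFit,
    SplineSpec,
    WaldResult,
    build_design,
    fit_gee,
    joint_wald_blocks,
    predict_curve,
    bspline_basis,
)
from .synthetic_cohort import PregnancyProfile
from .timeline import OUTCOME_LOSS, OUTCOME_TERM

log = logging.getLogger(__name__)

#: Length of the pre-end window, in days (inclusive of the end day).
WINDOW_DAYS = 28

#: Spline flexibility for the day-relative-to-end trend.
LOSS_SPLINE_DF = 3

#: Minimum data coverage required of a matched control in the window.
CONTROL_COVERAGE = 0.40

#: Divergence-onset threshold, z units: the fitted loss − term difference
#: must stay below −q from the onset day through the end day.
ONSET_THRESHOLD_Z = 0.25


@dataclass(frozen=True)
class MatchedPair:
    """A loss case and its gestational-age-matched term control."""

    case_id: str
    control_id: str
    end_gestational_day: int

    @property
    def window(self) -> Tuple[int, int]:
        return self.end_gestational_day - (WINDOW_DAYS - 1), self.end_gestational_day


@dataclass
class LossModelResult:
    """Fitted pre-loss divergence model for one metric."""

    metric: str
    fit: GEEFit
    outcome_wald: WaldResult
    delta_28d: float  # mean modelled (term − loss) difference, z units
    delta_7d: float
    n_pairs: int
    curves: pd.DataFrame  # day, fitted_term, fitted_loss


def extract_window(
    case: PregnancyProfile,
    daily_z: Dict[str, pd.Series],
    end_day: int,
) -> Optional[pd.Series]:
    """Daily z-values over the 28 days ending on the case's end day.

    A loss ending at gestational day ``d`` yields days ``d−27 .. d``
    (e.g. an end at 7w1d, day 50, yields days 23..50 = 3w2d .. 7w1d).
    Cases ending before day 28 cannot host a full pregnancy-period
    window and are dropped (returns None), as are cases without a valid
    baseline (absent from ``daily_z``).
    """
    if end_day < WINDOW_DAYS:
        log.info(
            "case %s ends at day %d; pre-end window would be truncated, dropped",
            case.participant_id,
            end_day,
        )
        return None
    series = daily_z.get(case.participant_id)
    if series is None:
        log.info("case %s has no valid baseline; dropped", case.participant_id)
        return None
    lo, hi = end_day - (WINDOW_DAYS - 1), end_day
    return series.reindex(np.arange(lo, hi + 1))


def sample_controls(
    cases: Sequence[Tuple[str, int]],
    term_coverage: Dict[str, pd.Series],
    rng: np.random.Generator,
    max_attempts: int = 50,
    coverage_threshold: float = CONTROL_COVERAGE,
) -> List[MatchedPair]:
    """Sample a gestational-age-matched term control for each loss case.

    ``cases`` are (participant_id, end gestational day) pairs;
    ``term_coverage`` maps each term candidate to its daily z-series
    (indexed by day offset).  Controls are drawn uniformly without
    replacement while the pool allows, then with replacement; a draw is
    rejected (up to ``max_attempts``) if the candidate observes fewer
    than ``coverage_threshold`` of the matched window days.
    """
    pool = sorted(term_coverage)
    if not pool:
        raise ValueError("empty term control pool")
    available = list(pool)
    pairs: List[MatchedPair] = []
    for case_id, end_day in cases:
        lo, hi = end_day - (WINDOW_DAYS - 1), end_day
        chosen = None
        for _ in range(max_attempts):
            source = available if available else pool
            cand = source[int(rng.integers(len(source)))]
            window = term_coverage[cand].reindex(np.arange(lo, hi + 1))
            frac = float(window.notna().mean())
            if frac >= coverage_threshold:
                chosen = cand
                break
        if chosen is None:
            log.warning("no eligible control for case %s (end day %d)", case_id, end_day)
            continue
        if chosen in available:
            available.remove(chosen)
        pairs.append(MatchedPair(case_id, chosen, end_day))
    return pairs


def build_pair_table(
    pairs: Sequence[MatchedPair],
    loss_z: Dict[str, pd.Series],
    term_z: Dict[str, pd.Series],
) -> pd.DataFrame:
    """Long table (cluster, day, outcome, z) for the paired GEE.

    ``day`` is the day relative to the case's pregnancy end (−27 .. 0);
    ``outcome`` is 1 for loss, 0 for term.  Clusters are pregnancies
    (case and control are separate clusters); interpolated series may
    still contain missing days, which are dropped.
    """
    rows = []
    for k, pair in enumerate(pairs):
        lo, hi = pair.window
        rel = np.arange(-(WINDOW_DAYS - 1), 1)
        for pid, z_map, is_loss in (
            (pair.case_id, loss_z, 1),
            (pair.control_id, term_z, 0),
        ):
            series = z_map[pid].reindex(np.arange(lo, hi + 1))
            vals = series.to_numpy(dtype=float)
            ok = np.isfinite(vals)
            if not ok.any():
                continue
            rows.append(
                pd.DataFrame(
                    {
                        # control clusters keyed per pair: reuse with
                        # replacement still yields distinct rows
                        "cluster": f"{pair.case_id}|{pid}",
                        "day": rel[ok],
                        "outcome": is_loss,
                        "z": vals[ok],
                    }
                )
            )
    if not rows:
        raise ValueError("no usable pair data")
    return pd.concat(rows, ignore_index=True)


def fit_loss_model(
    table: pd.DataFrame,
    metric: str,
    df: int = LOSS_SPLINE_DF,
) -> LossModelResult:
    """Fit the outcome-controlled pre-end GEE and its effect sizes."""
    n_pairs = int(table.loc[table["outcome"] == 1, "cluster"].nunique())
    if n_pairs < 10:
        raise ValueError(f"need >= 10 pairs, got {n_pairs}")
    spec = SplineSpec(df=df)
    X = build_design(
        table["day"].to_numpy(dtype=float),
        table["cluster"].to_numpy(),
        spec,
        outcome=table["outcome"].to_numpy(dtype=float),
    )
    fit = fit_gee(table["z"].to_numpy(dtype=float), X)
    if not fit.converged:
        log.warning("loss model for %s did not converge", metric)
    outcome_wald = joint_wald_blocks(fit, "outcome", "outcome_x_time")

    days = np.arange(-(WINDOW_DAYS - 1), 1, dtype=float)
    knots = fit.meta["time_knots"]

    def design_at(outcome_val: float) -> np.ndarray:
        basis, _ = bspline_basis(days, spec, knots=knots)
        out = np.full((len(days), 1), outcome_val)
        return np.hstack([np.ones((len(days), 1)), basis, out, out * days[:, None]])

    term_curve, _ = predict_curve(fit, design_at(0.0))
    loss_curve, _ = predict_curve(fit, design_at(1.0))
    diff = term_curve - loss_curve
    delta_28d = float(np.mean(diff))
    delta_7d = float(np.mean(diff[-7:]))
    curves = pd.DataFrame(
        {"day": days.astype(int), "fitted_term": term_curve, "fitted_loss": loss_curve}
    )
    return LossModelResult(
        metric=metric,
        fit=fit,
        outcome_wald=outcome_wald,
        delta_28d=delta_28d,
        delta_7d=delta_7d,
        n_pairs=n_pairs,
        curves=curves,
    )


def effect_sizes(result: LossModelResult) -> Tuple[float, float]:
    """(delta_28d, delta_7d): mean modelled term − loss differences."""
    return result.delta_28d, result.delta_7d


def estimate_divergence_onset(
    result: LossModelResult,
    threshold_z: float = ONSET_THRESHOLD_Z,
) -> Optional[int]:
    """Earliest day of sustained loss-below-term divergence, or None.

    Returns the most negative day d* (days relative to the end, so −14
    means two weeks before) such that the fitted loss − term difference
    is below −``threshold_z`` on every day in [d*, 0].  None when the
    end-day difference itself does not clear the threshold.
    """
    diff = (
        result.curves["fitted_loss"] - result.curves["fitted_term"]
    ).to_numpy()
    days = result.curves["day"].to_numpy()
    below = diff < -threshold_z
    if not below[-1]:
        return None
    k = len(below) - 1
    while k > 0 and below[k - 1]:
        k -= 1
    return int(days[k])


def run_loss_analysis(
    profiles: Sequence[PregnancyProfile],
    records: pd.DataFrame,
    metric: str,
    baselines: pd.DataFrame,
    seed_rng: np.random.Generator,
    n_pairs: Optional[int] = None,
) -> tuple[LossModelResult, Optional[int], List[MatchedPair]]:
    """End-to-end matched analysis for one metric.

    Computes daily z-series for loss cases and the term control pool,
    extracts 28-day pre-end windows, samples matched controls, fits the
    divergence GEE and estimates the onset.  ``n_pairs`` caps the number
    of cases analysed (first cases in participant order, for
    reproducibility).
    """
    starts = start_dates(profiles)
    losses = [p for p in profiles if p.outcome == OUTCOME_LOSS]
    terms = [p for p in profiles if p.outcome == OUTCOME_TERM]
    if not losses or not terms:
        raise ValueError("need both loss and term pregnancies")

    z_all = daily_zscores(records, profiles, metric, baselines)
    term_ids = {p.participant_id for p in terms}
    term_z = {pid: s for pid, s in z_all.items() if pid in term_ids}

    cases: List[Tuple[str, int]] = []
    loss_windows: Dict[str, pd.Series] = {}
    for p in sorted(losses, key=lambda q: q.participant_id):
        end_day = (p.end_date - starts[p.participant_id]).days
        window = extract_window(p, z_all, end_day)
        if window is None or window.notna().mean() < CONTROL_COVERAGE:
            continue
        cases.append((p.participant_id, end_day))
        loss_windows[p.participant_id] = z_all[p.participant_id]
        if n_pairs is not None and len(cases) >= n_pairs:
            break

    pairs = sample_controls(cases, term_z, seed_rng)
    table = build_pair_table(pairs, loss_windows, term_z)
    # build_pair_table keys clusters as case|participant; rebuild z maps keyed
    # accordingly is unnecessary because it reads from the participant maps.
    result = fit_loss_model(table, metric)
    onset = estimate_divergence_onset(result)
    return result, onset, pairs
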