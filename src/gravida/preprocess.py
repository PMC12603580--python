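"""Cleaning, availability exclusions, weekly aggregation and baseline z-scoring.

The pipeline mirrors the study's preprocessing order: duplicate daily
records are removed, sleep-period metrics from non-main-sleep nights
(naps, diurnal sleep) are blanked, pregnancies with under 40% of days
observed in the prepregnancy window or in any reached trimester are
excluded, daily values are averaged into gestational-week bins, and each
metric is normalised as a z-score against the individual's prepregnancy
baseline (mean and SD over the 28 days preceding the estimated start).
A linear gap-filling helper for daily series supports the pre-loss
analysis, which works at daily rather than weekly resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .synthetic_cohort import (
    METRICS,
    SLEEP_GATED_METRICS,
    PregnancyProfile,
)
from .timeline import classify_trimester, infer_pregnancy_start

log = logging.getLogger(__name__)

#: Availability threshold: fraction of days with data required in the
#: prepregnancy window and in each trimester the pregnancy reaches.
AVAILABILITY_THRESHOLD = 0.40

#: Baseline window in day offsets (inclusive): the 4 weeks before start.
BASELINE_WINDOW = (-28, -1)

#: Baseline validity floor: minimum observed days and SD.
BASELINE_MIN_DAYS = 7
BASELINE_SD_FLOOR = 1e-6

#: Longest interior gap (days) bridged by linear interpolation.
INTERPOLATION_MAX_GAP = 7


def start_dates(profiles: Sequence[PregnancyProfile]) -> Dict[str, "datetime.date"]:  # noqa: F821
    """Estimated pregnancy start per participant (due-date route first)."""
    return {
        p.participant_id: infer_pregnancy_start(p.lmp_date, p.due_date)
        for p in profiles
    }


def attach_day_offset(
    records: pd.DataFrame, profiles: Sequence[PregnancyProfile]
) -> pd.DataFrame:
    """Add ``day_offset`` (days since pregnancy start) and ``week`` columns."""
    starts = start_dates(profiles)
    out = records.copy()
    start_series = out["participant_id"].map(starts)
    if start_series.isna().any():
        unknown = out.loc[start_series.isna(), "participant_id"].unique()
        raise KeyError(f"records for participants without profiles: {unknown[:5]}")
    out["day_offset"] = (
        pd.to_datetime(out["date"]) - pd.to_datetime(start_series)
    ).dt.days
    out["week"] = np.floor(out["day_offset"] / 7).astype(int)
    return out


def deduplicate(records: pd.DataFrame) -> pd.DataFrame:
    """Keep one record per (participant, date); last-seen wins.

    Conflicting duplicates (same key, differing values) are resolved the
    same way but logged as a warning.
    """
    dup_mask = records.duplicated(subset=["participant_id", "date"], keep="last")
    if dup_mask.any():
        full_dup = records.duplicated(keep="last")
        n_conflict = int((dup_mask & ~full_dup).sum())
        if n_conflict:
            log.warning(
                "%d conflicting duplicate participant-days; keeping last-seen",
                n_conflict,
            )
    return records.loc[~dup_mask].reset_index(drop=True)


def filter_main_sleep(records: pd.DataFrame) -> pd.DataFrame:
    """Blank sleep/temperature/cardiorespiratory fields on non-main-sleep rows.

    Nap and diurnal-sleep rows keep their daily step counts — steps are a
    whole-day quantity — but contribute no nocturnal physiology.
    """
    out = records.copy()
    not_main = ~out["is_main_sleep"].astype(bool)
    if not_main.any():
        out.loc[not_main, SLEEP_GATED_METRICS] = np.nan
    return out


@dataclass(frozen=True)
class ExclusionRecord:
    participant_id: str
    reason: str
    segment: str
    fraction: float


def apply_availability_filter(
    records: pd.DataFrame,
    profiles: Sequence[PregnancyProfile],
    threshold: float = AVAILABILITY_THRESHOLD,
) -> Tuple[List[PregnancyProfile], pd.DataFrame]:
    """Drop pregnancies with < ``threshold`` of days observed per segment.

    Segments are the 8-week prepregnancy window and each trimester the
    pregnancy overlaps (a trimester is evaluated over its intersection
    with [0, end day]; trimesters never reached are not evaluated).
    Returns the retained profiles and a tidy exclusion report.
    """
    recs = attach_day_offset(records, profiles)
    counts = recs.groupby(["participant_id", "day_offset"]).size()
    observed: Dict[str, np.ndarray] = {
        pid: grp.index.get_level_values("day_offset").to_numpy()
        for pid, grp in counts.groupby(level="participant_id")
    }
    starts = start_dates(profiles)

    segments = {
        "pre": (-56, -1),
        "T1": (0, 97),
        "T2": (98, 195),
        "T3": (196, 286),
    }
    retained: List[PregnancyProfile] = []
    exclusions: List[ExclusionRecord] = []
    for p in profiles:
        end_day = (p.end_date - starts[p.participant_id]).days
        days = observed.get(p.participant_id, np.empty(0, dtype=int))
        failed = None
        for name, (lo, hi) in segments.items():
            if name != "pre":
                hi = min(hi, end_day)
                if hi < lo:
                    continue  # trimester never reached
            n_days = hi - lo + 1
            frac = float(np.sum((days >= lo) & (days <= hi))) / n_days
            if frac < threshold:
                failed = ExclusionRecord(
                    p.participant_id, "availability_below_threshold", name, frac
                )
                break
        if failed is None:
            retained.append(p)
        else:
            exclusions.append(failed)
    report = pd.DataFrame(
        [e.__dict__ for e in exclusions],
        columns=["participant_id", "reason", "segment", "fraction"],
    )
    if len(exclusions):
        log.info("excluded %d/%d pregnancies for availability", len(exclusions), len(profiles))
    return retained, report


@dataclass(frozen=True)
class BaselineStats:
    """Prepregnancy baseline mean/SD of one participant-metric."""

    participant_id: str
    metric: str
    mean: float
    sd: float
    n_days: int

    @property
    def valid(self) -> bool:
        return self.n_days >= BASELINE_MIN_DAYS and self.sd >= BASELINE_SD_FLOOR


def compute_baseline(
    records: pd.DataFrame,
    profiles: Sequence[PregnancyProfile],
    metrics: Iterable[str] = METRICS,
) -> pd.DataFrame:
    """Per participant-metric baseline over day offsets −28…−1.

    Returns a frame with columns participant_id, metric, mean, sd (sample,
    n−1 denominator), n_days and a ``valid`` flag (≥ 7 observed days and
    SD above floor; an essentially constant baseline makes z-scores
    meaningless and flags the participant-metric invalid).
    """
    recs = attach_day_offset(records, profiles)
    lo, hi = BASELINE_WINDOW
    base = recs[(recs["day_offset"] >= lo) & (recs["day_offset"] <= hi)]
    rows = []
    for metric in metrics:
        grp = base.groupby("participant_id")[metric]
        agg = grp.agg(mean="mean", sd="std", n_days="count")
        for pid, row in agg.iterrows():
            rows.append(
                {
                    "participant_id": pid,
                    "metric": metric,
                    "mean": row["mean"],
                    "sd": row["sd"] if np.isfinite(row["sd"]) else 0.0,
                    "n_days": int(row["n_days"]),
                }
            )
    out = pd.DataFrame(rows, columns=["participant_id", "metric", "mean", "sd", "n_days"])
    out["valid"] = (out["n_days"] >= BASELINE_MIN_DAYS) & (out["sd"] >= BASELINE_SD_FLOOR)
    return out


def weekly_aggregate(
    records: pd.DataFrame,
    profiles: Sequence[PregnancyProfile],
    metrics: Iterable[str] = METRICS,
) -> pd.DataFrame:
    """Arithmetic mean of available days per gestational-week bin.

    Weeks with no observed days are simply absent — no weekly-level
    imputation.  Returns a long frame (participant_id, metric, week,
    value_raw).
    """
    recs = attach_day_offset(records, profiles)
    long = recs.melt(
        id_vars=["participant_id", "week"],
        value_vars=list(metrics),
        var_name="metric",
        value_name="value",
    ).dropna(subset=["value"])
    out = (
        long.groupby(["participant_id", "metric", "week"], as_index=False)["value"]
        .mean()
        .rename(columns={"value": "value_raw"})
    )
    return out


def zscore(weekly: pd.DataFrame, baselines: pd.DataFrame) -> pd.DataFrame:
    """Baseline-normalise weekly values: z = (x − baseline mean) / baseline SD.

    Participant-metrics with an invalid baseline are dropped from that
    metric's analysis.
    """
    valid = baselines[baselines["valid"]]
    merged = weekly.merge(
        valid[["participant_id", "metric", "mean", "sd"]],
        on=["participant_id", "metric"],
        how="inner",
    )
    merged["value_z"] = (merged["value_raw"] - merged["mean"]) / merged["sd"]
    return merged.drop(columns=["mean", "sd"])


def interpolate_daily(
    values: pd.Series | np.ndarray,
    max_gap: int = INTERPOLATION_MAX_GAP,
) -> np.ndarray:
    """Linearly fill interior gaps of a consecutive-day series.

    ``values`` is indexed by consecutive days with NaN for missing days.
    Interior runs of at most ``max_gap`` missing days are filled linearly
    between the nearest observed neighbours; longer runs and leading or
    trailing gaps remain missing.
    """
    x = np.asarray(values, dtype=float)
    out = x.copy()
    obs = np.flatnonzero(~np.isnan(x))
    if len(obs) < 2:
        return out
    idx = np.arange(len(x))
    filled = np.interp(idx, obs, x[obs])
    # Identify missing runs and their lengths.
    isnan = np.isnan(x)
    boundaries = np.flatnonzero(np.diff(isnan.astype(int)) != 0) + 1
    run_starts = np.concatenate([[0], boundaries])
    run_ends = np.concatenate([boundaries, [len(x)]])
    for lo, hi in zip(run_starts, run_ends):
        if not isnan[lo]:
            continue
        interior = lo > obs[0] and hi - 1 < obs[-1]
        if interior and (hi - lo) <= max_gap:
            out[lo:hi] = filled[lo:hi]
    return out


def daily_zscores(
    records: pd.DataFrame,
    profiles: Sequence[PregnancyProfile],
    metric: str,
    baselines: pd.DataFrame,
    day_range: Optional[Tuple[int, int]] = None,
    max_gap: int = INTERPOLATION_MAX_GAP,
) -> Dict[str, pd.Series]:
    """Gap-filled daily z-series per participant for one metric.

    Returns, per participant with a valid baseline, a Series indexed by
    day offset (restricted to ``day_range`` when given) of interpolated,
    baseline-normalised daily values.
    """
    recs = attach_day_offset(records, profiles)
    base = baselines[(baselines["metric"] == metric) & baselines["valid"]]
    stats = base.set_index("participant_id")[["mean", "sd"]]
    out: Dict[str, pd.Series] = {}
    for pid, grp in recs.groupby("participant_id"):
        if pid not in stats.index:
            continue
        series = grp.set_index("day_offset")[metric].dropna()
        series = series[~series.index.duplicated(keep="last")].sort_index()
        if series.empty:
            continue
        lo = series.index.min() if day_range is None else day_range[0]
        hi = series.index.max() if day_range is None else day_range[1]
        full_idx = np.arange(lo, hi + 1)
        dense = series.reindex(full_idx)
        filled = interpolate_daily(dense.to_numpy(), max_gap=max_gap)
        mean, sd = stats.loc[pid, "mean"], stats.loc[pid, "sd"]
        out[pid] = pd.Series((filled - mean) / sd, index=full_idx)
    return out


def classify_week_segment(week: int) -> str:
    """Trimester label of a gestational week (via its first day)."""
    return classify_trimester(week * 7)
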