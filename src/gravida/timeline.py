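"""Pregnancy timeline arithmetic.

Gestational age is anchored at the first day of the last menstrual period
(LMP), the clinical convention: LMP day is day 0, conception occurs roughly
14 days later in a standard 28-day cycle.  Pregnancy start is inferred from
the self-reported expected due date when available (due date minus 280 days,
i.e. 40 weeks), otherwise from the self-reported LMP date directly.

The analysis window spans 64 weeks: 8 weeks before the estimated pregnancy
start through 56 weeks after it.  Gestational week ``w`` is the half-open
7-day bin covering day offsets ``7w .. 7w+6``; negative offsets bin the same
way (week −1 = days −7..−1), so "week 9" means days 63–69.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

log = logging.getLogger(__name__)

#: Analysis window in day offsets relative to pregnancy start (inclusive).
WINDOW_START_DAY = -56
WINDOW_END_DAY = 391  # 56 weeks * 7 - 1

#: Gestational duration assumed when deriving start from a due date (40 weeks).
TERM_DURATION_DAYS = 280

#: Conventional LMP-to-conception offset in a 28-day cycle.
CONCEPTION_OFFSET_DAYS = 14

# Trimester boundaries in completed gestational days (inclusive ranges):
# T1 = 0w0d–13w6d, T2 = 14w0d–27w6d, T3 = 28w0d–40w6d.
T1_LAST_DAY = 97
T2_LAST_DAY = 195
T3_LAST_DAY = 286

#: Outcome categories.
OUTCOME_LOSS = "loss"
OUTCOME_PRETERM = "preterm"
OUTCOME_TERM = "term"


class MissingDateError(ValueError):
    """Raised when neither an LMP date nor a due date is available."""


def infer_pregnancy_start(
    lmp_date: Optional[dt.date], due_date: Optional[dt.date]
) -> dt.date:
    """Estimated pregnancy start (LMP day 0) from self-reported dates.

    The due-date route takes precedence when both are reported: start is the
    expected due date minus 280 days.  Otherwise the reported LMP date is
    used directly.

    Raises
    ------
    MissingDateError
        If both dates are absent.
    """
    if due_date is not None:
        return due_date - dt.timedelta(days=TERM_DURATION_DAYS)
    if lmp_date is not None:
        return lmp_date
    raise MissingDateError("neither lmp_date nor due_date is available")


def estimated_conception(start: dt.date) -> dt.date:
    """Conception date estimate: pregnancy start (LMP) plus 14 days."""
    return start + dt.timedelta(days=CONCEPTION_OFFSET_DAYS)


def classify_trimester(day_offset: int) -> str:
    """Classify a day offset as 'pre', 'T1', 'T2', 'T3' or 'post'.

    Offsets are days since pregnancy start; the trimester bins are the
    inclusive day ranges 0–97, 98–195 and 196–286 (13w6d / 27w6d / 40w6d
    upper bounds).
    """
    if day_offset < 0:
        return "pre"
    if day_offset <= T1_LAST_DAY:
        return "T1"
    if day_offset <= T2_LAST_DAY:
        return "T2"
    if day_offset <= T3_LAST_DAY:
        return "T3"
    return "post"


def gestational_week(day_offset: int) -> int:
    """7-day week bin of a day offset (floor division; week 0 = days 0–6)."""
    return math.floor(day_offset / 7)


def compute_bmi(weight_kg: float, height_m: float) -> float:
    """Body-mass index: weight (kg) divided by height (m) squared."""
    if not (weight_kg > 0 and height_m > 0):
        raise ValueError(
            f"weight and height must be positive, got {weight_kg} kg, {height_m} m"
        )
    return weight_kg / (height_m**2)


@dataclass(frozen=True)
class StartSourceSummary:
    """Attribution of pregnancy-start estimates to their self-report source."""

    n_total: int
    n_due_date: int
    n_lmp: int

    @property
    def pct_due_date(self) -> float:
        return 100.0 * self.n_due_date / self.n_total if self.n_total else float("nan")

    @property
    def pct_lmp(self) -> float:
        return 100.0 * self.n_lmp / self.n_total if self.n_total else float("nan")


def summarize_start_sources(
    profiles: Iterable[Mapping] | "pandas.DataFrame",  # noqa: F821
) -> StartSourceSummary:
    """Count how many pregnancy starts derive from a due date vs the LMP.

    Accepts anything iterable over records with ``due_date``/``lmp_date``
    attributes or keys (including a pandas DataFrame, iterated row-wise).
    A record with a known due date is attributed to the due-date route
    regardless of whether an LMP date is also present, mirroring
    :func:`infer_pregnancy_start` precedence.
    """
    try:
        import pandas as pd

        if isinstance(profiles, pd.DataFrame):
            due_known = profiles["due_date"].notna()
            n = len(profiles)
            n_due = int(due_known.sum())
            return StartSourceSummary(n_total=n, n_due_date=n_due, n_lmp=n - n_due)
    except ImportError:  # pragma: no cover
        pass

    n = n_due = 0
    for p in profiles:
        due = p.get("due_date") if isinstance(p, Mapping) else getattr(p, "due_date")
        n += 1
        if due is not None:
            n_due += 1
    return StartSourceSummary(n_total=n, n_due_date=n_due, n_lmp=n - n_due)


def validate_outcome(outcome: str, ga_days_at_end: int) -> bool:
    """Check an outcome label against gestational age at pregnancy end.

    Early loss must end before 140 days (20 weeks) and at/after 28 days;
    preterm before 259 days (37 weeks); term between 259 and 294 days.
    Mismatches are logged as warnings, not raised — self-reported dates and
    labels carry recall noise.
    """
    ok = {
        OUTCOME_LOSS: 28 <= ga_days_at_end < 140,
        OUTCOME_PRETERM: ga_days_at_end < 259,
        OUTCOME_TERM: 259 <= ga_days_at_end <= 294,
    }.get(outcome, False)
    if not ok:
        log.warning(
            "outcome %r inconsistent with gestational age %d days at end",
            outcome,
            ga_days_at_end,
        )
    return ok
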