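"""Population trajectories of wearable metrics across term pregnancies.

Analysis 1: for each metric, a Gaussian GEE of the baseline-normalised
weekly values on an 8-df B-spline of gestational week (clusters =
participants, exchangeable working correlation, robust SEs), with a joint
Wald test on the spline block for the gestational-age effect.  An extended
model adds B-spline main effects for maternal age and prepregnancy BMI
plus tensor-product interactions with the gestational-age spline, testing
whether the covariates moderate the trajectory.  Fitted z-curves are
converted back to native units via the cohort-median prepregnancy
baseline SD, and summarised as mean deviations per trimester.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .spline_gee import (
    GEEFit,
    SplineSpec,
    WaldResult,
    bspline_basis,
    build_design,
    fit_gee,
    joint_wald,
    joint_wald_blocks,
    predict_curve,
    tensor_product,
)

log = logging.getLogger(__name__)

DEFAULT_GA_DF = 8
DEFAULT_COVARIATE_DF = 3

#: Gestational weeks considered "during gestation" for extrema (0 .. 40).
GESTATION_WEEKS = (0.0, 40.0)

#: Week bins summarised per trimester (postpartum added for completeness).
TRIMESTER_WEEKS = {
    "T1": (0, 13),
    "T2": (14, 27),
    "T3": (28, 40),
    "post": (41, 56),
}


@dataclass
class TrendResult:
    """Fitted trajectory of one metric."""

    metric: str
    fit: GEEFit
    ga_wald: WaldResult
    curve: pd.DataFrame  # week, fitted_z, se_z, fitted_native
    extremum_week: float
    extremum_z: float
    extremum_native: float
    baseline_sd: float  # cohort-median baseline SD used for conversion
    trimester_deltas_z: Dict[str, float] = field(default_factory=dict)
    trimester_deltas_native: Dict[str, float] = field(default_factory=dict)
    age_wald: Optional[WaldResult] = None
    bmi_wald: Optional[WaldResult] = None


def _metric_table(weekly_z: pd.DataFrame, metric: str) -> pd.DataFrame:
    tab = weekly_z[weekly_z["metric"] == metric].dropna(subset=["value_z"])
    if tab.empty:
        raise ValueError(f"no weekly z data for metric {metric!r}")
    return tab


def _median_baseline_sd(baselines: pd.DataFrame, metric: str) -> float:
    sds = baselines[(baselines["metric"] == metric) & baselines["valid"]]["sd"]
    return float(sds.median())


def _fine_grid(lo: float, hi: float, step: float = 0.1) -> np.ndarray:
    return np.arange(lo, hi + step / 2, step)


def _curve_frame(
    fit: GEEFit,
    design_fn,
    weeks: np.ndarray,
    baseline_sd: float,
) -> pd.DataFrame:
    X = design_fn(weeks)
    fitted, se = predict_curve(fit, X)
    return pd.DataFrame(
        {
            "week": weeks,
            "fitted_z": fitted,
            "se_z": se,
            "fitted_native": fitted * baseline_sd,
        }
    )


def fit_ga_model(
    weekly_z: pd.DataFrame,
    metric: str,
    baselines: pd.DataFrame,
    df: int = DEFAULT_GA_DF,
) -> TrendResult:
    """Gestational-age-only spline-GEE for one metric.

    ``weekly_z`` is the long z-scored weekly table (term pregnancies,
    availability-filtered); the B-spline covers the observed week range
    (prepregnancy weeks included).  The GA effect is the joint Wald test
    of the spline block on the robust covariance.
    """
    tab = _metric_table(weekly_z, metric)
    weeks = tab["week"].to_numpy(dtype=float)
    spec = SplineSpec(df=df)
    X = build_design(weeks, tab["participant_id"].to_numpy(), spec)
    fit = fit_gee(tab["value_z"].to_numpy(), X)
    if not fit.converged:
        log.warning("GA model for %s did not converge", metric)
    ga_wald = joint_wald(fit, "time_spline")

    knots = fit.meta["time_knots"]
    baseline_sd = _median_baseline_sd(baselines, metric)

    def design_at(w: np.ndarray) -> np.ndarray:
        basis, _ = bspline_basis(w, spec, knots=knots)
        return np.hstack([np.ones((len(w), 1)), basis])

    lo, hi = float(weeks.min()), float(weeks.max())
    week_grid = np.arange(int(np.ceil(lo)), int(np.floor(hi)) + 1, dtype=float)
    curve = _curve_frame(fit, design_at, week_grid, baseline_sd)

    g_lo = max(GESTATION_WEEKS[0], lo)
    g_hi = min(GESTATION_WEEKS[1], hi)
    fine = _fine_grid(g_lo, g_hi)
    fitted_fine, _ = predict_curve(fit, design_at(fine))
    k = int(np.argmax(np.abs(fitted_fine)))

    deltas_z, deltas_native = _trimester_deltas(curve)
    return TrendResult(
        metric=metric,
        fit=fit,
        ga_wald=ga_wald,
        curve=curve,
        extremum_week=float(fine[k]),
        extremum_z=float(fitted_fine[k]),
        extremum_native=float(fitted_fine[k] * baseline_sd),
        baseline_sd=baseline_sd,
        trimester_deltas_z=deltas_z,
        trimester_deltas_native={
            k2: v * baseline_sd for k2, v in deltas_z.items()
        },
    )


def curve_extremum(
    result: TrendResult,
    week_range: Tuple[float, float],
    mode: str = "abs",
) -> Tuple[float, float]:
    """(week, fitted z) of the curve extremum within ``week_range``.

    ``mode`` selects the largest absolute ('abs'), most positive ('max')
    or most negative ('min') fitted value, evaluated on a 0.1-week grid
    through the fitted spline.
    """
    fit = result.fit
    spec: SplineSpec = fit.meta["time_spec"]
    knots = fit.meta["time_knots"]
    lo = max(week_range[0], float(knots[0]))
    hi = min(week_range[1], float(knots[-1]))
    fine = _fine_grid(lo, hi)
    basis, _ = bspline_basis(fine, spec, knots=knots)
    X = np.hstack([np.ones((len(fine), 1)), basis])
    if X.shape[1] != len(fit.beta):
        raise ValueError("curve_extremum supports gestational-age-only fits")
    fitted, _ = predict_curve(fit, X)
    if mode == "abs":
        k = int(np.argmax(np.abs(fitted)))
    elif mode == "max":
        k = int(np.argmax(fitted))
    elif mode == "min":
        k = int(np.argmin(fitted))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(fine[k]), float(fitted[k])


def _trimester_deltas(curve: pd.DataFrame) -> Tuple[Dict[str, float], Dict[str, float]]:
    deltas = {}
    for name, (lo, hi) in TRIMESTER_WEEKS.items():
        sel = curve[(curve["week"] >= lo) & (curve["week"] <= hi)]
        deltas[name] = float(sel["fitted_z"].mean()) if len(sel) else float("nan")
    return deltas, deltas


def summarize_trimesters(result: TrendResult) -> pd.DataFrame:
    """Mean fitted deviation per trimester, in z and native units."""
    rows = [
        {
            "metric": result.metric,
            "segment": name,
            "delta_z": z,
            "delta_native": z * result.baseline_sd,
        }
        for name, z in result.trimester_deltas_z.items()
    ]
    return pd.DataFrame(rows)


def fit_covariate_model(
    weekly_z: pd.DataFrame,
    metric: str,
    baselines: pd.DataFrame,
    demographics: pd.DataFrame,
    df: int = DEFAULT_GA_DF,
    covariate_df: int = DEFAULT_COVARIATE_DF,
    combined_tests: bool = True,
) -> TrendResult:
    """Spline-GEE with age/BMI main effects and tensor-product interactions.

    ``demographics`` maps participant_id to age and bmi.  The age (BMI)
    Wald test is, by default, the joint test over the covariate's
    main-effect spline block and its tensor-product interaction block
    together; ``combined_tests=False`` tests the interaction block alone.
    """
    tab = _metric_table(weekly_z, metric).merge(
        demographics[["participant_id", "age", "bmi"]], on="participant_id"
    )
    weeks = tab["week"].to_numpy(dtype=float)
    spec = SplineSpec(df=df)
    cov_spec = SplineSpec(df=covariate_df)
    X = build_design(
        weeks,
        tab["participant_id"].to_numpy(),
        spec,
        age=tab["age"].to_numpy(dtype=float),
        bmi=tab["bmi"].to_numpy(dtype=float),
        covariate_spec=cov_spec,
    )
    fit = fit_gee(tab["value_z"].to_numpy(), X)
    if not fit.converged:
        log.warning("covariate model for %s did not converge", metric)
    ga_wald = joint_wald(fit, "time_spline")
    if combined_tests:
        age_wald = joint_wald_blocks(fit, "age_spline", "time_x_age")
        bmi_wald = joint_wald_blocks(fit, "bmi_spline", "time_x_bmi")
    else:
        age_wald = joint_wald(fit, "time_x_age")
        bmi_wald = joint_wald(fit, "time_x_bmi")

    baseline_sd = _median_baseline_sd(baselines, metric)
    knots = fit.meta["time_knots"]
    age_knots = fit.meta["age_knots"]
    bmi_knots = fit.meta["bmi_knots"]
    age_ref = float(np.median(tab["age"]))
    bmi_ref = float(np.median(tab["bmi"]))

    def design_at(w: np.ndarray, age: float = None, bmi: float = None) -> np.ndarray:
        a = age_ref if age is None else age
        b = bmi_ref if bmi is None else bmi
        t_basis, _ = bspline_basis(w, spec, knots=knots)
        a_basis, _ = bspline_basis(
            np.full(len(w), a), cov_spec, knots=age_knots
        )
        b_basis, _ = bspline_basis(
            np.full(len(w), b), cov_spec, knots=bmi_knots
        )
        return np.hstack(
            [
                np.ones((len(w), 1)),
                t_basis,
                a_basis,
                tensor_product(t_basis, a_basis),
                b_basis,
                tensor_product(t_basis, b_basis),
            ]
        )

    # Column order above must match build_design: intercept, time, age,
    # time×age, bmi, time×bmi.
    lo, hi = float(weeks.min()), float(weeks.max())
    week_grid = np.arange(int(np.ceil(lo)), int(np.floor(hi)) + 1, dtype=float)
    curve = _curve_frame(fit, design_at, week_grid, baseline_sd)
    deltas_z, _ = _trimester_deltas(curve)

    result = TrendResult(
        metric=metric,
        fit=fit,
        ga_wald=ga_wald,
        curve=curve,
        extremum_week=float("nan"),
        extremum_z=float("nan"),
        extremum_native=float("nan"),
        baseline_sd=baseline_sd,
        trimester_deltas_z=deltas_z,
        trimester_deltas_native={k: v * baseline_sd for k, v in deltas_z.items()},
        age_wald=age_wald,
        bmi_wald=bmi_wald,
    )
    result.fit.meta["design_at"] = design_at
    return result


def predict_at_covariates(
    result: TrendResult,
    weeks: np.ndarray,
    age: Optional[float] = None,
    bmi: Optional[float] = None,
) -> np.ndarray:
    """Fitted z-curve of a covariate model at chosen age/BMI values."""
    design_at = result.fit.meta.get("design_at")
    if design_at is None:
        raise ValueError("result does not come from fit_covariate_model")
    fitted, _ = predict_curve(result.fit, design_at(np.asarray(weeks, float), age, bmi))
    return fitted
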