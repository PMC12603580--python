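import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import gravida as g
from gravida.cli import RunConfig, preprocess_cohort

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_term_cohort():
    """120 term pregnancies, default templates, seed 5 — shared fast cohort."""
    cfg = g.term_only(g.CohortConfig(n_pregnancies=120, seed=5))
    profiles, daily = g.generate_cohort(cfg)
    return cfg, profiles, daily


@pytest.fixture(scope="session")
def small_term_prepped(small_term_cohort):
    """Preprocessed weekly z-scores and baselines for the shared cohort."""
    _, profiles, daily = small_term_cohort
    retained, clean, baselines, weekly_z, exclusions = preprocess_cohort(
        profiles, daily, RunConfig()
    )
    return {
        "profiles": retained,
        "daily": clean,
        "baselines": baselines,
        "weekly_z": weekly_z,
        "exclusions": exclusions,
    }


@pytest.fixture(scope="session")
def mixed_cohort():
    """Loss + term cohort (seed 11) for the matched pre-loss analysis."""
    cfg = dataclasses.replace(
        g.CohortConfig(n_pregnancies=200, seed=11),
        outcome_proportions={"loss": 0.42, "term": 0.58, "preterm": 0.0},
    )
    profiles, daily = g.generate_cohort(cfg)
    retained, clean, baselines, weekly_z, _ = preprocess_cohort(
        profiles, daily, RunConfig()
    )
    return {
        "profiles": retained,
        "daily": clean,
        "baselines": baselines,
        "weekly_z": weekly_z,
    }


def make_daily_frame(rows):
    """Build a daily-records frame from dicts, filling unset metrics."""
    frame = pd.DataFrame(rows)
    for metric in g.METRICS:
        if metric not in frame:
            frame[metric] = 1.0
    if "is_main_sleep" not in frame:
        frame["is_main_sleep"] = True
    return frame
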