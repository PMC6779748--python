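"""Shared fixtures: tiny synthetic cohorts and hand-built timelines."""

from __future__ import annotations

from datetime import date, datetime

import pytest

from relapsekit import (
    Hospitalization,
    SegmentationConfig,
    SyntheticConfig,
    Timeline,
    TimelineEvent,
    assign_posts,
    generate_cohort,
    segment_participant,
)
from relapsekit.pipeline import segment_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """10-participant cohort with default (planted-effect) conditions."""
    cfg = SyntheticConfig(n_participants=10, followup_days=540, seed=11)
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort_periods(small_cohort):
    cfg, (timelines, hosps, truth) = small_cohort
    return segment_cohort(timelines, hosps, SegmentationConfig())


@pytest.fixture()
def tiny_timeline():
    events = [
        TimelineEvent("p1", datetime(2017, 1, 2, 9, 30), "status", "I hate work today."),
        TimelineEvent("p1", datetime(2017, 1, 2, 13, 0), "like"),
        TimelineEvent("p1", datetime(2017, 1, 5, 23, 10), "co_tag", "", ("alice", "bob")),
        TimelineEvent("p1", datetime(2017, 2, 1, 6, 30), "photo", "sunset at the lake"),
    ]
    return Timeline("p1", events)


@pytest.fixture()
def two_hospitalizations():
    return [
        Hospitalization("p1", date(2017, 1, 1), date(2017, 1, 10)),
        Hospitalization("p1", date(2017, 6, 1), date(2017, 6, 14)),
    ]
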