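"""Study-window arithmetic, relapse-window clipping, and health tiling."""

from __future__ import annotations

from datetime import date, timedelta

import pytest

from relapsekit import (
    Hospitalization,
    SegmentationConfig,
    SyntheticConfig,
    assign_posts,
    generate_cohort,
    health_periods,
    relapse_windows,
    segment_participant,
    study_window,
)
from relapsekit.pipeline import segment_cohort
from relapsekit.segmentation import NoRelapseError, SegmentationError


def _hosp(pid, admit, discharge=None):
    return Hospitalization(pid, date.fromisoformat(admit),
                           date.fromisoformat(discharge) if discharge else None)


class TestStudyWindow:
    def test_single_hospitalization_is_no_relapse(self):
        with pytest.raises(NoRelapseError):
            study_window([_hosp("p1", "2017-01-01")])

    def test_two_admits(self):
        w = study_window([_hosp("p1", "2017-01-01"), _hosp("p1", "2017-06-01")])
        assert w == (date(2017, 1, 1), date(2017, 6, 1))

    def test_three_admits(self):
        hs = [_hosp("p1", "2016-03-05"), _hosp("p1", "2016-09-10"), _hosp("p1", "2017-02-20")]
        assert study_window(hs) == (date(2016, 3, 5), date(2017, 2, 20))
        rel = relapse_windows(hs)
        assert [p.anchor_hospitalization for p in rel] == [date(2016, 9, 10), date(2017, 2, 20)]

    def test_unsorted_input_rejected(self):
        with pytest.raises(SegmentationError):
            study_window([_hosp("p1", "2017-06-01"), _hosp("p1", "2017-01-01")])


class TestRelapseWindows:
    def test_thirty_day_window(self):
        hs = [_hosp("p1", "2017-01-01", "2017-01-10"), _hosp("p1", "2017-06-01")]
        (w,) = relapse_windows(hs)
        assert (w.start, w.end) == (date(2017, 5, 2), date(2017, 6, 1))
        assert w.label == "relapse"

    def test_clipped_at_previous_discharge(self):
        hs = [_hosp("p1", "2017-05-01", "2017-05-20"), _hosp("p1", "2017-06-05")]
        (w,) = relapse_windows(hs)
        assert (w.start, w.end) == (date(2017, 5, 20), date(2017, 6, 5))

    def test_empty_window_dropped(self):
        # readmission on the very day of the previous discharge
        hs = [_hosp("p1", "2017-05-01", "2017-06-05"), _hosp("p1", "2017-06-05")]
        assert relapse_windows(hs) == []

    def test_missing_discharge_imputed_for_clipping(self):
        # previous discharge imputed to admit + 13d = 2017-05-14
        hs = [_hosp("p1", "2017-05-01"), _hosp("p1", "2017-06-05")]
        (w,) = relapse_windows(hs)
        assert w.start == date(2017, 5, 14)


class TestHealthPeriods:
    def test_150_day_run_tiles_into_5(self):
        w = (date(2017, 1, 1), date(2017, 5, 31))  # 150 days
        periods = health_periods(w, [], [], SegmentationConfig(), participant_id="p1")
        assert len(periods) == 5
        assert all(p.length_days == 30 for p in periods)

    def test_remainder_dropped(self):
        w = (date(2017, 1, 1), date(2017, 4, 11))  # 100 days
        cfg = SegmentationConfig(health_granularity_days=90)
        periods = health_periods(w, [], [], cfg, participant_id="p1")
        assert len(periods) == 1
        assert periods[0].end == date(2017, 4, 1)

    def test_run_shorter_than_granularity(self):
        w = (date(2017, 1, 1), date(2017, 1, 20))
        assert health_periods(w, [], [], SegmentationConfig(), participant_id="p1") == []

    def test_inpatient_time_excluded_by_default(self):
        hs = [_hosp("p1", "2017-01-01", "2017-01-31"), _hosp("p1", "2017-08-01")]
        periods = segment_participant(hs)
        # no health period may overlap the inpatient stay [01-01, 01-31)
        for p in periods:
            if p.label == "health":
                assert p.start >= date(2017, 1, 31)


class TestAssignPosts:
    def test_half_open_boundaries(self, tiny_timeline):
        from relapsekit.segmentation import Period

        period = Period("p1", date(2017, 1, 2), date(2017, 2, 1), "health", 30)
        (p,) = assign_posts(tiny_timeline, [period])
        # events on the start date included, on the end date excluded
        assert p.n_posts == 3

    def test_overlap_rejected(self, tiny_timeline):
        from relapsekit.segmentation import Period

        a = Period("p1", date(2017, 1, 1), date(2017, 2, 1), "health", 30)
        b = Period("p1", date(2017, 1, 20), date(2017, 2, 20), "health", 30)
        with pytest.raises(SegmentationError):
            assign_posts(tiny_timeline, [a, b])

    def test_min_posts_flags_but_retains(self, tiny_timeline):
        from relapsekit.segmentation import Period

        period = Period("p1", date(2018, 1, 1), date(2018, 1, 31), "health", 30)
        (p,) = assign_posts(tiny_timeline, [period], min_posts_per_period=1)
        assert p.n_posts == 0 and p.excluded


class TestCohortInvariants:
    def test_truth_counts_match_assignment(self, small_cohort):
        """Generator truth event counts equal assigned relapse-window counts."""
        cfg, (timelines, hosps, truth) = small_cohort
        periods = segment_cohort(timelines, hosps, SegmentationConfig(),
                                 drop_excluded=False)
        by_pid = {}
        for p in periods:
            if p.label == "relapse":
                by_pid.setdefault(p.participant_id, []).append(p)
        for pid, part in truth.participants.items():
            got = sorted((p.start.isoformat(), p.end.isoformat()) for p in by_pid.get(pid, []))
            expected = sorted((s, e) for s, e in part["relapse_windows"])
            assert got == expected
            counts = {
                (p.start.isoformat(), p.end.isoformat()): p.n_posts
                for p in by_pid.get(pid, [])
            }
            for (s, e), n in zip(part["relapse_windows"], part["window_event_counts"]):
                assert counts[(s, e)] == n

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_partition_and_conservation(self, seed):
        cfg = SyntheticConfig(n_participants=4, followup_days=450, seed=seed)
        timelines, hosps, _ = generate_cohort(cfg)
        per = {}
        for h in hosps:
            per.setdefault(h.participant_id, []).append(h)
        for tl in timelines:
            periods = segment_participant(per[tl.participant_id])
            periods = assign_posts(tl, periods)
            # pairwise disjoint and within the study window
            w = study_window(per[tl.participant_id])
            for a, b in zip(periods, periods[1:]):
                assert a.end <= b.start
            for p in periods:
                assert w[0] <= p.start and p.end <= w[1]
            # conservation: assigned + unassigned == events in window
            in_window = [e for e in tl.events if w[0] <= e.timestamp.date() < w[1]]
            assigned = sum(p.n_posts for p in periods)
            assert assigned <= len(in_window)
            covered = sum(p.length_days for p in periods)
            assert covered <= (w[1] - w[0]).days

    def test_granularity_monotonicity(self, small_cohort):
        """More health periods at finer granularity: n(30) >= n(60) >= n(90)."""
        cfg, (timelines, hosps, _) = small_cohort
        counts = []
        for g in (30, 60, 90):
            periods = segment_cohort(
                timelines, hosps, SegmentationConfig(health_granularity_days=g),
                drop_excluded=False,
            )
            counts.append(sum(1 for p in periods if p.label == "health"))
        assert counts[0] >= counts[1] >= counts[2]
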