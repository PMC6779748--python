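"""Segment a participant's study window into relapse and health periods.

The study window runs from the first hospitalization admit date to the most
recent relapse admit date.  The 30 days before each non-index admission form
a *relapse* period (early warning signs become clinically apparent in that
month); all remaining time — minus, by default, inpatient stays — is tiled
into fixed-length *health* periods of 30, 60 or 90 days.

Conventions used throughout:

* every period is a half-open date interval ``[start, end)``;
* "1 month" means exactly 30 days (calendar months vary in length, and
  fixed-length periods keep features comparable across periods);
* each maximal healthy run is tiled left-to-right and a trailing remainder
  shorter than the granularity is dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from typing import Sequence

from .timeline import (
    DEFAULT_STAY_DAYS,
    Hospitalization,
    Timeline,
    TimelineEvent,
    normalize_hospitalizations,
)

logger = logging.getLogger(__name__)

RELAPSE = "relapse"
HEALTH = "health"


class SegmentationError(ValueError):
    pass


class NoRelapseError(SegmentationError):
    """Participant has a single hospitalization, hence no relapse event."""


@dataclass(frozen=True)
class SegmentationConfig:
    relapse_window_days: int = 30
    health_granularity_days: int = 30
    exclude_inpatient: bool = True
    min_posts_per_period: int = 1
    inpatient_stay_days: int = DEFAULT_STAY_DAYS

    def __post_init__(self) -> None:
        if self.relapse_window_days <= 0 or self.health_granularity_days <= 0:
            raise SegmentationError("window lengths must be positive")
        if self.min_posts_per_period < 0:
            raise SegmentationError("min_posts_per_period must be >= 0")


@dataclass
class Period:
    """A labeled half-open interval [start, end) of one participant's time."""

    participant_id: str
    start: date
    end: date
    label: str
    granularity_days: int
    anchor_hospitalization: date | None = None
    n_posts: int = 0
    excluded: bool = False
    events: list[TimelineEvent] = field(default_factory=list, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise SegmentationError(f"empty period [{self.start}, {self.end})")
        if self.label not in (RELAPSE, HEALTH):
            raise SegmentationError(f"unknown label {self.label!r}")

    @property
    def length_days(self) -> int:
        return (self.end - self.start).days

    def contains(self, ts: datetime | date) -> bool:
        d = ts.date() if isinstance(ts, datetime) else ts
        return self.start <= d < self.end

    @property
    def row_id(self) -> tuple[str, str, str]:
        return (self.participant_id, self.start.isoformat(), self.end.isoformat())


def study_window(hospitalizations: Sequence[Hospitalization]) -> tuple[date, date]:
    """[first admit, last admit) — the span within which periods are defined.

    Hospitalizations after the first are the participant's relapse events;
    a participant with exactly one hospitalization has no relapse and cannot
    be segmented.
    """
    if not hospitalizations:
        raise SegmentationError("no hospitalizations")
    admits = [h.admit_date for h in hospitalizations]
    if admits != sorted(admits):
        raise SegmentationError("hospitalizations must be sorted by admit date")
    if len(hospitalizations) < 2:
        raise NoRelapseError(
            f"participant {hospitalizations[0].participant_id} has no relapse "
            "hospitalization"
        )
    return (admits[0], admits[-1])


def relapse_windows(
    hospitalizations: Sequence[Hospitalization],
    cfg: SegmentationConfig = SegmentationConfig(),
) -> list[Period]:
    """One relapse period per non-index hospitalization.

    Each window is ``[admit - relapse_window_days, admit)``, clipped so it
    never starts before the previous hospitalization's (effective) discharge.
    Windows that are empty after clipping are dropped with a warning.
    """
    start_of_window, _ = study_window(hospitalizations)  # also validates order
    hosps = normalize_hospitalizations(
        hospitalizations, stay_days=cfg.inpatient_stay_days
    )
    periods: list[Period] = []
    for prev, hosp in zip(hosps, hosps[1:]):
        admit = hosp.admit_date
        start = admit - timedelta(days=cfg.relapse_window_days)
        floor = prev.effective_discharge(cfg.inpatient_stay_days)
        start = max(start, floor)
        if start >= admit:
            logger.warning(
                "dropping empty relapse window before %s for %s",
                admit,
                hosp.participant_id,
            )
            continue
        periods.append(
            Period(
                participant_id=hosp.participant_id,
                start=start,
                end=admit,
                label=RELAPSE,
                granularity_days=cfg.relapse_window_days,
                anchor_hospitalization=admit,
            )
        )
    return periods


def _subtract(intervals: list[tuple[date, date]], cut: tuple[date, date]) -> list[tuple[date, date]]:
    out = []
    cs, ce = cut
    for s, e in intervals:
        if ce <= s or cs >= e:
            out.append((s, e))
            continue
        if s < cs:
            out.append((s, cs))
        if ce < e:
            out.append((ce, e))
    return out


def health_periods(
    window: tuple[date, date],
    relapse_periods: Sequence[Period],
    inpatient_stays: Sequence[tuple[date, date]],
    cfg: SegmentationConfig = SegmentationConfig(),
    participant_id: str | None = None,
) -> list[Period]:
    """Tile the non-relapse (and, by default, non-inpatient) time with
    consecutive fixed-length health periods.

    The study window minus relapse windows minus inpatient stays decomposes
    into maximal runs; each run is tiled left-to-right with
    ``[t, t + granularity)`` periods and a short trailing remainder is dropped.
    """
    runs = [window]
    for p in relapse_periods:
        runs = _subtract(runs, (p.start, p.end))
    if cfg.exclude_inpatient:
        for stay in inpatient_stays:
            runs = _subtract(runs, stay)
    pid = participant_id or (
        relapse_periods[0].participant_id if relapse_periods else ""
    )
    gran = cfg.health_granularity_days
    periods = []
    for s, e in sorted(runs):
        t = s
        while (e - t).days >= gran:
            periods.append(
                Period(
                    participant_id=pid,
                    start=t,
                    end=t + timedelta(days=gran),
                    label=HEALTH,
                    granularity_days=gran,
                )
            )
            t += timedelta(days=gran)
    return periods


def inpatient_intervals(
    hospitalizations: Sequence[Hospitalization],
    stay_days: int = DEFAULT_STAY_DAYS,
) -> list[tuple[date, date]]:
    """Half-open [admit, discharge) stays, with missing discharges imputed."""
    hosps = normalize_hospitalizations(hospitalizations, stay_days=stay_days)
    out = []
    for h in hosps:
        discharge = h.effective_discharge(stay_days)
        if discharge > h.admit_date:
            out.append((h.admit_date, discharge))
    return out


def segment_participant(
    hospitalizations: Sequence[Hospitalization],
    cfg: SegmentationConfig = SegmentationConfig(),
) -> list[Period]:
    """Full segmentation: relapse windows plus tiled health periods."""
    window = study_window(hospitalizations)
    rel = relapse_windows(hospitalizations, cfg)
    stays = inpatient_intervals(hospitalizations, cfg.inpatient_stay_days)
    health = health_periods(
        window,
        rel,
        stays,
        cfg,
        participant_id=hospitalizations[0].participant_id,
    )
    return sorted(rel + health, key=lambda p: p.start)


def assign_posts(
    timeline: Timeline,
    periods: Sequence[Period],
    min_posts_per_period: int = 1,
) -> list[Period]:
    """Attach each event to the unique period containing its date.

    Periods must be pairwise disjoint.  Returns the periods with ``n_posts``
    and per-period event lists filled; periods with fewer than
    ``min_posts_per_period`` events are flagged ``excluded`` (retained for
    audit, never silently dropped).
    """
    ordered = sorted(periods, key=lambda p: p.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise SegmentationError(
                f"overlapping periods [{a.start},{a.end}) and [{b.start},{b.end})"
            )
    for p in ordered:
        p.events = []
    starts = [p.start for p in ordered]
    import bisect

    for event in timeline.events:
        d = event.timestamp.date()
        i = bisect.bisect_right(starts, d) - 1
        if i >= 0 and ordered[i].contains(d):
            ordered[i].events.append(event)
    for p in ordered:
        p.n_posts = len(p.events)
        p.excluded = p.n_posts < min_posts_per_period
    return ordered
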