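"""Per-period behavioral activity rates, overall and by diurnal bin.

Activity counts are taken per event kind and per local-clock diurnal bin and
normalized to a 30-day equivalent so health periods of 60 or 90 days remain
feature-comparable with 30-day relapse windows (unnormalized counts would
let a classifier learn period length instead of behavior).

The four diurnal bins partition the 24-hour wall clock:

* morning  = [05:00, 12:00)
* noon     = [12:00, 17:00)
* night    = [17:00, 22:00)
* midnight = [22:00, 05:00) (wraps past midnight)
"""

from __future__ import annotations

from datetime import datetime, time
from typing import Iterable, Sequence

from .segmentation import Period
from .timeline import EVENT_KINDS, TimelineEvent

DIURNAL_BINS = ("morning", "noon", "night", "midnight")

_BIN_EDGES = ((5, "morning"), (12, "noon"), (17, "night"), (22, "midnight"))


def diurnal_bin(timestamp: datetime | time) -> str:
    """Map a local-clock time to its unique diurnal bin."""
    hour = timestamp.hour
    if 5 <= hour < 12:
        return "morning"
    if 12 <= hour < 17:
        return "noon"
    if 17 <= hour < 22:
        return "night"
    return "midnight"


def behavior_feature_names() -> list[str]:
    """Column names: ``<kind>__overall`` and ``<kind>__<bin>`` for 9 kinds."""
    names = []
    for kind in EVENT_KINDS:
        names.append(f"{kind}__overall")
        for b in DIURNAL_BINS:
            names.append(f"{kind}__{b}")
    return names


def _counts_as_kind(event: TimelineEvent) -> list[str]:
    # co-tagging behavior = explicit co_tag events plus tagged statuses/photos
    kinds = [event.kind]
    if event.kind in ("status", "photo") and event.co_tagged:
        kinds.append("co_tag")
    return kinds


def activity_features(
    period: Period,
    events: Sequence[TimelineEvent] | None = None,
    normalize: bool = True,
) -> dict[str, float]:
    """Count events of each kind (overall + per diurnal bin) as 30-day rates.

    ``rate = count * 30 / period_length_days`` when ``normalize`` is on
    (default); the overall rate is exactly the sum of its four bin rates.
    Events must lie inside the period.
    """
    if events is None:
        events = period.events
    counts = {name: 0 for name in behavior_feature_names()}
    for event in events:
        if not period.contains(event.timestamp):
            raise ValueError(
                f"event at {event.timestamp} outside period "
                f"[{period.start}, {period.end})"
            )
        b = diurnal_bin(event.timestamp)
        for kind in _counts_as_kind(event):
            counts[f"{kind}__overall"] += 1
            counts[f"{kind}__{b}"] += 1
    scale = 30.0 / period.length_days if normalize else 1.0
    return {name: c * scale for name, c in counts.items()}


def activity_matrix(
    periods: Iterable[Period], normalize: bool = True
) -> dict[tuple, dict[str, float]]:
    """Behavioral feature map per period (keyed by period row_id)."""
    return {
        p.row_id: activity_features(p, normalize=normalize) for p in periods
    }
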