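"""Canonical timeline representation and archive I/O.

Social-media archive exports arrive as directories of JSON files holding
timestamped user activities.  This module normalizes them into a single
validated :class:`Timeline` per participant and reads/writes the canonical
JSONL interchange format (one event per line, schema-version header).

Timestamps are participant-local wall-clock times and are never converted
between timezones: the diurnal features downstream depend on local clock
semantics (a post at 23:10 is a late-night post wherever it was written).
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "timeline/1"
TIMESTAMP_FMT = "%Y-%m-%dT%H:%M"

#: The nine recognized activity kinds.
EVENT_KINDS = (
    "status",
    "comment",
    "share",
    "like",
    "photo",
    "check_in",
    "friend_add",
    "co_tag",
    "app_use",
)

#: Kinds that are behavioral-only and never carry text.
TEXTLESS_KINDS = frozenset({"like", "friend_add"})

#: Median inpatient stay (days) used to impute a missing discharge date.
DEFAULT_STAY_DAYS = 13


class TimelineError(ValueError):
    """Base error for timeline parsing and validation problems."""


class ArchiveInputError(TimelineError):
    """The archive root is missing, unreadable, or yields zero events."""


class EmptyTimelineError(ArchiveInputError):
    """No parseable events were found (insufficient data for analysis)."""


class SchemaVersionError(TimelineError):
    """Canonical file header does not declare a supported schema version."""


@dataclass(frozen=True)
class TimelineEvent:
    """One timestamped user activity (textual or behavioral)."""

    participant_id: str
    timestamp: datetime
    kind: str
    text: str = ""
    co_tagged: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise TimelineError(f"unknown event kind {self.kind!r}")
        object.__setattr__(self, "co_tagged", tuple(self.co_tagged))

    def to_record(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "timestamp": self.timestamp.strftime(TIMESTAMP_FMT),
            "kind": self.kind,
            "text": self.text,
            "co_tagged": list(self.co_tagged),
        }

    @classmethod
    def from_record(cls, record: dict) -> "TimelineEvent":
        return cls(
            participant_id=str(record["participant_id"]),
            timestamp=datetime.strptime(record["timestamp"], TIMESTAMP_FMT),
            kind=record["kind"],
            text=record.get("text", "") or "",
            co_tagged=tuple(record.get("co_tagged") or ()),
        )


@dataclass
class Timeline:
    """All events of one participant, sorted ascending by timestamp.

    Sorting is stable: events sharing a timestamp keep insertion order.
    """

    participant_id: str
    events: list[TimelineEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.timestamp)

    @property
    def span(self) -> tuple[datetime, datetime] | None:
        if not self.events:
            return None
        return (self.events[0].timestamp, self.events[-1].timestamp)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[TimelineEvent]:
        return iter(self.events)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Timeline):
            return NotImplemented
        return (
            self.participant_id == other.participant_id
            and self.events == other.events
        )


@dataclass(frozen=True)
class Hospitalization:
    """One inpatient admission; discharge may be unknown in the source CSV."""

    participant_id: str
    admit_date: date
    discharge_date: date | None = None
    discharge_imputed: bool = False

    def __post_init__(self) -> None:
        if self.discharge_date is not None and self.discharge_date < self.admit_date:
            raise TimelineError(
                f"discharge {self.discharge_date} precedes admit {self.admit_date}"
            )

    def effective_discharge(self, stay_days: int = DEFAULT_STAY_DAYS) -> date:
        if self.discharge_date is not None:
            return self.discharge_date
        return self.admit_date + timedelta(days=stay_days)


def normalize_hospitalizations(
    hospitalizations: Sequence[Hospitalization],
    stay_days: int = DEFAULT_STAY_DAYS,
) -> list[Hospitalization]:
    """Sort by admit date and impute missing discharges (flagged)."""
    out = []
    for h in sorted(hospitalizations, key=lambda h: h.admit_date):
        if h.discharge_date is None:
            out.append(
                replace(
                    h,
                    discharge_date=h.admit_date + timedelta(days=stay_days),
                    discharge_imputed=True,
                )
            )
        else:
            out.append(h)
    return out


# ---------------------------------------------------------------------------
# Archive parsing


@dataclass
class ParseStats:
    parsed: int = 0
    skipped: int = 0
    skipped_kinds: dict = field(default_factory=dict)


def _coerce_activity(record: dict, default_pid: str | None) -> TimelineEvent | None:
    kind = record.get("kind")
    if kind not in EVENT_KINDS:
        return None
    pid = str(record.get("participant_id") or default_pid or "")
    if not pid:
        return None
    try:
        ts = datetime.strptime(record["timestamp"], TIMESTAMP_FMT)
    except (KeyError, ValueError, TypeError):
        try:
            ts = datetime.fromisoformat(record["timestamp"])
            ts = ts.replace(second=0, microsecond=0, tzinfo=None)
        except (KeyError, ValueError, TypeError):
            return None
    text = record.get("text", "") or ""
    if kind in TEXTLESS_KINDS:
        text = ""
    return TimelineEvent(
        participant_id=pid,
        timestamp=ts,
        kind=kind,
        text=text,
        co_tagged=tuple(record.get("co_tagged") or ()),
    )


def parse_archive(root: str | Path, stats: ParseStats | None = None) -> Timeline:
    """Parse a directory of canonical-schema JSON files into one Timeline.

    Each ``*.json`` file is ``{"participant_id": ..., "activities": [...]}``.
    Unrecognized activity records (unknown kind, bad timestamp) are counted
    and logged, never fatal.  Zero parseable events raises
    :class:`EmptyTimelineError`.
    """
    root = Path(root)
    if not root.is_dir():
        raise ArchiveInputError(f"archive root {root} is not a readable directory")
    stats = stats if stats is not None else ParseStats()
    events: list[TimelineEvent] = []
    pid: str | None = None
    for path in sorted(root.glob("*.json")):
        try:
            payload = json.loads(path.read_text(encoding="utf-8"))
        except (OSError, json.JSONDecodeError) as exc:
            raise ArchiveInputError(f"cannot read archive file {path}: {exc}") from exc
        file_pid = payload.get("participant_id")
        if pid is None:
            pid = file_pid
        elif file_pid is not None and file_pid != pid:
            raise ArchiveInputError(
                f"archive mixes participants {pid!r} and {file_pid!r}"
            )
        for record in payload.get("activities", []):
            event = _coerce_activity(record, pid)
            if event is None:
                stats.skipped += 1
                k = record.get("kind", "<missing>")
                stats.skipped_kinds[k] = stats.skipped_kinds.get(k, 0) + 1
                logger.debug("skipping unrecognized record in %s: %r", path, record)
            else:
                events.append(event)
                stats.parsed += 1
    if not events:
        raise EmptyTimelineError(f"no parseable events under {root}")
    return Timeline(participant_id=events[0].participant_id, events=events)


# ---------------------------------------------------------------------------
# Canonical JSONL


def write_canonical(timeline: Timeline, path: str | Path) -> None:
    """Write a timeline as JSONL with a schema-version header line.

    Field order is fixed so output is byte-stable for a given timeline.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(json.dumps({"schema": SCHEMA_VERSION}) + "\n")
        for event in timeline.events:
            fh.write(json.dumps(event.to_record(), sort_keys=False) + "\n")


def read_canonical(path: str | Path) -> Timeline:
    """Read a canonical JSONL timeline; inverse of :func:`write_canonical`."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline()
        try:
            declared = json.loads(header).get("schema")
        except json.JSONDecodeError as exc:
            raise SchemaVersionError(f"{path}: malformed header line") from exc
        if declared != SCHEMA_VERSION:
            raise SchemaVersionError(
                f"{path}: schema {declared!r}, expected {SCHEMA_VERSION!r}"
            )
        events = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            try:
                events.append(TimelineEvent.from_record(json.loads(line)))
            except (json.JSONDecodeError, KeyError, ValueError) as exc:
                raise TimelineError(f"{path}: malformed event at line {lineno}") from exc
    pid = events[0].participant_id if events else _pid_from_filename(path)
    return Timeline(participant_id=pid, events=events)


def _pid_from_filename(path: Path) -> str:
    return path.stem


def read_canonical_many(paths: Iterable[str | Path]) -> list[Timeline]:
    return [read_canonical(p) for p in paths]


# ---------------------------------------------------------------------------
# Validation


def validate_timeline(timeline: Timeline) -> list[str]:
    """Return a list of invariant violations (empty iff the timeline is valid).

    Validation never raises; each violation names the offending event index.
    """
    violations: list[str] = []
    prev_ts: datetime | None = None
    for i, event in enumerate(timeline.events):
        if event.participant_id != timeline.participant_id:
            violations.append(f"participant mismatch at index {i}")
        if event.kind not in EVENT_KINDS:
            violations.append(f"unknown kind at index {i}")
        if event.kind in TEXTLESS_KINDS and event.text:
            violations.append(f"text on behavioral-only kind at index {i}")
        if prev_ts is not None and event.timestamp < prev_ts:
            violations.append(f"unsorted at index {i}")
        prev_ts = event.timestamp
    return violations


# ---------------------------------------------------------------------------
# Hospitalization CSV


def read_hospitalizations(path: str | Path) -> dict[str, list[Hospitalization]]:
    """Read the hospitalizations CSV (participant_id, admit_date, discharge_date).

    Dates are ISO-8601; discharge may be blank.  Returns hospitalizations per
    participant, sorted by admit date.
    """
    per: dict[str, list[Hospitalization]] = {}
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"participant_id", "admit_date", "discharge_date"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise TimelineError(
                f"{path}: expected columns {sorted(required)}, got {reader.fieldnames}"
            )
        for row in reader:
            discharge = row["discharge_date"].strip()
            hosp = Hospitalization(
                participant_id=row["participant_id"],
                admit_date=date.fromisoformat(row["admit_date"].strip()),
                discharge_date=date.fromisoformat(discharge) if discharge else None,
            )
            per.setdefault(hosp.participant_id, []).append(hosp)
    return {pid: sorted(hs, key=lambda h: h.admit_date) for pid, hs in per.items()}


def write_hospitalizations(
    hospitalizations: Iterable[Hospitalization], path: str | Path
) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["participant_id", "admit_date", "discharge_date"])
        for h in hospitalizations:
            writer.writerow(
                [
                    h.participant_id,
                    h.admit_date.isoformat(),
                    h.discharge_date.isoformat() if h.discharge_date else "",
                ]
            )


def ascii_alpha_fraction(texts: Iterable[str]) -> float:
    """Fraction of tokens that are pure ASCII-alphabetic, over all texts.

    Used by the CLI to optionally drop participants whose content is mostly
    non-English; returns 1.0 when there are no tokens.
    """
    total = 0
    ascii_alpha = 0
    for text in texts:
        for tok in text.split():
            total += 1
            if tok.isascii() and tok.isalpha():
                ascii_alpha += 1
    return ascii_alpha / total if total else 1.0
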