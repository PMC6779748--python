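"""Synthetic cohort generator with planted pre-relapse effects.

Real patient timelines cannot be shared, so every pipeline stage is
exercised against generated cohorts whose statistical structure mirrors
the analysis assumptions:

* per participant, 2–4 hospitalizations spaced Uniform(90, 300) days apart
  (matching an average of ~2.4 relapse admissions per participant and a
  13-day median inpatient stay);
* activities arrive as independent per-kind Poisson streams at
  ``base_post_rate`` events/day overall, thinned across four diurnal bins;
* post text is drawn token-by-token from category word lists at
  configurable per-token emission probabilities (defaults are the
  health-period category proportions observed in the study cohort), with
  the remainder drawn from a 200-word neutral filler vocabulary;
* inside each 30-day pre-relapse window, category emission probabilities,
  co-tagging/friending rates, and the midnight diurnal weight are scaled
  by ``effect_multipliers`` — raising swear/anger/death/hear/feel and
  pronoun usage, depressing work/friends/health/achievement/body, and
  shifting posting into the night, in the directions the relapse
  literature reports.

Every cohort carries a machine-readable :class:`SyntheticTruth` (planted
windows, realized counts, multipliers) so recovery tests can compare
pipeline output against ground truth.  All randomness flows from a single
seed; a fixed seed reproduces the cohort byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from datetime import date, datetime, timedelta
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .behavior import DIURNAL_BINS
from .lexicon import Lexicon, builtin_lexicon
from .timeline import (
    Hospitalization,
    Timeline,
    TimelineEvent,
    write_canonical,
    write_hospitalizations,
)

#: Default per-token category emission probabilities: the health-period
#: category proportions reported for the study cohort (first-person
#: singular is not tabulated there; 0.05 is a typical social-media rate).
DEFAULT_CATEGORY_PROBS: dict[str, float] = {
    "exclusive": 0.0079,
    "family": 0.0021,
    "inclusive": 0.0152,
    "feel": 0.0057,
    "money": 0.0020,
    "causation": 0.0113,
    "insight": 0.0076,
    "humans": 0.0043,
    "anger": 0.0032,
    "home": 0.0045,
    "sexual": 0.0033,
    "future_tense": 0.0016,
    "death": 0.0004,
    "negation": 0.0091,
    "discrepancies": 0.0051,
    "religion": 0.0025,
    "verbs": 0.0856,
    "health": 0.0092,
    "first_person_plural": 0.0005,
    "bio": 0.0180,
    "tentativeness": 0.0067,
    "body": 0.0045,
    "inhibition": 0.0012,
    "hear": 0.0024,
    "second_person": 0.0070,
    "quantifier": 0.0028,
    "friends": 0.0071,
    "achievement": 0.0067,
    "negative_affect": 0.0023,
    "anxiety": 0.0008,
    "certainty": 0.0091,
    "work": 0.0164,
    "indefinite_pronoun": 0.0235,
    "sadness": 0.0019,
    "swear": 0.0017,
    "first_person_singular": 0.05,
}

#: Default pre-relapse multipliers: relapse/health mean ratios from the
#: study cohort's screen (behavioral keys 'co_tag', 'friend_add' scale event
#: rates; 'midnight' scales the midnight diurnal weight).
DEFAULT_EFFECT_MULTIPLIERS: dict[str, float] = {
    "swear": 2.0,
    "anger": 1.53,
    "death": 2.0,
    "hear": 2.75,
    "feel": 1.04,
    "first_person_singular": 1.3,
    "first_person_plural": 3.2,
    "second_person": 1.16,
    "future_tense": 2.25,
    "inclusive": 1.66,
    "quantifier": 1.86,
    "inhibition": 1.92,
    "negative_affect": 1.26,
    "work": 0.5,
    "friends": 0.59,
    "health": 0.25,
    "achievement": 0.91,
    "body": 0.91,
    "home": 0.42,
    "causation": 0.25,
    "certainty": 0.44,
    "bio": 0.54,
    "co_tag": 3.24,
    "friend_add": 1.17,
    "midnight": 2.7,
}

#: Share of total activity per event kind (sums to 1).
DEFAULT_KIND_SHARES: dict[str, float] = {
    "status": 0.36,
    "comment": 0.20,
    "share": 0.08,
    "like": 0.15,
    "photo": 0.08,
    "check_in": 0.04,
    "friend_add": 0.04,
    "co_tag": 0.02,
    "app_use": 0.03,
}

#: Baseline diurnal weights (morning, noon, night, midnight).
DEFAULT_DIURNAL_WEIGHTS: tuple[float, float, float, float] = (0.25, 0.30, 0.30, 0.15)

_TEXT_KINDS = ("status", "comment")

_BIN_HOURS = {
    "morning": list(range(5, 12)),
    "noon": list(range(12, 17)),
    "night": list(range(17, 22)),
    "midnight": [22, 23, 0, 1, 2, 3, 4],
}


class SyntheticConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    n_participants: int = 51
    hospitalizations_per_participant: tuple[int, int] = (2, 4)
    followup_days: int = 720
    base_post_rate: float = 2.0
    base_category_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PROBS)
    )
    diurnal_weights: tuple[float, float, float, float] = DEFAULT_DIURNAL_WEIGHTS
    effect_multipliers: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_MULTIPLIERS)
    )
    kind_shares: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_KIND_SHARES)
    )
    relapse_window_days: int = 30
    inpatient_stay_days: int = 13
    gap_days: tuple[float, float] = (90.0, 300.0)
    tokens_mean: float = 8.0
    origin: date = date(2016, 1, 1)
    disjoint_synonyms: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.hospitalizations_per_participant
        if lo < 2 or hi < lo:
            raise SyntheticConfigError(
                "need at least 2 hospitalizations per participant"
            )
        if self.n_participants < 1 or self.base_post_rate <= 0:
            raise SyntheticConfigError("invalid cohort size or post rate")
        for p in self.base_category_probs.values():
            if not 0 <= p <= 1:
                raise SyntheticConfigError("category probabilities must be in [0,1]")
        for m in self.effect_multipliers.values():
            if m <= 0:
                raise SyntheticConfigError("effect multipliers must be positive")
        if abs(sum(self.diurnal_weights) - 1.0) > 1e-9:
            raise SyntheticConfigError("diurnal weights must sum to 1")
        if (lo - 1) * self.gap_days[0] > self.followup_days:
            raise SyntheticConfigError(
                "followup too short for the requested hospitalization spacing"
            )

    def null_effects(self) -> "SyntheticConfig":
        """Copy of this config with every planted multiplier set to 1."""
        from dataclasses import replace

        return replace(
            self,
            effect_multipliers={k: 1.0 for k in self.effect_multipliers},
        )


@dataclass
class SyntheticTruth:
    """Planted effect schedule of a generated cohort (test oracle)."""

    seed: int
    effect_multipliers: dict[str, float]
    null_effect: bool
    participants: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "effect_multipliers": self.effect_multipliers,
            "null_effect": self.null_effect,
            "participants": self.participants,
        }


@lru_cache(maxsize=1)
def _filler_vocabulary_cached() -> tuple[str, ...]:
    content = (
        resources.files("relapsekit.data").joinpath("filler_vocab.txt").read_text("utf-8")
    )
    words: list[str] = []
    for line in content.splitlines():
        line = line.split("#", 1)[0]
        words.extend(line.split())
    return tuple(words)


def filler_vocabulary() -> list[str]:
    """The 200-word neutral filler vocabulary bundled with the package."""
    return list(_filler_vocabulary_cached())


_CATEGORY_WORD_CACHE: dict[int, dict[str, list[str]]] = {}


def _category_words(lexicon: Lexicon) -> dict[str, list[str]]:
    """Emission word list per category: literals plus wildcard stems."""
    cached = _CATEGORY_WORD_CACHE.get(id(lexicon))
    if cached is not None:
        return cached
    out = {}
    for name, entries in lexicon.categories.items():
        words = sorted(e.rstrip("*") for e in entries if len(e.rstrip("*")) > 1)
        out[name] = words or sorted(e.rstrip("*") for e in entries)
    _CATEGORY_WORD_CACHE[id(lexicon)] = out
    return out


def _synonym_words(lexicon: Lexicon) -> dict[str, list[str]]:
    """Stand-in 'synonym' tokens per category that the lexicon cannot match.

    Used by the disjoint-synonym robustness mode: the cohort is generated
    from these tokens, so a matched analysis lexicon sees none of the
    planted category signal (emulating dictionary/vocabulary mismatch).
    """
    out = {}
    for name in lexicon.categories:
        words = []
        i = 0
        while len(words) < 8:
            candidate = f"zq{name.replace('_', '')}{i}"
            if not lexicon.categories_for(candidate):
                words.append(candidate)
            i += 1
        out[name] = words
    return out


def _adjusted_probs(
    base: Mapping[str, float],
    multipliers: Mapping[str, float],
    names: Sequence[str],
    pre_relapse: bool,
) -> np.ndarray:
    p = np.array([base.get(n, 0.0) for n in names], dtype=float)
    if pre_relapse:
        m = np.array([multipliers.get(n, 1.0) for n in names], dtype=float)
        p = p * m
    total = p.sum()
    if total > 1.0:
        p = p / total
    return p


def sample_post_text(
    state: str,
    lexicon: Lexicon,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> str:
    """One post's text: 1 + Poisson(tokens_mean) tokens, state-adjusted."""
    return _sample_texts(state, lexicon, cfg, rng, n_posts=1)[0]


def _sample_texts(
    state: str,
    lexicon: Lexicon,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    n_posts: int,
) -> list[str]:
    """Batch text sampler; one sentence per post."""
    if n_posts == 0:
        return []
    names = sorted(cfg.base_category_probs)
    words = (
        _synonym_words(lexicon) if cfg.disjoint_synonyms else _category_words(lexicon)
    )
    fillers = filler_vocabulary()
    p_cat = _adjusted_probs(
        cfg.base_category_probs,
        cfg.effect_multipliers,
        names,
        pre_relapse=(state == "pre_relapse"),
    )
    probs = np.append(p_cat, max(0.0, 1.0 - p_cat.sum()))
    probs = probs / probs.sum()
    lengths = 1 + rng.poisson(cfg.tokens_mean, size=n_posts)
    total = int(lengths.sum())
    sources = rng.choice(len(names) + 1, size=total, p=probs)
    tokens = np.empty(total, dtype=object)
    for i, name in enumerate(names):
        mask = sources == i
        k = int(mask.sum())
        if k:
            pool = words[name]
            tokens[mask] = [pool[j] for j in rng.integers(len(pool), size=k)]
    mask = sources == len(names)
    k = int(mask.sum())
    if k:
        tokens[mask] = [fillers[j] for j in rng.integers(len(fillers), size=k)]
    texts = []
    offset = 0
    for L in lengths:
        texts.append(" ".join(tokens[offset : offset + L]) + ".")
        offset += L
    return texts


def _draw_admits(
    cfg: SyntheticConfig, rng: np.random.Generator
) -> list[int]:
    lo, hi = cfg.hospitalizations_per_participant
    n_hosp = int(rng.integers(lo, hi + 1))
    if (n_hosp - 1) * cfg.gap_days[0] > cfg.followup_days:
        raise SyntheticConfigError(
            "followup too short for the drawn hospitalization count"
        )
    for _ in range(1000):
        gaps = rng.uniform(cfg.gap_days[0], cfg.gap_days[1], size=n_hosp - 1)
        if gaps.sum() <= cfg.followup_days:
            return [0] + [int(d) for d in np.cumsum(np.rint(gaps).astype(int))]
    raise SyntheticConfigError("could not place hospitalizations within followup")


def _diurnal_weights(cfg: SyntheticConfig, pre_relapse: bool) -> np.ndarray:
    w = np.array(cfg.diurnal_weights, dtype=float)
    if pre_relapse:
        w[DIURNAL_BINS.index("midnight")] *= cfg.effect_multipliers.get("midnight", 1.0)
    return w / w.sum()


def generate_participant(
    pid: str,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    lexicon: Lexicon,
) -> tuple[Timeline, list[Hospitalization], dict]:
    admit_days = _draw_admits(cfg, rng)
    start_offset = int(rng.integers(0, 60))
    origin = cfg.origin + timedelta(days=start_offset)
    admits = [origin + timedelta(days=d) for d in admit_days]
    hosps = [
        Hospitalization(
            participant_id=pid,
            admit_date=a,
            discharge_date=a + timedelta(days=cfg.inpatient_stay_days),
        )
        for a in admits
    ]

    # planted relapse windows: [admit - W, admit), clipped at prev discharge
    windows: list[tuple[date, date]] = []
    for prev, hosp in zip(hosps, hosps[1:]):
        w_start = max(
            hosp.admit_date - timedelta(days=cfg.relapse_window_days),
            prev.discharge_date,
        )
        if w_start < hosp.admit_date:
            windows.append((w_start, hosp.admit_date))

    n_days = (admits[-1] - admits[0]).days
    day_dates = [admits[0] + timedelta(days=i) for i in range(n_days)]
    pre = np.zeros(n_days, dtype=bool)
    for ws, we in windows:
        i0 = (ws - admits[0]).days
        i1 = (we - admits[0]).days
        pre[i0:i1] = True

    kinds = sorted(cfg.kind_shares)
    shares = np.array([cfg.kind_shares[k] for k in kinds], dtype=float)
    rate = cfg.base_post_rate * shares  # events/day per kind
    mult = np.array(
        [
            cfg.effect_multipliers.get(k, 1.0) if k in ("co_tag", "friend_add") else 1.0
            for k in kinds
        ]
    )
    rates = np.tile(rate, (n_days, 1))
    rates[pre] = rates[pre] * mult
    counts = rng.poisson(rates)  # (n_days, n_kinds)

    events: list[TimelineEvent] = []
    text_requests: list[tuple[bool, int]] = []  # (pre_relapse, event index)
    for di in range(n_days):
        d = day_dates[di]
        weights = _diurnal_weights(cfg, bool(pre[di]))
        day_total = int(counts[di].sum())
        if day_total == 0:
            continue
        bins = rng.choice(4, size=day_total, p=weights)
        minutes = rng.integers(0, 60, size=day_total)
        ei = 0
        for ki, kind in enumerate(kinds):
            for _ in range(counts[di, ki]):
                hours = _BIN_HOURS[DIURNAL_BINS[bins[ei]]]
                hour = hours[rng.integers(len(hours))]
                ts = datetime(d.year, d.month, d.day, hour, int(minutes[ei]))
                co_tagged: tuple[str, ...] = ()
                if kind == "co_tag":
                    n_tags = int(rng.integers(1, 4))
                    co_tagged = tuple(
                        f"handle{int(rng.integers(1000)):03d}" for _ in range(n_tags)
                    )
                elif kind == "photo" and rng.random() < 0.02:
                    co_tagged = (f"handle{int(rng.integers(1000)):03d}",)
                events.append(
                    TimelineEvent(
                        participant_id=pid,
                        timestamp=ts,
                        kind=kind,
                        text="",
                        co_tagged=co_tagged,
                    )
                )
                if kind in _TEXT_KINDS:
                    text_requests.append((bool(pre[di]), len(events) - 1))
                ei += 1

    # batch-fill post text by state
    for state_flag in (False, True):
        idxs = [i for flag, i in text_requests if flag == state_flag]
        texts = _sample_texts(
            "pre_relapse" if state_flag else "healthy", lexicon, cfg, rng, len(idxs)
        )
        for i, text in zip(idxs, texts):
            e = events[i]
            events[i] = TimelineEvent(
                participant_id=e.participant_id,
                timestamp=e.timestamp,
                kind=e.kind,
                text=text,
                co_tagged=e.co_tagged,
            )

    timeline = Timeline(participant_id=pid, events=events)
    window_counts = [
        sum(1 for e in events if ws <= e.timestamp.date() < we) for ws, we in windows
    ]
    truth = {
        "admits": [a.isoformat() for a in admits],
        "relapse_windows": [(s.isoformat(), e.isoformat()) for s, e in windows],
        "window_event_counts": window_counts,
        "n_events": len(events),
    }
    return timeline, hosps, truth


def generate_cohort(
    cfg: SyntheticConfig = SyntheticConfig(),
    lexicon: Lexicon | None = None,
) -> tuple[list[Timeline], list[Hospitalization], SyntheticTruth]:
    """Generate a full cohort of timelines + hospitalizations + truth log."""
    lexicon = lexicon or builtin_lexicon()
    rng = np.random.default_rng(cfg.seed)
    mult = dict(cfg.effect_multipliers)
    truth = SyntheticTruth(
        seed=cfg.seed,
        effect_multipliers=mult,
        null_effect=all(abs(m - 1.0) < 1e-12 for m in mult.values()),
    )
    timelines = []
    hospitalizations: list[Hospitalization] = []
    width = len(str(cfg.n_participants))
    for i in range(cfg.n_participants):
        pid = f"p{i + 1:0{width}d}"
        tl, hosps, part_truth = generate_participant(pid, cfg, rng, lexicon)
        timelines.append(tl)
        hospitalizations.extend(hosps)
        truth.participants[pid] = part_truth
    return timelines, hospitalizations, truth


def emit_fixture(
    cohort: tuple[list[Timeline], list[Hospitalization], SyntheticTruth],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write canonical JSONL timelines, hospitalizations CSV, truth JSON."""
    timelines, hospitalizations, truth = cohort
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for tl in timelines:
        p = out / f"{tl.participant_id}.jsonl"
        write_canonical(tl, p)
        paths[tl.participant_id] = p
    hosp_path = out / "hospitalizations.csv"
    write_hospitalizations(hospitalizations, hosp_path)
    paths["hospitalizations"] = hosp_path
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(truth.to_dict(), indent=2), encoding="utf-8")
    paths["truth"] = truth_path
    return paths
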