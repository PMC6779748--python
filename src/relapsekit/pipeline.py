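"""End-to-end experiment orchestration.

Chains the pipeline stages in leakage-safe order: segmentation →
train/heldout split of the health (inlier) periods → unigram vocabulary
built from *training* text only → featurization → CoV feature selection
and standardization fit on training inliers only → one-class model fit →
evaluation on the held-out health periods plus all relapse periods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import lexicon as lx
from .anomaly import (
    EnsembleOneClassSVM,
    EvalReport,
    ModelConfig,
    SplitSpec,
    evaluate,
    fit_ocsvm,
    split_inliers,
)
from .features import (
    CoVSelector,
    FeatureMatrix,
    PeriodScaler,
    featurize_periods,
)
from .segmentation import (
    NoRelapseError,
    Period,
    SegmentationConfig,
    assign_posts,
    segment_participant,
)
from .timeline import Hospitalization, Timeline, normalize_hospitalizations

logger = logging.getLogger(__name__)


def segment_cohort(
    timelines: Sequence[Timeline],
    hospitalizations: Sequence[Hospitalization],
    cfg: SegmentationConfig = SegmentationConfig(),
    drop_excluded: bool = True,
) -> list[Period]:
    """Segment and post-assign every participant; skip those without relapse.

    Participants with fewer than two hospitalizations (no relapse event)
    or with zero qualifying periods are skipped with a log message, matching
    the study's exclusion flow.
    """
    per_pid: dict[str, list[Hospitalization]] = {}
    for h in hospitalizations:
        per_pid.setdefault(h.participant_id, []).append(h)
    periods: list[Period] = []
    for tl in timelines:
        hosps = per_pid.get(tl.participant_id)
        if not hosps:
            logger.info("participant %s has no hospitalizations; skipped", tl.participant_id)
            continue
        hosps = normalize_hospitalizations(hosps, stay_days=cfg.inpatient_stay_days)
        try:
            parts = segment_participant(hosps, cfg)
        except NoRelapseError:
            logger.info("participant %s has no relapse; skipped", tl.participant_id)
            continue
        parts = assign_posts(tl, parts, min_posts_per_period=cfg.min_posts_per_period)
        if drop_excluded:
            parts = [p for p in parts if not p.excluded]
        periods.extend(parts)
    return periods


@dataclass
class ExperimentResult:
    report: EvalReport
    n_train: int
    n_heldout_health: int
    n_relapse: int
    n_features_total: int
    n_features_retained: int
    retained: list[str] = field(default_factory=list)
    heldout_predictions: pd.Series | None = None

    def to_dict(self) -> dict:
        out = self.report.to_dict()
        out.update(
            n_train=self.n_train,
            n_heldout_health=self.n_heldout_health,
            n_relapse=self.n_relapse,
            n_features_total=self.n_features_total,
            n_features_retained=self.n_features_retained,
        )
        return out


def run_experiment(
    timelines: Sequence[Timeline],
    hospitalizations: Sequence[Hospitalization],
    granularity_days: int = 30,
    model: ModelConfig = ModelConfig(),
    split: SplitSpec = SplitSpec(),
    use_ensemble: bool = False,
    lexicon: lx.Lexicon | None = None,
    unigram_k: int | None = 200,
    cov_k_sd: float = 1.0,
    cov_mode: str = "eliminate_outside",
    segmentation: SegmentationConfig | None = None,
) -> ExperimentResult:
    """Train and evaluate one data configuration (30/60/90-day health periods).

    Relapse windows are always 30 days; ``granularity_days`` sets the
    health-period length.  Returns the evaluation under the
    health=positive(inlier) convention.
    """
    lexicon = lexicon or lx.builtin_lexicon()
    seg_cfg = segmentation or SegmentationConfig(
        health_granularity_days=granularity_days
    )
    periods = segment_cohort(timelines, hospitalizations, seg_cfg)
    health = [p for p in periods if p.label == "health"]
    relapse = [p for p in periods if p.label == "relapse"]
    if len(health) < 2 or not relapse:
        raise ValueError(
            f"cohort too small to evaluate: {len(health)} health, "
            f"{len(relapse)} relapse periods"
        )

    train_ids, heldout_ids = split_inliers([p.row_id for p in health], split)
    train_set = set(train_ids)
    train_periods = [p for p in health if p.row_id in train_set]

    vocabulary = None
    if unigram_k:
        train_texts = [
            e.text for p in train_periods for e in p.events if e.text
        ]
        vocabulary = lx.build_vocabulary(train_texts, unigram_k)

    fm = featurize_periods(
        periods, lexicon=lexicon, vocabulary=vocabulary, drop_excluded=False
    )
    is_train = fm.data.index.isin(train_set)
    is_heldout_health = fm.data.index.isin(set(heldout_ids))
    is_relapse = (fm.labels == "relapse").to_numpy()

    selector = CoVSelector(k_sd=cov_k_sd, mode=cov_mode).fit(fm.data[is_train])
    scaler = PeriodScaler().fit(selector.transform(fm.data[is_train]))
    Z = scaler.transform(selector.transform(fm.data))

    X_train = Z[is_train].to_numpy()
    test_mask = is_heldout_health | is_relapse
    X_test = Z[test_mask].to_numpy()
    y_test = fm.labels[test_mask]

    if use_ensemble:
        est = EnsembleOneClassSVM.from_config(model).fit(X_train)
        predictions = est.predict(X_test)
    else:
        est = fit_ocsvm(X_train, model)
        predictions = est.predict(X_test)

    report = evaluate(predictions, y_test.to_numpy())
    retained = [n for n, keep in zip(fm.feature_names, selector.get_support()) if keep]
    return ExperimentResult(
        report=report,
        n_train=len(train_ids),
        n_heldout_health=len(heldout_ids),
        n_relapse=len(relapse),
        n_features_total=fm.data.shape[1],
        n_features_retained=len(retained),
        retained=retained,
        heldout_predictions=pd.Series(predictions, index=y_test.index),
    )
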