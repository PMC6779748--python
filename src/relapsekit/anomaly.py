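"""One-class SVM relapse detectors, the bagged ensemble, and evaluation.

Health periods are the single training class (inliers/positive); relapse
periods are never seen in training and should be flagged as outliers
(negative).  Under this convention *sensitivity* measures recognizing
health periods and *specificity* measures catching relapse periods:

* tp = health period predicted inlier
* fn = health period predicted outlier  ("false negative": a healthy
  period wrongly predicted as relapse)
* tn = relapse period predicted outlier
* fp = relapse period predicted inlier

The single model is a kernel one-class SVM (``sklearn.svm.OneClassSVM``);
``nu`` upper-bounds the fraction of training inliers placed outside the
learned boundary.  The ensemble bags ``n_members`` one-class SVMs over
seeded row and feature subsamples and votes: a point is an inlier only if
the inlier-vote fraction strictly exceeds ``vote_threshold`` — an exact tie
flags the point as an outlier, deliberately favoring relapse detection
(specificity over sensitivity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, OutlierMixin
from sklearn.svm import OneClassSVM
from sklearn.utils.validation import check_array, check_is_fitted

CONVENTION = "health=positive(inlier), relapse=negative(outlier)"


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class EnsembleConfig:
    n_members: int = 25
    row_fraction: float = 0.8
    feature_fraction: float = 0.7
    vote_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        if not (0 < self.row_fraction <= 1 and 0 < self.feature_fraction <= 1):
            raise ValueError("fractions must lie in (0, 1]")
        if not (0 < self.vote_threshold <= 1):
            raise ValueError("vote_threshold must lie in (0, 1]")


#: Smoothing factor for the default "wide" RBF bandwidth: gamma = 1/(WIDE_GAMMA_FACTOR * d).
#: The two-class default 1/(d*Var) draws a boundary tight enough to overfit
#: small one-class training sets, inflating held-out inlier rejection far
#: above nu; a wider kernel restores the nu semantics out of sample.
WIDE_GAMMA_FACTOR = 16


def resolve_gamma(gamma: float | str, n_features: int) -> float | str:
    """Translate the package's 'wide' bandwidth rule; pass others through."""
    if gamma == "wide":
        return 1.0 / (WIDE_GAMMA_FACTOR * n_features)
    return gamma


@dataclass(frozen=True)
class ModelConfig:
    kernel: str = "rbf"
    nu: float = 0.1
    gamma: float | str = "wide"
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)

    def __post_init__(self) -> None:
        if self.kernel not in ("rbf", "linear"):
            raise ValueError(f"unsupported kernel {self.kernel!r}")
        if not (0 < self.nu <= 1):
            raise ValueError("nu must lie in (0, 1]")
        if isinstance(self.gamma, (int, float)):
            if self.gamma <= 0:
                raise ValueError("gamma must be positive")
        elif self.gamma not in ("scale", "auto", "wide"):
            raise ValueError(f"unknown gamma rule {self.gamma!r}")


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.9
    seed: int = 0
    grouping: str = "period"

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.grouping not in ("period", "participant"):
            raise ValueError(f"unknown grouping {self.grouping!r}")


# ---------------------------------------------------------------------------
# Splitting


def split_inliers(
    inlier_ids: Sequence, spec: SplitSpec = SplitSpec()
) -> tuple[list, list]:
    """Split inlier period ids into (train, heldout), seeded.

    The heldout side has exactly ``round_half_up((1 - train_fraction) * n)``
    periods under period-level grouping (719/421/312 inliers at 0.9 give
    72/42/31 held out).  Participant grouping keeps all of a participant's
    periods on one side, so the heldout count is only approximate there.
    """
    ids = list(inlier_ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 inliers to split")
    target = round_half_up((1 - spec.train_fraction) * n)
    rng = np.random.default_rng(spec.seed)
    if spec.grouping == "period":
        order = rng.permutation(n)
        heldout = [ids[i] for i in order[:target]]
        train = [ids[i] for i in order[target:]]
    else:
        pids = sorted({i[0] for i in ids})
        order = rng.permutation(len(pids))
        heldout_pids: set = set()
        count = 0
        for j in order:
            if count >= target:
                break
            heldout_pids.add(pids[j])
            count += sum(1 for i in ids if i[0] == pids[j])
        heldout = [i for i in ids if i[0] in heldout_pids]
        train = [i for i in ids if i[0] not in heldout_pids]
    if not train or not heldout:
        raise ValueError("split left one side empty")
    return train, heldout


# ---------------------------------------------------------------------------
# Models


def fit_ocsvm(X, cfg: ModelConfig = ModelConfig()) -> OneClassSVM:
    """Fit a single one-class SVM on health-period feature rows.

    The returned model's ``decision_function`` is >= 0 for inliers; about a
    ``nu`` fraction of the training rows end up flagged as outliers.
    """
    X = np.asarray(X, dtype=float)
    model = OneClassSVM(
        kernel=cfg.kernel, nu=cfg.nu, gamma=resolve_gamma(cfg.gamma, X.shape[1])
    )
    model.fit(X)
    return model


class EnsembleOneClassSVM(BaseEstimator, OutlierMixin):
    """Bagged one-class SVMs over row and feature subsamples.

    Each member is fit on a seeded subsample of ``row_fraction`` rows
    (without replacement) and ``feature_fraction`` features; prediction is
    by vote: inlier (+1) iff the fraction of members voting inlier strictly
    exceeds ``vote_threshold``, outlier (−1) otherwise (ties included).

    With ``n_members=1`` and both fractions 1.0 the ensemble reduces
    exactly to the single one-class SVM.
    """

    def __init__(
        self,
        kernel: str = "rbf",
        nu: float = 0.1,
        gamma: float | str = "wide",
        n_members: int = 25,
        row_fraction: float = 0.8,
        feature_fraction: float = 0.7,
        vote_threshold: float = 0.5,
        random_state: int = 0,
    ):
        self.kernel = kernel
        self.nu = nu
        self.gamma = gamma
        self.n_members = n_members
        self.row_fraction = row_fraction
        self.feature_fraction = feature_fraction
        self.vote_threshold = vote_threshold
        self.random_state = random_state

    @classmethod
    def from_config(cls, cfg: ModelConfig) -> "EnsembleOneClassSVM":
        e = cfg.ensemble
        return cls(
            kernel=cfg.kernel,
            nu=cfg.nu,
            gamma=cfg.gamma,
            n_members=e.n_members,
            row_fraction=e.row_fraction,
            feature_fraction=e.feature_fraction,
            vote_threshold=e.vote_threshold,
            random_state=e.seed,
        )

    def fit(self, X, y=None):
        EnsembleConfig(
            n_members=self.n_members,
            row_fraction=self.row_fraction,
            feature_fraction=self.feature_fraction,
            vote_threshold=self.vote_threshold,
        )
        X = check_array(X, dtype=float)
        n, p = X.shape
        rng = np.random.default_rng(self.random_state)
        n_rows = max(1, round_half_up(self.row_fraction * n))
        n_feats = max(1, round_half_up(self.feature_fraction * p))
        self.members_ = []
        self.feature_indices_ = []
        self.row_indices_ = []
        for m in range(self.n_members):
            rows = rng.choice(n, size=n_rows, replace=False)
            feats = np.sort(rng.choice(p, size=n_feats, replace=False))
            try:
                model = OneClassSVM(
                    kernel=self.kernel,
                    nu=self.nu,
                    gamma=resolve_gamma(self.gamma, n_feats),
                ).fit(X[np.ix_(rows, feats)])
            except Exception as exc:  # pragma: no cover - member failure
                raise RuntimeError(f"ensemble member {m} failed to train") from exc
            self.members_.append(model)
            self.feature_indices_.append(feats)
            self.row_indices_.append(rows)
        self.n_features_in_ = p
        return self

    def vote_fraction(self, X) -> np.ndarray:
        """Fraction of members voting inlier for each row."""
        check_is_fitted(self, "members_")
        X = check_array(X, dtype=float)
        votes = np.zeros(X.shape[0])
        for model, feats in zip(self.members_, self.feature_indices_):
            votes += (model.predict(X[:, feats]) == 1).astype(float)
        return votes / self.n_members

    def decision_function(self, X) -> np.ndarray:
        """Signed margin of the vote: positive iff predicted inlier."""
        return self.vote_fraction(X) - self.vote_threshold

    def predict(self, X) -> np.ndarray:
        """+1 inlier / −1 outlier; an exact tie votes outlier."""
        return np.where(self.decision_function(X) > 0, 1, -1)

    def fit_predict(self, X, y=None):
        return self.fit(X).predict(X)


def grid_search_ocsvm(
    X,
    nus: Sequence[float] = (0.05, 0.1, 0.2),
    gammas: Sequence[float | str] = ("wide", "scale"),
    val_fraction: float = 0.2,
    seed: int = 0,
    kernel: str = "rbf",
) -> tuple[ModelConfig, float]:
    """Pick (nu, gamma) minimizing |validation rejection − nu|.

    Off by default in the pipeline: the search uses a training-internal
    validation split of inliers only (no relapse periods), and selects the
    configuration whose out-of-sample inlier rejection best matches its own
    nu — i.e. the best-calibrated boundary, not the best test score.
    """
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    n_val = max(1, round_half_up(val_fraction * n))
    order = rng.permutation(n)
    val, fit = order[:n_val], order[n_val:]
    if len(fit) < 2:
        raise ValueError("too few rows for a validation split")
    best: tuple[ModelConfig, float] | None = None
    for nu in nus:
        for gamma in gammas:
            cfg = ModelConfig(kernel=kernel, nu=nu, gamma=gamma)
            model = fit_ocsvm(X[fit], cfg)
            rejection = float((model.predict(X[val]) == -1).mean())
            gap = abs(rejection - nu)
            if best is None or gap < best[1]:
                best = (cfg, gap)
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Evaluation


@dataclass(frozen=True)
class EvalReport:
    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    convention: str = CONVENTION

    @staticmethod
    def from_counts(tp: int, fn: int, tn: int, fp: int) -> "EvalReport":
        def rate(num: int, den: int) -> float | None:
            return num / den if den else None

        return EvalReport(
            tp=tp,
            fn=fn,
            tn=tn,
            fp=fp,
            sensitivity=rate(tp, tp + fn),
            specificity=rate(tn, tn + fp),
            ppv=rate(tp, tp + fp),
            npv=rate(tn, tn + fn),
        )

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fn": self.fn,
            "tn": self.tn,
            "fp": self.fp,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "convention": self.convention,
        }

    def rounded(self, ndigits: int = 2) -> dict:
        out = self.to_dict()
        for k in ("sensitivity", "specificity", "ppv", "npv"):
            if out[k] is not None:
                out[k] = round(out[k], ndigits)
        return out


def _as_inlier_flags(predictions) -> np.ndarray:
    arr = np.asarray(predictions)
    if arr.dtype.kind in "UO":
        return np.asarray([str(v) in ("inlier", "health", "1", "+1") for v in arr])
    return arr == 1


def evaluate(predictions, true_labels) -> EvalReport:
    """Confusion counts and rates under the health=positive convention.

    ``predictions`` are +1/-1 (or 'inlier'/'outlier'); ``true_labels`` are
    'health'/'relapse'.  Undefined ratios are reported as None, never 0.
    """
    labels = np.asarray(true_labels)
    if len(labels) == 0:
        raise ValueError("empty evaluation input")
    inlier = _as_inlier_flags(predictions)
    if len(inlier) != len(labels):
        raise ValueError("predictions and labels differ in length")
    bad = set(labels) - {"health", "relapse"}
    if bad:
        raise ValueError(f"unknown labels {bad}")
    health = labels == "health"
    tp = int((health & inlier).sum())
    fn = int((health & ~inlier).sum())
    tn = int((~health & ~inlier).sum())
    fp = int((~health & inlier).sum())
    return EvalReport.from_counts(tp, fn, tn, fp)


def reconstruct_counts(
    sensitivity: float, specificity: float, n_health: int, n_relapse: int
) -> EvalReport:
    """Rebuild a confusion matrix from printed rates and class sizes.

    ``tp = round_half_up(sensitivity * n_health)`` and
    ``tn = round_half_up(specificity * n_relapse)``; complements give
    fn/fp, and PPV/NPV follow.  Used to audit reported performance tables
    whose underlying counts were not printed.
    """
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("rates must lie in [0, 1]")
    if n_health < 1 or n_relapse < 1:
        raise ValueError("counts must be >= 1")
    tp = round_half_up(sensitivity * n_health)
    tn = round_half_up(specificity * n_relapse)
    return EvalReport.from_counts(tp=tp, fn=n_health - tp, tn=tn, fp=n_relapse - tn)
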