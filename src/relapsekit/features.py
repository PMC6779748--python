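"""Assemble the periods × features matrix; CoV feature selection; scaling.

Feature selection is unsupervised: for each feature the coefficient of
variation ``cov = sd / |mean|`` is computed over training rows, then
features whose cov lies more than ``k_sd`` standard deviations from the
mean cov are eliminated (``eliminate_outside``, the default).  The inverted
rule (``keep_outside``: retain only the dispersed features) is also
provided, since the literal elimination rule retains the bulk of features
rather than a small dispersed subset; both directions are recomputable from
the persisted :class:`CovReport`.

`CoVSelector` and `PeriodScaler` are scikit-learn compatible transformers,
so they drop into ``sklearn.pipeline.Pipeline``; the module-level
`cov_select` / `standardize` functions are thin wrappers over them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from . import lexicon as lx
from .behavior import activity_features
from .segmentation import Period

ELIMINATE_OUTSIDE = "eliminate_outside"
KEEP_OUTSIDE = "keep_outside"


class EmptySelectionError(ValueError):
    """The CoV rule retained no features."""


@dataclass
class FeatureMatrix:
    """Periods × named features, with labels and participant ids.

    ``data`` is indexed by (participant_id, start, end); ``labels`` aligns
    with the rows and takes values 'relapse' / 'health'.
    """

    data: pd.DataFrame
    labels: pd.Series
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate feature names")
        bad = set(self.labels.unique()) - {"relapse", "health"}
        if bad:
            raise ValueError(f"unknown labels {bad}")

    @property
    def X(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def participant_ids(self) -> list[str]:
        return [idx[0] for idx in self.data.index]

    def rows(self, mask) -> "FeatureMatrix":
        return FeatureMatrix(self.data[mask], self.labels[mask], self.provenance)

    def select(self, columns: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(self.data[list(columns)], self.labels, self.provenance)

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# Featurization


def period_features(
    period: Period,
    lexicon: lx.Lexicon,
    vocabulary: Sequence[str] | None = None,
    normalize_rates: bool = True,
) -> dict[str, float]:
    """All features of one period: categories, structure, unigrams, behavior."""
    texts = [e.text for e in period.events if e.text]
    tokens: list[str] = []
    for t in texts:
        tokens.extend(lx.tokenize(t))
    feats: dict[str, float] = {}
    props = lx.category_proportions(tokens, lexicon)
    feats.update({f"liwc__{k}": v for k, v in props.items()})
    readability, repeat, mwl = lx.structural_features(texts)
    feats["struct__readability"] = readability
    feats["struct__repeatability"] = repeat
    feats["struct__mean_word_length"] = mwl
    if vocabulary:
        uni = lx.unigram_features(tokens, vocabulary)
        feats.update({f"unigram__{w}": v for w, v in uni.items()})
    feats.update(activity_features(period, normalize=normalize_rates))
    return feats


def build_matrix(
    periods: Sequence[Period],
    feature_maps: Mapping[tuple, Mapping[str, float]],
) -> FeatureMatrix:
    """Assemble a FeatureMatrix from per-period feature maps.

    Columns are sorted by name, rows by (participant_id, start); a feature
    absent for some period is backfilled with 0.
    """
    ids = [p.row_id for p in periods]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate period ids")
    ordered = sorted(periods, key=lambda p: (p.participant_id, p.start))
    all_cols = sorted({c for m in feature_maps.values() for c in m})
    rows = []
    for p in ordered:
        m = feature_maps[p.row_id]
        rows.append([float(m.get(c, 0.0)) for c in all_cols])
    index = pd.MultiIndex.from_tuples(
        [p.row_id for p in ordered], names=["participant_id", "start", "end"]
    )
    data = pd.DataFrame(rows, index=index, columns=all_cols)
    labels = pd.Series([p.label for p in ordered], index=index, name="label")
    digest = hashlib.sha1(
        json.dumps({"columns": all_cols, "n_rows": len(rows)}).encode()
    ).hexdigest()[:12]
    return FeatureMatrix(data, labels, provenance=digest)


def featurize_periods(
    periods: Sequence[Period],
    lexicon: lx.Lexicon | None = None,
    vocabulary: Sequence[str] | None = None,
    normalize_rates: bool = True,
    drop_excluded: bool = True,
) -> FeatureMatrix:
    """Featurize assigned periods end-to-end into a FeatureMatrix."""
    lexicon = lexicon or lx.builtin_lexicon()
    use = [p for p in periods if not (drop_excluded and p.excluded)]
    maps = {
        p.row_id: period_features(
            p, lexicon, vocabulary=vocabulary, normalize_rates=normalize_rates
        )
        for p in use
    }
    return build_matrix(use, maps)


# ---------------------------------------------------------------------------
# CoV selection


@dataclass
class CovReport:
    cov: pd.Series
    cov_mean: float
    cov_sd: float
    retained: list[str]
    mode: str
    k_sd: float
    zero_mean_columns: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "cov": {k: float(v) for k, v in self.cov.items()},
            "cov_mean": self.cov_mean,
            "cov_sd": self.cov_sd,
            "retained": self.retained,
            "mode": self.mode,
            "k_sd": self.k_sd,
            "zero_mean_columns": self.zero_mean_columns,
        }


def _column_cov(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column cov = sample sd / |mean|; zero-mean columns get cov 0."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero = mean == 0
    cov = np.zeros_like(mean)
    nz = ~zero
    cov[nz] = sd[nz] / np.abs(mean[nz])
    return cov, zero


class CoVSelector(BaseEstimator, TransformerMixin):
    """Coefficient-of-variation feature filter (unsupervised).

    Parameters
    ----------
    k_sd : float, default 1.0
        Band half-width in standard deviations of the cov distribution.
    mode : {'eliminate_outside', 'keep_outside'}, default 'eliminate_outside'
        'eliminate_outside' retains features with |cov - cov_mean| <= k_sd*cov_sd;
        'keep_outside' retains the complement.
    """

    def __init__(self, k_sd: float = 1.0, mode: str = ELIMINATE_OUTSIDE):
        self.k_sd = k_sd
        self.mode = mode

    def fit(self, X, y=None):
        if self.mode not in (ELIMINATE_OUTSIDE, KEEP_OUTSIDE):
            raise ValueError(f"unknown mode {self.mode!r}")
        columns = list(X.columns) if isinstance(X, pd.DataFrame) else None
        X = check_array(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("need >= 2 rows to estimate dispersion")
        cov, zero = _column_cov(X)
        cov_mean = float(cov.mean())
        cov_sd = float(cov.std(ddof=1)) if len(cov) > 1 else 0.0
        inside = np.abs(cov - cov_mean) <= self.k_sd * cov_sd
        support = inside if self.mode == ELIMINATE_OUTSIDE else ~inside
        if not support.any():
            raise EmptySelectionError(
                f"CoV rule ({self.mode}, k_sd={self.k_sd}) retained no features"
            )
        self.n_features_in_ = X.shape[1]
        self.cov_ = cov
        self.cov_mean_ = cov_mean
        self.cov_sd_ = cov_sd
        self.support_ = support
        self.feature_names_in_ = columns
        return self

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_

    def transform(self, X):
        check_is_fitted(self, "support_")
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.support_]
        X = check_array(X, dtype=float)
        return X[:, self.support_]

    def report(self) -> CovReport:
        check_is_fitted(self, "support_")
        names = self.feature_names_in_ or [
            f"x{i}" for i in range(self.n_features_in_)
        ]
        cov = pd.Series(self.cov_, index=names)
        retained = [n for n, keep in zip(names, self.support_) if keep]
        zero_mean = [n for n, z in zip(names, self.cov_ == 0) if z]
        return CovReport(
            cov=cov,
            cov_mean=self.cov_mean_,
            cov_sd=self.cov_sd_,
            retained=retained,
            mode=self.mode,
            k_sd=self.k_sd,
            zero_mean_columns=zero_mean,
        )


def cov_select(
    train: FeatureMatrix, k_sd: float = 1.0, mode: str = ELIMINATE_OUTSIDE
) -> CovReport:
    """Run the CoV filter on a training FeatureMatrix and return the report."""
    sel = CoVSelector(k_sd=k_sd, mode=mode).fit(train.data)
    return sel.report()


# ---------------------------------------------------------------------------
# Standardization


class PeriodScaler(BaseEstimator, TransformerMixin):
    """Column z-scoring with sample (n−1) sd; constant columns map to 0.

    Statistics are learned from the training rows only (conventionally the
    health/inlier training split) and reused verbatim on held-out rows.
    """

    def fit(self, X, y=None):
        columns = list(X.columns) if isinstance(X, pd.DataFrame) else None
        X = check_array(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
        self.scale_ = np.where(sd == 0, 1.0, sd)
        self.zero_sd_ = sd == 0
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = columns
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        frame_index = X.index if isinstance(X, pd.DataFrame) else None
        if isinstance(X, pd.DataFrame) and self.feature_names_in_ is not None:
            missing = set(self.feature_names_in_) - set(X.columns)
            if missing:
                raise KeyError(f"unseen schema: columns missing {sorted(missing)}")
            X = X[self.feature_names_in_]
        Xv = check_array(X, dtype=float)
        if Xv.shape[1] != self.n_features_in_:
            raise KeyError("column count differs from the fitted schema")
        Z = (Xv - self.mean_) / self.scale_
        Z[:, self.zero_sd_] = 0.0
        if frame_index is not None:
            return pd.DataFrame(Z, index=frame_index, columns=self.feature_names_in_)
        return Z

    def inverse_transform(self, Z):
        check_is_fitted(self, "mean_")
        Z = check_array(Z, dtype=float)
        return Z * self.scale_ + self.mean_


def standardize(
    matrix: FeatureMatrix, scaler: PeriodScaler | None = None
) -> tuple[FeatureMatrix, PeriodScaler]:
    """Standardize a FeatureMatrix; fit the scaler if not supplied."""
    if scaler is None:
        scaler = PeriodScaler().fit(matrix.data)
    data = scaler.transform(matrix.data)
    return FeatureMatrix(data, matrix.labels, matrix.provenance), scaler
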