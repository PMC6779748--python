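"""Feature-matrix assembly, CoV selection, and standardization."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from relapsekit.features import (
    CoVSelector,
    EmptySelectionError,
    FeatureMatrix,
    PeriodScaler,
    build_matrix,
    cov_select,
    featurize_periods,
    standardize,
)


def _fm(values, columns, labels=None):
    n = len(values)
    index = pd.MultiIndex.from_tuples(
        [("p1", f"2017-01-{i+1:02d}", f"2017-02-{i+1:02d}") for i in range(n)],
        names=["participant_id", "start", "end"],
    )
    data = pd.DataFrame(values, index=index, columns=columns)
    lab = pd.Series(labels or ["health"] * n, index=index, name="label")
    return FeatureMatrix(data, lab)


class TestBuildMatrix:
    def test_two_by_three(self, small_cohort_periods):
        periods = small_cohort_periods[:2]
        maps = {
            periods[0].row_id: {"a": 1.0, "b": 2.0, "c": 3.0},
            periods[1].row_id: {"a": 4.0, "b": 5.0, "c": 6.0},
        }
        fm = build_matrix(periods, maps)
        assert fm.data.shape == (2, 3)
        assert fm.feature_names == ["a", "b", "c"]

    def test_missing_feature_backfilled_zero(self, small_cohort_periods):
        periods = small_cohort_periods[:2]
        maps = {periods[0].row_id: {"a": 1.0}, periods[1].row_id: {"b": 2.0}}
        fm = build_matrix(periods, maps)
        assert fm.data["a"].tolist() in ([1.0, 0.0], [0.0, 1.0])

    def test_duplicate_ids_rejected(self, small_cohort_periods):
        p = small_cohort_periods[0]
        with pytest.raises(ValueError):
            build_matrix([p, p], {p.row_id: {"a": 1.0}})

    def test_deterministic_across_runs(self, small_cohort_periods):
        a = featurize_periods(small_cohort_periods[:20])
        b = featurize_periods(small_cohort_periods[:20])
        pd.testing.assert_frame_equal(a.data, b.data)


class TestCovSelect:
    def test_constant_positive_column_cov_zero(self):
        fm = _fm([[5.0, 1.0], [5.0, 3.0]], ["const", "var"])
        report = cov_select(fm)
        assert report.cov["const"] == 0.0

    def test_two_value_column_hand_cov(self):
        fm = _fm([[1.0, 0.0], [3.0, 1.0]], ["x", "pad"])
        report = cov_select(fm)
        # mean 2, sample sd sqrt(2) -> cov ~ 0.7071
        assert report.cov["x"] == pytest.approx(np.sqrt(2) / 2, abs=1e-12)

    def test_outlying_cov_eliminated(self):
        # engineer columns with covs ~ {0.10, 0.12, 5.00}
        rng = np.random.default_rng(0)

        def column(target_cov, n=400):
            # N(1, sd) has cov ~ sd for sd << 1; for 5.0 use a lognormal-ish spike
            if target_cov <= 1:
                return rng.normal(1.0, target_cov, n)
            x = np.zeros(n)
            x[: n // 25] = target_cov**2
            x += 1.0
            return x

        X = np.column_stack([column(0.10), column(0.12), column(5.0)])
        fm = _fm(X, ["a", "b", "c"])
        report = cov_select(fm)
        assert "c" not in report.retained
        assert set(report.retained) == {"a", "b"}

    def test_keep_outside_inverts(self):
        fm = _fm([[1.0, 1.0, 0.0], [1.1, 3.0, 100.0], [0.9, 1.0, 0.0]], ["a", "b", "c"])
        keep = cov_select(fm, mode="keep_outside")
        drop = cov_select(fm, mode="eliminate_outside")
        assert set(keep.retained) | set(drop.retained) == {"a", "b", "c"}
        assert not set(keep.retained) & set(drop.retained)

    def test_empty_selection_raises(self):
        fm = _fm([[1.0, 1.0], [1.0, 1.0]], ["a", "b"])
        with pytest.raises(EmptySelectionError):
            cov_select(fm, mode="keep_outside")

    def test_fewer_than_two_rows_rejected(self):
        fm = _fm([[1.0, 2.0]], ["a", "b"])
        with pytest.raises(ValueError):
            cov_select(fm)

    @given(scale=st.floats(min_value=0.01, max_value=1e4),
           seed=st.integers(min_value=0, max_value=100))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_cov_scale_invariance(self, scale, seed):
        """cov(c*x) == cov(x) for c > 0, so selection is scale-invariant."""
        rng = np.random.default_rng(seed)
        X = rng.gamma(2.0, 1.0, size=(30, 5)) + 0.1
        fm1 = _fm(X, list("abcde"))
        fm2 = _fm(X * scale, list("abcde"))
        r1, r2 = cov_select(fm1), cov_select(fm2)
        np.testing.assert_allclose(r1.cov.values, r2.cov.values, rtol=1e-9)
        assert r1.retained == r2.retained

    def test_selection_deterministic(self):
        rng = np.random.default_rng(3)
        X = rng.normal(1, 0.3, size=(50, 8))
        fm = _fm(X, [f"f{i}" for i in range(8)])
        assert cov_select(fm).retained == cov_select(fm).retained


class TestStandardize:
    def test_training_columns_become_standard(self):
        rng = np.random.default_rng(1)
        fm = _fm(rng.normal(3, 2, size=(40, 3)), ["a", "b", "c"])
        z, _ = standardize(fm)
        np.testing.assert_allclose(z.X.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.X.std(axis=0, ddof=1), 1.0, rtol=1e-12)

    def test_constant_column_maps_to_zero(self):
        fm = _fm([[7.0, 1.0], [7.0, 2.0], [7.0, 3.0]], ["const", "x"])
        z, _ = standardize(fm)
        assert (z.data["const"] == 0.0).all()

    def test_test_rows_use_training_stats(self):
        train = _fm([[0.0], [2.0]], ["x"])
        test = _fm([[4.0], [6.0]], ["x"])
        _, scaler = standardize(train)
        z = scaler.transform(test.data)
        # mean 1, sample sd sqrt(2)
        np.testing.assert_allclose(z["x"].values, [3 / np.sqrt(2), 5 / np.sqrt(2)])

    def test_round_trip(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 4))
        fm = _fm(X, list("abcd"))
        z, scaler = standardize(fm)
        back = scaler.inverse_transform(z.X)
        np.testing.assert_allclose(back, X, atol=1e-12)

    def test_unseen_schema_rejected(self):
        train = _fm([[0.0, 1.0], [2.0, 3.0]], ["a", "b"])
        _, scaler = standardize(train)
        with pytest.raises(KeyError):
            scaler.transform(_fm([[1.0]], ["a"]).data)

    def test_streaming_vs_two_pass_agreement(self):
        """Mean/sd via running sums agree with the two-pass computation."""
        rng = np.random.default_rng(5)
        X = rng.normal(50, 10, size=(500, 6))
        n = X.shape[0]
        s1, s2 = X.sum(axis=0), (X**2).sum(axis=0)
        stream_mean = s1 / n
        stream_sd = np.sqrt((s2 - s1**2 / n) / (n - 1))
        scaler = PeriodScaler().fit(X)
        np.testing.assert_allclose(scaler.mean_, stream_mean, atol=1e-9)
        np.testing.assert_allclose(scaler.scale_, stream_sd, atol=1e-9)


class TestSklearnCompat:
    def test_pipeline_composition(self):
        from sklearn.pipeline import Pipeline
        from sklearn.svm import OneClassSVM

        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(1, 0.2, size=(60, 6)), columns=list("abcdef"))
        pipe = Pipeline(
            [
                ("select", CoVSelector()),
                ("scale", PeriodScaler()),
                ("ocsvm", OneClassSVM(nu=0.1)),
            ]
        )
        preds = pipe.fit(X).predict(X)
        assert set(preds) <= {-1, 1}

    def test_get_set_params(self):
        sel = CoVSelector(k_sd=2.0, mode="keep_outside")
        assert sel.get_params() == {"k_sd": 2.0, "mode": "keep_outside"}
        sel.set_params(k_sd=1.0)
        assert sel.k_sd == 1.0
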