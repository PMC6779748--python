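"""Wilcoxon signed-rank implementation against brute-force enumeration."""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata, wilcoxon as scipy_wilcoxon

from relapsekit.features import FeatureMatrix
from relapsekit.screening import (
    PairingError,
    feature_screen,
    sample_pairs,
    wilcoxon_signed_rank,
)


def brute_force_wilcoxon(x, y):
    """Independent oracle: enumerate all 2^n sign assignments."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    ranks = rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in product((0, 1), repeat=n)
    ]
    lower = sum(1 for v in ws if v <= w + 1e-9) / 2**n
    upper = sum(1 for v in ws if v >= w - 1e-9) / 2**n
    return w, min(1.0, 2.0 * min(lower, upper))


class TestWilcoxon:
    def test_all_zero_differences(self):
        stat, p, method = wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert (stat, p, method) == (0.0, 1.0, "exact")

    def test_three_positive_differences(self):
        stat, p, method = wilcoxon_signed_rank([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert stat == 6.0
        assert p == pytest.approx(0.25)  # 2 * P(W+ >= 6) = 2/8
        assert method == "exact"

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0], [1.0, 2.0])

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_enumeration_oracle(self, seed):
        """Exact p equals full sign enumeration, including ties and zeros."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 11))
        x = rng.integers(0, 5, size=n).astype(float)
        y = rng.integers(0, 5, size=n).astype(float)
        stat, p, method = wilcoxon_signed_rank(x, y)
        w_ref, p_ref = brute_force_wilcoxon(x, y)
        assert method == "exact"
        assert stat == pytest.approx(w_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_on_tie_free_data(self, seed):
        rng = np.random.default_rng(100 + seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        stat, p, _ = wilcoxon_signed_rank(x, y)
        ref = scipy_wilcoxon(x, y, alternative="two-sided", method="exact")
        # scipy reports min(W+, W-); recover W+ via the rank-sum identity
        d = x - y
        ranks = rankdata(np.abs(d))
        assert stat == pytest.approx(float(ranks[d > 0].sum()))
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_and_normal_agree_near_cutoff(self):
        """Normal approximation with continuity correction tracks the exact
        tail within 0.01 at the crossover sample size."""
        rng = np.random.default_rng(42)
        for _ in range(10):
            x = rng.normal(0.2, 1.0, size=25)
            y = rng.normal(0.0, 1.0, size=25)
            d = x - y
            d = d[d != 0]
            ranks = rankdata(np.abs(d))
            _, p_exact, _ = wilcoxon_signed_rank(x, y)
            n = len(d)
            w = float(ranks[d > 0].sum())
            mu = n * (n + 1) / 4
            sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24)
            from scipy.stats import norm

            p_norm = min(1.0, 2 * norm.sf((abs(w - mu) - 0.5) / sigma))
            assert abs(p_exact - p_norm) < 0.01


def _matrix_from_values(rows):
    """rows: list of (pid, start, label, {feature: value})."""
    index = pd.MultiIndex.from_tuples(
        [(pid, start, start.replace("01-", "02-")) for pid, start, _, _ in rows],
        names=["participant_id", "start", "end"],
    )
    data = pd.DataFrame([vals for _, _, _, vals in rows], index=index).fillna(0.0)
    labels = pd.Series([lab for _, _, lab, _ in rows], index=index, name="label")
    return FeatureMatrix(data, labels)


class TestSamplePairs:
    def test_forced_unique_pair(self):
        fm = _matrix_from_values(
            [
                ("p1", "2017-01-01", "relapse", {"f": 1.0}),
                ("p1", "2017-01-05", "health", {"f": 0.0}),
            ]
        )
        pairs, excluded = sample_pairs(fm, seed=0)
        assert excluded == 0
        assert pairs == [(("p1", "2017-01-01", "2017-02-01"),
                          ("p1", "2017-01-05", "2017-02-05"))]

    def test_participant_without_health_excluded(self):
        fm = _matrix_from_values(
            [
                ("p1", "2017-01-01", "relapse", {"f": 1.0}),
                ("p2", "2017-01-01", "relapse", {"f": 1.0}),
                ("p2", "2017-01-05", "health", {"f": 0.0}),
            ]
        )
        pairs, excluded = sample_pairs(fm, seed=0)
        assert excluded == 1 and len(pairs) == 1

    def test_no_eligible_participant_raises(self):
        fm = _matrix_from_values([("p1", "2017-01-01", "relapse", {"f": 1.0})])
        with pytest.raises(PairingError):
            sample_pairs(fm, seed=0)

    def test_fixed_seed_reproducible(self, small_cohort):
        from relapsekit import SegmentationConfig, featurize_periods
        from relapsekit.pipeline import segment_cohort

        _, (timelines, hosps, _) = small_cohort
        fm = featurize_periods(segment_cohort(timelines, hosps, SegmentationConfig()))
        assert sample_pairs(fm, seed=5) == sample_pairs(fm, seed=5)


class TestFeatureScreen:
    def test_constant_feature_p_one(self):
        fm = _matrix_from_values(
            [
                ("p1", "2017-01-01", "relapse", {"f": 2.0, "g": 1.0}),
                ("p1", "2017-01-05", "health", {"f": 2.0, "g": 0.0}),
                ("p2", "2017-01-01", "relapse", {"f": 2.0, "g": 1.0}),
                ("p2", "2017-01-05", "health", {"f": 2.0, "g": 0.0}),
            ]
        )
        pairs, _ = sample_pairs(fm, seed=0)
        table = feature_screen(fm, pairs).set_index("feature")
        assert table.loc["f", "p_value"] == 1.0
        assert table.loc["f", "mean_relapse"] == table.loc["f", "mean_health"]

    def test_identical_features_identical_rows(self):
        fm = _matrix_from_values(
            [
                ("p1", "2017-01-01", "relapse", {"a": 3.0, "b": 3.0}),
                ("p1", "2017-01-05", "health", {"a": 1.0, "b": 1.0}),
                ("p2", "2017-01-01", "relapse", {"a": 2.0, "b": 2.0}),
                ("p2", "2017-01-05", "health", {"a": 0.5, "b": 0.5}),
            ]
        )
        pairs, _ = sample_pairs(fm, seed=0)
        table = feature_screen(fm, pairs).set_index("feature")
        cols = ["n_pairs", "mean_relapse", "mean_health", "statistic", "p_value"]
        assert table.loc["a", cols].tolist() == table.loc["b", cols].tolist()

    def test_direction_consistency(self, small_cohort):
        """Features with tiny p under elevated relapse means point upward."""
        from relapsekit import SegmentationConfig, featurize_periods
        from relapsekit.pipeline import segment_cohort

        _, (timelines, hosps, _) = small_cohort
        fm = featurize_periods(segment_cohort(timelines, hosps, SegmentationConfig()))
        pairs, _ = sample_pairs(fm, seed=2)
        table = feature_screen(fm, pairs, add_bh=True)
        assert (table["p_value"] <= table["q_value"] + 1e-12).all()
        assert table["p_value"].is_monotonic_increasing
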