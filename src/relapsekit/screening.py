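"""Exploratory cohort screen: paired Wilcoxon signed-rank tests per feature.

For each participant, one relapse period and one health period are drawn
uniformly at random (seeded), giving one matched pair per participant.
Each feature is then compared across pairs with a two-sided Wilcoxon
signed-rank test: zero differences are discarded (classic convention),
tied absolute differences receive mid-ranks, and the statistic is
W+ = sum of ranks of positive differences.

The exact two-sided p-value is used whenever the effective sample size is
at most 25; it is computed from the null distribution of W+ over all 2^n
equiprobable sign assignments (via a convolution over doubled mid-ranks,
which is exact even with ties).  Larger samples use the normal
approximation with tie correction and continuity correction.

p-values are reported raw by default; Benjamini–Hochberg q-values are
available as an extra column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

from .features import FeatureMatrix

EXACT_N_MAX = 25


class PairingError(ValueError):
    pass


@dataclass(frozen=True)
class WilcoxonResult:
    feature: str
    n_pairs: int
    statistic: float
    p_value: float
    mean_relapse: float
    mean_health: float
    method: str


def _exact_two_sided_p(doubled_ranks: np.ndarray, doubled_w: int) -> float:
    """P(2·min(tail)) of W+ over all sign assignments, by convolution.

    ``doubled_ranks`` are 2× the mid-ranks (integers even with ties), so the
    distribution of 2·W+ is an integer-supported convolution; equivalent to
    enumerating the 2^n sign assignments.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    lower = counts[: doubled_w + 1].sum()
    upper = counts[doubled_w:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_signed_rank(x, y) -> tuple[float, float, str]:
    """Two-sided paired Wilcoxon signed-rank test.

    Returns ``(W+, p_value, method)`` with method 'exact' or 'normal_approx'.
    All-zero differences give ``(0.0, 1.0, 'exact')``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if x.size == 0:
        raise ValueError("need at least one pair")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return (0.0, 1.0, "exact")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_N_MAX:
        doubled = np.rint(2 * ranks).astype(int)
        doubled_w = int(round(2 * w_plus))
        return (w_plus, _exact_two_sided_p(doubled, doubled_w), "exact")
    mu = n * (n + 1) / 4.0
    # tie correction on the variance
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if sigma2 <= 0:
        return (w_plus, 1.0, "normal_approx")
    z = (abs(w_plus - mu) - 0.5) / np.sqrt(sigma2)
    p = float(min(1.0, 2.0 * norm.sf(z)))
    return (w_plus, p, "normal_approx")


def sample_pairs(
    matrix: FeatureMatrix, seed: int
) -> tuple[list[tuple[tuple, tuple]], int]:
    """One (relapse, health) period pair per eligible participant.

    Participants lacking either label are excluded and counted.  Returns
    ``(pairs, n_excluded)`` where each pair holds two row-index tuples.
    """
    rng = np.random.default_rng(seed)
    labels = matrix.labels
    pairs: list[tuple[tuple, tuple]] = []
    excluded = 0
    participants = sorted({idx[0] for idx in matrix.data.index})
    for pid in participants:
        rows = [idx for idx in matrix.data.index if idx[0] == pid]
        rel = [r for r in rows if labels[r] == "relapse"]
        health = [r for r in rows if labels[r] == "health"]
        if not rel or not health:
            excluded += 1
            continue
        pairs.append(
            (rel[rng.integers(len(rel))], health[rng.integers(len(health))])
        )
    if not pairs:
        raise PairingError("no participant has both a relapse and a health period")
    return pairs, excluded


def feature_screen(
    matrix: FeatureMatrix,
    pairs: list[tuple[tuple, tuple]],
    add_bh: bool = False,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Paired Wilcoxon test per feature over the sampled pairs.

    Output columns: feature, n_pairs, mean_relapse, mean_health, statistic,
    p_value, method (plus q_value when ``add_bh``); sorted by p ascending,
    ties by feature name for determinism.
    """
    rel_rows = [p[0] for p in pairs]
    health_rows = [p[1] for p in pairs]
    cols = features if features is not None else matrix.feature_names
    X_rel = matrix.data.loc[rel_rows, cols].to_numpy(dtype=float)
    X_health = matrix.data.loc[health_rows, cols].to_numpy(dtype=float)
    records = []
    for j, name in enumerate(cols):
        stat, p, method = wilcoxon_signed_rank(X_rel[:, j], X_health[:, j])
        records.append(
            {
                "feature": name,
                "n_pairs": len(pairs),
                "mean_relapse": float(X_rel[:, j].mean()),
                "mean_health": float(X_health[:, j].mean()),
                "statistic": stat,
                "p_value": p,
                "method": method,
            }
        )
    table = pd.DataFrame.from_records(records)
    if add_bh:
        table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
    table = table.sort_values(
        ["p_value", "feature"], kind="mergesort"
    ).reset_index(drop=True)
    return table
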