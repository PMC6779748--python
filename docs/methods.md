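# Methods

## Segmentation model

A participant's analyzable time is the half-open interval from their
first hospitalization admit date to their most recent relapse admit date.
Hospitalizations after the first are relapse events; a participant with a
single hospitalization has no relapse and is excluded. Every period is a
half-open date interval `[start, end)`.

**Relapse periods.** `[admit − 30 d, admit)` for each non-index
admission. A window is clipped so it never starts before the previous
hospitalization's discharge (a patient still in hospital cannot generate
pre-relapse social-media signal), and dropped if it becomes empty.
"1 month" is fixed at 30 days: calendar months vary in length, and
fixed-length periods keep count-based features comparable.

**Health periods.** Study window minus relapse windows minus (by
default) inpatient stays decomposes into maximal runs; each run is tiled
left-to-right with `[t, t + g)` periods for granularity g ∈ {30, 60, 90}
days, and a trailing remainder shorter than g is dropped rather than
merged — merging would create variable-length periods. Whether health
time between a relapse window's start and the previous discharge should
count at all is genuinely open; the clipping rule above is this
package's documented choice. A missing discharge date is imputed as
admit + 13 days (the cohort's median inpatient stay) and flagged;
clipping always uses the effective (possibly imputed) discharge.

**Assignment.** An event belongs to the unique period containing its
date (half-open test). Periods with fewer than `min_posts_per_period`
events (default 1) are flagged excluded but retained for audit.

## Features

All timestamps are participant-local wall-clock times, never converted
across timezones — the diurnal bins (morning [05:00, 12:00), noon
[12:00, 17:00), night [17:00, 22:00), midnight [22:00, 05:00)) only make
sense in local time. Only the morning and midnight boundaries are
clinically anchored (early-morning and after-midnight activity); noon
and night are chosen to complete the partition.

Activity rates are `count × 30 / period_length_days` per event kind,
overall and per bin, so 60- and 90-day health periods remain comparable
with 30-day relapse windows; otherwise a classifier could learn period
length instead of behavior. Co-tagging counts explicit co-tag events
plus statuses/photos carrying tags. Normalization is a default-on
option (`normalize_rates`).

Psycholinguistic categories are proportions of period tokens matching a
category's word list; entries are literal words or prefix patterns
(`hate*`). A token may match several categories. Tokens are lowercase
maximal runs of letters/digits/apostrophes, with URLs and @-handles
removed. Pronoun/tense categories are closed-class word lists, not a POS
tagger — the same mechanism dictionary-based schemes use. The bundled
mini-lexicon (36 categories, ~10–30 entries each) is an open stand-in
for the proprietary full dictionary; any dictionary in the same format
can be substituted. Per-period text is pooled before computing
proportions (the per-post-then-average alternative is not implemented).

Structural measures: Flesch Reading Ease
(`206.835 − 1.015·W/S − 84.6·Syl/W`) with a vowel-group syllable
heuristic (silent final e handled, minimum one syllable); repeatability
`1 − distinct/total` tokens; mean word length in characters. Word usage
is top-k unigram proportions (default k = 200) over a vocabulary built
from training-split text only; bigrams are available behind a flag
(`ngram=2`) but unigrams are the default reading of "word usage".

## Feature selection and scaling

For each feature, `cov = sample sd / |mean|` over training rows
(zero-mean columns get cov 0 and a warning). The default rule
(`eliminate_outside`) retains features with
`|cov_f − mean(cov)| ≤ k·sd(cov)`, k = 1. Taken literally this keeps
the *bulk* of features rather than a small dispersed subset, so it
cannot by itself produce a ~13% retention rate; the inverted rule
(`keep_outside`) is provided, and both decisions are recomputable from
the persisted CoV report. Selection and the z-scoring statistics
(sample sd; constant columns map to 0) are computed on training inliers
only and reused on held-out rows.

## Wilcoxon screen

One relapse and one health period are drawn uniformly per participant
with a seeded generator (participants lacking either label are excluded
and counted). Per feature, the paired two-sided Wilcoxon signed-rank
test: zero differences discarded (classic convention; Pratt's treatment
is not used), mid-ranks for ties, statistic W⁺ = sum of ranks of
positive differences. For effective n ≤ 25 the p-value is exact,
computed from the null distribution of W⁺ by convolution over doubled
mid-ranks — arithmetically identical to enumerating all 2ⁿ sign
assignments, which serves as the independent oracle in the tests. For
larger n, normal approximation with tie-corrected variance and 0.5
continuity correction. p-values are reported raw (matching the original
analysis); Benjamini–Hochberg q-values are an optional column.

## One-class models

The single model is a ν-SVM with RBF kernel trained on health periods
only. ν (default 0.1) upper-bounds the training inlier-rejection
fraction. The default kernel bandwidth is the package's "wide" rule
γ = 1/(16·d): the common two-class heuristic γ = 1/(d·Var) produces a
boundary tight enough to overfit one-class training sets of a few
hundred periods — a large support-vector fraction and held-out inlier
rejection far above ν — whereas the wider kernel restores ν's semantics
out of sample. A small grid search over (ν, γ) on a training-internal
split is available but off by default for reproducibility.

The ensemble bags 25 members, each fit on a seeded subsample of 80% of
rows (without replacement) and 70% of features; a point is an inlier
only if the inlier-vote fraction strictly exceeds 0.5, so an exact tie
is flagged as an outlier. The tie rule deliberately favors flagging
relapse, consistent with prioritizing specificity (catching relapse)
over sensitivity. These ensemble hyperparameters are this package's
own reconstruction of an ensemble whose exact configuration was not
published.

Splits are seeded; held-out size is `round-half-up((1 − f)·n)` with
f = 0.9, reproducing held-out counts of 72/42/31 from 719/421/312
health periods. Default grouping is by period (a participant's periods
may fall on both sides, as the original counts imply);
participant-level grouping is available to measure the leakage effect.
Evaluation uses health = positive (inlier): tp = health predicted
inlier, fn = health predicted outlier, tn = relapse predicted outlier,
fp = relapse predicted inlier; undefined ratios are reported as null,
never 0. `reconstruct_counts` rebuilds a confusion matrix from printed
rates and class sizes with the same round-half-up convention.

## Synthetic cohort generator

The generator emulates the data-generating structure the analysis
assumes, not real language: per participant, 2–4 hospitalizations with
admit dates spaced Uniform(90, 300) days (multiple gaps per follow-up,
so all three health granularities are exercised), 13-day inpatient
stays, and per-kind Poisson event streams at `base_post_rate` = 2
events/day total, thinned over the diurnal bins. Post text is drawn
token-by-token (length 1 + Poisson(8)) from category word lists at the
per-token emission probabilities observed in the study cohort's healthy
periods, with the remainder from a 200-word neutral filler vocabulary
verified to match no category. Inside each 30-day pre-relapse window,
category probabilities, co-tag/friending rates, and the midnight
diurnal weight are multiplied by configurable effect sizes; the default
multipliers are the relapse/health mean ratios from the study cohort's
screen (multiplicative effects are the simplest monotone,
direction-faithful encoding). Probabilities are renormalized only if
category mass would exceed 1, so the filler mass absorbs small shifts.

What the generator does **not** emulate: natural-language syntax and
semantics, participant-level heterogeneity in base rates, comment
threads and network structure, archive dialect quirks, non-English
text, and gradual symptom escalation (effects switch on at the window
boundary). Passing tests therefore demonstrate the pipeline's
statistical machinery — calibration, recovery of planted structure,
leakage-safety — not clinical validity on real patients.

Every cohort carries a truth log (hospitalization dates, planted window
intervals, realized counts, multipliers) used by recovery tests, and a
fixed seed reproduces a cohort byte-for-byte.

## Problem sizes in the test suite

Stochastic suites run on cohorts sized for desk-scale runtime, chosen
once: null calibration uses 20 cohorts of 30 participants × 720 days;
screen-based effect recovery uses 20 cohorts of 60 participants
(planted ×3 on swear/anger/co-tagging); specificity monotonicity uses
20 participants × 540 days across multipliers {1, 2, 3, 5} × 20 seeds;
segmentation invariants use 50 cohorts of 3 participants. The
acceptance script's pipeline run uses the full default conditions
(51 participants × 720 days).

## Known limitations

* The canonical archive schema is defined by this project; real export
  formats vary by platform and vintage and need adaptation at ingest.
* The readability/repeatability/unigram definitions are this package's
  documented choices where the original analysis left details
  unspecified.
* With the literal `eliminate_outside` CoV rule, the retained feature
  count is data-dependent and typically large; no claim is made about
  reproducing a specific retained-feature count.
* An empty timeline written to JSONL carries no participant id to
  recover on read (the header stores only the schema version).
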