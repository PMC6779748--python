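# relapsekit

Anomaly-detection pipeline for identifying periods of psychiatric relapse
from timestamped social-media activity.

## The problem

In first-episode psychosis, most patients achieve remission but the
majority relapse within a few years, and each relapse carries real harm.
Early warning signs — irritability, social withdrawal, sleep disruption,
perceptual disturbances — often surface weeks before a hospitalization,
but detecting them requires frequent contact with clinicians. Routine
social-media activity is a continuously generated behavioral record:
what people write, when they post, whom they tag. `relapsekit`
implements an end-to-end analysis that asks whether the month before a
relapse hospitalization looks measurably different from periods of
relative health, and whether that difference supports prospective
prediction.

The pipeline targets clinical research teams who hold (with consent)
participant social-media archives and hospitalization dates from medical
records. Because such data cannot be shared, the package also ships a
synthetic cohort generator that emulates the assumed statistical
structure, so every stage is testable and demonstrable without any
patient data.

## Method

1. **Segmentation.** For each participant, the study window runs from the
   first hospitalization admit date to the most recent relapse admit
   date. The 30 days before each subsequent admission form a *relapse*
   period; remaining time (minus inpatient stays) is tiled into
   fixed-length *health* periods of 30, 60 or 90 days.
2. **Features.** Per period: LIWC-style psycholinguistic category
   proportions (swear, anger, death, pronouns, work, friends, health, …)
   from a dictionary with prefix wildcards; structural text measures
   (Flesch Reading Ease, word repeatability `1 − distinct/total`, mean
   word length); top-k unigram proportions from a training-defined
   vocabulary; and per-kind activity rates (posting, co-tagging,
   friending, check-ins, likes, shares, photos, app use), overall and by
   diurnal bin (morning 05–12, noon 12–17, night 17–22, midnight 22–05),
   normalized per 30 days.
3. **Feature selection.** Unsupervised filtering by the coefficient of
   variation `cov_f = σ_f / |μ_f|`: features whose cov lies more than one
   standard deviation from the mean cov are eliminated.
4. **Exploratory screen.** One randomly sampled relapse/health period
   pair per participant, compared per feature with the two-sided Wilcoxon
   signed-rank test (exact null distribution up to n = 25 effective
   pairs, normal approximation with tie and continuity corrections
   beyond).
5. **One-class classification.** A ν-SVM (RBF kernel) is trained on
   health periods only (inliers = positive class) and must flag unseen
   relapse periods as outliers. A bagged ensemble fits 25 members on row
   and feature subsamples and votes, with ties flagged as outliers —
   deliberately favoring relapse detection. Under the
   health-as-positive convention, *sensitivity* = recognized health
   periods, *specificity* = caught relapse periods; evaluation reports
   the full confusion matrix with PPV/NPV.

## Worked example

```python
from relapsekit import SyntheticConfig, SplitSpec, generate_cohort, featurize_periods
from relapsekit.pipeline import run_experiment, segment_cohort
from relapsekit.screening import sample_pairs, feature_screen
from relapsekit.segmentation import SegmentationConfig

cfg = SyntheticConfig(n_participants=20, followup_days=720, seed=7)
timelines, hosps, truth = generate_cohort(cfg)
periods = segment_cohort(timelines, hosps, SegmentationConfig())

fm = featurize_periods(periods)
pairs, _ = sample_pairs(fm, seed=7)
print(feature_screen(fm, pairs).head(5).to_string(index=False))

res = run_experiment(timelines, hosps, split=SplitSpec(seed=7),
                     use_ensemble=True, unigram_k=None)
print(res.report.rounded())
```

Output (20 participants, 16,280 events; 43 relapse and 185 health
periods):

```
        feature  mean_relapse  mean_health  statistic  p_value
   liwc__health      0.001727     0.008416        0.0 0.000002
liwc__causation      0.003452     0.012762        0.0 0.000004
     liwc__work      0.006927     0.017314        5.0 0.000019
share__midnight      2.000000     0.500000      136.0 0.000031
co_tag__overall      4.500000     1.650000      183.0 0.000088
{'tp': 17, 'fn': 1, 'tn': 35, 'fp': 8, 'sensitivity': 0.94,
 'specificity': 0.81, 'ppv': 0.68, 'npv': 0.97,
 'convention': 'health=positive(inlier), relapse=negative(outlier)'}
```

The screen surfaces the planted structure: health/work/causation word
usage drops before a relapse hospitalization, while co-tagging and
late-night activity rise. The ensemble, trained only on health periods,
catches 35 of 43 unseen relapse windows (specificity 0.81) while
accepting 17 of 18 held-out health windows (sensitivity 0.94).

A CLI mirrors the stages (`relapsekit simulate / ingest / segment /
featurize / stats / train / evaluate`); see `relapsekit --help`.

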