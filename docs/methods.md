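# Methods

## The zone estimator

For one participant and one CSAI-2 subscale, the optimal band is
`[M − SD/2, M + SD/2]`, with

* `M` — the mean subscale intensity over the recalled occasion(s) that
  attain the participant's maximum performance score. All occasions tied
  at the maximum contribute (`best_rule="all-tied-best"`); variants
  `top1`, `topk:K` and `quantile:Q` are available because "personal best"
  is ambiguous when scores tie. `top1` breaks ties by input order.
* `SD` — the standard deviation of the subscale over **all** recalled
  occasions. The default is the population convention (÷n): the recalled
  occasions are the participant's fixed measurement design, not a sample
  from which a variance is generalised. `sd_convention="sample"` switches
  to ÷(n−1).

Zone bounds are inclusive on both ends, which makes the equivalence
`classify(x, z) == "in"  ⇔  zone_distance(x, z) == 0` exact. Bounds are
carried at full precision internally and rounded to 1 decimal only on
reporting paths.

When the second phase re-estimates zones before the upcoming jury, it
re-uses all phase-1 recalled occasions; the design gives no additional
occasions to fold in.

## Phase-1 validity metrics

* **Outstanding threshold** — pooled mean + 1 SD of all recalled scores.
  The comparison is `score ≥ threshold`, so a performance exactly at the
  bar counts as outstanding (with integer jury scores, a strict `>`
  would silently demote scores exactly at the reported bar). The reported
  threshold is rounded to the nearest integer (92.45 → 92); the raw value
  is retained, and `floor`/`none` rounding is available.
* **D statistic** — mean in-zone score − mean out-of-zone score per
  participant and subscale; undefined (NaN, not zero) when either side is
  empty, and undefined values are excluded from cohort averages.
* **Correct classification** — per participant, the percentage of
  occasions where outstanding ↔ in-zone agree. Cohort summaries weight
  participants equally (unweighted mean of per-participant percentages).
* Cohort descriptive SDs (the descriptive and classification tables) use
  the sample convention (÷(n−1)), matching what standard statistical
  software prints for descriptives; within-person zone SDs are the
  population convention as above. A single-participant cohort reports its
  across-participant SD as 0.

## Phase-2 prediction

Below and above both collapse to "Out" for the 8-pattern combination
table (membership patterns are binary); the full below/in/above trichotomy
is retained in a separate tally. The table's subscale column order is
(SA, CA, SC) and the row order runs from all-In to all-Out.

Spearman ρ is the Pearson correlation of midranks (ties get average
ranks), computed via `scipy.stats.spearmanr`; the p-value uses the
t-approximation with n−2 degrees of freedom, appropriate at the cohort
sizes this design produces (n ≈ 30). For very small panels an exact
permutation p-value (n ≤ 10, full enumeration) is available. A constant
input vector leaves ρ undefined (NaN), never coerced to 0.

## The synthetic-cohort generator

Per participant, a latent optimal triplet `mu` is drawn from per-subscale
normal distributions with cohort means (CA 18.0, SA 17.3, SC 20.9) and
SDs (4.9, 4.8, 5.5) on the 9–36 instrument scale, clipped to the scale;
the true band is `mu ± true_zone_halfwidth`. Each occasion's reported
intensity is `round(clip(mu + N(0, state_sd)))` — the instrument is
integer-valued, the latent optimum is not. Performance declines linearly
with the mean distance of the three intensities from their true bands:

```
score* = base_score − penalty_beta · mean_s d(x_s, band_s) + N(0, score_noise_sd)
```

clipped to [1, 100]; each of `n_judges` judges reports
`round(clip(score* + N(0, judge_noise_sd)))` and the recorded score is the
trimmed panel aggregate, exactly as in the analysis path.

Defaults: 30 participants × (4 recalled + 1 predicted) occasions,
`state_sd = 2.6` (≈ twice the cohort-mean half-width the design implies;
within-person variance is otherwise unreported), `true_zone_halfwidth =
1.3 = state_sd/2` so that M ± ½SD is a *consistent* estimator of the true
band under the model — parameter recovery then tests the estimator, not a
misspecified target — `base_score = 93`, `penalty_beta = 2.0` score units
per distance unit, `score_noise_sd = 1.0`, 7 judges with
`judge_noise_sd = 2.0`. Subscales are independent by default; a 3×3
correlation-matrix hook exists but defaults to identity, as no
cross-subscale correlation structure is reported for the population the
defaults emulate.

What the generator does **not** emulate: item-level (27-question)
response processes, reverse-keyed items, systematic judge leniency or
rater drift, within-year learning trends, score ceilings from repertoire
difficulty, or recall bias in the retrospective occasions. Passing tests
therefore show that the pipeline recovers the structure *this model*
assumes; they cannot certify behaviour under violations of it.

## Calibration checks and problem sizes

* **Parameter recovery** — 20 seeds × 500 participants at the defaults:
  estimated zone-center cohort means land within ±0.5 of the calibration
  anchors, and the center MAE shrinks when `n_recalled` grows from 4
  to 32. Sizes chosen to keep Monte-Carlo error well below the ±0.5
  margin while the full suite stays fast.
* **Sign calibration** — the direction-of-effect check computes the
  phase-2 rank correlations against the generator's *true* zones: with
  `penalty_beta > 0` the per-subscale ρ is negative in ≥95 of 100 seeded
  30-participant runs, and with `penalty_beta = 0` the ρ≠0 test at
  α = 0.05 rejects at the nominal rate. True zones are used deliberately:
  this isolates the generator/correlation machinery's calibration from
  estimator attenuation. With zones estimated from only 4 recalled
  occasions, attenuation lowers the single-cohort negative-sign rate
  (to roughly 78–93% per subscale at these settings) — that attenuation
  is a property of the small fixed design, quantified separately by the
  recovery check, not a sign-calibration failure.

## Numerical and degenerate-input choices

* Trimming ties in judge panels removes exactly one instance of the
  maximum and one of the minimum (sort, drop one per end); a panel of
  N < 3 is an error.
* A zero-variance subscale yields a degenerate zone `[M, M]`, which still
  classifies `M` itself as in-zone.
* Missing values anywhere in the cohort file are rejected; no imputation.
* If both an aggregate score column and judge columns are present, the
  judge columns win and a discrepancy > 0.5 points warns (never errors);
  rows whose judge cells are all empty fall back to the score column.
* All simulation randomness flows from one `numpy` `default_rng` seed;
  identical seed and configuration give bit-identical cohorts and
  byte-identical report files.

## Limitations

The estimator inherits the design's weaknesses: with only 4 recalled
occasions the zone half-width is estimated from 4 points and the
personal-best mean from 1–2, so individual zones are noisy (center MAE
≈ 1.4 scale units at the default noise level). The combination table's
per-pattern statistics are unstable for patterns with n ≤ 2. The
t-approximation p-value is approximate under heavy ties at small n — use
the exact option there.
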