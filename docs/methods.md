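# Methods

## The scoring problem

A Concealed Information Test (CIT) question presents `n_items` items (one
crime-relevant, the rest matched irrelevant foils) in randomized order,
`n_reps` times each, while autonomic responses are recorded. The analysis
unit is one scalar response per (measure, item, repetition) cell — raw-signal
preprocessing (ECG to heart rate, pulse-wave to normalized pulse volume,
respiration line length extraction) happens upstream and is out of scope.
Four measures are supported by default with fixed response-direction
conventions: SCR (+1: larger to a recognized item), HR, RLL, NPV (−1:
smaller). Custom measures can be declared with a direction in the session
file; directions are data, not code.

The package answers two field questions. *Known-solution*: does the examinee
recognize the designated relevant item? *Searching*: does the examinee
recognize any item, and which? Both are answered with two deliberately
simple statistics that need no normative database and can be explained in
court: a standardized mean difference and a randomization-test p-value.

## Effect size d

Per measure, with `n1 = n_reps` relevant responses and
`n2 = n_reps * (n_items − 1)` irrelevant responses,

    s_p = sqrt( ((n1−1)·s1² + (n2−1)·s2²) / (n1 + n2 − 2) )
    d   = direction · (mean_rel − mean_irr) / s_p

with unbiased (n−1) variances, taken literally. No within-session
standardization is applied before the formula, and no alternative
standardizer (Glass's Δ, irrelevant-only SD) is offered. `s_p = 0` (all
responses identical) raises an explicit degenerate-data error rather than
returning ±∞ or 0; cohort pipelines count such sessions as inconclusive.
`n1 ≥ 2` is enforced, so single-repetition sessions cannot be scored with d
(Lykken scoring still works). Integration across measures is the unweighted
mean of the available per-measure d values; absent measures are skipped.

Note that the pooled-SD estimator is biased upward in small samples: under
normality E[d̂] = δ · sqrt(m/2)·Γ((m−1)/2)/Γ(m/2) with m = n1+n2−2, which is
1.0342 at the standard 5×5 design (m = 23). The parameter-recovery test and
the acceptance script check the simulator + estimator pipeline against this
closed form; no bias correction is applied to d itself, matching field use.

## Randomization test

Per measure, the observed statistic is mean(relevant) − mean(irrelevant).
Each of B relabelings (default B = 1,000, configurable) draws a uniformly
random subset of `n_reps` of the `n_items·n_reps` cells as pseudo-relevant;
only the partition matters for a mean difference, so unordered subsets are
sampled rather than permutations. The real difference is ranked among the B
generated differences in the measure's expected direction (largest-first for
SCR, smallest-first for HR/RLL/NPV), and p = x/B.

Tie and edge rules (Monte-Carlo mode): `x = 1 + #{generated more extreme
than or tied with the real difference}`. Consequences: a real difference
beyond every generated one yields p = 1/B, never 0; fully tied (constant)
data yield p = 1; on continuous data the rule reproduces "ranking 50th of
1,000 gives p = 0.05" exactly. Counting ties as extreme is the conservative
standard for sampled permutation tests.

When the labeling space C(n_items·n_reps, n_reps) has at most 10,000
subsets (configurable cap), exhaustive enumeration replaces sampling. The
true labeling is then itself one of the enumerated subsets, so the
self-inclusive count is used without the +1 — the exact permutation p.

### Integration across measures

The per-measure p-values are multiplied; the product is then calibrated
against its own permutation null rather than against Fisher's chi-square
reference, which would be wrong under cross-measure correlation. Each
relabeling b is assigned a per-measure pseudo-p: the self-inclusive
directional rank of its generated difference among all B (most extreme =
rank 1; ranking among all B rather than the other B−1 changes p by at most
1/B). Pseudo-p's are multiplied across measures, giving B generated
products; the integrated p is the rank of the original product among them,
divided by B, with the same tie rules. Missing measures are skipped in both
the original and generated products.

The *same* B relabelings are applied to every measure. This preserves the
within-repetition cross-measure dependence in the null distribution of the
product, which is what makes the calibration valid for correlated measures.
Internally the product comparison uses integer rank products (exact under
ties), falling back to floats only if `B^n_measures` would overflow int64.

Numerical notes: the real difference is computed through the same
arithmetic path as the generated differences, so in exhaustive mode the
true labeling ties with itself bit-exactly; all p-values are clipped to
[1/B, 1]; results are reproducible from (session, B, seed).

## Lykken scoring

Within each repetition block, responses are direction-adjusted
(multiplied by the measure sign); the relevant item scores 2 if strictly
largest, 1 if second largest, 0 otherwise; blocks are summed (range
[0, 2·n_reps]) and measures averaged. Under item exchangeability the
expected block score is 3/n_items (0.6 for five items). Ties — rare for
real-valued data — are resolved by placing the relevant item uniformly at
random within its tie block under a seeded generator. No decision
thresholds are attached to Lykken scores: the method necessarily awards
points in every block even without any salient response, and it is included
as a comparator only.

## Decision thresholds

Shipped presets (recognized cutoff / unrecognized cutoff):

| mode | statistic | strict | lenient |
|---|---|---|---|
| known-solution | d | > 0.4 / < 0 | > 0.3 / < 0.1 |
| known-solution | p | < 0.025 / > 0.6 | < 0.05 / > 0.4 |
| searching | d (max) | > 0.6 / < 0.2 | — |
| searching | p (min) | < 0.01 / > 0.2 | — |

Values exactly at a cutoff are judged *inconclusive*: the published bands
use strict inequalities on both sides, leaving boundaries undefined, and
inconclusive is the conservative assignment (boundaries are measure-zero
for continuous scores). No lenient searching preset exists, so none is
shipped. In searching mode the per-item p-values are not
multiplicity-corrected; family-wise error is controlled by the stricter
searching thresholds (0.01 vs 0.025), mirroring field practice. An optional
conjunctive mode labels a session recognized (or unrecognized) only when
the d and p rules agree, and inconclusive otherwise. Judgments of multiple
CIT questions are not combined into a verdict.

## Synthetic cohorts

The simulator emulates the structure of the laboratory mock-crime cohort
used to develop the thresholds: 80 recognizing + 72 unrecognizing
examinees, 5 items × 5 repetitions, four measures, ~25% electrodermal
non-responders. Defaults:

| parameter | default | meaning |
|---|---|---|
| n_recognizing / n_unrecognizing | 80 / 72 | cohort split |
| n_items × n_reps | 5 × 5 | design |
| effect_sizes | SCR 1.10, HR 0.50, RLL 0.50, NPV 0.40 | shift of relevant-item cell means, in noise-SD units, applied in each measure's direction |
| rho | 0.3 | pairwise cross-measure noise correlation (equicorrelated Gaussian; the real dataset's correlations are unpublished, so this is an exposed assumption) |
| habituation | 0.0 | geometric decay of the shift, (1−h)^(rep−1), motivated by reactivity declining over the test |
| nonresponder_prob / mode | 0.25 / drop | SCR dropped entirely (or replaced by effect-free noise with mode "noise") |
| noise_sd | 1.0 | baseline Gaussian noise SD, equal across items |

Baseline responses are zero-mean Gaussian noise, equal variance across
items — the simplest model consistent with scalar per-presentation
responses. The default effect sizes were calibrated once, by simulation, so
that the integrated-d AUC on the default cohort lands near 0.92, the
discrimination level reported for the real laboratory dataset; this is a
tuning target for realism of *difficulty*, not a claim of distributional
fidelity. With these defaults the cohort AUCs computed by
`scripts/acceptance.py` come out near 0.91 (integrated d), 0.90
(integrated p) and 0.87 (Lykken).

What the generator does **not** model: non-Gaussian and heteroskedastic
response distributions, between-subject reactivity differences beyond the
binary non-responder, serial dependence across presentations other than
geometric habituation, countermeasures, and item-salience confounds.
Passing tests therefore demonstrate correctness of the statistics and
calibration under exchangeable Gaussian nulls, not field validity of the
thresholds — the published hit/correct-rejection/inconclusive percentages
belong to the real 152-examinee dataset, which is not publicly deposited,
and are deliberately not reproduction targets.

## Evaluation conventions

The inconclusive rate is taken over all sessions; hit and correct-rejection
rates condition on conclusive sessions of the corresponding truth class.
Empty denominators are reported as undefined (`None`/NaN), never as 0 or
100. Degenerate-data sessions count as inconclusive and are flagged.
Searching cohorts are decomposed into hits (right item), type-1 false
positives (recognizing examinee, wrong item), type-2 false positives
(unrecognizing examinee judged recognizing), misses, correct rejections and
inconclusives. ROC AUC is the tie-averaged trapezoidal area
(scikit-learn), with p-type scores negated so larger always means more
recognizing; the test suite cross-checks it against independent
Mann–Whitney pair counting. Histogram bins for d
(<−0.2, −0.2–0, 0–0.2, 0.2–0.4, 0.4–0.6, >0.6) and p (0–0.025, 0.025–0.05,
0.05–0.1, 0.1–0.2, 0.2–0.4, 0.4–0.6, 0.6–0.8, 0.8–1) are left-closed,
right-open, with the top p bin closed at 1.

## Problem sizes used in the checks

The automated checks run at sizes chosen to keep Monte-Carlo error well
below the tested tolerances while completing in seconds: B = 1,000 for
session scoring (10,000 when compared against exhaustive enumeration on
3×2 and 4×3 designs); 2,000 simulated sessions for null calibration and
effect recovery (three-standard-error bands); 10,000 blocks for the Lykken
null mean; cohorts of 152 (the emulated design) for operating
characteristics and 800 for the effect-size/AUC monotonicity sweep.

## Known limitations

- The statistics are computed on whatever repetitions are supplied; if field
  practice discards a buffer first presentation, that exclusion must happen
  upstream.
- The integrated p is conservative by construction (up to ~2/B near the
  extremes) — it can never be smaller than 1/B.
- Lykken tie-breaking is randomized rather than rank-averaged; with
  heavily discretized data this adds seed-dependent variation.
- A measure must be entirely present or entirely absent; partial grids are
  rejected rather than imputed.
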