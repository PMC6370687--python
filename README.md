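# citscore

Statistical scoring for the **Concealed Information Test (CIT)**, the
memory-detection polygraph technique used in field criminal investigations.
A CIT question presents one crime-relevant item (e.g., the stolen object)
among several matched irrelevant items, each repeated several times, while
autonomic responses are recorded: skin conductance response (SCR), heart
rate (HR), respiration line length (RLL) and normalized pulse volume (NPV).
An examinee who recognizes the relevant item typically shows a larger SCR
but a smaller HR/RLL/NPV response to it.

`citscore` is for psychophysiologists and forensic examiners who need
simple, database-free, court-explainable statistics on a single session:

- **Effect size *d***: per measure, with n₁ responses to the relevant item
  and n₂ to the irrelevant items,

      s_p = sqrt( ((n₁−1)s₁² + (n₂−1)s₂²) / (n₁+n₂−2) )
      d   = direction · (x̄₁ − x̄₂) / s_p

  using unbiased variances; HR/RLL/NPV effects are sign-flipped so positive
  *d* always means a response in the expected direction. Measures are
  integrated by averaging (missing measures — e.g., the ~25% electrodermal
  non-responders — are simply skipped).
- **Randomization-test *p***: B random relabelings of the n₁·(n_items)
  response cells give a null distribution of mean differences; the real
  difference's directional rank x gives p = x/B. Per-measure p-values are
  multiplied across measures and the product is calibrated against its own
  permutation null (each relabeling gets a pseudo-p per measure; the
  original product is ranked among the B generated products), so the
  integrated p stays uniform under the null whatever the cross-measure
  correlation. Exhaustive enumeration replaces sampling on small designs.
- **Lykken scoring** (2 points if the relevant item has the largest
  direction-adjusted response in a repetition block, 1 if second largest),
  the traditional comparator.
- **Three-way judgments** (recognized / inconclusive / unrecognized) at
  published threshold presets, for both known-solution CITs (the relevant
  item is designated) and searching CITs (every item is scored as if
  relevant; the max-*d*/min-*p* item is identified).
- A **synthetic cohort simulator** (80 recognizing + 72 unrecognizing
  examinees, 5 items × 5 repetitions, 4 correlated measures, habituation,
  non-responders) and **cohort evaluation** (hit / correct-rejection /
  inconclusive rates, ROC AUC, binned score tables, searching-CIT error
  decomposition).

## Worked example

```python
import citscore as cs

cfg = cs.SyntheticConfig(seed=3, nonresponder_prob=0.0)
session, truth = cs.simulate_session(cfg, recognizing=True, seed=11,
                                     session_id="demo")
res = cs.CITModel(session).fit(B=1000, seed=5)
print(res.summary())
print("judgment (d, strict):", res.judge("d").label)
print("judgment (p, strict):", res.judge("p").label)
```

prints

```
Concealed Information Test — session statistics
=======================================================
session:   demo
items:     5 x 5 repetitions
relevant:  item1
B:         1000
-------------------------------------------------------
measure              d         p    Lykken
SCR              1.085     0.011       6.0
HR               0.365     0.253       3.0
RLL              0.570     0.130       6.0
NPV              0.441     0.180       4.0
integrated       0.615     0.026       4.8
=======================================================

judgment (d, strict): recognized
judgment (p, strict): inconclusive
```

The SCR response to the relevant item is about one pooled SD above the
irrelevant-item mean (d = 1.09) and only 11 of 1,000 random relabelings
produced a difference at least that large (p = 0.011). Averaged over the
four measures the integrated d is 0.615 — above the strict known-solution
cutoff of 0.4, hence *recognized* — while the calibrated integrated p of
0.026 falls just above the strict 0.025 cutoff, hence *inconclusive* by the
p rule (the two statistics may be combined conjunctively with
`res.judge("both")`).

A command-line interface mirrors the library
(`citscore simulate|score|judge|evaluate|run`); sessions are long-format
CSV files with a small metadata header, and all outputs are CSV/JSON. Item
positions are 1-based in every file and report, 0-based in the Python API.

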