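# humdea

Multi-level, time-series efficiency analysis for humanitarian-health
operations with data envelopment analysis (DEA).

Humanitarian operations involve many actors on several levels — national
governments running long-term health programmes, and NGOs running
short-term relief in a single refugee camp — all converting scarce inputs
(funds, staff, populations served) into multiple outputs (people treated,
lives extended, infrastructure delivered). `humdea` provides the frontier
toolkit for benchmarking such decision-making units (DMUs) over time:

* **Radial DEA** — the CCR (constant returns to scale) and BCC (variable
  returns to scale) envelopment programs in input and output orientation,
  plus the multiplier form with virtual-weight restrictions. Scores are
  Farrell efficiencies in (0, 1]; for the output orientation the LP solves

      max φ  s.t.  Σ λⱼ xⱼ ≤ x₀,  Σ λⱼ yⱼ ≥ φ y₀,  λ ≥ 0  (Σλ = 1 under VRS)

  and reports 1/φ.
* **Undesirable outputs** — deaths-style factors enter as per-period
  `max − value`, so less is better becomes more is better.
* **Smoothed bootstrap** — the homogeneous reflected-kernel bootstrap of
  radial scores, with first-order bias correction
  `θ̂_bc = 2θ̂ − mean(θ*)` and percentile confidence bounds, plus a
  bound-containment model-selection rule.
* **Malmquist index** — adjacent-period productivity change decomposed as
  MI = catch-up × frontier shift from four cross-period radial distances.
* **Window analysis** — sliding pools of w consecutive periods in which
  each DMU-period is scored against all near-in-time peers.
* **Regression & prognosis** — OLS of efficiency on one determinant at a
  time, a bootstrap-augmented pooled regression (T × B rows, DEA side
  resampled only, covariate link preserved), stabilization diagnostics
  over B, and managerial/temporal efficiency simulation along a fitted
  line.
* **Synthetic panels** — generators that plant known efficiencies on a
  concave VRS frontier (recovered exactly by DEA) and emulate the two
  case-study schemas: a 34-country × 14-year health panel with a bad
  output and a rural-share covariate, and an 8-NGO × 6-quarter funding
  panel with two outsized funders.

See `docs/methods.md` for the models, defaults, and numerical conventions.

## Worked example

Score a synthetic NGO panel: drop outsized funders, bootstrap the selected
model, and run a window analysis.

```python
import humdea as h

data = h.generate_schema("ngo", seed=42)
kept, report = h.exclude_heterogeneous_dmus(data.panel, "I1", ratio_threshold=10.0)
print("excluded:", report.excluded)

spec = h.modification_catalog("ngo")[7]   # VIII: BCC, output-oriented, I1/O1/O2
res = h.sw_bootstrap_period(kept, "Q4-2018", spec, h.BootstrapConfig(B=1000, seed=1))
print(res.table().round(2))

print(h.window_efficiencies(kept, spec, w=2).table().round(2))
```

prints

```
excluded: ('NGO-IOM', 'NGO-UNHCR')
       efficiency  bias_corrected  lower  upper
NGO-A        1.00            0.96   0.96   1.12
NGO-B        1.00            0.98   0.98   1.11
NGO-C        1.00            0.98   0.98   1.13
NGO-D        0.75            0.74   0.74   0.81
NGO-E        1.00            0.87   0.87   1.28
NGO-F        0.71            0.70   0.70   0.78
period  Q3-2017  Q4-2017  Q1-2018  Q2-2018  Q3-2018  Q4-2018  Mean
dmu
NGO-A      1.00     1.00     1.00     1.00     1.00     1.00  1.00
...
NGO-F      0.67     0.62     0.66     0.65     0.67     0.71  0.66
```

Two funders investing ~65× and ~250× the smallest quarterly investment are
excluded before benchmarking. In the bootstrap table, `efficiency` is the
radial score against the estimated frontier, `bias_corrected` removes the
finite-sample frontier bias (always weakly lower on average), and every
original score falls inside its 95% bounds. The window table averages each
quarter's score over the width-2 windows containing it; the `Mean` column
is the mean of those per-quarter averages.

The prognosis stage maps determinant scenarios through a fitted efficiency
line. With the stabilized line `eff = 6.663 − 0.068 · rural_share(%)`:

```python
fit = h.RegressionFit.from_line(6.663, -0.068, covariate="rural share (%)")
h.simulate_efficiency(fit, "managerial", grid=[90.0]).predictions   # -> [0.543]
```

i.e. a predicted efficiency of 54.3% when the rural-population share
reaches 90% — below the 60% mark at which operations are considered
significantly inefficient.

A thin CLI mirrors the stages: `humdea synth | dea | bootstrap |
malmquist | window | regress | simulate` (see `humdea --help`).

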