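# Methods

`humdea` implements a multi-level, time-series efficiency analysis for
humanitarian-health operations: radial data envelopment analysis (DEA) over
a DMU × period × factor panel, smoothed-bootstrap bias correction, Malmquist
productivity decomposition, window analysis, and a bootstrap-augmented
regression/prognosis stage. This note records the models, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
panels do and do not demonstrate.

## The panel model

A `FactorPanel` is a cube of nonnegative reals over DMUs (countries or
NGOs), ordered periods (years or quarters — opaque labels whose chronology
is their declared order, never parsed dates), and factors with a role
(input/output) and a desirability (good/bad). Inputs must be strictly
positive — the envelopment LP needs positive input columns — while outputs
may be zero, which the radial LP tolerates; this matters because the
undesirable-output transform necessarily produces one zero per period.

## Radial efficiency models

For a period cross-section with inputs `x_j ∈ R^m_+` and outputs
`y_j ∈ R^r_+`, the output-oriented envelopment program for DMU `o` is

    max φ   s.t.  Σ_j λ_j x_ij ≤ x_io   (each input i)
                  Σ_j λ_j y_rj ≥ φ y_ro (each output r)
                  λ ≥ 0, and Σ_j λ_j = 1 under VRS,

with the input-oriented analogue contracting inputs by θ. Scores are always
reported on the Farrell (0, 1] scale (output orientation reports 1/φ),
matching how efficiency tables are conventionally printed. CRS is the CCR
model (conic hull), VRS the BCC model (convex hull); CRS scores are
cellwise ≤ VRS scores by feasible-set nesting, and this is tested.

The multiplier (dual) form is implemented separately because virtual-weight
restrictions live there: for a restricted factor with share `s`, the
constraint `u_k y_ko ≥ s · Σ_r u_r y_ro` (and its input mirror) is appended.
The "weight x% on a factor" notion from GUI DEA tools is interpreted as
this *minimum virtual-weight share* (a lower bound, not an exact share):
it is the only reading that makes a single percentage per factor
well-defined in the multiplier LP. With no restrictions the two forms agree
by LP duality (tested to 1e-7); restrictions can only lower a score, and a
floor on a factor whose value is zero for the evaluated DMU is correctly
infeasible and flagged rather than silently ignored.

Numerical conventions: HiGHS (via `scipy.optimize.linprog`) with
feasibility tolerances 1e-9; any optimal basis is accepted (alternate
optimal intensity vectors are not resolved — tests assert scores, never λ
uniqueness); summary tables snap scores within 1e-6 of 1 to exactly 1 only
at print time, raw scores are retained. Each period is an independent
contemporaneous frontier. A failed LP is recorded as a status on the score
record; it is never mapped to a score of 1.

## Undesirable outputs

A bad output (e.g. disease deaths) is transformed per period as
`value' = max over DMUs − value`, flipping desirability to good. The
period-maximum DMU lands at exactly 0 — no epsilon shift, because shifting
would alter radial scores. The transform is period-local; applying it twice
returns the original values shifted down by the period minimum (pairwise
gaps are restored exactly), which is the honest arithmetic of the formula.
Pipeline entry points (`efficiency_table`, the bootstrap, Malmquist) apply
the transform automatically to active bad outputs; window analysis computes
the maximum within each pooled window, since a window is one reference set.

## Screening and exclusion

Cross-correlation screening pools all DMU-period observations and reports
Pearson correlations; pairs with |r| ≥ 0.8 (default) are flagged,
constant factors are reported as degenerate. Screening never drops factors
— the workflow it mirrors only reports the maximum correlation and
proceeds.

The heterogeneity rule excludes DMUs whose chosen input exceeds
`ratio_threshold ×` the contemporaneous minimum in *any* period, default
threshold 10. Observed real-world exclusions happen at ratios of roughly 65
and 250; 10 reproduces exactly those exclusions on the NGO-style synthetic
panel while remaining permissive for ordinary panels. Exclusion is monotone
in the threshold and refuses to empty a panel.

## Smoothed bootstrap

DEA scores are biased toward the frontier. The homogeneous smoothed
bootstrap resamples radial distances `δ ≥ 1` from their reflected empirical
distribution ({δ} ∪ {2−δ}), smooths with a Gaussian kernel whose bandwidth
follows the normal-reference rule `h = 0.9·min(sd, IQR/1.349)·(2n)^{-1/5}`
on the reflected sample, applies the usual variance-shrink correction
`1/√(1+h²/σ̂²)`, folds draws back to ≥ 1, scales the reference outputs onto
the resampled frontier (`y*_j = (δ̂_j/δ*_j) y_j`; inputs for the input
orientation), and re-scores every DMU's original data against the pseudo
reference set.

Per DMU, bias is estimated as `mean(replicates) − original` and the
bias-corrected score is `2·original − mean(replicates)` — the standard
first-order correction, which reproduces the expected direction (corrected
below original on average). Replicates are retained so the alternative
"plain replicate mean" convention can be read off the result object.

Confidence bounds at level α are percentile bounds of the *bias-corrected
replicates*, where each replicate is corrected by subtracting the per-DMU
bias estimate once (`θ*_b − bias`). This centres the interval near the
original score, with the doubly-corrected point estimate toward the lower
bound — the pattern visible in published bootstrap-DEA tables, where
original scores lie inside their own bounds. The reflected alternative
(`2θ̂ − θ*_b`) centres the interval a full bias away from the original and
empirically leaves ~0% of originals inside their bounds on 30+ DMU panels,
so it cannot be what those tables report. A zero-variance distance sample
degenerates cleanly: h = 0, replicates equal originals, bias 0.

Model selection among candidate specifications keeps those whose original
scores all lie within their bounds and, among them, prefers the one with
more active factors (a richer factor set is the more informative model).

## Malmquist index

For adjacent periods, with `D_a(b)` the output-oriented radial distance of
period-b data against the period-a frontier (own-period ≤ 1, cross-period
possibly > 1):

    CU = D_{t+1}(t+1) / D_t(t)
    FS = √[ (D_t(t+1)/D_{t+1}(t+1)) · (D_t(t)/D_{t+1}(t)) ]
    MI = CU × FS

This is the adjacent-period geometric-mean index; no fixed-base or global
variant. Distances default to CRS even where level estimates use VRS,
because VRS cross-period LPs can be infeasible; a VRS override flags
infeasible rows instead of failing. In the single-input/single-output CRS
case MI collapses to the productivity ratio `(y_{t+1}/x_{t+1})/(y_t/x_t)`,
which serves as an independent oracle, as do the exact identity MI = CU×FS
(1e-9 relative) and time-reversal reciprocity. `frontier_shift_share`
reports, per DMU, the fraction of period pairs with |log FS| ≥ |log CU| —
a computable version of "change is technology-driven".

## Window analysis

Width-w windows pool w consecutive periods into one reference set in which
every DMU-period is a distinct unit — including the DMU's own other-period
observations; that inclusion is precisely what distinguishes window DEA
from per-period runs. `w = 1` collapses to per-period frontiers and `w = T`
to one pooled frontier (both tested). A period's score is averaged over the
windows containing it (a period belongs to `min(index+1, w, T−index,
T−w+1)` windows), and the per-DMU mean is the mean of those per-period
averages — fixed as a convention here, since published window tables do not
always use simple row means and their exact averaging rule is not
recoverable.

## Regression and prognosis

Efficiency (0, 1] is regressed on one covariate at a time (percent units
for shares) by OLS. The bootstrap-augmented stage enlarges a single DMU's
T-period sample: B bootstrap replicates of the efficiency score per period
— resampling the DEA side only, so each replicate stays paired with its
period's *original* covariate value and the DMU-covariate link is never
broken — are pooled into an exactly `T × B`-row design. Pooled OLS standard
errors shrink like 1/√(TB) and overstate precision because replicate rows
are not independent; a cluster-robust SE per source period is therefore
emitted alongside and is the honest yardstick for coverage statements.
Stabilization over a B grid is declared at the first B from which all
successive coefficient changes stay within tolerance (defaults: 0.001 on
the slope, 0.05 on the intercept, matching the digit stability such tables
display between B = 500 and 2000).

`simulate_efficiency` maps covariate scenarios through a fitted (or
supplied) line: managerial mode sweeps a grid; temporal mode extrapolates a
linear covariate trend. Grid points outside the observed covariate range
are flagged inductive — predictions there have no empirical support.

## Synthetic panels

`generate_frontier_panel` draws anchor DMUs, projects each onto the convex
VRS frontier of the set (one rescaling pass — projected points lie on the
hull boundary, so the frontier is unchanged and every anchor ends exactly
efficient), then builds each remaining DMU as a Dirichlet-weighted convex
combination of anchors whose outputs are radially contracted to a planted
score *after* measuring its exact distance to the anchor hull. Recovery of
planted scores by output-oriented VRS DEA is therefore exact (tested to
1e-6; observed error ~1e-15). Fewer DMUs than inputs+outputs+1 triggers a
discrimination warning, not a failure.

The national-style schema (34 × 14 by default, 3 inputs / 5 outputs) adds:
a 3%/period frontier drift; a bad first output generated as
`deaths = ceiling − good value` with one anchor pinned to good value 0, so
the reciprocal transform restores the constructed output — and hence the
planted scores — exactly; and a rural-share covariate (percent) with
planted link `score = 1.5 − 0.0105·share + N(0, 0.02)`, anchors pinned at
the share where the line crosses 1 (noise there would attenuate the
recovered slope). The NGO-style schema (8 × 6, 1 input / 3 outputs) appends
two scaled clones whose input is 64.56× and 250× the period minimum, so the
default exclusion rule removes exactly those two.

What the synthetic panels do *not* emulate: the marginal distributions of
real health/funding indicators, measurement error, missingness, or
compositional change of the frontier over time (the cross-sectional
structure is fixed; periods differ by drift and planted scores). Passing
tests therefore demonstrate algorithmic correctness under known ground
truth, not robustness to real-data pathologies.

## Problem sizes and test design

The test suite runs the full 34 × 14 national panel for planted-score
recovery and for one B = 1000 bootstrap period (the bias-direction check);
the bootstrap-augmented regression checks use 10–12 DMU, 10–14 period
panels with a single evaluated DMU per iteration — the pseudo frontier is
always built from all DMUs, but only the target is re-scored, which is all
the pooled design needs. These sizes were chosen so each property is
exercised at the scale where it is informative while the whole suite stays
fast enough to run routinely.

## Known limitations

* No slack maximization: scores are radial only; weak efficiency
  (nonzero slacks at score 1) is not distinguished.
* No super-efficiency, SBM/additive, network DEA, or scale-efficiency
  decomposition beyond the CCR/BCC comparison.
* The homogeneous bootstrap assumes one inefficiency distribution for all
  DMUs; heterogeneous or two-stage (truncated-regression) bootstraps are
  out of scope.
* Monetary factors are used as given; no deflation or currency adjustment
  across periods.
* With VRS and heavy-tailed DMU sizes, cross-period and window LPs can be
  infeasible; these are flagged, not imputed.
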