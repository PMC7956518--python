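"""Synthetic DMU panels with planted (known) efficiencies.

The generator builds a concave variable-returns-to-scale technology from a
set of anchor DMUs, then places every other DMU inside it by radially
contracting its outputs to a planted Farrell score. Because the anchors are
emitted as DMUs themselves, an output-oriented VRS solve recovers the
planted scores exactly — the generator is the ground-truth oracle for the
whole pipeline.

Two case-study schemas are emulated on top of this machinery:

* ``national`` — 34 DMUs x 14 annual periods, 3 inputs and 5 outputs, the
  first output being a *bad* one (deaths) that the pipeline's reciprocal
  transform must undo, plus a rural-population-share covariate (in percent)
  linearly and negatively linked to the planted efficiency;
* ``ngo`` — 8 DMUs x 6 quarterly periods, 1 input (funds) and 3 outputs,
  with heavy-tailed input sizes (max/min ratio >= 60) so the default
  heterogeneity exclusion rule removes exactly the two large funders.

All randomness flows through one seeded generator; the same seed always
reproduces the same panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .dea import radial_lp
from .panel import BAD, GOOD, FactorDef, FactorPanel
from .regression import CovariateSeries


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic frontier panel.

    ``planted_scores`` may fix scores per (dmu index, period index);
    otherwise scores are drawn from the inefficiency distribution
    (``("uniform", (lo, hi))`` or ``("beta", (a, b))`` mapped to (0, 1]).
    ``frontier_drift`` grows all frontier outputs by that rate per period.
    ``covariate_link = (intercept, slope, noise_sd)`` ties planted scores to
    a generated covariate (percent units). ``bad_output`` replaces the first
    output with a deaths-style bad factor whose per-period max-minus-value
    transform restores the constructed good output exactly.
    """

    seed: int
    n_dmu: int = 34
    n_periods: int = 14
    n_inputs: int = 3
    n_outputs: int = 5
    planted_scores: Mapping[tuple[int, int], float] | None = None
    frontier_drift: float = 0.0
    inefficiency: tuple[str, tuple[float, ...]] = ("uniform", (0.55, 0.95))
    covariate_link: tuple[float, float, float] | None = None
    bad_output: bool = False
    size_heterogeneity_ratios: tuple[float, ...] = ()
    period_labels: tuple[str, ...] | None = None
    dmu_labels: tuple[str, ...] | None = None


@dataclass
class SyntheticPanel:
    """Generated panel plus its planted truth and optional covariate table."""

    panel: FactorPanel
    truth: pd.DataFrame  # dmu x period planted Farrell scores (NaN = not planted)
    covariates: pd.DataFrame | None = None  # dmu x period covariate values
    covariate_label: str = ""

    def covariate_series(self, dmu: str) -> CovariateSeries:
        if self.covariates is None:
            raise ValueError("this panel has no covariate table")
        return CovariateSeries(dmu, self.covariate_label, self.covariates.loc[dmu])


def _draw_scores(spec: SyntheticSpec, rng: np.random.Generator, size: int) -> np.ndarray:
    label, params = spec.inefficiency
    if label == "uniform":
        lo, hi = params
        return rng.uniform(lo, hi, size)
    if label == "beta":
        a, b = params
        return np.clip(rng.beta(a, b, size), 1e-3, 1.0)
    raise ValueError(f"unknown inefficiency distribution {label!r}")


def generate_frontier_panel(spec: SyntheticSpec) -> SyntheticPanel:
    """Build a panel whose output-oriented VRS scores are known by construction.

    Anchors (always >= inputs + outputs + 1 when the DMU budget allows) are
    drawn, then a single rescaling pass puts each anchor exactly on the
    convex-hull frontier of the set. Every non-anchor DMU is a convex
    combination of anchors whose outputs are contracted to the planted score
    after measuring its exact radial distance to the anchor hull — so DEA on
    the emitted panel returns the planted scores to solver precision.
    """
    rng = np.random.default_rng(spec.seed)
    m, r = spec.n_inputs, spec.n_outputs
    n = spec.n_dmu
    min_needed = m + r + 1
    if n < min_needed:
        warnings.warn(
            f"{n} DMUs < inputs + outputs + 1 = {min_needed}: poor discrimination, "
            "many spuriously efficient DMUs",
            stacklevel=2,
        )
    n_anchor = min(n, max(min_needed, int(round(n * 0.2))))

    # anchor technology: inputs in [1, 10], outputs loosely size-linked
    X_a = rng.uniform(1.0, 10.0, (n_anchor, m))
    scale = X_a.mean(axis=1) ** 0.6
    Y_a = rng.uniform(1.0, 6.0, (n_anchor, r)) * scale[:, None]
    if spec.bad_output:
        # one anchor pinned to 0 on the bad channel so the reciprocal
        # transform (max minus value) has an exact zero per period
        Y_a[0, 0] = 0.0
    # rescaling pass: project every anchor onto the hull frontier
    for i in range(n_anchor):
        factor, _, status = radial_lp(X_a, Y_a, X_a[i], Y_a[i], "output", "vrs")
        if factor is None:
            raise RuntimeError(f"anchor projection LP {status}")
        Y_a[i] = Y_a[i] * factor

    # non-anchor DMUs: convex combinations of anchors, contracted to s
    n_free = n - n_anchor
    mu = rng.dirichlet(np.ones(n_anchor), size=n_free) if n_free else np.zeros((0, n_anchor))
    X_f = mu @ X_a
    Y_mix = mu @ Y_a
    F_free = np.empty_like(Y_mix)  # frontier-projected outputs
    for i in range(n_free):
        factor, _, status = radial_lp(X_a, Y_a, X_f[i], Y_mix[i], "output", "vrs")
        if factor is None:
            raise RuntimeError(f"mixture projection LP {status}")
        F_free[i] = Y_mix[i] * factor

    X = np.vstack([X_a, X_f])
    F = np.vstack([Y_a, F_free])  # per-DMU frontier output profile
    anchors = np.arange(n) < n_anchor

    T = spec.n_periods
    scores = np.ones((n, T))
    covariates = None
    if spec.covariate_link is not None:
        a, b, sd = spec.covariate_link
        # per-DMU covariate path: base + mild trend + noise, in percent units
        base = rng.uniform(55.0, 80.0, n)
        trend = rng.uniform(-0.8, 0.8, n)
        cov = base[:, None] + trend[:, None] * np.arange(T)[None, :] + rng.normal(0.0, 1.0, (n, T))
        # anchors stay pinned at efficiency 1, so their covariate sits exactly
        # where the planted line crosses 1 — noise there would flatten the link
        cov[anchors, :] = (1.0 - a) / b
        scores = np.clip(a + b * cov + rng.normal(0.0, sd, (n, T)), 0.05, 0.995)
        covariates = cov
    else:
        scores = _draw_scores(spec, rng, (n, T)).reshape(n, T)
    scores[anchors, :] = 1.0
    if spec.planted_scores:
        for (i, t), s in spec.planted_scores.items():
            if not (0.0 < s <= 1.0):
                raise ValueError(f"planted score {s} outside (0, 1]")
            scores[i, t] = s
            if anchors[i] and s < 1.0:
                raise ValueError("anchor DMUs must keep planted score 1")

    dmus = list(spec.dmu_labels) if spec.dmu_labels else [f"DMU{i+1:02d}" for i in range(n)]
    periods = list(spec.period_labels) if spec.period_labels else [f"T{t+1:02d}" for t in range(T)]

    growth = (1.0 + spec.frontier_drift) ** np.arange(T)
    rows = []
    for i in range(n):
        for t in range(T):
            y = scores[i, t] * growth[t] * F[i]
            rows.append((dmus[i], periods[t], *X[i], *y))
    in_ids = [f"I{k+1}" for k in range(m)]
    out_ids = [f"O{k+1}" for k in range(r)]
    frame = pd.DataFrame(rows, columns=["dmu", "period", *in_ids, *out_ids]).set_index(["dmu", "period"])

    factors = [FactorDef(fid, "input", GOOD, "volume") for fid in in_ids]
    bad_first = spec.bad_output
    for k, fid in enumerate(out_ids):
        desirability = BAD if (bad_first and k == 0) else GOOD
        factors.append(FactorDef(fid, "output", desirability, "volume"))
    if bad_first:
        # encode the bad channel as deaths = ceiling - good value; the
        # per-period ceiling exceeds every good value and is attained by the
        # pinned anchor (good value 0), so max-minus-value restores the
        # constructed output exactly
        good = frame[out_ids[0]].unstack("period")
        ceiling = 1.05 * good.max(axis=0).replace(0.0, 1.0)
        deaths = (-good).add(ceiling, axis=1)
        frame[out_ids[0]] = deaths.stack().reorder_levels(["dmu", "period"]).loc[frame.index]

    panel = FactorPanel(dmus, periods, factors, frame)
    truth = pd.DataFrame(scores, index=dmus, columns=periods)
    cov_frame = pd.DataFrame(covariates, index=dmus, columns=periods) if covariates is not None else None
    result = SyntheticPanel(panel, truth, cov_frame, "rural_share" if cov_frame is not None else "")
    if spec.size_heterogeneity_ratios:
        pairs = tuple((f"BIG{k+1}", rho) for k, rho in enumerate(spec.size_heterogeneity_ratios))
        result = _append_outsized_funders(result, spec.seed, pairs)
    return result


def generate_schema(
    schema: str,
    seed: int,
    n_dmu: int | None = None,
    n_periods: int | None = None,
) -> SyntheticPanel:
    """Generate one of the two case-study panels.

    ``national``: default 34 DMUs x 14 years (2002-2015), 3 inputs, 5
    outputs with O1 bad, mild frontier drift, rural-share covariate with a
    negative planted efficiency link. ``ngo``: default 8 DMUs x 6 quarters,
    1 input, 3 outputs, two outsized funders (about 65x and 250x the
    smallest input) that trip the exclusion rule. Size overrides scale the
    same structure down for quick runs.
    """
    if schema == "national":
        n = n_dmu or 34
        T = n_periods or 14
        spec = SyntheticSpec(
            seed=seed,
            n_dmu=n,
            n_periods=T,
            n_inputs=3,
            n_outputs=5,
            frontier_drift=0.03,
            covariate_link=(1.5, -0.0105, 0.02),
            bad_output=True,
            period_labels=tuple(str(2002 + t) for t in range(T)),
        )
        return generate_frontier_panel(spec)
    if schema == "ngo":
        n = n_dmu or 8
        T = n_periods or 6
        if n < 3:
            raise ValueError("ngo schema needs at least 3 DMUs")
        base_labels = [f"NGO-{chr(65 + i)}" for i in range(n - 2)]
        quarters = ("Q3-2017", "Q4-2017", "Q1-2018", "Q2-2018", "Q3-2018", "Q4-2018")
        labels = tuple(quarters[t % 6] if T <= 6 else f"Q{t}" for t in range(T))
        spec = SyntheticSpec(
            seed=seed,
            n_dmu=n - 2,
            n_periods=T,
            n_inputs=1,
            n_outputs=3,
            inefficiency=("uniform", (0.3, 0.95)),
            covariate_link=(1.5, -0.0105, 0.03),
            period_labels=labels,
            dmu_labels=tuple(base_labels),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # 6 DMUs < m + r + 1 is intentional here
            result = generate_frontier_panel(spec)
        return _append_outsized_funders(result, seed)
    raise ValueError(f"unknown schema {schema!r}; expected 'national' or 'ngo'")


def _append_outsized_funders(
    base: SyntheticPanel,
    seed: int,
    pairs: tuple[tuple[str, float], ...] = (("NGO-IOM", 64.56), ("NGO-UNHCR", 250.0)),
) -> SyntheticPanel:
    """Add scaled-up clones whose first input is ``ratio`` x the period minimum."""
    rng = np.random.default_rng(seed + 17)
    panel = base.panel
    vals = panel.values.copy()
    in_id = panel.input_factors[0].factor_id
    per_min = vals[in_id].groupby(level="period").min()
    big_rows = []
    for label, ratio in pairs:
        donor = str(rng.choice(panel.dmu_ids))
        block = vals.loc[donor].copy()  # period-indexed
        scale = ratio * per_min.loc[block.index] / block[in_id]
        block = block.mul(scale, axis=0)
        # large funders convert scale poorly: damp outputs so they are not
        # trivially efficient, leaving the input ratio exact
        out_cols = [f.factor_id for f in panel.output_factors]
        block[out_cols] *= rng.uniform(0.55, 0.85)
        block.index = pd.MultiIndex.from_product([[label], block.index], names=["dmu", "period"])
        big_rows.append(block)
    new_vals = pd.concat([vals, *big_rows])
    labels = [label for label, _ in pairs]
    dmus = list(panel.dmu_ids) + labels
    new_panel = FactorPanel(dmus, panel.periods, panel.factors, new_vals)
    truth = base.truth.reindex(dmus)  # clones carry no planted score (NaN)
    cov = None
    if base.covariates is not None:
        cov = base.covariates.reindex(dmus)
        cov.loc[labels] = base.covariates.mean(axis=0).to_numpy()
    return SyntheticPanel(new_panel, truth, cov, base.covariate_label)
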