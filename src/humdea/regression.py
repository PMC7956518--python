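"""Efficiency determinants and ex-ante prognosis.

Second-stage analysis of DEA results: simple OLS of per-period efficiency on
one covariate at a time (e.g. rural-population share in percent), a
bootstrap-augmented pooled regression that enlarges the sample by pairing B
bootstrap replicates of the efficiency score with each DMU-period's
*original* covariate value (resampling only the DEA side keeps the DMU tied
to its characteristics), a stabilization diagnostic over increasing B, and
the managerial / temporal simulation that maps covariate scenarios through
the fitted line.

Efficiency enters the regressions on the (0, 1] Farrell scale; covariates
are taken in their natural units (percent for shares). Pooled OLS standard
errors treat replicate rows as independent — which they are not — so a
cluster-robust standard error per source DMU-period is emitted alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .bootstrap import BootstrapConfig, sw_bootstrap_period
from .panel import FactorPanel, ModelSpec


@dataclass
class CovariateSeries:
    """One DMU's covariate path over the panel periods."""

    dmu: str
    label: str
    values: pd.Series  # index: period labels

    def aligned(self, periods: Sequence[str]) -> pd.Series:
        missing = [p for p in periods if p not in self.values.index]
        if missing:
            raise ValueError(f"covariate {self.label!r} missing periods {missing}")
        return self.values.loc[list(periods)]


@dataclass
class RegressionFit:
    """Simple (one-covariate) OLS fit of efficiency on a determinant."""

    intercept: float
    slope: float
    se_intercept: float = float("nan")
    se_slope: float = float("nan")
    r2: float = float("nan")
    adj_r2: float = float("nan")
    resid_se: float = float("nan")
    fstat: float = float("nan")
    df_resid: int = 0
    n: int = 0
    covariate: str = ""
    x_min: float | None = None
    x_max: float | None = None
    cluster_se_intercept: float | None = None
    cluster_se_slope: float | None = None

    @classmethod
    def from_line(cls, intercept: float, slope: float, covariate: str = "") -> "RegressionFit":
        """A fit holding only a known line, for plugging printed equations in."""
        return cls(intercept=intercept, slope=slope, covariate=covariate)

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


@dataclass
class SimulationCurve:
    """Predicted efficiency over a covariate grid.

    ``inductive`` flags grid points outside the observed covariate range —
    predictions there extrapolate beyond any empirical support.
    """

    covariate: str
    grid: np.ndarray
    predictions: np.ndarray
    inductive: np.ndarray
    mode: str = "managerial"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"covariate": self.grid, "predicted_efficiency": self.predictions, "inductive": self.inductive}
        )


@dataclass
class StabilizationReport:
    """Coefficient changes between successive B values and the stabilizing B."""

    changes: pd.DataFrame  # index: B (the larger of each pair); columns: slope/intercept deltas
    slope_tol: float
    intercept_tol: float
    stabilized: bool
    stabilized_B: int | None


def fit_ols(
    efficiency: Sequence[float] | pd.Series,
    covariate: Sequence[float] | pd.Series | CovariateSeries,
    label: str = "",
    cluster_groups: Sequence | None = None,
) -> RegressionFit:
    """Least-squares fit of efficiency on a single covariate.

    Requires >= 3 paired observations and a non-constant covariate. A
    constant response yields slope 0 with R^2 reported as 0.
    """
    if isinstance(covariate, CovariateSeries):
        label = label or covariate.label
        covariate = covariate.values
    y = np.asarray(efficiency, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if y.shape != x.shape:
        raise ValueError("efficiency and covariate must align")
    if y.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0.0:
        raise ValueError("covariate has zero variance; slope undefined")
    design = sm.add_constant(x)
    model = sm.OLS(y, design)
    res = model.fit()
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = float(res.rsquared) if tss > 0 else 0.0
    adj = float(res.rsquared_adj) if tss > 0 else 0.0
    f = float(res.fvalue) if tss > 0 and np.isfinite(res.fvalue) else 0.0
    fit = RegressionFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        se_intercept=float(res.bse[0]),
        se_slope=float(res.bse[1]),
        r2=r2,
        adj_r2=adj,
        resid_se=float(np.sqrt(res.ssr / res.df_resid)) if res.df_resid > 0 else float("nan"),
        fstat=f,
        df_resid=int(res.df_resid),
        n=int(res.nobs),
        covariate=label,
        x_min=float(x.min()),
        x_max=float(x.max()),
    )
    if cluster_groups is not None:
        cres = model.fit(cov_type="cluster", cov_kwds={"groups": np.asarray(cluster_groups)})
        fit.cluster_se_intercept = float(cres.bse[0])
        fit.cluster_se_slope = float(cres.bse[1])
    return fit


def bootstrap_augmented_regression(
    panel: FactorPanel,
    spec: ModelSpec,
    dmu: str,
    covariate: CovariateSeries,
    config: BootstrapConfig,
    B_grid: Sequence[int],
) -> list[tuple[int, RegressionFit]]:
    """Pooled OLS fits of bootstrap-replicate efficiency on a covariate.

    For the target DMU, one smoothed-bootstrap run per period (at the
    largest B in the grid) produces replicate efficiency scores; for each B
    in the grid, the first B replicates of every period are pooled — each
    paired with that period's original covariate value — into an
    ``n_sample x B`` row design, and a simple OLS is fitted. The fit for
    ``B = 1`` therefore has exactly ``n_sample`` rows.
    """
    B_grid = sorted(set(int(b) for b in B_grid))
    if not B_grid or B_grid[0] < 1:
        raise ValueError("B_grid must contain integers >= 1")
    B_max = B_grid[-1]
    periods = list(panel.periods)
    x_per_period = covariate.aligned(periods)
    # one independent child seed per period, kept below 2^31
    child_seeds = np.random.SeedSequence(config.seed).generate_state(len(periods)) % (2**31 - 1)
    reps = np.empty((len(periods), B_max))
    for t, period in enumerate(periods):
        cfg = BootstrapConfig(B=B_max, alpha=config.alpha, bandwidth_rule=config.bandwidth_rule, seed=int(child_seeds[t]))
        result = sw_bootstrap_period(panel, period, spec, cfg, eval_dmus=[dmu])
        reps[t] = result.replicates.loc[dmu].to_numpy()
    fits: list[tuple[int, RegressionFit]] = []
    for B in B_grid:
        y = reps[:, :B].ravel()
        x = np.repeat(x_per_period.to_numpy(dtype=float), B)
        groups = np.repeat(np.arange(len(periods)), B)
        fit = fit_ols(y, x, label=covariate.label, cluster_groups=groups)
        assert fit.n == len(periods) * B  # pooled design size audit
        fits.append((B, fit))
    return fits


def stabilization_check(
    fits: Sequence[tuple[int, RegressionFit]],
    slope_tol: float = 0.001,
    intercept_tol: float = 0.05,
) -> StabilizationReport:
    """Find the smallest B from which the coefficients stop moving.

    Computes absolute slope and intercept changes between successive B
    values; the series is stabilized at the first step from which every
    subsequent change stays within tolerance.
    """
    if len(fits) < 2:
        raise ValueError("need fits for at least 2 B values")
    Bs = [b for b, _ in fits]
    d_slope = [abs(fits[i + 1][1].slope - fits[i][1].slope) for i in range(len(fits) - 1)]
    d_int = [abs(fits[i + 1][1].intercept - fits[i][1].intercept) for i in range(len(fits) - 1)]
    changes = pd.DataFrame({"d_slope": d_slope, "d_intercept": d_int}, index=Bs[1:])
    ok = [s <= slope_tol and i <= intercept_tol for s, i in zip(d_slope, d_int)]
    stabilized_B = None
    for k in range(len(ok)):
        if all(ok[k:]):
            stabilized_B = Bs[k + 1]
            break
    return StabilizationReport(changes, slope_tol, intercept_tol, stabilized_B is not None, stabilized_B)


def simulate_efficiency(
    fit: RegressionFit,
    mode: str = "managerial",
    grid: Sequence[float] | None = None,
    covariate: CovariateSeries | None = None,
    horizon: int = 0,
) -> SimulationCurve:
    """Map covariate scenarios through a fitted efficiency line.

    ``managerial`` mode sweeps an explicit covariate grid. ``temporal`` mode
    fits a linear time trend to an observed covariate path, extrapolates it
    ``horizon`` periods ahead, and maps the extrapolated values through the
    line. Points beyond the observed covariate range are flagged inductive.
    """
    if not (np.isfinite(fit.intercept) and np.isfinite(fit.slope)):
        raise ValueError("fit has non-finite coefficients")
    if mode == "managerial":
        if grid is None:
            raise ValueError("managerial mode needs a covariate grid")
        g = np.asarray(list(grid), dtype=float)
    elif mode == "temporal":
        if covariate is None or horizon < 1:
            raise ValueError("temporal mode needs an observed covariate path and horizon >= 1")
        x_obs = covariate.values.to_numpy(dtype=float)
        t_obs = np.arange(x_obs.size, dtype=float)
        trend = np.polyfit(t_obs, x_obs, 1)
        t_fut = np.arange(x_obs.size, x_obs.size + horizon, dtype=float)
        g = np.polyval(trend, t_fut)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    pred = np.asarray(fit.predict(g), dtype=float)
    if fit.x_min is not None and fit.x_max is not None:
        inductive = (g < fit.x_min) | (g > fit.x_max)
    else:
        inductive = np.ones_like(g, dtype=bool)
    return SimulationCurve(fit.covariate, g, pred, inductive, mode)
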