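"""Radial DEA: envelopment and multiplier linear programs.

Solves the Farrell-type radial efficiency models — CCR (constant returns to
scale) and BCC (variable returns to scale), in input and output orientation —
for every DMU of a period against that period's contemporaneous frontier.

Conventions
-----------
* Scores are reported on the Farrell (0, 1] scale for both orientations: an
  output-oriented solve finds the maximal proportional output expansion
  ``phi >= 1`` and reports ``1/phi``; an input-oriented solve reports the
  minimal contraction ``theta`` directly. 1 means "on the estimated frontier".
* Each period is an independent frontier (contemporaneous evaluation).
* Active output factors with bad desirability (e.g. deaths) are transformed
  with the per-period max-minus-value rule before solving.
* LP failures are recorded in :attr:`ScoreRecord.status`, never silently
  mapped to a score of 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .panel import (
    BAD,
    ROLE_INPUT,
    ROLE_OUTPUT,
    FactorPanel,
    ModelSpec,
    spec_errors,
    validate_spec,
)

#: LP solver tolerance; scores within SCORE_ATOL of 1 print as exactly 1.00
SOLVER_TOL = 1e-9
SCORE_ATOL = 1e-6

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


@dataclass
class ScoreRecord:
    """Radial efficiency of one DMU in one period.

    ``radial_factor`` is the raw LP optimum (phi for output orientation,
    theta for input orientation); ``farrell_score`` is its (0, 1] version.
    ``lambdas`` holds the peer intensities of an optimal envelopment basis
    (any optimal basis is accepted; alternate optima are not resolved).
    """

    dmu: str
    period: str
    status: str
    farrell_score: float | None = None
    radial_factor: float | None = None
    lambdas: dict[str, float] = field(default_factory=dict)
    weights: dict[str, float] | None = None

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


@dataclass
class EfficiencyTable:
    """Per-DMU, per-period scores for one model spec, plus summary statistics."""

    spec_label: str
    records: list[ScoreRecord]

    def scores(self) -> pd.DataFrame:
        """DMU x period matrix of Farrell scores (NaN where the LP failed)."""
        dmus = list(dict.fromkeys(r.dmu for r in self.records))
        periods = list(dict.fromkeys(r.period for r in self.records))
        out = pd.DataFrame(np.nan, index=dmus, columns=periods)
        for r in self.records:
            if r.ok:
                out.loc[r.dmu, r.period] = r.farrell_score
        return out

    def summary(self, decimals: int | None = None) -> pd.DataFrame:
        """Min / mean / median / SD across periods per DMU.

        Sample SD (ddof=1); 0.0 for a single period. With ``decimals`` set,
        scores within ``SCORE_ATOL`` of 1 are snapped to exactly 1 before
        rounding, mirroring two-decimal report tables.
        """
        sc = self.scores()
        vals = sc.to_numpy(dtype=float)
        if decimals is not None:
            vals = vals.copy()
            vals[np.abs(vals - 1.0) <= SCORE_ATOL] = 1.0
        df = pd.DataFrame(
            {
                "min": np.nanmin(vals, axis=1),
                "mean": np.nanmean(vals, axis=1),
                "median": np.nanmedian(vals, axis=1),
                "sd": np.nanstd(vals, axis=1, ddof=1) if vals.shape[1] > 1 else 0.0,
            },
            index=sc.index,
        )
        if decimals is not None:
            df = df.round(decimals)
        return df


# ---------------------------------------------------------------------------
# low-level LPs on numpy slices
# ---------------------------------------------------------------------------


def radial_lp(
    X: np.ndarray,
    Y: np.ndarray,
    x0: np.ndarray,
    y0: np.ndarray,
    orientation: str = "output",
    rts: str = "vrs",
) -> tuple[float | None, np.ndarray | None, str]:
    """Solve the radial envelopment LP against a reference set.

    X, Y are (n, m) and (n, r) reference arrays (rows = reference DMUs);
    (x0, y0) is the evaluated point, which need not belong to the reference
    set (cross-period Malmquist distances rely on this).

    Returns ``(radial_factor, lambdas, status)`` where the radial factor is
    phi (max output expansion) or theta (min input contraction).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    y0 = np.asarray(y0, dtype=float)
    n, m = X.shape
    r = Y.shape[1]
    nvar = n + 1
    c = np.zeros(nvar)
    A_ub = np.zeros((m + r, nvar))
    b_ub = np.zeros(m + r)
    if orientation == "output":
        # max phi  s.t.  X'lam <= x0,  Y'lam >= phi*y0
        c[-1] = -1.0
        A_ub[:m, :n] = X.T
        b_ub[:m] = x0
        A_ub[m:, :n] = -Y.T
        A_ub[m:, -1] = y0
    elif orientation == "input":
        # min theta  s.t.  X'lam <= theta*x0,  Y'lam >= y0
        c[-1] = 1.0
        A_ub[:m, :n] = X.T
        A_ub[:m, -1] = -x0
        A_ub[m:, :n] = -Y.T
        b_ub[m:] = -y0
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    A_eq = b_eq = None
    if rts == "vrs":
        A_eq = np.zeros((1, nvar))
        A_eq[0, :n] = 1.0
        b_eq = np.ones(1)
    elif rts != "crs":
        raise ValueError(f"unknown rts {rts!r}")
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=[(0.0, None)] * nvar,
        method="highs",
        options={"primal_feasibility_tolerance": SOLVER_TOL, "dual_feasibility_tolerance": SOLVER_TOL},
    )
    status = _STATUS.get(res.status, "failed")
    if res.status != 0:
        return None, None, status
    factor = float(res.x[-1])
    return factor, res.x[:n].copy(), status


def multiplier_lp(
    X: np.ndarray,
    Y: np.ndarray,
    x0: np.ndarray,
    y0: np.ndarray,
    orientation: str = "output",
    rts: str = "vrs",
    min_shares_out: Mapping[int, float] | None = None,
    min_shares_in: Mapping[int, float] | None = None,
) -> tuple[float | None, np.ndarray | None, np.ndarray | None, str]:
    """Solve the multiplier (dual) LP, optionally with virtual-weight floors.

    ``min_shares_out`` / ``min_shares_in`` map output / input column indices
    to minimum virtual-weight shares s: the constraint u_k y0_k >= s * u.y0
    (resp. v_k x0_k >= s * v.x0) is appended. Returns
    ``(radial_factor, u, v, status)``.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, m = X.shape
    r = Y.shape[1]
    min_shares_out = dict(min_shares_out or {})
    min_shares_in = dict(min_shares_in or {})
    vrs = rts == "vrs"
    # variables: u (r), v (m), [omega free, VRS only]; the sign of omega in
    # the ratio constraints must match its sign in the objective (dual of the
    # convexity row), which differs between orientations
    nvar = r + m + (1 if vrs else 0)
    omega_sign = -1.0 if orientation == "output" else 1.0
    rows_ub: list[np.ndarray] = []
    b_list: list[float] = []
    # ratio constraints u.Y_j - v.X_j (+/- omega) <= 0
    for j in range(n):
        row = np.zeros(nvar)
        row[:r] = Y[j]
        row[r : r + m] = -X[j]
        if vrs:
            row[-1] = omega_sign
        rows_ub.append(row)
        b_list.append(0.0)
    c = np.zeros(nvar)
    A_eq = np.zeros((1, nvar))
    if orientation == "output":
        # min v.x0 (+ omega)  s.t. u.y0 = 1
        c[r : r + m] = x0
        if vrs:
            c[-1] = 1.0
        A_eq[0, :r] = y0
        sign = 1.0
    elif orientation == "input":
        # max u.y0 (+ omega)  s.t. v.x0 = 1
        c[:r] = -y0
        if vrs:
            c[-1] = -1.0
        A_eq[0, r : r + m] = x0
        sign = -1.0
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    b_eq = np.ones(1)
    # virtual-weight floors; with the normalization u.y0=1 (output orientation)
    # the output-share constraint is linear either way because u.y0 / v.x0 is
    # itself a linear expression of the variables
    for k, s in min_shares_out.items():
        row = np.zeros(nvar)
        row[:r] = s * y0
        row[k] -= y0[k]
        rows_ub.append(row)  # s*u.y0 - u_k y0_k <= 0
        b_list.append(0.0)
    for k, s in min_shares_in.items():
        row = np.zeros(nvar)
        row[r : r + m] = s * x0
        row[r + k] -= x0[k]
        rows_ub.append(row)
        b_list.append(0.0)
    A_ub = np.vstack(rows_ub)
    b_ub = np.array(b_list)
    bounds = [(0.0, None)] * (r + m) + ([(None, None)] if vrs else [])
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": SOLVER_TOL, "dual_feasibility_tolerance": SOLVER_TOL},
    )
    status = _STATUS.get(res.status, "failed")
    if res.status != 0:
        return None, None, None, status
    factor = float(sign * res.fun)
    return factor, res.x[:r].copy(), res.x[r : r + m].copy(), status


# ---------------------------------------------------------------------------
# panel-level interface
# ---------------------------------------------------------------------------


def resolve_active(panel: FactorPanel, spec: ModelSpec) -> tuple[list[str], list[str]]:
    """Active (input_ids, output_ids) in panel factor order."""
    active = set(spec.active_factors) if spec.active_factors else set(panel.factor_ids)
    ins = [f.factor_id for f in panel.input_factors if f.factor_id in active]
    outs = [f.factor_id for f in panel.output_factors if f.factor_id in active]
    return ins, outs


def prepare_panel(panel: FactorPanel, spec: ModelSpec) -> FactorPanel:
    """Apply the reciprocal (max-minus-value) transform to active bad outputs."""
    from .factors import reciprocal_bad_output  # local import: factors builds on panel only

    _, outs = resolve_active(panel, spec)
    for fid in outs:
        if panel.factor(fid).desirability == BAD:
            panel, _ = reciprocal_bad_output(panel, fid)
    return panel


def _check_spec(panel: FactorPanel, spec: ModelSpec) -> None:
    errs = spec_errors(validate_spec(spec, panel))
    if errs:
        raise ValueError("; ".join(v.message for v in errs))


def _farrell(factor: float, orientation: str) -> float:
    return 1.0 / factor if orientation == "output" else factor


def solve_radial(
    panel: FactorPanel,
    period: str,
    dmu: str,
    spec: ModelSpec,
    *,
    prepared: bool = False,
) -> ScoreRecord:
    """Score one DMU against its period's frontier (envelopment form)."""
    _check_spec(panel, spec)
    if not prepared:
        panel = prepare_panel(panel, spec)
    ins, outs = resolve_active(panel, spec)
    X = panel.period_matrix(period, ins)
    Y = panel.period_matrix(period, outs)
    j = panel.dmu_ids.index(dmu)
    factor, lam, status = radial_lp(X, Y, X[j], Y[j], spec.orientation, spec.rts)
    if factor is None:
        return ScoreRecord(dmu, period, status)
    lambdas = {d: float(v) for d, v in zip(panel.dmu_ids, lam) if v > SCORE_ATOL}
    return ScoreRecord(dmu, period, status, _farrell(factor, spec.orientation), factor, lambdas)


def solve_multiplier(
    panel: FactorPanel,
    period: str,
    dmu: str,
    spec: ModelSpec,
    *,
    prepared: bool = False,
) -> ScoreRecord:
    """Score one DMU via the multiplier form, honouring weight restrictions.

    With no restrictions this agrees with :func:`solve_radial` by LP duality;
    with restrictions the score is weakly smaller. Restriction-induced
    infeasibility (e.g. a positive floor on a zero-valued output) is flagged
    in the record status.
    """
    _check_spec(panel, spec)
    if not prepared:
        panel = prepare_panel(panel, spec)
    ins, outs = resolve_active(panel, spec)
    X = panel.period_matrix(period, ins)
    Y = panel.period_matrix(period, outs)
    j = panel.dmu_ids.index(dmu)
    shares_out = {outs.index(f): s for f, s in spec.weight_restrictions.items() if f in outs}
    shares_in = {ins.index(f): s for f, s in spec.weight_restrictions.items() if f in ins}
    factor, u, v, status = multiplier_lp(
        X, Y, X[j], Y[j], spec.orientation, spec.rts, shares_out, shares_in
    )
    if factor is None:
        return ScoreRecord(dmu, period, status)
    weights = {**{f: float(w) for f, w in zip(outs, u)}, **{f: float(w) for f, w in zip(ins, v)}}
    return ScoreRecord(dmu, period, status, _farrell(factor, spec.orientation), factor, {}, weights)


def efficiency_table(panel: FactorPanel, spec: ModelSpec) -> EfficiencyTable:
    """Period-by-period radial solve for every DMU, with summary statistics.

    Uses the multiplier form when the spec carries weight restrictions, the
    envelopment form otherwise. LP failures are kept as flagged records.
    """
    _check_spec(panel, spec)
    panel = prepare_panel(panel, spec)
    solver = solve_multiplier if spec.weight_restrictions else solve_radial
    records = [
        solver(panel, period, dmu, spec, prepared=True)
        for period in panel.periods
        for dmu in panel.dmu_ids
    ]
    return EfficiencyTable(spec.label, records)
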