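"""Malmquist productivity index over adjacent periods.

For each DMU and adjacent period pair (t, t+1) the index decomposes
productivity change into catch-up (movement relative to the contemporaneous
frontier) and frontier shift (movement of the frontier itself):

    CU = D_{t+1}(t+1) / D_t(t)
    FS = sqrt[ (D_t(t+1) / D_{t+1}(t+1)) * (D_t(t) / D_{t+1}(t)) ]
    MI = CU * FS

where ``D_a(b)`` is the output-oriented radial distance of the period-b data
point against the period-a frontier, on the Farrell-like scale: own-period
distances lie in (0, 1]; cross-period distances may exceed 1 when the point
sits above the old frontier. MI > 1 means productivity gain.

Distances default to constant returns to scale even when level estimates use
VRS, because VRS cross-period LPs can be infeasible; requesting VRS flags
infeasible rows instead of failing. Bad outputs are transformed per period
with each period's own maximum before any distance is computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dea import prepare_panel, radial_lp, resolve_active, _check_spec
from .panel import FactorPanel, ModelSpec


@dataclass
class MalmquistRecord:
    """MI, catch-up, frontier shift and the four cross-period distances.

    ``d_tt`` is D_t(t), ``d_t_t1`` is D_t(t+1) (period t frontier, period
    t+1 data), ``d_t1_t`` is D_{t+1}(t), ``d_t1_t1`` is D_{t+1}(t+1).
    Infeasible distances are None and leave MI/CU/FS unset.
    """

    dmu: str
    period_from: str
    period_to: str
    mi: float | None
    cu: float | None
    fs: float | None
    d_tt: float | None
    d_t_t1: float | None
    d_t1_t: float | None
    d_t1_t1: float | None

    @property
    def feasible(self) -> bool:
        return None not in (self.d_tt, self.d_t_t1, self.d_t1_t, self.d_t1_t1)


def cross_period_distance(
    panel: FactorPanel,
    spec: ModelSpec,
    frontier_period: str,
    dmu: str,
    data_period: str,
    rts: str = "crs",
    *,
    prepared: bool = False,
) -> float | None:
    """Output distance of one DMU's data against another period's frontier.

    Returns None when the LP is infeasible (possible for VRS cross-period
    evaluation). Own-period distances are <= 1; cross-period values may
    exceed 1.
    """
    _check_spec(panel, spec)
    if not prepared:
        panel = prepare_panel(panel, spec)
    ins, outs = resolve_active(panel, spec)
    Xf = panel.period_matrix(frontier_period, ins)
    Yf = panel.period_matrix(frontier_period, outs)
    j = panel.dmu_ids.index(dmu)
    x0 = panel.period_matrix(data_period, ins)[j]
    y0 = panel.period_matrix(data_period, outs)[j]
    factor, _, status = radial_lp(Xf, Yf, x0, y0, "output", rts)
    if factor is None or factor <= 0:
        return None
    return 1.0 / factor


def malmquist_series(
    panel: FactorPanel,
    spec: ModelSpec,
    rts: str = "crs",
) -> list[MalmquistRecord]:
    """One record per DMU per adjacent period pair; MI = CU * FS when feasible."""
    _check_spec(panel, spec)
    if len(panel.periods) < 2:
        raise ValueError("Malmquist index needs at least 2 periods")
    panel = prepare_panel(panel, spec)
    records: list[MalmquistRecord] = []
    for t, t1 in zip(panel.periods[:-1], panel.periods[1:]):
        for dmu in panel.dmu_ids:
            d_tt = cross_period_distance(panel, spec, t, dmu, t, rts, prepared=True)
            d_t_t1 = cross_period_distance(panel, spec, t, dmu, t1, rts, prepared=True)
            d_t1_t = cross_period_distance(panel, spec, t1, dmu, t, rts, prepared=True)
            d_t1_t1 = cross_period_distance(panel, spec, t1, dmu, t1, rts, prepared=True)
            mi = cu = fs = None
            if None not in (d_tt, d_t_t1, d_t1_t, d_t1_t1):
                cu = d_t1_t1 / d_tt
                fs = math.sqrt((d_t_t1 / d_t1_t1) * (d_tt / d_t1_t))
                mi = cu * fs
            records.append(
                MalmquistRecord(dmu, t, t1, mi, cu, fs, d_tt, d_t_t1, d_t1_t, d_t1_t1)
            )
    return records


def records_frame(records: Sequence[MalmquistRecord]) -> pd.DataFrame:
    """Tabular view: dmu, period pair, MI, CU, FS."""
    return pd.DataFrame(
        {
            "dmu": [r.dmu for r in records],
            "period_from": [r.period_from for r in records],
            "period_to": [r.period_to for r in records],
            "mi": [r.mi for r in records],
            "cu": [r.cu for r in records],
            "fs": [r.fs for r in records],
        }
    )


def frontier_shift_share(records: Sequence[MalmquistRecord]) -> pd.Series:
    """Per DMU: fraction of feasible period pairs where frontier shift dominates.

    A pair counts when |log FS| >= |log CU|, i.e. the frontier movement is at
    least as large (multiplicatively) as the catch-up movement. A share near
    1 supports the reading that efficiency change is technology-driven.
    """
    feasible = [r for r in records if r.feasible]
    if not feasible:
        raise ValueError("no feasible Malmquist records")
    rows: dict[str, list[bool]] = {}
    for r in feasible:
        rows.setdefault(r.dmu, []).append(abs(math.log(r.fs)) >= abs(math.log(r.cu)))
    return pd.Series({d: float(np.mean(v)) for d, v in rows.items()}, name="fs_share")
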