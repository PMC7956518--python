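"""DEA window analysis over the pooled DMU-period panel.

A window of width ``w`` pools ``w`` consecutive periods into one reference
set in which every DMU-period observation is a distinct evaluation unit —
including a DMU's own observations from the other periods of the window.
Sliding the window by one period yields ``T - w + 1`` windows; a period's
score is averaged over the windows that contain it, and a DMU's overall mean
is the mean of those per-period averages.

``w = 1`` collapses to independent per-period frontiers; ``w = T`` collapses
to a single pooled frontier. For bad outputs, the max-minus-value transform
is computed within each window over all pooled DMU-periods.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dea import radial_lp, resolve_active, _check_spec
from .panel import BAD, FactorPanel, ModelSpec


@dataclass
class WindowResult:
    """Score cube and averages of one window analysis run.

    ``cube`` has one row per (dmu, period, window) evaluation;
    ``period_averages`` is the DMU x period matrix of scores averaged over
    containing windows; ``dmu_means`` averages those per-period values.
    """

    w: int
    windows: tuple[tuple[str, ...], ...]
    cube: pd.DataFrame
    period_averages: pd.DataFrame
    dmu_means: pd.Series

    def table(self) -> pd.DataFrame:
        """Periods x DMUs matrix plus a Mean column."""
        out = self.period_averages.copy()
        out["Mean"] = self.dmu_means
        return out


def build_windows(periods: Sequence[str], w: int) -> list[tuple[str, ...]]:
    """Sliding windows of ``w`` consecutive periods, stride 1."""
    T = len(periods)
    if not (1 <= w <= T):
        raise ValueError(f"window width {w} out of range 1..{T}")
    return [tuple(periods[i : i + w]) for i in range(T - w + 1)]


def window_efficiencies(panel: FactorPanel, spec: ModelSpec, w: int) -> WindowResult:
    """Score every DMU-period within each window containing it.

    LP failures are kept as NaN cells in the cube and ignored by the
    averages.
    """
    _check_spec(panel, spec)
    ins, outs = resolve_active(panel, spec)
    windows = build_windows(panel.periods, w)
    dmus = list(panel.dmu_ids)
    bad_outs = [fid for fid in outs if panel.factor(fid).desirability == BAD]
    rows = []
    for widx, win in enumerate(windows):
        # pooled units: (dmu, period) for every period of the window
        units = [(d, p) for p in win for d in dmus]
        X = np.vstack([panel.period_matrix(p, ins) for p in win])
        Y = np.vstack([panel.period_matrix(p, outs) for p in win])
        for fid in bad_outs:
            # transform against the pooled window maximum
            k = outs.index(fid)
            Y[:, k] = Y[:, k].max() - Y[:, k]
        for u, (d, p) in enumerate(units):
            factor, _, status = radial_lp(X, Y, X[u], Y[u], spec.orientation, spec.rts)
            score = np.nan
            if factor is not None:
                score = 1.0 / factor if spec.orientation == "output" else factor
            rows.append({"dmu": d, "period": p, "window": widx, "score": score, "status": status})
    cube = pd.DataFrame(rows)
    avg = (
        cube.pivot_table(index="dmu", columns="period", values="score", aggfunc="mean")
        .reindex(index=dmus, columns=list(panel.periods))
    )
    means = avg.mean(axis=1)
    means.name = "mean"
    return WindowResult(w, tuple(windows), cube, avg, means)
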