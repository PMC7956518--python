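"""Factor engineering: bad-output transform, screening, exclusions, catalogs.

Covers the bespoke data-preparation steps of the efficiency pipeline:

* the reciprocal transform for undesirable outputs — per period, each DMU's
  value becomes ``max over DMUs - own value``, so the worst DMU lands at
  exactly 0 and "more" of the transformed factor is better;
* pooled Pearson cross-correlation screening of factors (report-only);
* the size-heterogeneity exclusion rule that drops DMUs whose input dwarfs
  the period minimum (very large funders distort a small reference set);
* the two fixed modification catalogs: six national-model variants
  (factor drops and 5/10/15% virtual-weight floors on O3) and eight
  NGO-model variants crossing CCR/BCC x factor set x orientation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .panel import BAD, GOOD, ROLE_INPUT, ROLE_OUTPUT, FactorDef, FactorPanel, ModelSpec


@dataclass
class TransformLog:
    """Record of one reciprocal bad-output transform.

    ``per_period`` maps each period to ``(max_value_used, transformed_series)``
    where the series is indexed by DMU. Absent ties, exactly one DMU per
    period transforms to 0 (the one at the period maximum).
    """

    factor_id: str
    method: str
    per_period: dict[str, tuple[float, pd.Series]] = field(default_factory=dict)


@dataclass
class ExclusionReport:
    """Outcome of the input-heterogeneity exclusion rule.

    ``ratios`` is a DMU x period matrix of input value over the period
    minimum (>= 1 by construction); DMUs exceeding the threshold in any
    period are listed in ``excluded``.
    """

    ratios: pd.DataFrame
    threshold: float
    excluded: tuple[str, ...]


@dataclass
class CorrelationReport:
    """Pairwise Pearson correlations of factors pooled over DMU-periods."""

    matrix: pd.DataFrame
    threshold: float
    flagged: tuple[tuple[str, str], ...]
    degenerate: tuple[str, ...]

    @property
    def max_abs(self) -> float:
        """Largest off-diagonal |r| over defined pairs (NaN if none defined)."""
        vals = self.matrix.to_numpy(dtype=float).copy()
        np.fill_diagonal(vals, np.nan)
        return float(np.nanmax(np.abs(vals))) if np.isfinite(vals).any() else float("nan")


def reciprocal_bad_output(panel: FactorPanel, factor_id: str) -> tuple[FactorPanel, TransformLog]:
    """Turn a bad output into a good one via the per-period max-minus-value rule.

    For each period t: ``value'(n, t) = max_j value(j, t) - value(n, t)``.
    The factor's desirability flips to good; all transformed values are >= 0
    and the period-maximum DMU lands at exactly 0 (no epsilon shift — the
    envelopment LP tolerates zero outputs).
    """
    fdef = panel.factor(factor_id)
    if fdef.role != ROLE_OUTPUT or fdef.desirability != BAD:
        raise ValueError(f"factor {factor_id!r} is not a bad-desirability output")
    values = panel.values.copy()
    log = TransformLog(factor_id, method="max-minus-value")
    col = values[factor_id]
    for period in panel.periods:
        sub = col.xs(period, level="period")
        mx = float(sub.max())
        transformed = mx - sub
        values.loc[pd.IndexSlice[:, period], factor_id] = transformed.to_numpy()
        log.per_period[period] = (mx, transformed)
    new_factors = tuple(
        FactorDef(f.factor_id, f.role, GOOD, f.units) if f.factor_id == factor_id else f
        for f in panel.factors
    )
    return panel.with_values(values, new_factors), log


def screen_correlations(panel: FactorPanel, threshold: float = 0.8) -> CorrelationReport:
    """Pearson correlations over pooled DMU-period observations.

    Pairs with |r| >= threshold are flagged; constant factors have undefined
    correlations and are reported as degenerate rather than failed. The
    screening never drops factors — it is report-only.
    """
    if len(panel.values) < 3:
        raise ValueError("need at least 3 pooled observations per factor pair")
    data = panel.values
    degenerate = tuple(fid for fid in panel.factor_ids if data[fid].nunique() <= 1)
    mat = data.corr(method="pearson")
    flagged = []
    ids = list(panel.factor_ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            r = mat.loc[a, b]
            if np.isfinite(r) and abs(r) >= threshold:
                flagged.append((a, b))
    return CorrelationReport(mat, threshold, tuple(flagged), degenerate)


def exclude_heterogeneous_dmus(
    panel: FactorPanel,
    input_factor: str,
    ratio_threshold: float = 10.0,
) -> tuple[FactorPanel, ExclusionReport]:
    """Drop DMUs whose input exceeds ``ratio_threshold`` x the period minimum.

    The ratio matrix (input over contemporaneous minimum) is reported for all
    DMUs. Exclusion is monotone in the threshold: a larger threshold removes
    a subset of the DMUs a smaller one would. Raising the threshold to
    infinity keeps the panel untouched.
    """
    fdef = panel.factor(input_factor)
    if fdef.role != ROLE_INPUT:
        raise ValueError(f"factor {input_factor!r} is not an input")
    col = panel.values[input_factor].unstack("period")[list(panel.periods)].loc[list(panel.dmu_ids)]
    ratios = col.div(col.min(axis=0), axis=1)
    excluded = tuple(d for d in panel.dmu_ids if (ratios.loc[d] > ratio_threshold).any())
    report = ExclusionReport(ratios, ratio_threshold, excluded)
    keep = [d for d in panel.dmu_ids if d not in excluded]
    if not keep:
        raise ValueError("exclusion rule would remove every DMU")
    return panel.subset_dmus(keep), report


_NATIONAL_ALL = ("I1", "I2", "I3", "O1", "O2", "O3", "O4", "O5")


def modification_catalog(schema: str) -> list[ModelSpec]:
    """The fixed model-modification catalogs for the two case-study schemas.

    ``national``: six output-oriented specs — I uses all factors; II drops
    the HIV-related factors I1, O1, O2; III drops the infrastructure outputs
    O4, O5; IV-VI use all factors with a minimum virtual-weight share of
    5/10/15% on O3 (life expectancy).

    ``ngo``: eight specs crossing {CCR, BCC} x {with O3, without O3} x
    {input, output} orientation; VIII is BCC, output-oriented, on I1, O1, O2.
    """
    if schema == "national":
        return [
            ModelSpec("I", "output", "vrs", _NATIONAL_ALL),
            ModelSpec("II", "output", "vrs", ("I2", "I3", "O3", "O4", "O5")),
            ModelSpec("III", "output", "vrs", ("I1", "I2", "I3", "O1", "O2", "O3")),
            ModelSpec("IV", "output", "vrs", _NATIONAL_ALL, {"O3": 0.05}),
            ModelSpec("V", "output", "vrs", _NATIONAL_ALL, {"O3": 0.10}),
            ModelSpec("VI", "output", "vrs", _NATIONAL_ALL, {"O3": 0.15}),
        ]
    if schema == "ngo":
        four = ("I1", "O1", "O2", "O3")
        three = ("I1", "O1", "O2")
        return [
            ModelSpec("I", "input", "crs", four),
            ModelSpec("II", "input", "vrs", four),
            ModelSpec("III", "input", "crs", three),
            ModelSpec("IV", "input", "vrs", three),
            ModelSpec("V", "output", "crs", four),
            ModelSpec("VI", "output", "vrs", four),
            ModelSpec("VII", "output", "crs", three),
            ModelSpec("VIII", "output", "vrs", three),
        ]
    raise ValueError(f"unknown schema {schema!r}; expected 'national' or 'ngo'")
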