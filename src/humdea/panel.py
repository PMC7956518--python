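"""Panel data model and delimited-text I/O.

The central container is :class:`FactorPanel`: a DMU x period x factor cube of
nonnegative values, where each factor carries a role (``input`` / ``output``)
and a desirability (``good`` / ``bad``; a bad output, such as disease deaths,
is one where larger values are worse). Every downstream stage — radial DEA,
bootstrapping, Malmquist decomposition, window analysis — consumes this type.

Files are plain UTF-8 CSV. The canonical layout is *long*::

    dmu,period,factor,value

optionally extended with ``role``, ``desirability`` and ``units`` columns so
that factor metadata round-trips. A *wide* layout (one column per factor) is
supported for convenience. Periods are opaque ordered labels ("2002",
"Q3-2017"); their chronology is the order of first appearance in the file,
never parsed dates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

ROLE_INPUT = "input"
ROLE_OUTPUT = "output"
GOOD = "good"
BAD = "bad"


class PanelError(ValueError):
    """Base class for panel-related failures."""


class PanelParseError(PanelError):
    """A cell could not be parsed as a number."""


class PanelConflictError(PanelError):
    """The same (dmu, period, factor) cell appears more than once."""


class PanelValidationError(PanelError):
    """A structural invariant of the panel is violated."""


@dataclass(frozen=True)
class FactorDef:
    """Definition of one factor (column) of the panel.

    Parameters
    ----------
    factor_id:
        Unique label, e.g. ``"I1"`` or ``"O3"``.
    role:
        ``"input"`` or ``"output"``.
    desirability:
        ``"good"`` (default) or ``"bad"``. Only output factors may be bad;
        a bad output (e.g. deaths) is turned into a good one by the
        per-period max-minus-value transform in :mod:`humdea.factors`.
    units:
        Free-text unit annotation, used by the Dyson-style validation
        warnings (mixing index-type and volume-type factors).
    """

    factor_id: str
    role: str
    desirability: str = GOOD
    units: str = ""

    def __post_init__(self) -> None:
        if self.role not in (ROLE_INPUT, ROLE_OUTPUT):
            raise PanelValidationError(
                f"factor {self.factor_id!r}: role must be 'input' or 'output', got {self.role!r}"
            )
        if self.desirability not in (GOOD, BAD):
            raise PanelValidationError(
                f"factor {self.factor_id!r}: desirability must be 'good' or 'bad'"
            )
        if self.role == ROLE_INPUT and self.desirability == BAD:
            raise PanelValidationError(
                f"factor {self.factor_id!r}: bad desirability is only defined for outputs"
            )


@dataclass(frozen=True)
class ModelSpec:
    """One named DEA model configuration.

    ``orientation`` selects proportional input contraction (``"input"``) or
    output expansion (``"output"``); ``rts`` selects constant (``"crs"``,
    the CCR model) or variable (``"vrs"``, the BCC model) returns to scale.
    ``weight_restrictions`` maps factor ids to minimum virtual-weight shares
    in [0, 1), enforced in the multiplier form.
    """

    label: str
    orientation: str = "output"
    rts: str = "vrs"
    active_factors: tuple[str, ...] = ()
    weight_restrictions: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.orientation not in ("input", "output"):
            raise PanelValidationError(f"orientation must be 'input' or 'output', got {self.orientation!r}")
        if self.rts not in ("crs", "vrs"):
            raise PanelValidationError(f"rts must be 'crs' or 'vrs', got {self.rts!r}")
        object.__setattr__(self, "active_factors", tuple(self.active_factors))
        object.__setattr__(self, "weight_restrictions", dict(self.weight_restrictions))


@dataclass
class Violation:
    """One defect found by :func:`validate_spec`; severity 'error' or 'warning'."""

    severity: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.severity}: {self.message}"


class FactorPanel:
    """A validated DMU x period x factor value cube.

    Values are stored as a DataFrame indexed by (dmu, period) with one column
    per factor. DMU, period and factor orders are preserved as declared;
    period order is the panel's chronology.
    """

    def __init__(
        self,
        dmu_ids: Sequence[str],
        periods: Sequence[str],
        factors: Sequence[FactorDef],
        values: pd.DataFrame,
    ) -> None:
        self.dmu_ids: tuple[str, ...] = tuple(str(d) for d in dmu_ids)
        self.periods: tuple[str, ...] = tuple(str(p) for p in periods)
        self.factors: tuple[FactorDef, ...] = tuple(factors)
        idx = pd.MultiIndex.from_product([self.dmu_ids, self.periods], names=["dmu", "period"])
        self.values = values.reindex(index=idx, columns=[f.factor_id for f in self.factors])
        self.validate()

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_records(
        cls,
        records: pd.DataFrame,
        factors: Sequence[FactorDef] | None = None,
    ) -> "FactorPanel":
        """Build a panel from a long-form frame with dmu/period/factor/value columns."""
        required = {"dmu", "period", "factor", "value"}
        missing = required - set(records.columns)
        if missing:
            raise PanelParseError(f"long layout requires columns {sorted(required)}; missing {sorted(missing)}")
        rec = records.copy()
        for col in ("dmu", "period", "factor"):
            rec[col] = rec[col].astype(str)
        value = pd.to_numeric(rec["value"], errors="coerce")
        unparsed = value.isna() & rec["value"].notna()
        if unparsed.any():
            bad = rec.loc[unparsed].iloc[0]
            raise PanelParseError(
                f"non-numeric value {bad['value']!r} at (dmu={bad['dmu']}, period={bad['period']}, factor={bad['factor']})"
            )
        rec["value"] = value
        dup = rec.duplicated(subset=["dmu", "period", "factor"], keep=False)
        if dup.any():
            first = rec.loc[dup].iloc[0]
            raise PanelConflictError(
                f"duplicate cell (dmu={first['dmu']}, period={first['period']}, factor={first['factor']})"
            )
        dmu_ids = list(dict.fromkeys(rec["dmu"]))
        periods = list(dict.fromkeys(rec["period"]))
        factor_ids = list(dict.fromkeys(rec["factor"]))
        if factors is None:
            factors = [_infer_factor(rec, fid) for fid in factor_ids]
        else:
            known = [f.factor_id for f in factors]
            unknown = set(factor_ids) - set(known)
            if unknown:
                raise PanelValidationError(f"file contains undeclared factors {sorted(unknown)}")
            factors = [f for f in factors if f.factor_id in factor_ids]
        wide = rec.pivot(index=["dmu", "period"], columns="factor", values="value")
        return cls(dmu_ids, periods, factors, wide)

    def to_records(self, include_metadata: bool = True) -> pd.DataFrame:
        """Long-form frame; inverse of :meth:`from_records`."""
        long = self.values.stack().rename("value").reset_index()
        long.columns = ["dmu", "period", "factor", "value"]
        order = {f.factor_id: i for i, f in enumerate(self.factors)}
        long["_f"] = long["factor"].map(order)
        long["_d"] = long["dmu"].map({d: i for i, d in enumerate(self.dmu_ids)})
        long["_p"] = long["period"].map({p: i for i, p in enumerate(self.periods)})
        long = long.sort_values(["_d", "_p", "_f"]).drop(columns=["_d", "_p", "_f"]).reset_index(drop=True)
        if include_metadata:
            meta = {f.factor_id: f for f in self.factors}
            long["role"] = long["factor"].map(lambda fid: meta[fid].role)
            long["desirability"] = long["factor"].map(lambda fid: meta[fid].desirability)
            long["units"] = long["factor"].map(lambda fid: meta[fid].units)
        return long

    # -- accessors ------------------------------------------------------------

    @property
    def factor_ids(self) -> tuple[str, ...]:
        return tuple(f.factor_id for f in self.factors)

    @property
    def input_factors(self) -> tuple[FactorDef, ...]:
        return tuple(f for f in self.factors if f.role == ROLE_INPUT)

    @property
    def output_factors(self) -> tuple[FactorDef, ...]:
        return tuple(f for f in self.factors if f.role == ROLE_OUTPUT)

    def factor(self, factor_id: str) -> FactorDef:
        for f in self.factors:
            if f.factor_id == factor_id:
                return f
        raise KeyError(factor_id)

    def value(self, dmu: str, period: str, factor_id: str) -> float:
        return float(self.values.loc[(dmu, period), factor_id])

    def period_matrix(self, period: str, factor_ids: Sequence[str]) -> np.ndarray:
        """(n_dmu, len(factor_ids)) array for one period, rows ordered by dmu_ids."""
        sub = self.values.xs(period, level="period")
        return sub.loc[list(self.dmu_ids), list(factor_ids)].to_numpy(dtype=float)

    def with_values(self, values: pd.DataFrame, factors: Sequence[FactorDef] | None = None) -> "FactorPanel":
        return FactorPanel(self.dmu_ids, self.periods, factors or self.factors, values)

    def subset_dmus(self, keep: Iterable[str]) -> "FactorPanel":
        keep = [d for d in self.dmu_ids if d in set(keep)]
        vals = self.values.loc[pd.IndexSlice[keep, :], :]
        return FactorPanel(keep, self.periods, self.factors, vals)

    # -- validation -----------------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`PanelValidationError` naming the first defect found."""
        if not self.dmu_ids:
            raise PanelValidationError("panel has no DMUs")
        if not self.periods:
            raise PanelValidationError("panel has no periods")
        if len(set(self.dmu_ids)) != len(self.dmu_ids):
            raise PanelValidationError("duplicate DMU labels")
        if len(set(self.periods)) != len(self.periods):
            raise PanelValidationError("duplicate period labels")
        ids = [f.factor_id for f in self.factors]
        if len(set(ids)) != len(ids):
            raise PanelValidationError("duplicate factor ids")
        if not self.input_factors or not self.output_factors:
            raise PanelValidationError("panel needs at least one input and one output factor")
        arr = self.values.to_numpy(dtype=float)
        bad_cells = ~np.isfinite(arr)
        if bad_cells.any():
            i, j = np.argwhere(bad_cells)[0]
            dmu, period = self.values.index[i]
            raise PanelValidationError(
                f"missing or non-finite value at (dmu={dmu}, period={period}, factor={self.values.columns[j]})"
            )
        for f in self.factors:
            col = self.values[f.factor_id].to_numpy(dtype=float)
            if f.role == ROLE_INPUT:
                if (col <= 0).any():
                    i = int(np.argmax(col <= 0))
                    dmu, period = self.values.index[i]
                    raise PanelValidationError(
                        f"input factor {f.factor_id!r} must be strictly positive; "
                        f"offending cell (dmu={dmu}, period={period}, factor={f.factor_id})"
                    )
            else:
                if (col < 0).any():
                    i = int(np.argmax(col < 0))
                    dmu, period = self.values.index[i]
                    raise PanelValidationError(
                        f"output factor {f.factor_id!r} must be nonnegative; "
                        f"offending cell (dmu={dmu}, period={period}, factor={f.factor_id})"
                    )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FactorPanel):
            return NotImplemented
        return (
            self.dmu_ids == other.dmu_ids
            and self.periods == other.periods
            and self.factors == other.factors
            and self.values.equals(other.values)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"FactorPanel({len(self.dmu_ids)} DMUs x {len(self.periods)} periods x "
            f"{len(self.factors)} factors)"
        )


def _infer_factor(rec: pd.DataFrame, fid: str) -> FactorDef:
    """Factor metadata from optional columns, else role inferred from the id prefix."""
    sub = rec.loc[rec["factor"] == fid]
    if "role" in rec.columns:
        role = str(sub["role"].iloc[0])
    else:
        role = ROLE_INPUT if fid.upper().startswith("I") else ROLE_OUTPUT
    desirability = str(sub["desirability"].iloc[0]) if "desirability" in rec.columns else GOOD
    units = str(sub["units"].iloc[0]) if "units" in rec.columns else ""
    if units == "nan":
        units = ""
    return FactorDef(fid, role, desirability, units)


def read_panel(
    path: str | Path,
    layout: str = "long",
    factors: Sequence[FactorDef] | None = None,
) -> FactorPanel:
    """Read a delimited panel file.

    Long layout requires columns ``dmu,period,factor,value`` (plus optional
    ``role,desirability,units``); wide layout requires ``dmu,period`` plus one
    column per factor. When no metadata is present, factor roles are inferred
    from the id prefix (``I*`` = input, anything else = output).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if layout == "long":
        raw = pd.read_csv(path, dtype={"dmu": str, "period": str, "factor": str})
        panel = FactorPanel.from_records(raw, factors=factors)
    elif layout == "wide":
        raw = pd.read_csv(path, dtype={"dmu": str, "period": str})
        for col in ("dmu", "period"):
            if col not in raw.columns:
                raise PanelParseError(f"wide layout requires a {col!r} column")
        # melt preserves row order within each factor block, so first-appearance
        # order of dmu/period/factor matches the file
        long = raw.melt(id_vars=["dmu", "period"], var_name="factor", value_name="value")
        panel = FactorPanel.from_records(long, factors=factors)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    # missing cells surface as NaN after the pivot; validate() names the triple
    return panel


def write_panel(panel: FactorPanel, path: str | Path, layout: str = "long") -> Path:
    """Write a panel as CSV; the result re-reads to an identical panel."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if layout == "long":
        panel.to_records(include_metadata=True).to_csv(path, index=False)
    elif layout == "wide":
        wide = panel.values.reset_index()
        wide.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    return path


def validate_spec(spec: ModelSpec, panel: FactorPanel) -> list[Violation]:
    """Check that a model spec is runnable on a panel.

    Returns an empty list iff the spec can be solved on the panel. Dyson-style
    unit-mixing defects (an index/percentage factor next to volume measures)
    are reported with severity ``"warning"`` and do not block a run.
    """
    out: list[Violation] = []
    known = set(panel.factor_ids)
    active = list(spec.active_factors) if spec.active_factors else list(panel.factor_ids)
    for fid in active:
        if fid not in known:
            out.append(Violation("error", f"active factor {fid!r} is not in the panel"))
    present = [fid for fid in active if fid in known]
    roles = {fid: panel.factor(fid).role for fid in present}
    if not any(r == ROLE_INPUT for r in roles.values()):
        out.append(Violation("error", "spec has no active input factor"))
    if not any(r == ROLE_OUTPUT for r in roles.values()):
        out.append(Violation("error", "spec has no active output factor"))
    for fid, share in spec.weight_restrictions.items():
        if fid not in active:
            out.append(Violation("error", f"weight restriction on inactive factor {fid!r}"))
        if not (0.0 <= share < 1.0):
            out.append(Violation("error", f"weight share for {fid!r} must be in [0, 1), got {share}"))
    total = sum(spec.weight_restrictions.values())
    if total >= 1.0:
        out.append(Violation("error", f"weight shares sum to {total:.3f} >= 1"))
    # Dyson et al. style unit screening: indices/percentages mixed with volumes
    index_markers = ("%", "percent", "index", "years", "per capita")
    units = {fid: panel.factor(fid).units.lower() for fid in present}
    idx_like = [fid for fid, u in units.items() if u and any(m in u for m in index_markers)]
    vol_like = [fid for fid, u in units.items() if u and not any(m in u for m in index_markers)]
    if idx_like and vol_like:
        out.append(
            Violation(
                "warning",
                "mixing index-type factors "
                f"{idx_like} with volume-type factors {vol_like} can distort radial scores",
            )
        )
    return out


def spec_errors(violations: Iterable[Violation]) -> list[Violation]:
    """Just the blocking violations (severity 'error')."""
    return [v for v in violations if v.severity == "error"]
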