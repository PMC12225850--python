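"""Lipid-panel data model, derived quantities, eligibility filtering, and
NCEP-ATP III categorization.

All concentrations are in mg/dL. A cohort is a :class:`pandas.DataFrame`
with columns ``id, tc, hdl_c, tg`` and optionally ``ldl_d`` (directly
measured LDL-C, absent for estimation-only inputs). Derived columns are

``non_hdl``
    total cholesterol minus HDL-C (the cholesterol carried by all
    atherogenic particles),
``vldl_c``
    non-HDL-C minus directly measured LDL-C,
``tg_vldl_ratio``
    triglycerides over VLDL-C; undefined (NaN) when ``vldl_c <= 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LipidPanel",
    "DerivedPanel",
    "ExclusionReport",
    "NCEP_BOUNDS",
    "NCEP_LABELS",
    "REQUIRED_COLS",
    "derive_panel",
    "add_derived",
    "filter_eligible",
    "ncep_category",
    "ncep_categories",
    "read_cohort",
    "write_cohort",
    "round_half_up",
]

REQUIRED_COLS = ("tc", "hdl_c", "tg")

#: Guideline LDL-C treatment-band cut points, mg/dL. Intervals are
#: half-open [lo, hi): exactly 100 mg/dL falls in "100-129".
NCEP_BOUNDS = (70.0, 100.0, 130.0, 160.0, 190.0)
NCEP_LABELS = ("<70", "70-99", "100-129", "130-159", "160-189", ">=190")


class InputError(ValueError):
    """A required field is missing or unpaired."""


class ValidationError(ValueError):
    """A value violates a domain invariant (negative, non-finite, ...)."""


@dataclass(frozen=True)
class LipidPanel:
    """One individual's fasting lipid panel (mg/dL)."""

    id: object
    tc: float
    hdl_c: float
    tg: float
    ldl_d: Optional[float] = None

    def __post_init__(self) -> None:
        for name in REQUIRED_COLS:
            v = getattr(self, name)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                raise InputError(f"missing required field: {name}")
            if not math.isfinite(v):
                raise ValidationError(f"non-finite {name}: {v}")
            if v < 0:
                raise ValidationError(f"negative concentration {name}: {v}")
        if self.ldl_d is not None and self.ldl_d < 0:
            raise ValidationError(f"negative concentration ldl_d: {self.ldl_d}")


@dataclass(frozen=True)
class DerivedPanel:
    """Quantities derived from a :class:`LipidPanel`.

    ``tg_vldl_ratio`` is None (flagged undefined) when VLDL-C <= 0.
    """

    non_hdl: float
    vldl_c: Optional[float] = None
    tg_vldl_ratio: Optional[float] = None


def derive_panel(panel: LipidPanel) -> DerivedPanel:
    """Compute non-HDL-C, VLDL-C and the TG/VLDL-C ratio for one panel.

    non-HDL-C = TC - HDL-C; VLDL-C = non-HDL-C - LDL-C (measured); the
    ratio TG/VLDL-C is undefined when VLDL-C <= 0.
    """
    non_hdl = panel.tc - panel.hdl_c
    if panel.ldl_d is None:
        return DerivedPanel(non_hdl=non_hdl)
    vldl_c = non_hdl - panel.ldl_d
    ratio = panel.tg / vldl_c if vldl_c > 0 else None
    return DerivedPanel(non_hdl=non_hdl, vldl_c=vldl_c, tg_vldl_ratio=ratio)


def add_derived(cohort: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`derive_panel`: return a copy with derived columns.

    Adds ``non_hdl`` always; ``vldl_c`` and ``tg_vldl_ratio`` when the
    cohort carries measured LDL-C. Rows with ``vldl_c <= 0`` get NaN in
    ``tg_vldl_ratio``.
    """
    for name in REQUIRED_COLS:
        if name not in cohort.columns:
            raise InputError(f"missing required column: {name}")
    out = cohort.copy()
    out["non_hdl"] = out["tc"] - out["hdl_c"]
    if "ldl_d" in out.columns:
        out["vldl_c"] = out["non_hdl"] - out["ldl_d"]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = out["tg"] / out["vldl_c"]
        out["tg_vldl_ratio"] = ratio.where(out["vldl_c"] > 0)
    return out


@dataclass
class ExclusionReport:
    """Counts of rows dropped by :func:`filter_eligible`, by reason."""

    n_input: int = 0
    n_missing: int = 0
    n_negative: int = 0
    n_tg_high: int = 0
    n_kept: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def filter_eligible(
    cohort: pd.DataFrame, tg_max: float = 400.0
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Keep rows with complete required fields, non-negative values and
    TG strictly below ``tg_max`` (TG >= 400 mg/dL is excluded, mirroring
    the Friedewald validity restriction).

    Empty input yields an empty cohort with zero counts, not an error.
    """
    report = ExclusionReport(n_input=len(cohort))
    if len(cohort) == 0:
        return cohort.copy(), report
    for name in REQUIRED_COLS:
        if name not in cohort.columns:
            raise InputError(f"missing required column: {name}")
    req = cohort[list(REQUIRED_COLS)]
    missing = req.isna().any(axis=1)
    negative = (req < 0).any(axis=1) & ~missing
    if "ldl_d" in cohort.columns:
        negative |= (cohort["ldl_d"] < 0).fillna(False) & ~missing
    tg_high = ~missing & ~negative & (cohort["tg"] >= tg_max)
    keep = ~(missing | negative | tg_high)
    report.n_missing = int(missing.sum())
    report.n_negative = int(negative.sum())
    report.n_tg_high = int(tg_high.sum())
    report.n_kept = int(keep.sum())
    return cohort.loc[keep].copy(), report


def ncep_category(ldl: float) -> int:
    """Ordinal NCEP-ATP III category (0-5) of an LDL-C value in mg/dL.

    Bands: <70, 70-99, 100-129, 130-159, 160-189, >=190, half-open on
    continuous values with no rounding. Negative estimates (possible at
    high TG) map to category 0.
    """
    if not math.isfinite(ldl):
        raise ValidationError(f"non-finite LDL-C: {ldl}")
    return int(np.searchsorted(NCEP_BOUNDS, ldl, side="right"))


def ncep_categories(ldl: Sequence[float]) -> np.ndarray:
    """Vectorized :func:`ncep_category`."""
    arr = np.asarray(ldl, dtype=float)
    if not np.isfinite(arr).all():
        raise ValidationError("non-finite LDL-C value in input")
    return np.searchsorted(NCEP_BOUNDS, arr, side="right").astype(np.int64)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV (``id,tc,hdl_c,tg[,ldl_d]``, UTF-8, decimal point)."""
    df = pd.read_csv(path)
    for name in REQUIRED_COLS:
        if name not in df.columns:
            raise InputError(f"cohort file missing required column: {name}")
    return df


def write_cohort(cohort: pd.DataFrame, path, derived: bool = False) -> None:
    """Write a cohort CSV in the same dialect; with ``derived=True`` the
    derived columns ``non_hdl, vldl_c, tg_vldl_ratio`` are appended."""
    out = add_derived(cohort) if derived else cohort
    out.to_csv(path, index=False)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, the convention of printed clinical tables
    (79.55 -> 79.6), unlike banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
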