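"""LDL-C estimation equations and the ratio-table file format they consume.

Both estimators share one form

    LDL-C = non-HDL-C - TG / AF        (all in mg/dL)

where AF is the TG/VLDL-C "adjustable factor". Friedewald fixes AF = 5
everywhere; the Martin-Hopkins family looks AF up in a strata-specific
table (median or concordance-optimal per cell). Negative estimates are
flagged, never clipped.

Ratio-table files are JSON: ``{"scheme": {...}, "statistic": ..., "cells":
[{tg_lo, tg_hi, nonhdl_lo, nonhdl_hi, af, n, ci_lo, ci_hi, acl}, ...]}``
with open non-HDL-C bounds encoded as null. For derived tables
(statistic median/optimal) ``af`` is serialized as a decimal string with
one fractional digit — the grid resolution — so round-trips are
bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core import InputError, add_derived
from .strata import CellId, StratScheme, assign_cells

__all__ = [
    "RatioCell",
    "RatioTable",
    "SchemaError",
    "TableIntegrityError",
    "FRIEDEWALD_AF",
    "fixed_ratio_table",
    "estimate_friedewald",
    "estimate_martin_hopkins",
    "read_ratio_table",
    "write_ratio_table",
    "read_scheme",
    "write_scheme",
    "method_label",
]

FRIEDEWALD_AF = 5.0


class SchemaError(ValueError):
    pass


class TableIntegrityError(ValueError):
    pass


@dataclass
class RatioCell:
    """Per-cell adjustable factor with derivation metadata."""

    af: float
    n: Optional[int] = None
    ci_lo: Optional[float] = None
    ci_hi: Optional[float] = None
    acl: Optional[float] = None
    tie: bool = False


@dataclass
class RatioTable:
    """Per-cell AF lookup over a stratification scheme.

    ``statistic`` is one of ``fixed`` (any positive AF, e.g. the
    Friedewald 5), ``median`` or ``optimal`` (derived; AF on the
    [1.0, 10.0] grid).
    """

    scheme: StratScheme
    statistic: str
    cells: dict = field(default_factory=dict)  # CellId -> RatioCell

    def __post_init__(self):
        if self.statistic not in ("fixed", "median", "optimal"):
            raise SchemaError(f"unknown statistic {self.statistic!r}")
        for cid, cell in self.cells.items():
            if not cell.af > 0:
                raise TableIntegrityError(f"af must be positive in cell {cid}")
            if self.statistic != "fixed" and not (1.0 <= cell.af <= 10.0):
                raise TableIntegrityError(
                    f"derived af {cell.af} outside [1.0, 10.0] in cell {cid}"
                )

    def af_array(self, cohort: pd.DataFrame) -> np.ndarray:
        """Resolve the AF for every cohort row via cell assignment."""
        idx = assign_cells(cohort, self.scheme)
        missing = [
            cid
            for cid in map(
                lambda t: CellId(int(t[0]), int(t[1])),
                idx.itertuples(index=False),
            )
            if cid not in self.cells
        ]
        if missing:
            raise TableIntegrityError(f"table missing cells: {sorted(set(missing))[:5]}")
        return np.array(
            [self.cells[CellId(int(i), int(j))].af for i, j in idx.itertuples(index=False)]
        )


def fixed_ratio_table(scheme: StratScheme, af: float = FRIEDEWALD_AF) -> RatioTable:
    """A constant-AF table over ``scheme`` (AF=5 reproduces Friedewald)."""
    return RatioTable(
        scheme=scheme,
        statistic="fixed",
        cells={cid: RatioCell(af=float(af)) for cid, _ in scheme.cells()},
    )


def _require(cohort: pd.DataFrame, cols) -> None:
    for c in cols:
        if c not in cohort.columns:
            raise InputError(f"missing required column: {c}")
        if cohort[c].isna().any():
            raise InputError(f"missing values in column: {c}")


def estimate_friedewald(cohort: pd.DataFrame) -> pd.Series:
    """Friedewald LDL-C: (TC - HDL-C) - TG/5, mg/dL.

    Computed as non-HDL-C minus TG/5 so it is bit-identical to a
    Martin-Hopkins lookup with constant AF=5.
    """
    _require(cohort, ("tc", "hdl_c", "tg"))
    non_hdl = cohort["tc"] - cohort["hdl_c"]
    return (non_hdl - cohort["tg"] / FRIEDEWALD_AF).rename("ldl_f")


def estimate_martin_hopkins(cohort: pd.DataFrame, table: RatioTable) -> pd.Series:
    """Martin-Hopkins-form LDL-C: non-HDL-C - TG/AF(cell), mg/dL.

    The AF is resolved per row from ``table``; negative estimates are
    possible at high TG and left unclipped (flag downstream via ``< 0``).
    """
    _require(cohort, ("tc", "hdl_c", "tg"))
    af = table.af_array(cohort)
    non_hdl = cohort["tc"] - cohort["hdl_c"]
    return (non_hdl - cohort["tg"] / af).rename("ldl_mh")


def method_label(statistic: str, scheme: StratScheme, source: str = "K") -> str:
    """Method label in the field's subscript convention.

    ``LDL-C_F`` for the fixed Friedewald ratio; ``LDL-C_KM-N`` /
    ``LDL-C_KO-N`` for locally derived median/optimal N-cell tables, with
    suffix ``-TG`` when the scheme stratifies on TG alone; ``LDL-C_M-N``
    for the original published median tables (``source="M"``).
    """
    if statistic == "fixed":
        return "LDL-C_F"
    n = scheme.n_cells
    suffix = "" if scheme.uses_nonhdl else "-TG"
    if source == "M":
        return f"LDL-C_M-{n}"
    tag = "KM" if statistic == "median" else "KO"
    return f"LDL-C_{tag}-{n}{suffix}"


# ---------------------------------------------------------------------------
# file format

def _af_to_str(af: float, statistic: str) -> str:
    if statistic == "fixed":
        return repr(float(af))
    return f"{af:.1f}"


def write_ratio_table(table: RatioTable, path) -> None:
    cells = []
    for cid, bounds in table.scheme.cells():
        cell = table.cells[cid]
        tg_lo, tg_hi, nh_lo, nh_hi = bounds
        cells.append(
            {
                "tg_lo": tg_lo,
                "tg_hi": tg_hi,
                "nonhdl_lo": nh_lo,
                "nonhdl_hi": nh_hi,
                "af": _af_to_str(cell.af, table.statistic),
                "n": cell.n,
                "ci_lo": cell.ci_lo,
                "ci_hi": cell.ci_hi,
                "acl": cell.acl,
                "tie": cell.tie,
            }
        )
    doc = {
        "scheme": table.scheme.to_dict(),
        "statistic": table.statistic,
        "cells": cells,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def read_ratio_table(path) -> RatioTable:
    """Read and validate a ratio-table file.

    Schema errors: cells that overlap, fail to cover the scheme, or carry
    AF outside (0, inf) (or off the [1, 10] grid range for derived
    statistics).
    """
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    try:
        scheme = StratScheme.from_dict(doc["scheme"])
        statistic = doc["statistic"]
        raw_cells = doc["cells"]
    except (KeyError, TypeError) as e:
        raise SchemaError(f"malformed ratio-table file: {e}") from None

    expected = {bounds: cid for cid, bounds in scheme.cells()}
    cells: dict = {}
    for rc in raw_cells:
        bounds = (
            float(rc["tg_lo"]),
            float(rc["tg_hi"]),
            None if rc["nonhdl_lo"] is None else float(rc["nonhdl_lo"]),
            None if rc["nonhdl_hi"] is None else float(rc["nonhdl_hi"]),
        )
        if bounds not in expected:
            raise SchemaError(f"cell {bounds} overlaps or lies outside the scheme")
        cid = expected[bounds]
        if cid in cells:
            raise SchemaError(f"duplicate cell {bounds}")
        af = float(rc["af"])
        if not af > 0:
            raise SchemaError(f"af must be positive, got {af}")
        cells[cid] = RatioCell(
            af=af,
            n=rc.get("n"),
            ci_lo=rc.get("ci_lo"),
            ci_hi=rc.get("ci_hi"),
            acl=rc.get("acl"),
            tie=bool(rc.get("tie", False)),
        )
    missing = set(expected.values()) - set(cells)
    if missing:
        raise SchemaError(f"gap in coverage: missing cells {sorted(missing)[:5]}")
    try:
        return RatioTable(scheme=scheme, statistic=statistic, cells=cells)
    except TableIntegrityError as e:
        raise SchemaError(str(e)) from None


PACKAGED_TABLES = (
    "six_tg_median",
    "six_tg_optimal",
    "twelve_combined_median",
    "twelve_combined_optimal",
)


def packaged_table(name: str) -> RatioTable:
    """Load a ratio table shipped with the package (published 6- and
    12-cell median/optimal survey-derived values)."""
    from importlib import resources

    if name not in PACKAGED_TABLES:
        raise SchemaError(f"unknown packaged table {name!r}; have {PACKAGED_TABLES}")
    ref = resources.files(__package__) / "tables" / f"{name}.json"
    with resources.as_file(ref) as path:
        return read_ratio_table(path)


def write_scheme(scheme: StratScheme, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(scheme.to_dict(), fh, indent=1)
        fh.write("\n")


def read_scheme(path) -> StratScheme:
    with open(path, encoding="utf-8") as fh:
        return StratScheme.from_dict(json.load(fh))
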