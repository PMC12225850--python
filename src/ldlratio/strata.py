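"""Stratification schemes over TG and (optionally) non-HDL-C.

A scheme partitions the eligible TG range (0, 400) mg/dL into half-open
intervals [lo, hi); each TG interval may be further split by non-HDL-C
cut points, again half-open. Every eligible panel maps to exactly one
cell. Cells are addressed by ``CellId(tg_index, nonhdl_index)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .core import add_derived

__all__ = [
    "CellId",
    "StratScheme",
    "CellCensus",
    "BUILTIN_SCHEMES",
    "builtin_scheme",
    "assign_cells",
    "census",
]

TG_RANGE = (0.0, 400.0)


class ConfigurationError(ValueError):
    pass


class OutOfRangeError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class CellId:
    tg_index: int
    nonhdl_index: int = 0


@dataclass(frozen=True)
class StratScheme:
    """TG interval boundaries plus optional per-TG-stratum non-HDL-C
    boundaries defining N cells.

    ``tg_breaks`` are the interior TG cut points (ascending, inside
    (0, 400)); ``nonhdl_breaks_per_tg`` holds one (possibly empty)
    ascending list of non-HDL-C cut points per TG interval.
    """

    name: str
    tg_breaks: tuple[float, ...]
    nonhdl_breaks_per_tg: tuple[tuple[float, ...], ...] = None  # type: ignore[assignment]

    def __post_init__(self):
        breaks = tuple(float(b) for b in self.tg_breaks)
        if list(breaks) != sorted(set(breaks)):
            raise ConfigurationError("tg_breaks must be strictly ascending")
        if breaks and (breaks[0] <= TG_RANGE[0] or breaks[-1] >= TG_RANGE[1]):
            raise ConfigurationError("tg_breaks must lie strictly inside (0, 400)")
        object.__setattr__(self, "tg_breaks", breaks)
        nh = self.nonhdl_breaks_per_tg
        if nh is None:
            nh = tuple(() for _ in range(len(breaks) + 1))
        nh = tuple(tuple(float(c) for c in cuts) for cuts in nh)
        if len(nh) != len(breaks) + 1:
            raise ConfigurationError(
                "nonhdl_breaks_per_tg needs one entry per TG interval "
                f"({len(breaks) + 1}), got {len(nh)}"
            )
        for cuts in nh:
            if list(cuts) != sorted(set(cuts)):
                raise ConfigurationError("non-HDL-C cuts must be strictly ascending")
        object.__setattr__(self, "nonhdl_breaks_per_tg", nh)

    @property
    def n_tg(self) -> int:
        return len(self.tg_breaks) + 1

    @property
    def n_cells(self) -> int:
        return sum(1 + len(cuts) for cuts in self.nonhdl_breaks_per_tg)

    @property
    def uses_nonhdl(self) -> bool:
        return any(len(cuts) for cuts in self.nonhdl_breaks_per_tg)

    def tg_edges(self) -> tuple[float, ...]:
        return (TG_RANGE[0],) + self.tg_breaks + (TG_RANGE[1],)

    def cells(self) -> Iterator[tuple[CellId, tuple[float, float, Optional[float], Optional[float]]]]:
        """Yield (CellId, (tg_lo, tg_hi, nonhdl_lo, nonhdl_hi)); open
        non-HDL-C bounds are None."""
        edges = self.tg_edges()
        for i, cuts in enumerate(self.nonhdl_breaks_per_tg):
            nh_edges = (None,) + tuple(cuts) + (None,)
            for j in range(len(cuts) + 1):
                yield CellId(i, j), (edges[i], edges[i + 1], nh_edges[j], nh_edges[j + 1])

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "tg_breaks": list(self.tg_breaks),
            "nonhdl_breaks_per_tg": [list(c) for c in self.nonhdl_breaks_per_tg],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StratScheme":
        return cls(
            name=d["name"],
            tg_breaks=tuple(d["tg_breaks"]),
            nonhdl_breaks_per_tg=tuple(tuple(c) for c in d["nonhdl_breaks_per_tg"]),
        )


# The six conventional TG bands: <50, 50-99, 100-149, 150-199, 200-299,
# 300-399 mg/dL.
_SIX_TG_BREAKS = (50.0, 100.0, 150.0, 200.0, 300.0)


def _six_tg() -> StratScheme:
    return StratScheme("six_tg", _SIX_TG_BREAKS)


def _twelve_combined() -> StratScheme:
    # each TG band split at non-HDL-C 130 mg/dL
    return StratScheme(
        "twelve_combined", _SIX_TG_BREAKS, tuple((130.0,) for _ in range(6))
    )


def _packaged_scheme(filename: str) -> StratScheme:
    from importlib import resources
    import json

    ref = resources.files(__package__) / "tables" / filename
    return StratScheme.from_dict(json.loads(ref.read_text()))


def _twelve_tg() -> StratScheme:
    """12 TG-only intervals, loaded from the packaged scheme file. The
    shipped boundaries are synthetic (the published supplement's cut
    points are not available here); replace the file to use published
    values."""
    return _packaged_scheme("twelve_tg_scheme_synthetic.json")


def _twentyeight_combined() -> StratScheme:
    """28-cell TG x non-HDL-C scheme, loaded from the packaged scheme
    file. The shipped non-HDL-C cuts are synthetic (guideline-aligned,
    fewer in the sparse lowest TG band so cells stay populated on
    survey-like cohorts); replace the file to use published values."""
    return _packaged_scheme("twentyeight_combined_scheme_synthetic.json")


BUILTIN_SCHEMES = {
    "six_tg": _six_tg,
    "twelve_tg": _twelve_tg,
    "twelve_combined": _twelve_combined,
    "twentyeight_combined": _twentyeight_combined,
}


def builtin_scheme(name: str) -> StratScheme:
    """Return a packaged stratification scheme by name."""
    try:
        return BUILTIN_SCHEMES[name]()
    except KeyError:
        raise ConfigurationError(
            f"unknown scheme {name!r}; valid names: {sorted(BUILTIN_SCHEMES)}"
        ) from None


def assign_cells(cohort: pd.DataFrame, scheme: StratScheme) -> pd.DataFrame:
    """Assign each row to its (tg_index, nonhdl_index) cell.

    Deterministic half-open interval lookup: the TG interval is located
    first, then the non-HDL-C interval within it. Raises
    :class:`OutOfRangeError` for TG outside (0, 400).
    """
    tg = np.asarray(cohort["tg"], dtype=float)
    if (tg < TG_RANGE[0]).any() or (tg >= TG_RANGE[1]).any():
        bad = tg[(tg < TG_RANGE[0]) | (tg >= TG_RANGE[1])][0]
        raise OutOfRangeError(f"TG {bad} mg/dL outside scheme coverage [0, 400)")
    tg_idx = np.searchsorted(scheme.tg_breaks, tg, side="right")
    nh_idx = np.zeros(len(tg), dtype=np.int64)
    if scheme.uses_nonhdl:
        if "non_hdl" in cohort.columns:
            non_hdl = np.asarray(cohort["non_hdl"], dtype=float)
        else:
            non_hdl = np.asarray(add_derived(cohort)["non_hdl"], dtype=float)
        for i, cuts in enumerate(scheme.nonhdl_breaks_per_tg):
            if cuts:
                mask = tg_idx == i
                nh_idx[mask] = np.searchsorted(cuts, non_hdl[mask], side="right")
    out = pd.DataFrame(
        {"tg_index": tg_idx, "nonhdl_index": nh_idx}, index=cohort.index
    )
    return out


@dataclass
class CellCensus:
    """Per-cell sample counts with an occupancy threshold."""

    counts: dict  # CellId -> int
    min_n: int
    under_populated: list = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def census(cohort: pd.DataFrame, scheme: StratScheme, min_n: int = 100) -> CellCensus:
    """Count cohort members per cell; cells below ``min_n`` (the ratio
    tables' occupancy floor) are flagged, not errors."""
    idx = assign_cells(cohort, scheme)
    grouped = idx.groupby(["tg_index", "nonhdl_index"]).size()
    counts = {cid: 0 for cid, _ in scheme.cells()}
    for (i, j), n in grouped.items():
        counts[CellId(int(i), int(j))] = int(n)
    under = [cid for cid, n in counts.items() if n < min_n]
    return CellCensus(counts=counts, min_n=min_n, under_populated=sorted(under))
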