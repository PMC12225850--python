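"""Derive strata-specific median and concordance-optimal TG/VLDL-C ratio
tables from a cohort with measured LDL-C.

The optimal AF per cell is the value on the 1.0-10.0 grid (0.1 steps, 91
points) maximizing the number of cell members whose estimated guideline
category (from non-HDL-C - TG/AF) equals their measured category. The
median AF is the sample median of the per-individual TG/VLDL-C ratios,
with a distribution-free order-statistic confidence interval whose
achieved coverage (ACL) is reported because it can exceed the nominal
level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

from .core import add_derived, ncep_categories, round_half_up
from .estimators import RatioCell, RatioTable
from .strata import CellId, StratScheme, assign_cells

__all__ = [
    "RatioGrid",
    "DiscordanceCurve",
    "DerivationError",
    "default_grid",
    "median_ci",
    "median_ratio_table",
    "optimal_ratio_table",
    "discordance_curve",
    "concordance_by_grid",
]


class DerivationError(ValueError):
    pass


@dataclass(frozen=True)
class RatioGrid:
    """The AF search grid. Values are generated as integers/10 so each
    point is exactly the printed decimal (no 0.30000000000000004 labels)."""

    lo: float = 1.0
    hi: float = 10.0
    step: float = 0.1

    def __post_init__(self):
        if not (0 < self.lo < self.hi and self.step > 0):
            raise DerivationError(f"invalid grid ({self.lo}, {self.hi}, {self.step})")

    @property
    def values(self) -> np.ndarray:
        # integer arithmetic scaled by the step denominator avoids float
        # accumulation across the 91 points
        scale = int(round(1 / self.step))
        lo_i, hi_i = int(round(self.lo * scale)), int(round(self.hi * scale))
        return np.arange(lo_i, hi_i + 1) / scale


def default_grid() -> RatioGrid:
    return RatioGrid()


def median_ci(values: np.ndarray, confidence: float = 0.95) -> tuple[float, float, float]:
    """Distribution-free CI for the median from order statistics.

    Picks the symmetric-in-rank interval (l-th, (n+1-l)-th order
    statistics) that is narrowest in rank while its exact binomial
    coverage sum_{k=l}^{n-l} C(n,k)/2^n still reaches ``confidence``.
    When no symmetric pair reaches it (small n), widens to the extreme
    order statistics. Returns (lo, hi, achieved coverage).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n < 1:
        raise DerivationError("median_ci needs at least one value")
    if n == 1:
        return float(x[0]), float(x[0]), 0.0
    best = None
    for l in range(n // 2, 0, -1):
        u = n + 1 - l  # 1-based upper rank
        # coverage of [X_(l), X_(u)] is P(l <= B <= u - 1), B ~ Bin(n, 1/2)
        cov = float(binom.cdf(u - 1, n, 0.5) - binom.cdf(l - 1, n, 0.5))
        if cov >= confidence:
            best = (l, u, cov)
            break
    if best is None:
        l, u = 1, n
        cov = float(binom.cdf(u - 1, n, 0.5) - binom.cdf(l - 1, n, 0.5))
        best = (l, u, cov)
    l, u, cov = best
    return float(x[l - 1]), float(x[u - 1]), cov


def _cell_groups(cohort: pd.DataFrame, scheme: StratScheme) -> pd.core.groupby.DataFrameGroupBy:
    df = add_derived(cohort)
    idx = assign_cells(df, scheme)
    df = df.assign(tg_index=idx["tg_index"], nonhdl_index=idx["nonhdl_index"])
    return df.groupby(["tg_index", "nonhdl_index"])


def median_ratio_table(
    cohort: pd.DataFrame,
    scheme: StratScheme,
    confidence: float = 0.95,
    min_n: int = 100,
) -> RatioTable:
    """Per-cell sample-median TG/VLDL-C ratio with distribution-free CI.

    Individuals with undefined ratio (VLDL-C <= 0) are excluded from
    derivation; empty cells raise :class:`DerivationError`. The AF is the
    median rounded half-up to the 0.1 grid resolution (tables are stored
    at that resolution); CI endpoints keep full precision.
    """
    if "ldl_d" not in cohort.columns:
        raise DerivationError("median derivation requires measured LDL-C (ldl_d)")
    groups = _cell_groups(cohort, scheme)
    found: dict = {}
    for (i, j), g in groups:
        vals = g["tg_vldl_ratio"].dropna().to_numpy()
        if len(vals) == 0:
            continue
        med = float(np.median(vals))
        lo, hi, acl = median_ci(vals, confidence)
        found[CellId(int(i), int(j))] = RatioCell(
            af=round_half_up(med, 1), n=int(len(vals)), ci_lo=lo, ci_hi=hi, acl=acl
        )
    missing = [cid for cid, _ in scheme.cells() if cid not in found]
    if missing:
        raise DerivationError(f"empty cell(s) in median derivation: {missing[:5]}")
    return RatioTable(scheme=scheme, statistic="median", cells=found)


def concordance_by_grid(
    non_hdl: np.ndarray, tg: np.ndarray, measured_cat: np.ndarray, grid: RatioGrid
) -> np.ndarray:
    """Count, for every grid AF, the members whose estimated category
    equals their measured one. Vectorized over (members x grid)."""
    vals = grid.values
    est = non_hdl[:, None] - tg[:, None] / vals[None, :]
    est_cat = ncep_categories(est.ravel()).reshape(est.shape)
    return (est_cat == measured_cat[:, None]).sum(axis=0)


def optimal_ratio_table(
    cohort: pd.DataFrame, scheme: StratScheme, grid: RatioGrid | None = None
) -> RatioTable:
    """Per-cell concordance-maximizing AF over the grid.

    The objective needs only non-HDL-C, TG and the measured category, so
    undefined-ratio individuals (VLDL-C <= 0) are included. Ties at the
    maximum break to the lowest grid value and are recorded in the cell
    metadata.
    """
    if "ldl_d" not in cohort.columns:
        raise DerivationError("optimal derivation requires measured LDL-C (ldl_d)")
    grid = grid or default_grid()
    vals = grid.values
    groups = _cell_groups(cohort, scheme)
    found: dict = {}
    for (i, j), g in groups:
        non_hdl = g["non_hdl"].to_numpy(dtype=float)
        tg = g["tg"].to_numpy(dtype=float)
        meas_cat = ncep_categories(g["ldl_d"].to_numpy(dtype=float))
        counts = concordance_by_grid(non_hdl, tg, meas_cat, grid)
        best = int(np.argmax(counts))  # argmax takes the lowest index on ties
        tie = bool((counts == counts[best]).sum() > 1)
        found[CellId(int(i), int(j))] = RatioCell(
            af=float(vals[best]), n=int(len(g)), tie=tie
        )
    missing = [cid for cid, _ in scheme.cells() if cid not in found]
    if missing:
        raise DerivationError(f"empty cell(s) in optimal derivation: {missing[:5]}")
    return RatioTable(scheme=scheme, statistic="optimal", cells=found)


@dataclass
class DiscordanceCurve:
    """Concordance / under- / over-classification rates per grid AF.

    The three rates partition 1 at every grid point. Under-classification
    is non-increasing and over-classification non-decreasing in AF: the
    estimate is strictly increasing in AF at TG > 0, so raising AF can
    only move estimated categories upward.
    """

    af: np.ndarray
    concordance: np.ndarray
    under: np.ndarray
    over: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "af": self.af,
                "concordance": self.concordance,
                "under": self.under,
                "over": self.over,
            }
        )


def discordance_curve(cell_cohort: pd.DataFrame, grid: RatioGrid | None = None) -> DiscordanceCurve:
    """Rates of concordance, under- and over-classification across the
    grid for one cell's members (measured LDL-C required)."""
    if len(cell_cohort) == 0:
        raise DerivationError("empty cell cohort")
    grid = grid or default_grid()
    vals = grid.values
    df = add_derived(cell_cohort)
    non_hdl = df["non_hdl"].to_numpy(dtype=float)
    tg = df["tg"].to_numpy(dtype=float)
    meas_cat = ncep_categories(df["ldl_d"].to_numpy(dtype=float))
    est = non_hdl[:, None] - tg[:, None] / vals[None, :]
    est_cat = ncep_categories(est.ravel()).reshape(est.shape)
    n = len(df)
    conc = (est_cat == meas_cat[:, None]).sum(axis=0) / n
    under = (est_cat < meas_cat[:, None]).sum(axis=0) / n
    over = (est_cat > meas_cat[:, None]).sum(axis=0) / n
    return DiscordanceCurve(af=vals, concordance=conc, under=under, over=over)
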