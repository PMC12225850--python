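"""Concordance, reclassification, agreement and fit metrics comparing
estimated with directly measured LDL-C.

Classification uses the six guideline treatment bands (<70, 70-99,
100-129, 130-159, 160-189, >=190 mg/dL). An estimate is *concordant*
when it falls in the same band as the measurement, *under-classified*
when in a lower band, *over-classified* when in a higher one.
Inference is exact throughout: Clopper-Pearson intervals for rates and
the exact binomial McNemar test for paired concordance comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom
from statsmodels.stats.proportion import proportion_confint

from .core import (
    InputError,
    NCEP_LABELS,
    ValidationError,
    ncep_categories,
    round_half_up,
)
from .strata import StratScheme, builtin_scheme

__all__ = [
    "classify",
    "ConcordanceSummary",
    "concordance_summary",
    "clopper_pearson",
    "mcnemar_exact",
    "ReclassBlock",
    "ReclassTable",
    "reclassification",
    "AgreementSummary",
    "bland_altman",
    "fit_metrics",
]


def _aligned(*series) -> list[np.ndarray]:
    lengths = {len(s) for s in series}
    if len(lengths) != 1:
        raise InputError(f"unpaired inputs: lengths {sorted(lengths)}")
    return [np.asarray(s, dtype=float) for s in series]


def classify(estimates, measured) -> pd.DataFrame:
    """Per-individual estimated vs measured category with status.

    Returns a DataFrame with ``est_cat``, ``meas_cat`` (ordinals 0-5),
    ``status`` in {concordant, under, over} and ``negative_flag`` for
    negative estimates (classified as <70 but flagged)."""
    est, meas = _aligned(estimates, measured)
    est_cat = ncep_categories(est)
    meas_cat = ncep_categories(meas)
    status = np.where(
        est_cat == meas_cat, "concordant", np.where(est_cat < meas_cat, "under", "over")
    )
    index = estimates.index if isinstance(estimates, pd.Series) else None
    return pd.DataFrame(
        {
            "est_cat": est_cat,
            "meas_cat": meas_cat,
            "status": status,
            "negative_flag": est < 0,
        },
        index=index,
    )


def clopper_pearson(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) two-sided CI for a binomial proportion."""
    if not (0 <= k <= n) or n <= 0:
        raise ValidationError(f"invalid counts k={k}, n={n}")
    lo, hi = proportion_confint(k, n, alpha=1 - confidence, method="beta")
    return float(lo), float(hi)


@dataclass
class ConcordanceSummary:
    """Concordance counts and rate with exact CI for one group."""

    label: str
    n: int
    concordant: int
    under: int
    over: int
    ci_lo: float
    ci_hi: float

    @property
    def rate(self) -> float:
        return self.concordant / self.n

    @property
    def pct(self) -> float:
        """Rate as a percentage rounded half-up to one decimal, the
        printed-table convention."""
        return round_half_up(100.0 * self.rate, 1)

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "n": self.n,
            "concordant": self.concordant,
            "under": self.under,
            "over": self.over,
            "rate": self.rate,
            "pct": self.pct,
            "ci_lo": self.ci_lo,
            "ci_hi": self.ci_hi,
        }


def _summarize(label: str, sub: pd.DataFrame, confidence: float) -> ConcordanceSummary:
    n = len(sub)
    k = int((sub["status"] == "concordant").sum())
    lo, hi = clopper_pearson(k, n, confidence)
    return ConcordanceSummary(
        label=label,
        n=n,
        concordant=k,
        under=int((sub["status"] == "under").sum()),
        over=int((sub["status"] == "over").sum()),
        ci_lo=lo,
        ci_hi=hi,
    )


def concordance_summary(
    results: pd.DataFrame,
    group_by: Optional[str] = None,
    tg: Optional[Sequence[float]] = None,
    scheme: Optional[StratScheme] = None,
    confidence: float = 0.95,
) -> list[ConcordanceSummary]:
    """Concordance rates with exact CIs, overall or grouped.

    ``group_by`` is None (overall), ``"tg_strata"`` (requires ``tg``;
    TG bands from ``scheme``, default the six conventional bands) or
    ``"est_category"`` (initial classification by the estimated value,
    the printed-table convention). Empty groups are omitted.
    """
    if len(results) == 0:
        raise InputError("empty results")
    if group_by is None:
        return [_summarize("overall", results, confidence)]
    if group_by == "est_category":
        out = []
        for cat in range(len(NCEP_LABELS)):
            sub = results[results["est_cat"] == cat]
            if len(sub):
                out.append(_summarize(NCEP_LABELS[cat], sub, confidence))
        return out
    if group_by == "tg_strata":
        if tg is None:
            raise InputError("tg values required for tg_strata grouping")
        scheme = scheme or builtin_scheme("six_tg")
        tg_arr = np.asarray(tg, dtype=float)
        if len(tg_arr) != len(results):
            raise InputError("tg not aligned with results")
        edges = scheme.tg_edges()
        idx = np.searchsorted(scheme.tg_breaks, tg_arr, side="right")
        out = []
        for i in range(scheme.n_tg):
            sub = results[idx == i]
            if len(sub):
                out.append(_summarize(f"TG {edges[i]:g}-{edges[i+1]:g}", sub, confidence))
        return out
    raise InputError(f"unknown group_by {group_by!r}")


def mcnemar_exact(b: int, c: int) -> float:
    """Two-sided exact McNemar p-value from the two discordant counts.

    p = min(1, 2 * P(X <= min(b, c))) with X ~ Binomial(b + c, 1/2);
    tail doubling capped at 1. Returns 1.0 (degenerate) when b = c = 0.
    """
    if b < 0 or c < 0:
        raise ValidationError(f"negative discordant counts ({b}, {c})")
    n = b + c
    if n == 0:
        return 1.0
    return float(min(1.0, 2.0 * binom.cdf(min(b, c), n, 0.5)))


@dataclass
class ReclassBlock:
    """2x2 correct/incorrect cross-counts for one reference-method
    category block. ``cc`` = correct by both, ``ci`` = correct by the
    reference only, ``ic`` = correct by the alternative only, ``ii`` =
    incorrect by both; correctness is agreement with the measured
    category."""

    label: str
    n: int
    cc: int
    ci: int
    ic: int
    ii: int
    upward: int
    downward: int

    @property
    def p_value(self) -> float:
        return mcnemar_exact(self.ci, self.ic)

    def pct(self, count: int) -> float:
        return round_half_up(100.0 * count / self.n, 1)

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "n": self.n,
            "cc": self.cc,
            "ci": self.ci,
            "ic": self.ic,
            "ii": self.ii,
            "cc_pct": self.pct(self.cc),
            "ci_pct": self.pct(self.ci),
            "ic_pct": self.pct(self.ic),
            "ii_pct": self.pct(self.ii),
            "upward": self.upward,
            "downward": self.downward,
            "p_value": self.p_value,
        }


@dataclass
class ReclassTable:
    blocks: list = field(default_factory=list)  # per reference category
    overall: ReclassBlock = None  # type: ignore[assignment]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([b.as_dict() for b in self.blocks + [self.overall]])


def reclassification(ref_estimates, alt_estimates, measured) -> ReclassTable:
    """Reclassification analysis of an alternative estimator against a
    reference (conventionally Friedewald), judged by measured LDL-C.

    Rows are blocked by the reference method's category; within each
    block the 2x2 cross-counts of correct/incorrect classification by
    each method are tabulated with the exact McNemar p from the two
    discordant cells, plus upward/downward reclassification counts
    (alternative category above/below the reference one).
    """
    ref, alt, meas = _aligned(ref_estimates, alt_estimates, measured)
    ref_cat = ncep_categories(ref)
    alt_cat = ncep_categories(alt)
    meas_cat = ncep_categories(meas)
    ref_ok = ref_cat == meas_cat
    alt_ok = alt_cat == meas_cat

    def block(label: str, mask: np.ndarray) -> ReclassBlock:
        return ReclassBlock(
            label=label,
            n=int(mask.sum()),
            cc=int((mask & ref_ok & alt_ok).sum()),
            ci=int((mask & ref_ok & ~alt_ok).sum()),
            ic=int((mask & ~ref_ok & alt_ok).sum()),
            ii=int((mask & ~ref_ok & ~alt_ok).sum()),
            upward=int((mask & (alt_cat > ref_cat)).sum()),
            downward=int((mask & (alt_cat < ref_cat)).sum()),
        )

    blocks = [
        block(NCEP_LABELS[cat], ref_cat == cat)
        for cat in range(len(NCEP_LABELS))
        if (ref_cat == cat).any()
    ]
    overall = block("overall", np.ones(len(ref), dtype=bool))
    return ReclassTable(blocks=blocks, overall=overall)


@dataclass
class AgreementSummary:
    """Bland-Altman agreement: mean bias and 95% limits of agreement
    (bias +/- 1.96 SD of the paired differences), mg/dL."""

    n: int
    mean_bias: float
    sd: float

    @property
    def loa_lo(self) -> float:
        return self.mean_bias - 1.96 * self.sd

    @property
    def loa_hi(self) -> float:
        return self.mean_bias + 1.96 * self.sd


def bland_altman(
    estimates, measured, tg: Optional[Sequence[float]] = None,
    tg_interval: Optional[tuple[float, float]] = None,
) -> AgreementSummary:
    """Agreement between estimate and measurement, optionally restricted
    to a half-open TG subgroup [lo, hi)."""
    est, meas = _aligned(estimates, measured)
    if tg_interval is not None:
        if tg is None:
            raise InputError("tg values required for a TG subgroup")
        tg_arr = np.asarray(tg, dtype=float)
        mask = (tg_arr >= tg_interval[0]) & (tg_arr < tg_interval[1])
        est, meas = est[mask], meas[mask]
    n = len(est)
    if n < 2:
        raise InputError(f"bland_altman needs n >= 2, got {n}")
    diff = est - meas
    return AgreementSummary(n=n, mean_bias=float(diff.mean()), sd=float(diff.std(ddof=1)))


def fit_metrics(estimates, measured) -> dict:
    """Fit and error metrics of an estimator against measurement.

    ``r2`` = 1 - SSE/SST with the measured values as truth (a prediction
    R^2, which can be negative); ``mre`` = signed mean relative error in
    percent, rows with measured value 0 excluded (counted in
    ``mre_excluded``); ``mae`` mg/dL; ``mse`` mg/dL^2.
    """
    est, meas = _aligned(estimates, measured)
    if len(est) < 2:
        raise InputError("fit_metrics needs n >= 2")
    diff = est - meas
    sse = float((diff**2).sum())
    sst = float(((meas - meas.mean()) ** 2).sum())
    nonzero = meas != 0
    return {
        "r2": 1.0 - sse / sst,
        "mre": float(100.0 * (diff[nonzero] / meas[nonzero]).mean()),
        "mre_excluded": int((~nonzero).sum()),
        "mae": float(np.abs(diff).mean()),
        "mse": float((diff**2).mean()),
    }
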