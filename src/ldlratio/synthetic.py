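"""Synthetic lipid-panel cohorts with the joint structure the analysis
assumes, so every pipeline stage is testable without survey data access.

The generator draws TG and non-HDL-C from log-normal marginals
(parameterized by median and IQR — lipid distributions are right-skewed
and surveys report median/IQR) coupled by a Gaussian copula, assigns each
individual a true TG/VLDL-C ratio from a log-linear surface (rising in
TG, falling in non-HDL-C, the qualitative pattern of survey-derived
ratio tables) times multiplicative log-normal noise, and back-solves
VLDL-C = TG / ratio and measured LDL-C = non-HDL-C - VLDL-C. HDL-C has
its own marginal and TC = non-HDL-C + HDL-C, so derived quantities
reproduce the inputs exactly. Rows violating positivity are
rejection-resampled, preserving the documented marginals.

Presets emulate two survey populations: Population 1 (general, TG median
102 IQR 69-150 mg/dL), Population 2 (TG restricted to [200, 400)
mg/dL), and their 11,930 : 6,392 mixture used for ratio derivation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .estimators import RatioTable
from .strata import ConfigurationError

__all__ = [
    "SynthConfig",
    "GenerationError",
    "PRESET_NAMES",
    "preset",
    "generate_cohort",
    "lognormal_params",
]

#: standard normal upper quartile, for median/IQR -> (mu, sigma)
_Z75 = norm.ppf(0.75)

RATIO_CLAMP = (1.0, 12.0)


class GenerationError(RuntimeError):
    pass


def lognormal_params(median: float, iqr: tuple[float, float]) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with the given median and IQR."""
    q1, q3 = iqr
    if not (0 < q1 < median < q3):
        raise ConfigurationError(f"inconsistent median {median} / IQR {iqr}")
    return float(np.log(median)), float(np.log(q3 / q1) / (2 * _Z75))


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters. Concentrations mg/dL; ``tg_range`` is a
    half-open truncation interval [lo, hi); ``tg_nonhdl_dependence`` is a
    Spearman rank correlation; ``ratio_noise_sd`` is the log-scale sigma
    of the multiplicative ratio noise. ``ratio_table`` (optional)
    replaces the log-linear ratio surface with a cell-wise constant true
    ratio, for parameter-recovery studies. ``components`` makes the
    config a fixed-weight mixture (its own marginal fields are unused)."""

    n: int = 10000
    seed: int = 0
    tg_median: float = 102.0
    tg_iqr: tuple[float, float] = (69.0, 150.0)
    tg_range: tuple[float, float] = (0.0, 400.0)
    nonhdl_median: float = 132.0
    nonhdl_iqr: tuple[float, float] = (109.0, 158.0)
    hdl_median: float = 49.0
    hdl_iqr: tuple[float, float] = (42.0, 57.0)
    tg_nonhdl_dependence: float = 0.35
    ratio_base: float = 3.93
    ratio_tg_slope: float = 1.9
    ratio_nonhdl_slope: float = 1.6
    ratio_noise_sd: float = 0.20
    id_prefix: str = "syn-"
    ratio_table: Optional[RatioTable] = None
    components: Optional[tuple[tuple["SynthConfig", float], ...]] = None

    def __post_init__(self):
        if self.n < 0:
            raise ConfigurationError("n must be non-negative")
        if not (-1.0 <= self.tg_nonhdl_dependence <= 1.0):
            raise ConfigurationError("tg_nonhdl_dependence must be in [-1, 1]")
        if self.ratio_noise_sd < 0:
            raise ConfigurationError("ratio_noise_sd must be >= 0")


def _population1(n: int, seed: int) -> SynthConfig:
    return SynthConfig(n=n, seed=seed, id_prefix="p1-")


def _population2(n: int, seed: int) -> SynthConfig:
    # TG marginal constants calibrated (least squares, offline) so the
    # [200, 400)-truncated distribution has quartiles 219/247/291 mg/dL:
    # pre-truncation mu = 4.1012, sigma = 0.7581.
    return SynthConfig(
        n=n,
        seed=seed,
        tg_median=float(np.exp(4.1012)),
        tg_iqr=(
            float(np.exp(4.1012 - _Z75 * 0.7581)),
            float(np.exp(4.1012 + _Z75 * 0.7581)),
        ),
        tg_range=(200.0, 400.0),
        nonhdl_median=161.0,
        nonhdl_iqr=(138.0, 187.0),
        hdl_median=42.0,
        hdl_iqr=(37.0, 48.0),
        id_prefix="p2-",
    )


#: derivation-cohort mixture weights (validation : high-TG supplement)
COMBINED_WEIGHTS = (11930.0, 6392.0)


def _combined(n: int, seed: int) -> SynthConfig:
    w1, w2 = COMBINED_WEIGHTS
    return SynthConfig(
        n=n,
        seed=seed,
        id_prefix="mix-",
        components=(
            (_population1(0, 0), w1 / (w1 + w2)),
            (_population2(0, 0), w2 / (w1 + w2)),
        ),
    )


_PRESETS = {
    "population1": _population1,
    "population2": _population2,
    "combined": _combined,
}
PRESET_NAMES = tuple(sorted(_PRESETS))


def preset(name: str, n: int = 10000, seed: int = 0) -> SynthConfig:
    """A named preset config (``population1``, ``population2``,
    ``combined``)."""
    try:
        return _PRESETS[name](n, seed)
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; valid names: {list(PRESET_NAMES)}"
        ) from None


def set_ratio_noise(config: SynthConfig, sd: float) -> SynthConfig:
    """Copy of ``config`` with the ratio noise sigma replaced (recursing
    into mixture components) — for controlled recovery experiments."""
    if config.components:
        comps = tuple(
            (set_ratio_noise(sub, sd), w) for sub, w in config.components
        )
        return replace(config, ratio_noise_sd=sd, components=comps)
    return replace(config, ratio_noise_sd=sd)


def _true_ratio(config: SynthConfig, tg: np.ndarray, nonhdl: np.ndarray) -> np.ndarray:
    if config.ratio_table is not None:
        frame = pd.DataFrame({"tg": tg, "non_hdl": nonhdl})
        return config.ratio_table.af_array(frame)
    return (
        config.ratio_base
        + config.ratio_tg_slope * np.log(tg)
        - config.ratio_nonhdl_slope * np.log(nonhdl)
    )


def _draw(config: SynthConfig, rng: np.random.Generator, n: int) -> pd.DataFrame:
    mu_tg, s_tg = lognormal_params(config.tg_median, config.tg_iqr)
    mu_nh, s_nh = lognormal_params(config.nonhdl_median, config.nonhdl_iqr)
    mu_hdl, s_hdl = lognormal_params(config.hdl_median, config.hdl_iqr)
    # Gaussian copula: Spearman rho -> normal-score correlation
    rho = 2.0 * np.sin(np.pi * config.tg_nonhdl_dependence / 6.0)
    lo, hi = config.tg_range
    z_lo = -np.inf if lo <= 0 else (np.log(lo) - mu_tg) / s_tg
    z_hi = (np.log(hi) - mu_tg) / s_tg
    u = rng.uniform(norm.cdf(z_lo), norm.cdf(z_hi), size=n)
    z1 = norm.ppf(u)  # TG score, truncated to the configured range
    z2 = rho * z1 + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    tg = np.exp(mu_tg + s_tg * z1)
    nonhdl = np.exp(mu_nh + s_nh * z2)
    hdl = np.exp(mu_hdl + s_hdl * rng.standard_normal(n))
    ratio = _true_ratio(config, tg, nonhdl)
    if config.ratio_noise_sd > 0:
        ratio = ratio * np.exp(config.ratio_noise_sd * rng.standard_normal(n))
    ratio = np.clip(ratio, *RATIO_CLAMP)
    vldl = tg / ratio
    ldl_d = nonhdl - vldl
    return pd.DataFrame(
        {
            "tc": nonhdl + hdl,
            "hdl_c": hdl,
            "tg": tg,
            "ldl_d": ldl_d,
            "true_ratio": ratio,
        }
    )


def _generate_single(config: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n
    df = _draw(config, rng, n)
    drawn = n
    bad = df["ldl_d"] <= 0
    while bad.any():
        k = int(bad.sum())
        if drawn + k > 100 * max(n, 1):
            raise GenerationError(
                "infeasible config: positivity rejection exceeded 100x n draws"
            )
        df.loc[bad, :] = _draw(config, rng, k).to_numpy()
        drawn += k
        bad = df["ldl_d"] <= 0
    return df


def generate_cohort(config: SynthConfig) -> pd.DataFrame:
    """Generate a cohort DataFrame (``id, tc, hdl_c, tg, ldl_d,
    true_ratio``), deterministic for a fixed seed.

    Mixture configs split ``n`` by weight (largest remainder) and draw
    each component from an independently spawned stream, then shuffle.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    if config.components:
        weights = np.array([w for _, w in config.components], dtype=float)
        weights = weights / weights.sum()
        sizes = np.floor(weights * config.n).astype(int)
        rema = weights * config.n - sizes
        for i in np.argsort(-rema)[: config.n - sizes.sum()]:
            sizes[i] += 1
        parts = []
        streams = rng.spawn(len(sizes))
        for (sub, _), size, stream in zip(config.components, sizes, streams):
            sub = replace(sub, n=int(size), ratio_table=config.ratio_table)
            part = _generate_single(sub, stream)
            part.insert(0, "id", [f"{sub.id_prefix}{i:06d}" for i in range(len(part))])
            parts.append(part)
        df = pd.concat(parts, ignore_index=True)
        df = df.sample(frac=1.0, random_state=np.random.RandomState(config.seed % 2**31))
        df = df.reset_index(drop=True)
    else:
        df = _generate_single(config, rng)
        df.insert(0, "id", [f"{config.id_prefix}{i:06d}" for i in range(len(df))])
    return df
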