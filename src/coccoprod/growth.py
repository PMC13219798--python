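"""Relative growth-rate (mu) estimators from cell size and environment.

All estimators return divisions per day but are interpreted as *relative*
profiles: the literature regressions behind them were fitted on cultures, so
cross-estimator comparisons use correlation and rank agreement only, never
absolute differences.  Every coefficient set carries a provenance string so a
run records which literature values were transcribed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .stats import pearson


@dataclass(frozen=True)
class SizeMuConfig:
    """Inverse power law ``mu = mu_ref * (V / V_ref)^s`` with s < 0."""

    mu_ref: float = 1.0
    v_ref: float = 50.0
    exponent: float = -0.32
    provenance: str = "placeholder: culture size-mu inverse power law, transcribe from source"

    def __post_init__(self):
        if self.exponent >= 0:
            raise ValueError("size-mu exponent must be negative (inverse relation)")
        if self.mu_ref <= 0 or self.v_ref <= 0:
            raise ValueError("mu_ref and v_ref must be positive")


@dataclass(frozen=True)
class NutrientMuConfig:
    """Michaelis-Menten phosphate limitation ``mu = mu_max * P / (P + K)``."""

    mu_max: float = 1.4
    k_po4: float = 0.24
    provenance: str = "placeholder: nutrient-limited mu parametrization, transcribe from source"

    def __post_init__(self):
        if self.mu_max <= 0 or self.k_po4 <= 0:
            raise ValueError("mu_max and K_PO4 must be positive")


@dataclass(frozen=True)
class LinearMuConfig:
    """Linear driver response ``mu = max(0, intercept + slope * x)``."""

    slope: float
    intercept: float
    provenance: str = "placeholder: linear environmental mu response, transcribe from source"


@dataclass(frozen=True)
class MuRegressionConfig:
    """Bundle of the four mu estimators' coefficients."""

    size: SizeMuConfig = field(default_factory=SizeMuConfig)
    po4: NutrientMuConfig = field(default_factory=NutrientMuConfig)
    sst: LinearMuConfig = field(default_factory=lambda: LinearMuConfig(0.045, 0.0))
    co2: LinearMuConfig = field(default_factory=lambda: LinearMuConfig(0.06, 0.1))


def mu_from_size(volume, cfg: SizeMuConfig | None = None):
    """Size-based mu (div/day): strictly decreasing power law of cell volume."""
    cfg = cfg or SizeMuConfig()
    v = np.asarray(volume, dtype=float)
    if np.any(v <= 0):
        raise ValueError("cell volume must be positive")
    mu = cfg.mu_ref * (v / cfg.v_ref) ** cfg.exponent
    return float(mu) if mu.ndim == 0 else mu


def mu_from_po4(po4, cfg: NutrientMuConfig | None = None):
    """Phosphate-limited mu (div/day): saturating Michaelis-Menten curve."""
    cfg = cfg or NutrientMuConfig()
    p = np.asarray(po4, dtype=float)
    if np.any(p < 0):
        raise ValueError("phosphate concentration must be non-negative")
    mu = cfg.mu_max * p / (p + cfg.k_po4)
    return float(mu) if mu.ndim == 0 else mu


def mu_from_env(driver, which: str, cfg: MuRegressionConfig | None = None):
    """mu from a single environmental driver (``sst`` or ``co2``).

    Default response is linear with clamping at zero; the functional form and
    coefficients are fully config-driven.
    """
    cfg = cfg or MuRegressionConfig()
    try:
        lin = {"sst": cfg.sst, "co2": cfg.co2}[which]
    except KeyError:
        raise ValueError(f"unknown environmental mu driver {which!r}") from None
    x = np.asarray(driver, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("driver values must be finite")
    mu = np.maximum(0.0, lin.intercept + lin.slope * x)
    return float(mu) if mu.ndim == 0 else mu


def compare_mu_profiles(a: pd.Series, b: pd.Series) -> dict[str, float]:
    """Concordance of two mu profiles over co-located samples.

    Both series are indexed by sample id; returns Pearson R and p plus a
    rank-concordance coefficient (Pearson R of the explicit rank transforms,
    i.e. a Spearman-style statistic).
    """
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 co-located samples to compare mu profiles")
    if len(shared) < len(a.index.union(b.index)):
        raise ValueError("mismatched sample sets between mu profiles")
    x = a.loc[shared].to_numpy(dtype=float)
    y = b.loc[shared].to_numpy(dtype=float)
    r, p = pearson(x, y)
    rank_r, rank_p = pearson(rankdata(x), rankdata(y))
    return {"n": len(shared), "pearson_r": r, "p": p, "rank_r": rank_r, "rank_p": rank_p}
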