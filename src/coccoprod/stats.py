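"""Correlation screening between proxy profiles and environmental fields.

The screen follows the study design: every proxy-environment pair gets a
Pearson product-moment coefficient with a two-sided p-value from the exact
t transform, flagged significant at a flat alpha (default 0.05) with no
multiple-testing correction; Benjamini-Hochberg adjusted flags are available
as a clearly separated, off-by-default extension column.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist


def pearson(x, y) -> tuple[float, float]:
    """Pearson R and two-sided p for two equal-length series.

    Missing values are removed pairwise.  R is the product-moment coefficient;
    p comes from ``t = R * sqrt((n-2) / (1-R^2))`` against a t distribution
    with n-2 degrees of freedom.  ``|R| = 1`` gives p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError("need >= 3 complete pairs for a correlation")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = np.sqrt(np.sum(xd**2))
    sy = np.sqrt(np.sum(yd**2))
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in one of the series")
    r = float(np.sum(xd * yd) / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0 - 1e-14:  # perfectly collinear up to round-off
        return float(np.sign(r)), 0.0
    t_stat = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * t_dist.sf(abs(t_stat), df=n - 2)
    return r, float(p)


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (step-up), preserving input order."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


def correlation_matrix(
    proxies: pd.DataFrame,
    env: pd.DataFrame,
    alpha: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """Screen every proxy column against every environmental column.

    Both frames are indexed by sample id; only shared samples enter, with
    pairwise-complete deletion of missing values (per-pair n reported).
    Returns a long-format frame with columns ``x, y, n, r, p, significant``
    and, when ``adjust`` is set, ``p_bh, significant_bh``.
    """
    shared = proxies.index.intersection(env.index)
    if len(shared) == 0:
        raise ValueError("no shared samples between proxy and environment tables")
    px = proxies.loc[shared]
    ev = env.loc[shared]
    rows = []
    for xcol in px.columns:
        for ycol in ev.columns:
            x = px[xcol].to_numpy(dtype=float)
            y = ev[ycol].to_numpy(dtype=float)
            keep = np.isfinite(x) & np.isfinite(y)
            n = int(keep.sum())
            try:
                r, p = pearson(x, y)
            except ValueError:
                r, p = np.nan, np.nan
            rows.append({"x": xcol, "y": ycol, "n": n, "r": r, "p": p})
    out = pd.DataFrame(rows)
    out["significant"] = out["p"] <= alpha
    if adjust:
        ok = out["p"].notna()
        adj = np.full(len(out), np.nan)
        adj[ok.to_numpy()] = benjamini_hochberg(out.loc[ok, "p"].to_numpy())
        out["p_bh"] = adj
        out["significant_bh"] = out["p_bh"] <= alpha
    return out
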