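"""Group-specific calcite production and the latitudinal dominance boundary.

Calcite production per taxon is the product of its coccolith absolute
abundance N (coccoliths per gram of sediment) and its per-sample mean
coccolith mass, i.e. pg CaCO3 per gram of dry sediment.  Summing within the
low and high PIC/POC groups and normalizing yields the complementary percent
contributions whose 50% crossover along latitude defines the dominance
boundary between the two functional groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import HIGH_GROUP_TAXA, LOW_GROUP_TAXA


@dataclass(frozen=True)
class BoundaryResult:
    """Dominance-boundary detection along the transect.

    ``crossings`` holds every latitude where the smoothed high-group
    contribution crosses 50%; ``primary`` is the crossing with the steepest
    contribution change across its bracketing samples (None when the series
    never crosses).  ``environment`` optionally carries environmental fields
    interpolated at the primary boundary.
    """

    crossings: tuple[float, ...]
    primary: float | None
    environment: dict[str, float] = field(default_factory=dict)


def taxon_production(abundance, mean_mass):
    """Calcite production CP = N x mean coccolith mass (pg CaCO3 per g)."""
    n = np.asarray(abundance, dtype=float)
    m = np.asarray(mean_mass, dtype=float)
    if np.any(n < 0):
        raise ValueError("absolute abundance must be non-negative")
    if np.any(m <= 0):
        raise ValueError("mean coccolith mass must be positive")
    cp = n * m
    return float(cp) if cp.ndim == 0 else cp


def group_contributions(cp_by_taxon: dict[str, float]) -> dict[str, float]:
    """Percent contribution of the low and high PIC/POC groups to calcite.

    ``cp_by_taxon`` maps target-taxon name to its calcite production; taxa
    with missing (NaN) production are excluded with a warning.  The two
    percentages are complementary and sum to 100.
    """
    def group_sum(taxa):
        total = 0.0
        for t in taxa:
            cp = cp_by_taxon.get(t)
            if cp is None or not np.isfinite(cp):
                warnings.warn(
                    f"taxon {t!r} has no calcite production value; excluded from group sums",
                    stacklevel=2,
                )
                continue
            total += cp
        return total

    low = group_sum(LOW_GROUP_TAXA)
    high = group_sum(HIGH_GROUP_TAXA)
    total = low + high
    if total <= 0:
        raise ValueError("all-zero calcite production: group contributions undefined")
    return {"low": 100.0 * low / total, "high": 100.0 * high / total}


def build_production_table(
    abundance: pd.DataFrame, morphometry: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Per-sample production table from census abundances and morphometry.

    ``abundance`` needs ``sample_id, taxon, abundance_per_g``; ``morphometry``
    needs ``sample_id, taxon, mean_mass_pg, usable``; ``metadata`` maps
    ``sample_id`` to ``latitude``.  Returns one row per sample with per-taxon
    CP columns, group CPs and percent contributions, sorted by latitude.
    """
    merged = abundance.merge(
        morphometry[["sample_id", "taxon", "mean_mass_pg", "usable"]],
        on=["sample_id", "taxon"],
        how="left",
    )
    rows = []
    for sample_id, grp in merged.groupby("sample_id"):
        cp_by_taxon: dict[str, float] = {}
        for r in grp.itertuples(index=False):
            if r.abundance_per_g == 0:
                cp_by_taxon[r.taxon] = 0.0
            elif pd.isna(r.mean_mass_pg) or not bool(r.usable):
                cp_by_taxon[r.taxon] = np.nan  # N > 0 but no usable mass
            else:
                cp_by_taxon[r.taxon] = taxon_production(r.abundance_per_g, r.mean_mass_pg)
        pct = group_contributions(cp_by_taxon)
        low_cp = np.nansum([cp_by_taxon.get(t, np.nan) for t in LOW_GROUP_TAXA])
        high_cp = np.nansum([cp_by_taxon.get(t, np.nan) for t in HIGH_GROUP_TAXA])
        row = {"sample_id": sample_id}
        for taxon, cp in cp_by_taxon.items():
            row[f"cp_{taxon}"] = cp
        row.update(
            {
                "cp_low": low_cp,
                "cp_high": high_cp,
                "cp_total": low_cp + high_cp,
                "pct_low": pct["low"],
                "pct_high": pct["high"],
            }
        )
        rows.append(row)
    out = pd.DataFrame(rows).merge(
        metadata[["sample_id", "latitude"]], on="sample_id", how="left"
    )
    return out.sort_values("latitude", ignore_index=True)


def detect_boundary(
    latitudes, pct_high, smoothing_window: int = 1
) -> BoundaryResult:
    """Locate the 50% dominance crossover(s) of the high PIC/POC group.

    The series is sorted by latitude, optionally smoothed with a centred
    moving average (odd window; 1 = none), and every sign change of
    ``pct_high - 50`` is resolved to a latitude by linear interpolation.
    Samples sitting exactly at 50% are crossings at their own latitude.  The
    primary boundary is the crossing with the largest contribution change
    across its bracketing pair; a series that never crosses yields an empty
    result rather than an error.
    """
    lat = np.asarray(latitudes, dtype=float)
    pct = np.asarray(pct_high, dtype=float)
    if len(lat) < 3:
        raise ValueError("need >= 3 samples to detect a dominance boundary")
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValueError("smoothing window must be a positive odd count")
    order = np.argsort(lat)
    lat, pct = lat[order], pct[order]
    if np.any(np.diff(lat) == 0):
        raise ValueError("latitudes must be strictly ordered after sorting")
    if smoothing_window > 1:
        half = smoothing_window // 2
        sm = np.array(
            [pct[max(0, i - half) : i + half + 1].mean() for i in range(len(pct))]
        )
    else:
        sm = pct
    d = sm - 50.0

    crossings: list[float] = []
    gradients: list[float] = []
    for i in range(len(d)):
        if d[i] == 0.0:
            crossings.append(float(lat[i]))
            lo = d[i - 1] if i > 0 else d[i]
            hi = d[i + 1] if i < len(d) - 1 else d[i]
            gradients.append(abs(hi - lo))
    for i in range(len(d) - 1):
        if d[i] * d[i + 1] < 0.0:
            frac = d[i] / (d[i] - d[i + 1])
            crossings.append(float(lat[i] + frac * (lat[i + 1] - lat[i])))
            gradients.append(abs(d[i + 1] - d[i]))
    if not crossings:
        return BoundaryResult(crossings=(), primary=None)
    order = np.argsort(crossings)
    crossings_sorted = tuple(np.asarray(crossings)[order])
    primary = crossings[int(np.argmax(gradients))]
    return BoundaryResult(crossings=crossings_sorted, primary=primary)


def characterize_boundary(
    boundary: float, env: pd.DataFrame, fields: tuple[str, ...] | None = None
) -> dict[str, float]:
    """Interpolate environmental fields at the boundary latitude.

    Piecewise-linear interpolation in latitude of each requested field of the
    per-sample environment table (must contain ``latitude``).  Extrapolation
    beyond the sampled range is refused.
    """
    env_sorted = env.sort_values("latitude")
    lat = env_sorted["latitude"].to_numpy(dtype=float)
    if not lat[0] <= boundary <= lat[-1]:
        raise ValueError(
            f"boundary {boundary} outside sampled latitude range [{lat[0]}, {lat[-1]}]"
        )
    if fields is None:
        fields = tuple(
            c for c in env_sorted.columns if c != "latitude" and env_sorted[c].dtype.kind == "f"
        )
    return {
        f: float(np.interp(boundary, lat, env_sorted[f].to_numpy(dtype=float)))
        for f in fields
    }
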