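"""Assemblage census: absolute abundance, relative abundance and grouping.

Counts come from settling slides with known geometry: a known mass of dry
sediment settles homogeneously over a deposition area, and specimens are
counted over ``n_fov`` fields of view of known area.  The areal specimen
density scaled to the full deposition area and divided by the settled mass
gives the absolute abundance N in coccoliths per gram of dry sediment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .constants import PIC_POC_GROUP

#: Sample-validity thresholds: above the carbonate compensation influence,
#: supersaturated bottom waters, late-Holocene age, and a statistically
#: representative count.
MAX_DEPTH_M = 3000.0
MIN_OMEGA = 1.0
MAX_AGE_YR = 3000.0
MIN_COUNT = 300

#: Small/large Gephyrocapsa split; the conventional threshold is ~3/3.5 um.
DEFAULT_SIZE_THRESHOLD_UM = 3.0


class UnknownTaxonError(KeyError):
    """A taxon name outside the configured taxonomy."""

    def __init__(self, taxon: str):
        super().__init__(taxon)
        self.taxon = taxon

    def __str__(self) -> str:  # noqa: D105
        return f"taxon {self.taxon!r} is not in the configured taxonomy"


def assign_gephyrocapsa_size_class(
    length: float, threshold: float = DEFAULT_SIZE_THRESHOLD_UM
) -> str:
    """Classify a Gephyrocapsa coccolith as ``small`` or ``large`` by length.

    Lengths exactly at the threshold are classed ``large``.
    """
    if not np.isfinite(length) or length <= 0:
        raise ValueError(f"coccolith length must be positive, got {length}")
    return "small" if length < threshold else "large"


def assign_pic_poc_group(taxon: str, group_map: dict[str, str] | None = None) -> str:
    """Map a taxon to its PIC/POC functional group (``low`` or ``high``)."""
    groups = PIC_POC_GROUP if group_map is None else group_map
    try:
        return groups[taxon]
    except KeyError:
        raise UnknownTaxonError(taxon) from None


def absolute_abundance(count, n_fov, fov_area, deposition_area, sediment_mass):
    """Absolute abundance N (coccoliths per g dry sediment) from slide geometry.

    N = count * deposition_area / (n_fov * fov_area * sediment_mass), with
    areas in the same units and mass in grams.  Vectorized over array inputs.
    """
    count = np.asarray(count, dtype=float)
    n_fov = np.asarray(n_fov, dtype=float)
    fov_area = np.asarray(fov_area, dtype=float)
    deposition_area = np.asarray(deposition_area, dtype=float)
    sediment_mass = np.asarray(sediment_mass, dtype=float)
    if np.any(count < 0):
        raise ValueError("counts must be non-negative")
    for name, v in (
        ("n_fov", n_fov),
        ("fov_area", fov_area),
        ("deposition_area", deposition_area),
        ("sediment_mass", sediment_mass),
    ):
        if np.any(v <= 0):
            raise ValueError(f"{name} must be strictly positive")
    n = count * deposition_area / (n_fov * fov_area * sediment_mass)
    return float(n) if n.ndim == 0 else n


def relative_abundance(counts: pd.Series) -> pd.Series:
    """Fractional abundance per taxon within one sample; sums to 1."""
    total = counts.sum()
    if total <= 0:
        raise ValueError("all-zero sample: relative abundance undefined")
    return counts / total


def validate_sample(
    depth_m: float, omega_at_depth: float, age_yr: float, total_count: int
) -> set[str]:
    """Screen one sample against the study's validity criteria.

    Returns the set of raised flags (empty when the sample passes):
    ``depth`` (>= 3000 m), ``omega`` (Omega_calcite <= 1 at depth, i.e.
    dissolution-prone), ``age`` (>= 3000 yr BP) and ``count`` (< 300
    specimens).  Validation never aborts a run.
    """
    flags: set[str] = set()
    if depth_m >= MAX_DEPTH_M:
        flags.add("depth")
    if omega_at_depth <= MIN_OMEGA:
        flags.add("omega")
    if age_yr >= MAX_AGE_YR:
        flags.add("age")
    if total_count < MIN_COUNT:
        flags.add("count")
    return flags


def summarize_census(census: pd.DataFrame) -> pd.DataFrame:
    """Per sample x taxon absolute and relative abundances from a census table.

    Expects columns ``sample_id, taxon, count, n_fov, fov_area_mm2,
    deposition_area_mm2, sediment_mass_g``; adds ``abundance_per_g``
    (N), ``rel_abundance`` and the taxon's ``pic_poc_group``.  Taxa outside
    the five target groups are retained in totals (they enter relative
    abundance) but carry group ``n/a``.
    """
    out = census.copy()
    out["abundance_per_g"] = absolute_abundance(
        out["count"],
        out["n_fov"],
        out["fov_area_mm2"],
        out["deposition_area_mm2"],
        out["sediment_mass_g"],
    )
    out["rel_abundance"] = out.groupby("sample_id")["count"].transform(
        lambda c: relative_abundance(c)
    )
    out["pic_poc_group"] = [
        PIC_POC_GROUP.get(t, "n/a") for t in out["taxon"]
    ]
    return out
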