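"""Per-coccolith calcification-intensity indices and the morphometric PIC/POC.

A coccolith of mass ``m`` (pg CaCO3) spanning area ``A`` (um2) has mean
calcite thickness ``T = m / (rho * A)``.  Because thickness scales
allometrically with coccolith length, raw thickness confounds calcification
intensity with size; the size-normalized (SN) thickness rescales each
coccolith's thickness to a per-taxon reference length using a fitted power-law
exponent, leaving a size-independent index of calcite investment per platelet.
The elliptical shape factor ``kse = m / (rho * L^2 * W)`` is an alternative
dimensionless index, and for the small-celled low PIC/POC group a cellular
PIC/POC ratio is built from mean coccolith mass, coccoliths per cell and a
volume-to-organic-carbon allometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import CARBON_FRACTION_CALCITE, RHO_CALCITE

#: Minimum measured coccoliths for a usable allometry fit or sample index.
MIN_COCCOLITHS = 10


@dataclass(frozen=True)
class AllometryFit:
    """Fitted thickness-length allometry ``T = t0 * L^beta`` for one taxon."""

    taxon: str
    beta: float
    ln_t0: float
    l_ref: float
    n: int
    r_squared: float


@dataclass(frozen=True)
class CarbonQuota:
    """Cellular carbon quota: PIC and POC per cell (pg C) and their ratio."""

    taxon: str
    sample_id: str
    pic_pg_c: float
    poc_pg_c: float
    pic_poc: float


def mean_thickness(mass, area, rho_calcite: float = RHO_CALCITE):
    """Mean coccolith calcite thickness (um) from mass (pg) and area (um2)."""
    mass = np.asarray(mass, dtype=float)
    area = np.asarray(area, dtype=float)
    if np.any(mass <= 0) or np.any(area <= 0) or rho_calcite <= 0:
        raise ValueError("mass, area and calcite density must be positive")
    t = mass / (rho_calcite * area)
    return float(t) if t.ndim == 0 else t


def fit_allometry(records: pd.DataFrame, taxon: str | None = None) -> AllometryFit:
    """Fit ``ln T = ln t0 + beta ln L`` by OLS over one taxon's coccoliths.

    ``records`` needs columns ``length_um``, ``mass_pg``, ``area_um2`` (and
    optionally ``taxon`` when ``taxon`` is None).  The reference length is the
    geometric mean of the fitting set.
    """
    if taxon is None:
        taxa = records["taxon"].unique()
        if len(taxa) != 1:
            raise ValueError("records must contain a single taxon")
        taxon = taxa[0]
    n = len(records)
    if n < MIN_COCCOLITHS:
        raise ValueError(f"need >= {MIN_COCCOLITHS} coccoliths for an allometry fit, got {n}")
    length = records["length_um"].to_numpy(dtype=float)
    thick = mean_thickness(records["mass_pg"].to_numpy(), records["area_um2"].to_numpy())
    ln_l = np.log(length)
    ln_t = np.log(thick)
    if np.ptp(ln_l) == 0:
        raise ValueError("zero variance in coccolith length: allometry fit degenerate")
    beta, ln_t0 = np.polyfit(ln_l, ln_t, 1)
    resid = ln_t - (ln_t0 + beta * ln_l)
    ss_tot = np.sum((ln_t - ln_t.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
    return AllometryFit(
        taxon=taxon,
        beta=float(beta),
        ln_t0=float(ln_t0),
        l_ref=float(np.exp(ln_l.mean())),
        n=n,
        r_squared=float(r2),
    )


def sn_thickness(thickness, length, fit: AllometryFit):
    """Size-normalized thickness: rescale to the taxon reference length.

    ``SN = T * (L_ref / L)^beta``; at ``L = L_ref`` the index equals the raw
    thickness, and on the fitting set it is uncorrelated with length.
    """
    length = np.asarray(length, dtype=float)
    if np.any(length <= 0):
        raise ValueError("coccolith length must be positive")
    sn = np.asarray(thickness, dtype=float) * (fit.l_ref / length) ** fit.beta
    return float(sn) if sn.ndim == 0 else sn


def elliptical_shape_factor(mass, length, width, rho_calcite: float = RHO_CALCITE):
    """Dimensionless elliptical shape factor ``kse = m / (rho * L^2 * W)``.

    Reduces to the classic cubic shape factor ``m / (rho L^3)`` for circular
    coccoliths (W = L) and is invariant under uniform magnification.
    """
    length = np.asarray(length, dtype=float)
    width = np.asarray(width, dtype=float)
    mass = np.asarray(mass, dtype=float)
    if np.any(length <= 0) or np.any(width <= 0) or np.any(mass <= 0):
        raise ValueError("mass and axes must be positive")
    k = mass / (rho_calcite * length**2 * width)
    return float(k) if k.ndim == 0 else k


def cell_diameter_from_coccolith(length, alpha: float, beta: float):
    """Cell diameter (um) from coccolith length via a linear dimensional map.

    ``d = alpha + beta * L``.  The coefficients are calibration constants
    transcribed from the coccolith-to-cell dimensional literature and injected
    through configuration; ``beta = 0`` (constant diameter) is allowed but
    degenerate.
    """
    d = alpha + beta * np.asarray(length, dtype=float)
    if np.any(d <= 0):
        raise ValueError("derived cell diameter must be positive")
    return float(d) if np.ndim(d) == 0 else d


def cell_volume_from_diameter(diameter):
    """Spherical cell volume (um3) from diameter (um)."""
    d = np.asarray(diameter, dtype=float)
    v = (np.pi / 6.0) * d**3
    return float(v) if v.ndim == 0 else v


def cellular_pic_poc(
    mean_coccolith_mass: float,
    coccoliths_per_cell: int,
    cell_volume: float,
    poc_a: float = 0.216,
    poc_b: float = 0.939,
    taxon: str = "",
    sample_id: str = "",
) -> CarbonQuota:
    """Morphometric cellular PIC/POC ratio for the low PIC/POC group.

    PIC per cell converts the coccosphere calcite (mean coccolith mass x
    coccoliths per cell) to carbon with the 0.12 carbon mass fraction of
    CaCO3; POC per cell comes from the phytoplankton volume-to-carbon
    allometry ``POC = a * V^b`` (pg C, V in um3).  ``a``, ``b`` and
    ``coccoliths_per_cell`` are literature-style calibration constants.
    """
    if mean_coccolith_mass <= 0 or cell_volume <= 0:
        raise ValueError("coccolith mass and cell volume must be positive")
    if coccoliths_per_cell <= 0:
        raise ValueError("coccoliths per cell must be a positive count")
    pic = mean_coccolith_mass * coccoliths_per_cell * CARBON_FRACTION_CALCITE
    poc = poc_a * cell_volume**poc_b
    if pic <= 0 or poc <= 0:
        raise ValueError("carbon quota must be positive")
    return CarbonQuota(
        taxon=taxon, sample_id=sample_id, pic_pg_c=pic, poc_pg_c=poc, pic_poc=pic / poc
    )


def summarize_morphometrics(
    coccoliths: pd.DataFrame, min_n: int = MIN_COCCOLITHS
) -> tuple[pd.DataFrame, dict[str, AllometryFit]]:
    """Per sample x taxon morphometric indices from the coccolith table.

    Fits one global thickness-length allometry per taxon (pooled across
    samples), then averages per-coccolith indices within each sample x taxon
    cell.  Cells with fewer than ``min_n`` measured coccoliths are flagged
    missing (``usable = False``) rather than dropped.

    Returns the summary table and the per-taxon allometry fits.  When a
    taxon's pooled fit is unusable (too few coccoliths or degenerate lengths)
    the proportional normalization ``beta = 1`` is used as fallback.
    """
    fits: dict[str, AllometryFit] = {}
    for taxon, recs in coccoliths.groupby("taxon"):
        try:
            fits[taxon] = fit_allometry(recs, taxon=taxon)
        except ValueError:
            length = recs["length_um"].to_numpy(dtype=float)
            l_ref = float(np.exp(np.mean(np.log(length)))) if len(recs) else 1.0
            fits[taxon] = AllometryFit(
                taxon=taxon, beta=1.0, ln_t0=np.nan, l_ref=l_ref, n=len(recs), r_squared=np.nan
            )

    rows = []
    for (sample_id, taxon), recs in coccoliths.groupby(["sample_id", "taxon"]):
        fit = fits[taxon]
        thick = mean_thickness(recs["mass_pg"].to_numpy(), recs["area_um2"].to_numpy())
        sn = sn_thickness(thick, recs["length_um"].to_numpy(), fit)
        kse = elliptical_shape_factor(
            recs["mass_pg"].to_numpy(),
            recs["length_um"].to_numpy(),
            recs["width_um"].to_numpy(),
        )
        rows.append(
            {
                "sample_id": sample_id,
                "taxon": taxon,
                "n_measured": len(recs),
                "mean_length_um": recs["length_um"].mean(),
                "mean_mass_pg": recs["mass_pg"].mean(),
                "mean_thickness_um": float(np.mean(thick)),
                "sn_thickness_um": float(np.mean(sn)),
                "kse": float(np.mean(kse)),
                "usable": len(recs) >= min_n,
            }
        )
    return pd.DataFrame(rows), fits
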