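"""Calcification-intensity indices: thickness, allometry, SN thickness, kse."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coccoprod.morphometrics import (
    AllometryFit,
    cell_diameter_from_coccolith,
    cell_volume_from_diameter,
    cellular_pic_poc,
    elliptical_shape_factor,
    fit_allometry,
    mean_thickness,
    sn_thickness,
    summarize_morphometrics,
)
from coccoprod.stats import pearson


def _powerlaw_records(beta, t0=0.1, n=60, taxon="small Gephyrocapsa"):
    """Noiseless records with T = t0 * L^beta exactly."""
    rng = np.random.default_rng(5)
    length = rng.uniform(2.0, 12.0, n)
    thick = t0 * length**beta
    area = 0.8 * (np.pi / 4) * length * (0.85 * length)
    return pd.DataFrame(
        {
            "taxon": taxon,
            "sample_id": "S01",
            "length_um": length,
            "width_um": 0.85 * length,
            "area_um2": area,
            "mass_pg": 2.7 * area * thick,
        }
    )


def test_mean_thickness_definition():
    assert mean_thickness(2.7, 1.0) == pytest.approx(1.0)
    assert mean_thickness(5.4, 4.0) == pytest.approx(0.5)
    # inverse proportionality in area
    assert mean_thickness(5.4, 8.0) == pytest.approx(0.25)
    with pytest.raises(ValueError):
        mean_thickness(-1.0, 1.0)


@pytest.mark.parametrize("beta", [1.0, 0.7])
def test_allometry_fit_recovers_exact_exponent(beta):
    fit = fit_allometry(_powerlaw_records(beta))
    assert fit.beta == pytest.approx(beta, abs=1e-6)
    assert np.exp(fit.ln_t0) == pytest.approx(0.1, rel=1e-6)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-9)


def test_allometry_fit_degenerate_inputs():
    recs = _powerlaw_records(1.0, n=5)
    with pytest.raises(ValueError, match=">= 10"):
        fit_allometry(recs)
    const = _powerlaw_records(1.0)
    const["length_um"] = 5.0
    with pytest.raises(ValueError, match="variance"):
        fit_allometry(const)


def test_sn_thickness_reference_identity_and_example():
    fit = AllometryFit("t", beta=1.0, ln_t0=0.0, l_ref=3.0, n=50, r_squared=1.0)
    assert sn_thickness(0.4, 3.0, fit) == pytest.approx(0.4)  # L = L_ref
    assert sn_thickness(0.4, 6.0, fit) == pytest.approx(0.2)
    flat = AllometryFit("t", beta=0.0, ln_t0=0.0, l_ref=3.0, n=50, r_squared=1.0)
    assert sn_thickness(0.37, 9.9, flat) == pytest.approx(0.37)  # no-allometry limit


def test_sn_thickness_decorrelates_size_on_fitting_set():
    """After removing the fitted allometry the index carries no size trend.

    Exact power-law data makes SN constant (degenerate), so a small
    size-independent thickness scatter is added; the residual index must be
    uncorrelated with length."""
    rng = np.random.default_rng(21)
    n = 2000
    length = rng.uniform(2.0, 12.0, n)
    thick = 0.1 * length**0.85 * np.exp(rng.normal(0.0, 0.05, n))
    area = 0.8 * (np.pi / 4) * length * (0.85 * length)
    recs = pd.DataFrame(
        {
            "taxon": "small Gephyrocapsa",
            "sample_id": "S01",
            "length_um": length,
            "width_um": 0.85 * length,
            "area_um2": area,
            "mass_pg": 2.7 * area * thick,
        }
    )
    fit = fit_allometry(recs)
    assert fit.beta == pytest.approx(0.85, abs=0.01)
    sn = sn_thickness(thick, length, fit)
    r, _ = pearson(sn, length)
    assert abs(r) < 0.05


def test_kse_examples_and_circular_limit():
    assert elliptical_shape_factor(2.7, 1.0, 1.0) == pytest.approx(1.0)
    assert elliptical_shape_factor(162.0, 9.0, 8.0) == pytest.approx(162 / (2.7 * 81 * 8))
    # W = L reduces to the cubic shape factor m / (rho L^3)
    assert elliptical_shape_factor(27.0, 2.0, 2.0) == pytest.approx(27 / (2.7 * 8))


@settings(deadline=None, max_examples=50)
@given(
    length=st.floats(min_value=1.0, max_value=15.0),
    ratio=st.floats(min_value=0.3, max_value=1.0),
    kse=st.floats(min_value=0.01, max_value=0.2),
    scale=st.floats(min_value=0.25, max_value=4.0),
)
def test_kse_invariant_under_magnification(length, ratio, kse, scale):
    """(L, W, m) -> (sL, sW, s^3 m) leaves the shape factor unchanged."""
    width = ratio * length
    mass = kse * 2.7 * length**2 * width
    base = elliptical_shape_factor(mass, length, width)
    scaled = elliptical_shape_factor(mass * scale**3, length * scale, width * scale)
    assert scaled == pytest.approx(base, rel=1e-9)


def test_cell_diameter_linear_map():
    assert cell_diameter_from_coccolith(2.5, alpha=0.0, beta=2.0) == pytest.approx(5.0)
    assert cell_diameter_from_coccolith(9.9, alpha=4.2, beta=0.0) == pytest.approx(4.2)
    with pytest.raises(ValueError):
        cell_diameter_from_coccolith(1.0, alpha=-5.0, beta=1.0)
    lengths = np.linspace(2, 12, 20)
    d = cell_diameter_from_coccolith(lengths, alpha=1.0, beta=1.2)
    assert np.all(np.diff(d) > 0)


def test_cellular_pic_poc_worked_example():
    """m=1.5 pg, 15 liths/cell, d=5 um, POC = 0.216 V^0.939."""
    v = cell_volume_from_diameter(5.0)
    assert v == pytest.approx(np.pi / 6 * 125)
    q = cellular_pic_poc(1.5, 15, v, poc_a=0.216, poc_b=0.939)
    # independent log-space computation of POC
    poc_ref = np.exp(np.log(0.216) + 0.939 * np.log(v))
    assert q.pic_pg_c == pytest.approx(1.5 * 15 * 12.011 / 100.087, rel=1e-12)
    assert q.pic_pg_c == pytest.approx(2.70, abs=0.01)
    assert q.poc_pg_c == pytest.approx(poc_ref, rel=1e-12)
    assert q.poc_pg_c == pytest.approx(10.95, abs=0.05)
    assert q.pic_poc == pytest.approx(0.247, abs=0.005)


def test_cellular_pic_poc_linearity_and_errors():
    v = cell_volume_from_diameter(5.0)
    q1 = cellular_pic_poc(1.5, 15, v)
    q2 = cellular_pic_poc(3.0, 15, v)
    assert q2.pic_pg_c == pytest.approx(2 * q1.pic_pg_c)
    assert q2.pic_poc == pytest.approx(2 * q1.pic_poc)
    with pytest.raises(ValueError):
        cellular_pic_poc(1.5, 0, v)


def test_summary_flags_sparse_cells_missing(transect):
    _, _, _, coccoliths, _ = transect
    summary, fits = summarize_morphometrics(coccoliths)
    sparse = summary[summary["n_measured"] < 10]
    assert (~sparse["usable"]).all()
    assert set(fits) == set(coccoliths["taxon"].unique())


def test_coupling_sign_recovery_on_default_transect(transect):
    """Sample-mean SN thickness tracks true mu positively for the low
    PIC/POC group and negatively for the high group — the core contrast."""
    _, _, _, coccoliths, truth = transect
    summary, _ = summarize_morphometrics(coccoliths)
    merged = summary[summary["usable"]].merge(
        truth.per_sample_taxon, on=["sample_id", "taxon"]
    )
    for taxon, grp in merged.groupby("taxon"):
        r, _ = pearson(grp["sn_thickness_um"], grp["mu_true"])
        expected_sign = 1 if "Gephyrocapsa" in taxon else -1
        assert np.sign(r) == expected_sign, taxon
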