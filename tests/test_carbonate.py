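"""Carbonate-system solver tests against an independently coded oracle.

The oracle re-transcribes the published equilibrium-constant formulations
(Lueker 2000, Dickson 1990, Millero 1995, Mucci 1983) and solves the
alkalinity balance by coarse pH-grid scan plus bisection — a solution path
independent of the package's Brent solver.
"""

import numpy as np
import pytest

from coccoprod.carbonate import (
    CONSTANTS_DIALECT,
    calcium_concentration,
    dic_ta_ratio,
    preindustrial_sst,
    solve_carbonate,
    total_boron,
)


# --- independently coded reference implementation (oracle) -----------------

def _oracle_constants(t_c, s):
    """Surface equilibrium constants, retyped from the published fits."""
    tk = t_c + 273.15
    # Lueker et al. 2000
    k1 = 10 ** -(
        3633.86 / tk - 61.2172 + 9.67770 * np.log(tk) - 0.011555 * s + 0.0001152 * s**2
    )
    k2 = 10 ** -(
        471.78 / tk + 25.9290 - 3.16967 * np.log(tk) - 0.01781 * s + 0.0001122 * s**2
    )
    # Dickson 1990 boric acid
    kb = np.exp(
        (-8966.90 - 2890.53 * s**0.5 - 77.942 * s + 1.728 * s**1.5 - 0.0996 * s**2) / tk
        + 148.0248 + 137.1942 * s**0.5 + 1.62142 * s
        + (-24.4344 - 25.085 * s**0.5 - 0.2474 * s) * np.log(tk)
        + 0.053105 * s**0.5 * tk
    )
    # Millero 1995 water
    kw = np.exp(
        148.9802 - 13847.26 / tk - 23.6521 * np.log(tk)
        + (118.67 / tk - 5.977 + 1.0495 * np.log(tk)) * s**0.5 - 0.01615 * s
    )
    return k1, k2, kb, kw


def _oracle_solve(ta, dic, t_c, s):
    """Speciation by dense pH scan + bisection on the alkalinity residual."""
    k1, k2, kb, kw = _oracle_constants(t_c, s)
    bt = 0.000416 * s / 35.0
    ta_m, dic_m = ta * 1e-6, dic * 1e-6

    def resid(ph):
        h = 10.0**-ph
        d = h * h + k1 * h + k1 * k2
        return (
            dic_m * (k1 * h + 2 * k1 * k2) / d + bt * kb / (kb + h) + kw / h - h - ta_m
        )

    grid = np.linspace(2.0, 12.0, 2001)
    vals = np.array([resid(p) for p in grid])
    idx = int(np.argmax(np.sign(vals[:-1]) != np.sign(vals[1:])))
    lo, hi = grid[idx], grid[idx + 1]
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if resid(lo) * resid(mid) <= 0:
            hi = mid
        else:
            lo = mid
    ph = 0.5 * (lo + hi)
    h = 10.0**-ph
    d = h * h + k1 * h + k1 * k2
    return {
        "co2": dic * h * h / d,
        "hco3": dic * k1 * h / d,
        "co3": dic * k1 * k2 / d,
        "ph": ph,
    }


# --- tests ------------------------------------------------------------------

def test_speciation_matches_independent_oracle_on_grid():
    """Surface speciation agrees with the scan/bisection oracle within 0.5%."""
    rng = np.random.default_rng(11)
    n = 100
    ta = rng.uniform(2100, 2500, n)
    dic = ta * rng.uniform(0.83, 0.97, n)
    t = rng.uniform(0, 30, n)
    s = rng.uniform(30, 38, n)
    for i in range(n):
        got = solve_carbonate(ta[i], dic[i], t[i], s[i], 0.0)
        ref = _oracle_solve(ta[i], dic[i], t[i], s[i])
        for key in ("co2", "hco3", "co3"):
            assert getattr(got, key) == pytest.approx(ref[key], rel=5e-3)
        assert got.ph == pytest.approx(ref["ph"], abs=1e-3)


def test_species_sum_to_dic_and_alkalinity_residual_closes():
    spec = solve_carbonate(2300, 2100, 15, 35, 0.0)
    assert spec.co2 + spec.hco3 + spec.co3 == pytest.approx(2100, abs=1e-3)
    # alkalinity reconstructed from the species closes on TA
    h = 10**-spec.ph
    bt = total_boron(35) * 1e6
    from coccoprod.carbonate import _equilibrium_constants

    ks = _equilibrium_constants(15.0, 35.0, 0.0)
    boh4 = bt * ks["kb"] / (ks["kb"] + h)
    ta_back = spec.hco3 + 2 * spec.co3 + boh4 + ks["kw"] / h * 1e6 - h * 1e6
    assert ta_back == pytest.approx(2300, abs=1e-4)


def test_increasing_dic_at_fixed_ta_raises_co2_and_lowers_ph():
    dics = np.linspace(1900, 2250, 8)
    specs = [solve_carbonate(2300, d, 15, 35, 0.0) for d in dics]
    co2 = [s.co2 for s in specs]
    ph = [s.ph for s in specs]
    assert np.all(np.diff(co2) > 0)
    assert np.all(np.diff(ph) < 0)


def test_omega_is_carbonate_times_calcium_over_ksp():
    from coccoprod.carbonate import _equilibrium_constants

    spec = solve_carbonate(2350, 2120, 18, 35.5, 0.0)
    ks = _equilibrium_constants(18.0, 35.5, 0.0)
    omega = calcium_concentration(35.5) * spec.co3 * 1e-6 / ks["kspc"]
    assert spec.omega_calcite == pytest.approx(omega, rel=1e-12)


def test_pressure_lowers_omega():
    surf = solve_carbonate(2300, 2100, 2.5, 35, 0.0)
    deep = solve_carbonate(2300, 2100, 2.5, 35, 2500.0)
    assert deep.omega_calcite < surf.omega_calcite


def test_solver_is_deterministic():
    a = solve_carbonate(2300, 2100, 15, 35, 100.0)
    b = solve_carbonate(2300, 2100, 15, 35, 100.0)
    assert a == b
    assert a.constants_dialect == CONSTANTS_DIALECT


@pytest.mark.parametrize(
    "kwargs",
    [
        {"ta": 100.0},      # below accepted range
        {"dic": 5000.0},
        {"salinity": 60.0},
        {"temperature": 50.0},
        {"pressure": -5.0},
    ],
)
def test_out_of_range_inputs_rejected(kwargs):
    base = {"ta": 2300.0, "dic": 2100.0, "temperature": 15.0, "salinity": 35.0, "pressure": 0.0}
    base.update(kwargs)
    with pytest.raises(ValueError):
        solve_carbonate(**base)


def test_dic_ta_ratio_basics():
    assert dic_ta_ratio(2070, 2300) == pytest.approx(0.9)
    assert dic_ta_ratio(2300, 2300) == 1.0
    # invariant under common rescaling
    assert dic_ta_ratio(2070e-6, 2300e-6) == pytest.approx(0.9)
    with pytest.raises(ValueError):
        dic_ta_ratio(2000, 0)


def test_preindustrial_sst_subtracts_anomaly_and_commutes_with_interpolation():
    assert preindustrial_sst(15.8, 0.8) == pytest.approx(15.0)
    assert preindustrial_sst(12.3, 0.0) == 12.3
    # linearity: interpolate-then-correct == correct-then-interpolate
    sst = np.array([10.0, 20.0])
    anom = np.array([0.6, 1.0])
    mid_then = preindustrial_sst(np.interp(0.5, [0, 1], sst), np.interp(0.5, [0, 1], anom))
    then_mid = np.interp(0.5, [0, 1], preindustrial_sst(sst, anom))
    assert mid_then == pytest.approx(then_mid)
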