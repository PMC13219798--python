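"""Seawater carbonate-system speciation and derived environmental state.

Given total alkalinity (TA) and dissolved inorganic carbon (DIC) together with
temperature, salinity and pressure, the solver partitions DIC into dissolved
CO2, bicarbonate and carbonate, returns pH (total scale) and the calcite
saturation state Omega.  The equilibrium-constant dialect is the widely used
surface-ocean set: Lueker et al. (2000) carbonic acid constants, Dickson (1990)
borate, Millero (1995) water, Mucci (1983) calcite solubility, Uppstrom (1974)
total boron and Riley & Tongudai (1967) calcium, all on the total pH scale in
mol per kg of seawater.  Pressure corrections follow the standard molal-volume
formulation so Omega can be evaluated at sample water depth.

The alkalinity balance solved here includes the carbonate, borate and water
contributions; phosphate and silicate alkalinity are neglected, which is below
the per-mil level at open-ocean surface nutrient concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

CONSTANTS_DIALECT = "Lueker00-K1K2/Dickson90-KB/Millero95-KW/Mucci83-Kspc/total-scale"

# Gas constant in cm3 bar mol-1 K-1, for pressure corrections.
_R = 83.14472

_TA_RANGE = (500.0, 4000.0)
_DIC_RANGE = (500.0, 4000.0)
_S_RANGE = (0.0, 45.0)
_T_RANGE = (-2.0, 40.0)


@dataclass(frozen=True)
class CarbonateSpeciation:
    """Equilibrium speciation of the CO2 system (concentrations in umol/kg)."""

    co2: float
    hco3: float
    co3: float
    ph: float
    omega_calcite: float
    constants_dialect: str = CONSTANTS_DIALECT


def _equilibrium_constants(t_c: float, s: float, p_bar: float) -> dict[str, float]:
    """Stoichiometric constants on the total scale at T (degC), S, P (bar)."""
    t = t_c + 273.15
    lnt = np.log(t)
    sqs = np.sqrt(s)

    # Lueker et al. (2000), pK on total scale.
    pk1 = 3633.86 / t - 61.2172 + 9.67770 * lnt - 0.011555 * s + 0.0001152 * s * s
    pk2 = 471.78 / t + 25.9290 - 3.16967 * lnt - 0.01781 * s + 0.0001122 * s * s
    k1 = 10.0 ** (-pk1)
    k2 = 10.0 ** (-pk2)

    # Dickson (1990) boric acid.
    lnkb = (
        (-8966.90 - 2890.53 * sqs - 77.942 * s + 1.728 * s * sqs - 0.0996 * s * s) / t
        + 148.0248
        + 137.1942 * sqs
        + 1.62142 * s
        + (-24.4344 - 25.085 * sqs - 0.2474 * s) * lnt
        + 0.053105 * sqs * t
    )
    kb = np.exp(lnkb)

    # Millero (1995) water dissociation, total scale.
    lnkw = (
        148.9802
        - 13847.26 / t
        - 23.6521 * lnt
        + (118.67 / t - 5.977 + 1.0495 * lnt) * sqs
        - 0.01615 * s
    )
    kw = np.exp(lnkw)

    # Mucci (1983) calcite stoichiometric solubility product.
    log10ksp = (
        -171.9065
        - 0.077993 * t
        + 2839.319 / t
        + 71.595 * np.log10(t)
        + (-0.77712 + 0.0028426 * t + 178.34 / t) * sqs
        - 0.07711 * s
        + 0.0041249 * s * sqs
    )
    kspc = 10.0 ** log10ksp

    if p_bar > 0.0:
        k1 *= _pressure_factor(-25.50 + 0.1271 * t_c, (-3.08 + 0.0877 * t_c) / 1000.0, t, p_bar)
        k2 *= _pressure_factor(-15.82 - 0.0219 * t_c, (1.13 - 0.1475 * t_c) / 1000.0, t, p_bar)
        kb *= _pressure_factor(
            -29.48 + 0.1622 * t_c + 0.002608 * t_c * t_c, -2.84 / 1000.0, t, p_bar
        )
        kw *= _pressure_factor(
            -20.02 + 0.1119 * t_c - 0.001409 * t_c * t_c,
            (-5.13 + 0.0794 * t_c) / 1000.0,
            t,
            p_bar,
        )
        kspc *= _pressure_factor(
            -48.76 + 0.5304 * t_c, (-11.76 + 0.3692 * t_c) / 1000.0, t, p_bar
        )

    return {"k1": k1, "k2": k2, "kb": kb, "kw": kw, "kspc": kspc}


def _pressure_factor(dv: float, dk: float, t_k: float, p_bar: float) -> float:
    return np.exp((-dv + 0.5 * dk * p_bar) * p_bar / (_R * t_k))


def total_boron(s: float) -> float:
    """Total boron (mol/kg) from salinity, Uppstrom (1974)."""
    return 0.000416 * s / 35.0


def calcium_concentration(s: float) -> float:
    """Conservative [Ca2+] (mol/kg) from salinity, Riley & Tongudai (1967)."""
    return (0.02128 / 40.087) * (s / 1.80655)


def solve_carbonate(
    ta: float,
    dic: float,
    temperature: float,
    salinity: float,
    pressure: float = 0.0,
) -> CarbonateSpeciation:
    """Solve the CO2 system from the (TA, DIC) pair.

    Parameters
    ----------
    ta, dic
        Total alkalinity and dissolved inorganic carbon, umol/kg.
    temperature
        In-situ temperature, degC.
    salinity
        Practical salinity.
    pressure
        Hydrostatic pressure, dbar (0 at the surface).

    Returns
    -------
    CarbonateSpeciation
        Species in umol/kg, pH on the total scale, Omega for calcite.
    """
    for name, value, (lo, hi) in (
        ("TA", ta, _TA_RANGE),
        ("DIC", dic, _DIC_RANGE),
        ("salinity", salinity, _S_RANGE),
        ("temperature", temperature, _T_RANGE),
    ):
        if not np.isfinite(value) or not lo <= value <= hi:
            raise ValueError(f"{name}={value} outside accepted range [{lo}, {hi}]")
    if pressure < 0.0 or not np.isfinite(pressure):
        raise ValueError(f"pressure={pressure} must be finite and non-negative")

    ks = _equilibrium_constants(temperature, salinity, pressure / 10.0)
    ta_mol = ta * 1e-6
    dic_mol = dic * 1e-6
    bt = total_boron(salinity)

    def residual(ph: float) -> float:
        h = 10.0 ** (-ph)
        denom = h * h + ks["k1"] * h + ks["k1"] * ks["k2"]
        hco3 = dic_mol * ks["k1"] * h / denom
        co3 = dic_mol * ks["k1"] * ks["k2"] / denom
        boh4 = bt * ks["kb"] / (ks["kb"] + h)
        return hco3 + 2.0 * co3 + boh4 + ks["kw"] / h - h - ta_mol

    lo, hi = 2.0, 12.0
    if residual(lo) * residual(hi) > 0.0:
        raise ValueError("no carbonate-system root for pH in [2, 12]")
    ph = brentq(residual, lo, hi, xtol=1e-13, rtol=8.9e-16)

    h = 10.0 ** (-ph)
    denom = h * h + ks["k1"] * h + ks["k1"] * ks["k2"]
    co2 = dic_mol * h * h / denom
    hco3 = dic_mol * ks["k1"] * h / denom
    co3 = dic_mol * ks["k1"] * ks["k2"] / denom
    omega = calcium_concentration(salinity) * co3 / ks["kspc"]

    return CarbonateSpeciation(
        co2=co2 * 1e6, hco3=hco3 * 1e6, co3=co3 * 1e6, ph=ph, omega_calcite=omega
    )


def dic_ta_ratio(dic: float, ta: float) -> float:
    """DIC/TA ratio; tracks the carbonate-system state of surface seawater."""
    if ta == 0:
        raise ValueError("TA must be non-zero")
    return dic / ta


def preindustrial_sst(sst_modern: float, anomaly: float) -> float:
    """Remove the industrial warming anomaly from a modern SST value."""
    return sst_modern - anomaly


def derive_env_state(env, surface_pressure: float = 100.0, bottom_temperature: float = 2.5):
    """Attach derived carbonate-system fields to a per-sample environment table.

    Speciation of the surface fields is evaluated at a standardized 100 m
    equivalent pressure (``surface_pressure`` dbar); Omega is additionally
    evaluated at each sample's water depth when a ``water_depth_m`` column is
    present, using ``bottom_temperature`` (degC) as the in-situ deep
    temperature since the input carries surface fields only.  Adds columns
    ``co2_umol_kg``, ``hco3_umol_kg``, ``co3_umol_kg``, ``ph``, ``dic_ta``,
    ``sst_preindustrial_c``, ``omega_calcite_surface`` and
    ``omega_calcite_depth``, plus a ``constants_dialect`` provenance column.
    """
    out = env.copy()
    co2, hco3, co3, ph, omg_s, omg_d = [], [], [], [], [], []
    for row in env.itertuples(index=False):
        spec = solve_carbonate(
            row.ta_umol_kg, row.dic_umol_kg, row.sst_c, row.sss_psu, surface_pressure
        )
        co2.append(spec.co2)
        hco3.append(spec.hco3)
        co3.append(spec.co3)
        ph.append(spec.ph)
        omg_s.append(spec.omega_calcite)
        if hasattr(row, "water_depth_m") and np.isfinite(row.water_depth_m):
            deep = solve_carbonate(
                row.ta_umol_kg,
                row.dic_umol_kg,
                bottom_temperature,
                row.sss_psu,
                row.water_depth_m,
            )
            omg_d.append(deep.omega_calcite)
        else:
            omg_d.append(np.nan)
    out["co2_umol_kg"] = co2
    out["hco3_umol_kg"] = hco3
    out["co3_umol_kg"] = co3
    out["ph"] = ph
    out["omega_calcite_surface"] = omg_s
    out["omega_calcite_depth"] = omg_d
    out["dic_ta"] = out["dic_umol_kg"] / out["ta_umol_kg"]
    out["sst_preindustrial_c"] = out["sst_c"] - out["sst_anomaly_c"]
    out["constants_dialect"] = CONSTANTS_DIALECT
    return out
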