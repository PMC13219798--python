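"""Derive per-sample proxies from the simulated input tables.

Reads results/synthetic/ (run 01 first) and computes, per sample x taxon:
absolute abundance N (coccoliths per g of sediment), relative abundance,
mean coccolith morphometry with the calcification-intensity indices
(SN thickness, kse), cellular PIC/POC for the low PIC/POC group, growth-rate
estimates (size-, phosphate-, SST- and CO2-based), and the carbonate-system
environmental state.  Writes the stage tables under results/.

Run from the repository root:  python analysis/02_derive_proxies.py
"""

import dataclasses
from pathlib import Path

import pandas as pd

from coccoprod import carbonate, census, morphometrics
from coccoprod.constants import LOW_GROUP_TAXA
from coccoprod.io import read_table, write_table
from coccoprod.pipeline import RunConfig, mu_size_table
from coccoprod import growth

IN = Path("results/synthetic")
OUT = Path("results")


def main() -> None:
    cfg = RunConfig()
    census_tbl = read_table(IN / "census.csv", "census")
    coccoliths = read_table(IN / "coccoliths.csv", "coccoliths")
    env = read_table(IN / "environment.csv", "environment")

    env_state = carbonate.derive_env_state(env)
    abundance = census.summarize_census(census_tbl)
    morpho, fits = morphometrics.summarize_morphometrics(coccoliths)

    mu_size = mu_size_table(morpho, cfg)
    mu_env = []
    for r in env_state.itertuples(index=False):
        for est, val in (
            ("po4", growth.mu_from_po4(r.po4_umol_l, cfg.mu.po4)),
            ("sst", growth.mu_from_env(r.sst_preindustrial_c, "sst", cfg.mu)),
            ("co2", growth.mu_from_env(r.co2_umol_kg, "co2", cfg.mu)),
        ):
            mu_env.append(
                {"sample_id": r.sample_id, "taxon": "assemblage",
                 "estimator": est, "mu_div_day": val}
            )
    mu_table = pd.concat([mu_size, pd.DataFrame(mu_env)], ignore_index=True)

    quotas = []
    for r in morpho[morpho["usable"]].itertuples(index=False):
        if r.taxon not in LOW_GROUP_TAXA:
            continue
        d = morphometrics.cell_diameter_from_coccolith(
            r.mean_length_um, cfg.cell_diameter.alpha, cfg.cell_diameter.beta
        )
        q = morphometrics.cellular_pic_poc(
            r.mean_mass_pg, cfg.carbon_quota.coccoliths_per_cell,
            morphometrics.cell_volume_from_diameter(d),
            cfg.carbon_quota.poc_a, cfg.carbon_quota.poc_b,
            taxon=r.taxon, sample_id=r.sample_id,
        )
        quotas.append(dataclasses.asdict(q))

    write_table(env_state, OUT / "env_state.csv")
    write_table(abundance, OUT / "abundance.csv")
    write_table(morpho, OUT / "morphometry.csv")
    write_table(mu_table, OUT / "mu_profiles.csv")
    write_table(pd.DataFrame(quotas), OUT / "pic_poc_quotas.csv")

    n_total = abundance.groupby("sample_id")["abundance_per_g"].sum()
    print(f"N (total assemblage): {n_total.min():.2e} - {n_total.max():.2e} coccoliths/g")
    for taxon, fit in sorted(fits.items()):
        print(f"  allometry {taxon}: beta={fit.beta:.2f}, L_ref={fit.l_ref:.2f} um, n={fit.n}")
    q = pd.DataFrame(quotas)
    print(f"low-group cellular PIC/POC: {q['pic_poc'].min():.2f} - {q['pic_poc'].max():.2f}")
    print("stage tables written to results/")


if __name__ == "__main__":
    main()
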