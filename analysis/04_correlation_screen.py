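"""Pearson screen of proxy profiles against environmental fields.

Builds per-sample proxy profiles (per-taxon N and SN thickness) from the
stage tables (run 02 first) and correlates each against the surface
environmental fields, flagging pairs significant at p <= 0.05, as in the
study's statistical analysis.  Writes the long-format correlation table to
results/correlations.csv.

Run from the repository root:  python analysis/04_correlation_screen.py
"""

from pathlib import Path

import pandas as pd

from coccoprod.io import write_table
from coccoprod.stats import correlation_matrix

IN = Path("results")

ENV_FIELDS = [
    "sst_preindustrial_c", "sss_psu", "po4_umol_l", "ta_umol_kg", "dic_umol_kg",
    "co2_umol_kg", "hco3_umol_kg", "dic_ta", "d13c_dic_permil", "mld_m",
]


def main() -> None:
    abundance = pd.read_csv(IN / "abundance.csv")
    morpho = pd.read_csv(IN / "morphometry.csv")
    env_state = pd.read_csv(IN / "env_state.csv")

    n_wide = abundance.pivot(index="sample_id", columns="taxon", values="abundance_per_g")
    n_wide.columns = [f"N {t}" for t in n_wide.columns]
    sn_wide = morpho[morpho["usable"]].pivot(
        index="sample_id", columns="taxon", values="sn_thickness_um"
    )
    sn_wide.columns = [f"SN {t}" for t in sn_wide.columns]
    proxies = n_wide.join(sn_wide, how="outer")
    env_idx = env_state.set_index("sample_id")[ENV_FIELDS]

    corr = correlation_matrix(proxies, env_idx, alpha=0.05)
    write_table(corr, IN / "correlations.csv")

    sig = corr[corr["significant"]]
    print(f"{len(corr)} proxy-environment pairs screened, {len(sig)} significant at p<=0.05")
    key = corr[(corr.x == "SN small Gephyrocapsa") & (corr.y == "d13c_dic_permil")].iloc[0]
    print(f"SN thickness (small Gephyrocapsa) vs d13C_DIC: "
          f"R={key.r:.2f}, p={key.p:.2g}, n={key.n}")
    strongest = sig.iloc[sig["r"].abs().argsort()[::-1]].head(5)
    for row in strongest.itertuples(index=False):
        print(f"  {row.x} ~ {row.y}: R={row.r:+.2f} (p={row.p:.2g})")
    print("results/correlations.csv written")


if __name__ == "__main__":
    main()
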