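"""End-to-end pipeline: tables in, proxies, production, boundary and stats out.

``run_pipeline`` chains the stages exactly as the CLI subcommands do: read or
simulate the four input tables, derive the carbonate-system environmental
state, turn census counts into absolute/relative abundances, compute
morphometric calcification indices, estimate growth-rate profiles, build the
production table, locate and characterize the dominance boundary, and screen
proxy-environment correlations.  Outputs are stage CSVs plus one JSON summary
embedding the configuration hash and all provenance strings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import carbonate, census, growth, io, morphometrics, production, stats
from .constants import LOW_GROUP_TAXA, TARGET_TAXA
from .synthetic import GeneratorConfig, TaxonParams, generate_transect


@dataclass(frozen=True)
class CellDiameterConfig:
    """Linear coccolith-length to cell-diameter map ``d = alpha + beta * L``."""

    alpha: float = 1.0
    beta: float = 1.2
    provenance: str = "placeholder: coccolith-to-cell dimensional relationship, transcribe from source"


@dataclass(frozen=True)
class CarbonQuotaConfig:
    """Coccoliths per cell and the POC-volume allometry for cellular PIC/POC."""

    coccoliths_per_cell: int = 15
    poc_a: float = 0.216
    poc_b: float = 0.939
    provenance: str = "calibration constants: POC = a*V^b (pg C, um3) and coccosphere quota"


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run."""

    simulate: bool = True
    seed: int = 0
    inputs: dict[str, str] | None = None  # kind -> CSV path when simulate=False
    outdir: str | None = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    mu: growth.MuRegressionConfig = field(default_factory=growth.MuRegressionConfig)
    cell_diameter: CellDiameterConfig = field(default_factory=CellDiameterConfig)
    carbon_quota: CarbonQuotaConfig = field(default_factory=CarbonQuotaConfig)
    size_threshold_um: float = census.DEFAULT_SIZE_THRESHOLD_UM
    alpha: float = 0.05
    smoothing_window: int = 1
    min_coccoliths: int = morphometrics.MIN_COCCOLITHS
    bh_adjust: bool = False


def _build(cls, data: dict):
    """Construct a (possibly nested) config dataclass, rejecting unknown keys."""
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        ftype = names[key].type
        nested = {
            "GeneratorConfig": GeneratorConfig,
            "MuRegressionConfig": growth.MuRegressionConfig,
            "SizeMuConfig": growth.SizeMuConfig,
            "NutrientMuConfig": growth.NutrientMuConfig,
            "LinearMuConfig": growth.LinearMuConfig,
            "CellDiameterConfig": CellDiameterConfig,
            "CarbonQuotaConfig": CarbonQuotaConfig,
        }
        base = str(ftype).replace("coccoprod.", "").split(".")[-1].strip("'> ")
        if isinstance(value, dict) and base in nested:
            kwargs[key] = _build(nested[base], value)
        elif isinstance(value, dict) and key == "taxa":
            kwargs[key] = {t: _build(TaxonParams, v) for t, v in value.items()}
        elif isinstance(value, dict) and key == "mu":
            kwargs[key] = _build(growth.MuRegressionConfig, value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Load a YAML run configuration, rejecting unknown keys at every level."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _build(RunConfig, data)


def config_hash(cfg: RunConfig) -> str:
    """Stable hash of the scientific configuration for output provenance.

    The output directory is excluded: it changes where results land, not
    what they are.
    """
    payload = dataclasses.asdict(cfg)
    payload.pop("outdir", None)
    blob = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def mu_size_table(morpho: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Size-based mu per sample x taxon from mean coccolith length.

    Cell diameter comes from the linear coccolith-to-cell map and volume from
    a spherical cell; the inverse volume power law then yields mu.  The same
    inverse relation is applied to all five taxa (for the high PIC/POC group
    no taxon-specific equation exists, so the generic inverse law is assumed).
    """
    d = morphometrics.cell_diameter_from_coccolith(
        morpho["mean_length_um"].to_numpy(), cfg.cell_diameter.alpha, cfg.cell_diameter.beta
    )
    v = morphometrics.cell_volume_from_diameter(d)
    out = morpho[["sample_id", "taxon"]].copy()
    out["estimator"] = "size"
    out["mu_div_day"] = growth.mu_from_size(v, cfg.mu.size)
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and return (and optionally write) the summary."""
    if cfg.simulate:
        gen = dataclasses.replace(cfg.generator, seed=cfg.seed)
        metadata, env, census_tbl, coccoliths, truth = generate_transect(gen)
    else:
        if not cfg.inputs:
            raise ValueError("simulate=False requires the four input CSV paths")
        tables = io.read_tables(cfg.inputs)
        metadata = tables["metadata"]
        env = tables["environment"]
        census_tbl = tables["census"]
        coccoliths = tables["coccoliths"]
        truth = None

    # Environmental state with carbonate speciation.
    env_state = carbonate.derive_env_state(env)

    # Census: absolute and relative abundances.
    abundance = census.summarize_census(census_tbl)

    # Morphometric indices.
    morpho, fits = morphometrics.summarize_morphometrics(coccoliths, cfg.min_coccoliths)

    # Growth-rate estimators.
    mu_size = mu_size_table(morpho, cfg)
    mu_env_rows = []
    for row in env_state.itertuples(index=False):
        mu_env_rows += [
            {"sample_id": row.sample_id, "taxon": "assemblage", "estimator": "po4",
             "mu_div_day": growth.mu_from_po4(row.po4_umol_l, cfg.mu.po4)},
            {"sample_id": row.sample_id, "taxon": "assemblage", "estimator": "sst",
             "mu_div_day": growth.mu_from_env(row.sst_preindustrial_c, "sst", cfg.mu)},
            {"sample_id": row.sample_id, "taxon": "assemblage", "estimator": "co2",
             "mu_div_day": growth.mu_from_env(row.co2_umol_kg, "co2", cfg.mu)},
        ]
    mu_table = pd.concat([mu_size, pd.DataFrame(mu_env_rows)], ignore_index=True)

    # Cellular PIC/POC for the low PIC/POC group.
    quota_rows = []
    for r in morpho.itertuples(index=False):
        if r.taxon not in LOW_GROUP_TAXA or not r.usable:
            continue
        d = morphometrics.cell_diameter_from_coccolith(
            r.mean_length_um, cfg.cell_diameter.alpha, cfg.cell_diameter.beta
        )
        q = morphometrics.cellular_pic_poc(
            r.mean_mass_pg,
            cfg.carbon_quota.coccoliths_per_cell,
            morphometrics.cell_volume_from_diameter(d),
            cfg.carbon_quota.poc_a,
            cfg.carbon_quota.poc_b,
            taxon=r.taxon,
            sample_id=r.sample_id,
        )
        quota_rows.append(dataclasses.asdict(q))
    quotas = pd.DataFrame(quota_rows)

    # Production, boundary and its environmental characterization.
    prod = production.build_production_table(abundance, morpho, metadata)
    boundary = production.detect_boundary(
        prod["latitude"], prod["pct_high"], cfg.smoothing_window
    )
    boundary_env: dict[str, float] = {}
    if boundary.primary is not None:
        boundary_env = production.characterize_boundary(
            boundary.primary,
            env_state,
            fields=(
                "sst_c", "sst_preindustrial_c", "po4_umol_l", "co2_umol_kg",
                "hco3_umol_kg", "dic_ta", "d13c_dic_permil", "sss_psu",
            ),
        )

    # Validation flags.
    counts = census_tbl.groupby("sample_id")["count"].sum()
    flags = {}
    for r in metadata.itertuples(index=False):
        omega = float(
            env_state.loc[env_state["sample_id"] == r.sample_id, "omega_calcite_depth"].iloc[0]
        )
        flags[r.sample_id] = sorted(
            census.validate_sample(r.water_depth_m, omega, r.age_yr_bp, counts[r.sample_id])
        )

    # Correlation screen: per-taxon N and SN thickness vs environment.
    n_wide = abundance.pivot(index="sample_id", columns="taxon", values="abundance_per_g")
    n_wide.columns = [f"N {t}" for t in n_wide.columns]
    sn_wide = (
        morpho[morpho["usable"]]
        .pivot(index="sample_id", columns="taxon", values="sn_thickness_um")
    )
    sn_wide.columns = [f"SN {t}" for t in sn_wide.columns]
    proxies = n_wide.join(sn_wide, how="outer")
    env_cols = [
        "sst_preindustrial_c", "sss_psu", "po4_umol_l", "ta_umol_kg", "dic_umol_kg",
        "co2_umol_kg", "hco3_umol_kg", "dic_ta", "d13c_dic_permil", "mld_m",
    ]
    env_idx = env_state.set_index("sample_id")[env_cols]
    correlations = stats.correlation_matrix(proxies, env_idx, cfg.alpha, cfg.bh_adjust)

    summary = {
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "n_samples": int(len(metadata)),
        "constants_dialect": carbonate.CONSTANTS_DIALECT,
        "provenance": {
            "mu_size": cfg.mu.size.provenance,
            "mu_po4": cfg.mu.po4.provenance,
            "mu_sst": cfg.mu.sst.provenance,
            "mu_co2": cfg.mu.co2.provenance,
            "cell_diameter": cfg.cell_diameter.provenance,
            "carbon_quota": cfg.carbon_quota.provenance,
        },
        "boundary": {
            "crossings_deg": list(boundary.crossings),
            "primary_deg": boundary.primary,
            "environment": boundary_env,
        },
        "group_production": {
            "mean_cp_low_pg_g": float(prod["cp_low"].mean()),
            "mean_cp_high_pg_g": float(prod["cp_high"].mean()),
            "mean_pct_low": float(prod["pct_low"].mean()),
            "mean_pct_high": float(prod["pct_high"].mean()),
        },
        "validation_flags": flags,
        "n_significant_correlations": int(correlations["significant"].sum()),
        "allometry": {
            t: {"beta": f.beta, "l_ref_um": f.l_ref, "n": f.n, "r_squared": f.r_squared}
            for t, f in fits.items()
        },
    }
    if truth is not None:
        summary["truth_crossover_deg"] = truth.crossover_latitude

    result = {
        "summary": summary,
        "metadata": metadata,
        "env_state": env_state,
        "abundance": abundance,
        "morphometry": morpho,
        "mu": mu_table,
        "quotas": quotas,
        "production": prod,
        "correlations": correlations,
        "boundary": boundary,
        "truth": truth,
    }

    if cfg.outdir is not None:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_table(metadata, out / "metadata.csv")
        io.write_table(env_state, out / "env_state.csv")
        io.write_table(abundance, out / "abundance.csv")
        io.write_table(morpho, out / "morphometry.csv")
        io.write_table(mu_table, out / "mu_profiles.csv")
        if len(quotas):
            io.write_table(quotas, out / "pic_poc_quotas.csv")
        io.write_table(prod, out / "production.csv")
        io.write_table(correlations, out / "correlations.csv")
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
    return result
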