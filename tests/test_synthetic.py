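"""Synthetic transect generator: determinism, closure, truth recovery."""

import dataclasses
import io as stdio

import numpy as np
import pytest
from scipy.stats import binom

from coccoprod.constants import C_PELAGICUS, SMALL_GEPHYROCAPSA
from coccoprod.io import write_table
from coccoprod.synthetic import (
    GeneratorConfig,
    TaxonParams,
    environmental_fields,
    generate_transect,
    niche_weight,
    sample_latitudes,
    true_crossover,
)

PARAMS = TaxonParams(
    sst_opt=18.0, niche_width=5.0, k_po4=0.2, max_weight=1.0, mu_max=1.0,
    mean_length_um=3.0, length_log_sd=0.1, width_ratio=0.85,
    t0=0.1, beta_true=1.0, gamma=0.5,
)


def test_niche_weight_examples():
    assert niche_weight(18.0, 1e9, PARAMS) == pytest.approx(1.0)
    assert niche_weight(18.0, 0.2, PARAMS) == pytest.approx(0.5)
    assert niche_weight(18.0 + 5.0, 0.2, PARAMS) == pytest.approx(
        np.exp(-0.5) * 0.5, abs=1e-4
    )
    with pytest.raises(ValueError):
        niche_weight(np.nan, 0.2, PARAMS)


def test_niche_weight_maximal_at_optimum():
    sst = np.linspace(0, 30, 301)
    w = niche_weight(sst, 0.5, PARAMS)
    assert sst[np.argmax(w)] == pytest.approx(PARAMS.sst_opt, abs=0.1)
    assert np.all((w >= 0) & (w <= 1))


def test_config_invariants_enforced():
    with pytest.raises(ValueError, match="gamma > 0"):
        taxa = dict(GeneratorConfig().taxa)
        taxa[SMALL_GEPHYROCAPSA] = dataclasses.replace(taxa[SMALL_GEPHYROCAPSA], gamma=-0.5)
        GeneratorConfig(taxa=taxa)
    with pytest.raises(ValueError, match="gamma < 0"):
        taxa = dict(GeneratorConfig().taxa)
        taxa[C_PELAGICUS] = dataclasses.replace(taxa[C_PELAGICUS], gamma=0.5)
        GeneratorConfig(taxa=taxa)
    with pytest.raises(ValueError, match=">= 300"):
        GeneratorConfig(total_count=200)
    with pytest.raises(ValueError, match="at least 3"):
        GeneratorConfig(n_samples=2)


def test_same_seed_gives_identical_csv_bytes():
    def render():
        tables = generate_transect(GeneratorConfig(seed=42))
        bufs = []
        for tbl in tables[:4]:
            buf = stdio.StringIO()
            write_table(tbl, buf)
            bufs.append(buf.getvalue())
        return bufs

    assert render() == render()


def test_different_seeds_differ():
    a = generate_transect(GeneratorConfig(seed=1))[2]
    b = generate_transect(GeneratorConfig(seed=2))[2]
    assert not a["count"].equals(b["count"])


def test_multinomial_closure(transect):
    _, _, census, _, _ = transect
    totals = census.groupby("sample_id")["count"].sum()
    assert (totals == GeneratorConfig().total_count).all()


def test_latitude_layout_spans_range_densely_in_north():
    cfg = GeneratorConfig()
    lat = sample_latitudes(cfg)
    assert len(lat) == cfg.n_samples
    assert lat[0] == cfg.lat_north and lat[-1] == cfg.lat_south
    north_spacing = np.abs(np.diff(lat[lat >= 30])).mean()
    south_spacing = np.abs(np.diff(lat[lat <= 30])).mean()
    assert north_spacing < south_spacing


def test_environmental_fields_structure():
    env = environmental_fields(np.array([60.0, 40.0, 0.0, -30.0]))
    # equatorward DIC/TA decrease and poleward phosphate enrichment
    ratio = env["dic_umol_kg"] / env["ta_umol_kg"]
    assert ratio.iloc[0] > ratio.iloc[1] > ratio.iloc[2]
    assert env["po4_umol_l"].iloc[0] > env["po4_umol_l"].iloc[2]
    assert env["sst_c"].iloc[2] > env["sst_c"].iloc[0]


def test_counts_recover_truth_within_binomial_ci(transect):
    """Census counts sit inside the 99% binomial envelope of the true
    relative abundances (multinomial sampling is unbiased)."""
    _, _, census, _, truth = transect
    merged = census.merge(truth.per_sample_taxon, on=["sample_id", "taxon"])
    totals = census.groupby("sample_id")["count"].sum()
    for r in merged.itertuples(index=False):
        n = totals[r.sample_id]
        lo = binom.ppf(0.005, n, r.rel_abundance_true)
        hi = binom.ppf(0.995, n, r.rel_abundance_true)
        assert lo <= r.count <= hi


def test_truth_abundances_sum_to_one(transect):
    _, _, _, _, truth = transect
    sums = truth.per_sample_taxon.groupby("sample_id")["rel_abundance_true"].sum()
    assert np.allclose(sums, 1.0, atol=1e-12)
    assert (truth.per_sample_taxon["mu_true"] > 0).all()


def test_true_crossover_within_transect_and_near_40n():
    cfg = GeneratorConfig()
    cx = true_crossover(cfg)
    assert cfg.lat_south < cx < cfg.lat_north
    # calibration pins the dominance switch to the northern mid-latitudes
    assert 35.0 < cx < 45.0


def test_recovered_n_close_to_truth(transect):
    """Absolute abundance from counts and slide geometry lands near the
    generator's true per-taxon N (within multinomial + geometry rounding)."""
    from coccoprod.census import summarize_census

    _, _, census, _, truth = transect
    ab = summarize_census(census).merge(
        truth.per_sample_taxon, on=["sample_id", "taxon"]
    )
    big = ab[ab["rel_abundance_true"] > 0.05]
    rel_err = (big["abundance_per_g"] - big["abundance_true_per_g"]).abs() / big[
        "abundance_true_per_g"
    ]
    assert rel_err.median() < 0.15
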