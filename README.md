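# coccoprod

Reconstructing coccolithophore physiology and calcite production from
sediment coccolith archives along a latitudinal transect.

## The scientific problem

Coccolithophores — unicellular calcifying algae — produce a large share of
the open ocean's calcite as interlocking platelets (coccoliths) that
accumulate in sea-floor sediments. Their net calcite output depends on how
many cells grow (population density and growth rate μ, in divisions per
day) and how much calcite each cell invests per coccolith (calcification
intensity). Because taxa differ in their ratio of particulate inorganic to
organic carbon production, the community splits into a **low PIC/POC group**
(small and large *Gephyrocapsa*) and a **high PIC/POC group**
(*Helicosphaera* spp., *Calcidiscus* spp., *Coccolithus pelagicus*), with
opposite couplings between growth rate and calcification intensity.

This package implements the full sediment-based workflow that turns coccolith
census counts and per-coccolith morphometry into those physiological and
biogeochemical quantities, plus a calibrated synthetic-transect generator so
the entire chain is testable end to end without any data downloads:

- **Absolute abundance** N = count × deposition area / (fields counted ×
  field area × settled sediment mass), in coccoliths g⁻¹ — a productivity
  proxy.
- **Calcification-intensity indices**: mean thickness T̄ = m/(ρ·A);
  size-normalized thickness SN = T̄·(L_ref/L)^β with β fitted per taxon by
  OLS of ln T̄ on ln L; elliptical shape factor kse = m/(ρ·L²·W); and a
  morphometric cellular PIC/POC for the low PIC/POC group, with
  PIC = m̄·n_liths·0.12 and POC = a·V^b.
- **Growth-rate estimators**: μ_size = μ_ref·(V/V_ref)^s (s < 0, the inverse
  cell-size–μ law), Michaelis–Menten μ_[PO4] = μ_max·P/(P+K), and linear
  clamped SST/CO₂ responses — compared as relative profiles only.
- **Carbonate system**: TA/DIC speciation ([CO₂], [HCO₃⁻], [CO₃²⁻], pH,
  Ω_calcite, with pressure corrections for Ω at sample depth) by Brent root
  solve of the alkalinity balance on the total pH scale.
- **Calcite production**: CP = N × mean coccolith mass per taxon and sample
  (pg CaCO₃ g⁻¹ sediment); complementary percent contributions of the two
  groups; and the **dominance boundary** — the latitude where the high
  PIC/POC share crosses 50%, located by linear interpolation and
  characterized by interpolating the environmental fields there.
- **Statistics**: Pearson R with exact t-based two-sided p-values, screened
  at p ≤ 0.05 (optional Benjamini–Hochberg flags as a labelled extension).

## Worked example

```bash
python analysis/01_simulate_transect.py
python analysis/02_derive_proxies.py
python analysis/03_production_boundary.py
python analysis/04_correlation_screen.py
```

which prints (seed 42, the default of script 01):

```
true dominance crossover: 40.49 deg N
...
high PIC/POC contribution north of 45 N: 98.3%
high PIC/POC contribution south of 20 N: 8.5%
primary dominance boundary: 40.59 deg N (1 crossing(s))
  boundary environment: SST 13.7 C, [PO4] 0.59 umol/L, [CO2] 14.7 umol/kg, DIC/TA 0.902
...
SN thickness (small Gephyrocapsa) vs d13C_DIC: R=0.94, p=1.2e-09, n=19
```

Reading: the pipeline recovers the generator's true 50% dominance crossover
(40.49°N) to within 0.1°, the boundary sits in temperate, moderately
nutrient-rich water with DIC/TA ≈ 0.9, and the low PIC/POC group's
calcification intensity rises with the carbon-utilisation signal (δ¹³C of
DIC) — the positive μ–calcification coupling of that group. Stage tables
land under `results/`.

The same stages are exposed as CLI subcommands
(`coccoprod simulate | census | morpho | mu | env | production | boundary |
correlate | run`); `coccoprod run --seed 7 --outdir out` chains everything
and writes `out/summary.json`.

## Layout

```
src/coccoprod/      library (generator, census, morphometrics, growth,
                    carbonate, production, stats, io, pipeline, cli)
analysis/           numbered narrative drivers writing results/
tests/              pytest suite incl. end-to-end acceptance checks
scripts/            acceptance.py
docs/methods.md     model description, parameter defaults, limitations
```
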