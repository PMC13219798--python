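# Methods

## Scope and model

The package reconstructs coccolithophore population dynamics, physiology
(growth rate μ, calcification intensity) and group-specific calcite
production from two sedimentary observables — census counts of coccoliths
per taxon and per-coccolith morphometry (length L, width W, area A, mass m)
— combined with per-sample surface-ocean environmental state. Five taxa are
tracked and grouped by their PIC/POC production style: small and large
*Gephyrocapsa* (low PIC/POC; split at a 3.0 µm length threshold, 3.5 µm
selectable; ties classify as large) and *Helicosphaera* spp., *Calcidiscus*
spp. and *Coccolithus pelagicus* (high PIC/POC). Taxa outside these five are
retained in relative-abundance totals but excluded from group-level
production.

### Abundance accounting

Slides are assumed prepared by a settling protocol in which a known mass of
dry sediment settles homogeneously over a known deposition area. Absolute
abundance is then

    N = count × deposition_area / (n_fov × fov_area × sediment_mass)

in coccoliths per gram. All geometry is explicit in the input schema, so any
dilution protocol can be expressed through the "mass settled over the
deposition area" field. N is degree-1 homogeneous in count and degree −1 in
mass; both are asserted as property tests. Samples are screened (flags, not
aborts) against depth ≥ 3000 m, Ω_calcite ≤ 1 at depth, age ≥ 3000 yr BP and
total counts < 300.

### Calcification-intensity indices

Mean thickness per coccolith is T̄ = m/(ρ·A) with ρ = 2.7 pg µm⁻³. Because
thickness scales allometrically with length, the size-normalized thickness
rescales each coccolith to its taxon's reference length:

    SN = T̄ · (L_ref / L)^β

with β and ln t₀ from an OLS fit of ln T̄ on ln L pooled over **all samples
of a taxon** (one global reference per taxon; L_ref is the geometric-mean
length of the fitting set; ≥ 10 coccoliths required, else β = 1 proportional
fallback). On the fitting set SN is uncorrelated with L. A per-sample×taxon
index is the arithmetic mean over its measured coccoliths, reported only
when ≥ 10 were measured. The elliptical shape factor kse = m/(ρ·L²·W) is the
minimal elliptical generalization of the classic cubic shape factor and is
invariant under uniform magnification.

One caveat surfaced by the synthetic experiments: when growth rate modulates
both coccolith size and thickness across samples, the pooled OLS exponent
absorbs part of the between-sample coupling (fitted β can differ widely from
the within-sample allometry). SN thickness nevertheless retains the coupling
signal — the recovery tests quantify exactly this.

### Cellular PIC/POC (low PIC/POC group)

Cell diameter follows a linear coccolith-to-cell map d = α + β·L (defaults
α = 1.0 µm, β = 1.2; placeholders to be transcribed from the cited
dimensional literature — the provenance string in the config records what
was used). Cell volume is spherical, V = (π/6)d³. Then

    PIC = m̄ × n_liths × 0.1200   (pg C; 0.1200 = 12.011/100.087)
    POC = a · V^b                 (defaults a = 0.216, b = 0.939)

with n_liths = 15 coccoliths per cell. a, b and n_liths are calibration
constants, not measured values.

### Growth-rate estimators

All μ outputs are treated as **relative** profiles; cross-estimator
comparisons use correlation and rank agreement only. Defaults (each with a
mandatory provenance string):

| estimator | form | defaults |
|---|---|---|
| μ_size | μ_ref·(V/V_ref)^s, s < 0 | μ_ref = 1.0 d⁻¹, V_ref = 50 µm³, s = −0.32 |
| μ_[PO4] | μ_max·P/(P+K) | μ_max = 1.4 d⁻¹, K = 0.24 µmol L⁻¹ |
| μ_SST | max(0, a + b·SST) | b = 0.045 d⁻¹ °C⁻¹, a = 0 |
| μ_CO2 | max(0, a + b·[CO₂]) | b = 0.06, a = 0.1 |

The linear-with-clamp environmental forms are declared stand-ins; the
functional form is config-driven. The same inverse size–μ law is applied to
the high PIC/POC taxa, for which no taxon-specific regression exists.

### Carbonate system

Speciation from the (TA, DIC) pair solves the alkalinity balance
(carbonate + borate + water; phosphate/silicate alkalinity neglected, a
sub-per-mil effect at open-ocean surface nutrient levels) for pH ∈ [2, 12]
by Brent's method to |residual| < 10⁻⁴ µmol kg⁻¹. Constants dialect
(recorded in every output): Lueker et al. (2000) K1/K2, Dickson (1990) KB,
Millero (1995) KW, Mucci (1983) calcite Ksp, Uppström (1974) boron, Riley &
Tongudai (1967) calcium, total pH scale, with standard molal-volume pressure
corrections. Surface speciation is evaluated at a standardized 100 dbar;
Ω_calcite at sample depth additionally uses a configurable deep in-situ
temperature (default 2.5 °C) because the inputs carry surface fields only —
the resulting Ω_depth is an approximation adequate for the > 1 preservation
screen, not a full deep-carbonate reconstruction. Within this dialect,
DIC/TA ≈ 0.90 at 15 °C implies [CO₂] ≈ 14 µmol kg⁻¹; reported boundary CO₂
follows from the ratio rather than being an independent dial.

### Production and the dominance boundary

Per taxon and sample, CP = N × mean coccolith mass (pg CaCO₃ g⁻¹ sediment);
the per-sample mean mass is used (never a global mean). A taxon with N > 0
but no usable mass is excluded from group sums with a warning; N = 0 yields
CP = 0. Group percentages are complementary and close to 100 at machine
precision. The dominance boundary is every latitude where the (optionally
moving-average smoothed; default none) high-group share crosses 50%, located
by linear interpolation on the latitude-sorted series; the **primary**
boundary is the crossing with the largest share change across its bracketing
pair — a declared heuristic for noisy transects (the calibrated default
transect has a single sharp switch). A series that never crosses reports an
absent boundary, not an error. Environmental conditions at the boundary are
piecewise-linear interpolations of the per-sample fields; extrapolation is
refused.

### Correlation screen

Pearson R with p from t = R·√((n−2)/(1−R²)) against t(n−2), two-sided;
pairwise-complete deletion with per-pair n; flat α = 0.05 with no
multiple-testing correction (matching the analysis style this reproduces);
Benjamini–Hochberg adjusted flags are available as a clearly labelled,
off-by-default extra column. No spatial-autocorrelation correction is
applied — transect samples are treated as independent replicates, a known
caveat.

## The synthetic transect generator

The generator emulates a ~19-sample Atlantic-style surface-sediment transect
(60°N–30°S) with the statistical structure the analysis assumes, and returns
the noise-free truth alongside the sampled tables.

**Environment.** Smooth latitudinal curves plus Gaussian noise: a tanh SST
front centred at 38°N (27 °C tropics → ~5.5 °C at 60°N), phosphate enriched
toward the subpolar north (0.08 → 1.18 µmol L⁻¹), salinity peaking in the
subtropics with TA linear in salinity, DIC/TA decreasing equatorward
(≈ 0.918 at 60°N → 0.864 at the equator), mixed layers deepening northward,
and δ¹³C_DIC tracking the photosynthetic carbon utilisation of the dominant
small-*Gephyrocapsa* niche. Noise sd defaults: SST 0.25 °C, PO₄ 0.02
µmol L⁻¹, SSS 0.05, δ¹³C 0.06 ‰, DIC/TA 0.002, MLD 5 m.

**Niches and growth.** Habitat suitability is a Gaussian thermal response
times Michaelis–Menten nutrient limitation; true μ is μ_max times that
weight. Defaults place small/large *Gephyrocapsa* optima at 22/24 °C,
*Helicosphaera* at 21 °C (warm-temperate), *Calcidiscus* at 15 °C and
*C. pelagicus* at 4 °C (subpolar), with μ_max 1.2/1.0/0.5/0.45/0.4 d⁻¹ — so
*C. pelagicus* divides at about a third of the small-*Gephyrocapsa* rate. An
abundance floor of 10⁻⁴ prevents zero-probability multinomials.

**Morphometry.** Lengths are lognormal per taxon; the median responds
inversely to μ via a power law bounded to a [0.85, 1.15] size factor
(unbounded responses give off-niche taxa unphysical coccolith masses).
Thickness is t₀·L^β_true modulated by 1 + γ·(μ − μ_ref), with γ > 0 for the
low PIC/POC taxa and γ < 0 for the high group — the opposite-signed
μ–calcification coupling the pipeline must detect. Mass is ρ·A·T with
A = 0.82·(π/4)·L·W. Resulting per-coccolith masses span ~2.6 pg (small
*Gephyrocapsa*) to ~210 pg (*C. pelagicus*), an ~80-fold endmember contrast.

**Sampling.** Counts are multinomial (500 specimens/sample by default,
≥ 300 enforced) with slide geometry back-computed so recovered N matches the
truth up to integer fields-of-view rounding. Two-thirds of the samples span
60–30°N at 3° spacing, the rest 30°N–30°S — emulating the uneven northern
coverage of real Atlantic core-top sets and giving the subpolar taxa enough
samples for per-taxon statistics. Measured coccoliths per taxon and sample
number min(35, 5 × count): morphometric scans cover several times the census
area, so a taxon seen once cannot contribute a 35-specimen mean.

**Truth and calibration.** The noise-free dominance crossover is computed
from expected per-taxon production on a 0.05° latitude grid using the
analytic lognormal mass expectation. Defaults were calibrated once so the
truth reproduces the study conditions this workflow targets: a single sharp
low/high dominance switch at ≈ 40°N lying at SST ≈ 14 °C, [PO₄] ≈ 0.55
µmol L⁻¹, DIC/TA ≈ 0.90 (hence [CO₂] ≈ 14 µmol kg⁻¹), high-group share
≈ 20–30% in the south and > 95% at subpolar latitudes.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no seasonality (annual means only), no sediment
transport, bioturbation, dissolution or preservation gradients, no
taxon-level coccoliths-per-cell variability, no spatial autocorrelation
structure beyond the smooth latitudinal curves, and export is folded into a
single μ-weighted abundance-to-flux proportionality (standing stock and
flux are not modelled separately).

## Numerical choices

- Carbonate root solve: Brent on pH ∈ [2, 12], xtol 10⁻¹³; identical inputs
  give bit-identical outputs.
- Perfect collinearity (|R| ≥ 1 − 10⁻¹⁴) reports p = 0 exactly.
- Boundary ties: samples exactly at 50% are crossings at their own latitude;
  among multiple crossings the largest bracketing share change wins.
- Tables are CSV (UTF-8, header, signed decimal degrees north-positive,
  depths positive down, ages yr BP) written with 10 significant digits;
  write-then-read round trips are value-identity at that precision.
- Config files are YAML; unknown keys are rejected at every nesting level;
  every coefficient group carries a provenance string and the summary embeds
  a hash of the scientific configuration (output paths excluded).

## Problem sizes

Default test and acceptance runs use 19-sample transects with 500 counted
specimens and ≤ 35 measured coccoliths per taxon-sample, 20-seed replication
for boundary recovery, 1000 null repetitions for the screen calibration and
a 100-point oracle grid for the carbonate solver — sizes chosen to mirror
the emulated study design while keeping a full run in seconds.

## Known limitations

- All literature regression coefficients (size–μ, nutrient–μ, SST/CO₂–μ,
  coccolith-to-cell dimensions, POC–volume) are placeholder defaults wired
  through configuration; quantitative application to real data requires
  transcribing the published values (the provenance strings exist to force
  that bookkeeping).
- The SN-thickness normalization uses one global per-taxon reference; if
  real data demand per-sample references the AllometryFit seam is the single
  place to change.
- Ω at depth approximates the deep carbonate system from surface TA/DIC plus
  a fixed deep temperature.
- The μ estimators are not absolutely calibrated; only profile shapes and
  ranks are meaningful.
- δ¹³C_DIC and the industrial SST anomaly are consumed as pre-corrected
  inputs; no isotope or warming model is included.
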