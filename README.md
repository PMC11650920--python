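# sticklesim

Agent-based bioenergetics simulation of three-spined stickleback
(*Gasterosteus aculeatus*) populations under projected climate heating.

## The problem

Warming changes a freshwater fish population twice over: it raises every
individual's metabolic costs, and it changes how much invertebrate food the
ecosystem produces. Whether a population inflates or declines under a given
IPCC warming level therefore depends on where it sits along the latitudinal
gradient of temperature and productivity. `sticklesim` is for ecological
modellers who want a mechanistic, individual-level answer: it simulates
closed stickleback populations representing latitudes 50–60 °N under the
IPCC long-term (2100) warming levels ΔT ∈ {1.4, 2.7, 4.4} °C, with food
supply co-varying with both latitude and warming.

## The model

A 20 m² enclosed habitat of 500 patches (10% vegetated and food-bearing)
hosts individual fish, each running a daily energy budget

```
assimilated = maintenance + reproduction + growth + Δreserves (+ overflow)
```

with ingestion, growth and development scaled by a Q10 thermal response
inside a tolerance window, and maintenance by a pure Q10 (costs keep rising
with temperature). Fish forage by the ideal free distribution (occupancy
tracks patch food input), males compete for nest sites (one territorial male
per vegetated patch), and survival includes stage-specific background rates,
density-dependent compensation, starvation and senescence.

Environmental drivers come from published empirical regressions:

- `GPP = 38.13·Lat + 88.0` (mg C m⁻² d⁻¹) — river productivity vs latitude,
- `PCP = 0.02·GPP + 9.04` — primary-consumer production vs GPP, converted to
  0.0196 / 0.0211 / 0.0226 g food patch⁻¹ d⁻¹ at 50 / 55 / 60 °N,
- `log10(biomass) = 0.138·T + 1.090` — invertebrate biomass vs temperature,
  so ΔT of warming multiplies food by `10^(0.138·ΔT)` (offsets 1.28 / 1.46 /
  1.70 on the log10 scale for the three warming levels).

The experiment layer reproduces the study design: warm-up under control
drivers, scenario switch, replicated runs, April-1 pre-breeding censuses of
density, biomass and mean metabolic rate, and a 5% detection rule on
treatment-period mean density. See `docs/methods.md` for the full model
description and parameter table.

## Worked example

Resolve scenarios and check the food chain (annual means print the derived
food densities; at ΔT = 0 they are the three values derived above):

```
$ python analysis/01_build_scenarios.py
lat 50.0°N  ΔT 0.0°C  annual mean food 0.0196 g/patch/day
lat 50.0°N  ΔT 4.4°C  annual mean food 0.0792 g/patch/day
...
lat 60.0°N  ΔT 0.0°C  annual mean food 0.0226 g/patch/day
lat 60.0°N  ΔT 4.4°C  annual mean food 0.0916 g/patch/day
```

Bootstrap the GPP–latitude slope on a synthetic 27-site dataset built around
the published trend (slope 38.13, weak fit R² ≈ 0.16):

```
$ python analysis/02_bootstrap_gpp.py
fitted slope          35.504 mg C m⁻² d⁻¹ per °N
bootstrap bias        -0.160
bootstrap SE          15.935 (44.9% of the slope)
95% percentile CI   [4.01, 66.66]  (5000 resamples)
```

The slope estimate is accurate (bias ≪ slope) but imprecise, as expected for
so scattered a relationship — the trend, not the point value, carries into
the scenarios. Run the scaled warming experiment (3 latitudes × 4 ΔT ×
5 replicates, 5+5 years; a few minutes):

```
$ python analysis/03_run_experiment.py
 latitude  delta_t  density_mean  biomass_mean  mean_metabolic_rate_mean  density_pct_change  biomass_pct_change
     50.0      0.0          8.46         0.861                     3.688               0.000               0.000
     50.0      4.4          9.37         3.071                    12.149              10.757             256.797
     55.0      0.0          7.99         0.982                     3.428               0.000               0.000
     55.0      4.4          9.32         3.470                    10.782              16.646             253.529
     60.0      0.0          7.62         1.016                     2.911               0.000               0.000
     60.0      4.4          9.80         3.063                     7.532              28.609             201.588
60°N +4.4°C vs control, density: 5/5 replicates higher (sign test p = 0.0312)
60°N +4.4°C vs control, biomass: 5/5 replicates higher (sign test p = 0.0312)
```

(Intermediate warming levels omitted here for width.) Reading the numbers:
density and biomass inflate under warming because the food increase outruns
the metabolic-cost increase, the density inflation strengthens with latitude
(+11% at 50 °N vs +29% at 60 °N under +4.4 °C), and mean individual
metabolic rate rises with warming within every latitude while being lowest
at the coldest (highest) latitude. Absolute magnitudes depend on the
package's default bioenergetic parameterisation; the directional structure
is the robust result. Single-fish ration responses
(`analysis/04_ration_response.py`) show the underlying energetics: final
mass, length and egg production all increase with food ration (egg ratios
1 : 1.7 : 3.0 across low/medium/high).

## Layout

```
src/sticklesim/     library: scenario, landscape, fish, population,
                    experiment, synthetic, params, io
analysis/           numbered narrative drivers writing results/
scripts/            acceptance.py
tests/              pytest suite
docs/methods.md     model description, parameters, design rationale
```
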