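# Methods

## The model in one paragraph

`sticklesim` is an agent-based bioenergetics model of a closed three-spined
stickleback (*Gasterosteus aculeatus*) population in a 20 m² freshwater
habitat of 500 patches (20 × 20 cm), 50 of which are vegetated and hold food.
Each fish runs a daily energy budget — ingestion, assimilation, maintenance,
reproduction, growth, storage — whose rates scale with water temperature;
fish compete for food by moving over the patches according to the ideal free
distribution, and males compete for nest sites (one territorial male per
vegetated patch). Population dynamics are not prescribed: carrying capacity,
recruitment pulses and latitudinal differences all emerge from the
individual rules. The experiment layer applies the climate question: how do
populations representing 50, 55 and 60 °N respond to the IPCC long-term
(2100) warming levels of +1.4, +2.7 and +4.4 °C when warming also increases
invertebrate food supply?

## Scenario construction

Annual-mean food on vegetated patches is derived from latitude by chaining
two published empirical regressions and a unit conversion:

1. river gross primary production, `GPP = 38.13·Lat + 88.0` (mg C m⁻² d⁻¹);
2. daily primary-consumer (secondary) production,
   `PCP = 0.02·GPP + 9.04` (mg C m⁻² d⁻¹);
3. spread over the habitat: `PCP × 20 m² / 1000 / 50 vegetated patches`,
   taking consumer carbon production 1:1 as available wet food mass (an
   optional conversion factor defaults to 1).

This yields 0.0196 / 0.0211 / 0.0226 g patch⁻¹ d⁻¹ at 50 / 55 / 60 °N.
Warming acts on food through the mesocosm regression
`log10(invertebrate biomass) = 0.138·T + 1.090`. Evaluated at the warming
increments 1.4 / 2.7 / 4.4 °C the linear predictor gives the offsets
1.28 / 1.46 / 1.70 (2 dp); subtracting the baseline intercept and
back-transforming leaves a multiplicative food factor `10^(0.138·ΔT)`
(≈ 1.56 / 2.36 / 4.05). We apply this factor to every monthly food value
— the additive-on-log-scale prose admits an "added biomass" (B + ΔB)
reading, but only the multiplicative reading reproduces the printed offsets
as a consistent chain, and it commutes with the seasonal rescaling. Monthly
food values are a 12-weight seasonal shape rescaled so its mean equals the
(warming-adjusted) annual mean; the shape's overall scale is therefore
irrelevant and the annual mean is honoured to 1e-9 relative.

Monthly temperatures are a user-supplied baseline plus ΔT elementwise. The
default baselines are synthetic sinusoids (below), floored at 0.2 °C —
fresh water under ice does not cool much below zero.

## Synthetic drivers and datasets

Monthly-temperature extracts and the global GPP compilation behind the
regressions are not redistributable, so the `synthetic` module generates
stand-ins with the statistical structure the pipeline assumes:

- **Seasonal temperature templates** — cosine year
  `mean + amplitude·cos(2π(m − phase)/12)` with optional Gaussian noise.
  Defaults per latitude: annual mean 13 °C at 50 °N falling 0.6 °C per
  degree of latitude (7 °C at 60 °N), amplitude 7 °C, July warmest. These
  are package conventions for a plausible north-temperate gradient, not
  fitted values; users with real monthly tables should supply them.
- **GPP–latitude datasets** — sites uniform over 18–78 °N, GPP linear in
  latitude plus iid Gaussian noise. The default noise SD (~1513 mg C m⁻²
  d⁻¹) is solved analytically so the expected R² is 0.16 at the default 27
  sites, matching the weak-but-significant character of the real
  compilation. With n = 27 and R² = 0.16 the analytic relative SE of the
  slope is ≈ 46%, so bootstrap runs on the synthetic default report a
  larger relative SE than a larger real compilation would.
- **Ration fixtures** — configs for competition-free single-fish runs at
  fixed rations, used for growth/fecundity response checks.

What the synthetic drivers deliberately do not emulate: spatial/temporal
autocorrelation of real water temperatures, inter-annual variability
(every simulated year repeats the same monthly cycle), and site-level
covariates of the GPP compilation. Tests passing on these drivers show the
machinery is correct under the model's assumptions, not that the model is
calibrated to any particular water body.

## Bioenergetics

Rates follow mass-allometry × thermal response:

| parameter | default | units | rationale |
|---|---|---|---|
| max ingestion coeff | 0.04 | g food·g⁻⁰·⁷⁵·d⁻¹ | ~4% body mass per day for a 1 g fish at 15 °C |
| ingestion / metabolic mass exponent | 0.75 | – | generic ¾-power scaling |
| assimilation efficiency | 0.7 | – | typical for carnivorous fish on invertebrate prey |
| food energy density | 3000 | J/g wet | macroinvertebrates/zooplankton |
| maintenance coeff | 24 | J·g⁻⁰·⁷⁵·d⁻¹ | within the span of stickleback resting metabolism at 15 °C |
| Q10 (ingestion, metabolism) | 2.0 | – | canonical ectotherm value |
| reference temperature | 15 | °C | mid-range of the habitats modelled |
| tissue energy density | 4000 | J/g wet | somatic growth cost |
| reserve energy density | 25000 | J/g | mixed lipid/protein stores |
| max reserve fraction | 0.2 | of structural mass | condition ceiling |
| growth cap coeff | 60 | J·g⁻⁰·⁷⁵·d⁻¹ | lets fry grow ~4–5%/d, rarely binds for adults |
| growth fraction | 0.6 | – | split of surplus between growth and storage (see below) |
| length–weight a, b | 5.5e-6, 3.1 | g, mm | stickleback length–weight relation |
| fecundity | 80 | eggs/g | clutches of ~50–100 eggs for 0.6–1.2 g females |
| clutch interval | 10 | d | inter-spawning interval |
| egg mass | 0.001 | g | ~1 mg eggs |
| breeding season | day 121–212 | – | May 1 – July 31 |
| gonad quota | 25 | J·g⁻⁰·⁷⁵·d⁻¹ | fills a clutch in roughly one interval under good food |
| maturity mass | 0.15 | g | ≈ 30 mm, first breeding at age 1 |
| egg / larval duration | 6 / 15 | d at 15 °C | temperature-scaled |
| thermal window (CT_min, CT_opt, CT_max) | −2, 24, 32 | °C | sticklebacks feed (slowly) in near-freezing water and tolerate ~30 °C |

These defaults are the package's own parameterisation: generic allometric
and thermal constants combined with magnitudes plausible for the species,
adjusted during model development until default simulations hold a stable
carrying capacity of a few fish per m² at every modelled latitude. They are
not transcribed from any calibrated dataset, and every value is overridable
through a YAML config (sections `geometry`, `bioenergetics`, `mortality`).

**Thermal responses.** Window-limited rates (ingestion, growth capacity,
egg/larval development) use `Q10^((T−15)/10)` multiplied by a linear ramp
from 0 at CT_min over 2 °C and a linear taper from CT_opt to 0 at CT_max —
continuous in T, zero outside the window. Maintenance uses the pure Q10
response with no window: metabolic costs keep rising as water warms, which
is exactly the mechanism that squeezes energy budgets at warm, low-latitude
sites, and they stay positive in cold water where feeding has effectively
stopped (overwinter reserve drain).

**Daily allocation.** Priority: maintenance first (shortfalls drawn from
reserves; an unpayable remainder flags deterministic starvation death), then
gonad investment up to the daily quota for adult females in season, then the
remaining surplus is split `growth_fraction : (1 − growth_fraction)` between
structural growth (further capped by the thermal growth maximum) and
reserves (capped by capacity; the residue beyond both caps is discarded as
overflow). A strict growth-before-storage priority was tried first and
rejected: it leaves fish no autumn lipid deposition, and whole cohorts
starve in midwinter. The ledger identity
`assimilated = maintenance + reproduction + growth + storage_delta + overflow`
holds to 1e-9 J every fish-day and is asserted over multi-year runs.
Reproductive energy is metered through females only (egg production is the
budgeted cost); male courtship and nest costs are not separately tracked.

**Reproduction.** Nest sites are the vegetated patches, at most one
territorial male each; surplus males sit out the day — the density
dependence of reproduction. Ripe females (interval elapsed, gonad + reserves
covering the clutch cost) are matched at random to territorial males, one
spawning per male per day. Clutch size is `round(80 × mass)` eggs, paid at
`eggs × egg mass × tissue energy density` from gonad first, then reserves.

**Mortality.** Daily background rates per stage (egg 0.08, larva 0.06,
juvenile and adult 0.004) times a Beverton–Holt style penalty
`1/(1 + γ·N/A)` with γ = 0.0002 m² and N the post-larval abundance.
γ is deliberately small: the load-bearing density dependence is trophic
(food competition) and reproductive (nest sites), so that changes in food
supply propagate into census density rather than being clamped by a
non-trophic term. Starvation and exceeding the 3-year maximum age kill
deterministically.

## Movement

Mobile post-larval fish redistribute every day by sequential best response:
in random order, each joins the vegetated patch maximising expected intake,
patch food / (competitors + 1). For identically-weighted fish this greedy
process is exactly a highest-averages apportionment, so the day loop
computes the occupancy counts in one vectorised pass (the sequential
reference implementation is kept and the two are tested for exact count
agreement, and against the closed-form input-matching prediction on static
two-patch problems: occupancy proportional to food, ±1 fish). Territorial
males do not move while holding a nest.

## Study design

Each latitude × ΔT × replicate simulation runs a warm-up under ΔT = 0
drivers, then switches to the treatment drivers; an April-1 pre-breeding
census (day 91) records post-larval density, biomass (structural mass per
m²) and mean individual metabolic rate (the maintenance demand at that day's
temperature — maintenance-only by design; total expenditure can be derived
from the daily logs). Replicate r of every treatment runs on seed
`base_seed + r`, pairing treatments with their control through shared
initial conditions. Extinct replicates stay in all summaries as zero-density
rows.

Effects are reported two ways, since the aggregation order is a genuine
choice: the percent change of replicate-mean endpoints at the final census
(the headline numbers), and a detection rule — detectable when the mean
density over the whole treatment period deviates more than 5% from the
control mean. The paired warming contrast (does +4.4 °C beat control at
60 °N?) uses each replicate's treatment-period mean and a one-sided sign
test across the five pairs (α = 0.05, i.e. all five pairs must agree).

**Problem sizes.** The shipped drivers and the acceptance pipeline run the
scaled-down design: 3 latitudes × 4 ΔT × 5 replicates, 5-year warm-up +
5-year treatment — chosen as the smallest design that cleanly separates the
warming trends from census noise at the model's default carrying capacity
(~8 fish m⁻², so ~160 post-larval fish per census). The full-scale
layout (10 + 10 years, 15 replicates) is a flag away
(`analysis/03_run_experiment.py --replicates 15 --warmup-years 10
--treatment-years 10`) and takes roughly ten times longer. Absolute
percent-change magnitudes depend on the bioenergetic parameterisation and
are *not* reproduction targets at the package defaults; the directional
structure (density/biomass inflation with warming, stronger at high
latitude; metabolic rate rising with ΔT and falling with latitude) is.

## Numerical choices

- 365-day calendar, no leap days; months at standard day-of-year cut points;
  April 1 = day 91.
- Daily food renewal resets vegetated stocks to the month's production rate
  (the drivers are daily rates); carry-over accumulation is available via
  `food_carryover` for sensitivity checks. Food mass balance
  (renewal − consumed = remaining) is asserted to 1e-12 g daily.
- Scramble competition splits a patch's stock in proportion to individual
  maximum ingestion; a size-ordered contest mode is config-selectable.
- Development progress accumulates `scaling(T)/duration` per day with a
  1e-9 completion epsilon so a duration-D stage finishes in exactly D days
  at the reference temperature despite floating-point accumulation.
- One RNG stream (numpy PCG64) per replicate; populations are kept in
  stable insertion order so runs are bit-identical under a seed.
- Bootstrap resamples with zero latitude variance (a single site drawn n
  times) have no defined slope and are redrawn; with 27 distinct sites this
  is a ~1e-39 event per resample, but the guard keeps tiny inputs exact.

## Known limitations

- Closed population: no migration, no anadromy; results do not generalise
  to open or migrating populations.
- No predators, no behavioural thermal responses, no genetic adaptation —
  deliberately out of scope.
- The bioenergetic constants are plausible rather than calibrated; absolute
  densities and percent changes shift with them, the qualitative
  temperature/food mechanisms do not.
- Warming shifts monthly means only; variance and extremes (heat waves,
  droughts) are unmodelled.
- The GPP→food chain treats consumer carbon production as immediately and
  fully edible, and the biomass–temperature regression extrapolates below
  the latitude of the mesocosm study it came from.
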