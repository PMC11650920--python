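"""Daily population schedule: movement, feeding, allocation, breeding, death.

Each simulated day runs, in order: food renewal → ideal-free redistribution →
patch-level food sharing and ingestion → energy allocation and growth →
egg/larva development → breeding (in season) → mortality → ageing. Population
dynamics (carrying capacity, recruitment pulses, latitudinal differences)
emerge from these rules; nothing at the population level is imposed.

Movement follows a sequential best-response approximation to the ideal free
distribution: mobile post-larval fish, in random order, each join the
vegetated patch maximising expected intake (patch food divided by competitors
already there plus one). Territorial males competing for nest sites (one per
vegetated patch) do not move while holding a territory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fish import (
    ADULT, EGG, JUVENILE, LARVA,
    DailyEnergyLedger, Fish,
    allocate_energy, assimilate, grow, max_ingestion, maintenance_cost,
    temperature_scaling,
)
from .landscape import LandscapeState, consume, init_landscape, renew_food
from .params import BioenergeticsParams, ModelConfig, MortalityParams
from .scenario import Scenario

__all__ = [
    "Population",
    "DayRecord",
    "SimResult",
    "init_population",
    "share_patch_food",
    "move_ifd",
    "attempt_breeding",
    "apply_mortality",
    "step_day",
    "run_population",
    "simulate_single_fish",
]


@dataclass
class Population:
    """The agent collection plus a monotone id source."""

    fish: list[Fish] = field(default_factory=list)
    next_id: int = 0

    def new_id(self) -> int:
        i = self.next_id
        self.next_id += 1
        return i

    def count_stage(self, stage: str) -> int:
        return sum(1 for f in self.fish if f.stage == stage and f.alive)

    def post_larval(self) -> list[Fish]:
        return [f for f in self.fish if f.alive and f.post_larval]


@dataclass(slots=True)
class DayRecord:
    """Aggregate log emitted by :func:`step_day`."""

    day_of_year: int
    n_egg: int
    n_larva: int
    n_juvenile: int
    n_adult: int
    biomass: float  # g structural mass, post-larval
    mean_mass: float  # g, post-larval (nan if none)
    mean_metabolic_rate: float  # J d⁻¹ fish⁻¹, post-larval (nan if none)
    food_after_renewal: float  # g, landscape total right after renewal
    food_consumed: float  # g
    food_remaining: float  # g, end of day
    ledger_residual_max: float  # J, worst energy-balance residual of the day
    n_spawnings: int


@dataclass
class SimResult:
    census: pd.DataFrame  # one row per simulated year at the census day
    daily: pd.DataFrame | None
    extinct: bool


# ---------------------------------------------------------------------------
# initialisation

def _reference_growth_curve(age_days: float) -> float:
    # coarse asymptotic mass-at-age used only to seed plausible initial sizes
    return 1.2 * (1.0 - np.exp(-0.004 * age_days)) ** 3


def init_population(
    config: ModelConfig, land: LandscapeState, rng: np.random.Generator
) -> Population:
    """Seed juveniles and adults with stochastic age, sex and position.

    Adult year-class is geometric (older cohorts geometrically rarer, capped
    at age 3), sex is 1:1 Bernoulli, positions uniform over vegetated patches,
    masses follow a coarse growth curve with lognormal scatter, reserves start
    at 60% of capacity.
    """
    p = config.bio
    pop = Population()
    veg = land.vegetated_indices

    def place() -> int:
        if veg.size:
            return int(veg[rng.integers(veg.size)])
        return int(rng.integers(land.geometry.n_patches))

    def make(stage: str, age: int, mass: float) -> Fish:
        return Fish(
            id=pop.new_id(),
            sex="M" if rng.random() < 0.5 else "F",
            age=age,
            stage=stage,
            structural_mass=mass,
            reserves=0.6 * p.reserve_capacity(mass),
            length=p.length_from_mass(mass),
            patch_index=place(),
            days_since_spawn=100,
        )

    for _ in range(config.initial_adults):
        year_class = min(int(rng.geometric(0.5)), 2)
        age = int(365 * year_class + rng.uniform(0, 120))
        mass = float(np.clip(
            _reference_growth_curve(age) * np.exp(rng.normal(0.0, 0.15)),
            p.maturity_mass * 1.05, 2.0,
        ))
        pop.fish.append(make(ADULT, age, mass))
    for _ in range(config.initial_juveniles):
        age = int(rng.uniform(180, 320))
        mass = float(np.clip(
            _reference_growth_curve(age) * np.exp(rng.normal(0.0, 0.2)),
            0.03, p.maturity_mass * 0.95,
        ))
        pop.fish.append(make(JUVENILE, age, mass))
    return pop


# ---------------------------------------------------------------------------
# daily sub-steps

def share_patch_food(
    fish_on_patch: list[Fish],
    available: float,
    temperature: float,
    p: BioenergeticsParams,
    mode: str = "scramble",
) -> np.ndarray:
    """Split a patch's food among its occupants for one day.

    Demands are individual maximum ingestion rates. If joint demand fits the
    stock, everyone feeds ad libitum; otherwise scramble competition splits
    the stock in proportion to demand, while contest competition feeds fish
    in descending mass order until the stock runs out. No fish exceeds its
    demand and the total never exceeds the stock.
    """
    if available < 0:
        raise ValueError("available food must be nonnegative")
    demands = np.array([max_ingestion(f, temperature, p) for f in fish_on_patch])
    total = demands.sum()
    if available <= 0 or total <= 0:
        return np.zeros(len(fish_on_patch))
    if total <= available:
        return demands
    if mode == "scramble":
        return demands * (available / total)
    # contest: largest fish feed first
    order = sorted(range(len(fish_on_patch)),
                   key=lambda i: (-fish_on_patch[i].structural_mass, i))
    intakes = np.zeros(len(fish_on_patch))
    left = available
    for i in order:
        take = min(demands[i], left)
        intakes[i] = take
        left -= take
        if left <= 0:
            break
    return intakes


def move_ifd(
    pop: Population,
    land: LandscapeState,
    temperature: float,
    rng: np.random.Generator,
) -> None:
    """Redistribute mobile post-larval fish over vegetated patches.

    Sequential best response in random order: each mover joins the patch with
    the highest food per (competitors + 1); ties break to the lowest patch
    slot. Territorial males stay put but count as competitors. For equal
    per-capita weighting this converges to input matching (occupancy roughly
    proportional to food input); ``temperature`` is accepted for signature
    symmetry with the other daily operations — the equilibrium assignment is
    unchanged by a common thermal scaling of demands.
    """
    veg = land.vegetated_indices
    if veg.size == 0:
        return
    stocks = land.food[veg]
    counts = np.zeros(veg.size)
    slot_of = {int(pi): s for s, pi in enumerate(veg)}
    movers: list[Fish] = []
    for f in pop.fish:
        if not (f.alive and f.post_larval):
            continue
        if f.is_territorial:
            s = slot_of.get(f.patch_index)
            if s is not None:
                counts[s] += 1
        else:
            movers.append(f)
    for i in rng.permutation(len(movers)):
        s = int(np.argmax(stocks / (counts + 1.0)))
        movers[i].patch_index = int(veg[s])
        counts[s] += 1


def _feed(
    pop: Population,
    land: LandscapeState,
    temperature: float,
    config: ModelConfig,
) -> tuple[dict[int, float], float]:
    """Share and consume patch food; returns (fish id → intake g, total g)."""
    by_patch: dict[int, list[Fish]] = {}
    for f in pop.fish:
        if f.alive and f.post_larval:
            by_patch.setdefault(f.patch_index, []).append(f)
    intakes: dict[int, float] = {}
    total = 0.0
    for patch in sorted(by_patch):
        group = by_patch[patch]
        shares = share_patch_food(
            group, float(land.food[patch]), temperature, config.bio,
            config.competition,
        )
        got = consume(land, patch, float(shares.sum()))
        total += got
        for f, s in zip(group, shares):
            intakes[f.id] = float(s)
    return intakes, total


def _develop_all(
    pop: Population,
    temperature: float,
    p: BioenergeticsParams,
    rng: np.random.Generator,
) -> None:
    """Bulk equivalent of :func:`sticklesim.fish.develop_offspring`."""
    scale = temperature_scaling(
        temperature, p.q10_ingestion, p.reference_temperature,
        p.thermal_window, p.cold_ramp,
    )
    if scale <= 0:
        return
    inc_egg = scale / p.egg_duration_days
    inc_larva = scale / p.larva_duration_days
    lo, hi = p.offspring_mass_range
    for f in pop.fish:
        if f.stage == EGG:
            f.develop_progress += inc_egg
            if f.develop_progress >= 1.0 - 1e-9:
                f.develop_progress = 0.0
                f.stage = LARVA
        elif f.stage == LARVA:
            f.develop_progress += inc_larva
            if f.develop_progress >= 1.0 - 1e-9:
                f.develop_progress = 0.0
                f.stage = JUVENILE
                f.structural_mass = float(np.clip(
                    rng.normal(p.offspring_mass_mean, p.offspring_mass_sd), lo, hi
                ))
                f.reserves = 0.2 * p.reserve_capacity(f.structural_mass)
                f.length = p.length_from_mass(f.structural_mass)


def attempt_breeding(
    pop: Population,
    land: LandscapeState,
    day_of_year: int,
    rng: np.random.Generator,
    p: BioenergeticsParams,
) -> list[tuple[int, int, int, int]]:
    """One day of territory competition and spawning.

    Nest sites are the vegetated patches, at most one territorial male each;
    surplus males are excluded for the day (density dependence). Ripe females
    (clutch interval elapsed, gonad plus reserves covering the clutch's energy
    cost) are matched at random to territorial males, at most one spawning per
    male per day. A female of mass m lays round(fecundity_coeff · m) eggs on
    the male's patch, paying eggs × egg_mass × tissue_energy_density from her
    gonad buffer first, then reserves.

    Returns (female_id, male_id, patch, n_eggs) per spawning.
    """
    s, e = p.breeding_season
    if not s <= day_of_year <= e:
        return []
    veg = land.vegetated_indices
    if veg.size == 0:
        return []

    occupied = {
        f.patch_index for f in pop.fish
        if f.alive and f.is_territorial and f.stage == ADULT and f.sex == "M"
    }
    free = [int(i) for i in veg if int(i) not in occupied]
    claimants = [
        f for f in pop.fish
        if f.alive and f.stage == ADULT and f.sex == "M" and not f.is_territorial
    ]
    if free and claimants:
        order = rng.permutation(len(claimants))
        sites = rng.permutation(len(free))
        for k, ci in enumerate(order[: len(free)]):
            male = claimants[int(ci)]
            male.is_territorial = True
            male.patch_index = free[int(sites[k])]

    males = [f for f in pop.fish if f.alive and f.is_territorial]
    ready: list[tuple[Fish, int, float]] = []
    for f in pop.fish:
        if not (f.alive and f.stage == ADULT and f.sex == "F"):
            continue
        if f.days_since_spawn < p.clutch_interval:
            continue
        clutch = int(round(p.fecundity_coeff * f.structural_mass))
        if clutch < 1:
            continue
        cost = clutch * p.egg_mass * p.tissue_energy_density
        if f.gonad + f.reserves >= cost:
            ready.append((f, clutch, cost))
    if not males or not ready:
        return []

    events: list[tuple[int, int, int, int]] = []
    f_order = rng.permutation(len(ready))
    m_order = rng.permutation(len(males))
    for fi, mi in zip(f_order, m_order):
        female, clutch, cost = ready[int(fi)]
        male = males[int(mi)]
        from_gonad = min(cost, female.gonad)
        female.gonad -= from_gonad
        female.reserves -= cost - from_gonad
        female.days_since_spawn = 0
        is_male = rng.random(clutch) < 0.5
        for sex_m in is_male:
            pop.fish.append(Fish(
                id=pop.new_id(),
                sex="M" if sex_m else "F",
                age=0,
                stage=EGG,
                structural_mass=p.egg_mass,
                patch_index=male.patch_index,
                days_since_spawn=0,
            ))
        events.append((female.id, male.id, male.patch_index, clutch))
    return events


def apply_mortality(
    pop: Population,
    area: float,
    rng: np.random.Generator,
    mort: MortalityParams,
) -> int:
    """Remove the day's deaths; returns the survivor count.

    Starvation-flagged fish and fish beyond the maximum age die
    deterministically; everyone else survives with probability
    (1 − m_stage) × 1/(1 + γ·N/A), N being post-larval abundance.
    """
    fish = pop.fish
    if not fish:
        return 0
    n = len(fish)
    rate_of = {EGG: mort.egg, LARVA: mort.larva,
               JUVENILE: mort.juvenile, ADULT: mort.adult}
    rates = np.empty(n)
    n_post = 0
    for i, f in enumerate(fish):
        st = f.stage
        rates[i] = rate_of[st]
        if st == JUVENILE or st == ADULT:
            n_post += 1
    penalty = 1.0 / (1.0 + mort.gamma * n_post / area)
    keep = rng.random(n) < (1.0 - rates) * penalty
    survivors: list[Fish] = []
    max_age = mort.max_age_days
    for i, f in enumerate(fish):
        if f.alive and not f.starved and f.age <= max_age and keep[i]:
            survivors.append(f)
        else:
            f.alive = False
    pop.fish = survivors
    return len(survivors)


# ---------------------------------------------------------------------------
# the day loop

def _greedy_slots(
    stocks: np.ndarray, init_counts: np.ndarray, m: int
) -> np.ndarray:
    """Slot sequence produced by m sequential best-response joins.

    Each join takes the patch with the largest current quotient
    stock/(count + 1), so the chosen quotients are exactly the m largest of
    the highest-averages table — a batch computation that reproduces the
    occupancy counts of the sequential loop in :func:`move_ifd` without
    iterating per fish. Returns slots in join order (descending quotient).
    """
    n_patches = stocks.size
    cols = max(4, m // max(n_patches, 1) + 4)
    while True:
        if n_patches * cols <= m:
            cols *= 2
            continue
        denom = init_counts[:, None] + np.arange(1, cols + 1)[None, :]
        flat = (stocks[:, None] / denom).ravel()
        chosen = np.argpartition(-flat, m - 1)[:m] if m < flat.size else np.arange(m)
        counts = np.bincount(chosen // cols, minlength=n_patches)
        if np.any(counts == cols):
            # some patch may deserve more seats than enumerated; widen
            cols *= 2
            continue
        order = chosen[np.argsort(-flat[chosen], kind="stable")]
        return order // cols


def step_day(
    pop: Population,
    land: LandscapeState,
    scenario: Scenario,
    day_of_year: int,
    rng: np.random.Generator,
    config: ModelConfig,
) -> DayRecord:
    """Advance the whole system by one day; returns the aggregate log record.

    The post-larval pipeline (movement, food sharing, energy allocation,
    growth) is computed with vectorised equivalents of the per-fish
    operations in :mod:`sticklesim.fish` and the reference functions in this
    module; equivalence is covered by the test suite.
    """
    p = config.bio
    temperature = scenario.temperature_on(day_of_year)
    season_start, season_end = p.breeding_season
    in_season = season_start <= day_of_year <= season_end

    food_after_renewal = renew_food(land, scenario, day_of_year,
                                    config.food_carryover)
    if not in_season:
        for f in pop.fish:
            f.is_territorial = False

    post = [f for f in pop.fish if f.alive and f.post_larval]
    n_post = len(post)
    veg = land.vegetated_indices
    consumed = 0.0
    residual_max = 0.0
    biomass = 0.0
    mean_mass = float("nan")
    mmr = float("nan")

    if n_post:
        scale_ing = temperature_scaling(
            temperature, p.q10_ingestion, p.reference_temperature,
            p.thermal_window, p.cold_ramp,
        )
        scale_met = (
            p.q10_metabolism ** ((temperature - p.reference_temperature) / 10.0)
        )
        mass = np.array([f.structural_mass for f in post])
        mass_bm = mass ** p.metabolic_mass_exponent
        demand = p.max_ingestion_coeff * mass ** p.ingestion_mass_exponent * scale_ing

        # movement: territorial males hold their nest patch, everyone else
        # joins the patch maximising food per (competitors + 1)
        slot = np.full(n_post, -1, dtype=np.int64)
        if veg.size:
            slot_of = {int(pi): s for s, pi in enumerate(veg)}
            counts0 = np.zeros(veg.size)
            movers: list[int] = []
            for i, f in enumerate(post):
                s = slot_of.get(f.patch_index, -1)
                if f.is_territorial and s >= 0:
                    counts0[s] += 1
                    slot[i] = s
                else:
                    movers.append(i)
            if movers:
                seq = _greedy_slots(land.food[veg], counts0, len(movers))
                perm = rng.permutation(len(movers))
                for k in range(len(movers)):
                    i = movers[perm[k]]
                    s = int(seq[k])
                    slot[i] = s
                    post[i].patch_index = int(veg[s])

        # feeding: ad libitum if the patch stock covers joint demand,
        # otherwise scramble (demand-proportional) or contest split
        intake = np.zeros(n_post)
        if veg.size:
            on_veg = slot >= 0
            if config.competition == "scramble":
                tot_demand = np.bincount(
                    slot[on_veg], weights=demand[on_veg], minlength=veg.size
                )
                stocks = land.food[veg]
                safe = np.maximum(tot_demand, 1e-300)
                ratio = np.where(tot_demand > stocks, stocks / safe, 1.0)
                intake[on_veg] = demand[on_veg] * ratio[slot[on_veg]]
                eaten = np.minimum(tot_demand, stocks)
                land.food[veg] = stocks - eaten
                consumed = float(eaten.sum())
            else:
                intakes_map, consumed = _feed(pop, land, temperature, config)
                intake = np.array([intakes_map.get(f.id, 0.0) for f in post])

        # energy allocation: maintenance → (female) gonads → growth/storage
        assim = intake * (p.food_energy_density * p.assimilation_efficiency)
        maint = p.maintenance_coeff * mass_bm * scale_met
        reserves = np.array([f.reserves for f in post])
        shortfall = np.maximum(maint - assim, 0.0)
        draw = np.minimum(shortfall, reserves)
        reserves = reserves - draw
        storage_delta = -draw
        paid = np.where(shortfall > 0, assim + draw, maint)
        deficit = shortfall - draw
        starved = deficit > 1e-12
        remaining = np.maximum(assim - maint, 0.0)

        repro = np.zeros(n_post)
        if in_season:
            eligible = np.fromiter(
                (f.stage == ADULT and f.sex == "F" for f in post),
                dtype=bool, count=n_post,
            )
            repro = np.where(
                eligible,
                np.minimum(remaining, p.repro_quota_coeff * mass_bm),
                0.0,
            )
            remaining = remaining - repro

        growth = np.minimum(
            remaining * p.growth_fraction,
            p.growth_max_coeff * mass_bm * scale_ing,
        )
        to_store = remaining - growth
        capacity = np.maximum(
            p.max_reserve_fraction * mass * p.reserve_energy_density - reserves,
            0.0,
        )
        stored = np.minimum(to_store, capacity)
        reserves = reserves + stored
        storage_delta = storage_delta + stored
        overflow = to_store - stored

        residual = assim - (paid + repro + growth + storage_delta + overflow)
        residual_max = float(np.max(np.abs(residual)))

        new_mass = mass + growth / p.tissue_energy_density
        new_length = (new_mass / p.length_weight_a) ** (1.0 / p.length_weight_b)
        biomass = float(new_mass.sum())
        mean_mass = biomass / n_post
        mmr = float(maint.mean())  # full metabolic demand, paid or not

        for i, f in enumerate(post):
            f.structural_mass = float(new_mass[i])
            f.reserves = float(reserves[i])
            if new_length[i] > f.length:
                f.length = float(new_length[i])
            if starved[i]:
                f.starved = True
            g = repro[i]
            if g > 0:
                f.gonad += float(g)

    _develop_all(pop, temperature, p, rng)
    events = attempt_breeding(pop, land, day_of_year, rng, p) if in_season else []
    apply_mortality(pop, land.geometry.area, rng, config.mortality)

    n_stage = {EGG: 0, LARVA: 0, JUVENILE: 0, ADULT: 0}
    for f in pop.fish:
        f.age += 1
        if f.sex == "F":
            f.days_since_spawn += 1
        if f.stage == JUVENILE and f.structural_mass >= p.maturity_mass:
            f.stage = ADULT
        n_stage[f.stage] += 1

    return DayRecord(
        day_of_year=day_of_year,
        n_egg=n_stage[EGG],
        n_larva=n_stage[LARVA],
        n_juvenile=n_stage[JUVENILE],
        n_adult=n_stage[ADULT],
        biomass=biomass,
        mean_mass=mean_mass,
        mean_metabolic_rate=mmr,
        food_after_renewal=food_after_renewal,
        food_consumed=consumed,
        food_remaining=land.total_food(),
        ledger_residual_max=residual_max,
        n_spawnings=len(events),
    )


def _census_row(
    pop: Population,
    scenario: Scenario,
    day_of_year: int,
    year: int,
    config: ModelConfig,
) -> dict:
    temperature = scenario.temperature_on(day_of_year)
    p = config.bio
    post = pop.post_larval()
    if config.census_post_larval_only:
        abundance = len(post)
    else:
        abundance = sum(1 for f in pop.fish if f.alive)
    area = config.geometry.area
    biomass = sum(f.structural_mass for f in post)
    mmr = (
        sum(maintenance_cost(f, temperature, p) for f in post) / len(post)
        if post else float("nan")
    )
    return {
        "year": year,
        "day_of_year": day_of_year,
        "abundance": abundance,
        "density": abundance / area,
        "biomass": biomass / area,
        "mean_metabolic_rate": mmr,
        "extinct": len(post) == 0,
    }


_DAILY_COLUMNS = [
    "day_index", "year", "day_of_year", "n_egg", "n_larva", "n_juvenile",
    "n_adult", "biomass", "mean_mass", "mean_metabolic_rate",
    "food_after_renewal", "food_consumed", "food_remaining",
    "ledger_residual_max", "n_spawnings",
]


def run_population(
    config: ModelConfig,
    yearly_scenarios: list[Scenario],
    seed: int,
    census_day: int = 91,
    collect_daily: bool = False,
) -> SimResult:
    """Run one replicate over a sequence of yearly scenarios.

    One scenario per simulated 365-day year (repeat entries for multi-year
    phases such as a warm-up). The annual census is a state snapshot taken at
    the start of ``census_day`` (April 1 by default, the pre-breeding census).
    A single RNG stream seeded with ``seed`` drives everything.
    """
    rng = np.random.default_rng(seed)
    land = init_landscape(config.geometry, rng)
    pop = init_population(config, land, rng)
    censuses: list[dict] = []
    daily: list[tuple] = []
    day_index = 0
    for year, scen in enumerate(yearly_scenarios, start=1):
        for doy in range(1, 366):
            if doy == census_day:
                censuses.append(_census_row(pop, scen, doy, year, config))
            rec = step_day(pop, land, scen, doy, rng, config)
            day_index += 1
            if collect_daily:
                daily.append((
                    day_index, year, doy, rec.n_egg, rec.n_larva,
                    rec.n_juvenile, rec.n_adult, rec.biomass, rec.mean_mass,
                    rec.mean_metabolic_rate, rec.food_after_renewal,
                    rec.food_consumed, rec.food_remaining,
                    rec.ledger_residual_max, rec.n_spawnings,
                ))
    census = pd.DataFrame(censuses)
    return SimResult(
        census=census,
        daily=pd.DataFrame(daily, columns=_DAILY_COLUMNS) if collect_daily else None,
        extinct=bool(census["extinct"].iloc[-1]) if len(census) else True,
    )


# ---------------------------------------------------------------------------
# single-fish (competition-free) trajectories

def simulate_single_fish(
    food_g_per_day: float,
    temperature_c: float,
    days: int,
    p: BioenergeticsParams | None = None,
    start_mass: float = 0.3,
    sex: str = "F",
) -> dict:
    """Deterministic one-fish trajectory at a fixed ration and temperature.

    The fish feeds on min(ration, maximum ingestion) every day; a female
    spawns whenever ripe (clutch interval elapsed, gonad plus reserves
    covering the clutch cost) without needing a mate. Used for ration-response
    checks of growth and fecundity.
    """
    p = p or BioenergeticsParams()
    fish = Fish(
        id=0, sex=sex, age=365, stage=ADULT,
        structural_mass=start_mass,
        reserves=0.5 * p.reserve_capacity(start_mass),
        length=p.length_from_mass(start_mass),
        days_since_spawn=p.clutch_interval,
    )
    season_start, season_end = p.breeding_season
    eggs = clutches = 0
    alive = True
    for d in range(days):
        doy = d % 365 + 1
        in_season = season_start <= doy <= season_end
        intake = min(food_g_per_day, max_ingestion(fish, temperature_c, p))
        ledger = allocate_energy(
            fish, assimilate(intake, p), temperature_c, in_season, p
        )
        grow(fish, ledger.growth, p)
        if fish.starved:
            alive = False
            break
        fish.age += 1
        fish.days_since_spawn += 1
        if (
            sex == "F" and in_season
            and fish.days_since_spawn >= p.clutch_interval
        ):
            clutch = int(round(p.fecundity_coeff * fish.structural_mass))
            cost = clutch * p.egg_mass * p.tissue_energy_density
            if clutch >= 1 and fish.gonad + fish.reserves >= cost:
                from_gonad = min(cost, fish.gonad)
                fish.gonad -= from_gonad
                fish.reserves -= cost - from_gonad
                fish.days_since_spawn = 0
                eggs += clutch
                clutches += 1
    return {
        "final_mass": fish.structural_mass,
        "final_length": fish.length,
        "eggs_spawned": eggs,
        "clutches": clutches,
        "alive": alive,
    }
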