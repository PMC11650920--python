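"""Per-fish state and daily bioenergetics.

Each fish carries structural mass (g), an energy reserve (J), a length (mm)
tied to mass through the length-weight relation, a life stage
(egg → larva → juvenile → adult) and reproductive state. Assimilated energy
is allocated every day in priority order: maintenance first (shortfalls drawn
from reserves; an unpayable shortfall flags the fish for starvation death),
then gonad investment for adult females in the breeding season, then the
remaining surplus split between structural growth (capped by a
temperature-scaled maximum growth rate) and reserves (capped by reserve
capacity; any residue beyond both caps is discarded as overflow). The daily
ledger satisfies, exactly:

    assimilated = maintenance + reproduction + growth + storage_delta + overflow

with ``storage_delta`` negative on days reserves are drawn down.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import BioenergeticsParams

__all__ = [
    "Fish",
    "DailyEnergyLedger",
    "EGG", "LARVA", "JUVENILE", "ADULT", "POST_LARVAL",
    "temperature_scaling",
    "metabolic_scaling",
    "max_ingestion",
    "assimilate",
    "maintenance_cost",
    "max_growth_energy",
    "allocate_energy",
    "grow",
    "develop_offspring",
]

EGG = "egg"
LARVA = "larva"
JUVENILE = "juvenile"
ADULT = "adult"
POST_LARVAL = (JUVENILE, ADULT)


@dataclass(slots=True)
class Fish:
    id: int
    sex: str  # "M" or "F"
    age: int = 0  # days
    stage: str = ADULT
    structural_mass: float = 0.0  # g
    reserves: float = 0.0  # J
    length: float = 0.0  # mm
    patch_index: int = 0
    is_territorial: bool = False  # males holding a nest patch
    days_since_spawn: int = 10_000  # females; large = ready whenever ripe
    alive: bool = True
    gonad: float = 0.0  # J, female reproductive buffer
    starved: bool = False
    develop_progress: float = 0.0  # egg/larva stage completion in [0, 1)

    @property
    def post_larval(self) -> bool:
        return self.stage in POST_LARVAL


@dataclass(slots=True)
class DailyEnergyLedger:
    """One fish-day of energy book-keeping (all entries J except ingested, g)."""

    ingested: float = 0.0
    assimilated: float = 0.0
    maintenance: float = 0.0
    reproduction: float = 0.0
    growth: float = 0.0
    storage_delta: float = 0.0
    overflow: float = 0.0
    deficit: float = 0.0  # maintenance that could not be paid (starvation)

    def residual(self) -> float:
        """Deviation from the balance identity; zero for a consistent day."""
        return self.assimilated - (
            self.maintenance + self.reproduction + self.growth
            + self.storage_delta + self.overflow
        )


def temperature_scaling(
    temperature: float,
    q10: float,
    reference_temperature: float,
    thermal_window: tuple[float, float, float],
    cold_ramp: float = 2.0,
) -> float:
    """Thermal multiplier for rate processes confined to a tolerance window.

    A Q10 response ``q10^((T − T_ref)/10)`` multiplied by a linear ramp from
    0 at CT_min over ``cold_ramp`` degrees, and by a linear taper from 1 at
    CT_opt to 0 at CT_max. Continuous in T; exactly zero at or beyond the
    window edges; equals the plain Q10 value between the ramp top and CT_opt.
    """
    ct_min, ct_opt, ct_max = thermal_window
    if not np.isfinite(temperature):
        raise ValueError("temperature must be finite")
    if temperature <= ct_min or temperature >= ct_max:
        return 0.0
    base = q10 ** ((temperature - reference_temperature) / 10.0)
    cold = min(1.0, (temperature - ct_min) / cold_ramp)
    warm = 1.0 if temperature <= ct_opt else (ct_max - temperature) / (ct_max - ct_opt)
    return base * cold * warm


def metabolic_scaling(
    temperature: float,
    q10: float,
    reference_temperature: float,
) -> float:
    """Pure Q10 multiplier for maintenance metabolism (no window clipping).

    Costs keep rising with temperature — the mechanism by which warming
    squeezes energy budgets — and stay positive in cold water where feeding
    has ceased.
    """
    if not np.isfinite(temperature):
        raise ValueError("temperature must be finite")
    return q10 ** ((temperature - reference_temperature) / 10.0)


def _require_feeding_stage(fish: Fish) -> None:
    if not fish.alive:
        raise ValueError(f"fish {fish.id} is dead")
    if not fish.post_larval:
        raise ValueError(f"fish {fish.id} is {fish.stage}; eggs/larvae do not feed")


def max_ingestion(fish: Fish, temperature: float, p: BioenergeticsParams) -> float:
    """Maximum daily food intake (g) for a post-larval fish at temperature T."""
    _require_feeding_stage(fish)
    scale = temperature_scaling(
        temperature, p.q10_ingestion, p.reference_temperature,
        p.thermal_window, p.cold_ramp,
    )
    return p.max_ingestion_coeff * fish.structural_mass ** p.ingestion_mass_exponent * scale


def assimilate(ingested: float, p: BioenergeticsParams) -> float:
    """Energy (J) assimilated from ``ingested`` g of food."""
    if ingested < 0:
        raise ValueError("ingested mass must be nonnegative")
    return ingested * p.food_energy_density * p.assimilation_efficiency


def maintenance_cost(fish: Fish, temperature: float, p: BioenergeticsParams) -> float:
    """Daily maintenance metabolism (J) of a live fish."""
    if not fish.alive:
        raise ValueError(f"fish {fish.id} is dead")
    scale = metabolic_scaling(temperature, p.q10_metabolism, p.reference_temperature)
    return p.maintenance_coeff * fish.structural_mass ** p.metabolic_mass_exponent * scale


def max_growth_energy(fish: Fish, temperature: float, p: BioenergeticsParams) -> float:
    """Temperature-scaled cap on daily energy routed to structural growth (J)."""
    scale = temperature_scaling(
        temperature, p.q10_ingestion, p.reference_temperature,
        p.thermal_window, p.cold_ramp,
    )
    return p.growth_max_coeff * fish.structural_mass ** p.metabolic_mass_exponent * scale


def allocate_energy(
    fish: Fish,
    assimilated: float,
    temperature: float,
    in_breeding_season: bool,
    p: BioenergeticsParams,
) -> DailyEnergyLedger:
    """Allocate one day's assimilated energy; mutates reserves/gonad/flags.

    Order: maintenance (reserves buffer a shortfall; an unpayable remainder
    sets ``starved`` and is recorded as ``deficit``), then gonad investment up
    to the daily quota for adult females in season, then the surplus split
    ``growth_fraction`` : rest between growth (further capped by the thermal
    maximum growth rate) and reserves. The returned ledger balances exactly;
    the growth energy is *not* yet applied to mass — callers pass
    ``ledger.growth`` to :func:`grow`.
    """
    _require_feeding_stage(fish)
    ledger = DailyEnergyLedger(assimilated=assimilated)
    maint = maintenance_cost(fish, temperature, p)

    if assimilated >= maint:
        ledger.maintenance = maint
        remaining = assimilated - maint
    else:
        shortfall = maint - assimilated
        draw = min(shortfall, fish.reserves)
        fish.reserves -= draw
        ledger.storage_delta -= draw
        ledger.maintenance = assimilated + draw
        remaining = 0.0
        if draw < shortfall - 1e-12:
            ledger.deficit = shortfall - draw
            fish.starved = True

    if in_breeding_season and fish.stage == ADULT and fish.sex == "F" and remaining > 0:
        quota = p.repro_quota_coeff * fish.structural_mass ** p.metabolic_mass_exponent
        invest = min(remaining, quota)
        fish.gonad += invest
        ledger.reproduction = invest
        remaining -= invest

    if remaining > 0:
        growth = min(remaining * p.growth_fraction,
                     max_growth_energy(fish, temperature, p))
        ledger.growth = growth
        to_store = remaining - growth
        capacity = p.reserve_capacity(fish.structural_mass) - fish.reserves
        stored = min(to_store, max(capacity, 0.0))
        fish.reserves += stored
        ledger.storage_delta += stored
        ledger.overflow = to_store - stored

    return ledger


def grow(fish: Fish, growth_energy: float, p: BioenergeticsParams) -> Fish:
    """Convert growth energy (J) into structural mass and update length.

    Mass and length never decrease; length tracks mass through the inverse
    length-weight relation.
    """
    if growth_energy < 0:
        raise ValueError("growth_energy must be nonnegative")
    if growth_energy > 0:
        fish.structural_mass += growth_energy / p.tissue_energy_density
        fish.length = max(fish.length, p.length_from_mass(fish.structural_mass))
    return fish


def develop_offspring(
    fish: Fish,
    temperature: float,
    p: BioenergeticsParams,
    rng: np.random.Generator,
) -> Fish:
    """Advance an egg or larva by one day of temperature-dependent development.

    Progress accrues at ``scaling(T) / base_duration`` per day (the ingestion
    thermal response is reused, so development halts at or below CT_min).
    On completing the egg stage the fish becomes a larva; on completing the
    larval stage it becomes a free-feeding juvenile with an initial mass drawn
    from the configured distribution and a small initial reserve.
    """
    if fish.stage not in (EGG, LARVA):
        raise ValueError(f"fish {fish.id} is {fish.stage}, not egg or larva")
    scale = temperature_scaling(
        temperature, p.q10_ingestion, p.reference_temperature,
        p.thermal_window, p.cold_ramp,
    )
    duration = p.egg_duration_days if fish.stage == EGG else p.larva_duration_days
    fish.develop_progress += scale / duration
    # epsilon so D increments of 1/D complete in exactly D days despite rounding
    if fish.develop_progress >= 1.0 - 1e-9:
        fish.develop_progress = 0.0
        if fish.stage == EGG:
            fish.stage = LARVA
        else:
            fish.stage = JUVENILE
            lo, hi = p.offspring_mass_range
            fish.structural_mass = float(
                np.clip(rng.normal(p.offspring_mass_mean, p.offspring_mass_sd), lo, hi)
            )
            fish.reserves = 0.2 * p.reserve_capacity(fish.structural_mass)
            fish.length = p.length_from_mass(fish.structural_mass)
    return fish
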