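"""Model parameters and configuration handling.

The bioenergetic constants here are the package's own default parameter set:
generic allometric/thermal values (3/4-power mass scaling, Q10 = 2 around a
15 °C reference) combined with magnitudes plausible for a small temperate
fish, calibrated during model development so that default simulations settle
at a stable carrying capacity of a few fish per square metre. They are not a
species-calibrated dataset; every value can be overridden from a YAML config
file (see :func:`load_config`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

from .scenario import SystemGeometry, DEFAULT_GEOMETRY

__all__ = [
    "BioenergeticsParams",
    "MortalityParams",
    "ModelConfig",
    "ConfigError",
    "load_config",
    "config_from_dict",
    "config_to_dict",
    "validate_config",
]


class ConfigError(ValueError):
    """Raised for malformed or inconsistent configuration input."""


@dataclass(frozen=True)
class BioenergeticsParams:
    """Energy-budget, growth and reproduction constants for one fish.

    Rates follow mass^exponent allometry scaled by a Q10 temperature response
    around ``reference_temperature``; ingestion (and development, growth) are
    additionally confined to the thermal window (CT_min, CT_opt, CT_max):
    zero at or below CT_min, a short linear ramp above it, and a linear taper
    to zero between CT_opt and CT_max. Maintenance uses the pure Q10 response
    so that metabolic costs keep rising with temperature up to CT_max.
    """

    # ingestion
    max_ingestion_coeff: float = 0.04  # g food · g^-b_ing · d⁻¹ at T_ref
    ingestion_mass_exponent: float = 0.75
    assimilation_efficiency: float = 0.7  # fraction of ingested energy
    food_energy_density: float = 3000.0  # J per g food (wet)

    # maintenance metabolism
    maintenance_coeff: float = 24.0  # J · g^-b_met · d⁻¹ at T_ref
    metabolic_mass_exponent: float = 0.75
    q10_ingestion: float = 2.0
    q10_metabolism: float = 2.0
    reference_temperature: float = 15.0  # °C

    # tissue and reserves
    tissue_energy_density: float = 4000.0  # J per g structural (wet) mass
    reserve_energy_density: float = 25000.0  # J per g reserve tissue
    max_reserve_fraction: float = 0.2  # of structural mass, as reserve tissue

    # growth
    growth_max_coeff: float = 60.0  # J · g^-b_met · d⁻¹ at T_ref, cap
    growth_fraction: float = 0.6  # share of post-reproduction surplus to growth

    # length-weight relation  mass = a · length^b  (g, mm)
    length_weight_a: float = 5.5e-6
    length_weight_b: float = 3.1

    # reproduction
    fecundity_coeff: float = 80.0  # eggs per g female structural mass
    clutch_interval: int = 10  # days between clutches
    egg_mass: float = 0.001  # g per egg
    breeding_season: tuple[int, int] = (121, 212)  # day-of-year, May 1 - Jul 31
    repro_quota_coeff: float = 25.0  # J · g^-b_met · d⁻¹ gonad investment cap
    maturity_mass: float = 0.15  # g (≈30 mm), juvenile → adult threshold

    # early life history
    egg_duration_days: float = 6.0  # at T_ref
    larva_duration_days: float = 15.0  # at T_ref
    offspring_mass_mean: float = 0.008  # g at juvenile onset
    offspring_mass_sd: float = 0.0015
    offspring_mass_range: tuple[float, float] = (0.004, 0.015)

    # thermal window (CT_min, CT_opt, CT_max), °C; sticklebacks keep feeding
    # (slowly) in near-freezing water, hence a CT_min below 0
    thermal_window: tuple[float, float, float] = (-2.0, 24.0, 32.0)
    cold_ramp: float = 2.0  # °C over which rates ramp up from CT_min

    def __post_init__(self) -> None:
        positive = (
            "max_ingestion_coeff", "food_energy_density", "maintenance_coeff",
            "q10_ingestion", "q10_metabolism", "tissue_energy_density",
            "reserve_energy_density", "growth_max_coeff", "length_weight_a",
            "length_weight_b", "fecundity_coeff", "egg_mass",
            "repro_quota_coeff", "maturity_mass", "egg_duration_days",
            "larva_duration_days", "offspring_mass_mean", "cold_ramp",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0 < self.assimilation_efficiency <= 1:
            raise ConfigError("assimilation_efficiency must be in (0, 1]")
        if not 0 <= self.growth_fraction <= 1:
            raise ConfigError("growth_fraction must be in [0, 1]")
        if not 0 < self.max_reserve_fraction <= 1:
            raise ConfigError("max_reserve_fraction must be in (0, 1]")
        ct_min, ct_opt, ct_max = self.thermal_window
        if not ct_min < ct_opt < ct_max:
            raise ConfigError("thermal_window must satisfy CT_min < CT_opt < CT_max")
        s, e = self.breeding_season
        if not (1 <= s <= e <= 365):
            raise ConfigError("breeding_season must be an ordered day-of-year pair")
        if self.clutch_interval < 1:
            raise ConfigError("clutch_interval must be >= 1 day")

    def reserve_capacity(self, structural_mass: float) -> float:
        """Maximum reserve energy (J) a fish of given structural mass can hold."""
        return self.max_reserve_fraction * structural_mass * self.reserve_energy_density

    def length_from_mass(self, mass: float) -> float:
        """Invert the length-weight relation: length (mm) from mass (g)."""
        return (mass / self.length_weight_a) ** (1.0 / self.length_weight_b)

    def mass_from_length(self, length: float) -> float:
        return self.length_weight_a * length ** self.length_weight_b


@dataclass(frozen=True)
class MortalityParams:
    """Daily background mortality by stage plus density-dependent survival.

    Each fish survives a day with probability ``(1 − m_stage) · 1/(1 + γ·N/A)``
    where N is post-larval abundance and A the habitat area (a Beverton-Holt
    style compensation). Starvation (reserves exhausted below maintenance)
    kills deterministically, as does exceeding the maximum age.
    """

    egg: float = 0.08
    larva: float = 0.06
    juvenile: float = 0.004
    adult: float = 0.004
    gamma: float = 0.0002  # m² per fish, density-penalty coefficient
    max_age_days: int = 1095  # 3 years

    def __post_init__(self) -> None:
        for name in ("egg", "larva", "juvenile", "adult"):
            if not 0 <= getattr(self, name) < 1:
                raise ConfigError(f"mortality rate {name} must be in [0, 1)")
        if self.gamma < 0:
            raise ConfigError("gamma must be nonnegative")
        if self.max_age_days < 1:
            raise ConfigError("max_age_days must be positive")

    def base_rate(self, stage: str) -> float:
        return getattr(self, stage)


@dataclass(frozen=True)
class ModelConfig:
    """Everything one replicate simulation needs apart from the scenario."""

    geometry: SystemGeometry = DEFAULT_GEOMETRY
    bio: BioenergeticsParams = field(default_factory=BioenergeticsParams)
    mortality: MortalityParams = field(default_factory=MortalityParams)
    initial_adults: int = 24
    initial_juveniles: int = 36
    food_carryover: bool = False  # True: unconsumed food accumulates day-to-day
    competition: str = "scramble"  # or "contest" (size-ordered)
    census_post_larval_only: bool = True

    def __post_init__(self) -> None:
        if self.initial_adults < 0 or self.initial_juveniles < 0:
            raise ConfigError("initial population sizes must be nonnegative")
        if self.competition not in ("scramble", "contest"):
            raise ConfigError("competition must be 'scramble' or 'contest'")


_SECTION_TYPES = {
    "geometry": SystemGeometry,
    "bioenergetics": BioenergeticsParams,
    "mortality": MortalityParams,
}

# YAML represents tuples as lists; these fields need converting back.
_TUPLE_FIELDS = {
    "breeding_season", "thermal_window", "offspring_mass_range",
}


def _build_section(cls, data: dict[str, Any], section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown keys in section '{section}': {sorted(unknown)}")
    coerced = {
        k: tuple(v) if k in _TUPLE_FIELDS and isinstance(v, list) else v
        for k, v in data.items()
    }
    return cls(**coerced)


def config_from_dict(data: dict[str, Any]) -> ModelConfig:
    """Build a :class:`ModelConfig` from nested plain dictionaries."""
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    kwargs: dict[str, Any] = {}
    top_fields = {f.name for f in dataclasses.fields(ModelConfig)}
    for key, value in data.items():
        if key in _SECTION_TYPES:
            if not isinstance(value, dict):
                raise ConfigError(f"section '{key}' must be a mapping")
            target = {"geometry": "geometry", "bioenergetics": "bio",
                      "mortality": "mortality"}[key]
            kwargs[target] = _build_section(_SECTION_TYPES[key], value, key)
        elif key in top_fields:
            kwargs[key] = value
        else:
            raise ConfigError(f"unknown config key: {key!r}")
    return ModelConfig(**kwargs)


def config_to_dict(config: ModelConfig) -> dict[str, Any]:
    """Round-trippable plain-dict form of a config (lists for tuples)."""

    def plain(obj):
        d = dataclasses.asdict(obj)
        return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}

    return {
        "geometry": plain(config.geometry),
        "bioenergetics": plain(config.bio),
        "mortality": plain(config.mortality),
        "initial_adults": config.initial_adults,
        "initial_juveniles": config.initial_juveniles,
        "food_carryover": config.food_carryover,
        "competition": config.competition,
        "census_post_larval_only": config.census_post_larval_only,
    }


def load_config(path) -> ModelConfig:
    """Load and validate a YAML model configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def validate_config(data: dict[str, Any]) -> list[str]:
    """Validate a config mapping; returns [] if valid, else the error messages."""
    try:
        config_from_dict(data)
    except (ConfigError, TypeError) as exc:
        return [str(exc)]
    return []
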