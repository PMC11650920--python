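"""Climate and food scenarios for the latitude/warming simulations.

A scenario couples a latitude in the north temperate zone (50--60 °N) with an
IPCC long-term warming level (ΔT of 0, 1.4, 2.7 or 4.4 °C, corresponding to
SSP1-1.9, SSP2-4.5 and SSP5-8.5) and resolves both into twelve monthly driver
values: water temperature (°C) and food density on vegetated patches
(g patch⁻¹ day⁻¹).

Food density is derived by chaining three published empirical regressions:

1. river gross primary production (GPP, mg C m⁻² d⁻¹) increases linearly with
   latitude: ``GPP = 38.13·Lat + 88.0``;
2. daily primary-consumer (secondary) production is linear in GPP:
   ``PCP = 0.02·GPP + 9.04``;
3. macroinvertebrate standing biomass increases log-linearly with water
   temperature: ``log10(biomass) = 0.138·T + 1.090`` — warming of ΔT therefore
   multiplies food availability by ``10^(0.138·ΔT)``.

Primary-consumer carbon production is taken 1:1 as available wet food mass
(an optional conversion factor is exposed) and spread over the vegetated
patches of the model habitat.

The module also provides a bootstrap robustness check for the GPP--latitude
slope: ordinary least squares refitted on resamples (rows drawn with
replacement) of a (latitude, GPP) dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RegressionSpec",
    "SystemGeometry",
    "Scenario",
    "BootstrapResult",
    "GPP_VS_LATITUDE",
    "CONSUMER_PRODUCTION_VS_GPP",
    "INVERTEBRATE_BIOMASS_VS_TEMPERATURE",
    "DEFAULT_GEOMETRY",
    "MONTH_LENGTHS",
    "month_of_day",
    "gpp_from_latitude",
    "pcp_from_gpp",
    "food_per_patch",
    "annual_food_for_latitude",
    "warming_log10_offset",
    "warming_food_factor",
    "apply_warming_food_increase",
    "build_scenario",
    "bootstrap_slope",
]

#: Latitude range (°N) over which the GPP regression was verified against a
#: literature compilation; predictions outside it warn but do not fail.
VERIFIED_LATITUDE_RANGE = (18.0, 78.0)

#: IPCC long-term (2100) warming levels used in the study design, °C.
IPCC_DELTA_T = (1.4, 2.7, 4.4)

# 365-day model calendar (no leap days).
MONTH_LENGTHS = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)
_MONTH_END = np.cumsum(MONTH_LENGTHS)


def month_of_day(day_of_year: int) -> int:
    """Month (1--12) containing ``day_of_year`` (1--365) in the model calendar."""
    if not 1 <= day_of_year <= 365:
        raise ValueError(f"day_of_year must be in 1..365, got {day_of_year}")
    return int(np.searchsorted(_MONTH_END, day_of_year)) + 1


@dataclass(frozen=True)
class RegressionSpec:
    """A fitted simple linear regression ``response = slope·x + intercept``.

    ``response_scale`` records whether the fitted response is on the natural
    scale (``"linear"``) or base-10 logarithmic (``"log10"``), in which case
    :meth:`predict` back-transforms while :meth:`linear_predictor` does not.
    """

    slope: float
    intercept: float
    response_scale: str = "linear"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise ValueError("slope and intercept must be finite")
        if self.response_scale not in ("linear", "log10"):
            raise ValueError(f"unknown response_scale {self.response_scale!r}")

    def linear_predictor(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept

    def predict(self, x):
        eta = self.linear_predictor(x)
        return 10.0 ** eta if self.response_scale == "log10" else eta


#: GPP (mg C m⁻² d⁻¹) as a linear function of latitude (°N).
GPP_VS_LATITUDE = RegressionSpec(slope=38.13, intercept=88.0)

#: Daily primary-consumer production (mg C m⁻² d⁻¹) as a function of GPP.
CONSUMER_PRODUCTION_VS_GPP = RegressionSpec(slope=0.02, intercept=9.04)

#: log10 macroinvertebrate biomass (mg m⁻²) as a function of temperature (°C).
INVERTEBRATE_BIOMASS_VS_TEMPERATURE = RegressionSpec(
    slope=0.138, intercept=1.090, response_scale="log10"
)


@dataclass(frozen=True)
class SystemGeometry:
    """Geometry of the enclosed model habitat.

    The default is a 20 m² pond divided into 500 patches of 20 × 20 cm, one in
    ten of which is vegetated and food-bearing (50 food patches).
    """

    area: float = 20.0  # m²
    n_patches: int = 500
    vegetated_ratio: float = 0.1

    def __post_init__(self) -> None:
        if self.area <= 0 or self.n_patches <= 0:
            raise ValueError("area and n_patches must be positive")
        if not 0.0 <= self.vegetated_ratio <= 1.0:
            raise ValueError("vegetated_ratio must be in [0, 1]")
        n_veg = self.n_patches * self.vegetated_ratio
        if abs(n_veg - round(n_veg)) > 1e-9:
            raise ValueError(
                f"n_patches × vegetated_ratio must be integral, got {n_veg}"
            )

    @property
    def n_vegetated(self) -> int:
        return int(round(self.n_patches * self.vegetated_ratio))

    @property
    def patch_area(self) -> float:
        """Area of one patch, m² (0.04 m² for the default 20 × 20 cm grid)."""
        return self.area / self.n_patches


DEFAULT_GEOMETRY = SystemGeometry()


def gpp_from_latitude(lat: float) -> float:
    """Gross primary production (mg C m⁻² d⁻¹) predicted from latitude (°N)."""
    if not np.isfinite(lat):
        raise ValueError(f"latitude must be finite, got {lat}")
    lo, hi = VERIFIED_LATITUDE_RANGE
    if not lo <= lat <= hi:
        warnings.warn(
            f"latitude {lat}°N is outside the verified range {lo}-{hi}°N; "
            "the GPP regression is an extrapolation there",
            stacklevel=2,
        )
    return float(GPP_VS_LATITUDE.predict(lat))


def pcp_from_gpp(gpp: float) -> float:
    """Daily primary-consumer production (mg C m⁻² d⁻¹) from GPP."""
    if not np.isfinite(gpp) or gpp < 0:
        raise ValueError(f"gpp must be finite and nonnegative, got {gpp}")
    return float(CONSUMER_PRODUCTION_VS_GPP.predict(gpp))


def food_per_patch(
    pcp: float,
    geometry: SystemGeometry = DEFAULT_GEOMETRY,
    carbon_to_wet_mass: float = 1.0,
) -> float:
    """Convert areal consumer production into food per vegetated patch.

    Parameters
    ----------
    pcp
        Primary-consumer production, mg C m⁻² d⁻¹. Consumer carbon production
        is assumed available 1:1 as food mass for the fish; an explicit
        conversion factor (g wet food per mg C, beyond the mg→g unit change)
        can be supplied via ``carbon_to_wet_mass``.
    geometry
        Habitat geometry; only vegetated patches hold food.

    Returns
    -------
    float
        Food input, g patch⁻¹ d⁻¹, spread over the vegetated patches.
    """
    if not np.isfinite(pcp) or pcp < 0:
        raise ValueError(f"pcp must be finite and nonnegative, got {pcp}")
    if carbon_to_wet_mass <= 0:
        raise ValueError("carbon_to_wet_mass must be positive")
    if geometry.n_vegetated == 0:
        raise ValueError("geometry has no vegetated patches to hold food")
    grams_per_day = pcp * geometry.area / 1000.0 * carbon_to_wet_mass
    return grams_per_day / geometry.n_vegetated


def annual_food_for_latitude(
    lat: float,
    geometry: SystemGeometry = DEFAULT_GEOMETRY,
    carbon_to_wet_mass: float = 1.0,
) -> float:
    """Baseline (no-warming) annual-mean food density, g patch⁻¹ d⁻¹."""
    return food_per_patch(pcp_from_gpp(gpp_from_latitude(lat)), geometry,
                          carbon_to_wet_mass)


def warming_log10_offset(delta_t: float) -> float:
    """log10 biomass level implied by a warming of ``delta_t`` °C.

    Evaluates the macroinvertebrate biomass regression at the temperature
    *increase*: ``1.090 + 0.138·ΔT``. The study's scenario labels round this
    to two decimals (1.28 / 1.46 / 1.70 for ΔT 1.4 / 2.7 / 4.4 °C); the
    returned value is unrounded.
    """
    if not np.isfinite(delta_t) or delta_t < 0:
        raise ValueError(f"delta_t must be finite and nonnegative, got {delta_t}")
    return float(INVERTEBRATE_BIOMASS_VS_TEMPERATURE.linear_predictor(delta_t))


def warming_food_factor(delta_t: float) -> float:
    """Multiplicative increase in food availability under ΔT of warming.

    Adding the warming offset on the log10 scale and subtracting the baseline
    intercept leaves the pure warming increment 0.138·ΔT, whose back-transform
    is the factor ``10^(0.138·ΔT)`` applied to food density.
    """
    if not np.isfinite(delta_t) or delta_t < 0:
        raise ValueError(f"delta_t must be finite and nonnegative, got {delta_t}")
    return float(10.0 ** (INVERTEBRATE_BIOMASS_VS_TEMPERATURE.slope * delta_t))


def apply_warming_food_increase(baseline_food: float, delta_t: float) -> float:
    """Scale a baseline food density by the warming-driven biomass increase."""
    if not np.isfinite(baseline_food) or baseline_food <= 0:
        raise ValueError(f"baseline_food must be positive, got {baseline_food}")
    return baseline_food * warming_food_factor(delta_t)


@dataclass
class Scenario:
    """Resolved monthly drivers for one latitude × warming treatment."""

    latitude: float
    delta_t: float
    monthly_temperature: np.ndarray  # °C, 12 values
    monthly_food_per_patch: np.ndarray  # g patch⁻¹ d⁻¹, 12 values
    annual_mean_food: float  # g patch⁻¹ d⁻¹

    def __post_init__(self) -> None:
        self.monthly_temperature = np.asarray(self.monthly_temperature, float)
        self.monthly_food_per_patch = np.asarray(self.monthly_food_per_patch, float)
        if self.monthly_temperature.shape != (12,):
            raise ValueError("monthly_temperature must have 12 entries")
        if self.monthly_food_per_patch.shape != (12,):
            raise ValueError("monthly_food_per_patch must have 12 entries")
        if np.any(self.monthly_food_per_patch < 0):
            raise ValueError("food densities must be nonnegative")
        mean = self.monthly_food_per_patch.mean()
        if self.annual_mean_food > 0 and not np.isclose(
            mean, self.annual_mean_food, rtol=1e-9, atol=0
        ):
            raise ValueError(
                f"mean monthly food {mean} does not match annual mean "
                f"{self.annual_mean_food}"
            )

    def temperature_on(self, day_of_year: int) -> float:
        return float(self.monthly_temperature[month_of_day(day_of_year) - 1])

    def food_on(self, day_of_year: int) -> float:
        return float(self.monthly_food_per_patch[month_of_day(day_of_year) - 1])


def build_scenario(
    latitude: float,
    delta_t: float,
    seasonal_shape: np.ndarray | None = None,
    monthly_temperature_baseline: np.ndarray | None = None,
    geometry: SystemGeometry = DEFAULT_GEOMETRY,
    carbon_to_wet_mass: float = 1.0,
) -> Scenario:
    """Resolve a latitude and warming level into monthly driver schedules.

    The annual-mean food density comes from the latitude regression chain,
    multiplied by the warming factor ``10^(0.138·ΔT)``; the twelve monthly food
    values are the (positive) ``seasonal_shape`` weights rescaled so their mean
    equals that annual mean, so any overall scaling of the shape is irrelevant.
    Monthly temperatures are the baseline series plus ``delta_t`` elementwise.

    When ``seasonal_shape`` or ``monthly_temperature_baseline`` is omitted, the
    package's synthetic seasonal defaults for the latitude are used (sinusoidal
    year with a July peak; see :mod:`sticklesim.synthetic`).
    """
    from . import synthetic  # local import: synthetic provides the defaults

    if seasonal_shape is None:
        seasonal_shape = synthetic.default_food_shape()
    shape = np.asarray(seasonal_shape, dtype=float)
    if shape.shape != (12,):
        raise ValueError("seasonal_shape must have 12 entries")
    if np.any(shape <= 0) or not np.all(np.isfinite(shape)):
        raise ValueError("seasonal_shape entries must be positive and finite")

    if monthly_temperature_baseline is None:
        monthly_temperature_baseline = synthetic.default_monthly_temperature_baseline(
            latitude
        )
    temps0 = np.asarray(monthly_temperature_baseline, dtype=float)
    if temps0.shape != (12,):
        raise ValueError("monthly_temperature_baseline must have 12 entries")
    if not np.all(np.isfinite(temps0)):
        raise ValueError("baseline temperatures must be finite")

    annual = annual_food_for_latitude(latitude, geometry, carbon_to_wet_mass)
    if delta_t != 0:
        annual = apply_warming_food_increase(annual, delta_t)
    monthly_food = shape / shape.mean() * annual
    return Scenario(
        latitude=latitude,
        delta_t=delta_t,
        monthly_temperature=temps0 + delta_t,
        monthly_food_per_patch=monthly_food,
        annual_mean_food=annual,
    )


@dataclass
class BootstrapResult:
    """Outcome of the GPP--latitude slope bootstrap."""

    n_boot: int
    slope_estimates: np.ndarray
    fitted_slope: float
    bias: float  # mean bootstrap slope − full-data slope
    se_relative: float  # SD of bootstrap slopes ÷ full-data slope
    seed: int


def _ols_slope_intercept(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    xm, ym = x.mean(), y.mean()
    den = float(((x - xm) ** 2).sum())
    if den == 0:
        raise ValueError("degenerate dataset: all predictor values identical")
    slope = float(((x - xm) * (y - ym)).sum()) / den
    return slope, ym - slope * xm


def bootstrap_slope(
    latitudes,
    gpp,
    n_boot: int = 5000,
    seed: int = 0,
) -> BootstrapResult:
    """Nonparametric bootstrap of the OLS slope of GPP on latitude.

    Rows are resampled with replacement (same n as the input) ``n_boot`` times
    and the slope refitted on each resample. Resamples whose latitudes are all
    identical (slope undefined) are redrawn. Reports the bias of the bootstrap
    mean relative to the full-data slope and the bootstrap standard error as a
    fraction of the slope.
    """
    x = np.asarray(latitudes, dtype=float).ravel()
    y = np.asarray(gpp, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("latitudes and gpp must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 data points")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    fitted, _ = _ols_slope_intercept(x, y)

    rng = np.random.default_rng(seed)
    n = x.size
    idx = rng.integers(0, n, size=(n_boot, n))
    xs, ys = x[idx], y[idx]
    xc = xs - xs.mean(axis=1, keepdims=True)
    yc = ys - ys.mean(axis=1, keepdims=True)
    den = (xc * xc).sum(axis=1)
    # redraw any resample that happened to pick a single site repeatedly
    while np.any(den == 0):
        bad = np.flatnonzero(den == 0)
        idx[bad] = rng.integers(0, n, size=(bad.size, n))
        xs, ys = x[idx], y[idx]
        xc = xs - xs.mean(axis=1, keepdims=True)
        yc = ys - ys.mean(axis=1, keepdims=True)
        den = (xc * xc).sum(axis=1)
    slopes = (xc * yc).sum(axis=1) / den

    sd = float(np.std(slopes, ddof=1)) if n_boot > 1 else 0.0
    return BootstrapResult(
        n_boot=n_boot,
        slope_estimates=slopes,
        fitted_slope=fitted,
        bias=float(slopes.mean() - fitted),
        se_relative=sd / fitted,
        seed=seed,
    )
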