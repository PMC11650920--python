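"""Study design orchestration: warm-up, scenario switch, replication, census.

Each latitude × warming treatment × replicate runs a warm-up phase under the
no-warming drivers to reach a stable population, then switches to the
treatment drivers; an April-1 pre-breeding census is recorded each treatment
year. Effects are summarised two ways: the percentage change in density and
biomass at the final pre-breeding census, and a detection rule — a treatment
is detectable when its mean census density over the treatment decade deviates
from the control mean by more than the detection threshold (5% by default).

Replicates are paired across treatments: replicate r of every treatment uses
RNG seed ``base_seed + r``, so treatment contrasts within a replicate share
initial conditions and demographic luck.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .params import ModelConfig, config_to_dict
from .population import run_population
from .scenario import MONTH_LENGTHS, Scenario, build_scenario

__all__ = [
    "ExperimentConfig",
    "EffectResult",
    "run_experiment",
    "percent_change",
    "detect_effect",
    "effects_table",
    "summarize_final_census",
    "write_outputs",
]

ENDPOINTS = ("density", "biomass")


def _day_of_year(month: int, day: int) -> int:
    return int(np.sum(MONTH_LENGTHS[: month - 1])) + day


@dataclass(frozen=True)
class ExperimentConfig:
    """Design of a full simulation experiment."""

    warmup_years: int = 10
    treatment_years: int = 10
    n_replicates: int = 15
    census_month_day: tuple[int, int] = (4, 1)
    latitudes: tuple[float, ...] = (50.0, 55.0, 60.0)
    delta_ts: tuple[float, ...] = (0.0, 1.4, 2.7, 4.4)
    base_seed: int = 0
    detection_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.warmup_years < 0 or self.treatment_years < 1:
            raise ValueError("invalid experiment durations")
        if 0.0 not in self.delta_ts:
            raise ValueError("delta_ts must include the ΔT = 0 control")
        if not 0 < self.detection_threshold:
            raise ValueError("detection_threshold must be positive")

    @property
    def census_day(self) -> int:
        return _day_of_year(*self.census_month_day)


def run_experiment(
    config: ExperimentConfig,
    model_config: ModelConfig | None = None,
    scenario_overrides: dict | None = None,
) -> pd.DataFrame:
    """Run the full design; returns the long-format census table.

    One row per latitude × ΔT × replicate × treatment year with columns
    latitude, delta_t, replicate, year_index, density (fish m⁻²), biomass
    (g m⁻²), mean_metabolic_rate (J d⁻¹ fish⁻¹) and an extinction flag.
    Extinct populations stay in the table as zero-density rows.

    ``scenario_overrides`` are passed through to
    :func:`sticklesim.scenario.build_scenario` (seasonal shape, baseline
    temperatures, geometry).
    """
    model_config = model_config or ModelConfig()
    overrides = scenario_overrides or {}
    rows: list[dict] = []
    for lat in config.latitudes:
        control = build_scenario(lat, 0.0, **overrides)
        for dt in config.delta_ts:
            treatment = (
                control if dt == 0.0 else build_scenario(lat, dt, **overrides)
            )
            schedule = (
                [control] * config.warmup_years
                + [treatment] * config.treatment_years
            )
            for rep in range(config.n_replicates):
                result = run_population(
                    model_config,
                    schedule,
                    seed=config.base_seed + rep,
                    census_day=config.census_day,
                )
                census = result.census
                treat = census[census["year"] > config.warmup_years]
                for _, rec in treat.iterrows():
                    rows.append({
                        "latitude": lat,
                        "delta_t": dt,
                        "replicate": rep,
                        "year_index": int(rec["year"]) - config.warmup_years,
                        "density": rec["density"],
                        "biomass": rec["biomass"],
                        "mean_metabolic_rate": rec["mean_metabolic_rate"],
                        "extinct": bool(rec["extinct"]),
                    })
    return pd.DataFrame(rows)


def percent_change(control_mean: float, treatment_mean: float) -> float:
    """Signed percentage change of treatment relative to control."""
    if not np.isfinite(control_mean) or control_mean <= 0:
        raise ValueError(
            f"percent change undefined for control mean {control_mean}"
        )
    return 100.0 * (treatment_mean - control_mean) / control_mean


@dataclass(frozen=True)
class EffectResult:
    """Treatment effect for one latitude × ΔT × endpoint."""

    latitude: float
    delta_t: float
    endpoint: str
    percent_change: float  # at the final pre-breeding census
    decade_percent_change: float  # of the treatment-decade mean
    detectable: bool  # decade-mean rule against the detection threshold


def detect_effect(
    control_records: pd.DataFrame,
    treatment_records: pd.DataFrame,
    threshold: float = 0.05,
    endpoint: str = "density",
) -> EffectResult:
    """Apply the detection rule to one control/treatment census group pair.

    Both inputs are census rows for a single latitude (all replicates, all
    treatment years). The effect is detectable when the mean ``endpoint`` over
    the treatment years deviates from the control mean by more than
    ``threshold`` (a fraction). The final-census percent change is reported
    alongside.
    """
    if endpoint not in ENDPOINTS:
        raise ValueError(f"endpoint must be one of {ENDPOINTS}")
    if control_records.empty or treatment_records.empty:
        raise ValueError("both record groups must be non-empty")
    lat_c = set(control_records["latitude"].unique())
    lat_t = set(treatment_records["latitude"].unique())
    if lat_c != lat_t or len(lat_c) != 1:
        raise ValueError(f"mismatched latitude grouping: {lat_c} vs {lat_t}")

    control_mean = float(control_records[endpoint].mean())
    treatment_mean = float(treatment_records[endpoint].mean())

    final = int(control_records["year_index"].max())
    final_c = float(
        control_records.loc[control_records["year_index"] == final, endpoint].mean()
    )
    final_t = float(
        treatment_records.loc[
            treatment_records["year_index"] == final, endpoint
        ].mean()
    )
    if control_mean <= 0 or final_c <= 0:
        # extinct control: change undefined, flagged rather than raised
        import warnings

        warnings.warn(
            "control group is extinct; percent change undefined", stacklevel=2
        )
        decade_change = float("nan")
        final_change = float("nan")
        detectable = False
    else:
        decade_change = percent_change(control_mean, treatment_mean)
        final_change = percent_change(final_c, final_t)
        detectable = abs(decade_change) > 100.0 * threshold
    return EffectResult(
        latitude=float(next(iter(lat_c))),
        delta_t=float(treatment_records["delta_t"].iloc[0]),
        endpoint=endpoint,
        percent_change=final_change,
        decade_percent_change=decade_change,
        detectable=detectable,
    )


def effects_table(census: pd.DataFrame, threshold: float = 0.05) -> pd.DataFrame:
    """Detection-rule results for every latitude × nonzero ΔT × endpoint."""
    rows = []
    for lat in sorted(census["latitude"].unique()):
        at_lat = census[census["latitude"] == lat]
        control = at_lat[at_lat["delta_t"] == 0.0]
        for dt in sorted(at_lat["delta_t"].unique()):
            if dt == 0.0:
                continue
            treatment = at_lat[at_lat["delta_t"] == dt]
            for endpoint in ENDPOINTS:
                eff = detect_effect(control, treatment, threshold, endpoint)
                rows.append({
                    "latitude": eff.latitude,
                    "delta_t": eff.delta_t,
                    "endpoint": eff.endpoint,
                    "percent_change_final": eff.percent_change,
                    "percent_change_decade_mean": eff.decade_percent_change,
                    "detectable": eff.detectable,
                })
    return pd.DataFrame(rows)


def summarize_final_census(census: pd.DataFrame) -> pd.DataFrame:
    """Replicate mean and SD of the endpoints at the final census.

    Per latitude × ΔT: mean and SD over replicates of density, biomass and
    mean metabolic rate in the final treatment year, plus percent change of
    the density/biomass means against the ΔT = 0 control at that latitude
    (columns absent, with a warning, if control rows are missing).
    """
    import warnings

    if "year_index" not in census or census.empty:
        raise ValueError("census table is empty or malformed")
    final = int(census["year_index"].max())
    at_final = census[census["year_index"] == final]
    rows = []
    for (lat, dt), grp in at_final.groupby(["latitude", "delta_t"], sort=True):
        row = {
            "latitude": lat,
            "delta_t": dt,
            "n_replicates": len(grp),
            "extinct_replicates": int(grp["extinct"].sum()),
        }
        for endpoint in ("density", "biomass", "mean_metabolic_rate"):
            vals = grp[endpoint].to_numpy(dtype=float)
            finite = vals[~np.isnan(vals)]
            row[f"{endpoint}_mean"] = float(finite.mean()) if finite.size else np.nan
            row[f"{endpoint}_sd"] = (
                float(finite.std(ddof=1)) if finite.size > 1 else 0.0
            )
        rows.append(row)
    out = pd.DataFrame(rows)

    have_control = set(out.loc[out["delta_t"] == 0.0, "latitude"])
    missing = set(out["latitude"]) - have_control
    if missing:
        warnings.warn(
            f"no ΔT = 0 control rows for latitudes {sorted(missing)}; "
            "percent-change columns omitted",
            stacklevel=2,
        )
        return out
    for endpoint in ENDPOINTS:
        changes = []
        for _, row in out.iterrows():
            control = out[
                (out["latitude"] == row["latitude"]) & (out["delta_t"] == 0.0)
            ][f"{endpoint}_mean"].iloc[0]
            if row["delta_t"] == 0.0:
                changes.append(0.0)
            elif control > 0:
                changes.append(percent_change(control, row[f"{endpoint}_mean"]))
            else:
                changes.append(np.nan)
        out[f"{endpoint}_pct_change"] = changes
    return out


def write_outputs(
    census: pd.DataFrame,
    out_dir,
    config: ExperimentConfig,
    model_config: ModelConfig | None = None,
) -> dict[str, Path]:
    """Write census.csv, summary.csv, effects.csv and a provenance manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "census": out / "census.csv",
        "summary": out / "summary.csv",
        "effects": out / "effects.csv",
        "manifest": out / "manifest.yaml",
    }
    census.to_csv(paths["census"], index=False)
    summarize_final_census(census).to_csv(paths["summary"], index=False)
    effects_table(census, config.detection_threshold).to_csv(
        paths["effects"], index=False
    )
    model_dict = config_to_dict(model_config or ModelConfig())
    manifest = {
        "experiment": {
            "warmup_years": config.warmup_years,
            "treatment_years": config.treatment_years,
            "n_replicates": config.n_replicates,
            "census_month_day": list(config.census_month_day),
            "latitudes": list(config.latitudes),
            "delta_ts": list(config.delta_ts),
            "base_seed": config.base_seed,
            "detection_threshold": config.detection_threshold,
        },
        "model": model_dict,
        "replicate_seeds": [
            config.base_seed + r for r in range(config.n_replicates)
        ],
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(model_dict, sort_keys=True).encode()
        ).hexdigest(),
    }
    with open(paths["manifest"], "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return paths
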