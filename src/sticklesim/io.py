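"""Delimited-text readers and writers for the pipeline's small inputs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .landscape import LandscapeState, landscape_from_layout, layout_frame
from .scenario import Scenario, SystemGeometry, DEFAULT_GEOMETRY

__all__ = [
    "read_gpp_csv",
    "monthly_table",
    "write_monthly_table",
    "read_monthly_table",
    "write_layout",
    "read_layout",
]


def read_gpp_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a (latitude, GPP) dataset: CSV, header row, two numeric columns."""
    frame = pd.read_csv(path)
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (latitude, GPP)")
    lat = frame.iloc[:, 0].to_numpy(dtype=float)
    gpp = frame.iloc[:, 1].to_numpy(dtype=float)
    if not (np.all(np.isfinite(lat)) and np.all(np.isfinite(gpp))):
        raise ValueError(f"{path}: non-finite values in dataset")
    return lat, gpp


def monthly_table(scenario: Scenario) -> pd.DataFrame:
    """Twelve-row monthly driver table for a scenario."""
    return pd.DataFrame({
        "month": np.arange(1, 13),
        "temperature_c": scenario.monthly_temperature,
        "food_g_per_patch_day": scenario.monthly_food_per_patch,
    })


def write_monthly_table(path, scenario: Scenario) -> Path:
    path = Path(path)
    monthly_table(scenario).to_csv(path, index=False)
    return path


def read_monthly_table(path) -> pd.DataFrame:
    """Read a monthly driver table (month 1-12, temperature °C, food g/patch/d)."""
    frame = pd.read_csv(path)
    required = {"month", "temperature_c", "food_g_per_patch_day"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if sorted(frame["month"].tolist()) != list(range(1, 13)):
        raise ValueError(f"{path}: must contain months 1..12 exactly once")
    return frame.sort_values("month").reset_index(drop=True)


def write_layout(path, state: LandscapeState) -> Path:
    path = Path(path)
    layout_frame(state).to_csv(path, index=False)
    return path


def read_layout(path, geometry: SystemGeometry = DEFAULT_GEOMETRY) -> LandscapeState:
    return landscape_from_layout(pd.read_csv(path), geometry)
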