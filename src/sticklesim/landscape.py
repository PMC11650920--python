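"""The patchy habitat: a grid of patches, one in ten vegetated and food-bearing.

The default habitat is 20 m² divided into 500 patches on a 25 × 20 grid;
50 randomly placed vegetated patches hold food, the rest never do. Food on
vegetated patches is renewed every day to the scenario's monthly production
rate (a daily reset by default — unconsumed food does not carry over, since
the drivers are daily production rates; carry-over accumulation is available
behind a config flag) and is depleted by fish feeding during the day.

Patch adjacency never matters: movement is by a global ideal free
distribution, so patches are identified by index only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scenario import Scenario, SystemGeometry, DEFAULT_GEOMETRY

__all__ = [
    "Patch",
    "LandscapeState",
    "init_landscape",
    "renew_food",
    "consume",
    "grid_shape_for",
    "layout_frame",
    "landscape_from_layout",
]

VEGETATED = "vegetated"
NONVEGETATED = "nonvegetated"


@dataclass(frozen=True)
class Patch:
    """Snapshot of one patch (static habitat plus current food stock)."""

    index: int
    row: int
    col: int
    habitat: str
    food_stock: float


def grid_shape_for(n_patches: int) -> tuple[int, int]:
    """Near-square (rows, cols) factorisation of the patch count.

    The default 500-patch habitat maps to 25 × 20.
    """
    best = (n_patches, 1)
    for rows in range(int(np.sqrt(n_patches)), 0, -1):
        if n_patches % rows == 0:
            best = max(rows, n_patches // rows), min(rows, n_patches // rows)
            break
    return best


class LandscapeState:
    """Mutable daily state of the habitat.

    Food stocks live in the ``food`` array (g per patch); the boolean
    ``vegetated`` mask and grid positions are fixed at initialisation.
    """

    def __init__(self, geometry: SystemGeometry, vegetated: np.ndarray):
        vegetated = np.asarray(vegetated, dtype=bool)
        if vegetated.shape != (geometry.n_patches,):
            raise ValueError("vegetated mask must have one entry per patch")
        if int(vegetated.sum()) != geometry.n_vegetated:
            raise ValueError(
                f"expected {geometry.n_vegetated} vegetated patches, "
                f"got {int(vegetated.sum())}"
            )
        self.geometry = geometry
        self.grid_shape = grid_shape_for(geometry.n_patches)
        self.vegetated = vegetated
        self.vegetated_indices = np.flatnonzero(vegetated)
        self.food = np.zeros(geometry.n_patches)
        self.day_of_year = 0
        self.current_food_density = 0.0

    # -- accessors ---------------------------------------------------------
    def patch(self, index: int) -> Patch:
        rows, cols = self.grid_shape
        return Patch(
            index=index,
            row=index // cols,
            col=index % cols,
            habitat=VEGETATED if self.vegetated[index] else NONVEGETATED,
            food_stock=float(self.food[index]),
        )

    @property
    def n_vegetated(self) -> int:
        return int(self.vegetated.sum())

    def total_food(self) -> float:
        return float(self.food.sum())


def init_landscape(
    geometry: SystemGeometry = DEFAULT_GEOMETRY,
    seed: int | np.random.Generator = 0,
) -> LandscapeState:
    """Create a landscape with vegetated patches placed uniformly at random.

    The layout is fixed for the life of the simulation; all food stocks start
    at zero (no food until the first renewal). Identical seeds give identical
    layouts.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    vegetated = np.zeros(geometry.n_patches, dtype=bool)
    if geometry.n_vegetated > 0:
        chosen = rng.choice(
            geometry.n_patches, size=geometry.n_vegetated, replace=False
        )
        vegetated[chosen] = True
    return LandscapeState(geometry, vegetated)


def renew_food(
    state: LandscapeState,
    scenario: Scenario,
    day_of_year: int,
    carryover: bool = False,
) -> float:
    """Renew food on vegetated patches for the day; returns total food after.

    Default behaviour resets every vegetated stock to the current month's
    production rate; with ``carryover`` the rate is added to what remains.
    Nonvegetated patches stay at zero. Idempotent (without carry-over): two
    renewals without consumption leave the state unchanged.
    """
    density = scenario.food_on(day_of_year)
    if carryover:
        state.food[state.vegetated_indices] += density
    else:
        state.food[state.vegetated_indices] = density
    state.day_of_year = day_of_year
    state.current_food_density = density
    return state.total_food()


def consume(state: LandscapeState, patch_index: int, demand: float) -> float:
    """Remove up to ``demand`` g of food from a patch; returns the amount taken.

    Nonvegetated patches hold no food, so consumption there returns 0.
    Stocks never go negative.
    """
    if demand < 0:
        raise ValueError("demand must be nonnegative")
    taken = min(demand, float(state.food[patch_index]))
    state.food[patch_index] -= taken
    return taken


# -- layout import/export (plain text, for reproducible fixtures) ----------

def layout_frame(state: LandscapeState) -> pd.DataFrame:
    """Landscape layout as a table: index, row, col, habitat."""
    rows, cols = state.grid_shape
    idx = np.arange(state.geometry.n_patches)
    return pd.DataFrame(
        {
            "index": idx,
            "row": idx // cols,
            "col": idx % cols,
            "habitat": np.where(state.vegetated, VEGETATED, NONVEGETATED),
        }
    )


def landscape_from_layout(
    frame: pd.DataFrame, geometry: SystemGeometry = DEFAULT_GEOMETRY
) -> LandscapeState:
    """Rebuild a landscape from an exported layout table."""
    frame = frame.sort_values("index")
    if len(frame) != geometry.n_patches:
        raise ValueError("layout row count does not match geometry")
    vegetated = (frame["habitat"].to_numpy() == VEGETATED)
    return LandscapeState(geometry, vegetated)
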