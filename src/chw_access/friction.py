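"""Per-cell traversal cost (the friction surface).

Each cell of the analysis grid gets the time in minutes to cross it on
foot.  The walking speed starts from a land-cover class table (baseline
5 km/h on bare ground and all roads, reduced for e.g. dense forest), is
modulated by terrain slope through Tobler's hiking function, and river
cells wide enough to need a canoe (medium) or ferry (large) add a fixed
crossing delay.  Open water off the river network is impassable (+inf).

Tobler's hiking function W(s) = 6·exp(−3.5·|s + 0.05|) km/h predicts
walking speed from slope s (rise/run).  It is applied here as the
multiplicative factor W(s)/W(0), normalised to flat ground, so the
configured flat-ground class speeds are preserved exactly and the slope
effect does not double-count the baseline.  Slope direction is collapsed
to magnitude: the accumulated-cost surface is isotropic, so a cell's cost
cannot depend on which way the walker crosses it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .geodata import Grid
from .hydrology import RiverGrid, WIDTH_LARGE, WIDTH_MEDIUM

__all__ = [
    "SpeedTable",
    "tobler_factor",
    "slope_grid",
    "build_friction",
    "IMPASSABLE",
]

IMPASSABLE = float("inf")

_TOBLER_A = 6.0      # km/h at the optimum
_TOBLER_B = 3.5
_TOBLER_OFFSET = 0.05  # fastest walking on a 5% downhill grade


@dataclass
class SpeedTable:
    """Walking speeds and crossing rules for the friction surface.

    ``class_speeds`` maps land-cover integer class to km/h; ``None`` marks an
    impassable class (open water).  ``crossing_delay_min`` gives the waiting
    delay for medium (dugout canoe) and large (ferry) river cells; small
    streams incur no delay.
    """

    base_speed_kmh: float = 5.0
    class_speeds: dict[int, float | None] = field(default_factory=dict)
    road_speed_kmh: float = 5.0
    crossing_delay_min: dict[str, float] = field(
        default_factory=lambda: {"medium": 15.0, "large": 60.0}
    )
    apply_slope_to_roads: bool = True
    class_labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.base_speed_kmh <= 0 or self.road_speed_kmh <= 0:
            raise ValueError("speeds must be positive")
        for cls, v in self.class_speeds.items():
            if v is not None and v <= 0:
                raise ValueError(f"class {cls}: speed must be positive or null (impassable)")
        for k, v in self.crossing_delay_min.items():
            if v < 0:
                raise ValueError(f"crossing delay for {k} must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path | None = None) -> "SpeedTable":
        """Load a speed table; with no path, the packaged defaults."""
        if path is None:
            text = resources.files("chw_access.data").joinpath("default_speeds.yaml").read_text()
        else:
            text = Path(path).read_text()
        cfg = yaml.safe_load(text)
        classes = cfg.get("class_speeds", {})
        speeds = {int(k): (None if v is None else float(v)) for k, v in classes.items()}
        return cls(
            base_speed_kmh=float(cfg.get("base_speed_kmh", 5.0)),
            class_speeds=speeds,
            road_speed_kmh=float(cfg.get("road_speed_kmh", 5.0)),
            crossing_delay_min={k: float(v) for k, v in cfg.get("crossing_delay_min", {"medium": 15.0, "large": 60.0}).items()},
            apply_slope_to_roads=bool(cfg.get("apply_slope_to_roads", True)),
            class_labels={int(k): str(v) for k, v in cfg.get("class_labels", {}).items()},
        )


def tobler_factor(slope: np.ndarray | float) -> np.ndarray | float:
    """Slope multiplier W(s)/W(0) from Tobler's hiking function.

    Equals 1 on flat ground and peaks at exp(0.175) ≈ 1.19 on a gentle 5%
    downhill; symmetric about s = −0.05, so factor(−0.10) == factor(0).
    With slope reduced to magnitude upstream, only s ≥ 0 occurs in the
    pipeline, where the factor decays monotonically.
    """
    s = np.asarray(slope, dtype=float)
    f = np.exp(-_TOBLER_B * np.abs(s + _TOBLER_OFFSET)) / np.exp(-_TOBLER_B * _TOBLER_OFFSET)
    return float(f) if np.isscalar(slope) else f


def slope_grid(dem: Grid) -> Grid:
    """Dimensionless slope magnitude |∇z| via central differences.

    Interior cells use central differences over 2·cell_size; border cells
    fall back to one-sided differences.
    """
    z = np.asarray(dem.values, dtype=float)
    dz_dy, dz_dx = np.gradient(z, dem.cell_size)
    return dem.with_values(np.hypot(dz_dx, dz_dy))


def build_friction(
    landcover: Grid,
    roads: Grid | None,
    slope: Grid,
    rivers: RiverGrid | None,
    table: SpeedTable,
) -> Grid:
    """Combine layers into traversal minutes per cell.

    speed = road speed on road cells, else the land-cover class speed;
    multiplied by the Tobler slope factor (on roads only when
    ``apply_slope_to_roads``); minutes = (cell_size/1000)/speed·60; medium
    and large river cells add their crossing delay.  Impassable land cover
    is +inf, except on the river network itself where the cell is crossed
    (at base speed) rather than walked around.
    """
    lc = np.asarray(landcover.values)
    for cls in np.unique(lc):
        if int(cls) not in table.class_speeds:
            raise KeyError(f"land-cover class {int(cls)} has no entry in the speed table")

    speed = np.empty(lc.shape, dtype=float)
    impassable = np.zeros(lc.shape, dtype=bool)
    for cls, v in table.class_speeds.items():
        m = lc == cls
        if v is None:
            impassable |= m
            speed[m] = table.base_speed_kmh  # only relevant on river cells
        else:
            speed[m] = v

    on_road = np.zeros(lc.shape, dtype=bool)
    if roads is not None:
        on_road = np.asarray(roads.values) > 0
        speed[on_road] = table.road_speed_kmh
        impassable &= ~on_road  # a road/bridge overrides impassable cover

    factor = np.asarray(tobler_factor(np.asarray(slope.values, dtype=float)))
    if not table.apply_slope_to_roads:
        factor = np.where(on_road, 1.0, factor)
    speed = speed * factor

    minutes = (landcover.cell_size / 1000.0) / speed * 60.0

    if rivers is not None:
        wc = np.asarray(rivers.width_class.values)
        delay = np.zeros(lc.shape, dtype=float)
        delay[wc == WIDTH_MEDIUM] = table.crossing_delay_min["medium"]
        delay[wc == WIDTH_LARGE] = table.crossing_delay_min["large"]
        minutes = minutes + delay
        impassable &= wc == 0  # water on the stream network is crossed, not avoided

    minutes[impassable] = IMPASSABLE
    return landcover.with_values(minutes, nodata=IMPASSABLE)
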