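"""NDVI compositing, grass yield, and theoretical carrying capacity.

Grass yield is a fixed affine function of peak-season NDVI,

    Y = -47.021 + 440.21 * X,

applied to the per-cell maximal-value composite of the NDVI stack (the
standard trick for suppressing cloud and atmospheric lows). Negative yields
(NDVI below ~0.1068) are clamped to zero by default, with the count
recorded. The theoretical carrying capacity per unit area converts usable
forage into sheep units,

    C_tp = Y * E * U / (I * T),

with E the edible forage ratio (0.85), U the grazing utilisation rate
(0.65), I the daily intake per sheep unit (4.0 kg/day) and T the grazing
days per year (365).

The yield unit of the affine model is configuration, not physics: the
default is g/m^2 (equivalently t/km^2), which puts realistic alpine-steppe
NDVI (~0.2-0.3) at county totals of the order of a million tonnes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import Raster

__all__ = [
    "YieldParams",
    "CapacityParams",
    "max_value_composite",
    "ndvi_to_yield",
    "theoretical_capacity_per_area",
    "theoretical_capacity_total",
    "convert_yield",
    "YIELD_UNITS_KG_PER_KM2",
]

#: kg per km^2 represented by one unit of each supported yield unit
YIELD_UNITS_KG_PER_KM2 = {
    "g/m^2": 1_000.0,  # 1 g/m^2 x 1e6 m^2/km^2 = 1000 kg/km^2 (== 1 t/km^2)
    "t/km^2": 1_000.0,
    "kg/ha": 100.0,
    "kg/km^2": 1.0,
    "t/ha": 100_000.0,
}


def convert_yield(value: float | np.ndarray, from_unit: str, to_unit: str) -> float | np.ndarray:
    """Convert a yield-per-area quantity between supported units."""
    try:
        f = YIELD_UNITS_KG_PER_KM2[from_unit]
        t = YIELD_UNITS_KG_PER_KM2[to_unit]
    except KeyError as e:
        raise ValueError(f"unknown yield unit {e.args[0]!r}; known: {sorted(YIELD_UNITS_KG_PER_KM2)}") from None
    return value * (f / t)


@dataclass(frozen=True)
class YieldParams:
    intercept: float = -47.021
    slope: float = 440.21
    unit: str = "g/m^2"
    clamp_negative: bool = True

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if self.unit not in YIELD_UNITS_KG_PER_KM2:
            raise ValueError(f"unknown yield unit {self.unit!r}")


@dataclass(frozen=True)
class CapacityParams:
    edible_ratio: float = 0.85
    utilization: float = 0.65
    intake_kg_per_day: float = 4.0
    grazing_days: float = 365.0

    def __post_init__(self) -> None:
        if not (0.0 < self.edible_ratio <= 1.0):
            raise ValueError("edible_ratio must be in (0, 1]")
        if not (0.0 < self.utilization <= 1.0):
            raise ValueError("utilization must be in (0, 1]")
        if self.intake_kg_per_day <= 0 or self.grazing_days <= 0:
            raise ValueError("intake and grazing days must be positive")

    @property
    def annual_intake_kg(self) -> float:
        """Forage demand of one sheep unit over the grazing period, kg."""
        return self.intake_kg_per_day * self.grazing_days


def max_value_composite(layers: list[Raster]) -> Raster:
    """Per-cell maximum over the stack, ignoring nodata.

    A cell is nodata in the composite only if it is nodata in every layer.
    """
    if not layers:
        raise ValueError("empty NDVI stack")
    specs = {r.spec for r in layers}
    if len(specs) != 1:
        raise ValueError("NDVI layers must share one grid")
    stack = np.stack([r.filled(np.nan) for r in layers])
    with np.errstate(all="ignore"):
        out = np.nanmax(stack, axis=0)
    nodata = layers[0].nodata
    out = np.where(np.isnan(out), nodata, out)
    return Raster(layers[0].spec, out, nodata=nodata)


def ndvi_to_yield(ndvi: Raster, params: YieldParams = YieldParams()) -> tuple[Raster, int]:
    """Affine NDVI-to-yield conversion; returns (yield raster, clamp count)."""
    valid = ndvi.valid_mask()
    vals = ndvi.values
    if np.any((vals[valid] < -1.0 - 1e-9) | (vals[valid] > 1.0 + 1e-9)):
        raise ValueError("NDVI values outside [-1, 1]")
    y = params.intercept + params.slope * vals
    n_clamped = 0
    if params.clamp_negative:
        neg = valid & (y < 0)
        n_clamped = int(neg.sum())
        y = np.where(neg, 0.0, y)
    y = np.where(valid, y, ndvi.nodata)
    return Raster(ndvi.spec, y, nodata=ndvi.nodata), n_clamped


def theoretical_capacity_per_area(
    yield_raster: Raster,
    params: CapacityParams = CapacityParams(),
    yield_unit: str = "g/m^2",
) -> Raster:
    """Theoretical carrying capacity per km^2 (sheep units / km^2).

    The yield raster is converted to kg/km^2 before dividing by the annual
    intake of one sheep unit, so the result integrates directly over cell
    areas in km^2.
    """
    valid = yield_raster.valid_mask()
    y_kg_km2 = convert_yield(yield_raster.values, yield_unit, "kg/km^2")
    ctp = y_kg_km2 * params.edible_ratio * params.utilization / params.annual_intake_kg
    ctp = np.where(valid, ctp, yield_raster.nodata)
    return Raster(yield_raster.spec, ctp, nodata=yield_raster.nodata)


def theoretical_capacity_total(total_yield_kg: float, params: CapacityParams = CapacityParams()) -> float:
    """County-total theoretical carrying capacity (sheep units) from total yield in kg."""
    if total_yield_kg < 0:
        raise ValueError("total yield must be >= 0")
    return total_yield_kg * params.edible_ratio * params.utilization / params.annual_intake_kg
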