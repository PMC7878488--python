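"""Line-transect densities and discovery rates.

Counts from strip transects become species abundance densities (SAD,
animals/km^2) per survey line: density = count / (2 x halfwidth x length).
Discovery rates (animals per km walked per season) summarise survey effort
and are the quantity the strip estimator inverts. Seasonal densities at the
same routes are merged (mean by default) into one point set per species for
interpolation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from shapely import wkt as shapely_wkt

__all__ = ["estimate_sad", "discovery_rate", "seasonal_merge"]

_RECORD_COLUMNS = {"transect_id", "species", "season", "count", "length_km"}


def _check_records(records: pd.DataFrame) -> None:
    missing = _RECORD_COLUMNS - set(records.columns)
    if missing:
        raise ValueError(f"transect table missing columns: {sorted(missing)}")
    if (records["length_km"] <= 0).any() or not np.isfinite(records["length_km"]).all():
        raise ValueError("every transect length must be finite and positive")
    if (records["count"] < 0).any():
        raise ValueError("counts must be non-negative")


def _midpoints(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if "wkt_geometry" in records.columns:
        pts = [shapely_wkt.loads(w).interpolate(0.5, normalized=True) for w in records["wkt_geometry"]]
        return np.array([p.x for p in pts]), np.array([p.y for p in pts])
    if {"x", "y"} <= set(records.columns):
        return records["x"].to_numpy(float), records["y"].to_numpy(float)
    raise ValueError("transect table needs either 'wkt_geometry' or 'x'/'y' columns")


def estimate_sad(records: pd.DataFrame, halfwidth_km: float = 0.5) -> pd.DataFrame:
    """Per-line species abundance density under the strip-transect estimator.

    Returns one row per input record with columns
    ``transect_id, species, season, sad, length_km, x, y`` where ``sad`` is
    animals/km^2 and (x, y) is the line midpoint used as the interpolation
    support point.
    """
    if halfwidth_km <= 0:
        raise ValueError("halfwidth_km must be positive")
    _check_records(records)
    x, y = _midpoints(records)
    sad = records["count"].to_numpy(float) / (2.0 * halfwidth_km * records["length_km"].to_numpy(float))
    return pd.DataFrame(
        {
            "transect_id": records["transect_id"].to_numpy(),
            "species": records["species"].to_numpy(),
            "season": records["season"].to_numpy(),
            "sad": sad,
            "length_km": records["length_km"].to_numpy(float),
            "x": x,
            "y": y,
        }
    )


def discovery_rate(records: pd.DataFrame, species: str, season: str | None = None) -> float:
    """Animals recorded per km of transect for a species.

    With ``season`` given: total count / total length in that season.
    Without: the arithmetic mean of the per-season rates (the
    "per km per season" convention).
    """
    _check_records(records)
    sel = records[records["species"] == species]
    if season is not None:
        sel = sel[sel["season"] == season]
        if sel.empty:
            raise ValueError(f"no records for species={species!r}, season={season!r}")
        return float(sel["count"].sum() / sel["length_km"].sum())
    if sel.empty:
        raise ValueError(f"no records for species={species!r}")
    rates = sel.groupby("season").apply(
        lambda g: g["count"].sum() / g["length_km"].sum(), include_groups=False
    )
    return float(rates.mean())


def seasonal_merge(densities: pd.DataFrame, rule: str = "mean") -> pd.DataFrame:
    """Merge seasonal SADs at matched routes into one value per line per species.

    ``rule``: "mean" (default), "max", or "none" (per-season passthrough).
    Routes must coincide across seasons (same transect_id implies the same
    midpoint).
    """
    if rule == "none":
        return densities.copy()
    if rule not in ("mean", "max"):
        raise ValueError(f"unknown merge rule {rule!r}")

    def _agg(g: pd.DataFrame) -> pd.Series:
        if g["x"].nunique() > 1 or g["y"].nunique() > 1:
            raise ValueError(
                f"transect {g.name} has mismatched locations across seasons; cannot merge"
            )
        sad = g["sad"].mean() if rule == "mean" else g["sad"].max()
        return pd.Series({"sad": sad, "x": g["x"].iloc[0], "y": g["y"].iloc[0]})

    out = (
        densities.groupby(["species", "transect_id"])
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    return out
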