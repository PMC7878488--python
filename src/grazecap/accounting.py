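"""Per-parcel carrying-capacity ledger.

Each land parcel's account balances exactly:

    C_w  = sum_i D_i * S_i * K_i     (wildlife forage demand, sheep units)
    C_t  = C_tp_total - C_w          (ecological carrying capacity)
    RCC  = C_t - actual              (residual carrying capacity)

where D_i is the parcel-mean density of wild species i (animals/km^2), S_i
the parcel area (km^2), K_i the species' sheep-unit conversion (kiang 6,
Tibetan gazelle 0.3), C_tp_total the parcel's theoretical capacity
integrated from the forage surface, and ``actual`` the livestock load in
sheep units. A parcel is overloaded iff RCC < 0 (RCC = 0 is "at
capacity"). County totals are sums over parcels, so every quantity is
conserved under the parcel partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely import contains_xy
from shapely.prepared import prep

from .grid import Raster

__all__ = [
    "WILDLIFE_SHEEP_UNITS",
    "LIVESTOCK_SHEEP_UNITS",
    "zonal_mean",
    "wildlife_offset",
    "ecological_capacity",
    "actual_load",
    "residual_capacity",
    "build_parcel_accounts",
]

#: sheep units per animal for the wild ungulates
WILDLIFE_SHEEP_UNITS = {"kiang": 6.0, "gazelle": 0.3}
#: sheep units per head for livestock classes (sheep fixed at 1 by definition)
LIVESTOCK_SHEEP_UNITS = {"cattle": 4.5, "sheep": 1.0, "horse": 6.0}


def zonal_mean(raster: Raster, parcels: pd.DataFrame) -> pd.DataFrame:
    """Per-parcel mean and integral of a raster by cell-centre containment.

    Every valid cell is assigned to exactly one parcel (first covering
    polygon in parcel order; stray centres landing on no polygon due to
    round-off go to the nearest one), so parcel integrals sum to the county
    integral exactly. A parcel containing no cell centre is flagged with
    null values.

    Returns columns ``parcel_id, n_cells, area_cells_km2, mean, integral``
    where integral = sum(cell value) x cell area.
    """
    spec = raster.spec
    X, Y = spec.center_mesh()
    xs, ys = X.ravel(), Y.ravel()
    vals = raster.filled(np.nan).ravel()

    assignment = np.full(xs.size, -1, dtype=int)
    for _, row in parcels.iterrows():
        g = prep(row["geometry"])
        free = assignment < 0
        if not free.any():
            break
        hit = np.zeros(xs.size, dtype=bool)
        hit[free] = contains_xy(row["geometry"], xs[free], ys[free])
        # covers() for centres exactly on the boundary of this polygon
        if not hit[free].all():
            rem = free & ~hit
            idx = np.flatnonzero(rem)
            from shapely.geometry import Point

            for i in idx:
                if g.covers(Point(xs[i], ys[i])):
                    hit[i] = True
        assignment[hit] = int(row["parcel_id"])
    if (assignment < 0).any():  # numerical slivers: nearest parcel
        from shapely.geometry import Point

        geoms = list(parcels["geometry"])
        pids = parcels["parcel_id"].to_numpy()
        for i in np.flatnonzero(assignment < 0):
            p = Point(xs[i], ys[i])
            d = [g.distance(p) for g in geoms]
            assignment[i] = int(pids[int(np.argmin(d))])

    rows = []
    for pid in parcels["parcel_id"]:
        m = (assignment == int(pid)) & ~np.isnan(vals)
        n = int(m.sum())
        if n == 0:
            rows.append(
                {"parcel_id": int(pid), "n_cells": 0, "area_cells_km2": 0.0, "mean": np.nan, "integral": np.nan}
            )
            continue
        rows.append(
            {
                "parcel_id": int(pid),
                "n_cells": n,
                "area_cells_km2": n * spec.cell_area,
                "mean": float(vals[m].mean()),
                "integral": float(vals[m].sum() * spec.cell_area),
            }
        )
    return pd.DataFrame(rows)


def wildlife_offset(
    densities: pd.DataFrame,
    conversions: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Wildlife forage demand C_w = sum_i D_i * S_i * K_i per parcel.

    ``densities`` has columns ``parcel_id, species, density, area_km2``
    (density = parcel-mean animals/km^2 of the masked surface).
    """
    conversions = dict(conversions or WILDLIFE_SHEEP_UNITS)
    unknown = set(densities["species"]) - set(conversions)
    if unknown:
        raise ValueError(f"no sheep-unit conversion for species: {sorted(unknown)}")
    d = densities.copy()
    d["su"] = d["density"].fillna(0.0) * d["area_km2"] * d["species"].map(conversions)
    out = d.groupby("parcel_id", as_index=False)["su"].sum().rename(columns={"su": "C_w"})
    return out


def ecological_capacity(accounts: pd.DataFrame) -> pd.DataFrame:
    """C_t = C_tp_total - C_w per parcel; negative values allowed and flagged."""
    out = accounts.copy()
    out["C_t"] = out["C_tp_total"] - out["C_w"]
    out["wildlife_exceeds_forage"] = out["C_t"] < 0
    return out


def actual_load(
    livestock: pd.DataFrame,
    conversions: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Livestock load in sheep units per parcel.

    ``livestock`` is either head counts by class (columns = class names) or
    a table with a ``sheep_units`` column (passthrough mode, used when the
    herd is already aggregated).
    """
    if "sheep_units" in livestock.columns:
        out = livestock[["parcel_id", "sheep_units"]].copy()
        return out.rename(columns={"sheep_units": "actual_su"})
    conversions = dict(conversions or LIVESTOCK_SHEEP_UNITS)
    classes = [c for c in livestock.columns if c != "parcel_id"]
    unknown = set(classes) - set(conversions)
    if unknown:
        raise ValueError(f"no sheep-unit rate for livestock class: {sorted(unknown)}")
    su = sum(livestock[c].to_numpy(float) * conversions[c] for c in classes)
    return pd.DataFrame({"parcel_id": livestock["parcel_id"].to_numpy(int), "actual_su": su})


def residual_capacity(accounts: pd.DataFrame) -> pd.DataFrame:
    """RCC = C_t - actual per parcel; overloaded iff RCC < 0 (strict)."""
    out = accounts.copy()
    out["RCC"] = out["C_t"] - out["actual_su"]
    out["overloaded"] = out["RCC"] < 0
    return out


def build_parcel_accounts(
    parcels: pd.DataFrame,
    ctp_raster: Raster,
    masked_densities: dict[str, Raster],
    livestock: pd.DataFrame,
    wildlife_conversions: dict[str, float] | None = None,
    livestock_conversions: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Assemble the full per-parcel ledger and county summary.

    Returns (parcel table, county totals). The parcel table carries one
    density column per species plus C_w, C_tp_total, C_t, actual_su, RCC
    and the overload flag; the county row is the exact parcel sum.
    """
    ctp_zonal = zonal_mean(ctp_raster, parcels)
    acc = parcels[["parcel_id", "area_km2"]].copy()
    acc = acc.merge(
        ctp_zonal[["parcel_id", "integral", "area_cells_km2"]].rename(columns={"integral": "C_tp_total"}),
        on="parcel_id",
    )
    acc["C_tp_total"] = acc["C_tp_total"].fillna(0.0)

    dens_rows = []
    for sp, surface in masked_densities.items():
        z = zonal_mean(surface, parcels)
        acc[f"density_{sp}"] = acc["parcel_id"].map(z.set_index("parcel_id")["mean"])
        dens_rows.append(
            pd.DataFrame(
                {
                    "parcel_id": z["parcel_id"],
                    "species": sp,
                    "density": z["mean"],
                    # densities integrate over the cells actually assigned to
                    # the parcel so the partition conserves animal totals
                    "area_km2": z["area_cells_km2"],
                }
            )
        )
    if dens_rows:
        cw = wildlife_offset(pd.concat(dens_rows, ignore_index=True), wildlife_conversions)
        acc = acc.merge(cw, on="parcel_id", how="left")
        acc["C_w"] = acc["C_w"].fillna(0.0)
    else:
        acc["C_w"] = 0.0

    acc = ecological_capacity(acc)
    acc = acc.merge(actual_load(livestock, livestock_conversions), on="parcel_id", how="left")
    acc["actual_su"] = acc["actual_su"].fillna(0.0)
    acc = residual_capacity(acc)

    county = acc[["area_km2", "C_tp_total", "C_w", "C_t", "actual_su", "RCC"]].sum()
    county["n_overloaded"] = int(acc["overloaded"].sum())
    return acc, county
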