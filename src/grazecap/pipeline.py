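"""End-to-end orchestration of the carrying-capacity pipeline.

Stages (each runnable on its own from the files earlier stages wrote):

1. ``generate``    — synthetic county, surveys, NDVI stack, livestock table
2. ``density``     — transect records -> per-line abundance densities
3. ``krige``       — densities -> gridded abundance surfaces per species
4. ``suitability`` — maxent range masks; clip the kriged surfaces
5. ``yield``       — NDVI composite -> grass yield -> theoretical capacity
6. ``account``     — per-parcel ledger: C_w, C_tp, C_t, actual, RCC
7. ``report``      — provenance report (+ plain choropleth of RCC)

Every artifact is a text file (.asc raster, GeoJSON, CSV, JSON) in the run
directory; every stage records its parameters and warnings in a JSON
fragment, and the run report stitches those together so any number in it
can be recomputed from the recorded config and seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import accounting, forage, habitat, kriging, synthetic, transects
from .grid import Raster, parcels_from_geojson, parcels_to_geojson

__all__ = ["run_all", "worked_example_ledger", "STAGES"]

STAGES = ("generate", "density", "krige", "suitability", "yield", "account", "report")

SPECIES = ("kiang", "gazelle")


def _write_stage(outdir: Path, name: str, payload: dict) -> None:
    (outdir / f"stage_{name}.json").write_text(json.dumps(payload, indent=1, default=str))


def _design_from_config(cfg: dict) -> synthetic.SurveyDesign:
    s = cfg["survey"]
    return synthetic.SurveyDesign(
        n_lines=int(s["n_lines"]),
        seasons=tuple(s["seasons"]),
        transect_length_km=float(s["length_km"]),
        halfwidth_km=float(s["halfwidth_km"]),
        detection_prob=float(s["detection_prob"]),
        seasonal_cv=float(s["seasonal_cv"]),
    )


# ------------------------------------------------------------------ stages


def stage_generate(cfg: dict, outdir: Path) -> None:
    syn = cfg["synthetic"]
    seed = int(cfg["seed"])
    spec = synthetic.CountySpec(
        extent=tuple(syn["extent"]),
        cell_size=float(syn["cell_size"]),
        n_parcels=int(syn["n_parcels"]),
        seed=seed,
    )
    county = synthetic.make_county(spec)
    parcels_to_geojson(county.parcels, outdir / "parcels.geojson", extra_columns=["area_km2"])
    for name, r in county.covariates.items():
        r.write_asc(outdir / f"cov_{name}.asc")

    design = _design_from_config(cfg)
    scale = float(syn["wildlife_scale"])
    truths = []
    for i, params in enumerate(synthetic.default_species_params(design)):
        if scale != 1.0:
            from dataclasses import replace

            params = replace(params, mean_density=params.mean_density * scale)
        truth = synthetic.make_truth(county.grid, county.covariates, params, seed=seed + 101 + i)
        truth.density.write_asc(outdir / f"truth_density_{params.species_id}.asc")
        truth.suitability_truth.write_asc(outdir / f"truth_suitability_{params.species_id}.asc")
        truths.append(truth)

    records = synthetic.simulate_surveys(truths, design, seed=seed + 7)
    records.to_csv(outdir / "transects.csv", index=False)

    livestock = synthetic.simulate_livestock(
        county.parcels,
        mix=cfg["livestock"]["mix"],
        total_sheep_units=float(cfg["livestock"]["total_sheep_units"]),
        seed=seed + 13,
        rates=cfg["conversions"]["livestock"],
    )
    livestock.to_csv(outdir / "livestock.csv", index=False)

    layers, labels = synthetic.make_ndvi_stack(
        county,
        n_dates=int(syn["ndvi"]["n_dates"]),
        seed=seed + 29,
        mean_ndvi=float(syn["ndvi"]["mean"]),
        sd_ndvi=float(syn["ndvi"]["sd"]),
        cloud_prob=float(syn["ndvi"]["cloud_prob"]),
    )
    for r, lab in zip(layers, labels):
        r.write_asc(outdir / f"ndvi_{lab}.asc")

    _write_stage(
        outdir,
        "generate",
        {
            "seed": seed,
            "extent": list(spec.extent),
            "n_parcels": spec.n_parcels,
            "wildlife_scale": scale,
            "species": [t.species_id for t in truths],
            "truth_populations": {t.species_id: t.total_population for t in truths},
            "n_transect_records": int(len(records)),
        },
    )


def stage_density(cfg: dict, outdir: Path) -> None:
    path = outdir / "transects.csv"
    if not path.exists():
        raise FileNotFoundError(f"missing upstream artifact: {path}")
    records = pd.read_csv(path)
    halfwidth = float(cfg["density"]["halfwidth_km"])
    sad = transects.estimate_sad(records, halfwidth_km=halfwidth)
    merged = transects.seasonal_merge(sad, rule=cfg["density"]["merge_rule"])
    rates = {}
    for sp in sorted(records["species"].unique()):
        merged[merged["species"] == sp].to_csv(outdir / f"sad_{sp}.csv", index=False)
        rates[sp] = transects.discovery_rate(records, sp)
    _write_stage(
        outdir,
        "density",
        {"halfwidth_km": halfwidth, "merge_rule": cfg["density"]["merge_rule"], "discovery_rates": rates},
    )


def stage_krige(cfg: dict, outdir: Path) -> None:
    kcfg = cfg["kriging"]
    grid = Raster.read_asc(outdir / "cov_elevation.asc").spec
    info = {}
    for path in sorted(outdir.glob("sad_*.csv")):
        sp = path.stem.removeprefix("sad_")
        sad = pd.read_csv(path)
        pts = sad[["x", "y"]].to_numpy(float)
        vals = sad["sad"].to_numpy(float)
        lags, gammas, counts = kriging.empirical_semivariogram(
            pts, vals, lag_width=float(kcfg["lag_width_km"]), max_lag=float(kcfg["max_lag_km"])
        )
        variogram, diag = kriging.fit_semivariogram(lags, gammas, counts, model=kcfg["model"])
        result = kriging.krige(pts, vals, variogram, grid, neighborhood_size=int(kcfg["neighborhood"]))
        result.cross_validation = kriging.cross_validate(
            pts, vals, variogram, neighborhood_size=int(kcfg["neighborhood"])
        )
        result.prediction.write_asc(outdir / f"density_{sp}.asc")
        result.variance.write_asc(outdir / f"variance_{sp}.asc")
        info[sp] = {
            "variogram": {
                "model": variogram.model,
                "nugget": variogram.nugget,
                "sill": variogram.sill,
                "range_km": variogram.range_km,
            },
            "fit": diag,
            "n_points": int(len(pts)),
            "n_clamped": result.n_clamped,
            "cross_validation": result.cross_validation,
        }
    if not info:
        raise FileNotFoundError(f"missing upstream artifacts: {outdir}/sad_*.csv")
    _write_stage(outdir, "krige", {"settings": kcfg, "species": info})


def stage_suitability(cfg: dict, outdir: Path) -> None:
    hcfg = cfg["habitat"]
    covs = {
        p.stem.removeprefix("cov_"): Raster.read_asc(p) for p in sorted(outdir.glob("cov_*.asc"))
    }
    if not covs:
        raise FileNotFoundError(f"missing upstream artifacts: {outdir}/cov_*.asc")
    features = habitat.build_features(covs)
    grid = features.grid
    records = pd.read_csv(outdir / "transects.csv")
    sad_species = [p.stem.removeprefix("density_") for p in sorted(outdir.glob("density_*.asc"))]
    info = {}
    for sp in sad_species:
        density = Raster.read_asc(outdir / f"density_{sp}.asc")
        pres = records[(records["species"] == sp) & (records["count"] > 0)]
        if pres.empty:
            # nothing was ever observed: no estimable range, empty mask
            zeros = density.with_values(np.zeros(grid.shape))
            zeros.write_asc(outdir / f"suitability_{sp}.asc")
            zeros.write_asc(outdir / f"mask_{sp}.asc")
            zeros.write_asc(outdir / f"masked_density_{sp}.asc")
            info[sp] = {"n_presence_cells": 0, "suitable_area_km2": 0.0, "masked_out_animals": density.total()}
            continue
        sadlike = transects.estimate_sad(pres, halfwidth_km=float(cfg["density"]["halfwidth_km"]))
        rows, cols = grid.cell_of(sadlike["x"].to_numpy(), sadlike["y"].to_numpy())
        presence_rows = np.unique(rows * grid.ncols + cols)
        model = habitat.fit_maxent(
            presence_rows, features, beta=float(hcfg["beta"]), max_iter=int(hcfg["max_iter"])
        )
        mask = habitat.threshold_range(
            model, presence_rows, percentile=float(hcfg["threshold_percentile"])
        )
        clipped, removed = habitat.mask_density(density, mask)
        model.suitability().write_asc(outdir / f"suitability_{sp}.asc")
        mask.mask.write_asc(outdir / f"mask_{sp}.asc")
        clipped.write_asc(outdir / f"masked_density_{sp}.asc")
        info[sp] = {
            "n_presence_cells": int(len(presence_rows)),
            "threshold": mask.threshold,
            "suitable_area_km2": mask.suitable_area_km2,
            "masked_out_animals": removed,
            "iterations": len(model.objective_trace) - 1,
            "max_normalization_error": model.max_normalization_error,
        }
    _write_stage(outdir, "suitability", {"settings": hcfg, "species": info})


def stage_yield(cfg: dict, outdir: Path) -> None:
    layers = [Raster.read_asc(p) for p in sorted(outdir.glob("ndvi_date_*.asc"))]
    if not layers:
        raise FileNotFoundError(f"missing upstream artifacts: {outdir}/ndvi_date_*.asc")
    ycfg = cfg["yield"]
    params = forage.YieldParams(
        intercept=float(ycfg["intercept"]),
        slope=float(ycfg["slope"]),
        unit=ycfg["unit"],
        clamp_negative=bool(ycfg["clamp_negative"]),
    )
    cap = forage.CapacityParams(**{k: float(v) for k, v in cfg["capacity"].items()})
    composite = forage.max_value_composite(layers)
    yield_raster, n_clamped = forage.ndvi_to_yield(composite, params)
    ctp = forage.theoretical_capacity_per_area(yield_raster, cap, yield_unit=params.unit)
    composite.write_asc(outdir / "ndvi_composite.asc")
    yield_raster.write_asc(outdir / "yield.asc")
    ctp.write_asc(outdir / "ctp.asc")
    total_yield_kg = forage.convert_yield(yield_raster.total(), params.unit, "kg/km^2")
    _write_stage(
        outdir,
        "yield",
        {
            "yield_params": dict(ycfg),
            "capacity_params": dict(cfg["capacity"]),
            "n_layers": len(layers),
            "n_clamped_cells": n_clamped,
            "county_yield_tons": total_yield_kg / 1000.0,
            "county_ctp_su": ctp.total(),
        },
    )


def stage_account(cfg: dict, outdir: Path) -> None:
    parcels = parcels_from_geojson(outdir / "parcels.geojson")
    ctp = Raster.read_asc(outdir / "ctp.asc")
    masked = {
        p.stem.removeprefix("masked_density_"): Raster.read_asc(p)
        for p in sorted(outdir.glob("masked_density_*.asc"))
    }
    livestock = pd.read_csv(outdir / "livestock.csv")
    acc, county = accounting.build_parcel_accounts(
        parcels,
        ctp,
        masked,
        livestock,
        wildlife_conversions=cfg["conversions"]["wildlife"],
        livestock_conversions=cfg["conversions"]["livestock"],
    )
    cols = [c for c in acc.columns if c != "geometry"] if "geometry" in acc else list(acc.columns)
    acc[cols].to_csv(outdir / "parcel_accounts.csv", index=False, float_format="%.6f")
    county.to_frame("value").to_csv(outdir / "county_summary.csv")
    joined = parcels.merge(acc[["parcel_id", "RCC", "overloaded"]], on="parcel_id")
    parcels_to_geojson(joined, outdir / "parcels_rcc.geojson")
    _write_stage(
        outdir,
        "account",
        {
            "county": {k: float(v) for k, v in county.items()},
            "n_parcels": int(len(acc)),
            "empty_parcels": int((acc["C_tp_total"] == 0).sum()),
        },
    )


def stage_report(cfg: dict, outdir: Path) -> dict:
    report = {"software": {"package": "grazecap", "version": __version__}, "config": cfg, "stages": {}}
    for p in sorted(outdir.glob("stage_*.json")):
        report["stages"][p.stem.removeprefix("stage_")] = json.loads(p.read_text())
    (outdir / "report.json").write_text(json.dumps(report, indent=1, default=str))

    lines = [f"grazecap {__version__} run report", "=" * 34, ""]
    acct = report["stages"].get("account")
    if acct:
        lines.append("County summary (sheep units unless noted):")
        for k, v in acct["county"].items():
            lines.append(f"  {k:>12}: {v:,.1f}")
        lines.append("")
    for name, frag in report["stages"].items():
        lines.append(f"[{name}] {json.dumps(frag, default=str)[:400]}")
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")

    rcc_path = outdir / "parcels_rcc.geojson"
    if rcc_path.exists():
        _plot_choropleth(rcc_path, outdir / "rcc_map.png")
    return report


def _plot_choropleth(geojson_path: Path, out_png: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib import cm, colors

    parcels = parcels_from_geojson(geojson_path)
    vals = parcels["RCC"].to_numpy(float)
    vmax = max(abs(vals).max(), 1.0)
    norm = colors.Normalize(vmin=-vmax, vmax=vmax)
    fig, ax = plt.subplots(figsize=(6, 6))
    for _, row in parcels.iterrows():
        geoms = getattr(row["geometry"], "geoms", [row["geometry"]])
        for g in geoms:
            xs, ys = g.exterior.xy
            ax.fill(xs, ys, color=cm.RdYlGn(norm(row["RCC"])), edgecolor="k", linewidth=0.4)
    ax.set_aspect("equal")
    ax.set_title("Residual carrying capacity (sheep units)")
    fig.colorbar(cm.ScalarMappable(norm=norm, cmap="RdYlGn"), ax=ax, shrink=0.7)
    fig.savefig(out_png, dpi=120)
    plt.close(fig)


_STAGE_FUNCS = {
    "generate": stage_generate,
    "density": stage_density,
    "krige": stage_krige,
    "suitability": stage_suitability,
    "yield": stage_yield,
    "account": stage_account,
    "report": stage_report,
}


def run_stage(name: str, cfg: dict, outdir: str | Path):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        return _STAGE_FUNCS[name](cfg, outdir)
    except KeyError:
        raise ValueError(f"unknown stage {name!r}; stages: {STAGES}") from None
    except Exception as e:
        raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e


def run_all(cfg: dict, outdir: str | Path) -> dict:
    """Execute every stage in order; returns the run report dict."""
    report = None
    for name in STAGES:
        report = run_stage(name, cfg, outdir)
    return report


# -------------------------------------------------------- worked example


def worked_example_ledger(
    total_yield_tons: float,
    wildlife_populations: dict[str, float],
    actual_sheep_units: float,
    capacity: forage.CapacityParams = forage.CapacityParams(),
    conversions: dict[str, float] | None = None,
) -> dict[str, float]:
    """County-level ledger computed directly from aggregate totals.

    Feeds a county's total annual grass yield (tonnes), wild ungulate
    population totals (animals) and actual livestock load (sheep units)
    through the capacity equations, bypassing the spatial stages. This is
    how the accounting behaves when the inputs are already county
    aggregates rather than rasters.
    """
    conversions = dict(conversions or accounting.WILDLIFE_SHEEP_UNITS)
    unknown = set(wildlife_populations) - set(conversions)
    if unknown:
        raise ValueError(f"no sheep-unit conversion for species: {sorted(unknown)}")
    c_tp = forage.theoretical_capacity_total(total_yield_tons * 1000.0, capacity)
    c_w = sum(n * conversions[sp] for sp, n in wildlife_populations.items())
    c_t = c_tp - c_w
    rcc = c_t - actual_sheep_units
    return {
        "C_tp": c_tp,
        "C_w": c_w,
        "C_t": c_t,
        "actual": actual_sheep_units,
        "RCC": rcc,
    }
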