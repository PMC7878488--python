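"""Synthetic county generator.

Emulates the study system of a high-plateau rangeland county: ~27
grazing-management parcels tiling a square county, smooth topographic and
climate covariates, two wild ungulate species with distinct latent density
surfaces (a large-bodied equid and a small gazelle), seasonal line-transect
surveys calibrated to mean discovery rates of 1.33 and 0.49 animals per km
per season, a July-August NDVI stack whose composited grass yield is of the
order of a million tonnes county-wide, and a household livestock table with
a 73/24/3 % cattle/sheep/horse sheep-unit mix.

Every generator is a pure function of its configuration and seed, so each
downstream stage can be tested for parameter recovery against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString, MultiPoint, Point, box
from shapely.ops import voronoi_diagram

from .grid import GridSpec, Raster

__all__ = [
    "CountySpec",
    "SpeciesParams",
    "SurveyDesign",
    "LatentSpeciesTruth",
    "County",
    "make_county",
    "make_truth",
    "simulate_surveys",
    "simulate_livestock",
    "make_ndvi_stack",
    "sample_presence_cells",
    "default_species_params",
    "DEFAULT_LIVESTOCK_RATES",
    "DEFAULT_LIVESTOCK_MIX",
    "DEFAULT_TOTAL_SHEEP_UNITS",
]

#: sheep units per head used when synthesising livestock tables
DEFAULT_LIVESTOCK_RATES = {"cattle": 4.5, "sheep": 1.0, "horse": 6.0}
#: sheep-unit shares of the county herd by class
DEFAULT_LIVESTOCK_MIX = {"cattle": 0.73, "sheep": 0.24, "horse": 0.03}
#: county herd size in sheep units
DEFAULT_TOTAL_SHEEP_UNITS = 338_159.0


@dataclass(frozen=True)
class CountySpec:
    """Geometry of the synthetic county."""

    extent: tuple[float, float, float, float] = (0.0, 0.0, 160.0, 160.0)
    cell_size: float = 5.0
    n_parcels: int = 27
    seed: int = 0

    def __post_init__(self) -> None:
        xmin, ymin, xmax, ymax = self.extent
        if not (xmax > xmin and ymax > ymin):
            raise ValueError(f"degenerate extent {self.extent!r}")
        if self.n_parcels < 1:
            raise ValueError("n_parcels must be >= 1")


@dataclass(frozen=True)
class SpeciesParams:
    """Latent truth configuration for one species.

    ``mean_density`` is the county-wide mean (animals/km^2 averaged over
    every cell, suitable or not); the population total is therefore
    mean_density x county area. ``suitability_weights`` act on
    standardised covariates through a logistic link; cells with positive
    linear predictor form the true range.
    """

    species_id: str
    mean_density: float
    suitability_weights: dict[str, float]
    suitability_intercept: float = 0.0
    log_sd: float = 0.6
    correlation_km: float = 15.0

    def __post_init__(self) -> None:
        if self.mean_density < 0:
            raise ValueError("mean_density must be >= 0")


@dataclass(frozen=True)
class SurveyDesign:
    """Line-transect survey design shared by all species.

    The same ``n_lines`` routes are traversed once per season. Counts are
    Poisson with mean = (mean density along the line) x 2 x halfwidth x
    length x detection_prob. Per-season density surfaces are i.i.d.
    multiplicative (mean-one lognormal) perturbations of the truth with
    coefficient of variation ``seasonal_cv``.
    """

    n_lines: int = 250
    seasons: tuple[str, ...] = ("2015", "2016")
    transect_length_km: float = 10.0
    halfwidth_km: float = 0.5
    detection_prob: float = 1.0
    seasonal_cv: float = 0.15

    def __post_init__(self) -> None:
        if self.transect_length_km <= 0 or self.halfwidth_km <= 0:
            raise ValueError("transect length and halfwidth must be positive")
        if not (0.0 <= self.detection_prob <= 1.0):
            raise ValueError("detection_prob must lie in [0, 1]")
        if len(self.seasons) < 1:
            raise ValueError("at least one season required")


@dataclass
class LatentSpeciesTruth:
    """Ground-truth surfaces for one species (for parameter-recovery tests)."""

    species_id: str
    density: Raster  # animals/km^2, zero outside the true range
    suitability_truth: Raster  # binary {0,1}
    suitability_prob: Raster  # logistic probability behind the binary truth

    @property
    def total_population(self) -> float:
        return self.density.total()


@dataclass
class County:
    spec: CountySpec
    grid: GridSpec
    parcels: pd.DataFrame  # columns: parcel_id, geometry, area_km2
    covariates: dict[str, Raster]


# ------------------------------------------------------------------ fields


def _smooth_unit_field(shape: tuple[int, int], rng: np.random.Generator, sigma_cells: float) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian random field via smoothed white noise."""
    white = rng.standard_normal(shape)
    f = gaussian_filter(white, sigma=sigma_cells, mode="wrap")
    sd = f.std()
    if sd < 1e-12:  # pathological tiny grids
        return np.zeros(shape)
    return (f - f.mean()) / sd


def _standardize(values: np.ndarray) -> np.ndarray:
    sd = values.std()
    if sd < 1e-12:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


# ------------------------------------------------------------------ county


def make_county(spec: CountySpec) -> County:
    """Generate parcels and covariate rasters on a shared grid.

    Parcels are the Voronoi cells of ``n_parcels`` random seed points
    clipped to the extent, mimicking irregular grazing-management
    boundaries; they tile the extent exactly.
    """
    grid = GridSpec.from_extent(spec.extent, spec.cell_size)
    rng = np.random.default_rng(spec.seed)

    parcels = _voronoi_parcels(spec, rng)

    shape = grid.shape
    X, Y = grid.center_mesh()
    elev = 4500.0 + 180.0 * _smooth_unit_field(shape, rng, sigma_cells=4.0)
    gy, gx = np.gradient(elev, grid.cell_size)
    slope = np.degrees(np.arctan(np.hypot(gx, gy) / 1000.0))  # elevation m over km
    aspect = np.degrees(np.arctan2(-gx, gy)) % 360.0
    # climate: weak latitudinal trends plus smooth local structure
    ymid = 0.5 * (spec.extent[1] + spec.extent[3])
    yspan = spec.extent[3] - spec.extent[1]
    temp = -3.8 + 2.0 * (Y - ymid) / max(yspan, 1e-9) + 0.8 * _smooth_unit_field(shape, rng, 5.0)
    precip = 304.0 + 60.0 * _smooth_unit_field(shape, rng, 5.0) - 20.0 * (Y - ymid) / max(yspan, 1e-9)

    covs = {
        "elevation": Raster(grid, elev),
        "slope": Raster(grid, slope),
        "aspect": Raster(grid, aspect),
        "temperature": Raster(grid, temp),
        "precipitation": Raster(grid, precip),
    }
    return County(spec=spec, grid=grid, parcels=parcels, covariates=covs)


def _voronoi_parcels(spec: CountySpec, rng: np.random.Generator) -> pd.DataFrame:
    xmin, ymin, xmax, ymax = spec.extent
    extent_poly = box(xmin, ymin, xmax, ymax)
    if spec.n_parcels == 1:
        geoms = [extent_poly]
    else:
        pts = np.column_stack(
            [rng.uniform(xmin, xmax, spec.n_parcels), rng.uniform(ymin, ymax, spec.n_parcels)]
        )
        cells = voronoi_diagram(MultiPoint([Point(p) for p in pts]), envelope=extent_poly)
        clipped = [g.intersection(extent_poly) for g in cells.geoms]
        # voronoi_diagram does not preserve input order: match cell -> seed point
        geoms = [None] * spec.n_parcels
        for g in clipped:
            if g.is_empty:
                continue
            for i, p in enumerate(pts):
                if geoms[i] is None and g.covers(Point(p)):
                    geoms[i] = g
                    break
        if any(g is None for g in geoms):  # coincident seeds etc.
            raise ValueError("Voronoi partition failed to produce one cell per seed; try another seed")
    return pd.DataFrame(
        {
            "parcel_id": np.arange(1, len(geoms) + 1),
            "geometry": geoms,
            "area_km2": [g.area for g in geoms],
        }
    )


# ------------------------------------------------------------------ truth


def default_species_params(design: SurveyDesign | None = None) -> list[SpeciesParams]:
    """The two default species, calibrated to the target discovery rates.

    A discovery rate r (animals/km/season) over transects placed uniformly
    in the county corresponds to a county-mean density of
    r / (2 x halfwidth x detection_prob).
    """
    design = design or SurveyDesign()
    denom = 2.0 * design.halfwidth_km * design.detection_prob
    return [
        SpeciesParams(
            species_id="kiang",
            mean_density=1.33 / denom,
            suitability_weights={"elevation": -1.1, "precipitation": 0.8},
            suitability_intercept=0.25,
        ),
        SpeciesParams(
            species_id="gazelle",
            mean_density=0.49 / denom,
            suitability_weights={"elevation": 0.9, "temperature": 0.7},
            suitability_intercept=-0.15,
            log_sd=0.7,
        ),
    ]


def make_truth(
    grid: GridSpec,
    covariates: dict[str, Raster],
    params: SpeciesParams,
    seed: int,
) -> LatentSpeciesTruth:
    """Latent density and suitability truth for one species.

    Suitability is a logistic function of standardised covariates,
    binarised at probability 0.5; density is a log-Gaussian field on the
    suitable cells, scaled so the county-mean density matches the
    configuration exactly.
    """
    for name, r in covariates.items():
        if r.spec != grid:
            raise ValueError(f"covariate {name!r} is not on the shared grid")
    rng = np.random.default_rng(seed)

    eta = np.full(grid.shape, params.suitability_intercept, dtype=float)
    for name, w in params.suitability_weights.items():
        if name not in covariates:
            raise ValueError(f"unknown covariate {name!r} in suitability weights")
        eta += w * _standardize(covariates[name].values)
    prob = 1.0 / (1.0 + np.exp(-eta))
    suitable = (eta > 0).astype(float)

    sigma_cells = max(params.correlation_km / grid.cell_size, 0.5)
    base = np.exp(params.log_sd * _smooth_unit_field(grid.shape, rng, sigma_cells))
    density = base * suitable
    mean_now = density.mean()
    if mean_now > 0 and params.mean_density > 0:
        density *= params.mean_density / mean_now
    else:
        density = np.zeros(grid.shape)

    return LatentSpeciesTruth(
        species_id=params.species_id,
        density=Raster(grid, density),
        suitability_truth=Raster(grid, suitable),
        suitability_prob=Raster(grid, prob),
    )


# ------------------------------------------------------------------ surveys


def _place_lines(grid: GridSpec, design: SurveyDesign, rng: np.random.Generator) -> list[LineString]:
    """Random transect routes: uniform midpoints, uniform orientation, clipped.

    Midpoints are drawn from the extent buffered by half the transect
    length; after clipping, the survey effort per unit area is uniform over
    the county (no edge under-coverage), so the expected discovery rate is
    the county-mean density times the effective strip width.
    """
    xmin, ymin, xmax, ymax = grid.extent
    extent_poly = box(xmin, ymin, xmax, ymax)
    half = design.transect_length_km / 2.0
    lines = []
    while len(lines) < design.n_lines:
        cx = rng.uniform(xmin - half, xmax + half)
        cy = rng.uniform(ymin - half, ymax + half)
        theta = rng.uniform(0, np.pi)
        dx, dy = half * np.cos(theta), half * np.sin(theta)
        seg = LineString([(cx - dx, cy - dy), (cx + dx, cy + dy)]).intersection(extent_poly)
        if seg.is_empty or seg.geom_type != "LineString" or seg.length < 1e-6:
            continue
        lines.append(seg)
    return lines


def _line_mean_density(density: Raster, line: LineString, step_km: float = 0.25) -> float:
    n = max(int(np.ceil(line.length / step_km)), 2)
    ts = (np.arange(n) + 0.5) / n
    pts = [line.interpolate(float(t), normalized=True) for t in ts]
    xs = np.array([p.x for p in pts])
    ys = np.array([p.y for p in pts])
    vals = density.sample_nearest(xs, ys)
    return float(np.nanmean(vals))


def simulate_surveys(
    truths: LatentSpeciesTruth | list[LatentSpeciesTruth],
    design: SurveyDesign,
    seed: int,
) -> pd.DataFrame:
    """Simulate seasonal strip-transect surveys over shared routes.

    Returns the transect-record table with columns
    ``transect_id, species, season, count, length_km, wkt_geometry``.
    """
    if isinstance(truths, LatentSpeciesTruth):
        truths = [truths]
    if not truths:
        raise ValueError("at least one species truth required")
    grid = truths[0].density.spec
    rng = np.random.default_rng(seed)
    lines = _place_lines(grid, design, rng)

    strip = 2.0 * design.halfwidth_km * design.detection_prob
    rows = []
    for truth in truths:
        line_means = np.array([_line_mean_density(truth.density, ln) for ln in lines])
        for season in design.seasons:
            if design.seasonal_cv > 0:
                sigma = np.sqrt(np.log1p(design.seasonal_cv**2))
                field = _smooth_unit_field(grid.shape, rng, 3.0)
                seasonal = Raster(grid, truth.density.values * np.exp(sigma * field - sigma**2 / 2.0))
                means = np.array([_line_mean_density(seasonal, ln) for ln in lines])
            else:
                means = line_means
            lengths = np.array([ln.length for ln in lines])
            lam = means * strip * lengths
            counts = rng.poisson(np.nan_to_num(lam, nan=0.0))
            for i, ln in enumerate(lines):
                rows.append(
                    {
                        "transect_id": f"T{i + 1:04d}",
                        "species": truth.species_id,
                        "season": season,
                        "count": int(counts[i]),
                        "length_km": float(lengths[i]),
                        "wkt_geometry": ln.wkt,
                    }
                )
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ livestock


def simulate_livestock(
    parcels: pd.DataFrame,
    mix: dict[str, float] | None = None,
    total_sheep_units: float = DEFAULT_TOTAL_SHEEP_UNITS,
    seed: int = 0,
    rates: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-parcel head counts whose sheep-unit total matches the configured county herd.

    Sheep units are allocated across parcels proportionally to area with
    random gamma weights; cattle and horse head counts are rounded, and
    the sheep count (1 SU/head) absorbs the residual so each parcel's
    sheep-unit total is within 0.5 SU of its allocation.
    """
    mix = dict(mix or DEFAULT_LIVESTOCK_MIX)
    rates = dict(rates or DEFAULT_LIVESTOCK_RATES)
    if total_sheep_units < 0:
        raise ValueError("total_sheep_units must be >= 0")
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("mix fractions must sum to 1")
    rng = np.random.default_rng(seed)

    w = parcels["area_km2"].to_numpy() * rng.gamma(4.0, 1.0, len(parcels))
    su = total_sheep_units * w / w.sum()

    rows = []
    for pid, su_p in zip(parcels["parcel_id"], su):
        cattle = int(round(mix.get("cattle", 0.0) * su_p / rates["cattle"]))
        horse = int(round(mix.get("horse", 0.0) * su_p / rates["horse"]))
        sheep = int(round(su_p - cattle * rates["cattle"] - horse * rates["horse"]))
        sheep = max(sheep, 0)
        rows.append({"parcel_id": int(pid), "cattle": cattle, "sheep": sheep, "horse": horse})
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ NDVI


def make_ndvi_stack(
    county: County,
    n_dates: int = 4,
    seed: int = 0,
    mean_ndvi: float = 0.22,
    sd_ndvi: float = 0.06,
    cloud_prob: float = 0.5,
) -> tuple[list[Raster], list[str]]:
    """Peak-season NDVI time stack with cloud-like negative artefacts.

    The clean greenness field tracks precipitation plus its own smooth
    structure; each date is the clean field degraded by random
    multiplicative cloud dips, so the maximal-value composite recovers
    (approximately) the clean field. Default levels put the composited
    county grass yield near 1.3 million tonnes.
    """
    rng = np.random.default_rng(seed)
    grid = county.grid
    pz = _standardize(county.covariates["precipitation"].values)
    clean = mean_ndvi + sd_ndvi * (0.6 * pz + 0.8 * _smooth_unit_field(grid.shape, rng, 4.0))
    clean = np.clip(clean, 0.02, 0.9)

    layers, labels = [], []
    for d in range(n_dates):
        clouded = rng.random(grid.shape) < cloud_prob
        dip = rng.uniform(0.2, 0.8, grid.shape)
        vals = np.where(clouded, clean * dip, clean)
        layers.append(Raster(grid, vals))
        labels.append(f"date_{d + 1}")
    return layers, labels


# ------------------------------------------------------------------ helpers


def sample_presence_cells(weights: Raster, n: int, seed: int) -> pd.DataFrame:
    """Sample cell-centre presence points with probability proportional to ``weights``."""
    rng = np.random.default_rng(seed)
    w = np.clip(weights.filled(0.0), 0.0, None).ravel()
    if w.sum() <= 0:
        raise ValueError("weights raster has no positive mass")
    idx = rng.choice(w.size, size=n, replace=True, p=w / w.sum())
    rows, cols = np.unravel_index(idx, weights.spec.shape)
    X, Y = weights.spec.center_mesh()
    return pd.DataFrame({"x": X[rows, cols], "y": Y[rows, cols]})
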