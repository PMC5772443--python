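"""Self-contained synthetic study system with known ground truth.

Emulates, at desk scale, the ingredients of a basin-wide tree-species study:
smooth gridded climate fields (two pairs deliberately collinear so the
screening step has work to do), a six-region partition, a forest mask with
non-forested "savanna" blobs, species with Gaussian environmental niches
multiplied by dispersal kernels around population centers, ~1-ha plot censuses
whose stem counts are multinomial draws from the local true relative
abundances, and herbarium-style collection records whose spatial intensity
follows an accessibility field (distance decay around synthetic river/road
polylines) times RA^gamma with gamma < 1, over-representing areas of low
abundance the way collectors do.

Georeferencing errors are then injected at configured rates — missing
coordinates, exact zeros, latitude equal to longitude, capital and
province-centroid assignments, within-cell duplicates, and misidentifications
(a record relabelled to a species whose range excludes it). Every record
carries its injected-error label, giving each cleaning stage an exact
acceptance surface. The generator keeps clean records of one species in
distinct grid cells and keeps gazetteer points away from record jitter, so
the deterministic cleaning rules can be held to perfect recall and zero false
positives against the labels.

Everything is a deterministic function of the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .grid import (GridSpec, RasterLayer, RegionPartition, cell_centers,
                   write_raster, write_region_raster)
from .cleaning import Gazetteer

__all__ = ["SyntheticConfig", "SpeciesTruth", "SyntheticWorld",
           "generate_world", "write_world"]

ENV_NAMES = [
    "isothermality",
    "temp_seasonality",
    "max_temp_warmest",
    "annual_precip",
    "precip_wettest",
    "precip_driest",
]

ERROR_LABELS = ["missing_coord", "zero_coord", "lat_eq_lon", "capital_assign",
                "centroid_assign", "duplicate", "misidentification"]
CLEAN_LABEL = "clean"


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study system (defaults = study conditions)."""

    grid: GridSpec = field(default_factory=lambda: GridSpec(
        west=-80.0, south=-20.0, cell_size=0.5, n_cols=60, n_rows=60))
    n_env: int = 6
    n_species: int = 15
    n_plots: int = 400
    stems_per_plot_mean: int = 550
    records_per_species: int = 120
    ra_max: float = 0.05  # cell-max true relative abundance per species
    collector_bias_exponent: float = 0.5  # gamma < 1: rare areas over-collected
    error_rates: dict = field(default_factory=lambda: {
        "missing_coord": 0.10,
        "zero_coord": 0.02,
        "lat_eq_lon": 0.02,
        "capital_assign": 0.04,
        "centroid_assign": 0.04,
        "duplicate": 0.15,
        "misidentification": 0.03,
    })
    n_capitals: int = 8
    n_centroids: int = 12
    nonforest_fraction: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        for k, v in self.error_rates.items():
            if not (0 <= v < 0.5):
                raise ValueError(f"error rate {k}={v} must be in [0, 0.5)")
        if sum(self.error_rates.values()) >= 1:
            raise ValueError("error rates must sum to < 1")
        if self.n_species * self.ra_max > 1:
            raise ValueError("n_species * ra_max must be <= 1 "
                             "(relative abundances share each cell)")


@dataclass
class SpeciesTruth:
    """Ground-truth surfaces and parameters of one synthetic species."""

    name: str
    true_suitability: RasterLayer  # in [0, 1]
    true_ra: RasterLayer  # in [0, ra_max], 0 outside the dispersal envelope
    niche: dict  # env layer name -> (center, width)
    population_centers: np.ndarray  # (k, 2) lon/lat
    narrow: bool


@dataclass
class SyntheticWorld:
    config: SyntheticConfig
    env: dict  # name -> RasterLayer
    regions: RegionPartition
    forest_mask: np.ndarray  # True = forested
    species: list  # of SpeciesTruth
    plots: pd.DataFrame
    records: pd.DataFrame  # incl. truth_label column
    gazetteer: Gazetteer

    @property
    def grid(self) -> GridSpec:
        return self.config.grid

    def env_matrix(self) -> np.ndarray:
        """(n_valid_cells, n_env) values over forested cells, fixed order."""
        return np.column_stack(
            [self.env[n].values[self.forest_mask] for n in self.env]
        )


def _smooth_field(shape, rng, sigma) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma,
                        mode="reflect")
    return f


def _rescale01(f: np.ndarray) -> np.ndarray:
    lo, hi = f.min(), f.max()
    if hi == lo:
        return np.zeros_like(f)
    return (f - lo) / (hi - lo)


def gen_env_stack(config: SyntheticConfig, rng) -> dict:
    """Low-order trend + smoothed noise per layer, rescaled to [0, 1].

    Layers 1 and 4 are built as noisy copies of layers 0 and 3, giving two
    pairs with |Spearman rho| > 0.7 for the collinearity screen to find.
    """
    g = config.grid
    lon, lat = cell_centers(g)
    lon01 = _rescale01(lon)
    lat01 = _rescale01(lat)
    layers: list[np.ndarray] = []
    for j in range(config.n_env):
        if j == 1 or j == 4:
            base = layers[j - 1] + 0.08 * _smooth_field(g.shape, rng, 2.0)
        else:
            a, b, c = rng.uniform(-1, 1, size=3)
            trend = a * lon01 + b * lat01 + c * lon01 * lat01
            base = trend + 0.6 * _smooth_field(g.shape, rng, 4.0)
        layers.append(_rescale01(base))
    names = (ENV_NAMES * ((config.n_env // len(ENV_NAMES)) + 1))[:config.n_env]
    names = [n if names.count(n) == 1 else f"{n}_{i}"
             for i, n in enumerate(names)]
    return {name: RasterLayer(g, vals) for name, vals in zip(names, layers)}


def gen_regions(config: SyntheticConfig) -> RegionPartition:
    """Six rectangular regions: a 3 x 2 block partition of the grid."""
    g = config.grid
    rows = np.arange(g.n_rows)[:, None] * 2 // g.n_rows  # 0..1 south/north
    cols = np.arange(g.n_cols)[None, :] * 3 // g.n_cols  # 0..2 west/east
    region = (rows * 3 + cols + 1) * np.ones(g.shape, dtype=int)
    return RegionPartition(g, region)


def gen_forest_mask(config: SyntheticConfig, rng) -> np.ndarray:
    """All forest except smoothed-noise blobs covering ~nonforest_fraction."""
    f = _smooth_field(config.grid.shape, rng, 3.0)
    cut = np.quantile(f, 1.0 - config.nonforest_fraction)
    return f < cut


def gen_species_truth(env: dict, regions: RegionPartition,
                      forest_mask: np.ndarray, config: SyntheticConfig,
                      species_index: int, rng) -> SpeciesTruth:
    """Gaussian niche on 1-2 env layers times a dispersal kernel.

    Narrow species (every third) get one population center and a tight
    kernel, confining them to few regions; the rest get 2-3 centers and a
    broad kernel. The kernel is truncated at 4 sigma so true RA is exactly
    zero outside the dispersal envelope.
    """
    g = config.grid
    names = list(env)
    n_niche = int(rng.integers(1, 3))
    niche_on = list(rng.choice(names, size=n_niche, replace=False))
    niche = {}
    suit = np.ones(g.shape)
    for name in niche_on:
        center = float(rng.uniform(0.25, 0.75))
        width = float(rng.uniform(0.15, 0.30))
        niche[name] = (center, width)
        suit *= np.exp(-0.5 * ((env[name].values - center) / width) ** 2)
    suit = _rescale01(suit)

    narrow = species_index % 3 == 0
    n_centers = 1 if narrow else int(rng.integers(2, 4))
    sigma = float(rng.uniform(1.5, 2.5)) if narrow else float(
        rng.uniform(4.0, 7.0))
    # centers drawn among forested cells with decent suitability
    lonc, latc = cell_centers(g)
    good = forest_mask & (suit > np.quantile(suit[forest_mask], 0.7))
    cand = np.flatnonzero(good.ravel())
    if cand.size == 0:
        cand = np.flatnonzero(forest_mask.ravel())
    picks = rng.choice(cand, size=n_centers, replace=False)
    centers = np.column_stack([lonc.ravel()[picks], latc.ravel()[picks]])

    def envelope(radius: float) -> np.ndarray:
        disp = np.zeros(g.shape)
        for cx, cy in centers:
            d2 = (lonc - cx) ** 2 + (latc - cy) ** 2
            kern = np.exp(-0.5 * d2 / sigma**2)
            kern[d2 > radius**2] = 0.0  # hard dispersal envelope
            disp = np.maximum(disp, kern)
        return disp

    radius = 4.0 * sigma
    ra = suit * envelope(radius)
    ra[~forest_mask] = 0.0
    if narrow:
        # a narrow endemic stays within at most 3 of the 6 regions: shrink
        # the dispersal envelope until the occupied-region count complies
        while radius > g.cell_size:
            occupied = np.unique(regions.region_id[ra > 0])
            if occupied[occupied > 0].size <= 3:
                break
            radius *= 0.8
            ra = suit * envelope(radius)
            ra[~forest_mask] = 0.0
    if ra.max() > 0:
        ra = ra * (config.ra_max / ra.max())
    return SpeciesTruth(
        name=f"species{species_index:02d}",
        true_suitability=RasterLayer(g, suit, forest_mask.copy()),
        true_ra=RasterLayer(g, ra, forest_mask.copy()),
        niche=niche,
        population_centers=centers,
        narrow=narrow,
    )


def gen_plots(species: list, forest_mask: np.ndarray,
              config: SyntheticConfig, rng) -> pd.DataFrame:
    """Plot censuses: multinomial stem counts from local true RA.

    Plots land uniformly on forested cells (several plots may share a cell),
    jittered within the cell; total stems N ~ 1 + Poisson(mean - 1); stems
    split multinomially over species RA at the plot's cell with the residual
    mass as "other" species.
    """
    g = config.grid
    cells = np.flatnonzero(forest_mask.ravel())
    picks = rng.choice(cells, size=config.n_plots, replace=True)
    rows, cols = np.unravel_index(picks, g.shape)
    jitter = rng.uniform(0.25, 0.75, size=(config.n_plots, 2))
    lon = g.west + (cols + jitter[:, 0]) * g.cell_size
    lat = g.south + (rows + jitter[:, 1]) * g.cell_size
    n_total = 1 + rng.poisson(config.stems_per_plot_mean - 1,
                              size=config.n_plots)

    ra_stack = np.stack([sp.true_ra.values for sp in species])  # (S, R, C)
    probs = ra_stack[:, rows, cols].T  # (n_plots, S)
    other = 1.0 - probs.sum(axis=1)
    table = {"plot_id": [f"plot{i:04d}" for i in range(config.n_plots)],
             "lon": lon, "lat": lat, "N_total": n_total}
    counts = np.empty((config.n_plots, len(species)), dtype=int)
    for i in range(config.n_plots):
        p = np.append(probs[i], max(other[i], 0.0))
        s = p.sum()
        if s <= 0:
            counts[i] = 0  # zero-probability cell: all stems are "other"
            continue
        draw = rng.multinomial(n_total[i], p / s)
        counts[i] = draw[:-1]
    for j, sp in enumerate(species):
        table[sp.name] = counts[:, j]
    return pd.DataFrame(table)


def _accessibility(config: SyntheticConfig, rng) -> np.ndarray:
    """Distance-decay field around random polylines (rivers/roads)."""
    g = config.grid
    lonc, latc = cell_centers(g)
    pts = []
    for _ in range(3):
        k = int(rng.integers(3, 6))
        verts = np.column_stack([
            rng.uniform(g.west, g.east, size=k),
            rng.uniform(g.south, g.north, size=k),
        ])
        for a, b in zip(verts[:-1], verts[1:]):
            t = np.linspace(0, 1, 60)[:, None]
            pts.append(a + t * (b - a))
    tree = cKDTree(np.vstack(pts))
    d, _ = tree.query(np.column_stack([lonc.ravel(), latc.ravel()]))
    access = np.exp(-d / 1.5) + 0.02
    return access.reshape(g.shape)


def gen_gazetteer(config: SyntheticConfig, rng) -> Gazetteer:
    """Capitals and province centroids placed near cell corners.

    Records are jittered into the central half of their cell, so a 0.05-degree
    snap tolerance can never catch a genuine record.
    """
    g = config.grid

    def corner_points(n):
        rows = rng.integers(0, g.n_rows, size=n)
        cols = rng.integers(0, g.n_cols, size=n)
        lon = g.west + (cols + 0.05) * g.cell_size
        lat = g.south + (rows + 0.05) * g.cell_size
        return pd.DataFrame({"lon": lon, "lat": lat})

    caps = corner_points(config.n_capitals)
    caps["name"] = [f"capital{i}" for i in range(len(caps))]
    cents = corner_points(config.n_centroids)
    cents["name"] = [f"province{i}" for i in range(len(cents))]
    return Gazetteer(capitals=caps, centroids=cents)


def collection_intensity(ra: np.ndarray, access: np.ndarray, gamma: float,
                         forest_mask: np.ndarray) -> np.ndarray:
    """Per-cell collecting intensity: accessibility x RA^gamma on the range.

    gamma < 1 flattens the abundance signal, over-representing areas of low
    relative abundance the way herbarium collecting does; gamma = 1 with flat
    accessibility makes intensity exactly proportional to RA.
    """
    intensity = access * np.where(ra > 0, ra, 0.0) ** gamma
    intensity = np.where(forest_mask & (ra > 0), intensity, 0.0)
    return intensity


def gen_collections(species: list, forest_mask: np.ndarray,
                    gazetteer: Gazetteer, config: SyntheticConfig,
                    rng) -> pd.DataFrame:
    """Biased collection records with labelled injected errors.

    Per species, base records sample distinct cells with probability
    proportional to accessibility x RA^gamma (gamma < 1). Error injection then
    corrupts a configured fraction, each record keeping its ``truth_label``.
    """
    g = config.grid
    access = _accessibility(config, rng)
    ra_stack = np.stack([sp.true_ra.values for sp in species])

    rows_out: list[dict] = []
    rid = 0

    def new_record(sp_name, lon, lat, label):
        nonlocal rid
        rec = {
            "record_id": f"rec{rid:06d}",
            "species": sp_name,
            "decimalLongitude": lon,
            "decimalLatitude": lat,
            "locality": f"locality-{rid}",
            "countryCode": "SY",
            "truth_label": label,
        }
        rid += 1
        rows_out.append(rec)
        return rec

    rates = config.error_rates
    labels, cum = list(rates), np.cumsum([rates[k] for k in rates])

    for s_idx, sp in enumerate(species):
        ra = sp.true_ra.values
        intensity = collection_intensity(
            ra, access, config.collector_bias_exponent, forest_mask)
        flat = intensity.ravel()
        positive = np.flatnonzero(flat > 0)
        if positive.size == 0:
            continue
        n_rec = min(config.records_per_species, positive.size)
        p = flat[positive] / flat[positive].sum()
        picks = rng.choice(positive, size=n_rec, replace=False,
                           p=p)  # distinct cells: clean records never collide
        prow, pcol = np.unravel_index(picks, g.shape)
        jit = rng.uniform(0.25, 0.75, size=(n_rec, 2))
        lons = g.west + (pcol + jit[:, 0]) * g.cell_size
        lats = g.south + (prow + jit[:, 1]) * g.cell_size

        u = rng.uniform(size=n_rec)
        base_records = []
        for i in range(n_rec):
            j = int(np.searchsorted(cum, u[i]))
            label = labels[j] if j < len(labels) else CLEAN_LABEL
            lon, lat = float(lons[i]), float(lats[i])
            if label == "missing_coord":
                new_record(sp.name, np.nan, np.nan, label)
            elif label == "zero_coord":
                new_record(sp.name, 0.0, 0.0, label)
            elif label == "lat_eq_lon":
                new_record(sp.name, lat, lat, label)
            elif label == "capital_assign":
                cap = gazetteer.capitals.iloc[
                    int(rng.integers(len(gazetteer.capitals)))]
                new_record(sp.name, float(cap["lon"]), float(cap["lat"]),
                           label)
            elif label == "centroid_assign":
                cen = gazetteer.centroids.iloc[
                    int(rng.integers(len(gazetteer.centroids)))]
                new_record(sp.name, float(cen["lon"]), float(cen["lat"]),
                           label)
            elif label == "misidentification":
                # relabel to a species whose range excludes this cell
                r, c = prow[i], pcol[i]
                others = [t.name for k, t in enumerate(species)
                          if k != s_idx and t.true_ra.values[r, c] <= 0]
                if others:
                    tgt = others[int(rng.integers(len(others)))]
                    new_record(tgt, lon, lat, label)
                else:  # no excluding species at this cell: keep clean
                    base_records.append(new_record(sp.name, lon, lat,
                                                   CLEAN_LABEL))
            elif label == "duplicate":
                base_records.append(("dup", lon, lat))
            else:
                base_records.append(new_record(sp.name, lon, lat,
                                               CLEAN_LABEL))

        clean_recs = [r for r in base_records if isinstance(r, dict)]
        for item in base_records:
            if isinstance(item, dict):
                continue
            # duplicate an existing clean record: same cell, new jitter
            if not clean_recs:
                continue
            src = clean_recs[int(rng.integers(len(clean_recs)))]
            slon, slat = src["decimalLongitude"], src["decimalLatitude"]
            ccol = int(np.floor((slon - g.west) / g.cell_size))
            crow = int(np.floor((slat - g.south) / g.cell_size))
            jit2 = rng.uniform(0.25, 0.75, size=2)
            dlon = g.west + (ccol + jit2[0]) * g.cell_size
            dlat = g.south + (crow + jit2[1]) * g.cell_size
            new_record(src["species"], float(dlon), float(dlat), "duplicate")

    return pd.DataFrame(rows_out)


def generate_world(config: SyntheticConfig | None = None,
                   seed: int | None = None) -> SyntheticWorld:
    """Generate the full synthetic study system; determined by the seed."""
    config = config or SyntheticConfig()
    if seed is not None:
        config = SyntheticConfig(**{**config.__dict__, "seed": seed})
    ss = np.random.SeedSequence(config.seed)
    r_env, r_forest, r_species, r_plots, r_gaz, r_coll = (
        np.random.default_rng(s) for s in ss.spawn(6))

    env = gen_env_stack(config, r_env)
    regions = gen_regions(config)
    forest = gen_forest_mask(config, r_forest)
    species = [
        gen_species_truth(env, regions, forest, config, i, r_species)
        for i in range(config.n_species)
    ]
    plots = gen_plots(species, forest, config, r_plots)
    gaz = gen_gazetteer(config, r_gaz)
    records = gen_collections(species, forest, gaz, config, r_coll)
    return SyntheticWorld(config=config, env=env, regions=regions,
                          forest_mask=forest, species=species, plots=plots,
                          records=records, gazetteer=gaz)


def write_world(world: SyntheticWorld, outdir) -> None:
    """Write occurrence/plot CSVs, rasters, gazetteer, and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    world.records.to_csv(outdir / "occurrences.csv", index=False)
    world.plots.to_csv(outdir / "plots.csv", index=False)
    (outdir / "env").mkdir(exist_ok=True)
    for name, layer in world.env.items():
        write_raster(layer, outdir / "env" / f"{name}.asc")
    write_region_raster(world.regions, outdir / "regions.asc")
    write_raster(RasterLayer(world.grid,
                             world.forest_mask.astype(float)),
                 outdir / "forest_mask.asc")
    (outdir / "truth").mkdir(exist_ok=True)
    for sp in world.species:
        write_raster(sp.true_ra, outdir / "truth" / f"{sp.name}_ra.asc")
        write_raster(sp.true_suitability,
                     outdir / "truth" / f"{sp.name}_suitability.asc")
    world.gazetteer.capitals.to_csv(outdir / "capitals.csv", index=False)
    world.gazetteer.centroids.to_csv(outdir / "centroids.csv", index=False)
    cfg = {**world.config.__dict__}
    cfg["grid"] = world.grid.__dict__
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)
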