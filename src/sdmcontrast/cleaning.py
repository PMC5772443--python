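"""Two-step occurrence-record cleaning pipeline.

Step 1 is deterministic geo-validation and grid-resolution deduplication:
records missing longitude, latitude or locality text, records with latitude
exactly equal to longitude, records at exactly (0, 0), records snapped to
capital cities or province centroids from a gazetteer, and records landing
outside their stated country are removed; the survivors are deduplicated to
one record per (species, 0.5-degree cell). Step 2 removes spatial outliers by
ranking each record's fixed-bandwidth Gaussian kernel-density estimate and
cutting below an empirical quantile. The quantile is larger for species
occurring in one to three of the six Amazonian regions (narrow) than for
species spread over more than three (wide), so widely distributed species do
not lose whole peripheral occurrence clusters.

Every removed record carries exactly one reason code — the first triggering
rule in a fixed precedence order — and the per-stage counts reconcile with the
input size, so the cleaning report can be audited record by record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .grid import GridSpec, RegionPartition

__all__ = [
    "Gazetteer",
    "KdeConfig",
    "CleaningReport",
    "validate_records",
    "dedupe_to_cells",
    "kde_density",
    "kde_outlier_filter",
    "clean_pipeline",
    "OccurrenceCleaner",
]

# precedence order of the deterministic reason codes
MISSING_GEO = "MISSING_GEO"
LAT_EQ_LON = "LAT_EQ_LON"
ZERO_COORD = "ZERO_COORD"
CAPITAL = "CAPITAL"
PROVINCE_CENTROID = "PROVINCE_CENTROID"
COUNTRY_MISMATCH = "COUNTRY_MISMATCH"
DUPLICATE_CELL = "DUPLICATE_CELL"
KDE_OUTLIER = "KDE_OUTLIER"
KEPT = "kept"

LON = "decimalLongitude"
LAT = "decimalLatitude"


@dataclass
class Gazetteer:
    """Reference tables used by the geo-validation step.

    ``capitals`` and ``centroids`` are DataFrames with lon/lat columns;
    ``country_polygons`` optionally maps a country code to a shapely geometry
    (records outside their stated country are flagged only when supplied).
    """

    capitals: pd.DataFrame | None = None
    centroids: pd.DataFrame | None = None
    country_polygons: dict | None = None


@dataclass
class KdeConfig:
    """Spatial-outlier filter settings.

    bandwidth: Gaussian kernel bandwidth in degrees (~2 grid cells).
    quantile_narrow / quantile_wide: density quantile removed for species in
    at most 3 regions vs more than 3; narrow >= wide so restricted species
    are cleaned more aggressively.
    """

    bandwidth: float = 1.0
    quantile_narrow: float = 0.05
    quantile_wide: float = 0.01

    def __post_init__(self) -> None:
        for q in (self.quantile_narrow, self.quantile_wide):
            if not (0 < q < 0.5):
                raise ValueError("quantiles must lie in (0, 0.5)")
        if self.quantile_narrow < self.quantile_wide:
            raise ValueError("quantile_narrow must be >= quantile_wide")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")


@dataclass
class CleaningReport:
    """Per-record dispositions plus per-stage removal counts."""

    dispositions: pd.Series  # index = record_id, value = KEPT or reason code
    stage_counts: dict = field(default_factory=dict)

    @property
    def n_input(self) -> int:
        return int(len(self.dispositions))

    @property
    def n_removed(self) -> int:
        return int((self.dispositions != KEPT).sum())

    @property
    def fraction_removed(self) -> float:
        return self.n_removed / self.n_input if self.n_input else 0.0

    def counts(self) -> dict:
        out = self.dispositions.value_counts().to_dict()
        out.setdefault(KEPT, 0)
        return out

    def to_frame(self) -> pd.DataFrame:
        return self.dispositions.rename("disposition").reset_index()


def _missing(series: pd.Series) -> np.ndarray:
    vals = series
    na = vals.isna().to_numpy()
    if vals.dtype == object:
        na |= vals.astype(str).str.strip().eq("").to_numpy()
    return na


def validate_records(records: pd.DataFrame, gazetteer: Gazetteer | None = None,
                     tolerance: float = 0.05) -> pd.Series:
    """Deterministic geo-validation; returns a disposition per record_id.

    Rules fire in fixed precedence: MISSING_GEO (lon, lat or locality absent)
    -> LAT_EQ_LON (exact, nonzero) -> ZERO_COORD (both exactly 0) -> CAPITAL /
    PROVINCE_CENTROID (within ``tolerance`` degrees of a gazetteer point) ->
    COUNTRY_MISMATCH (outside stated country polygon, when polygons exist).
    """
    idx = records["record_id"]
    reason = pd.Series(KEPT, index=pd.Index(idx, name="record_id"), dtype=object)

    lon = pd.to_numeric(records[LON], errors="coerce").to_numpy()
    lat = pd.to_numeric(records[LAT], errors="coerce").to_numpy()
    missing = ~np.isfinite(lon) | ~np.isfinite(lat)
    if "locality" in records.columns:
        missing |= _missing(records["locality"])
    open_ = ~missing
    reason.iloc[np.flatnonzero(missing)] = MISSING_GEO

    lat_eq_lon = open_ & (lat == lon) & (lat != 0)
    reason.iloc[np.flatnonzero(lat_eq_lon)] = LAT_EQ_LON
    open_ &= ~lat_eq_lon

    zero = open_ & (lat == 0) & (lon == 0)
    reason.iloc[np.flatnonzero(zero)] = ZERO_COORD
    open_ &= ~zero

    if gazetteer is None or (gazetteer.capitals is None
                             and gazetteer.centroids is None):
        warnings.warn("no gazetteer supplied: capital/centroid checks skipped")
    else:
        for table, code in ((gazetteer.capitals, CAPITAL),
                            (gazetteer.centroids, PROVINCE_CENTROID)):
            if table is None or len(table) == 0 or not open_.any():
                continue
            pts = np.column_stack([lon[open_], lat[open_]])
            ref = table[["lon", "lat"]].to_numpy(dtype=float)
            near = (cdist(pts, ref) <= tolerance).any(axis=1)
            hit = np.flatnonzero(open_)[near]
            reason.iloc[hit] = code
            open_[hit] = False

    if (gazetteer is not None and gazetteer.country_polygons
            and "countryCode" in records.columns and open_.any()):
        from shapely.geometry import Point

        codes = records["countryCode"].to_numpy()
        for i in np.flatnonzero(open_):
            poly = gazetteer.country_polygons.get(codes[i])
            if poly is not None and not poly.covers(Point(lon[i], lat[i])):
                reason.iloc[i] = COUNTRY_MISMATCH
    return reason


def dedupe_to_cells(records: pd.DataFrame, grid: GridSpec) -> pd.Series:
    """One record per (species, 0.5-degree cell); lowest record_id wins.

    Cell indices come from the grid's half-open convention but are not
    clipped to its extent, so off-grid records also deduplicate at the same
    resolution.
    """
    lon = pd.to_numeric(records[LON], errors="coerce").to_numpy()
    lat = pd.to_numeric(records[LAT], errors="coerce").to_numpy()
    col = np.floor((lon - grid.west) / grid.cell_size).astype(int)
    row = np.floor((lat - grid.south) / grid.cell_size).astype(int)
    key = pd.DataFrame({
        "record_id": records["record_id"].to_numpy(),
        "species": records["species"].to_numpy(),
        "row": row,
        "col": col,
    })
    keep_ids = set(
        key.sort_values("record_id")
        .groupby(["species", "row", "col"], sort=False)["record_id"]
        .first()
    )
    reason = pd.Series(
        [KEPT if rid in keep_ids else DUPLICATE_CELL
         for rid in records["record_id"]],
        index=pd.Index(records["record_id"], name="record_id"),
        dtype=object,
    )
    return reason


def kde_density(points: np.ndarray, bandwidth: float = 1.0) -> np.ndarray:
    """Fixed-bandwidth Gaussian kernel density at each point of a pattern.

    density_i = sum_j exp(-d_ij^2 / (2 h^2)) / (2 pi h^2 n), the sum running
    over all points including the point itself. Only the ranking matters for
    outlier removal, but the normalization makes values comparable across
    bandwidths.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2) lon/lat")
    n = pts.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points for a density ranking")
    d2 = cdist(pts, pts, "sqeuclidean")
    k = np.exp(-d2 / (2.0 * bandwidth**2))
    return k.sum(axis=1) / (2.0 * np.pi * bandwidth**2 * n)


def kde_outlier_filter(records: pd.DataFrame, regions: RegionPartition,
                       config: KdeConfig | None = None) -> pd.Series:
    """Remove low-density records; quantile depends on regional spread.

    The species' region count (regions holding at least one record) selects
    the quantile: ``quantile_narrow`` for 1-3 regions, ``quantile_wide`` for
    more. The threshold is the empirical quantile of the per-record densities;
    records strictly below it are flagged KDE_OUTLIER.
    """
    config = config or KdeConfig()
    reason = pd.Series(KEPT, index=pd.Index(records["record_id"],
                                            name="record_id"), dtype=object)
    if len(records) < 2:
        warnings.warn("fewer than 2 records: KDE outlier step skipped")
        return reason
    lon = records[LON].to_numpy(dtype=float)
    lat = records[LAT].to_numpy(dtype=float)
    dens = kde_density(np.column_stack([lon, lat]), config.bandwidth)
    labels = regions.regions_of_points(lon, lat)
    n_regions = np.unique(labels[labels > 0]).size
    q = config.quantile_narrow if n_regions <= 3 else config.quantile_wide
    threshold = np.quantile(dens, q)
    reason.iloc[np.flatnonzero(dens < threshold)] = KDE_OUTLIER
    return reason


def clean_pipeline(records: pd.DataFrame, grid: GridSpec,
                   gazetteer: Gazetteer | None = None,
                   regions: RegionPartition | None = None,
                   kde_config: KdeConfig | None = None,
                   tolerance: float = 0.05,
                   ) -> tuple[pd.DataFrame, CleaningReport]:
    """Full two-step cleaning: validate -> dedupe -> KDE outlier removal.

    Returns the surviving records and a report whose dispositions cover every
    input record with its first-triggering reason. The deterministic stages
    are idempotent: re-running them on their own output removes nothing.
    """
    records = records.reset_index(drop=True)
    disp = validate_records(records, gazetteer, tolerance)
    stage_counts = {"input": len(records),
                    "validate_removed": int((disp != KEPT).sum())}

    alive = records[disp.to_numpy() == KEPT]
    if len(alive):
        d2 = dedupe_to_cells(alive, grid)
        removed = d2.index[d2 == DUPLICATE_CELL]
        disp.loc[removed] = DUPLICATE_CELL
        alive = alive[d2.to_numpy() == KEPT]
    stage_counts["dedupe_removed"] = int((disp == DUPLICATE_CELL).sum())

    if regions is not None and len(alive) >= 2:
        d3 = kde_outlier_filter(alive, regions, kde_config)
        removed = d3.index[d3 == KDE_OUTLIER]
        disp.loc[removed] = KDE_OUTLIER
        alive = alive[d3.to_numpy() == KEPT]
    stage_counts["kde_removed"] = int((disp == KDE_OUTLIER).sum())
    stage_counts["kept"] = len(alive)

    report = CleaningReport(disp, stage_counts)
    return alive.reset_index(drop=True), report


class OccurrenceCleaner:
    """Object wrapper over :func:`clean_pipeline` for repeated use.

    ``transform(records)`` returns the cleaned frame; the report from the most
    recent call is available as ``report_``.
    """

    def __init__(self, grid: GridSpec, gazetteer: Gazetteer | None = None,
                 regions: RegionPartition | None = None,
                 kde_config: KdeConfig | None = None,
                 tolerance: float = 0.05):
        self.grid = grid
        self.gazetteer = gazetteer
        self.regions = regions
        self.kde_config = kde_config
        self.tolerance = tolerance

    def transform(self, records: pd.DataFrame) -> pd.DataFrame:
        cleaned, report = clean_pipeline(
            records, self.grid, self.gazetteer, self.regions,
            self.kde_config, self.tolerance,
        )
        self.report_ = report
        return cleaned
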