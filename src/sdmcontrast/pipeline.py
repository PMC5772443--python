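"""Per-species workflow: clean -> IDW -> MaxEnt -> clip -> validate -> compare.

A :class:`Study` bundles the shared inputs (grid, climate layers, forest mask,
region partition, gazetteer, plot table, occurrence table). ``run_species``
executes the stage graph for one species and returns its statistics row plus
map artifacts; species failing a gate (too few cleaned presences, or a
suitability model not significantly better than the bias-corrected null) are
excluded from the comparison statistics but logged with the gate that removed
them. ``run_all`` iterates the cohort with per-species isolation — one
species' failure never aborts the rest — and ``summarize`` reduces the rows to
the cohort report (proportion of significant positive collection-abundance
GLMs, mean Spearman rho, mean 90th-percentile slope, median sensitivities both
ways, median areas of occupancy).

Every source of randomness (background sample, null replicates, bootstrap)
derives from the study seed and the species' position, so a rerun with the
same config reproduces every output.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cleaning import Gazetteer, KdeConfig, clean_pipeline
from .grid import GridSpec, RasterLayer, RegionPartition, points_to_cells
from .idw import IdwAbundance, idw_binary_map, idw_surface
from .maxent import (LinearQuadraticFeatures, MaxentLQ, sample_background,
                     threshold_10pct, training_auc)
from .ranges import area_of_occupancy, clip_to_range, hull_buffer, sensitivity
from .validation import (glm_collection_vs_abundance, null_model_test,
                         quantile_reg_90, spearman_suit_vs_abundance)

log = logging.getLogger("sdmcontrast")

__all__ = ["Study", "PipelineSettings", "SpeciesResult", "bias_from_records",
           "run_species", "run_all", "summarize"]

STATS_COLUMNS = [
    "species", "n_records_raw", "n_cleaned", "auc", "null_rank",
    "significant", "rho", "rho_p", "q_slope", "q_slope_ci_low",
    "q_slope_ci_high", "q_slope_p", "glm_beta1", "glm_p",
    "sens_idw_vs_collections", "sens_maxent_vs_plots", "aoo_maxent",
    "aoo_idw", "gate",
]


@dataclass
class Study:
    """Shared inputs of one study system."""

    grid: GridSpec
    env: dict  # name -> RasterLayer
    forest_mask: np.ndarray
    regions: RegionPartition
    gazetteer: Gazetteer
    plots: pd.DataFrame
    records: pd.DataFrame
    species_names: list

    @classmethod
    def from_world(cls, world) -> "Study":
        return cls(
            grid=world.grid,
            env=world.env,
            forest_mask=world.forest_mask,
            regions=world.regions,
            gazetteer=world.gazetteer,
            plots=world.plots,
            records=world.records,
            species_names=[sp.name for sp in world.species],
        )


@dataclass
class PipelineSettings:
    """All stage knobs in one serializable place."""

    kde: KdeConfig = field(default_factory=KdeConfig)
    gazetteer_tolerance: float = 0.05
    idw_k_max: int = 150
    idw_d_max: float = 3.0
    idw_power: float = 0.5
    reg_multiplier: float = 1.0
    n_background: int = 10_000
    n_null: int = 99
    min_presences: int = 5
    buffer_deg: float = 3.0
    n_boot: int = 200
    spearman_use_observed_ra: bool = True  # vs IDW value at the plot's cell
    seed: int = 0


@dataclass
class SpeciesResult:
    row: dict
    suitability: RasterLayer | None = None
    maxent_binary: RasterLayer | None = None
    idw_ra: RasterLayer | None = None
    idw_binary: RasterLayer | None = None
    cleaning_report: object = None


def bias_from_records(records: pd.DataFrame, grid: GridSpec,
                      forest_mask: np.ndarray | None = None) -> RasterLayer:
    """Survey-effort layer: 1 where any species has >= 1 valid record."""
    lon = pd.to_numeric(records["decimalLongitude"], errors="coerce")
    lat = pd.to_numeric(records["decimalLatitude"], errors="coerce")
    ok = np.isfinite(lon) & np.isfinite(lat)
    row, col = points_to_cells(lon[ok].to_numpy(), lat[ok].to_numpy(), grid)
    vals = np.zeros(grid.shape)
    on = row >= 0
    vals[row[on], col[on]] = 1.0
    valid = (np.ones(grid.shape, bool) if forest_mask is None
             else np.asarray(forest_mask, bool))
    vals[~valid] = 0.0
    return RasterLayer(grid, vals, valid)


def _presence_cells(records: pd.DataFrame, grid: GridSpec,
                    forest_mask: np.ndarray) -> np.ndarray:
    """Unique flat cell indices (within the forest mask) of record points."""
    row, col = points_to_cells(records["decimalLongitude"].to_numpy(float),
                               records["decimalLatitude"].to_numpy(float),
                               grid)
    on = row >= 0
    on[on.copy()] = forest_mask[row[on], col[on]]
    flat = row[on] * grid.n_cols + col[on]
    return np.unique(flat)


def run_species(name: str, study: Study, settings: PipelineSettings,
                bias: RasterLayer, species_seed: int) -> SpeciesResult:
    """Execute the full stage graph for one species."""
    t0 = time.time()
    grid = study.grid
    forest = study.forest_mask
    row: dict = {c: np.nan for c in STATS_COLUMNS}
    row["species"] = name
    row["gate"] = ""

    # ---- stage 1: cleaning -------------------------------------------------
    raw = study.records[study.records["species"] == name]
    row["n_records_raw"] = len(raw)
    cleaned, report = clean_pipeline(
        raw, grid, study.gazetteer, study.regions, settings.kde,
        settings.gazetteer_tolerance,
    )
    row["n_cleaned"] = len(cleaned)
    result = SpeciesResult(row=row, cleaning_report=report)
    log.info("clean %s: %d -> %d", name, len(raw), len(cleaned))

    # ---- stage 2: IDW abundance surface ------------------------------------
    if name in study.plots.columns:
        idw_cfg = IdwAbundance(k_max=settings.idw_k_max,
                               d_max=settings.idw_d_max,
                               power=settings.idw_power)
        surface = idw_surface(study.plots, grid, idw_cfg, forest, name)
        ibmap = idw_binary_map(surface)
        result.idw_ra = surface
        result.idw_binary = ibmap
        row["aoo_idw"] = area_of_occupancy(ibmap)
        if len(cleaned):
            pts = cleaned[["decimalLongitude", "decimalLatitude"]].to_numpy(
                float)
            row["sens_idw_vs_collections"] = sensitivity(ibmap, pts)
        # collection probability vs interpolated abundance, over forest cells
        coll_cells = _presence_cells(cleaned, grid, forest)
        indicator = np.zeros(grid.n_cells)
        indicator[coll_cells] = 1.0
        indicator = indicator.reshape(grid.shape)[forest]
        ra_cells = surface.values[forest]
        if 0 < indicator.sum() < indicator.size and np.ptp(ra_cells) > 0:
            glm = glm_collection_vs_abundance(indicator, ra_cells)
            row["glm_beta1"] = glm.slope
            row["glm_p"] = glm.p_value

    # ---- gate: enough presences --------------------------------------------
    pres_idx_grid = _presence_cells(cleaned, grid, forest)
    if pres_idx_grid.size < settings.min_presences:
        row["gate"] = "insufficient presences"
        log.warning("%s gated: %s", name, row["gate"])
        return result

    # ---- stage 3: MaxEnt ---------------------------------------------------
    env_names = list(study.env)
    env_mat = np.column_stack(
        [study.env[n].values.ravel() for n in env_names])
    forest_flat = np.flatnonzero(forest.ravel())
    bias_flat = bias.values.ravel()[forest_flat]

    ss = np.random.SeedSequence([settings.seed, species_seed])
    s_bg, s_null = ss.spawn(2)
    bg_local = sample_background(bias_flat, settings.n_background, s_bg)

    feats = LinearQuadraticFeatures(feature_names=env_names)
    feats.fit(env_mat[forest_flat[bg_local]])
    forest_features = feats.transform(env_mat[forest_flat])

    pos_in_forest = np.searchsorted(forest_flat, pres_idx_grid)
    model = MaxentLQ(reg_multiplier=settings.reg_multiplier,
                     min_presences=settings.min_presences)
    Xbg = forest_features[bg_local]
    Xpres = forest_features[pos_in_forest]
    model.fit(np.vstack([Xbg, Xpres]),
              np.concatenate([np.zeros(len(Xbg)), np.ones(len(Xpres))]))
    row["auc"] = training_auc(model.decision_function(Xpres),
                              model.decision_function(Xbg))

    logistic_forest = model.predict_logistic(forest_features)
    suit_vals = np.zeros(grid.shape)
    suit_vals[forest] = logistic_forest
    suitability = RasterLayer(grid, suit_vals, forest.copy())
    result.suitability = suitability

    # ---- gate: bias-corrected null-model significance ----------------------
    null = null_model_test(
        pos_in_forest, forest_features, bias_flat, bg_local,
        n_null=settings.n_null, reg_multiplier=settings.reg_multiplier,
        seed=s_null, min_presences=settings.min_presences,
    )
    row["null_rank"] = null.rank
    row["significant"] = bool(null.significant)
    if not null.significant:
        row["gate"] = "null model not significant"
        log.warning("%s gated: %s (rank %d)", name, row["gate"], null.rank)
        return result

    # ---- stage 4: binary map, clip, AOO, sensitivity -----------------------
    thr = threshold_10pct(model.predict_logistic(Xpres))
    bvals = ((suit_vals >= thr) & forest).astype(float)
    bmap = RasterLayer(grid, bvals, forest.copy())
    pts = cleaned[["decimalLongitude", "decimalLatitude"]].to_numpy(float)
    hull = hull_buffer(pts[np.isfinite(pts).all(axis=1)],
                       settings.buffer_deg)
    bmap = clip_to_range(bmap, hull)
    result.maxent_binary = bmap
    row["aoo_maxent"] = area_of_occupancy(bmap)

    if name in study.plots.columns:
        present_plots = study.plots[study.plots[name] > 0]
        if len(present_plots):
            row["sens_maxent_vs_plots"] = sensitivity(
                bmap, present_plots[["lon", "lat"]].to_numpy(float))

        # ---- stage 5: comparison statistics at plot localities -------------
        prow, pcol = points_to_cells(study.plots["lon"].to_numpy(),
                                     study.plots["lat"].to_numpy(), grid)
        onf = (prow >= 0)
        onf[onf.copy()] = forest[prow[onf], pcol[onf]]
        plots_on = study.plots[onf]
        suit_at_plots = suit_vals[prow[onf], pcol[onf]]
        if settings.spearman_use_observed_ra:
            ra_at_plots = (plots_on[name] / plots_on["N_total"]).to_numpy()
        else:
            ra_at_plots = result.idw_ra.values[prow[onf], pcol[onf]]
        if len(plots_on) >= 3 and np.ptp(suit_at_plots) > 0 \
                and np.ptp(ra_at_plots) > 0:
            rho, rho_p = spearman_suit_vs_abundance(suit_at_plots,
                                                    ra_at_plots)
            row["rho"], row["rho_p"] = rho, rho_p
        if len(plots_on) >= 10 and np.ptp(suit_at_plots) > 0:
            qr = quantile_reg_90(suit_at_plots, ra_at_plots,
                                 n_boot=settings.n_boot,
                                 seed=np.random.SeedSequence(
                                     [settings.seed, species_seed, 2]))
            row["q_slope"] = qr.slope
            row["q_slope_ci_low"] = qr.ci_low
            row["q_slope_ci_high"] = qr.ci_high
            row["q_slope_p"] = qr.p_value

    log.info("%s done in %.1fs", name, time.time() - t0)
    return result


def run_all(study: Study, settings: PipelineSettings | None = None
            ) -> tuple[pd.DataFrame, dict]:
    """Run every species with per-species isolation; returns (rows, results)."""
    settings = settings or PipelineSettings()
    bias = bias_from_records(study.records, study.grid, study.forest_mask)
    rows = []
    results: dict[str, SpeciesResult] = {}
    for i, name in enumerate(study.species_names):
        try:
            res = run_species(name, study, settings, bias, species_seed=i)
            rows.append(res.row)
            results[name] = res
        except Exception as exc:  # per-species isolation
            log.error("species %s failed: %s", name, exc)
            rows.append({**{c: np.nan for c in STATS_COLUMNS},
                         "species": name, "gate": f"failed: {exc}"})
    frame = pd.DataFrame(rows, columns=STATS_COLUMNS)
    return frame, results


def summarize(rows: pd.DataFrame) -> dict:
    """Cohort report over the per-species statistics rows."""
    if len(rows) == 0:
        raise ValueError("no species rows to summarize")
    passed = rows[rows["gate"] == ""]
    glm_ok = rows.dropna(subset=["glm_beta1", "glm_p"])
    sig_pos = (glm_ok["glm_beta1"] > 0) & (glm_ok["glm_p"] < 0.05)
    report = {
        "n_species": int(len(rows)),
        "n_passed_gates": int(len(passed)),
        "n_gated_insufficient": int(
            (rows["gate"] == "insufficient presences").sum()),
        "n_gated_null": int(
            (rows["gate"] == "null model not significant").sum()),
        "n_glm_tested": int(len(glm_ok)),
        "n_glm_significant_positive": int(sig_pos.sum()),
        "prop_glm_significant_positive": float(sig_pos.mean())
        if len(glm_ok) else float("nan"),
        "mean_rho": float(passed["rho"].mean()),
        "mean_q_slope": float(passed["q_slope"].mean()),
        "median_sens_idw_vs_collections": float(
            rows["sens_idw_vs_collections"].median()),
        "median_sens_maxent_vs_plots": float(
            passed["sens_maxent_vs_plots"].median()),
        "median_aoo_maxent": float(passed["aoo_maxent"].median()),
        "median_aoo_idw": float(rows["aoo_idw"].median()),
        "n_aoo_maxent_larger": int(
            (passed["aoo_maxent"] > passed["aoo_idw"]).sum()),
        "n_aoo_idw_larger": int(
            (passed["aoo_idw"] > passed["aoo_maxent"]).sum()),
        "mean_fraction_records_removed": float(
            1.0 - (rows["n_cleaned"] / rows["n_records_raw"]).mean()
        ) if rows["n_records_raw"].notna().any() else float("nan"),
    }
    return report
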