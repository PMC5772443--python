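import numpy as np
import pandas as pd
import pytest

from sdmcontrast.cleaning import (CAPITAL, DUPLICATE_CELL, KDE_OUTLIER, KEPT,
                                  LAT_EQ_LON, MISSING_GEO, PROVINCE_CENTROID,
                                  ZERO_COORD, CleaningReport, Gazetteer,
                                  KdeConfig, clean_pipeline, dedupe_to_cells,
                                  kde_density, kde_outlier_filter,
                                  validate_records)
from sdmcontrast.grid import GridSpec, RegionPartition


def make_records(rows):
    defaults = {"species": "sp", "locality": "somewhere",
                "countryCode": "SY"}
    out = []
    for i, r in enumerate(rows):
        rec = {"record_id": f"r{i:03d}", **defaults, **r}
        out.append(rec)
    return pd.DataFrame(out)


@pytest.fixture
def grid():
    return GridSpec(west=-80.0, south=-20.0, cell_size=0.5, n_cols=20,
                    n_rows=20)


@pytest.fixture
def regions(grid):
    ids = np.ones(grid.shape, int)
    ids[:, 10:] = 2
    return RegionPartition(grid, ids)


@pytest.fixture
def gazetteer():
    return Gazetteer(
        capitals=pd.DataFrame({"lon": [-75.0], "lat": [-10.0]}),
        centroids=pd.DataFrame({"lon": [-78.0], "lat": [-18.0]}),
    )


class TestValidateRecords:
    def test_reason_codes_and_precedence(self, gazetteer):
        records = make_records([
            {"decimalLongitude": -79.1, "decimalLatitude": -19.1},   # kept
            {"decimalLongitude": None, "decimalLatitude": -19.0},    # missing
            {"decimalLongitude": 4.2, "decimalLatitude": 4.2},       # lat==lon
            {"decimalLongitude": 0.0, "decimalLatitude": 0.0},       # zeros
            {"decimalLongitude": -75.01, "decimalLatitude": -10.0},  # capital
            {"decimalLongitude": -78.0, "decimalLatitude": -18.02},  # centroid
            {"decimalLongitude": -79.2, "decimalLatitude": -19.2,
             "locality": ""},                                        # missing
        ])
        disp = validate_records(records, gazetteer, tolerance=0.05)
        assert list(disp) == [KEPT, MISSING_GEO, LAT_EQ_LON, ZERO_COORD,
                              CAPITAL, PROVINCE_CENTROID, MISSING_GEO]

    def test_zero_coord_requires_both_zero(self, gazetteer):
        records = make_records([
            {"decimalLongitude": 0.0, "decimalLatitude": -5.0},
            {"decimalLongitude": -5.0, "decimalLatitude": 0.0},
        ])
        disp = validate_records(records, gazetteer)
        assert (disp == KEPT).all()

    def test_missing_geo_takes_precedence_over_lat_eq_lon(self, gazetteer):
        records = make_records([
            {"decimalLongitude": 4.2, "decimalLatitude": 4.2,
             "locality": None},
        ])
        assert validate_records(records, gazetteer).iloc[0] == MISSING_GEO

    def test_country_mismatch_only_with_polygons(self):
        from shapely.geometry import box
        records = make_records([
            {"decimalLongitude": -79.0, "decimalLatitude": -19.0,
             "countryCode": "AA"},
        ])
        gaz = Gazetteer(capitals=pd.DataFrame({"lon": [], "lat": []}),
                        centroids=None,
                        country_polygons={"AA": box(-75, -15, -70, -10)})
        disp = validate_records(records, gaz)
        assert disp.iloc[0] == "COUNTRY_MISMATCH"

    def test_no_gazetteer_warns_and_skips(self):
        records = make_records([
            {"decimalLongitude": -75.0, "decimalLatitude": -10.0},
        ])
        with pytest.warns(UserWarning, match="gazetteer"):
            disp = validate_records(records, None)
        assert disp.iloc[0] == KEPT


class TestDedupe:
    def test_many_records_one_cell_keep_lowest_id(self, grid):
        records = make_records(
            [{"decimalLongitude": -79.9 + 0.0001 * i,
              "decimalLatitude": -19.9} for i in range(543)]
        )
        disp = dedupe_to_cells(records, grid)
        assert (disp == KEPT).sum() == 1
        assert disp.loc["r000"] == KEPT
        assert (disp == DUPLICATE_CELL).sum() == 542

    def test_distinct_cells_all_kept(self, grid):
        records = make_records(
            [{"decimalLongitude": -79.75 + 0.5 * i,
              "decimalLatitude": -19.75} for i in range(5)]
        )
        assert (dedupe_to_cells(records, grid) == KEPT).all()

    def test_boundary_points_fall_in_distinct_cells(self, grid):
        records = make_records([
            {"decimalLongitude": -79.5001, "decimalLatitude": -19.75},
            {"decimalLongitude": -79.5, "decimalLatitude": -19.75},
        ])
        assert (dedupe_to_cells(records, grid) == KEPT).all()

    def test_different_species_never_deduped(self, grid):
        records = make_records([
            {"decimalLongitude": -79.9, "decimalLatitude": -19.9,
             "species": "a"},
            {"decimalLongitude": -79.9, "decimalLatitude": -19.9,
             "species": "b"},
        ])
        assert (dedupe_to_cells(records, grid) == KEPT).all()


class TestKdeDensity:
    def test_coincident_points_equal_density(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [3.0, 1.0]])
        d = kde_density(pts, bandwidth=1.0)
        assert d[0] == pytest.approx(d[1])

    def test_matches_direct_kernel_sum(self, rng):
        pts = rng.uniform(0, 5, size=(30, 2))
        h = 1.3
        d = kde_density(pts, h)
        i = 7
        direct = sum(
            np.exp(-((pts[i] - p) ** 2).sum() / (2 * h * h)) for p in pts
        ) / (2 * np.pi * h * h * len(pts))
        assert d[i] == pytest.approx(direct, rel=1e-12)

    def test_isolated_point_has_minimal_density(self, rng):
        cluster = rng.normal(0, 0.3, size=(20, 2))
        far = np.array([[10.0, 10.0]])  # 10 bandwidths away
        d = kde_density(np.vstack([cluster, far]), bandwidth=1.0)
        assert d[-1] < d[:-1].min()

    def test_order_invariant(self, rng):
        pts = rng.uniform(0, 5, size=(25, 2))
        perm = rng.permutation(25)
        d1 = kde_density(pts)
        d2 = kde_density(pts[perm])
        assert np.allclose(d1[perm], d2)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            kde_density(np.array([[0.0, 0.0]]))


class TestKdeOutlierFilter:
    def _records_from_points(self, pts, species="sp"):
        return make_records([
            {"decimalLongitude": x, "decimalLatitude": y, "species": species}
            for x, y in pts
        ])

    def test_far_point_removed_cluster_kept(self, grid, regions, rng):
        cluster = np.column_stack([rng.uniform(-79.5, -78.5, 20),
                                   rng.uniform(-19.5, -18.5, 20)])
        far = np.array([[-71.0, -11.0]])
        records = self._records_from_points(np.vstack([cluster, far]))
        disp = kde_outlier_filter(records, regions, KdeConfig())
        assert disp.iloc[-1] == KDE_OUTLIER
        assert (disp.iloc[:-1] == KEPT).all()

    def test_lattice_interior_survives(self, grid, regions):
        xs, ys = np.meshgrid(np.linspace(-79.5, -76.5, 7),
                             np.linspace(-19.5, -16.5, 7))
        records = self._records_from_points(
            np.column_stack([xs.ravel(), ys.ravel()]))
        disp = kde_outlier_filter(records, regions,
                                  KdeConfig(bandwidth=1.0,
                                            quantile_narrow=0.05))
        removed = records[disp.to_numpy() == KDE_OUTLIER]
        # any removals sit on the margin of the lattice, never the interior
        for _, r in removed.iterrows():
            on_margin = (r.decimalLongitude in (-79.5, -76.5)
                         or r.decimalLatitude in (-19.5, -16.5))
            assert on_margin
        assert (disp == KDE_OUTLIER).sum() <= np.floor(0.05 * 49) + 1

    def test_narrow_quantile_removes_at_least_as_many(self, grid, rng):
        pts = np.column_stack([rng.uniform(-80, -71, 60),
                               rng.uniform(-20, -11, 60)])
        records = self._records_from_points(pts)
        ids_all = np.ones(grid.shape, int)  # one region: narrow
        ids_split = (np.arange(grid.n_cols)[None, :] * 6 // grid.n_cols) + 1
        ids_split = np.broadcast_to(ids_split, grid.shape)  # six regions: wide
        cfg = KdeConfig(quantile_narrow=0.10, quantile_wide=0.02)
        narrow = kde_outlier_filter(records, RegionPartition(grid, ids_all),
                                    cfg)
        wide = kde_outlier_filter(records,
                                  RegionPartition(grid, ids_split.copy()),
                                  cfg)
        assert (narrow == KDE_OUTLIER).sum() >= (wide == KDE_OUTLIER).sum()


class TestCleanPipeline:
    def test_synthetic_corpus_deterministic_codes_exact(self, world):
        """All injected deterministic errors caught with the right code."""
        mapping = {"missing_coord": MISSING_GEO, "zero_coord": ZERO_COORD,
                   "lat_eq_lon": LAT_EQ_LON, "capital_assign": CAPITAL,
                   "centroid_assign": PROVINCE_CENTROID,
                   "duplicate": DUPLICATE_CELL}
        det_codes = set(mapping.values())
        for name, grp in world.records.groupby("species"):
            cleaned, report = clean_pipeline(grp, world.grid,
                                             world.gazetteer, world.regions)
            labels = grp.set_index("record_id")["truth_label"]
            disp = report.dispositions
            for label, code in mapping.items():
                sel = labels.index[labels == label]
                assert (disp.loc[sel] == code).all()
            clean_sel = labels.index[labels == "clean"]
            assert not disp.loc[clean_sel].isin(det_codes).any()

    def test_report_accounts_for_every_record(self, world):
        grp = world.records[world.records["species"]
                            == world.species[0].name]
        cleaned, report = clean_pipeline(grp, world.grid, world.gazetteer,
                                         world.regions)
        assert report.n_input == len(grp)
        assert sum(report.counts().values()) == len(grp)
        assert report.fraction_removed == pytest.approx(
            report.n_removed / len(grp))
        assert len(cleaned) == report.counts()[KEPT]

    def test_output_subset_of_input(self, world):
        grp = world.records[world.records["species"]
                            == world.species[1].name]
        cleaned, _ = clean_pipeline(grp, world.grid, world.gazetteer,
                                    world.regions)
        assert set(cleaned["record_id"]) <= set(grp["record_id"])

    def test_deterministic_stages_idempotent(self, world):
        grp = world.records[world.records["species"]
                            == world.species[2].name]
        cleaned, _ = clean_pipeline(grp, world.grid, world.gazetteer,
                                    None)  # no KDE: deterministic only
        again, report = clean_pipeline(cleaned, world.grid, world.gazetteer,
                                       None)
        assert report.n_removed == 0
        assert len(again) == len(cleaned)

    def test_empty_input_is_not_an_error(self, world):
        empty = world.records.iloc[0:0]
        cleaned, report = clean_pipeline(empty, world.grid, world.gazetteer,
                                         world.regions)
        assert len(cleaned) == 0
        assert report.n_input == 0
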