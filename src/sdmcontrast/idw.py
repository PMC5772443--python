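"""Plot-based relative-abundance surfaces by inverse distance weighting.

Each 1-ha inventory plot contributes its relative abundance RA = n_i / N (stems
of the focal species over all stems >= 10 cm dbh). A cell's interpolated value
is the weighted mean of the nearest ``k_max`` plots within ``d_max`` degrees of
its center, with weights w_k = d_k^(-p); the default exponent p = 0.5 makes the
weight the reciprocal square root of the distance in degrees. Cells with no
plot within ``d_max`` are predicted absent (RA = 0): in a purely spatial model
the range is bounded by dispersal, not climate, so support never extends more
than ``d_max`` from an occupied plot.

Binary range maps set a cell to 1 wherever interpolated RA > 0 (strict), then
zero out naturally non-forested cells.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, RegressorMixin

from .grid import GridSpec, RasterLayer, cell_centers

__all__ = ["IdwAbundance", "plot_relative_abundance", "idw_surface",
           "idw_binary_map"]


def plot_relative_abundance(n_i, n_total):
    """RA = n_i / N for a plot census row (scalar or array)."""
    n_i = np.asarray(n_i, dtype=float)
    n_total = np.asarray(n_total, dtype=float)
    if np.any(n_total < 1):
        raise ValueError("plot must contain at least one stem")
    if np.any(n_i > n_total) or np.any(n_i < 0):
        raise ValueError("focal stem count must satisfy 0 <= n_i <= N")
    return n_i / n_total


class IdwAbundance(BaseEstimator, RegressorMixin):
    """Inverse-distance-weighted interpolator over plot coordinates.

    ``fit(X, y)`` takes plot coordinates X = (n_plots, 2) as (lon, lat) in
    decimal degrees and y = per-plot relative abundance. ``predict`` returns
    the weighted mean of the nearest ``k_max`` training plots within ``d_max``
    degrees (Euclidean in degree space) of each query point, 0 where no plot
    is in range. Query points coinciding with plots (distance < ``eps``)
    short-circuit to the mean RA of the coincident plots, making the
    interpolator exact at the data.
    """

    def __init__(self, k_max: int = 150, d_max: float = 3.0, power: float = 0.5,
                 eps: float = 1e-9):
        self.k_max = k_max
        self.d_max = d_max
        self.power = power
        self.eps = eps

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_plots, 2) lon/lat")
        if y.shape != (X.shape[0],):
            raise ValueError("y must hold one RA value per plot")
        if self.k_max < 1 or self.d_max <= 0 or self.power <= 0:
            raise ValueError("k_max >= 1, d_max > 0 and power > 0 required")
        self.X_ = X
        self.y_ = y
        self.tree_ = cKDTree(X)
        return self

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        k = min(self.k_max, self.X_.shape[0])
        dist, idx = self.tree_.query(X, k=k, distance_upper_bound=self.d_max)
        if k == 1:
            dist = dist[:, None]
            idx = idx[:, None]
        out = np.zeros(X.shape[0])
        in_range = np.isfinite(dist)
        for i in range(X.shape[0]):
            sel = in_range[i]
            if not sel.any():
                continue
            d = dist[i, sel]
            v = self.y_[idx[i, sel]]
            coincident = d < self.eps
            if coincident.any():
                out[i] = v[coincident].mean()
            else:
                w = d ** (-self.power)
                out[i] = (w * v).sum() / w.sum()
        return out


def idw_surface(plots, grid: GridSpec, config: IdwAbundance | None = None,
                forest_mask: np.ndarray | None = None,
                species: str | None = None) -> RasterLayer:
    """Interpolate a plot table onto every valid forested cell of the grid.

    ``plots`` is a DataFrame with columns lon, lat, N_total and either an
    ``RA`` column or a per-species stem-count column named ``species``.
    """
    model = config if config is not None else IdwAbundance()
    if species is not None:
        ra = plot_relative_abundance(plots[species].to_numpy(),
                                     plots["N_total"].to_numpy())
    else:
        ra = plots["RA"].to_numpy(dtype=float)
    xy = plots[["lon", "lat"]].to_numpy(dtype=float)
    mask = (np.ones(grid.shape, dtype=bool) if forest_mask is None
            else np.asarray(forest_mask, dtype=bool))
    values = np.zeros(grid.shape)
    if len(xy) == 0:
        warnings.warn("empty plot table: surface is all-zero")
        return RasterLayer(grid, values, mask)
    model.fit(xy, ra)
    lon, lat = cell_centers(grid)
    pts = np.column_stack([lon[mask], lat[mask]])
    values[mask] = model.predict(pts)
    return RasterLayer(grid, values, mask)


def idw_binary_map(surface: RasterLayer,
                   nonforest_mask: np.ndarray | None = None) -> RasterLayer:
    """Presence map: 1 iff RA > 0 on a valid forested cell."""
    present = (surface.values > 0) & surface.valid
    if nonforest_mask is not None:
        present &= ~np.asarray(nonforest_mask, dtype=bool)
    return RasterLayer(surface.grid, present.astype(float), surface.valid)
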