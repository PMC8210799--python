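"""Trapezoidal environmental-envelope habitat suitability.

Per-variable suitability is a trapezoid over (abs_min, pref_min,
pref_max, abs_max): zero outside the absolute bounds, one inside the
preferred range, linear ramps between.  Cell suitability is the product
over variables (the AquaMaps convention); habitat area sums spherical
cell areas above a probability threshold (0.3 for core habitat), and
range shifts are summarised by the mean latitude of suitable cells with
a Mann-Whitney U comparison between periods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .datatypes import RasterGrid

EARTH_RADIUS_KM = 6371.0


@dataclass
class EnvelopeParams:
    """(abs_min, pref_min, pref_max, abs_max) per variable, in the
    variable's units (depth m, SST degC, ice fraction, salinity PSU)."""

    variables: dict[str, tuple[float, float, float, float]]

    def __post_init__(self) -> None:
        for name, (a, p1, p2, b) in self.variables.items():
            if not (a <= p1 <= p2 <= b):
                raise ValueError(f"envelope for '{name}' not ordered: "
                                 f"{a} <= {p1} <= {p2} <= {b} fails")


def trapezoid(value, params) -> np.ndarray:
    """Trapezoidal suitability in [0, 1]; exactly 0 at the absolute
    bounds (closed support convention)."""
    a, p1, p2, b = params
    v = np.asarray(value, dtype=float)
    out = np.zeros_like(v)
    inside = (v >= p1) & (v <= p2)
    out[inside] = 1.0
    lo = (v > a) & (v < p1)
    if p1 > a:
        out[lo] = (v[lo] - a) / (p1 - a)
    hi = (v > p2) & (v < b)
    if b > p2:
        out[hi] = (b - v[hi]) / (b - p2)
    return out if out.shape else float(out)


def predict_suitability(
    layers: dict[str, RasterGrid], env: EnvelopeParams
) -> RasterGrid:
    """Product of per-variable trapezoids; nodata propagates."""
    grids = list(layers.values())
    first = grids[0]
    for g in grids[1:]:
        if not first.same_grid(g):
            raise ValueError("environmental layers are not on the same grid")
    P = np.ones_like(first.values)
    nodata_mask = np.zeros(first.values.shape, dtype=bool)
    for name, grid in layers.items():
        if name not in env.variables:
            raise ValueError(f"no envelope parameters for layer '{name}'")
        nodata_mask |= grid.mask()
        P *= trapezoid(grid.values, env.variables[name])
    P[nodata_mask] = first.nodata
    return RasterGrid(P, first.cell_size, first.xllcorner, first.yllcorner,
                      first.nodata)


def cell_areas_km2(grid: RasterGrid) -> np.ndarray:
    """Spherical area of each cell row: R^2 dlambda (sin top - sin bottom)."""
    dlam = np.radians(grid.cell_size)
    lats_top = grid.yllcorner + (np.arange(grid.n_rows)[::-1] + 1) * grid.cell_size
    lats_bot = lats_top - grid.cell_size
    band = EARTH_RADIUS_KM**2 * dlam * (
        np.sin(np.radians(lats_top)) - np.sin(np.radians(lats_bot))
    )
    return np.repeat(band[:, None], grid.n_cols, axis=1)


def habitat_area(map_: RasterGrid, threshold: float = 0.3) -> float:
    """Total km^2 of cells with suitability >= threshold."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    suitable = (map_.values >= threshold) & ~map_.mask()
    return float(cell_areas_km2(map_)[suitable].sum())


def latitude_shift(
    map_a: RasterGrid,
    map_b: RasterGrid,
    threshold: float = 0.3,
    area_weighted: bool = True,
) -> dict:
    """Latitudinal summary of suitable habitat in two periods.

    Returns mean latitude (area-weighted by default, since cell area
    shrinks poleward), the 5th/95th percentiles, and a two-sided
    Mann-Whitney U on the cell-latitude samples (normal approximation
    with tie correction).
    """

    def lat_sample(m: RasterGrid):
        suitable = (m.values >= threshold) & ~m.mask()
        lats, _ = m.cell_centers()
        lat_grid = np.repeat(lats[:, None], m.n_cols, axis=1)
        w = cell_areas_km2(m) if area_weighted else np.ones_like(lat_grid)
        return lat_grid[suitable], w[suitable]

    la, wa = lat_sample(map_a)
    lb, wb = lat_sample(map_b)
    if la.size == 0 or lb.size == 0:
        return dict(defined=False)

    def summarise(lat, w):
        mean = float(np.average(lat, weights=w))
        order = np.argsort(lat)
        cum = np.cumsum(w[order]) / w.sum()
        p5 = float(lat[order][np.searchsorted(cum, 0.05)])
        p95 = float(lat[order][np.searchsorted(cum, 0.95)])
        return mean, p5, p95

    mean_a, p5a, p95a = summarise(la, wa)
    mean_b, p5b, p95b = summarise(lb, wb)
    u = sps.mannwhitneyu(la, lb, alternative="two-sided", method="asymptotic")
    return dict(
        defined=True,
        mean_lat_a=mean_a, mean_lat_b=mean_b,
        percentiles_a=(p5a, p95a), percentiles_b=(p5b, p95b),
        U_statistic=float(u.statistic), p=float(u.pvalue),
        shift=mean_b - mean_a,
    )
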