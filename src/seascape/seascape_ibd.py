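"""Bathymetry-constrained marine distances and isolation-by-distance.

Marine distances are shortest paths over the graph of bathymetry cells
whose depth lies in a habitable window (default -650..-10 m, the depth
band where porpoises travel), with 8-neighbour connectivity and
great-circle edge weights, so deep basins and land both act as
barriers.  Isolation by distance regresses FST/(1-FST) (or Phi_ST
transformed the same way) on marine distance; significance comes from
Mantel permutations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from ._util import rng_from
from .datatypes import DistanceMatrix, RasterGrid

EARTH_RADIUS_KM = 6371.0


def great_circle_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Haversine distance in km (array-aware)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


@dataclass
class MarineGraph:
    """Sparse weighted adjacency over habitable bathymetry cells."""

    bathy: RasterGrid
    cell_index: np.ndarray      # (rows, cols) -> node id or -1
    node_cells: np.ndarray      # node id -> (row, col)
    adjacency: "coo_matrix"

    @property
    def n_nodes(self) -> int:
        return self.node_cells.shape[0]


def build_marine_graph(
    bathy: RasterGrid, depth_window=(-650.0, -10.0), wrap_lon: bool = True
) -> MarineGraph:
    """Cells within the depth window, 8-connected, great-circle weights.

    Diagonal edges use the true great-circle between cell centres (not
    sqrt(2) x cell size), limiting distortion at high latitudes; the
    longitude seam at +-180 deg is joined when ``wrap_lon`` and the grid
    spans the full circle.
    """
    lo, hi = depth_window
    valid = (
        (bathy.values >= lo) & (bathy.values <= hi) & ~bathy.mask()
    )
    rows, cols = bathy.n_rows, bathy.n_cols
    cell_index = np.full((rows, cols), -1, dtype=int)
    rr, cc = np.nonzero(valid)
    cell_index[rr, cc] = np.arange(rr.size)
    node_cells = np.stack([rr, cc], axis=1)
    lats, lons = bathy.cell_centers()
    full_circle = wrap_lon and np.isclose(cols * bathy.cell_size, 360.0)

    src, dst, wts = [], [], []
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for dr, dc in offsets:
        r2 = rr + dr
        c2 = cc + dc
        if full_circle:
            c2 = c2 % cols
        ok = (r2 >= 0) & (r2 < rows) & (c2 >= 0) & (c2 < cols)
        a = cell_index[rr[ok], cc[ok]]
        b = cell_index[r2[ok], c2[ok]]
        good = b >= 0
        a, b = a[good], b[good]
        la1 = lats[node_cells[a, 0]]
        lo1 = lons[node_cells[a, 1]]
        la2 = lats[node_cells[b, 0]]
        lo2 = lons[node_cells[b, 1]]
        src.append(a)
        dst.append(b)
        wts.append(great_circle_km(la1, lo1, la2, lo2))
    src = np.concatenate(src) if src else np.array([], int)
    dst = np.concatenate(dst) if dst else np.array([], int)
    wts = np.concatenate(wts) if wts else np.array([], float)
    adj = coo_matrix((wts, (src, dst)), shape=(rr.size, rr.size))
    return MarineGraph(bathy, cell_index, node_cells, adj)


def snap_to_graph(
    graph: MarineGraph, lat: float, lon: float, radius_km: float = 50.0
) -> int:
    """Nearest habitable cell within the search radius.

    Ties between equidistant cells break toward the deeper cell.
    Raises when no habitable cell is in range.
    """
    lats, lons = graph.bathy.cell_centers()
    cl = lats[graph.node_cells[:, 0]]
    cn = lons[graph.node_cells[:, 1]]
    d = great_circle_km(lat, lon, cl, cn)
    if d.min() > radius_km:
        raise ValueError(
            f"no habitable cell within {radius_km} km of ({lat}, {lon})"
        )
    near = np.flatnonzero(np.isclose(d, d.min()))
    if near.size > 1:
        depths = graph.bathy.values[
            graph.node_cells[near, 0], graph.node_cells[near, 1]
        ]
        return int(near[np.argmin(depths)])  # deepest = most negative
    return int(near[0])


def marine_distance(
    bathy: RasterGrid,
    points,                      # iterable of (label, lat, lon)
    depth_window=(-650.0, -10.0),
    snap_radius_km: float = 50.0,
) -> DistanceMatrix:
    """Shortest by-sea distance (km) between labelled points.

    Pairs in disconnected basins get infinite distance (flagged by the
    caller via ``np.isinf``).
    """
    graph = build_marine_graph(bathy, depth_window)
    labels, nodes = [], []
    for label, lat, lon in points:
        try:
            nodes.append(snap_to_graph(graph, lat, lon, snap_radius_km))
        except ValueError as err:
            raise ValueError(f"sample '{label}': {err}") from err
        labels.append(str(label))
    dist = dijkstra(graph.adjacency.tocsr(), directed=False, indices=nodes)
    vals = dist[:, nodes]
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(labels, vals)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def mantel_test(
    a: DistanceMatrix, b: DistanceMatrix, n_perm: int = 10_000, seed=None,
    tail: str = "greater",
) -> dict:
    """Mantel correlation between two distance matrices.

    Pearson r on the off-diagonal upper triangles; the null permutes the
    row/column labels of one matrix jointly; one-tailed
    p = (# r_perm >= r_obs + 1)/(n_perm + 1) (or <= for tail='less').
    """
    if a.labels != b.labels:
        b = b.align_to(a.labels)
    n = a.n
    iu = np.triu_indices(n, k=1)
    x = a.values[iu]
    y = b.values[iu]
    ok = np.isfinite(x) & np.isfinite(y)
    if not ok.all():
        raise ValueError("non-finite entries; exclude pairs before testing")
    xc = x - x.mean()
    yc = y - y.mean()
    obs = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    rng = rng_from(seed)
    count = 0
    yv = b.values
    for _ in range(n_perm):
        p = rng.permutation(n)
        yp = yv[np.ix_(p, p)][iu]
        ypc = yp - yp.mean()
        r = np.dot(xc, ypc) / np.sqrt(np.dot(xc, xc) * np.dot(ypc, ypc))
        if tail == "greater" and r >= obs - 1e-12:
            count += 1
        elif tail == "less" and r <= obs + 1e-12:
            count += 1
    return dict(r=obs, p=(count + 1) / (n_perm + 1), n_perm=n_perm)


# ---------------------------------------------------------------------------
# IBD regression
# ---------------------------------------------------------------------------

@dataclass
class IbdResult:
    slope: float
    intercept: float
    r_squared: float
    mantel_r: float
    p_value: float
    n_pairs: int
    marker_class: str = ""


def linearised(values: np.ndarray) -> np.ndarray:
    """Rousset's transform F/(1-F); negative estimates truncated to 0
    before the transform (only here, never in the exported matrices)."""
    f = np.clip(values, 0.0, None)
    return f / (1.0 - f)


def ibd_analysis(
    genetic: DistanceMatrix,
    geographic: DistanceMatrix,
    transform: bool = True,
    n_perm: int = 10_000,
    seed=None,
    marker_class: str = "",
    tail: str = "greater",
) -> IbdResult:
    """OLS of (transformed) genetic distance on marine distance (km),
    with a Mantel permutation p-value.

    Pairs with infinite geographic distance are excluded (logged via
    n_pairs).
    """
    geographic = geographic.align_to(genetic.labels)
    gvals = linearised(genetic.values) if transform else genetic.values.copy()
    np.fill_diagonal(gvals, 0.0)
    n = genetic.n
    iu = np.triu_indices(n, k=1)
    x = geographic.values[iu]
    y = gvals[iu]
    ok = np.isfinite(x) & np.isfinite(y)
    res = sps.linregress(x[ok], y[ok])
    # Mantel on the finite submatrix
    finite_rows = np.isfinite(geographic.values).all(axis=1)
    keep = [genetic.labels[i] for i in np.flatnonzero(finite_rows)]
    gm = DistanceMatrix(keep, _sub(gvals, genetic.labels, keep), bounded=False)
    dm = geographic.align_to(keep)
    mt = mantel_test(dm, gm, n_perm=n_perm, seed=seed, tail=tail)
    return IbdResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        mantel_r=mt["r"],
        p_value=mt["p"],
        n_pairs=int(ok.sum()),
        marker_class=marker_class,
    )


def _sub(values, labels, keep):
    idx = [labels.index(l) for l in keep]
    return values[np.ix_(idx, idx)]


def relatedness_vs_distance(
    relatedness: DistanceMatrix,
    geographic: DistanceMatrix,
    n_perm: int = 10_000,
    seed=None,
) -> IbdResult:
    """Mean pairwise relatedness against marine distance.

    Same machinery as ``ibd_analysis`` without the F/(1-F) transform;
    under restricted dispersal the expected slope is negative (nearby
    groups are more related).
    """
    # one-tailed in the direction actually expected (negative slope)
    return ibd_analysis(
        relatedness,
        geographic,
        transform=False,
        n_perm=n_perm,
        seed=seed,
        marker_class="relatedness",
        tail="less",
    )
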