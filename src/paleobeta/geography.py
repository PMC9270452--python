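"""Geographic primitives: great circles, the Behrmann equal-area grid,
cluster-hull range size, occupancy, distance decay, multivariate dispersion,
and the space-for-time similarity map.

All spherical math uses a sphere of radius 6371 km.  Projected coordinates are
kilometres under a cylindrical equal-area (Behrmann) projection with standard
parallel 30 N, the projection under which the 100 km occupancy grid is laid
out, so every grid cell covers the same ground area regardless of latitude.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from shapely.geometry import MultiPoint

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0
_COS30 = math.cos(math.radians(30.0))


def great_circle_km(lon1, lat1, lon2, lat2):
    """Haversine great-circle distance in km (array-safe)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float)) for v in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(h)))


def behrmann_project(lon, lat):
    """Forward Behrmann projection (degrees -> km): x = R lam cos30, y = R sin(phi)/cos30."""
    lam = np.radians(np.asarray(lon, dtype=float))
    phi = np.radians(np.asarray(lat, dtype=float))
    return EARTH_RADIUS_KM * lam * _COS30, EARTH_RADIUS_KM * np.sin(phi) / _COS30


def behrmann_unproject(x, y):
    """Inverse Behrmann projection (km -> degrees)."""
    lon = np.degrees(np.asarray(x, dtype=float) / (EARTH_RADIUS_KM * _COS30))
    lat = np.degrees(np.arcsin(np.clip(np.asarray(y, dtype=float) * _COS30 / EARTH_RADIUS_KM, -1.0, 1.0)))
    return lon, lat


# ---------------------------------------------------------------------------
# equal-area grid


@dataclass(frozen=True)
class GridSpec:
    """Equal-area grid of ``cell_km`` squares in Behrmann-projected space.

    ``x0, y0`` is the lower-left corner (km); cells are indexed row-major from
    the south-west, cell index = row * ncols + col.
    """

    x0: float
    y0: float
    ncols: int
    nrows: int
    cell_km: float = 100.0

    @property
    def n_cells(self) -> int:
        return self.ncols * self.nrows

    @classmethod
    def from_lonlat(cls, lon_min, lon_max, lat_min, lat_max, cell_km: float = 100.0) -> "GridSpec":
        x0, y0 = behrmann_project(lon_min, lat_min)
        x1, y1 = behrmann_project(lon_max, lat_max)
        ncols = int(math.ceil((x1 - x0) / cell_km))
        nrows = int(math.ceil((y1 - y0) / cell_km))
        return cls(x0=float(x0), y0=float(y0), ncols=ncols, nrows=nrows, cell_km=cell_km)

    @classmethod
    def north_america(cls, cell_km: float = 100.0) -> "GridSpec":
        """Default continental window (168.5W-51.5W, 6N-84N)."""
        return cls.from_lonlat(-168.5, -51.5, 6.0, 84.0, cell_km=cell_km)

    def cell_centers_xy(self):
        """Projected (x, y) centers, each of length n_cells, row-major order."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        cx = self.x0 + (cols + 0.5) * self.cell_km
        cy = self.y0 + (rows + 0.5) * self.cell_km
        xx, yy = np.meshgrid(cx, cy)
        return xx.ravel(), yy.ravel()

    def cell_centers_lonlat(self):
        x, y = self.cell_centers_xy()
        return behrmann_unproject(x, y)

    def assign_xy(self, x, y, names: Sequence[str] | None = None) -> np.ndarray:
        """Nearest-center cell index for projected points; boundary ties go to the lower index."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        tx = (x - self.x0) / self.cell_km
        ty = (y - self.y0) / self.cell_km
        bad = (tx < 0) | (tx > self.ncols) | (ty < 0) | (ty > self.nrows)
        if bad.any():
            who = [names[i] if names is not None else str(i) for i in np.nonzero(bad)[0]]
            raise ValueError(f"points outside grid extent: {who}")
        col = np.floor(tx).astype(int)
        on_edge = (tx == col) & (col > 0)
        col[on_edge] -= 1
        col = np.minimum(col, self.ncols - 1)
        row = np.floor(ty).astype(int)
        on_edge = (ty == row) & (row > 0)
        row[on_edge] -= 1
        row = np.minimum(row, self.nrows - 1)
        return row * self.ncols + col

    def assign_lonlat(self, lon, lat, names: Sequence[str] | None = None) -> np.ndarray:
        x, y = behrmann_project(lon, lat)
        return self.assign_xy(x, y, names=names)


def assign_to_cells(sites: Iterable, grid: GridSpec) -> dict:
    """Map species -> set of occupied cell indices; co-located sites share a cell.

    ``sites`` are :class:`~paleobeta.occurrences.SiteAssemblage` objects.  Each
    site maps to exactly one nearest-center cell, so spatially clustered sites
    never inflate occupancy.
    """
    sites = list(sites)
    if not sites:
        return {}
    idx = grid.assign_lonlat([s.lon for s in sites], [s.lat for s in sites], names=[s.site_id for s in sites])
    cells: dict = {}
    for s, cell in zip(sites, idx):
        for sp in s.species:
            cells.setdefault(sp, set()).add(int(cell))
    return cells


def occupancy(cells: set, grid: GridSpec) -> float:
    """Proportion of grid cells occupied."""
    return len(cells) / grid.n_cells


# ---------------------------------------------------------------------------
# cluster-hull range size


def _single_linkage_clusters(points: np.ndarray) -> list:
    """Nearest-neighbour single-linkage clustering of projected points.

    Greedy growth: the cheapest move at each step is either (a) attaching an
    unassigned point to the cluster to whose three nearest members it has the
    smallest mean distance, or (b) seeding a new cluster from an unassigned
    point and its two nearest unassigned neighbours (scored by the triple's
    mean pairwise distance).  Joins are preferred on ties, then lowest point
    index, which makes the procedure fully deterministic.
    """
    n = len(points)
    if n == 0:
        return []
    if n <= 2:
        return [list(range(n))]
    D = squareform(pdist(points))
    unassigned = np.ones(n, dtype=bool)
    clusters: list = []
    # per cluster: the three smallest point-to-member distances (n x 3, sorted)
    # and the derived join score (mean over min(3, |cluster|) nearest members),
    # updated incrementally as members join
    top3: list = []
    scores: list = []

    def _new_cluster(members) -> None:
        members = list(members)
        clusters.append(members)
        cols = np.sort(D[:, members], axis=1)
        t = np.full((n, 3), np.inf)
        k = min(3, len(members))
        t[:, :k] = cols[:, :k]
        top3.append(t)
        scores.append(t[:, :k].mean(axis=1))

    def _add_member(ci: int, p: int) -> None:
        clusters[ci].append(p)
        stacked = np.column_stack([top3[ci], D[:, p]])
        stacked.sort(axis=1)
        top3[ci] = stacked[:, :3]
        k = min(3, len(clusters[ci]))
        scores[ci] = top3[ci][:, :k].mean(axis=1)

    while unassigned.any():
        ua = np.nonzero(unassigned)[0]
        best = None  # (score, kind, point index, payload); kind 0 = join, 1 = seed
        if clusters:
            S = np.column_stack(scores)[ua]
            j, ci = np.unravel_index(int(np.argmin(S)), S.shape)
            best = (float(S[j, ci]), 0, int(ua[j]), (int(ci), int(ua[j])))
        if len(ua) >= 3:
            sub = D[np.ix_(ua, ua)].copy()
            np.fill_diagonal(sub, np.inf)
            nn2 = np.argpartition(sub, 1, axis=1)[:, :2]
            rows = np.arange(len(ua))
            tri = (sub[rows, nn2[:, 0]] + sub[rows, nn2[:, 1]] + sub[nn2[:, 0], nn2[:, 1]]) / 3.0
            j = int(np.argmin(tri))
            trio = (int(ua[j]), int(ua[nn2[j, 0]]), int(ua[nn2[j, 1]]))
            cand = (float(tri[j]), 1, trio[0], trio)
            if best is None or cand[:3] < best[:3]:
                best = cand
        if best is None:
            # fewer than 3 points remain and no cluster exists yet
            _new_cluster(ua.tolist())
            unassigned[ua] = False
            continue
        _, kind, _, payload = best
        if kind == 0:
            ci, p = payload
            _add_member(ci, p)
            unassigned[p] = False
        else:
            _new_cluster(payload)
            unassigned[list(payload)] = False
    return clusters


def _hull_area(points: np.ndarray) -> float:
    """Convex-hull area (km^2); 0 for < 3 distinct points or collinear sets."""
    if len(np.unique(points, axis=0)) < 3:
        return 0.0
    return float(MultiPoint([tuple(p) for p in points]).convex_hull.area)


def cluster_hull_range(points: np.ndarray, level: float = 0.95, min_points: int = 5) -> float:
    """Range area (km^2) as summed convex hulls of single-linkage point clusters.

    Clusters are retained in order of decreasing size (then increasing mean
    distance of members to the cluster centroid, then lowest member index)
    until at least ``level`` of the points are enclosed; outlying small
    clusters beyond that coverage are excluded, which is what makes this a
    95%-level estimate.  Raises for fewer than ``min_points`` points.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < min_points:
        raise ValueError(f"cluster_hull_range needs >= {min_points} points, got {len(points)}")
    clusters = _single_linkage_clusters(points)

    def sort_key(members):
        pts = points[members]
        centroid = pts.mean(axis=0)
        spread = float(np.linalg.norm(pts - centroid, axis=1).mean())
        return (-len(members), spread, min(members))

    ordered = sorted(clusters, key=sort_key)
    covered = 0
    area = 0.0
    target = level * len(points)
    for members in ordered:
        area += _hull_area(points[members])
        covered += len(members)
        if covered >= target - 1e-9:
            break
    return area


@dataclass(frozen=True)
class RangeEstimate:
    """Per-species per-bin range area and grid occupancy."""

    species_id: str
    bin_label: str
    n_points: int
    area_km2: float
    occupancy: float


def range_estimates(binned, grid: GridSpec, level: float = 0.95, min_points: int = 5) -> list:
    """Cluster-hull range area and occupancy for every qualifying species/bin.

    A species qualifies for a hull in a bin when it occurs at >= ``min_points``
    sites there; occupancy is computed for every species in the bin regardless
    (occupancy of sparsely recorded species is still defined).  Species below
    the point threshold get ``area_km2 = nan``.
    """
    out = []
    for lab, members in binned.bins:
        if not members:
            continue
        cells = assign_to_cells(members, grid)
        coords: dict = {}
        for s in members:
            for sp in s.species:
                coords.setdefault(sp, []).append((s.lon, s.lat))
        skipped = 0
        for sp in sorted(coords):
            lonlat = np.asarray(coords[sp], dtype=float)
            x, y = behrmann_project(lonlat[:, 0], lonlat[:, 1])
            pts = np.column_stack([x, y])
            if len(pts) >= min_points:
                area = cluster_hull_range(pts, level=level, min_points=min_points)
            else:
                area = float("nan")
                skipped += 1
            out.append(
                RangeEstimate(
                    species_id=sp,
                    bin_label=lab,
                    n_points=len(pts),
                    area_km2=area,
                    occupancy=occupancy(cells[sp], grid),
                )
            )
        if skipped:
            logger.info("bin %s: %d species below the %d-site range threshold", lab, skipped, min_points)
    return out


def mean_range_size(binned, grid: GridSpec, level: float = 0.95, min_points: int = 5):
    """Per-bin mean range area (+/- SEM) and mean occupancy (+/- SD) as a DataFrame."""
    import pandas as pd

    estimates = range_estimates(binned, grid, level=level, min_points=min_points)
    rows = []
    for lab in binned.labels:
        areas = np.asarray([e.area_km2 for e in estimates if e.bin_label == lab and np.isfinite(e.area_km2)])
        occs = np.asarray([e.occupancy for e in estimates if e.bin_label == lab])
        if areas.size == 0:
            warnings.warn(f"bin {lab}: no species meet the {min_points}-site range threshold")
        rows.append(
            {
                "bin": lab,
                "mean_area_km2": float(areas.mean()) if areas.size else float("nan"),
                "sem_area_km2": float(areas.std(ddof=1) / math.sqrt(areas.size)) if areas.size > 1 else 0.0,
                "n_species_area": int(areas.size),
                "mean_occupancy": float(occs.mean()) if occs.size else float("nan"),
                "sd_occupancy": float(occs.std(ddof=1)) if occs.size > 1 else 0.0,
                "n_species_occupancy": int(occs.size),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# distance decay of similarity


@dataclass(frozen=True)
class DecayFit:
    """Distance-decay regression: similarity ~ exp(intercept + slope * km)."""

    slope: float
    intercept: float
    deviance: float
    family: str


def distance_decay(similarities, distances_km, family: str = "binomial_log") -> DecayFit:
    """Regress pairwise similarity on great-circle distance.

    Default is a binomial GLM with log link (classic exponential decay for a
    bounded similarity); ``family="ols"`` fits ordinary least squares instead.
    """
    import statsmodels.api as sm

    y = np.asarray(similarities, dtype=float)
    d = np.asarray(distances_km, dtype=float)
    if y.shape != d.shape or y.size < 3:
        raise ValueError("need equal-length similarity/distance arrays with >= 3 pairs")
    if not (np.isfinite(y).all() and np.isfinite(d).all()):
        raise ValueError("non-finite inputs to distance_decay")
    X = sm.add_constant(d)
    if family == "ols":
        res = sm.OLS(y, X).fit()
        return DecayFit(slope=float(res.params[1]), intercept=float(res.params[0]),
                        deviance=float(res.ssr), family="ols")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial(link=sm.families.links.Log()))
        res = model.fit(start_params=np.array([math.log(max(y.mean(), 1e-6)), 0.0]), maxiter=200)
    return DecayFit(slope=float(res.params[1]), intercept=float(res.params[0]),
                    deviance=float(res.deviance), family="binomial_log")


# ---------------------------------------------------------------------------
# multivariate dispersion (distance to group centroid in PCoA space)


def multivariate_dispersion(dissimilarity: np.ndarray, groups: Sequence) -> dict:
    """Mean distance to group centroid in a principal-coordinates embedding.

    Follows Anderson's treatment of negative eigenvalues: squared distances on
    imaginary axes are subtracted from those on real axes before the square
    root (clipped at zero).  ``dissimilarity`` is a square symmetric matrix
    with zero diagonal; ``groups`` labels its rows.
    """
    D = np.asarray(dissimilarity, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("dissimilarity must be a square symmetric matrix")
    n = D.shape[0]
    groups = np.asarray(groups)
    A = -0.5 * D ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    eigval, eigvec = np.linalg.eigh((G + G.T) / 2.0)
    tol = 1e-10 * max(1.0, float(np.abs(eigval).max()))
    pos = eigval > tol
    neg = eigval < -tol
    Xr = eigvec[:, pos] * np.sqrt(eigval[pos])
    Xi = eigvec[:, neg] * np.sqrt(-eigval[neg])
    out = {}
    for g in dict.fromkeys(groups.tolist()):
        mask = groups == g
        cr = Xr[mask].mean(axis=0) if Xr.size else np.zeros(0)
        ci = Xi[mask].mean(axis=0) if Xi.size else np.zeros(0)
        d2 = np.zeros(int(mask.sum()))
        if Xr.size:
            d2 += ((Xr[mask] - cr) ** 2).sum(axis=1)
        if Xi.size:
            d2 -= ((Xi[mask] - ci) ** 2).sum(axis=1)
        out[g] = float(np.sqrt(np.clip(d2, 0.0, None)).mean())
    return out


# ---------------------------------------------------------------------------
# space-for-time similarity map


def space_for_time_map(
    occupancy_matrix: np.ndarray,
    grid: GridSpec,
    window_km: float = 1000.0,
    n_subsample: int = 10,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-cell mean Jaccard similarity of inverse-distance-sampled neighbours.

    ``occupancy_matrix`` is species x cells boolean.  For each occupied focal
    cell, neighbouring occupied cells within ``window_km`` (great circle
    between cell centers) are sampled without replacement with probability
    proportional to 1/distance; the cell's value is the mean pairwise Jaccard
    similarity among the sampled cell assemblages.  Cells with no occupied
    neighbour (or unoccupied cells) are NaN.  Returns an (nrows, ncols) array.
    """
    rng = np.random.default_rng() if rng is None else rng
    occ = np.asarray(occupancy_matrix, dtype=bool)
    if occ.size == 0:
        raise ValueError("empty occupancy matrix")
    occupied = np.nonzero(occ.any(axis=0))[0]
    lon, lat = grid.cell_centers_lonlat()
    values = np.full(grid.n_cells, np.nan)
    sub = occ[:, occupied].astype(np.int64)
    for k, cell in enumerate(occupied):
        d = great_circle_km(lon[cell], lat[cell], lon[occupied], lat[occupied])
        near = np.nonzero((d > 0) & (d <= window_km))[0]
        if near.size == 0:
            continue
        take = min(n_subsample, near.size)
        w = 1.0 / d[near]
        chosen = rng.choice(near, size=take, replace=False, p=w / w.sum())
        if take < 2:
            chosen = np.append(chosen, k)  # pair the lone neighbour with the focal cell
        block = sub[:, chosen]
        shared = block.T @ block
        r = block.sum(axis=0)
        iu = np.triu_indices(len(chosen), k=1)
        a = shared[iu]
        union = r[iu[0]] + r[iu[1]] - a
        with np.errstate(invalid="ignore"):
            jac = np.where(union > 0, a / np.maximum(union, 1), np.nan)
        values[cell] = float(np.nanmean(jac))
    return values.reshape(grid.nrows, grid.ncols)
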