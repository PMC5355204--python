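"""Brownian-bridge utilization distributions, isopleths, land subtraction, overlap.

The Brownian bridge movement model treats the path between two successive
fixes ``z_i`` (time ``t_i``) and ``z_{i+1}`` as a conditioned Brownian motion.
At bridge fraction ``alpha`` the animal's position is bivariate normal with

    mean      (1 - alpha) z_i + alpha z_{i+1}
    variance  T alpha (1 - alpha) sig1^2
              + (1 - alpha)^2 sig2_i^2 + alpha^2 sig2_{i+1}^2

where ``T = t_{i+1} - t_i``, ``sig1`` scales the animal's motion variance
(km / sqrt(hr)) and ``sig2_i`` is the location-error SD (km) of fix ``i``.
A step's contribution to the utilization distribution (UD) is the
``alpha``-quadrature average of that density, weighted by ``T``; the summed
surface is normalized to unit mass over the grid.

All bridge math is planar, in a local azimuthal-equidistant projection
centered on the track centroid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator

from .geodesy import to_local_plane

#: Location-error SD (km) by Argos quality class: 68th-percentile errors from
#: GPS double-tagging calibration.
DEFAULT_ERROR_MODEL = {"3": 0.5, "2": 1.0, "1": 1.2, "0": 4.2, "A": 6.2, "B": 10.3}


@dataclass
class BridgeParams:
    """Smoothing and quadrature parameters of the bridge estimator."""

    sig1: float = 1.0           # motion SD scale, km / sqrt(hr)
    max_gap_hr: float = 24.0    # steps longer than this are excluded
    alpha_steps: int = 25       # midpoint-rule quadrature points per bridge

    def validate(self) -> None:
        if self.sig1 < 0:
            raise ValueError("sig1 must be nonnegative")
        if self.alpha_steps < 3:
            raise ValueError("alpha_steps must be >= 3")


@dataclass
class UDGrid:
    """Gridded probability surface in the local plane.

    Cell centers are at ``x0 + j * cell_km`` / ``y0 + i * cell_km``;
    ``probs[i, j]`` is the probability mass of cell (row i, col j) and sums
    to 1 over the grid.
    """

    x0: float
    y0: float
    cell_km: float
    probs: np.ndarray
    lon0: float = 0.0
    lat0: float = 0.0
    animal_id: str = ""
    month: str = ""

    def same_geometry(self, other: "UDGrid") -> bool:
        return (self.probs.shape == other.probs.shape
                and np.isclose(self.x0, other.x0)
                and np.isclose(self.y0, other.y0)
                and np.isclose(self.cell_km, other.cell_km))


@dataclass
class Isopleth:
    """Smallest cell set holding ``level`` of a UD's mass."""

    level: float
    mask: np.ndarray            # boolean, same shape as the source UD
    cell_km: float
    area_km2: float
    area_km2_land_free: float | None = None
    grid: UDGrid | None = field(default=None, repr=False)


def bb_step_density(z1, z2, t1: float, t2: float, params: BridgeParams,
                    grid: UDGrid, sig2_1: float, sig2_2: float) -> np.ndarray:
    """Un-normalized UD contribution of one step, already weighted by T.

    ``z1``/``z2`` are (x, y) km in the grid's plane, times in hours. Returns
    an array shaped like ``grid.probs`` holding T times the quadrature
    average of the bridge density integrated over each cell (midpoint
    approximation: density at the cell center times cell area).
    """
    T = float(t2) - float(t1)
    if T <= 0:
        warnings.warn("non-positive step duration; step skipped")
        return np.zeros_like(grid.probs)
    params.validate()
    ny, nx = grid.probs.shape
    xs = grid.x0 + grid.cell_km * np.arange(nx)
    ys = grid.y0 + grid.cell_km * np.arange(ny)
    z1 = np.asarray(z1, float)
    z2 = np.asarray(z2, float)

    from scipy.special import ndtr

    m = params.alpha_steps
    alphas = (np.arange(m) + 0.5) / m
    out = np.zeros((ny, nx))
    half = grid.cell_km / 2.0
    for a in alphas:
        mu = (1.0 - a) * z1 + a * z2
        var = (T * a * (1.0 - a) * params.sig1 ** 2
               + (1.0 - a) ** 2 * sig2_1 ** 2 + a ** 2 * sig2_2 ** 2)
        if var <= 0:
            # degenerate point mass: all density in the containing cell
            j = int(round((mu[0] - grid.x0) / grid.cell_km))
            i = int(round((mu[1] - grid.y0) / grid.cell_km))
            if 0 <= i < ny and 0 <= j < nx:
                out[i, j] += 1.0
            continue
        # exact bivariate-normal mass per cell: product of 1-D CDF differences
        sd = np.sqrt(var)
        gx = ndtr((xs + half - mu[0]) / sd) - ndtr((xs - half - mu[0]) / sd)
        gy = ndtr((ys + half - mu[1]) / sd) - ndtr((ys - half - mu[1]) / sd)
        out += np.outer(gy, gx)
    return out * (T / m)


def bridge_loglik(sig1: float, xy: np.ndarray, t_hr: np.ndarray,
                  sig2: np.ndarray, max_gap_hr: float = np.inf) -> float:
    """Leave-one-out bridge log-likelihood of ``sig1``.

    Every odd-indexed fix is scored under the bridge formed by its two
    neighbours at its own time fraction ``alpha``; the independent even fixes
    define the bridges. This is the likelihood the ML smoothing-parameter
    search maximizes.
    """
    ll = 0.0
    n_used = 0
    for i in range(1, len(t_hr) - 1, 2):
        T = t_hr[i + 1] - t_hr[i - 1]
        if T <= 0 or T > max_gap_hr:
            continue
        a = (t_hr[i] - t_hr[i - 1]) / T
        mu = (1.0 - a) * xy[i - 1] + a * xy[i + 1]
        var = (T * a * (1.0 - a) * sig1 ** 2
               + (1.0 - a) ** 2 * sig2[i - 1] ** 2 + a ** 2 * sig2[i + 1] ** 2)
        if var <= 0:
            return -np.inf
        d2 = np.sum((xy[i] - mu) ** 2)
        ll += -np.log(2.0 * np.pi * var) - d2 / (2.0 * var)
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable fix triples for the likelihood")
    return ll


def estimate_sig1(track: pd.DataFrame,
                  error_model: dict = None,
                  search_interval=(1e-3, 50.0),
                  max_gap_hr: float = np.inf) -> float:
    """ML estimate of the motion parameter ``sig1`` (km/sqrt(hr)).

    ``track`` needs columns timestamp, lon, lat and (for per-fix error SDs)
    lc; at least 3 fixes. Maximization is bounded golden-section over
    ``search_interval``; a flat likelihood returns the interval boundary
    with a warning.
    """
    if len(track) < 3:
        raise ValueError("sig1 estimation needs at least 3 fixes")
    error_model = dict(DEFAULT_ERROR_MODEL if error_model is None else error_model)
    lon = track["lon"].to_numpy(float)
    lat = track["lat"].to_numpy(float)
    x, y = to_local_plane(lon, lat, float(lon.mean()), float(lat.mean()))
    xy = np.column_stack([x, y])
    t_hr = (pd.to_datetime(track["timestamp"]).astype("int64").to_numpy()
            / 1e9 / 3600.0)
    t_hr = t_hr - t_hr[0]
    if "lc" in track.columns:
        sig2 = track["lc"].astype(str).map(error_model).to_numpy(float)
    else:
        sig2 = np.zeros(len(track))

    res = minimize_scalar(
        lambda s: -bridge_loglik(s, xy, t_hr, sig2, max_gap_hr),
        bounds=search_interval, method="bounded",
        options={"xatol": 1e-4 * (search_interval[1] - search_interval[0])})
    sig1 = float(res.x)
    lo, hi = search_interval
    tol = 1e-3 * (hi - lo)
    if sig1 - lo < tol or hi - sig1 < tol:
        warnings.warn("sig1 estimate at the boundary of the search interval; "
                      "the likelihood may be flat")
    return sig1


def make_grid(xy: np.ndarray, cell_km: float, margin_km: float,
              lon0: float = 0.0, lat0: float = 0.0) -> UDGrid:
    """Regular grid covering the fixes plus a margin on every side."""
    xmin, ymin = xy.min(axis=0) - margin_km
    xmax, ymax = xy.max(axis=0) + margin_km
    nx = max(2, int(np.ceil((xmax - xmin) / cell_km)) + 1)
    ny = max(2, int(np.ceil((ymax - ymin) / cell_km)) + 1)
    return UDGrid(x0=float(xmin), y0=float(ymin), cell_km=cell_km,
                  probs=np.zeros((ny, nx)), lon0=lon0, lat0=lat0)


def _month_key(ts: pd.Timestamp) -> str:
    return f"{ts.year:04d}-{ts.month:02d}"


def bb_ud(track: pd.DataFrame, params: BridgeParams,
          error_model: dict = None, cell_km: float = 1.0,
          margin_factor: float = 3.0, monthly: bool = True,
          grid: UDGrid = None) -> list[UDGrid]:
    """Brownian-bridge UDs for one animal (or a pooled multi-animal table).

    Steps join consecutive fixes within each animal; steps longer than
    ``params.max_gap_hr`` are excluded. With ``monthly=True`` one UD is
    returned per calendar month (UTC) of the step's start fix; months with
    fewer than 2 fixes are omitted with a warning. Each UD sums to 1.
    """
    params.validate()
    error_model = dict(DEFAULT_ERROR_MODEL if error_model is None else error_model)
    track = track.assign(timestamp=pd.to_datetime(track["timestamp"]))
    lon = track["lon"].to_numpy(float)
    lat = track["lat"].to_numpy(float)
    lon0, lat0 = float(lon.mean()), float(lat.mean())
    x, y = to_local_plane(lon, lat, lon0, lat0)
    xy = np.column_stack([x, y])
    if grid is None:
        margin = margin_factor * max(error_model.values())
        grid = make_grid(xy, cell_km, margin, lon0, lat0)

    t_hr = track["timestamp"].astype("int64").to_numpy() / 1e9 / 3600.0
    sig2 = (track["lc"].astype(str).map(error_model).to_numpy(float)
            if "lc" in track.columns else np.zeros(len(track)))
    groups = (track.groupby("animal_id", sort=False).indices.values()
              if "animal_id" in track.columns else [np.arange(len(track))])

    sums: dict[str, np.ndarray] = {}
    fix_counts: dict[str, int] = {}
    for idx in groups:
        idx = np.asarray(idx)
        for k, mon in zip(idx, track["timestamp"].iloc[idx]):
            key = _month_key(mon) if monthly else "all"
            fix_counts[key] = fix_counts.get(key, 0) + 1
        for a, b in zip(idx[:-1], idx[1:]):
            T = t_hr[b] - t_hr[a]
            if T <= 0 or T > params.max_gap_hr:
                continue
            key = _month_key(track["timestamp"].iloc[a]) if monthly else "all"
            contrib = bb_step_density(xy[a], xy[b], t_hr[a], t_hr[b],
                                      params, grid, sig2[a], sig2[b])
            sums[key] = sums.get(key, 0) + contrib

    out = []
    for key in sorted(fix_counts):
        if fix_counts[key] < 2 or key not in sums:
            warnings.warn(f"month {key}: fewer than 2 usable fixes; omitted")
            continue
        total = sums[key].sum()
        if total <= 0:
            warnings.warn(f"month {key}: zero UD mass (all steps off-grid?); omitted")
            continue
        out.append(UDGrid(grid.x0, grid.y0, grid.cell_km, sums[key] / total,
                          grid.lon0, grid.lat0,
                          str(track["animal_id"].iloc[0]) if "animal_id" in track else "",
                          key if monthly else ""))
    return out


def isopleth(ud: UDGrid, level: float) -> Isopleth:
    """Smallest cell set, by descending probability, holding ``level`` mass.

    Ties are broken deterministically by (probability desc, row, column).
    """
    if not 0.0 < level <= 1.0:
        raise ValueError("level must lie in (0, 1]")
    p = ud.probs
    ny, nx = p.shape
    rows, cols = np.divmod(np.arange(p.size), nx)
    order = np.lexsort((cols, rows, -p.ravel()))
    csum = np.cumsum(p.ravel()[order])
    n_cells = int(np.searchsorted(csum, level - 1e-12) + 1)
    n_cells = min(n_cells, int((p.ravel() > 0).sum())) if level >= 1.0 else n_cells
    mask = np.zeros(p.size, bool)
    mask[order[:n_cells]] = True
    mask = mask.reshape(ny, nx)
    area = n_cells * ud.cell_km ** 2
    return Isopleth(level=level, mask=mask, cell_km=ud.cell_km,
                    area_km2=float(area), grid=ud)


def subtract_land(iso: Isopleth, land) -> Isopleth:
    """Subtract the land-intersection area from an isopleth.

    ``land`` is a shapely (multi)polygon in lon/lat degrees; it is projected
    into the isopleth's plane and intersected cell by cell.
    """
    from shapely.geometry import box
    from shapely.ops import transform as shp_transform
    from shapely.validation import explain_validity

    if iso.grid is None:
        raise ValueError("isopleth carries no grid geometry")
    if not land.is_valid:
        raise ValueError(f"invalid land polygon: {explain_validity(land)}")
    g = iso.grid
    land_plane = shp_transform(
        lambda lon, lat: to_local_plane(np.asarray(lon), np.asarray(lat),
                                        g.lon0, g.lat0), land)
    half = g.cell_km / 2.0
    covered = 0.0
    ii, jj = np.nonzero(iso.mask)
    for i, j in zip(ii, jj):
        cx, cy = g.x0 + j * g.cell_km, g.y0 + i * g.cell_km
        cell = box(cx - half, cy - half, cx + half, cy + half)
        if land_plane.intersects(cell):
            covered += land_plane.intersection(cell).area
    out = Isopleth(iso.level, iso.mask, iso.cell_km, iso.area_km2, grid=iso.grid)
    out.area_km2_land_free = max(0.0, iso.area_km2 - covered)
    return out


def overlap_fraction(iso_a: Isopleth, iso_b: Isopleth) -> tuple[float, float]:
    """Fractions (area(a∩b)/area(a), area(a∩b)/area(b)) on a shared grid."""
    if iso_a.mask.shape != iso_b.mask.shape or not np.isclose(
            iso_a.cell_km, iso_b.cell_km):
        raise ValueError("isopleths live on mismatched grids")
    if iso_a.grid is not None and iso_b.grid is not None \
            and not iso_a.grid.same_geometry(iso_b.grid):
        raise ValueError("isopleths live on mismatched grids")
    inter = float(np.logical_and(iso_a.mask, iso_b.mask).sum())
    na, nb = float(iso_a.mask.sum()), float(iso_b.mask.sum())
    return (inter / na if na else 0.0, inter / nb if nb else 0.0)


class BrownianBridgeUD(BaseEstimator):
    """Brownian-bridge UD estimator with sklearn conventions.

    ``fit`` takes a filtered location table (one animal, or several when
    pooling a species), estimates ``sig1`` by maximum likelihood when
    ``sig1="estimate"``, computes (monthly) UDs and extracts isopleths.

    Fitted attributes: ``sig1_``, ``uds_`` (list of :class:`UDGrid`),
    ``isopleths_`` (dict (month, level) -> :class:`Isopleth`).
    """

    def __init__(self, sig1="estimate", error_model=None, cell_km: float = 1.0,
                 margin_factor: float = 3.0, alpha_steps: int = 25,
                 max_gap_hr: float = 24.0, levels=(0.50, 0.90),
                 monthly: bool = True, sig1_search=(1e-3, 50.0)):
        self.sig1 = sig1
        self.error_model = error_model
        self.cell_km = cell_km
        self.margin_factor = margin_factor
        self.alpha_steps = alpha_steps
        self.max_gap_hr = max_gap_hr
        self.levels = levels
        self.monthly = monthly
        self.sig1_search = sig1_search

    def fit(self, X: pd.DataFrame, y=None):
        if self.sig1 == "estimate":
            self.sig1_ = estimate_sig1(X, self.error_model, self.sig1_search,
                                       self.max_gap_hr)
        else:
            self.sig1_ = float(self.sig1)
        params = BridgeParams(sig1=self.sig1_, max_gap_hr=self.max_gap_hr,
                              alpha_steps=self.alpha_steps)
        self.uds_ = bb_ud(X, params, self.error_model, self.cell_km,
                          self.margin_factor, self.monthly)
        self.isopleths_ = {}
        for ud in self.uds_:
            for lev in self.levels:
                self.isopleths_[(ud.month, lev)] = isopleth(ud, lev)
        return self
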