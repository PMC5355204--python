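"""Synthetic data generators for the telemetry-and-genetics pipeline.

Three generators emulate the data the analysis consumes, with full generating
truth retained so every downstream stage can be tested without field data:

* :func:`simulate_tracks` — two-state (haul-out / at-sea) movement with
  Argos-class positional error and gross outliers;
* :func:`simulate_dive_histograms` — multinomial dive counts in 10 depth and
  10 duration bins per 6-hr interval, with controllable focus;
* :func:`simulate_genotypes` — two-population Hardy-Weinberg diploid
  microsatellite genotypes with optional F1 hybrids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd

from .geodesy import from_local_plane, to_local_plane

ARGOS_CLASSES = ("3", "2", "1", "0", "A", "B", "Z")

#: Isotropic positional error SD (km) by Argos quality class, from GPS
#: double-tagging calibration (68th percentile error). Class Z carries no
#: usable position; it is given a nominal large SD for simulation only.
DEFAULT_CLASS_ERROR_KM = {"3": 0.5, "2": 1.0, "1": 1.2, "0": 4.2,
                          "A": 6.2, "B": 10.3, "Z": 15.0}

#: Pre-filter Argos class mix reconstructed from the study dataset's reported
#: composition of discarded and retained fixes, with a nominal 1% class Z.
DEFAULT_CLASS_PROBS = {"3": 0.047, "2": 0.077, "1": 0.134, "0": 0.095,
                       "A": 0.244, "B": 0.393, "Z": 0.010}


def _rng(seed: int, *stream) -> np.random.Generator:
    """Deterministic sub-stream derived from one global integer seed."""
    return np.random.default_rng([int(seed)] + [int(s) for s in stream])


@dataclass
class SimTrackParams:
    """Parameters of the two-state movement simulator.

    The animal alternates haul-out bouts (stationary at a haul-out site) and
    at-sea bouts (correlated random walk pinned to start and end at haul-out
    sites) with exponential bout durations. Argos fixes arrive as a Poisson
    process; each fix gets a quality class, isotropic positional error with a
    class-specific SD, and optionally a gross outlier displacement.
    """

    n_animals: int = 5
    start_date: str = "2000-09-15"
    n_days: int = 30
    haulout_sites: list = field(default_factory=lambda: [(-157.5, 58.3), (-157.0, 57.8)])
    trip_rate: float = 0.5          # expected at-sea trips per day
    trip_step_km: float = 2.5      # mean hourly step of the at-sea walk (km)
    turn_concentration: float = 0.8  # directional persistence in [0, 1]
    haulout_mean_hr: float = 8.0   # mean haul-out bout duration
    fix_rate_per_day: float = 8.0
    class_probs: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PROBS))
    class_error_km: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_ERROR_KM))
    outlier_fraction: float = 0.0
    outlier_km: float = 100.0
    seed: int = 0

    def validate(self) -> None:
        if not self.haulout_sites:
            raise ValueError("haulout_sites must contain at least one lon/lat point")
        total = sum(self.class_probs.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"class_probs must sum to 1 (got {total})")
        if any(v < 0 for v in self.class_error_km.values()):
            raise ValueError("class_error_km values must be nonnegative")
        for name in ("trip_rate", "trip_step_km", "fix_rate_per_day",
                     "outlier_fraction", "outlier_km", "haulout_mean_hr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 <= self.turn_concentration <= 1.0:
            raise ValueError("turn_concentration must lie in [0, 1]")


def _crw_path(rng, n_steps, step_km, persistence):
    """Hourly correlated-random-walk displacements in the local plane (km)."""
    kappa = 1e-9 + 20.0 * persistence / max(1e-9, (1.0 - persistence))
    headings = np.cumsum(np.concatenate([
        [rng.uniform(0, 2 * np.pi)], rng.vonmises(0.0, kappa, n_steps - 1)]))
    # gamma(4) step lengths: right-skewed but light-tailed, so hourly swim
    # speeds stay within a phocid's realistic range
    steps = rng.gamma(4.0, step_km / 4.0, n_steps)
    return np.cumsum(steps * np.cos(headings)), np.cumsum(steps * np.sin(headings))


def _simulate_animal(params: SimTrackParams, animal_idx: int) -> pd.DataFrame:
    rng = _rng(params.seed, animal_idx)
    total_hr = params.n_days * 24.0
    sites = np.asarray(params.haulout_sites, float)
    lon0, lat0 = sites.mean(axis=0)
    sites_xy = np.column_stack(to_local_plane(sites[:, 0], sites[:, 1], lon0, lat0))

    # Bout schedule: alternating haul-out / at-sea with exponential durations.
    # trip_rate trips/day fixes the mean cycle length; the haul-out share of
    # the cycle is haulout_mean_hr.
    cycle_hr = 24.0 / max(params.trip_rate, 1e-6)
    sea_mean_hr = max(cycle_hr - params.haulout_mean_hr, 1.0)
    bouts = []  # (t_start, t_end, hauled_out, site_from, site_to)
    t, site = 0.0, rng.integers(len(sites_xy))
    hauled = True
    while t < total_hr:
        if hauled:
            dur = rng.exponential(params.haulout_mean_hr)
            bouts.append((t, min(t + dur, total_hr), True, site, site))
        else:
            dur = rng.exponential(sea_mean_hr)
            nxt = rng.integers(len(sites_xy))
            bouts.append((t, min(t + dur, total_hr), False, site, nxt))
            site = nxt
        t += dur
        hauled = not hauled

    # Continuous true path sampled hourly, then interpolated at fix times.
    grid_t = [0.0]
    grid_xy = [sites_xy[bouts[0][3]]]
    for t0, t1, hauled, s_from, s_to in bouts:
        dur = t1 - t0
        if dur <= 0:
            continue
        n = max(2, int(np.ceil(dur)))
        tt = np.linspace(t0, t1, n + 1)[1:]
        if hauled:
            xy = np.tile(sites_xy[s_from], (n, 1))
        else:
            dx, dy = _crw_path(rng, n, params.trip_step_km * dur / n,
                               params.turn_concentration)
            # pin the walk to start at s_from and end at s_to (bridge correction)
            frac = np.arange(1, n + 1) / n
            xy = sites_xy[s_from] + np.column_stack([dx, dy])
            xy -= np.outer(frac, xy[-1] - sites_xy[s_to])
        grid_t.extend(tt)
        grid_xy.extend(xy)
    grid_t = np.asarray(grid_t)
    grid_xy = np.asarray(grid_xy)

    # Poisson fix times
    n_fix = rng.poisson(params.fix_rate_per_day * params.n_days)
    fix_t = np.sort(rng.uniform(0.0, total_hr, n_fix))
    fix_t = fix_t[np.concatenate([[True], np.diff(fix_t) > 1e-6])]
    tx = np.interp(fix_t, grid_t, grid_xy[:, 0])
    ty = np.interp(fix_t, grid_t, grid_xy[:, 1])
    hauled_at = np.zeros(fix_t.size, bool)
    for t0, t1, hauled, s_from, _ in bouts:
        if hauled:
            m = (fix_t >= t0) & (fix_t < t1)
            hauled_at |= m
            tx[m], ty[m] = sites_xy[s_from]

    classes = np.asarray(list(params.class_probs.keys()))
    lc = classes[rng.choice(len(classes), fix_t.size,
                            p=np.asarray(list(params.class_probs.values())))]
    err_sd = np.asarray([params.class_error_km[c] for c in lc])
    ox = tx + rng.normal(0.0, 1.0, fix_t.size) * err_sd
    oy = ty + rng.normal(0.0, 1.0, fix_t.size) * err_sd

    is_outlier = rng.random(fix_t.size) < params.outlier_fraction
    # keep outliers isolated in time: never two in a row
    for i in range(1, fix_t.size):
        if is_outlier[i] and is_outlier[i - 1]:
            is_outlier[i] = False
    n_out = int(is_outlier.sum())
    if n_out:
        theta = rng.uniform(0, 2 * np.pi, n_out)
        mag = params.outlier_km * (1.0 + rng.exponential(0.3, n_out))
        ox[is_outlier] += mag * np.cos(theta)
        oy[is_outlier] += mag * np.sin(theta)

    t0 = datetime.fromisoformat(params.start_date).replace(tzinfo=timezone.utc)
    stamps = [t0 + timedelta(hours=float(h)) for h in fix_t]
    lon, lat = from_local_plane(ox, oy, lon0, lat0)
    tlon, tlat = from_local_plane(tx, ty, lon0, lat0)
    return pd.DataFrame({
        "animal_id": f"SIM{animal_idx:03d}",
        "timestamp": stamps,
        "lon": lon, "lat": lat,
        "lc": lc,
        "hauled_out": hauled_at.astype(int),
        "true_lon": tlon, "true_lat": tlat,
        "outlier": is_outlier.astype(int),
    })


def simulate_tracks(params: SimTrackParams) -> pd.DataFrame:
    """Simulate Argos tracks for ``params.n_animals`` animals.

    Returns a time-ordered DataFrame per the location-CSV dialect
    (animal_id, timestamp, lon, lat, lc, hauled_out) plus the generating
    truth columns ``true_lon``, ``true_lat`` and ``outlier``.
    """
    params.validate()
    frames = [_simulate_animal(params, i) for i in range(params.n_animals)]
    return pd.concat(frames, ignore_index=True)


@dataclass
class SimDiveParams:
    """Parameters of the binned dive-histogram simulator.

    Per 6-hr interval the number of dives is Poisson and the dives fall into
    10 bins multinomially. The focal bin carries probability weight
    ``(1 + c) / (10 + c)`` where ``c = focus_concentration`` — 0 gives exactly
    uniform bin probabilities, large ``c`` concentrates all dives in one bin.
    ``effects`` shifts the focal-bin index additively by covariate level,
    e.g. ``{"species": {"spotted": 2}, "month": {11: 1}}``.
    """

    depth_bin_edges: tuple = (0, 4, 10, 20, 30, 40, 50, 75, 100, 150, 250)
    duration_bin_edges: tuple = (0, 1, 2, 3, 4, 5, 6, 8, 10, 15, 30)
    dives_per_interval: float = 25.0
    focus_concentration: float = 40.0
    base_focal_bin: int = 3          # 1-based focal bin before covariate shifts
    effects: dict = field(default_factory=dict)
    n_intervals_per_animal: int = 120
    start_date: str = "2000-09-15"
    seed: int = 0

    def validate(self) -> None:
        for edges in (self.depth_bin_edges, self.duration_bin_edges):
            if len(edges) != 11 or np.any(np.diff(edges) <= 0):
                raise ValueError("bin edges must be 11 strictly increasing values")
        if self.dives_per_interval <= 0:
            raise ValueError("dives_per_interval must be positive")
        if self.focus_concentration < 0:
            raise ValueError("focus_concentration must be nonnegative")


def _focal_probs(focal_bin: int, concentration: float) -> np.ndarray:
    if np.isinf(concentration):
        p = np.zeros(10)
        p[focal_bin - 1] = 1.0
        return p
    w = (1.0 + concentration) / (10.0 + concentration)
    p = np.full(10, (1.0 - w) / 9.0)
    p[focal_bin - 1] = w
    return p


def simulate_dive_histograms(params: SimDiveParams,
                             covariates: pd.DataFrame) -> pd.DataFrame:
    """Simulate per-interval depth and duration histograms for each animal.

    ``covariates`` must carry one row per animal with columns ``animal_id``,
    ``species``, ``sex`` and ``mass``. Output is long format: one row per
    (animal, interval, bin_type, bin), with truth column ``true_focal_bin``.
    """
    params.validate()
    required = {"animal_id", "species", "sex", "mass"}
    if not required.issubset(covariates.columns):
        raise ValueError(f"covariates must have columns {sorted(required)}")
    t0 = datetime.fromisoformat(params.start_date).replace(tzinfo=timezone.utc)
    rows = []
    for a_idx, cov in enumerate(covariates.itertuples(index=False)):
        rng = _rng(params.seed, 1, a_idx)
        for j in range(params.n_intervals_per_animal):
            start = t0 + timedelta(hours=6 * j)
            shift = 0
            for covar, level_map in params.effects.items():
                level = start.month if covar == "month" else getattr(cov, covar)
                shift += level_map.get(level, 0)
            focal = int(np.clip(params.base_focal_bin + shift, 1, 10))
            n_dives = rng.poisson(params.dives_per_interval)
            p = _focal_probs(focal, params.focus_concentration)
            for bin_type, edges in (("depth", params.depth_bin_edges),
                                    ("duration", params.duration_bin_edges)):
                counts = rng.multinomial(n_dives, p)
                for b in range(10):
                    rows.append((cov.animal_id, start, bin_type, b + 1,
                                 edges[b], edges[b + 1], counts[b], focal))
    return pd.DataFrame(rows, columns=[
        "animal_id", "interval_start", "bin_type", "bin_index",
        "bin_lower", "bin_upper", "count", "true_focal_bin"])


@dataclass
class SimGenotypeParams:
    """Parameters of the two-population microsatellite genotype simulator.

    Allele frequencies per species per locus are drawn from a symmetric
    Dirichlet with concentration ``divergence``: small values produce spiky,
    strongly diverged frequency vectors; ``inf`` makes both species exactly
    uniform (identical — no assignment information). ``diagnostic=True``
    instead gives the species disjoint allele sets (fully diagnostic loci).
    """

    n_loci: int = 20
    alleles_per_locus: int = 4
    divergence: float = 0.3
    n_per_species: tuple = (15, 15)
    n_f1: int = 0
    missing_rate: float = 0.0
    diagnostic: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.alleles_per_locus < 2:
            raise ValueError("alleles_per_locus must be >= 2")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


MISSING = -9


@dataclass
class GenotypeMatrix:
    """Diploid multilocus genotypes: integer allele labels, ``-9`` missing."""

    alleles: np.ndarray           # (n_individuals, n_loci, 2) int
    individual_ids: list
    labels: list                  # true origin: species name or "F1"
    locus_names: list

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]


def simulate_genotypes(params: SimGenotypeParams):
    """Simulate genotypes for two species plus optional F1 hybrids.

    Returns ``(GenotypeMatrix, freqs)`` where ``freqs`` is the true
    (2, n_loci, alleles_per_locus) frequency array. Pure individuals are
    Hardy-Weinberg draws from their species' frequencies; each F1 draws one
    allele per locus from each species.
    """
    params.validate()
    rng = _rng(params.seed, 2)
    L, m = params.n_loci, params.alleles_per_locus
    if params.diagnostic:
        half = m // 2
        if half < 1 or m - half < 1:
            raise ValueError("diagnostic loci need >= 2 alleles")
        freqs = np.zeros((2, L, m))
        freqs[0, :, :half] = 1.0 / half
        freqs[1, :, half:] = 1.0 / (m - half)
    elif np.isinf(params.divergence):
        freqs = np.full((2, L, m), 1.0 / m)
    else:
        freqs = rng.dirichlet(np.full(m, params.divergence), size=(2, L))

    species_names = ("species_A", "species_B")
    ids, labels, rows = [], [], []
    for sp in (0, 1):
        for i in range(params.n_per_species[sp]):
            g = np.stack([
                np.array([rng.choice(m, p=freqs[sp, l]) for l in range(L)]),
                np.array([rng.choice(m, p=freqs[sp, l]) for l in range(L)]),
            ], axis=1) + 1
            rows.append(g)
            ids.append(f"{species_names[sp]}_{i:03d}")
            labels.append(species_names[sp])
    for i in range(params.n_f1):
        g = np.stack([
            np.array([rng.choice(m, p=freqs[0, l]) for l in range(L)]),
            np.array([rng.choice(m, p=freqs[1, l]) for l in range(L)]),
        ], axis=1) + 1
        rows.append(g)
        ids.append(f"F1_{i:03d}")
        labels.append("F1")

    alleles = np.asarray(rows)          # (n, L, 2)
    if params.missing_rate > 0:
        miss = rng.random((alleles.shape[0], L)) < params.missing_rate
        alleles[miss] = MISSING
    return GenotypeMatrix(alleles, ids, labels,
                          [f"locus_{l + 1}" for l in range(L)]), freqs
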