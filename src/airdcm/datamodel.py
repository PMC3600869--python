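"""Domain types, validation, temporal aggregation and variable transforms.

Conventions used throughout the package:

* A monitoring network is *heterotopic*: each pollutant has its own site
  list and the lists may overlap arbitrarily or be disjoint.
* Missing observations are carried as ``NaN`` in float arrays (a dedicated
  in-memory flag, never 0); file formats use an empty field.
* The time index is a run of consecutive days, internally 0-based.
* Distances between sites are great-circle (haversine) kilometres for
  lon/lat coordinates, or planar kilometres for synthetic scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def haversine_km(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Great-circle distance matrix (km) between two (n,2) lon/lat arrays."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    lon1, lat1 = np.radians(a[:, 0])[:, None], np.radians(a[:, 1])[:, None]
    lon2, lat2 = np.radians(b[:, 0])[None, :], np.radians(b[:, 1])[None, :]
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    h = np.clip(h, 0.0, 1.0)
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))


def planar_km(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Euclidean distance matrix between two (n,2) coordinate arrays in km."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    d = a[:, None, :] - b[None, :, :]
    return np.sqrt((d ** 2).sum(axis=-1))


# ---------------------------------------------------------------------------
# network / observations
# ---------------------------------------------------------------------------

@dataclass
class StationNetwork:
    """Per-pollutant monitoring site lists.

    Parameters
    ----------
    pollutants : list of str
        Pollutant names, e.g. ``["NO2", "O3", "PM10"]``.
    site_ids : mapping pollutant -> list of str
        Site identifiers, unique within a pollutant.
    coords : mapping pollutant -> (n_i, 2) array
        Site coordinates (lon, lat in degrees, or x, y in km for the
        planar convention).
    distance : {"haversine", "planar"}
        Distance convention used for all covariance evaluations.
    """

    pollutants: List[str]
    site_ids: Dict[str, List[str]]
    coords: Dict[str, np.ndarray]
    distance: str = "haversine"

    def __post_init__(self) -> None:
        if self.distance not in ("haversine", "planar"):
            raise ValueError(f"unknown distance convention {self.distance!r}")
        for pol in self.pollutants:
            ids = self.site_ids[pol]
            if len(ids) != len(set(ids)):
                raise ValueError(f"duplicate site ids for pollutant {pol}")
            xy = np.asarray(self.coords[pol], dtype=float)
            if xy.ndim != 2 or xy.shape != (len(ids), 2):
                raise ValueError(f"coords for {pol} must be ({len(ids)}, 2)")
            if not np.all(np.isfinite(xy)):
                raise ValueError(f"non-finite coordinate for pollutant {pol}")
            if len(ids) < 1:
                raise ValueError(f"pollutant {pol} has no sites")
            self.coords[pol] = xy

    @property
    def q(self) -> int:
        return len(self.pollutants)

    def n_sites(self, pollutant: str) -> int:
        return len(self.site_ids[pollutant])

    @property
    def site_counts(self) -> Dict[str, int]:
        return {p: self.n_sites(p) for p in self.pollutants}

    @property
    def n_total(self) -> int:
        return sum(self.n_sites(p) for p in self.pollutants)

    def stacked_coords(self) -> np.ndarray:
        """All site coordinates stacked pollutant-major, shape (N, 2)."""
        return np.concatenate([self.coords[p] for p in self.pollutants], axis=0)

    def stacked_pollutant_index(self) -> np.ndarray:
        """Pollutant index (0..q-1) of each stacked row, shape (N,)."""
        return np.concatenate(
            [np.full(self.n_sites(p), i) for i, p in enumerate(self.pollutants)]
        ).astype(int)

    def distance_matrix(self, a: np.ndarray, b: Optional[np.ndarray] = None) -> np.ndarray:
        if b is None:
            b = a
        fn = haversine_km if self.distance == "haversine" else planar_km
        return fn(a, b)


@dataclass
class TransformRecord:
    """Invertible record of per-variable log transform and standardization.

    ``centers``/``scales`` are the constants applied after the (optional)
    log, i.e. transformed = (maybe_log(x) - center) / scale.  The
    standardization divisor convention is recorded in ``ddof`` (default 1,
    the n-1 sample standard deviation).
    """

    log_applied: Dict[str, bool]
    centers: Dict[str, float]
    scales: Dict[str, float]
    ddof: int = 1

    def __post_init__(self) -> None:
        for name, s in self.scales.items():
            if not s > 0:
                raise ValueError(f"scale for {name} must be > 0, got {s}")

    def apply(self, name: str, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.log_applied.get(name, False):
            with np.errstate(divide="ignore", invalid="ignore"):
                x = np.log(x)
        return (x - self.centers[name]) / self.scales[name]

    def invert(self, name: str, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        x = z * self.scales[name] + self.centers[name]
        if self.log_applied.get(name, False):
            x = np.exp(x)
        return x

    def invert_mean(self, name: str, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
        """Back-transform a predictive mean.

        For log-transformed variables this is the lognormal mean
        exp(mu + sigma^2/2) on the original scale, where mu and sigma are
        the log-scale predictive mean and standard deviation.
        """
        mu = np.asarray(mean, dtype=float) * self.scales[name] + self.centers[name]
        if self.log_applied.get(name, False):
            s = np.asarray(sd, dtype=float) * self.scales[name]
            return np.exp(mu + 0.5 * s ** 2)
        return mu


@dataclass
class ObservationSet:
    """Multivariate station time series with explicit missing data.

    ``values[pollutant]`` is an (n_i, T) float array; missing entries are
    NaN.  ``transform`` records how raw concentrations were mapped to the
    working (e.g. log-standardized) scale, or None for raw data.
    """

    network: StationNetwork
    time_index: pd.Index
    values: Dict[str, np.ndarray]
    transform: Optional[TransformRecord] = None

    def __post_init__(self) -> None:
        T = len(self.time_index)
        if isinstance(self.time_index, pd.DatetimeIndex):
            if T > 1:
                steps = np.diff(self.time_index.values).astype("timedelta64[D]")
                if not np.all(steps == np.timedelta64(1, "D")):
                    raise ValueError("time index must be consecutive days")
        for pol in self.network.pollutants:
            v = np.asarray(self.values[pol], dtype=float)
            expect = (self.network.n_sites(pol), T)
            if v.shape != expect:
                raise ValueError(
                    f"values for {pol} must have shape {expect}, got {v.shape}"
                )
            self.values[pol] = v

    @property
    def T(self) -> int:
        return len(self.time_index)

    def stacked(self) -> np.ndarray:
        """All observations stacked pollutant-major, shape (N, T), NaN missing."""
        return np.concatenate(
            [self.values[p] for p in self.network.pollutants], axis=0
        )

    def missing_fraction(self, pollutant: str) -> float:
        v = self.values[pollutant]
        return float(np.isnan(v).mean())

    def copy(self) -> "ObservationSet":
        return ObservationSet(
            network=self.network,
            time_index=self.time_index,
            values={p: v.copy() for p, v in self.values.items()},
            transform=self.transform,
        )


@dataclass
class CovariateField:
    """Covariate values at stations and (optionally) on a prediction grid.

    ``station[pollutant]`` has shape (n_i, T, k); ``grid`` has shape
    (ncell, T, k) or (ncell, k) for time-invariant covariates.  Covariates
    used in fitting may not contain missing values.
    """

    names: List[str]
    station: Dict[str, np.ndarray]
    grid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        k = len(self.names)
        for pol, arr in self.station.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 3 or arr.shape[2] != k:
                raise ValueError(f"station covariates for {pol} must be (n, T, {k})")
            if np.isnan(arr).any():
                raise ValueError(f"missing covariate value for pollutant {pol}")
            self.station[pol] = arr
        if self.grid is not None:
            g = np.asarray(self.grid, dtype=float)
            if g.shape[-1] != k:
                raise ValueError(f"grid covariates must have {k} variables")
            self.grid = g

    @property
    def k(self) -> int:
        return len(self.names)

    def grid_at(self, t: int) -> np.ndarray:
        """Grid covariates for day t, shape (ncell, k)."""
        if self.grid is None:
            raise ValueError("no grid covariates available")
        if self.grid.ndim == 2:
            return self.grid
        return self.grid[:, t, :]


@dataclass
class GridSpec:
    """Rectangular cell-centre prediction grid with a region mask.

    ``lons``/``lats`` are the coordinates of the cell-centre columns/rows
    (degrees, or km in the planar convention); ``mask`` is (nlat, nlon)
    True for cells inside the region.
    """

    lons: np.ndarray
    lats: np.ndarray
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.lons = np.asarray(self.lons, dtype=float)
        self.lats = np.asarray(self.lats, dtype=float)
        if self.mask is None:
            self.mask = np.ones((self.lats.size, self.lons.size), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (self.lats.size, self.lons.size):
            raise ValueError("mask shape must be (nlat, nlon)")

    @property
    def n_cells(self) -> int:
        return int(self.mask.sum())

    def cell_centres(self) -> np.ndarray:
        """Coordinates of masked cells, shape (n_cells, 2) as (lon, lat)."""
        lon_g, lat_g = np.meshgrid(self.lons, self.lats)
        return np.column_stack([lon_g[self.mask], lat_g[self.mask]])

    @property
    def resolution(self) -> float:
        if self.lons.size > 1:
            return float(np.diff(self.lons).mean())
        return float(np.diff(self.lats).mean()) if self.lats.size > 1 else np.nan


@dataclass
class PopulationRaster:
    """Time-invariant population counts on a GridSpec (masked cells only)."""

    grid: GridSpec
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.grid.n_cells,):
            raise ValueError(
                f"counts must have shape ({self.grid.n_cells},), got {self.counts.shape}"
            )
        if np.any(self.counts < 0):
            raise ValueError("population counts must be >= 0")

    @property
    def total(self) -> float:
        """Total population D of the region."""
        return float(self.counts.sum())


@dataclass
class Thresholds:
    """Regulatory exceedance thresholds and index scaling constants.

    ``L`` maps pollutant -> daily threshold in µg m⁻³ (original scale),
    ``M`` is the day-count limit of the air-quality objective, and ``F``
    maps pollutant -> scaling factor (µg m⁻³ per index unit).
    """

    L: Dict[str, float]
    M: int = 7
    F: Optional[Dict[str, float]] = None

    def __post_init__(self) -> None:
        for pol, v in self.L.items():
            if not v > 0:
                raise ValueError(f"threshold L for {pol} must be > 0")
        if not (isinstance(self.M, (int, np.integer)) and self.M >= 0):
            raise ValueError("M must be a non-negative integer")
        if self.F is not None:
            for pol, v in self.F.items():
                if not v > 0:
                    raise ValueError(f"scaling factor F for {pol} must be > 0")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def aggregate_hourly_to_daily(hourly: Sequence[float], min_hours: int = 18) -> float:
    """Daily mean of up to 24 hourly values, or NaN under the 75% rule.

    A day with fewer than ``min_hours`` (default 18, i.e. 75% of 24) valid
    hourly values is flagged missing.
    """
    arr = np.asarray(hourly, dtype=float)
    if arr.ndim != 1 or arr.size > 24:
        raise ValueError(f"a day has at most 24 hourly slots, got {arr.size}")
    valid = np.isfinite(arr)
    if valid.sum() < min_hours:
        return float("nan")
    return float(arr[valid].mean())


def log_standardize(
    series: Mapping[str, np.ndarray],
    log_vars: Optional[Sequence[str]] = None,
    ddof: int = 1,
) -> tuple[Dict[str, np.ndarray], TransformRecord]:
    """Log-transform selected variables and standardize each to mean 0, sd 1.

    Statistics are computed network-wide per variable over non-missing
    entries.  ``ddof=1`` (the n-1 divisor) is the default convention.
    Returns the transformed arrays and a TransformRecord that inverts the
    transform exactly.

    Raises
    ------
    ValueError
        If a non-positive value is found under a log transform (the
        offending location is named), or a series has zero variance.
    """
    if log_vars is None:
        log_vars = list(series.keys())
    log_set = set(log_vars)
    out: Dict[str, np.ndarray] = {}
    logf: Dict[str, bool] = {}
    centers: Dict[str, float] = {}
    scales: Dict[str, float] = {}
    for name, arr in series.items():
        arr = np.asarray(arr, dtype=float)
        x = arr.copy()
        if name in log_set:
            bad = np.isfinite(x) & (x <= 0)
            if bad.any():
                idx = tuple(int(i[0]) for i in np.nonzero(bad))
                raise ValueError(
                    f"non-positive value under log transform for {name!r} at index {idx}"
                )
            with np.errstate(invalid="ignore"):
                x = np.log(x)
        vals = x[np.isfinite(x)]
        if vals.size == 0:
            raise ValueError(f"series {name!r} has no observed values")
        center = float(vals.mean())
        scale = float(vals.std(ddof=ddof)) if vals.size > ddof else 0.0
        if not scale > 0:
            raise ValueError(f"series {name!r} has zero variance")
        out[name] = (x - center) / scale
        logf[name] = name in log_set
        centers[name] = center
        scales[name] = scale
    record = TransformRecord(log_applied=logf, centers=centers, scales=scales, ddof=ddof)
    return out, record


def transform_observations(
    obs: ObservationSet,
    log_vars: Optional[Sequence[str]] = None,
    ddof: int = 1,
) -> ObservationSet:
    """Return a log-standardized copy of an ObservationSet (raw input only)."""
    if obs.transform is not None:
        raise ValueError("observations are already transformed")
    vals, record = log_standardize(obs.values, log_vars=log_vars, ddof=ddof)
    return ObservationSet(
        network=obs.network, time_index=obs.time_index, values=vals, transform=record
    )


def validate_observation_set(obs: ObservationSet) -> Dict[str, object]:
    """Report-only diagnostics of an ObservationSet (never mutates data)."""
    report: Dict[str, object] = {}
    counts = {}
    missing = {}
    empty_stations: Dict[str, List[str]] = {}
    dup_coords: Dict[str, List[tuple]] = {}
    for pol in obs.network.pollutants:
        v = obs.values[pol]
        counts[pol] = v.shape[0]
        missing[pol] = float(np.isnan(v).mean())
        ids = obs.network.site_ids[pol]
        empty = [ids[i] for i in range(v.shape[0]) if np.isnan(v[i]).all()]
        if empty:
            empty_stations[pol] = empty
        xy = obs.network.coords[pol]
        seen: Dict[tuple, str] = {}
        dups = []
        for i, row in enumerate(xy):
            key = (round(float(row[0]), 9), round(float(row[1]), 9))
            if key in seen:
                dups.append((seen[key], ids[i]))
            else:
                seen[key] = ids[i]
        if dups:
            dup_coords[pol] = dups
    stacked = obs.stacked()
    report["station_counts"] = counts
    report["missing_fraction"] = missing
    report["stations_fully_missing"] = empty_stations
    report["duplicated_coordinates"] = dup_coords
    report["days_with_no_observation"] = [
        int(t) for t in range(obs.T) if np.isnan(stacked[:, t]).all()
    ]
    return report


# ---------------------------------------------------------------------------
# text-format I/O
# ---------------------------------------------------------------------------

def read_observations_csv(
    path, distance: str = "haversine", hourly: bool = False
) -> ObservationSet:
    """Read long-format observations.

    Columns: station_id, lon, lat, date (ISO-8601), pollutant, value; the
    hourly variant adds an ``hour`` column and is aggregated to daily means
    under the 75% completeness rule.  Empty value fields are missing.
    """
    df = pd.read_csv(path, dtype={"station_id": str, "pollutant": str})
    required = {"station_id", "lon", "lat", "date", "pollutant", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"observations file must contain columns {sorted(required)}")
    df["date"] = pd.to_datetime(df["date"])
    if hourly:
        if "hour" not in df.columns:
            raise ValueError("hourly observations need an 'hour' column")
        daily = (
            df.groupby(["pollutant", "station_id", "lon", "lat", "date"])["value"]
            .apply(lambda s: aggregate_hourly_to_daily(s.to_numpy()))
            .reset_index()
        )
        df = daily

    pollutants = sorted(df["pollutant"].unique())
    dates = pd.DatetimeIndex(sorted(df["date"].unique()))
    full = pd.date_range(dates[0], dates[-1], freq="D")
    site_ids: Dict[str, List[str]] = {}
    coords: Dict[str, np.ndarray] = {}
    values: Dict[str, np.ndarray] = {}
    for pol in pollutants:
        sub = df[df["pollutant"] == pol]
        sites = sub.drop_duplicates("station_id")[["station_id", "lon", "lat"]]
        sites = sites.sort_values("station_id")
        site_ids[pol] = sites["station_id"].tolist()
        coords[pol] = sites[["lon", "lat"]].to_numpy(dtype=float)
        mat = np.full((len(site_ids[pol]), len(full)), np.nan)
        sidx = {s: i for i, s in enumerate(site_ids[pol])}
        tidx = {d: i for i, d in enumerate(full)}
        for _, row in sub.iterrows():
            mat[sidx[row["station_id"]], tidx[row["date"]]] = row["value"]
        values[pol] = mat
    network = StationNetwork(
        pollutants=pollutants, site_ids=site_ids, coords=coords, distance=distance
    )
    return ObservationSet(network=network, time_index=full, values=values)


def write_observations_csv(obs: ObservationSet, path) -> None:
    """Write an ObservationSet in long format (missing rows omitted)."""
    rows = []
    for pol in obs.network.pollutants:
        ids = obs.network.site_ids[pol]
        xy = obs.network.coords[pol]
        v = obs.values[pol]
        for i, sid in enumerate(ids):
            ok = np.isfinite(v[i])
            for t in np.nonzero(ok)[0]:
                date = obs.time_index[t]
                rows.append(
                    (sid, xy[i, 0], xy[i, 1],
                     date.date().isoformat() if hasattr(date, "date") else date,
                     pol, v[i, t])
                )
    pd.DataFrame(
        rows, columns=["station_id", "lon", "lat", "date", "pollutant", "value"]
    ).to_csv(path, index=False)


def read_raster_csv(path, distance: str = "planar") -> PopulationRaster:
    """Read a delimited-text raster: columns cell_lon, cell_lat, value."""
    df = pd.read_csv(path)
    required = {"cell_lon", "cell_lat", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"raster file must contain columns {sorted(required)}")
    lons = np.array(sorted(df["cell_lon"].unique()))
    lats = np.array(sorted(df["cell_lat"].unique()))
    li = {v: i for i, v in enumerate(lons)}
    la = {v: i for i, v in enumerate(lats)}
    mask = np.zeros((lats.size, lons.size), dtype=bool)
    val = np.full((lats.size, lons.size), np.nan)
    for _, row in df.iterrows():
        mask[la[row["cell_lat"]], li[row["cell_lon"]]] = True
        val[la[row["cell_lat"]], li[row["cell_lon"]]] = row["value"]
    grid = GridSpec(lons=lons, lats=lats, mask=mask)
    return PopulationRaster(grid=grid, counts=val[mask])


def write_raster_csv(raster: PopulationRaster, path) -> None:
    centres = raster.grid.cell_centres()
    pd.DataFrame(
        {"cell_lon": centres[:, 0], "cell_lat": centres[:, 1], "value": raster.counts}
    ).to_csv(path, index=False)
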