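"""Conditional-probability-function (CPF) risk mapping on a geographic grid.

Trajectory endpoints are binned into an axis-aligned km grid around a
receptor. For each cell, n_ij counts all endpoints and m_ij the endpoints
belonging to days whose receptor risk metric (HI, CR or ILCR) is at or
above a percentile threshold (default the 75th); cpf_raw = m_ij / n_ij is
then down-weighted in sparsely visited cells with the standard step
weighting scheme, because a cell crossed by two trajectories that both
happen to be high-risk days says little.

Coordinates use a local equirectangular projection about the grid origin
(adequate below ~100 km domain scale); cells are half-open on their east
and north edges so every in-bounds point lands in exactly one cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .datatypes import RiskSeries, Trajectory, ValidationError

KM_PER_DEG_LAT = 110.574
KM_PER_DEG_LON_EQ = 111.320

#: Default step weights: (lower bound on n_ij / n_mean, weight], evaluated
#: top-down; the final band covers everything at or below 0.5 * n_mean.
DEFAULT_WEIGHT_STEPS = ((2.0, 1.0), (1.0, 0.7), (0.5, 0.42), (0.0, 0.05))


@dataclass(frozen=True)
class GridSpec:
    """Receptor-centred analysis grid.

    origin_lat/origin_lon locate the south-west corner; cell_km is the
    square cell edge; default 32 x 32 cells of 1 km.
    """

    origin_lat: float
    origin_lon: float
    cell_km: float = 1.0
    n_rows: int = 32
    n_cols: int = 32

    def __post_init__(self) -> None:
        if self.cell_km <= 0 or self.n_rows < 1 or self.n_cols < 1:
            raise ValidationError("grid must have positive cell size and dimensions")

    def to_xy_km(self, lat, lon) -> tuple[np.ndarray, np.ndarray]:
        """Project lat/lon to km east (x) and north (y) of the origin."""
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        y = (lat - self.origin_lat) * KM_PER_DEG_LAT
        x = (lon - self.origin_lon) * KM_PER_DEG_LON_EQ * np.cos(
            np.deg2rad(self.origin_lat))
        return x, y

    def cell_of(self, lat, lon) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(row i, col j, in_bounds) for arrays of lat/lon.

        West/south edges are closed, east/north edges open: a point exactly
        on a shared edge belongs to the cell whose west (or south) side it
        touches.
        """
        x, y = self.to_xy_km(lat, lon)
        # snap to 1e-9 cell units before flooring so a point constructed on
        # an edge is not pushed across it by projection round-off
        j = np.floor(np.round(x / self.cell_km, 9)).astype(int)
        i = np.floor(np.round(y / self.cell_km, 9)).astype(int)
        ok = (i >= 0) & (i < self.n_rows) & (j >= 0) & (j < self.n_cols)
        return i, j, ok

    def cell_center_latlon(self, i, j) -> tuple[np.ndarray, np.ndarray]:
        i = np.asarray(i, dtype=float)
        j = np.asarray(j, dtype=float)
        y = (i + 0.5) * self.cell_km
        x = (j + 0.5) * self.cell_km
        lat = self.origin_lat + y / KM_PER_DEG_LAT
        lon = self.origin_lon + x / (KM_PER_DEG_LON_EQ
                                     * np.cos(np.deg2rad(self.origin_lat)))
        return lat, lon


@dataclass
class EndpointAssignment:
    grid: GridSpec
    #: (i, j) -> list of (trajectory_id, day) per endpoint
    cells: Mapping[tuple, list]
    out_of_bounds: int
    total_endpoints: int


def assign_endpoints(trajectories: Sequence[Trajectory],
                     grid: GridSpec) -> EndpointAssignment:
    """Bin every trajectory endpoint into its grid cell.

    Each endpoint is tagged with its trajectory's start day (the day whose
    receptor risk value conditions the CPF). Out-of-bounds endpoints are
    counted, not silently dropped.
    """
    cells: dict[tuple, list] = {}
    oob = 0
    total = 0
    for t in trajectories:
        day = pd.Timestamp(t.start_time).normalize()
        ll = t.latlon()
        i, j, ok = grid.cell_of(ll[:, 0], ll[:, 1])
        total += len(ll)
        oob += int((~ok).sum())
        for ii, jj in zip(i[ok], j[ok]):
            cells.setdefault((int(ii), int(jj)), []).append((t.trajectory_id, day))
    return EndpointAssignment(grid=grid, cells=cells, out_of_bounds=oob,
                              total_endpoints=total)


def weight_function(n_ij: float, n_mean: float,
                    steps=DEFAULT_WEIGHT_STEPS) -> float:
    """Step down-weighting of sparsely visited cells.

    Default: w=1 for n_ij > 2*n_mean, 0.7 for n_mean < n_ij <= 2*n_mean,
    0.42 for 0.5*n_mean < n_ij <= n_mean, 0.05 otherwise.
    """
    if n_ij < 0:
        raise ValidationError(f"endpoint count must be >= 0, got {n_ij}")
    if n_mean <= 0:
        raise ValidationError(f"mean endpoint count must be > 0, got {n_mean}")
    for bound, w in steps:
        if n_ij > bound * n_mean:
            return w
    return steps[-1][1]


def cpf(assignment: EndpointAssignment, risk: RiskSeries,
        percentile_threshold: float = 75.0,
        weight_steps=DEFAULT_WEIGHT_STEPS) -> pd.DataFrame:
    """Conditional probability of high receptor risk per grid cell.

    The high-risk day set is {day : risk >= threshold} where the threshold
    is the given percentile of the daily risk series (linear-interpolation
    quantile). Returns a tidy frame (i, j, lat, lon, n, m, cpf_raw, weight,
    cpf_weighted); cells never visited are absent.
    """
    values = {pd.Timestamp(d).normalize(): float(v)
              for d, v in risk.values.items()}
    if not values:
        raise ValidationError("risk series is empty")
    threshold = float(np.percentile(list(values.values()), percentile_threshold))
    high_days = {d for d, v in values.items() if v >= threshold}
    if all(v < threshold for v in values.values()):
        warnings.warn("no day reaches the high-risk threshold; CPF map is all zero",
                      stacklevel=2)

    rows = []
    for (i, j), endpoints in assignment.cells.items():
        n = len(endpoints)
        missing = [d for _, d in endpoints if d not in values]
        if missing:
            raise ValidationError(
                f"cell ({i},{j}): trajectory day(s) {sorted(set(missing))[:3]} "
                f"have no {risk.metric} value")
        m = sum(1 for _, d in endpoints if d in high_days)
        rows.append((i, j, n, m))
    df = pd.DataFrame(rows, columns=["i", "j", "n", "m"])
    n_mean = df["n"].mean()
    df["cpf_raw"] = df["m"] / df["n"]
    df["weight"] = [weight_function(n, n_mean, weight_steps) for n in df["n"]]
    df["cpf_weighted"] = df["cpf_raw"] * df["weight"]
    lat, lon = assignment.grid.cell_center_latlon(df["i"], df["j"])
    df.insert(2, "lat", lat)
    df.insert(3, "lon", lon)
    df.attrs["threshold"] = threshold
    df.attrs["percentile"] = percentile_threshold
    df.attrs["metric"] = risk.metric
    return df.sort_values(["i", "j"]).reset_index(drop=True)


def resample_trajectory(t: Trajectory, n_points: int) -> np.ndarray:
    """Linearly resample a trajectory to n_points equally spaced in time."""
    ll = t.latlon()
    old = np.linspace(0.0, 1.0, len(ll))
    new = np.linspace(0.0, 1.0, n_points)
    return np.column_stack([np.interp(new, old, ll[:, 0]),
                            np.interp(new, old, ll[:, 1])])


@dataclass
class ClusterResult:
    labels: np.ndarray
    mean_paths: np.ndarray  # (k, n_points, 2) lat/lon
    silhouette: Optional[float]


def cluster_trajectories(trajectories: Sequence[Trajectory], k: int,
                         n_points: int = 13, seed: int = 0,
                         ref_lat: Optional[float] = None) -> ClusterResult:
    """k-means clustering of trajectories resampled to equal point counts.

    Coordinates are scaled to km (latitude stretched less than longitude at
    low latitudes) before the Euclidean k-means, a planar approximation
    adequate at sub-100 km domain scale. Deterministic under seed; the
    silhouette score is reported when 1 < k < n.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > len(trajectories):
        raise ValidationError(
            f"k={k} exceeds the number of trajectories ({len(trajectories)})")
    paths = np.stack([resample_trajectory(t, n_points) for t in trajectories])
    if ref_lat is None:
        ref_lat = float(paths[:, :, 0].mean())
    scale = np.array([KM_PER_DEG_LAT,
                      KM_PER_DEG_LON_EQ * np.cos(np.deg2rad(ref_lat))])
    X = (paths * scale).reshape(len(trajectories), -1)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
    centers = (km.cluster_centers_.reshape(k, n_points, 2)) / scale
    sil = None
    if 1 < k < len(trajectories) and len(np.unique(km.labels_)) > 1:
        sil = float(silhouette_score(X, km.labels_))
    return ClusterResult(labels=km.labels_, mean_paths=centers, silhouette=sil)
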