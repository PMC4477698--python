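"""Grid-box geometry and spatial correlation machinery.

The calibration operates on 20-degree latitude/longitude boxes whose
centroids carry Gaussian-process distributed regression parameters.  This
module provides the box geometry, great-circle distances, and the
Matern(nu=3/2) correlation used to couple nearby boxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "GridSpec",
    "CorrelationModel",
    "assign_grid_box",
    "centroid_distance_km",
    "matern32",
    "build_correlation_matrix",
    "correlation_cholesky",
]


@dataclass(frozen=True)
class GridSpec:
    """Global grid of 20x20 degree boxes anchored at (-90, -180).

    Boxes are indexed row-major: ``index = row * n_lon + col`` with rows
    ordered south to north.  Edge intervals are half-open ``[edge, edge+20)``
    except that the north pole (lat=90) belongs to the top row and lon=180
    wraps to -180.
    """

    box_size_deg: float = 20.0
    lat_edges: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    lon_edges: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        step = self.box_size_deg
        if 180.0 % step or 360.0 % step:
            raise ValueError("box_size_deg must divide 180 and 360")
        object.__setattr__(self, "lat_edges", np.arange(-90.0, 90.0 + step / 2, step))
        object.__setattr__(self, "lon_edges", np.arange(-180.0, 180.0 + step / 2, step))

    @property
    def n_lat(self) -> int:
        return len(self.lat_edges) - 1

    @property
    def n_lon(self) -> int:
        return len(self.lon_edges) - 1

    @property
    def n_boxes(self) -> int:
        return self.n_lat * self.n_lon

    @property
    def centroids(self) -> np.ndarray:
        """(n_boxes, 2) array of (lat, lon) box centres, row-major order."""
        half = self.box_size_deg / 2.0
        lats = self.lat_edges[:-1] + half
        lons = self.lon_edges[:-1] + half
        la, lo = np.meshgrid(lats, lons, indexing="ij")
        return np.column_stack([la.ravel(), lo.ravel()])

    def centroid(self, index: int) -> tuple[float, float]:
        c = self.centroids[index]
        return float(c[0]), float(c[1])


def normalize_lon(lon):
    """Map longitudes into [-180, 180)."""
    return (np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0


def assign_grid_box(lat, lon, grid: GridSpec | None = None):
    """Return the box index containing each (lat, lon) point.

    Accepts scalars or arrays.  lat must lie in [-90, 90]; lon is
    normalized to [-180, 180) first.  lat = 90 maps to the top row.
    """
    if grid is None:
        grid = GridSpec()
    lat = np.asarray(lat, dtype=float)
    if np.any(lat < -90.0) or np.any(lat > 90.0):
        raise ValueError("latitude outside [-90, 90]")
    lon = normalize_lon(lon)
    step = grid.box_size_deg
    row = np.floor((lat + 90.0) / step).astype(int)
    row = np.minimum(row, grid.n_lat - 1)  # lat == 90 -> top row
    col = np.floor((lon + 180.0) / step).astype(int)
    col = np.minimum(col, grid.n_lon - 1)
    idx = row * grid.n_lon + col
    if idx.ndim == 0:
        return int(idx)
    return idx


def centroid_distance_km(c1, c2) -> np.ndarray | float:
    """Great-circle (haversine) distance in km between (lat, lon) points.

    Broadcasts over leading dimensions; sphere radius 6371 km.
    """
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    la1, lo1 = np.radians(c1[..., 0]), np.radians(c1[..., 1])
    la2, lo2 = np.radians(c2[..., 0]), np.radians(c2[..., 1])
    h = (
        np.sin((la2 - la1) / 2.0) ** 2
        + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2.0) ** 2
    )
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(h)))
    if d.ndim == 0:
        return float(d)
    return d


def chordal_distance_km(c1, c2) -> np.ndarray | float:
    """Straight-line (through-Earth) distance between points on the sphere."""
    gc = np.asarray(centroid_distance_km(c1, c2))
    d = 2.0 * EARTH_RADIUS_KM * np.sin(gc / (2.0 * EARTH_RADIUS_KM))
    if d.ndim == 0:
        return float(d)
    return d


def matern32(d_km, phi):
    """Matern correlation with smoothness 3/2 and inverse range ``phi`` (1/km).

    ``(1 + sqrt(3)*phi*d) * exp(-sqrt(3)*phi*d)``: equals 1 at d=0 and
    decreases monotonically to 0.  With this scaling 1/phi is the distance
    at which correlation has dropped to roughly 0.48.
    """
    d_km = np.asarray(d_km, dtype=float)
    if np.any(d_km < 0):
        raise ValueError("distance must be nonnegative")
    if phi <= 0:
        raise ValueError("phi must be positive")
    s = np.sqrt(3.0) * phi * d_km
    r = (1.0 + s) * np.exp(-s)
    if r.ndim == 0:
        return float(r)
    return r


@dataclass(frozen=True)
class CorrelationModel:
    """Matern-3/2 spatial correlation settings.

    ``metric`` selects the distance fed to the Matern function.  The default
    is chordal distance: Matern correlations are guaranteed positive
    definite on the sphere for chordal but *not* for great-circle distance
    (great-circle matrices on the full global grid go indefinite for small
    phi).  Great-circle remains available for comparison.
    """

    nu: float = 1.5
    phi: float = 5e-4  # per km
    jitter: float = 1e-8
    metric: str = "chordal"  # or "great_circle"

    def __post_init__(self) -> None:
        if self.nu != 1.5:
            raise ValueError("only smoothness nu = 3/2 is supported")
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        if self.metric not in ("chordal", "great_circle"):
            raise ValueError(f"unknown metric {self.metric!r}")

    def distance_matrix(self, centroids: np.ndarray) -> np.ndarray:
        c = np.asarray(centroids, dtype=float)
        func = chordal_distance_km if self.metric == "chordal" else centroid_distance_km
        return np.asarray(func(c[:, None, :], c[None, :, :]))


def build_correlation_matrix(
    centroids, model: CorrelationModel | None = None, phi: float | None = None
) -> np.ndarray:
    """Correlation matrix R between box centroids (no jitter applied).

    Symmetric with exact unit diagonal.  ``phi`` overrides the model value,
    which lets a sampler reuse one distance matrix across a phi grid.
    """
    if model is None:
        model = CorrelationModel()
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    d = model.distance_matrix(centroids)
    R = matern32(d, model.phi if phi is None else phi)
    R = np.asarray(R, dtype=float)
    np.fill_diagonal(R, 1.0)
    return 0.5 * (R + R.T)


def correlation_cholesky(R: np.ndarray, jitter: float = 1e-8, max_tries: int = 6):
    """Lower Cholesky factor of R + jitter*I, escalating jitter on failure.

    Returns (L, jitter_used).  Raises LinAlgError-derived RuntimeError with
    conditioning info if factorization fails even after escalation.
    """
    n = R.shape[0]
    j = jitter
    for _ in range(max_tries):
        try:
            L = cholesky(R + j * np.eye(n), lower=True)
            return L, j
        except np.linalg.LinAlgError:
            j *= 100.0
    eigmin = float(np.linalg.eigvalsh(R).min())
    raise RuntimeError(
        f"correlation matrix not positive definite (min eigenvalue {eigmin:.3e}) "
        f"even with jitter up to {j:.1e}"
    )
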