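"""Synthetic data generators mirroring the calibration model's structure.

Everything the rest of the package consumes — core-top databases,
climatology grids, downcore proxy series — can be generated here with
known ground truth, so the full pipeline is testable without any external
data products.  All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .gdgt import CoreTopRecord, GdgtFractions
from .spatial import (
    CorrelationModel,
    GridSpec,
    assign_grid_box,
    build_correlation_matrix,
    correlation_cholesky,
)
from .targets import ClimatologyGrid, extract_point_temperature

__all__ = [
    "SyntheticTruth",
    "simulate_parameter_fields",
    "make_truth",
    "simulate_coretops",
    "simulate_climatology",
    "simulate_downcore",
]

# Defaults chosen so simulated databases resemble the scatter of real
# core-top compilations: slope ~0.018 per degC, interlaboratory-scale
# noise of 0.03 proxy units.
DEFAULT_MU_ALPHA = 0.25
DEFAULT_MU_BETA = 0.018
DEFAULT_TAU = 0.03


@dataclass
class SyntheticTruth:
    """Known generating parameters for recovery experiments."""

    alpha_true: np.ndarray  # per-box
    beta_true: np.ndarray  # per-box, strictly positive
    tau2_true: float
    mu_alpha_true: float
    mu_beta_true: float
    sigma2_alpha_true: float
    sigma2_beta_true: float
    phi_true: float
    seed: int
    grid: GridSpec = field(default_factory=GridSpec)

    def __post_init__(self) -> None:
        if np.any(self.beta_true <= 0):
            raise ValueError("beta_true must be strictly positive everywhere")


def simulate_parameter_fields(
    grid: GridSpec,
    mu: float,
    sigma2: float,
    phi: float,
    truncate_positive: bool = False,
    seed: int = 0,
    box_ids=None,
    correlation: CorrelationModel | None = None,
    max_redraws: int = 1000,
) -> np.ndarray:
    """One Gaussian-process field draw N(mu*1, sigma2*R) on box centroids.

    With ``truncate_positive`` the draw is redrawn until all entries are
    positive — conditioning on positivity rather than exact truncated-MVN
    sampling, acceptable for test data when negativity is rare.
    """
    if sigma2 < 0 or phi <= 0:
        raise ValueError("need sigma2 >= 0 and phi > 0")
    box_ids = np.arange(grid.n_boxes) if box_ids is None else np.asarray(box_ids, dtype=int)
    rng = np.random.default_rng(seed)
    if sigma2 == 0:
        return np.full(len(box_ids), mu)
    correlation = correlation or CorrelationModel(phi=phi)
    R = build_correlation_matrix(grid.centroids[box_ids], correlation, phi=phi)
    L, _ = correlation_cholesky(R, jitter=correlation.jitter)
    scale = np.sqrt(sigma2)
    for _ in range(max_redraws):
        x = mu + scale * (L @ rng.standard_normal(len(box_ids)))
        if not truncate_positive or np.all(x > 0):
            return x
    raise RuntimeError(
        f"positivity acceptance rate below {1/max_redraws:.1e}; "
        "choose a larger mean or smaller variance"
    )


def make_truth(
    grid: GridSpec | None = None,
    box_ids=None,
    mu_alpha: float = DEFAULT_MU_ALPHA,
    mu_beta: float = DEFAULT_MU_BETA,
    tau: float = DEFAULT_TAU,
    sigma2_alpha: float = 1e-3,
    sigma2_beta: float = 1e-5,
    phi: float = 5e-4,
    seed: int = 0,
) -> SyntheticTruth:
    """Draw a complete ground truth (alpha and beta fields plus scalars)."""
    grid = grid or GridSpec()
    alpha = simulate_parameter_fields(grid, mu_alpha, sigma2_alpha, phi, seed=seed, box_ids=box_ids)
    beta = simulate_parameter_fields(
        grid, mu_beta, sigma2_beta, phi, truncate_positive=True, seed=seed + 1, box_ids=box_ids
    )
    if box_ids is not None:
        full_a = np.full(grid.n_boxes, np.nan)
        full_b = np.full(grid.n_boxes, np.nan)
        full_a[np.asarray(box_ids)] = alpha
        full_b[np.asarray(box_ids)] = beta
        # boxes outside the requested subset fall back to the field means
        alpha = np.where(np.isnan(full_a), mu_alpha, full_a)
        beta = np.where(np.isnan(full_b), mu_beta, full_b)
    return SyntheticTruth(
        alpha_true=alpha,
        beta_true=beta,
        tau2_true=tau**2,
        mu_alpha_true=mu_alpha,
        mu_beta_true=mu_beta,
        sigma2_alpha_true=sigma2_alpha,
        sigma2_beta_true=sigma2_beta,
        phi_true=phi,
        seed=seed,
        grid=grid,
    )


def _fractions_for_tex(tex: float, rng: np.random.Generator) -> GdgtFractions:
    """GDGT fractional abundances consistent with a target proxy value."""
    denom = rng.uniform(0.2, 0.4)  # mass in the four index compounds
    num = tex * denom
    f1 = denom - num
    f2 = num * 0.25
    f3 = num * 0.25
    fcp = num * 0.5
    rest = 1.0 - denom
    f0 = rest * 0.4
    fc = rest * 0.6
    return GdgtFractions(f0, f1, f2, f3, fc, fcp)


def simulate_coretops(
    n_sites: int,
    truth: SyntheticTruth,
    temperature_field=None,
    seed: int = 0,
    lat_range: tuple[float, float] = (-75.0, 75.0),
    with_fractions: bool = False,
    box_ids=None,
    max_clip_fraction: float = 0.05,
) -> list[CoreTopRecord]:
    """Generate synthetic core-top records from the generating model.

    ``temperature_field`` maps (lat, lon) to a site temperature in degC;
    the default is a smooth warm-equator/cold-pole surface.  Proxy values
    are alpha_box + beta_box * T + N(0, tau2) noise, clipped to [0, 1]
    with a warning (an error if clipping exceeds ``max_clip_fraction``).
    When ``box_ids`` is given, sites are drawn only within those boxes.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    if temperature_field is None:
        temperature_field = lambda lat, lon: -2.0 + 30.0 * np.cos(np.radians(lat)) ** 2

    grid = truth.grid
    lats = np.empty(n_sites)
    lons = np.empty(n_sites)
    if box_ids is None:
        lats = rng.uniform(lat_range[0], lat_range[1], n_sites)
        lons = rng.uniform(-180.0, 180.0, n_sites)
    else:
        box_ids = np.asarray(box_ids, dtype=int)
        chosen = rng.choice(box_ids, size=n_sites)
        half = grid.box_size_deg / 2.0
        cents = grid.centroids[chosen]
        lats = np.clip(cents[:, 0] + rng.uniform(-half, half, n_sites), -89.99, 89.99)
        lons = cents[:, 1] + rng.uniform(-half, half, n_sites)

    boxes = assign_grid_box(lats, lons, grid)
    temps = np.array([float(temperature_field(la, lo)) for la, lo in zip(lats, lons)])
    tex = (
        truth.alpha_true[boxes]
        + truth.beta_true[boxes] * temps
        + np.sqrt(truth.tau2_true) * rng.standard_normal(n_sites)
    )
    clipped = int(np.sum((tex < 0) | (tex > 1)))
    if clipped > max_clip_fraction * n_sites:
        raise ValueError(
            f"{clipped}/{n_sites} proxy values fell outside [0,1]; "
            "generating parameters are implausible"
        )
    if clipped:
        warnings.warn(f"clipped {clipped} proxy values into [0, 1]", stacklevel=2)
        tex = np.clip(tex, 0.0, 1.0)

    records = []
    for i in range(n_sites):
        records.append(
            CoreTopRecord(
                core_id=f"SYN-{i:05d}",
                core_type="synthetic",
                lat=float(lats[i]),
                lon=float(lons[i]),
                water_depth_m=float(rng.uniform(200, 4000)),
                sample_depth_cm=0.0,
                tex86=float(tex[i]),
                fractions=_fractions_for_tex(float(tex[i]), rng) if with_fractions else None,
                sst_woa_C=float(temps[i]),
                subT_gamma_C=float(temps[i]),
                reference="synthetic",
            )
        )
    return records


def simulate_climatology(
    resolution_deg: float = 4.0,
    profile_shape: str = "exponential",
    seed: int = 0,
    depths=None,
    with_land: bool = True,
) -> ClimatologyGrid:
    """Smooth synthetic depth-resolved climatology with a land mask.

    Surface temperature decreases from equator to poles; profiles decay
    with depth toward a 2 degC abyss (``profile_shape='exponential'``) or
    stay isothermal (``'isothermal'``).
    """
    if profile_shape not in ("exponential", "isothermal"):
        raise ValueError(f"unknown profile_shape {profile_shape!r}")
    rng = np.random.default_rng(seed)
    lat = np.arange(-90 + resolution_deg / 2, 90, resolution_deg)
    lon = np.arange(-180 + resolution_deg / 2, 180, resolution_deg)
    if depths is None:
        depths = np.array([0.0, 10, 20, 30, 50, 75, 100, 125, 150, 200], dtype=float)
    depths = np.asarray(depths, dtype=float)

    sst = -2.0 + 30.0 * np.cos(np.radians(lat)) ** 2
    surface = np.repeat(sst[:, None], len(lon), axis=1)
    if profile_shape == "isothermal":
        values = np.repeat(surface[None, :, :], len(depths), axis=0)
    else:
        decay = np.exp(-depths / 120.0)  # -> 2 degC abyssal floor
        values = 2.0 + (surface[None, :, :] - 2.0) * decay[:, None, None]

    if with_land:
        # two deterministic rectangular "continents"
        mask = np.zeros((len(lat), len(lon)), dtype=bool)
        mask[(lat >= -30)[:, None] & (lat <= 60)[:, None] & (lon >= -100)[None, :] & (lon <= -60)[None, :]] = True
        mask[(lat >= -10)[:, None] & (lat <= 50)[:, None] & (lon >= 10)[None, :] & (lon <= 60)[None, :]] = True
        values = values.copy()
        values[:, mask] = np.nan
    _ = rng  # reserved for future stochastic texture
    return ClimatologyGrid(lat_axis=lat, lon_axis=lon, values=values, depth_axis=depths)


def ocean_temperature_sampler(grid: ClimatologyGrid):
    """(lat, lon) -> surface temperature from a synthetic climatology."""

    def fn(lat, lon):
        sub = ClimatologyGrid(grid.lat_axis, grid.lon_axis, grid.surface_field())
        return extract_point_temperature(sub, lat, lon)

    return fn


def simulate_downcore(
    truth: SyntheticTruth,
    box_id: int,
    temperatures,
    ages=None,
    tau2: float | None = None,
    seed: int = 0,
):
    """Downcore proxy series from a known temperature history at one box.

    Returns (ages, tex86, temperatures).  ``tau2=None`` uses the truth's
    noise variance; pass 0 for a noise-free series.
    """
    temperatures = np.asarray(temperatures, dtype=float)
    n = len(temperatures)
    if n < 2:
        raise ValueError("need at least 2 time points")
    ages = np.arange(n, dtype=float) * 0.1 if ages is None else np.asarray(ages, dtype=float)
    t2 = truth.tau2_true if tau2 is None else tau2
    rng = np.random.default_rng(seed)
    tex = (
        truth.alpha_true[box_id]
        + truth.beta_true[box_id] * temperatures
        + np.sqrt(t2) * rng.standard_normal(n)
    )
    return ages, np.clip(tex, 0.0, 1.0), temperatures
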