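"""Synthetic single-molecule TIRF/TOCCSL data generator.

Every public function is a pure function of its parameters and an integer
seed: identical inputs give bit-identical outputs. Spots are sparse
diffraction-limited signals whose brightness is the sum of 1..n
single-fluorophore draws; frames carry a full camera model (offset,
inverse gain, shot noise, Gaussian read noise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import erf

__all__ = [
    "MonomerBrightnessLaw",
    "GroundTruth",
    "CameraModel",
    "ToccslTiming",
    "Aperture",
    "generate_monomer_brightness",
    "generate_mixture_spots",
    "render_image",
    "simulate_toccsl_run",
    "simulate_repeated_runs",
    "simulate_frap_trace",
]


@dataclass(frozen=True)
class MonomerBrightnessLaw:
    """Lognormal single-fluorophore brightness law.

    Parameters are the median brightness in photons and the geometric
    standard deviation (dimensionless, >= 1). ``geometric_sd == 1`` is the
    degenerate law concentrated at ``median``.
    """

    median: float = 100.0
    geometric_sd: float = 1.4

    def __post_init__(self) -> None:
        if self.median <= 0:
            raise ValueError(f"median must be > 0, got {self.median}")
        if self.geometric_sd < 1:
            raise ValueError(
                f"geometric_sd must be >= 1, got {self.geometric_sd}"
            )

    @property
    def mu_log(self) -> float:
        return math.log(self.median)

    @property
    def sigma_log(self) -> float:
        return math.log(self.geometric_sd)

    def mean(self) -> float:
        """Analytic mean of the lognormal law."""
        return self.median * math.exp(0.5 * self.sigma_log**2)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.sigma_log == 0.0:
            return np.full(n, self.median)
        return rng.lognormal(self.mu_log, self.sigma_log, size=n)


@dataclass(frozen=True)
class GroundTruth:
    """Simulation truth: spot-wise oligomer fractions and brightness law."""

    fractions: tuple[float, ...] = (0.6, 0.4)
    monomer_law: MonomerBrightnessLaw = field(
        default_factory=MonomerBrightnessLaw
    )
    active_prob: float = 1.0
    density: float = 0.5  # spots per um^2
    seed: int = 0

    def __post_init__(self) -> None:
        frac = np.asarray(self.fractions, dtype=float)
        if frac.size < 1 or np.any(frac < 0):
            raise ValueError("fractions must be nonnegative and nonempty")
        if abs(frac.sum() - 1.0) > 1e-12:
            raise ValueError(
                f"fractions must sum to 1 within 1e-12, got sum {frac.sum()!r}"
            )
        if not 0.0 <= self.active_prob <= 1.0:
            raise ValueError(
                f"active_prob must be in [0, 1], got {self.active_prob}"
            )
        if self.density < 0:
            raise ValueError(f"density must be >= 0, got {self.density}")


@dataclass(frozen=True)
class CameraModel:
    """Camera metadata: counts = photons / inverse_gain + offset."""

    offset: float = 100.0
    inverse_gain: float = 4.0  # photons per count
    read_noise_sd: float = 1.5  # counts
    pixel_size: float = 0.16  # um

    def __post_init__(self) -> None:
        if self.inverse_gain <= 0:
            raise ValueError(
                f"inverse_gain must be > 0, got {self.inverse_gain}"
            )
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.read_noise_sd < 0:
            raise ValueError(
                f"read_noise_sd must be >= 0, got {self.read_noise_sd}"
            )


@dataclass(frozen=True)
class ToccslTiming:
    """Illumination timing protocol (ms / kW cm^-2)."""

    t_bl_ms: float = 2000.0
    i_bl: float = 2.0
    recovery_ms: float = 5000.0
    t_exp_ms: float = 5.0
    i_im: float = 0.5

    def __post_init__(self) -> None:
        for name in ("t_bl_ms", "i_bl", "recovery_ms", "t_exp_ms", "i_im"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class Aperture:
    """Axis-aligned rectangular bleach region in pixel coordinates.

    Bounds are half-open: a spot at (x, y) is inside iff
    x0 <= x < x1 and y0 <= y < y1.
    """

    x0: float
    x1: float
    y0: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError("aperture must have positive extent")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (
            (x >= self.x0) & (x < self.x1) & (y >= self.y0) & (y < self.y1)
        )


def generate_monomer_brightness(
    law: MonomerBrightnessLaw, n: int, seed: int
) -> np.ndarray:
    """Draw ``n`` i.i.d. single-fluorophore brightness values (photons)."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    return law.sample(n, rng)


def generate_mixture_spots(
    truth: GroundTruth, n: int, seed: int
) -> pd.DataFrame:
    """Draw ``n`` spots from the oligomer mixture.

    Each spot's true order is drawn from ``truth.fractions``; its number of
    active fluorophores is Binomial(order, active_prob); its brightness is
    the sum of that many independent monomer draws. Spots with zero active
    fluorophores have brightness 0 and ``visible == False``.

    Returns a DataFrame with columns
    ``true_order, active_count, brightness, visible``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    frac = np.asarray(truth.fractions, dtype=float)
    orders = rng.choice(np.arange(1, frac.size + 1), size=n, p=frac)
    if truth.active_prob >= 1.0:
        active = orders.copy()
    else:
        active = rng.binomial(orders, truth.active_prob)
    brightness = np.zeros(n)
    total_active = int(active.sum())
    if total_active > 0:
        draws = truth.monomer_law.sample(total_active, rng)
        stops = np.cumsum(active)
        starts = stops - active
        sums = np.add.reduceat(draws, starts[active > 0])
        brightness[active > 0] = sums
    return pd.DataFrame(
        {
            "true_order": orders.astype(int),
            "active_count": active.astype(int),
            "brightness": brightness,
            "visible": active > 0,
        }
    )


def _integrated_gaussian(
    shape: tuple[int, int],
    x: np.ndarray,
    y: np.ndarray,
    brightness: np.ndarray,
    psf_sigma: float,
) -> np.ndarray:
    """Expected photons/pixel for spots rendered as integrated Gaussians.

    Pixel (row r, col c) covers [c-0.5, c+0.5] x [r-0.5, r+0.5]; the spot
    at continuous position (x, y) deposits ``brightness`` photons in total
    over the infinite plane.
    """
    ny, nx = shape
    img = np.zeros(shape, dtype=float)
    s = psf_sigma * math.sqrt(2.0)
    cols = np.arange(nx + 1) - 0.5
    rows = np.arange(ny + 1) - 0.5
    for xi, yi, bi in zip(x, y, brightness):
        if bi <= 0:
            continue
        cx = 0.5 * (erf((cols[1:] - xi) / s) - erf((cols[:-1] - xi) / s))
        cy = 0.5 * (erf((rows[1:] - yi) / s) - erf((rows[:-1] - yi) / s))
        img += bi * np.outer(cy, cx)
    return img


def render_image(
    x: Sequence[float],
    y: Sequence[float],
    brightness: Sequence[float],
    psf_sigma: float,
    camera: CameraModel,
    shape: tuple[int, int],
    seed: int,
    noise: bool = True,
) -> np.ndarray:
    """Render spots into a raw 16-bit camera frame.

    Each spot contributes an integrated isotropic 2D Gaussian of total
    expected photons equal to its brightness. With ``noise=True``,
    per-pixel Poisson shot noise is applied to the photon image and
    Gaussian read noise (in counts) is added after gain conversion.
    Counts are offset-shifted, clipped to [0, 65535] and rounded.
    """
    ny, nx = int(shape[0]), int(shape[1])
    if ny <= 0 or nx <= 0:
        raise ValueError(f"shape must be positive, got {shape}")
    if psf_sigma <= 0:
        raise ValueError(f"psf_sigma must be > 0, got {psf_sigma}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    brightness = np.asarray(brightness, dtype=float)
    if x.size and (
        x.min() < -0.5 or x.max() > nx - 0.5 or y.min() < -0.5 or y.max() > ny - 0.5
    ):
        raise ValueError("spot positions must lie inside the frame")
    photons = _integrated_gaussian((ny, nx), x, y, brightness, psf_sigma)
    rng = np.random.default_rng(seed)
    if noise:
        photons = rng.poisson(photons).astype(float)
    counts = photons / camera.inverse_gain + camera.offset
    if noise and camera.read_noise_sd > 0:
        counts = counts + rng.normal(0.0, camera.read_noise_sd, size=counts.shape)
    return np.clip(np.rint(counts), 0, 65535).astype(np.uint16)


def simulate_toccsl_run(
    truth: GroundTruth,
    timing: ToccslTiming,
    diffusion_d: float,
    aperture: Aperture,
    camera: CameraModel,
    shape: tuple[int, int],
    psf_sigma: float,
    seed: int,
    noise: bool = True,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Simulate one TOCCSL run: prebleach frame, postbleach frame, truth table.

    The prebleach frame holds a Poisson number of spots at the configured
    density. All fluorophores of a spot inside the aperture bleach
    together (spot-wise bleaching). Positions then evolve by Brownian
    displacements with per-axis variance 2*D*t over the recovery time; the
    postbleach frame shows surviving spots currently inside the aperture.
    """
    if diffusion_d < 0:
        raise ValueError(f"diffusion_d must be >= 0, got {diffusion_d}")
    ny, nx = int(shape[0]), int(shape[1])
    if not (
        0 <= aperture.x0 < aperture.x1 <= nx
        and 0 <= aperture.y0 < aperture.y1 <= ny
    ):
        raise ValueError("aperture must lie inside the frame")
    rng = np.random.default_rng(seed)
    area_um2 = ny * nx * camera.pixel_size**2
    n_spots = int(rng.poisson(truth.density * area_um2))
    if n_spots > 0:
        spots = generate_mixture_spots(
            truth, n_spots, seed=int(rng.integers(2**31))
        )
    else:
        spots = pd.DataFrame(
            {
                "true_order": np.array([], dtype=int),
                "active_count": np.array([], dtype=int),
                "brightness": np.array([], dtype=float),
                "visible": np.array([], dtype=bool),
            }
        )
    x = rng.uniform(0.0, nx - 1e-9, size=n_spots) - 0.5
    y = rng.uniform(0.0, ny - 1e-9, size=n_spots) - 0.5
    x = np.clip(x, -0.499, nx - 0.501)
    y = np.clip(y, -0.499, ny - 0.501)

    pre = render_image(
        x, y, spots["brightness"].to_numpy(), psf_sigma, camera, (ny, nx),
        seed=int(rng.integers(2**31)), noise=noise,
    )

    bleached = aperture.contains(x, y)
    # Brownian recovery; variance 2 D t per axis, converted to pixels.
    t_s = timing.recovery_ms / 1000.0
    sd_px = math.sqrt(2.0 * diffusion_d * t_s) / camera.pixel_size
    if sd_px > 0:
        x_post = x + rng.normal(0.0, sd_px, size=n_spots)
        y_post = y + rng.normal(0.0, sd_px, size=n_spots)
    else:
        x_post, y_post = x.copy(), y.copy()

    active_post = spots["visible"].to_numpy() & ~bleached
    in_ap_post = aperture.contains(x_post, y_post)
    render_mask = (
        active_post
        & in_ap_post
        & (x_post > -0.5) & (x_post < nx - 0.5)
        & (y_post > -0.5) & (y_post < ny - 0.5)
    )
    post = render_image(
        x_post[render_mask],
        y_post[render_mask],
        spots.loc[render_mask, "brightness"].to_numpy(),
        psf_sigma,
        camera,
        (ny, nx),
        seed=int(rng.integers(2**31)),
        noise=noise,
    )

    table = pd.DataFrame(
        {
            "spot_id": np.arange(n_spots),
            "run": 0,
            "x_px": x,
            "y_px": y,
            "x_post_px": x_post,
            "y_post_px": y_post,
            "true_order": spots["true_order"],
            "active_count": np.where(bleached, 0, spots["active_count"]),
            "brightness_photons": np.where(bleached, 0.0, spots["brightness"]),
            "bleached": bleached,
            "in_aperture_post": in_ap_post,
            "rendered_post": render_mask,
        }
    )
    return pre, post, table


def simulate_repeated_runs(
    truth: GroundTruth,
    survival_prob_per_run: float,
    exchange: bool,
    runs: int,
    seed: int,
    n_spots: int = 1000,
) -> pd.DataFrame:
    """Simulate repeated TOCCSL runs with or without subunit exchange.

    ``exchange=False``: whole spots survive each bleach cycle with
    probability ``s``; a surviving spot keeps its full composition.
    ``exchange=True``: individual fluorophores survive each cycle with
    probability ``s`` and oligomers re-pair randomly within each order
    class before every imaging step, so an order-n spot's active count at
    run r is Binomial(n, s^r).

    Returns a table with one row per (run, spot): columns
    ``run, spot_id, true_order, active_count, brightness, visible``.
    """
    if runs < 1:
        raise ValueError(f"runs must be >= 1, got {runs}")
    if not 0.0 <= survival_prob_per_run <= 1.0:
        raise ValueError(
            f"survival_prob_per_run must be in [0, 1], got {survival_prob_per_run}"
        )
    if n_spots < 1:
        raise ValueError(f"n_spots must be >= 1, got {n_spots}")
    rng = np.random.default_rng(seed)
    frac = np.asarray(truth.fractions, dtype=float)
    orders = rng.choice(np.arange(1, frac.size + 1), size=n_spots, p=frac)
    s = survival_prob_per_run

    rows = []
    if not exchange:
        alive = np.ones(n_spots, dtype=bool)
        for r in range(runs):
            if r > 0 and s < 1.0:
                alive &= rng.random(n_spots) < s
            active = np.where(alive, orders, 0)
            rows.append((r, active))
    else:
        # Per-order fluorophore pools with persistent bleach state,
        # reshuffled into spots before each imaging step (well-mixed
        # re-pairing).
        pools = {}
        for order in np.unique(orders):
            count = int((orders == order).sum())
            pools[int(order)] = np.ones(count * int(order), dtype=bool)
        for r in range(runs):
            if r > 0 and s < 1.0:
                for order, pool in pools.items():
                    pool &= rng.random(pool.size) < s
            active = np.zeros(n_spots, dtype=int)
            for order, pool in pools.items():
                idx = np.flatnonzero(orders == order)
                shuffled = rng.permutation(pool).reshape(idx.size, order)
                active[idx] = shuffled.sum(axis=1)
            rows.append((r, active))

    frames = []
    for r, active in rows:
        brightness = np.zeros(n_spots)
        total = int(active.sum())
        if total > 0:
            draws = truth.monomer_law.sample(total, rng)
            stops = np.cumsum(active)
            starts = stops - active
            brightness[active > 0] = np.add.reduceat(
                draws, starts[active > 0]
            )
        frames.append(
            pd.DataFrame(
                {
                    "run": r,
                    "spot_id": np.arange(n_spots),
                    "true_order": orders.astype(int),
                    "active_count": active.astype(int),
                    "brightness": brightness,
                    "visible": active > 0,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_frap_trace(
    mf: float,
    k: float,
    times: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Simulate a normalized FRAP recovery trace.

    I(t)/I0 = mf * (1 - exp(-K t)), plus additive Gaussian noise.
    """
    if not 0.0 <= mf <= 1.0:
        raise ValueError(f"mf must be in [0, 1], got {mf}")
    if k <= 0:
        raise ValueError(f"k must be > 0, got {k}")
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be nonnegative")
    trace = mf * (1.0 - np.exp(-k * t))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        trace = trace + rng.normal(0.0, noise_sd, size=t.shape)
    return trace
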