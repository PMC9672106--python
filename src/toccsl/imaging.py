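"""Photon conversion, sparse spot detection, and integrated-Gaussian fitting.

Raw camera frames are converted to photon counts (offset subtraction,
inverse-gain multiplication), candidate diffraction-limited spots are found
with a Gaussian matched filter plus a robust threshold, and each candidate
is fit with a constant background plus an integrated isotropic 2D Gaussian
whose volume is the single-spot brightness B in photons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.spatial import cKDTree
from scipy.special import erf

from toccsl.synthetic import CameraModel

__all__ = [
    "PhotonImage",
    "SpotFit",
    "counts_to_photons",
    "detect_spots",
    "fit_gaussian_spot",
    "extract_brightness_table",
    "estimate_surface_density",
]


@dataclass(frozen=True)
class PhotonImage:
    """2D grid of photon counts with the physical pixel size in um."""

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a nonempty 2D array")
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")


@dataclass(frozen=True)
class SpotFit:
    """One fitted diffraction-limited signal."""

    x: float
    y: float
    sigma: float
    background: float
    brightness: float  # integrated photons above background (B)
    residual_rms: float
    accepted: bool
    reason: str = ""


def counts_to_photons(raw: np.ndarray, camera: CameraModel) -> PhotonImage:
    """Convert raw camera counts to photons.

    photons = max(raw - offset, 0) * inverse_gain, elementwise. Negative
    offset-subtracted values are clipped to zero.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("raw image must be nonempty")
    pixels = np.clip(raw - camera.offset, 0.0, None) * camera.inverse_gain
    return PhotonImage(pixels=pixels, pixel_size=camera.pixel_size)


def detect_spots(
    img: PhotonImage,
    psf_sigma_hint: float,
    k_sigma: float = 5.0,
) -> np.ndarray:
    """Find candidate spot positions (x, y) in pixel coordinates.

    A Gaussian matched filter at ``psf_sigma_hint`` is applied; candidates
    are 3x3 local maxima of the filtered image exceeding
    median + k_sigma * 1.4826 * MAD. Candidate pairs closer than
    4 * psf_sigma_hint are both discarded as unresolvable.
    """
    if psf_sigma_hint <= 0:
        raise ValueError(f"psf_sigma_hint must be > 0, got {psf_sigma_hint}")
    filt = ndimage.gaussian_filter(img.pixels, psf_sigma_hint, mode="nearest")
    med = np.median(filt)
    mad = np.median(np.abs(filt - med))
    threshold = med + k_sigma * 1.4826 * mad
    local_max = filt == ndimage.maximum_filter(filt, size=3, mode="nearest")
    # Suppress flat plateaus: require strictly above the threshold and
    # strictly above at least one neighbor.
    local_min = filt == ndimage.minimum_filter(filt, size=3, mode="nearest")
    mask = local_max & ~local_min & (filt > threshold)
    ys, xs = np.nonzero(mask)
    if xs.size == 0:
        return np.empty((0, 2))
    pos = np.column_stack([xs, ys]).astype(float)
    if pos.shape[0] > 1:
        tree = cKDTree(pos)
        pairs = tree.query_pairs(4.0 * psf_sigma_hint)
        bad = set()
        for i, j in pairs:
            bad.add(i)
            bad.add(j)
        if bad:
            keep = np.setdiff1d(np.arange(pos.shape[0]), sorted(bad))
            pos = pos[keep]
    return pos


def _spot_model(
    coords: tuple[np.ndarray, np.ndarray],
    x0: float,
    y0: float,
    sigma: float,
    bg: float,
    b: float,
) -> np.ndarray:
    """Constant background + integrated 2D Gaussian over unit pixels."""
    cx, cy = coords
    s = sigma * math.sqrt(2.0)
    gx = 0.5 * (erf((cx + 0.5 - x0) / s) - erf((cx - 0.5 - x0) / s))
    gy = 0.5 * (erf((cy + 0.5 - y0) / s) - erf((cy - 0.5 - y0) / s))
    return bg + b * gx * gy


def fit_gaussian_spot(
    img: PhotonImage,
    pos: Sequence[float],
    window: int = 9,
    psf_sigma_hint: float = 1.2,
    sigma_range: tuple[float, float] = (0.5, 2.5),
) -> SpotFit:
    """Least-squares fit of one candidate spot.

    The model is a free constant background plus an integrated isotropic
    2D Gaussian; ``brightness`` is the analytically integrated Gaussian
    volume (robust to window truncation). The fit is rejected -- not an
    exception -- if the window leaves the frame, the optimizer fails,
    sigma falls outside ``sigma_range * psf_sigma_hint``, or B <= 0.
    """
    if window < 7:
        raise ValueError(f"window must be >= 7 px, got {window}")
    half = window // 2
    xc, yc = int(round(pos[0])), int(round(pos[1]))
    ny, nx = img.pixels.shape
    if not (half <= xc < nx - half and half <= yc < ny - half):
        return SpotFit(
            x=float(pos[0]), y=float(pos[1]), sigma=np.nan,
            background=np.nan, brightness=np.nan, residual_rms=np.nan,
            accepted=False, reason="window outside frame",
        )
    patch = img.pixels[yc - half : yc + half + 1, xc - half : xc + half + 1]
    cy, cx = np.mgrid[yc - half : yc + half + 1, xc - half : xc + half + 1]
    cx = cx.astype(float).ravel()
    cy = cy.astype(float).ravel()
    z = patch.astype(float).ravel()

    bg0 = float(np.median(z))
    b0 = float(max(z.sum() - bg0 * z.size, 1.0))
    p0 = [float(pos[0]), float(pos[1]), psf_sigma_hint, bg0, b0]
    lo = [xc - half, yc - half, 1e-3, -np.inf, 0.0]
    hi = [xc + half, yc + half, float(window), np.inf, np.inf]
    try:
        res = optimize.least_squares(
            lambda p: _spot_model((cx, cy), *p) - z,
            p0,
            bounds=(lo, hi),
            method="trf",
        )
    except Exception:
        return SpotFit(
            x=float(pos[0]), y=float(pos[1]), sigma=np.nan,
            background=np.nan, brightness=np.nan, residual_rms=np.nan,
            accepted=False, reason="fit diverged",
        )
    x0, y0, sigma, bg, b = res.x
    rms = float(np.sqrt(np.mean(res.fun**2)))
    smin = sigma_range[0] * psf_sigma_hint
    smax = sigma_range[1] * psf_sigma_hint
    reason = ""
    accepted = bool(res.success)
    if not accepted:
        reason = "fit diverged"
    elif not (smin <= sigma <= smax):
        accepted, reason = False, "sigma out of range"
    elif b <= 0:
        accepted, reason = False, "nonpositive brightness"
    return SpotFit(
        x=float(x0), y=float(y0), sigma=float(sigma), background=float(bg),
        brightness=float(b), residual_rms=rms, accepted=accepted,
        reason=reason,
    )


def extract_brightness_table(
    images: Iterable[np.ndarray],
    camera: CameraModel,
    psf_sigma_hint: float = 1.2,
    k_sigma: float = 5.0,
    window: int = 9,
    condition: str = "",
) -> pd.DataFrame:
    """Detect and fit spots across raw frames; return the brightness table.

    Columns: frame, x_px, y_px, sigma_px, background, B_photons, accepted,
    condition. Only rows from successful fits are marked accepted; rejected
    fits are kept for audit.
    """
    rows = []
    for frame_id, raw in enumerate(images):
        photo = counts_to_photons(np.asarray(raw), camera)
        for cand in detect_spots(photo, psf_sigma_hint, k_sigma):
            fit = fit_gaussian_spot(
                photo, cand, window=window, psf_sigma_hint=psf_sigma_hint
            )
            rows.append(
                {
                    "frame": frame_id,
                    "x_px": fit.x,
                    "y_px": fit.y,
                    "sigma_px": fit.sigma,
                    "background": fit.background,
                    "B_photons": fit.brightness,
                    "accepted": fit.accepted,
                    "condition": condition,
                }
            )
    columns = [
        "frame", "x_px", "y_px", "sigma_px", "background", "B_photons",
        "accepted", "condition",
    ]
    return pd.DataFrame(rows, columns=columns)


def estimate_surface_density(
    prebleach: PhotonImage,
    single_brightness: float,
    cell_mask: np.ndarray | None = None,
    background: float = 0.0,
) -> float:
    """Estimate molecule surface density in molecules per um^2.

    density = (mean background-corrected photons per um^2 over the mask)
    / single_brightness. ``background`` is in photons per pixel.
    """
    if single_brightness <= 0:
        raise ValueError(
            f"single_brightness must be > 0, got {single_brightness}"
        )
    if cell_mask is None:
        cell_mask = np.ones_like(prebleach.pixels, dtype=bool)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if cell_mask.shape != prebleach.pixels.shape:
        raise ValueError("cell_mask shape must match image shape")
    if not cell_mask.any():
        raise ValueError("cell_mask must be nonempty")
    corrected = np.clip(prebleach.pixels[cell_mask] - background, 0.0, None)
    area_um2 = cell_mask.sum() * prebleach.pixel_size**2
    return float(corrected.sum() / area_um2 / single_brightness)
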