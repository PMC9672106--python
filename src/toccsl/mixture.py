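"""Brightness-PDF estimation, autoconvolution, and oligomer mixture fitting.

The observed single-spot brightness density rho(B) is modeled as

    rho(B) = sum_n alpha_n * rho_n(B),    sum_n alpha_n = 1, alpha_n >= 0,

where rho_1 is the empirical single-fluorophore brightness PDF and rho_n
its (n-1)-fold autoconvolution. The primary fit maximizes the sample
log-likelihood over the simplex; a least-squares-on-histogram fit is kept
as an independent cross-check oracle. Uncertainties come from repeated
50% subsampling (default 100 repetitions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import gaussian_kde

__all__ = [
    "EmpiricalPDF",
    "OligomerDistribution",
    "estimate_monomer_pdf",
    "autoconvolve_pdf",
    "fit_mixture",
    "fit_mixture_lsq",
    "bootstrap_fractions",
    "average_oligomeric_state",
]

MIN_MONOMER_SAMPLES = 50
MIN_MIXTURE_SAMPLES = 100
DEFAULT_GRID_POINTS = 1024


@dataclass(frozen=True)
class EmpiricalPDF:
    """Tabulated probability density on a uniform brightness grid.

    ``grid`` is in photons, ``values`` in 1/photons; the trapezoidal
    integral over the grid is 1.
    """

    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if grid.ndim != 1 or grid.size < 2 or values.shape != grid.shape:
            raise ValueError("grid and values must be matching 1D arrays")
        dx = np.diff(grid)
        if not np.allclose(dx, dx[0], rtol=1e-9, atol=1e-12):
            raise ValueError("grid spacing must be uniform")
        if np.any(values < 0):
            raise ValueError("density values must be nonnegative")
        total = np.trapezoid(values, grid)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"density must integrate to 1 within 1e-6, got {total!r}"
            )
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "values", values)

    @property
    def dx(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def mean(self) -> float:
        return float(np.trapezoid(self.grid * self.values, self.grid))

    def evaluate(self, b: np.ndarray) -> np.ndarray:
        """Linear interpolation; zero density outside the grid."""
        return np.interp(b, self.grid, self.values, left=0.0, right=0.0)

    @staticmethod
    def from_unnormalized(grid: np.ndarray, values: np.ndarray) -> "EmpiricalPDF":
        values = np.clip(np.asarray(values, dtype=float), 0.0, None)
        total = np.trapezoid(values, grid)
        if total <= 0:
            raise ValueError("cannot normalize an all-zero density")
        return EmpiricalPDF(grid=np.asarray(grid, float), values=values / total)


@dataclass(frozen=True)
class OligomerDistribution:
    """Fitted oligomer fractions alpha_1..alpha_nmax with bootstrap SDs."""

    alphas: np.ndarray
    alpha_sds: np.ndarray | None
    n_max: int
    n_samples: int
    n_clipped: int = 0
    log_likelihood: float = np.nan

    def __post_init__(self) -> None:
        alphas = np.asarray(self.alphas, dtype=float)
        if alphas.size != self.n_max:
            raise ValueError("alphas must have length n_max")
        if np.any(alphas < -1e-12):
            raise ValueError("alphas must be nonnegative")
        if abs(alphas.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"alphas must sum to 1 within 1e-9, got {alphas.sum()!r}"
            )
        object.__setattr__(self, "alphas", alphas)

    @property
    def avg_state(self) -> float:
        """Average oligomeric state <n> = sum_n n * alpha_n."""
        return float(
            np.dot(np.arange(1, self.n_max + 1), self.alphas)
        )


def estimate_monomer_pdf(
    samples: np.ndarray,
    n_max: int = 3,
    n_grid: int = DEFAULT_GRID_POINTS,
    grid_pad: float = 1.2,
) -> EmpiricalPDF:
    """Kernel density estimate of the single-fluorophore brightness PDF.

    A Gaussian KDE with Silverman bandwidth is evaluated on a uniform grid
    from 0 to ``n_max * max(samples) * grid_pad`` (so the autoconvolutions
    up to order n_max fit on the same grid), clipped at zero brightness and
    renormalized to unit integral.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < MIN_MONOMER_SAMPLES:
        raise ValueError(
            f"need at least {MIN_MONOMER_SAMPLES} monomer brightness samples, "
            f"got {samples.size}"
        )
    if np.any(samples <= 0):
        raise ValueError("brightness samples must be positive")
    grid = np.linspace(0.0, n_max * samples.max() * grid_pad, n_grid)
    if np.std(samples) == 0:
        # Degenerate law: a single-cell spike at the common value.
        values = np.zeros(n_grid)
        idx = int(np.argmin(np.abs(grid - samples[0])))
        values[idx] = 1.0
        return EmpiricalPDF.from_unnormalized(grid, values)
    kde = gaussian_kde(samples, bw_method="silverman")
    return EmpiricalPDF.from_unnormalized(grid, kde(grid))


def autoconvolve_pdf(rho1: EmpiricalPDF, n: int) -> EmpiricalPDF:
    """Brightness PDF of n active fluorophores: (n-1)-fold autoconvolution.

    Computed as a discrete convolution on the (uniform, zero-anchored)
    grid and renormalized; n=1 returns rho1 unchanged.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if n == 1:
        return rho1
    if abs(rho1.grid[0]) > 1e-9:
        raise ValueError("autoconvolution requires a grid starting at 0")
    values = rho1.values
    out = values.copy()
    m = rho1.grid.size
    for _ in range(n - 1):
        out = np.convolve(out, values)[:m] * rho1.dx
    return EmpiricalPDF.from_unnormalized(rho1.grid, out)


def _component_matrix(
    samples: np.ndarray, rho1: EmpiricalPDF, n_max: int
) -> tuple[np.ndarray, int]:
    """Densities rho_n(B_i) as an (n_samples, n_max) matrix.

    Samples outside the grid support are clipped to the nearest edge;
    the clipped count is returned.
    """
    lo, hi = rho1.grid[0], rho1.grid[-1]
    clipped = int(np.sum((samples < lo) | (samples > hi)))
    b = np.clip(samples, lo, hi)
    cols = [autoconvolve_pdf(rho1, n).evaluate(b) for n in range(1, n_max + 1)]
    return np.column_stack(cols), clipped


def fit_mixture(
    samples: np.ndarray,
    rho1: EmpiricalPDF,
    n_max: int = 3,
    alpha_sds: np.ndarray | None = None,
) -> OligomerDistribution:
    """Maximum-likelihood mixture fit of the oligomer fractions.

    Maximizes sum_i log sum_n alpha_n rho_n(B_i) over the probability
    simplex, parameterized by normalized exponentials (softmax) and
    optimized with analytic gradients.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < MIN_MIXTURE_SAMPLES:
        raise ValueError(
            f"need at least {MIN_MIXTURE_SAMPLES} brightness samples, "
            f"got {samples.size}"
        )
    if n_max < 1:
        raise ValueError(f"n_max must be >= 1, got {n_max}")
    dens, n_clipped = _component_matrix(samples, rho1, n_max)
    if n_max == 1:
        ll = float(np.sum(np.log(np.clip(dens[:, 0], 1e-300, None))))
        return OligomerDistribution(
            alphas=np.array([1.0]), alpha_sds=alpha_sds, n_max=1,
            n_samples=samples.size, n_clipped=n_clipped, log_likelihood=ll,
        )
    if not np.any(dens.sum(axis=1) > 0):
        raise RuntimeError(
            "mixture fit failed: zero likelihood for all samples"
        )

    eps = 1e-300

    def neg_ll_and_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
        w = np.exp(theta - theta.max())
        alpha = w / w.sum()
        mix = dens @ alpha + eps
        nll = -np.sum(np.log(mix))
        # d nll / d alpha_n, then chain through softmax
        g_alpha = -np.sum(dens / mix[:, None], axis=0)
        g_theta = alpha * (g_alpha - np.dot(g_alpha, alpha))
        return nll, g_theta

    theta0 = np.zeros(n_max)
    res = optimize.minimize(
        neg_ll_and_grad, theta0, jac=True, method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-10},
    )
    w = np.exp(res.x - res.x.max())
    alphas = w / w.sum()
    alphas = np.clip(alphas, 0.0, None)
    alphas = alphas / alphas.sum()
    return OligomerDistribution(
        alphas=alphas, alpha_sds=alpha_sds, n_max=n_max,
        n_samples=samples.size, n_clipped=n_clipped,
        log_likelihood=float(-res.fun),
    )


def fit_mixture_lsq(
    samples: np.ndarray,
    rho1: EmpiricalPDF,
    n_max: int = 3,
    n_bins: int = 60,
) -> OligomerDistribution:
    """Least-squares-on-histogram mixture fit (cross-check oracle).

    Fits the histogram density of the samples as a nonnegative linear
    combination of rho_1..rho_nmax via NNLS, then renormalizes the
    weights onto the simplex.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < MIN_MIXTURE_SAMPLES:
        raise ValueError(
            f"need at least {MIN_MIXTURE_SAMPLES} brightness samples, "
            f"got {samples.size}"
        )
    hist, edges = np.histogram(samples, bins=n_bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    design = np.column_stack(
        [autoconvolve_pdf(rho1, n).evaluate(centers) for n in range(1, n_max + 1)]
    )
    coef, _ = optimize.nnls(design, hist)
    if coef.sum() <= 0:
        raise RuntimeError("least-squares mixture fit failed: zero solution")
    alphas = coef / coef.sum()
    return OligomerDistribution(
        alphas=alphas, alpha_sds=None, n_max=n_max, n_samples=samples.size,
    )


def bootstrap_fractions(
    samples: np.ndarray,
    rho1: EmpiricalPDF,
    n_max: int = 3,
    subsample_frac: float = 0.5,
    reps: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """SD of each alpha_n over repeated subsample fits.

    Random subsamples of ``subsample_frac`` of the data (drawn without
    replacement) are fit ``reps`` times; the per-order standard deviation
    over repetitions is returned.
    """
    if reps < 2:
        raise ValueError(f"reps must be >= 2, got {reps}")
    if not 0.0 < subsample_frac < 1.0:
        raise ValueError(
            f"subsample_frac must be in (0, 1), got {subsample_frac}"
        )
    samples = np.asarray(samples, dtype=float)
    rng = np.random.default_rng(seed)
    size = max(int(round(subsample_frac * samples.size)), MIN_MIXTURE_SAMPLES)
    size = min(size, samples.size)
    alphas = np.empty((reps, n_max))
    for r in range(reps):
        sub = rng.choice(samples, size=size, replace=False)
        alphas[r] = fit_mixture(sub, rho1, n_max).alphas
    return alphas.std(axis=0, ddof=1)


def average_oligomeric_state(dist: OligomerDistribution) -> float:
    """<n> = sum_n n * alpha_n."""
    return dist.avg_state
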