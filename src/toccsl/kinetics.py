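"""FRAP recovery fitting and the repeated-run subunit-exchange model.

FRAP traces are fit with the one-phase association model
I(t)/I0 = mf * (1 - exp(-K t)). Repeated photobleaching runs are compared
against two scenarios: stable oligomers (whole spots bleach, apparent
composition unchanged) versus subunit exchange (fluorophores bleach
individually and re-pair, shifting visible spots toward apparent
monomers). Exchange across runs is tested with the Friedman test followed
by Dunn's posthoc comparisons against the first run.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "FrapTrace",
    "FrapFit",
    "ExchangeTestResult",
    "fit_frap",
    "predict_apparent_fractions",
    "active_fluorophore_decline",
    "exchange_test",
]


@dataclass(frozen=True)
class FrapTrace:
    """A normalized FRAP recovery trace: I(t)/I0 versus time in seconds."""

    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        if t.ndim != 1 or t.shape != i.shape:
            raise ValueError("times and intensities must be matching 1D arrays")
        if t.size and (t[0] < 0 or np.any(np.diff(t) <= 0)):
            raise ValueError("times must be strictly increasing and start >= 0")
        if not np.all(np.isfinite(i)):
            raise ValueError("intensities must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", i)


@dataclass(frozen=True)
class FrapFit:
    """One-phase association fit result."""

    mf: float
    k: float
    ci95_mf: tuple[float, float]
    ci95_k: tuple[float, float]
    rss: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.mf <= 1.1:
            warnings.warn(
                f"mobile fraction {self.mf:.3f} outside [0, 1.1]; "
                "check trace normalization",
                stacklevel=3,
            )


@dataclass(frozen=True)
class ExchangeTestResult:
    """Friedman test over runs plus Dunn posthoc versus the first run."""

    avg_states: np.ndarray  # mean <n> per run
    friedman_statistic: float
    friedman_p: float
    posthoc_p: dict[int, float]  # run index -> Dunn-corrected p vs run 0
    posthoc_significant: dict[int, bool]


def _frap_model(t: np.ndarray, mf: float, k: float) -> np.ndarray:
    return mf * (1.0 - np.exp(-k * t))


def fit_frap(trace: FrapTrace) -> FrapFit:
    """Nonlinear least-squares fit of the one-phase association model.

    Initialization: mf0 = mean of the last 10% of intensities; K0 from the
    time at which the trace first reaches half of mf0. The 95% CI is taken
    from the parameter covariance. Raises RuntimeError on nonconvergence.
    """
    t, y = trace.times, trace.intensities
    if t.size < 5:
        raise ValueError(f"need at least 5 points, got {t.size}")
    n_tail = max(1, int(math.ceil(0.1 * t.size)))
    mf0 = float(np.mean(y[-n_tail:]))
    if mf0 <= 1e-9:
        # Flat-zero trace: the model collapses to mf = 0 with K unidentifiable.
        rss = float(np.sum(y**2))
        return FrapFit(
            mf=0.0, k=math.nan, ci95_mf=(0.0, 0.0),
            ci95_k=(math.nan, math.nan), rss=rss,
        )
    above = np.nonzero(y >= 0.5 * mf0)[0]
    t_half = t[above[0]] if above.size and t[above[0]] > 0 else (
        t[-1] / 2 if t[-1] > 0 else 1.0
    )
    k0 = math.log(2.0) / t_half
    try:
        popt, pcov = optimize.curve_fit(
            _frap_model, t, y, p0=[min(mf0, 1.0), k0],
            bounds=([0.0, 1e-9], [1.5, np.inf]), maxfev=10000,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"FRAP fit did not converge (initial mf0={mf0:.4g}, K0={k0:.4g})"
        ) from exc
    mf, k = popt
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    rss = float(np.sum((_frap_model(t, mf, k) - y) ** 2))
    ci_mf = (float(mf - 1.96 * perr[0]), float(mf + 1.96 * perr[0]))
    ci_k = (float(k - 1.96 * perr[1]), float(k + 1.96 * perr[1]))
    if t[-1] * k < 1.0:
        warnings.warn(
            "trace may be too short: K*t_max < 1, plateau poorly constrained",
            stacklevel=2,
        )
    return FrapFit(mf=float(mf), k=float(k), ci95_mf=ci_mf, ci95_k=ci_k, rss=rss)


def predict_apparent_fractions(
    fractions: np.ndarray, q: float, exchange: bool
) -> np.ndarray:
    """Apparent visible-spot fractions after partial bleaching.

    ``q`` is the per-fluorophore active probability (survival fraction).
    Without exchange, whole oligomers are either fully active or fully
    dark, so the visible composition equals the truth for any q > 0. With
    exchange, fluorophores bleach independently and re-pair: an order-n
    spot shows k active fluorophores with probability C(n,k) q^k (1-q)^(n-k),
    and visible spots (k >= 1) are binned by apparent order k.
    """
    fractions = np.asarray(fractions, dtype=float)
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must be in [0, 1], got {q}")
    if abs(fractions.sum() - 1.0) > 1e-9 or np.any(fractions < 0):
        raise ValueError("fractions must be a probability vector")
    n_max = fractions.size
    if not exchange or q == 1.0:
        if q == 0.0:
            raise ZeroDivisionError("q=0 leaves no visible spots")
        return fractions.copy()
    apparent = np.zeros(n_max)
    for n in range(1, n_max + 1):
        a = fractions[n - 1]
        if a == 0:
            continue
        for k in range(1, n + 1):
            apparent[k - 1] += a * math.comb(n, k) * q**k * (1 - q) ** (n - k)
    total = apparent.sum()
    if total <= 0:
        raise ZeroDivisionError("q=0 leaves no visible spots")
    return apparent / total


def enumerate_apparent_fractions(
    fractions: np.ndarray, q: float
) -> np.ndarray:
    """Brute-force oracle for :func:`predict_apparent_fractions` (exchange).

    Enumerates every per-fluorophore bleach-state combination of each
    oligomer order explicitly instead of using binomial coefficients.
    """
    fractions = np.asarray(fractions, dtype=float)
    n_max = fractions.size
    apparent = np.zeros(n_max)
    for n in range(1, n_max + 1):
        a = fractions[n - 1]
        for states in product([0, 1], repeat=n):
            k = sum(states)
            if k == 0:
                continue
            prob = 1.0
            for s in states:
                prob *= q if s else (1 - q)
            apparent[k - 1] += a * prob
    total = apparent.sum()
    if total <= 0:
        raise ZeroDivisionError("q=0 leaves no visible spots")
    return apparent / total


def active_fluorophore_decline(counts: np.ndarray) -> np.ndarray:
    """Percent decrease of active-fluorophore counts versus the first run.

    Returns 100 * (1 - counts[r] / counts[0]) for each r >= 1.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 1 or counts[0] <= 0:
        raise ValueError("counts[0] must be positive")
    return 100.0 * (1.0 - counts[1:] / counts[0])


def exchange_test(
    avg_state_matrix: np.ndarray | pd.DataFrame,
    alpha: float = 0.05,
) -> ExchangeTestResult:
    """Test for subunit exchange across repeated runs.

    ``avg_state_matrix`` holds the per-cell average oligomeric state with
    one row per cell and one column per run (the same cells in every run).
    Runs are compared with the Friedman test; runs >= 2 are compared to the
    first run with Dunn's posthoc test (normal approximation on Friedman
    mean ranks, Bonferroni-style correction over the comparisons made).
    """
    mat = np.asarray(avg_state_matrix, dtype=float)
    if mat.ndim != 2:
        raise ValueError("avg_state_matrix must be 2D (cells x runs)")
    n_cells, n_runs = mat.shape
    if n_runs < 3:
        raise ValueError(f"need >= 3 runs, got {n_runs}")
    if n_cells < 6:
        raise ValueError(f"need >= 6 cells, got {n_cells}")
    if not np.all(np.isfinite(mat)):
        raise ValueError("avg_state_matrix must be finite (equal cell sets)")

    if np.allclose(mat, mat[:, [0]]):
        # Identical values in every run: no effect by construction.
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.friedmanchisquare(*(mat[:, j] for j in range(n_runs)))

    ranks = np.apply_along_axis(stats.rankdata, 1, mat)
    mean_ranks = ranks.mean(axis=0)
    se = math.sqrt(n_runs * (n_runs + 1) / (6.0 * n_cells))
    n_comp = n_runs - 1
    posthoc_p: dict[int, float] = {}
    posthoc_sig: dict[int, bool] = {}
    for j in range(1, n_runs):
        z = (mean_ranks[j] - mean_ranks[0]) / se
        p_raw = 2.0 * stats.norm.sf(abs(z))
        p_adj = min(1.0, p_raw * n_comp)
        posthoc_p[j] = float(p_adj)
        posthoc_sig[j] = bool(p_adj < alpha)
    return ExchangeTestResult(
        avg_states=mat.mean(axis=0),
        friedman_statistic=float(stat),
        friedman_p=float(p),
        posthoc_p=posthoc_p,
        posthoc_significant=posthoc_sig,
    )
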