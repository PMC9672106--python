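"""End-to-end pipeline: photon conversion -> detection -> Gaussian fits ->
density -> mixture fit -> bootstrap, plus condition-comparison statistics.

Outputs are deterministic: every CSV carries a header comment with the
config hash and seed, and reruns with identical config are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import stats

from toccsl.config import RunConfig, config_hash
from toccsl.imaging import (
    counts_to_photons,
    estimate_surface_density,
    extract_brightness_table,
)
from toccsl.mixture import (
    MIN_MIXTURE_SAMPLES,
    bootstrap_fractions,
    estimate_monomer_pdf,
    fit_mixture,
)

logger = logging.getLogger("toccsl")

__all__ = [
    "PipelineResult",
    "run_pipeline",
    "density_oligomer_correlation",
    "compare_conditions",
    "write_csv",
]


@dataclass
class PipelineResult:
    per_cell: pd.DataFrame
    aggregate: pd.DataFrame
    brightness: pd.DataFrame
    output_dir: Path


def write_csv(df: pd.DataFrame, path: Path, header: str) -> None:
    """Write a CSV with a reproducibility header comment."""
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")


def _read_frames(path: Path) -> list[np.ndarray]:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        return [arr]
    return [arr[i] for i in range(arr.shape[0])]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full analysis described by ``config``.

    For each cell: read frames, convert to photons, detect and fit spots,
    estimate surface density from the prebleach frame, then fit the
    oligomer mixture (per cell, and pooled per condition when
    ``config.pooling == 'experiment'``). Unreadable images are recorded as
    per-cell failures and the pipeline continues.
    """
    mono_path = config.resolve(config.monomer_brightness_csv)
    mono = pd.read_csv(mono_path, comment="#")
    col = "B_photons" if "B_photons" in mono.columns else "brightness"
    if col not in mono.columns:
        raise ValueError(
            f"monomer CSV {mono_path} needs a 'B_photons' or 'brightness' column"
        )
    monomer_samples = mono[col].to_numpy(dtype=float)
    monomer_samples = monomer_samples[monomer_samples > 0]
    rho1 = estimate_monomer_pdf(monomer_samples, n_max=config.n_max)
    single_brightness = float(monomer_samples.mean())
    tag = f"config_hash={config_hash(config)} seed={config.seed}"

    cell_rows = []
    bright_frames = []
    for cell in config.cells:
        row: dict = {
            "cell_id": cell.cell_id,
            "condition": cell.condition,
            "status": "ok",
            "density_per_um2": np.nan,
            "n_spots": 0,
        }
        try:
            frames = []
            for p in cell.postbleach_tiffs:
                frames.extend(_read_frames(config.resolve(p)))
            table = extract_brightness_table(
                frames,
                config.camera,
                psf_sigma_hint=config.psf_sigma_px,
                k_sigma=config.k_sigma,
                window=config.window_px,
                condition=cell.condition,
            )
            table.insert(0, "cell_id", cell.cell_id)
            bright_frames.append(table)
            accepted = table[table["accepted"]]
            row["n_spots"] = int(len(accepted))
            n_rej = int(len(table) - len(accepted))
            if n_rej:
                logger.debug("cell %s: %d rejected spots", cell.cell_id, n_rej)
            if cell.prebleach_tiff:
                pre = _read_frames(config.resolve(cell.prebleach_tiff))[0]
                photo = counts_to_photons(pre, config.camera)
                row["density_per_um2"] = estimate_surface_density(
                    photo, single_brightness
                )
        except (OSError, ValueError) as exc:
            logger.warning("cell %s failed: %s", cell.cell_id, exc)
            row["status"] = f"failed: {exc}"
        cell_rows.append(row)

    brightness = (
        pd.concat(bright_frames, ignore_index=True)
        if bright_frames
        else pd.DataFrame(
            columns=[
                "cell_id", "frame", "x_px", "y_px", "sigma_px", "background",
                "B_photons", "accepted", "condition",
            ]
        )
    )

    per_cell = pd.DataFrame(cell_rows)
    alpha_cols = [f"alpha_{n}" for n in range(1, config.n_max + 1)]
    sd_cols = [f"alpha_{n}_sd" for n in range(1, config.n_max + 1)]
    for c in alpha_cols + sd_cols + ["avg_state"]:
        per_cell[c] = np.nan

    def _fit_block(samples: np.ndarray, seed: int):
        dist = fit_mixture(samples, rho1, config.n_max)
        sds = bootstrap_fractions(
            samples, rho1, config.n_max,
            subsample_frac=config.subsample_frac,
            reps=config.bootstrap_reps, seed=seed,
        )
        return dist, sds

    if config.pooling == "cell":
        for idx, cell in enumerate(config.cells):
            sub = brightness[
                (brightness["cell_id"] == cell.cell_id) & brightness["accepted"]
            ]
            samples = sub["B_photons"].to_numpy()
            if samples.size < MIN_MIXTURE_SAMPLES:
                logger.warning(
                    "cell %s skipped: %d spots < %d",
                    cell.cell_id, samples.size, MIN_MIXTURE_SAMPLES,
                )
                continue
            dist, sds = _fit_block(samples, config.seed + idx)
            per_cell.loc[idx, alpha_cols] = dist.alphas
            per_cell.loc[idx, sd_cols] = sds
            per_cell.loc[idx, "avg_state"] = dist.avg_state

    agg_rows = []
    for cond, group in brightness[brightness["accepted"]].groupby(
        "condition", sort=True
    ):
        samples = group["B_photons"].to_numpy()
        if samples.size < MIN_MIXTURE_SAMPLES:
            logger.warning(
                "condition %s skipped: %d spots < %d",
                cond, samples.size, MIN_MIXTURE_SAMPLES,
            )
            continue
        dist, sds = _fit_block(samples, config.seed)
        agg_rows.append(
            {
                "condition": cond,
                "n_samples": int(samples.size),
                **{c: a for c, a in zip(alpha_cols, dist.alphas)},
                **{c: s for c, s in zip(sd_cols, sds)},
                "avg_state": dist.avg_state,
            }
        )
    aggregate = pd.DataFrame(
        agg_rows,
        columns=["condition", "n_samples", *alpha_cols, *sd_cols, "avg_state"],
    )

    out = Path(config.base_dir) / config.output_dir
    write_csv(per_cell, out / "per_cell.csv", tag)
    write_csv(aggregate, out / "aggregate.csv", tag)
    write_csv(brightness, out / "brightness.csv", tag)
    return PipelineResult(
        per_cell=per_cell, aggregate=aggregate, brightness=brightness,
        output_dir=out,
    )


def density_oligomer_correlation(
    densities: np.ndarray, avg_states: np.ndarray
) -> tuple[float, float]:
    """Spearman rank correlation of surface density versus <n>.

    Returns (r, two-tailed p). Requires >= 10 cells; constant input raises.
    """
    d = np.asarray(densities, dtype=float)
    a = np.asarray(avg_states, dtype=float)
    if d.size != a.size or d.size < 10:
        raise ValueError(f"need >= 10 paired cells, got {d.size}")
    if np.ptp(d) == 0 or np.ptp(a) == 0:
        raise ValueError("correlation undefined for constant input")
    res = stats.spearmanr(d, a)
    return float(res.statistic), float(res.pvalue)


def compare_conditions(
    group_a: np.ndarray, group_b: np.ndarray
) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test between two condition groups."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError(
            f"each group needs >= 3 values, got {a.size} and {b.size}"
        )
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
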