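"""Structured run configuration (YAML) for the pipeline CLI."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from toccsl.synthetic import CameraModel

__all__ = ["CellSpec", "RunConfig", "ConfigError", "load_config", "config_hash"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass(frozen=True)
class CellSpec:
    cell_id: str
    condition: str = "control"
    prebleach_tiff: str | None = None
    postbleach_tiffs: tuple[str, ...] = ()


@dataclass(frozen=True)
class RunConfig:
    seed: int
    output_dir: str
    camera: CameraModel
    monomer_brightness_csv: str
    cells: tuple[CellSpec, ...]
    psf_sigma_px: float = 1.2
    k_sigma: float = 5.0
    window_px: int = 9
    n_max: int = 3
    bootstrap_reps: int = 100
    subsample_frac: float = 0.5
    pooling: str = "experiment"  # "experiment" pools spots across cells
    base_dir: str = "."
    raw: dict = field(default_factory=dict, compare=False)

    def resolve(self, path: str) -> Path:
        p = Path(path)
        return p if p.is_absolute() else Path(self.base_dir) / p


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the configuration content."""
    canon = yaml.safe_dump(cfg.raw, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    All referenced input files must exist at load time.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"config must be a mapping, got {type(raw).__name__}")
    base_dir = str(path.parent)
    try:
        cam = raw.get("camera", {})
        camera = CameraModel(
            offset=float(cam.get("offset", 100.0)),
            inverse_gain=float(cam.get("inverse_gain", 4.0)),
            read_noise_sd=float(cam.get("read_noise_sd", 1.5)),
            pixel_size=float(cam.get("pixel_size", 0.16)),
        )
        det = raw.get("detection", {})
        mix = raw.get("mixture", {})
        cells = tuple(
            CellSpec(
                cell_id=str(c["cell_id"]),
                condition=str(c.get("condition", "control")),
                prebleach_tiff=c.get("prebleach_tiff"),
                postbleach_tiffs=tuple(c.get("postbleach_tiffs", ())),
            )
            for c in raw.get("cells", [])
        )
        cfg = RunConfig(
            seed=int(raw.get("seed", 0)),
            output_dir=str(raw.get("output_dir", "toccsl_out")),
            camera=camera,
            monomer_brightness_csv=str(raw["monomer_brightness_csv"]),
            cells=cells,
            psf_sigma_px=float(det.get("psf_sigma_px", 1.2)),
            k_sigma=float(det.get("k_sigma", 5.0)),
            window_px=int(det.get("window_px", 9)),
            n_max=int(mix.get("n_max", 3)),
            bootstrap_reps=int(mix.get("bootstrap_reps", 100)),
            subsample_frac=float(mix.get("subsample_frac", 0.5)),
            pooling=str(mix.get("pooling", "experiment")),
            base_dir=base_dir,
            raw=raw,
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"invalid config {path}: {exc}") from exc
    if cfg.pooling not in ("experiment", "cell"):
        raise ConfigError(f"pooling must be 'experiment' or 'cell', got {cfg.pooling!r}")
    missing = []
    mono = cfg.resolve(cfg.monomer_brightness_csv)
    if not mono.exists():
        missing.append(str(mono))
    for cell in cfg.cells:
        for p in ([cell.prebleach_tiff] if cell.prebleach_tiff else []) + list(
            cell.postbleach_tiffs
        ):
            if not cfg.resolve(p).exists():
                missing.append(str(cfg.resolve(p)))
    if missing:
        raise ConfigError("missing input files: " + ", ".join(missing))
    if not cfg.cells:
        raise ConfigError("config lists no cells")
    return cfg
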