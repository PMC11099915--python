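"""Config-driven orchestration: simulate -> analyze -> summarize -> report.

One YAML config (or a RunConfig built in code) drives the full loop:
render synthetic scenes per genotype preset, run the whole-image
filter/ratio analysis and the ROI core/corona analysis on each, pool
per-genotype summaries, and write every artifact plus a manifest that
records parameters, seeds and SHA-256 checksums.  Re-running the same
config reproduces every stochastic output bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cube_io import export_wavelength_matrix, write_cube
from .roi_ratiometry import (
    InsufficientRegionError,
    auto_place_rois,
    records_to_frame,
    roi_ratios,
    summarize_regions,
)
from .spectral_model import make_wavelength_grid
from .synthetic_data import (
    DEFAULT_FIELD_SHAPE,
    GENOTYPE_PRESETS,
    genotype_preset,
    render_cube,
    single_plaque_scene,
)
from .whole_image_analysis import (
    GENOTYPE_FILTER_DEFAULTS,
    FilterSettings,
    background_mask,
    gaussian_cutoff,
    image_set_mean,
    pooled_density,
    ratio_matrix,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    """Everything one pipeline run needs; seeds are mandatory."""

    presets: list[str] = field(default_factory=lambda: list(GENOTYPE_PRESETS))
    n_images: int = 5
    seed: int | None = 0
    field_shape: tuple[int, int] = DEFAULT_FIELD_SHAPE
    grid: tuple[float, float, float] = (450.0, 700.0, 10.0)
    filter_settings: dict[str, FilterSettings] = field(default_factory=dict)
    roi_policy: str = "auto"  # "auto" | "skip"
    roi_window: int = 5
    out_dir: str = "lcoratio_run"

    def __post_init__(self) -> None:
        unknown = set(self.presets) - set(GENOTYPE_PRESETS)
        if unknown:
            raise ValueError(f"unknown presets: {sorted(unknown)}")
        if self.seed is None:
            raise ValueError("a seed is required (noise is always stochastic)")
        if self.roi_policy not in ("auto", "skip"):
            raise ValueError("roi_policy must be 'auto' or 'skip'")
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if "filter_settings" in doc:
        doc["filter_settings"] = {
            k: FilterSettings(**v) for k, v in doc["filter_settings"].items()
        }
    if "field_shape" in doc:
        doc["field_shape"] = tuple(doc["field_shape"])
    if "grid" in doc:
        doc["grid"] = tuple(doc["grid"])
    return RunConfig(**doc)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = make_wavelength_grid(*config.grid, require_ratiometry=True)
    produced: list[Path] = []
    summary: dict = {"per_genotype": {}}

    for preset in config.presets:
        try:
            stage = "simulate+whole-image"
            settings = config.filter_settings.get(
                preset, GENOTYPE_FILTER_DEFAULTS.get(preset, FilterSettings()))
            rms = []
            for i in range(config.n_images):
                scene = genotype_preset(preset, config.field_shape,
                                        seed=config.seed * 1000 + i)
                cube, truth = render_cube(scene, grid, seed=config.seed * 1000 + i)
                cube_path = out / f"{preset}_img{i}.tif"
                write_cube(cube, cube_path)
                produced.append(cube_path)
                low = cube.plane(500.0)
                high = cube.plane(540.0)
                for lam, mat_name in ((500.0, "I500"), (540.0, "I540")):
                    mat_path = out / f"{preset}_img{i}_{mat_name}.tsv"
                    export_wavelength_matrix(cube, lam, mat_path)
                    produced.append(mat_path)
                mask = background_mask(low, high, settings)
                rms.append(ratio_matrix(low, high, mask))
            mean_ratio, n_px = image_set_mean(rms)
            curve = pooled_density(rms)
            dens_path = out / f"{preset}_density.csv"
            pd.DataFrame({"ratio": curve.ratio, "density": curve.density}).to_csv(
                dens_path, index=False)
            produced.append(dens_path)
            mu_l, sd_l, cut_l = gaussian_cutoff(low, settings.k_upper_low)
            mu_h, sd_h, cut_h = gaussian_cutoff(high, settings.k_lower_high)
            geno_summary = {
                "mean_ratio": mean_ratio,
                "n_kept_pixels": n_px,
                "kept_fraction": n_px / (config.n_images * np.prod(config.field_shape)),
                "density_mode": curve.mode,
                "filter": asdict(settings),
                "last_image_cutoffs": {
                    "mu_low": mu_l, "sigma_low": sd_l, "upper_low": cut_l,
                    "mu_high": mu_h, "sigma_high": sd_h, "lower_high": cut_h,
                },
            }

            if config.roi_policy == "auto":
                stage = "roi"
                records = []
                for i in range(config.n_images):
                    scene = single_plaque_scene(preset, seed=config.seed * 1000 + i,
                                                field_shape=config.field_shape)
                    cube, truth = render_cube(scene, grid,
                                              seed=config.seed * 1000 + i)
                    try:
                        table = auto_place_rois(
                            truth, plaque_id=0, window=config.roi_window,
                            seed=config.seed * 1000 + i,
                            image_id=f"{preset}_plaque{i}",
                        )
                    except InsufficientRegionError as exc:
                        logger.warning("skipping plaque: %s", exc)
                        continue
                    records.extend(roi_ratios(cube, table))
                if records:
                    frame = records_to_frame(records)
                    roi_path = out / f"{preset}_roi_records.csv"
                    frame.to_csv(roi_path, index=False)
                    produced.append(roi_path)
                    region_stats = {
                        s.group[0]: {"n": s.n, "mean": s.mean, "sem": s.sem}
                        for s in summarize_regions(frame)
                    }
                    geno_summary["roi"] = region_stats
            summary["per_genotype"][preset] = geno_summary
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{stage}' failed for {preset}: {exc}"
                               ) from exc

    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2))
    produced.append(summary_path)

    manifest = {
        "version": __version__,
        "config": {
            "presets": config.presets,
            "n_images": config.n_images,
            "seed": config.seed,
            "field_shape": list(config.field_shape),
            "grid": list(config.grid),
            "roi_policy": config.roi_policy,
            "roi_window": config.roi_window,
            "filter_settings": {k: asdict(v)
                                for k, v in config.filter_settings.items()},
        },
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in produced},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
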