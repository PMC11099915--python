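"""Cube, per-wavelength text-matrix and ROI-table I/O.

A hyperspectral cube is stored as a multi-page TIFF, one page per
emission channel, with the wavelength list and acquisition metadata in
the image-description tag.  The per-wavelength tab-delimited matrix
format mirrors the export path of the original spectral-camera
workflow (one H x W intensity matrix per wavelength, loaded into an
analysis session as a plain matrix) and is the fidelity bridge for
feeding externally exported data into this pipeline.

Coordinate convention, repo-wide: row-major, 0-based, coordinates name
pixel centers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

from .spectral_model import WavelengthGrid

__all__ = [
    "SpectralCube",
    "write_cube",
    "read_cube",
    "export_wavelength_matrix",
    "import_wavelength_matrix",
    "read_roi_table",
    "write_roi_table",
    "validate_roi_table",
    "ROI_COLUMNS",
    "REGION_LABELS",
]

REGION_LABELS = ("core", "corona")
ROI_COLUMNS = ["image_id", "plaque_id", "region", "center_row", "center_col", "window"]


@dataclass
class SpectralCube:
    """H x W x L stack of emission intensities on a wavelength grid."""

    data: np.ndarray
    grid: WavelengthGrid
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be H x W x L")
        if self.data.shape[2] != self.grid.n_channels:
            raise ValueError(
                f"cube has {self.data.shape[2]} channels but grid declares "
                f"{self.grid.n_channels}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube intensities must be finite")
        if np.any(self.data < 0):
            raise ValueError("cube intensities must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    def plane(self, wavelength_nm: float) -> np.ndarray:
        """The H x W intensity matrix at the nearest channel."""
        return self.data[:, :, self.grid.channel_index(wavelength_nm)]


def write_cube(cube: SpectralCube, path) -> None:
    """Write a cube as a page-per-channel TIFF with JSON metadata."""
    pages = np.moveaxis(cube.data, 2, 0)  # (L, H, W)
    desc = json.dumps(
        {
            "wavelengths_nm": [float(x) for x in cube.grid.channels],
            "grid": {
                "start_nm": cube.grid.start_nm,
                "stop_nm": cube.grid.stop_nm,
                "step_nm": cube.grid.step_nm,
            },
            "meta": cube.meta,
        }
    )
    tifffile.imwrite(path, pages, description=desc, photometric="minisblack")


def read_cube(path) -> SpectralCube:
    """Read a cube written by :func:`write_cube` (lossless round-trip)."""
    with tifffile.TiffFile(path) as tf:
        desc = tf.pages[0].description
        if not desc:
            raise ValueError(f"{path}: missing wavelength metadata")
        try:
            info = json.loads(desc)
            wavelengths = info["wavelengths_nm"]
            gspec = info["grid"]
        except (json.JSONDecodeError, KeyError) as exc:
            raise ValueError(f"{path}: malformed wavelength metadata") from exc
        data = tf.asarray()
    if data.ndim == 2:
        data = data[None]
    if data.shape[0] != len(wavelengths):
        raise ValueError(
            f"{path}: {data.shape[0]} pages but {len(wavelengths)} declared wavelengths"
        )
    grid = WavelengthGrid(gspec["start_nm"], gspec["stop_nm"], gspec["step_nm"])
    if grid.n_channels != len(wavelengths):
        raise ValueError(f"{path}: grid spec inconsistent with wavelength list")
    return SpectralCube(
        data=np.moveaxis(data, 0, 2), grid=grid, meta=info.get("meta", {})
    )


def export_wavelength_matrix(cube: SpectralCube, wavelength_nm: float, path) -> None:
    """Export one channel as a headerless tab-delimited H x W text matrix.

    Values are printed with 6 significant digits, '.' decimal separator.
    """
    np.savetxt(path, cube.plane(wavelength_nm), fmt="%.6g", delimiter="\t")


def import_wavelength_matrix(path) -> np.ndarray:
    """Read a tab-delimited intensity matrix; rows must be rectangular."""
    mat = np.loadtxt(path, delimiter="\t", ndmin=2)
    return mat


def validate_roi_table(table: pd.DataFrame, image_shape: tuple[int, int] | None = None
                       ) -> pd.DataFrame:
    """Validate an ROI table against the repo-wide ROI contract."""
    missing = [c for c in ROI_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"ROI table missing columns: {missing}")
    bad_region = set(table["region"]) - set(REGION_LABELS)
    if bad_region:
        raise ValueError(f"unknown region labels: {sorted(bad_region)}")
    windows = table["window"].to_numpy()
    if np.any(windows < 1) or np.any(windows % 2 == 0):
        raise ValueError("ROI windows must be odd and >= 1")
    if image_shape is not None:
        h, w = image_shape
        half = windows // 2
        rows = table["center_row"].to_numpy()
        cols = table["center_col"].to_numpy()
        inside = (
            (rows - half >= 0) & (rows + half < h)
            & (cols - half >= 0) & (cols + half < w)
        )
        if not np.all(inside):
            raise ValueError(
                f"{np.count_nonzero(~inside)} ROI window(s) clipped by the image border"
            )
    return table


def read_roi_table(path, image_shape: tuple[int, int] | None = None) -> pd.DataFrame:
    table = pd.read_csv(path)
    return validate_roi_table(table, image_shape)


def write_roi_table(table: pd.DataFrame, path) -> None:
    validate_roi_table(table)
    table.to_csv(path, index=False)
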