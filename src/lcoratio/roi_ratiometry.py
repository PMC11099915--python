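"""ROI-based core/corona ratiometric analysis.

The protocol this reproduces: from each plaque, four 5x5-pixel regions
of interest (~1x1 um at the default pixel pitch) are taken from the
core and four from the corona; each ROI's emission intensity at 500 nm
(qFTAA) is divided by its intensity at 540 nm and at 588 nm (the two
hFTAA peaks), and the per-region ratio means +/- SEM separate compact
core fibrils from the diffusely packed corona.

ROI statistic: mean intensity per channel, then the ratio of means (not
the mean of per-pixel ratios) -- stabler at low counts; switchable via
``per_pixel=True`` in :func:`roi_ratios`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion

from .cube_io import ROI_COLUMNS, SpectralCube, validate_roi_table
from .spectral_model import HFTAA_PEAK1_NM, HFTAA_PEAK2_NM, QFTAA_PEAK_NM
from .synthetic_data import GroundTruth, LABEL_CORE, LABEL_CORONA

__all__ = [
    "ROIRatioRecord",
    "RegionSummary",
    "roi_intensity",
    "roi_ratios",
    "auto_place_rois",
    "summarize_regions",
    "InsufficientRegionError",
]


class InsufficientRegionError(ValueError):
    """A plaque region is too small to host the requested ROI windows."""


@dataclass(frozen=True)
class ROIRatioRecord:
    """Intensities and ratios of one ROI (NaN ratio = undefined)."""

    image_id: str
    plaque_id: int
    region: str
    i500: float
    i540: float
    i588: float
    r540: float
    r588: float


@dataclass(frozen=True)
class RegionSummary:
    group: tuple
    n: int
    mean: float
    sem: float


def roi_intensity(
    cube: SpectralCube,
    center_row: int,
    center_col: int,
    wavelength_nm: float,
    window: int = 5,
) -> float:
    """Arithmetic mean intensity of the window x window ROI at a channel."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    half = window // 2
    h, w = cube.shape
    if not (half <= center_row < h - half and half <= center_col < w - half):
        raise ValueError(
            f"ROI at ({center_row}, {center_col}) window {window} clipped by border"
        )
    plane = cube.plane(wavelength_nm)
    block = plane[
        center_row - half : center_row + half + 1,
        center_col - half : center_col + half + 1,
    ]
    return float(block.mean())


def _safe_ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def roi_ratios(
    cube: SpectralCube, roi_table: pd.DataFrame, *, per_pixel: bool = False
) -> list[ROIRatioRecord]:
    """One ratio record per ROI row.

    Default statistic is ratio-of-means over the window; with
    ``per_pixel=True`` it is the mean of per-pixel ratios instead
    (undefined pixels excluded).  Undefined ratios are reported as NaN,
    never dropped silently.
    """
    validate_roi_table(roi_table, cube.shape)
    records = []
    for row in roi_table.itertuples(index=False):
        args = (cube, int(row.center_row), int(row.center_col))
        window = int(row.window)
        i500 = roi_intensity(*args, QFTAA_PEAK_NM, window)
        i540 = roi_intensity(*args, HFTAA_PEAK1_NM, window)
        i588 = roi_intensity(*args, HFTAA_PEAK2_NM, window)
        if per_pixel:
            half = window // 2
            sl = (
                slice(int(row.center_row) - half, int(row.center_row) + half + 1),
                slice(int(row.center_col) - half, int(row.center_col) + half + 1),
            )
            p500 = cube.plane(QFTAA_PEAK_NM)[sl]
            r540 = _masked_pixel_ratio_mean(p500, cube.plane(HFTAA_PEAK1_NM)[sl])
            r588 = _masked_pixel_ratio_mean(p500, cube.plane(HFTAA_PEAK2_NM)[sl])
        else:
            r540 = _safe_ratio(i500, i540)
            r588 = _safe_ratio(i500, i588)
        records.append(
            ROIRatioRecord(
                image_id=str(row.image_id),
                plaque_id=int(row.plaque_id),
                region=str(row.region),
                i500=i500, i540=i540, i588=i588, r540=r540, r588=r588,
            )
        )
    return records


def _masked_pixel_ratio_mean(num: np.ndarray, den: np.ndarray) -> float:
    ok = den > 0
    if not ok.any():
        return float("nan")
    return float((num[ok] / den[ok]).mean())


def records_to_frame(records: list[ROIRatioRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def auto_place_rois(
    truth: GroundTruth,
    plaque_id: int,
    n_core: int = 4,
    n_corona: int = 4,
    window: int = 5,
    seed: int = 0,
    image_id: str = "synthetic",
) -> pd.DataFrame:
    """Sample ROI centers inside one plaque's core and corona labels.

    The original analysis picked ROIs ocularly; unattended runs need a
    deterministic stand-in.  Candidate centers are pixels whose whole
    window lies inside the region label (morphological erosion by the
    window footprint), ordered row-major, then sampled without
    replacement with the given seed.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    rng = np.random.default_rng(seed)
    rows_out: list[dict] = []
    for region_label, region_name, n_want in (
        (LABEL_CORE, "core", n_core),
        (LABEL_CORONA, "corona", n_corona),
    ):
        region = (truth.label_map == region_label) & (truth.plaque_map == plaque_id)
        if window > 1:
            interior = binary_erosion(
                region, structure=np.ones((window, window), dtype=bool)
            )
        else:
            interior = region
        cand_rows, cand_cols = np.nonzero(interior)  # row-major order
        if cand_rows.size < n_want:
            raise InsufficientRegionError(
                f"plaque {plaque_id} {region_name}: {cand_rows.size} candidate "
                f"centers for {n_want} ROIs of window {window}"
            )
        pick = rng.choice(cand_rows.size, size=n_want, replace=False)
        for i in np.sort(pick):
            rows_out.append(
                {
                    "image_id": image_id,
                    "plaque_id": plaque_id,
                    "region": region_name,
                    "center_row": int(cand_rows[i]),
                    "center_col": int(cand_cols[i]),
                    "window": window,
                }
            )
    return pd.DataFrame(rows_out, columns=ROI_COLUMNS)


def summarize_regions(
    records: list[ROIRatioRecord] | pd.DataFrame,
    group_by: list[str] = ("region",),
    value: str = "r540",
) -> list[RegionSummary]:
    """Per-group n, mean and SEM of one ratio column.

    Undefined (NaN) ratios are excluded with a warning that states the
    count; a group of a single defined value gets SEM 0 with a warning.
    """
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    n_undefined = int(frame[value].isna().sum())
    if n_undefined:
        warnings.warn(f"excluding {n_undefined} undefined {value} ratio(s)")
    frame = frame.dropna(subset=[value])
    summaries = []
    for key, sub in frame.groupby(list(group_by), sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        vals = sub[value].to_numpy()
        if vals.size == 0:
            raise ValueError(f"group {key}: no defined ratios")
        if vals.size == 1:
            warnings.warn(f"group {key}: single observation, SEM set to 0")
            sem = 0.0
        else:
            sem = float(vals.std(ddof=1) / np.sqrt(vals.size))
        summaries.append(
            RegionSummary(group=key, n=int(vals.size), mean=float(vals.mean()), sem=sem)
        )
    if not summaries:
        raise ValueError("no groups with defined ratios")
    return summaries
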