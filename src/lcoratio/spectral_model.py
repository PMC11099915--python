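"""Emission-spectrum model for two-dye LCO amyloid staining.

The two luminescent conjugated oligothiophenes used to stain amyloid
deposits have conformation-dependent emission: the short probe qFTAA,
which binds tightly packed bundled fibrils, emits with a single peak at
500 nm, while the long probe hFTAA, which binds both single and bundled
fibrils, emits with a double peak at 540 and 588 nm.  Every pixel of a
co-stained hyperspectral image is modelled as a nonnegative linear
mixture of three endmembers -- qFTAA, hFTAA and a broad tissue
background -- and the conformation readout is the intensity ratio
I500/I540 (or I500/I588) of that mixture.

This module defines the wavelength grid, the endmember templates, linear
mixing and the nearest-channel ratio operation that every downstream
stage uses.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import fsolve

__all__ = [
    "WavelengthGrid",
    "EmissionTemplate",
    "MixWeights",
    "make_wavelength_grid",
    "dye_template",
    "mix_spectrum",
    "ratio_at",
    "write_template",
    "read_template",
    "QFTAA_PEAK_NM",
    "HFTAA_PEAK1_NM",
    "HFTAA_PEAK2_NM",
    "RATIOMETRY_WAVELENGTHS_NM",
]

# Emission peaks of the dye-bound probes (nm).
QFTAA_PEAK_NM = 500.0
HFTAA_PEAK1_NM = 540.0
HFTAA_PEAK2_NM = 588.0

#: The three channels every ratiometry-capable grid must resolve.
RATIOMETRY_WAVELENGTHS_NM = (QFTAA_PEAK_NM, HFTAA_PEAK1_NM, HFTAA_PEAK2_NM)

# Band-shape configuration.  Peak positions are measured quantities; the
# widths and the 540:588 height ratio are model choices (see
# docs/methods.md) and can be overridden via dye_template keyword
# arguments.
QFTAA_SIGMA_NM = 25.0
HFTAA_SIGMA_NM = 22.0
HFTAA_PEAK2_REL_HEIGHT = 0.85
BACKGROUND_LEVEL_AT_450 = 1.0
BACKGROUND_LEVEL_AT_700 = 0.3

DYE_IDS = ("qFTAA", "hFTAA", "background")


@dataclass(frozen=True)
class WavelengthGrid:
    """Regular emission-wavelength grid (nm) of a hyperspectral cube."""

    start_nm: float
    stop_nm: float
    step_nm: float

    def __post_init__(self) -> None:
        if not self.start_nm < self.stop_nm:
            raise ValueError(
                f"start_nm ({self.start_nm}) must be < stop_nm ({self.stop_nm})"
            )
        if not self.step_nm > 0:
            raise ValueError(f"step_nm must be positive, got {self.step_nm}")

    @property
    def channels(self) -> np.ndarray:
        """Channel centers start, start+step, ... <= stop (nm)."""
        n = int(np.floor((self.stop_nm - self.start_nm) / self.step_nm + 1e-9)) + 1
        return self.start_nm + self.step_nm * np.arange(n)

    @property
    def n_channels(self) -> int:
        return self.channels.size

    def channel_index(self, wavelength_nm: float) -> int:
        """Index of the nearest channel; the match must be within step/2."""
        ch = self.channels
        i = int(np.argmin(np.abs(ch - wavelength_nm)))
        if abs(ch[i] - wavelength_nm) > self.step_nm / 2 + 1e-9:
            raise ValueError(
                f"wavelength {wavelength_nm} nm not resolvable on grid "
                f"[{self.start_nm}, {self.stop_nm}] step {self.step_nm}"
            )
        return i

    def supports_ratiometry(self) -> bool:
        """True if 500, 540 and 588 nm all resolve to a channel."""
        try:
            for wl in RATIOMETRY_WAVELENGTHS_NM:
                self.channel_index(wl)
        except ValueError:
            return False
        return True


def make_wavelength_grid(
    start_nm: float, stop_nm: float, step_nm: float, require_ratiometry: bool = False
) -> WavelengthGrid:
    """Build a regular wavelength grid.

    With ``require_ratiometry=True`` the grid is rejected unless it can
    index 500, 540 and 588 nm each within half a step, which the ratio
    operations need.
    """
    grid = WavelengthGrid(start_nm, stop_nm, step_nm)
    if require_ratiometry and not grid.supports_ratiometry():
        raise ValueError(
            "grid cannot resolve the ratiometry channels (500/540/588 nm) "
            "within step/2"
        )
    return grid


@dataclass(frozen=True)
class EmissionTemplate:
    """Unit-max normalized endmember emission spectrum on a grid."""

    dye_id: str
    grid: WavelengthGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.dye_id not in DYE_IDS:
            raise ValueError(f"unknown dye_id {self.dye_id!r}; expected one of {DYE_IDS}")
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.grid.n_channels,):
            raise ValueError("values length does not match grid channel count")
        if np.any(v < 0):
            raise ValueError("template values must be nonnegative")
        if not np.isclose(v.max(), 1.0):
            raise ValueError("template must be unit-max normalized")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class MixWeights:
    """Absolute brightness contributions of the three endmembers (a.u.).

    Weights are not forced to sum to one: a bright pixel simply has large
    weights.  ``qftaa_fraction`` is the packing readout w_q/(w_q+w_h).
    """

    w_q: float = 0.0
    w_h: float = 0.0
    w_bg: float = 0.0

    def __post_init__(self) -> None:
        if self.w_q < 0 or self.w_h < 0 or self.w_bg < 0:
            raise ValueError("mixture weights must be nonnegative")

    @property
    def qftaa_fraction(self) -> float:
        tot = self.w_q + self.w_h
        return self.w_q / tot if tot > 0 else 0.0


def _gaussian(x: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / sigma) ** 2)


@functools.lru_cache(maxsize=None)
def _hftaa_band_parameters(
    sigma: float, peak2_height: float
) -> tuple[float, float, float, float]:
    """Component amplitudes/centers for the hFTAA double band.

    The template is a sum of two Gaussian bands, but the observable
    constraint is on the *sum*: local maxima exactly at 540 and 588 nm
    with heights 1 and ``peak2_height``.  Because the bands overlap, the
    component centers must sit slightly outside the target peaks; we
    solve the four conditions f(540)=1, f(588)=h, f'(540)=0, f'(588)=0
    for the two amplitudes and two centers.
    """

    p1, p2 = HFTAA_PEAK1_NM, HFTAA_PEAK2_NM

    def equations(params: np.ndarray) -> list[float]:
        a1, c1, a2, c2 = params

        def f(x: float) -> float:
            return a1 * np.exp(-0.5 * ((x - c1) / sigma) ** 2) + a2 * np.exp(
                -0.5 * ((x - c2) / sigma) ** 2
            )

        def fprime(x: float) -> float:
            return a1 * np.exp(-0.5 * ((x - c1) / sigma) ** 2) * (
                -(x - c1) / sigma**2
            ) + a2 * np.exp(-0.5 * ((x - c2) / sigma) ** 2) * (-(x - c2) / sigma**2)

        return [f(p1) - 1.0, f(p2) - peak2_height, fprime(p1), fprime(p2)]

    guess = np.array([1.0, p1 - 4.0, peak2_height, p2 + 5.0])
    sol, info, ier, msg = fsolve(equations, guess, full_output=True)
    if ier != 1:
        raise RuntimeError(f"hFTAA band solve failed: {msg}")
    return tuple(float(x) for x in sol)


def dye_template(
    dye_id: str,
    grid: WavelengthGrid,
    *,
    qftaa_sigma_nm: float = QFTAA_SIGMA_NM,
    hftaa_sigma_nm: float = HFTAA_SIGMA_NM,
    hftaa_peak2_rel_height: float = HFTAA_PEAK2_REL_HEIGHT,
) -> EmissionTemplate:
    """Endmember emission template for qFTAA, hFTAA or tissue background.

    qFTAA is a single Gaussian band peaking at 500 nm; hFTAA a double
    Gaussian band with summed-spectrum maxima exactly at 540 and 588 nm
    (second peak at ``hftaa_peak2_rel_height`` of the first); background
    a slowly decaying broad ramp.  All templates are unit-max normalized.
    """
    if grid.start_nm > 460 or grid.stop_nm < 650:
        raise ValueError("template grid must span at least 460-650 nm")
    lam = grid.channels
    if dye_id == "qFTAA":
        v = _gaussian(lam, QFTAA_PEAK_NM, qftaa_sigma_nm)
    elif dye_id == "hFTAA":
        a1, c1, a2, c2 = _hftaa_band_parameters(hftaa_sigma_nm, hftaa_peak2_rel_height)
        v = a1 * _gaussian(lam, c1, hftaa_sigma_nm) + a2 * _gaussian(
            lam, c2, hftaa_sigma_nm
        )
    elif dye_id == "background":
        # Linear decay from 1.0 at 450 nm to 0.3 at 700 nm, clipped.
        v = BACKGROUND_LEVEL_AT_450 + (BACKGROUND_LEVEL_AT_700 - BACKGROUND_LEVEL_AT_450) * (
            lam - 450.0
        ) / (700.0 - 450.0)
        v = np.clip(v, 0.0, None)
    else:
        raise ValueError(f"unknown dye_id {dye_id!r}; expected one of {DYE_IDS}")
    v = v / v.max()
    return EmissionTemplate(dye_id=dye_id, grid=grid, values=v)


def standard_templates(grid: WavelengthGrid) -> dict[str, EmissionTemplate]:
    """The three default endmembers on one grid, keyed by dye_id."""
    return {d: dye_template(d, grid) for d in DYE_IDS}


def mix_spectrum(
    weights: MixWeights, templates: dict[str, EmissionTemplate]
) -> np.ndarray:
    """Linear forward model: w_q*T_q + w_h*T_h + w_bg*T_bg per channel."""
    grids = {t.grid for t in templates.values()}
    if len(grids) != 1:
        raise ValueError("all templates must share one wavelength grid")
    grid = next(iter(grids))
    out = np.zeros(grid.n_channels)
    for w, dye in ((weights.w_q, "qFTAA"), (weights.w_h, "hFTAA"), (weights.w_bg, "background")):
        if w != 0.0:
            out += w * templates[dye].values
    return out


def ratio_at(
    spectrum: np.ndarray,
    grid: WavelengthGrid,
    num_nm: float = QFTAA_PEAK_NM,
    den_nm: float = HFTAA_PEAK1_NM,
) -> float:
    """Intensity ratio I(num)/I(den) at the nearest grid channels.

    An undefined ratio (denominator intensity <= 0) is returned as NaN so
    that it propagates as masked rather than as +/-infinity.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    num = spectrum[grid.channel_index(num_nm)]
    den = spectrum[grid.channel_index(den_nm)]
    if den <= 0:
        return float("nan")
    return float(num / den)


def write_template(template: EmissionTemplate, path) -> None:
    """Serialize a template as wavelength_nm <TAB> relative_intensity."""
    arr = np.column_stack([template.grid.channels, template.values])
    np.savetxt(path, arr, fmt="%.6g", delimiter="\t", comments="",
               header=f"# dye_id={template.dye_id}")


def read_template(path, dye_id: str) -> EmissionTemplate:
    """Read a two-column template file back onto its implied grid."""
    arr = np.loadtxt(path, delimiter="\t", comments="#")
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("template file must have two columns")
    lam, vals = arr[:, 0], arr[:, 1]
    steps = np.diff(lam)
    if not np.allclose(steps, steps[0]):
        raise ValueError("template wavelengths must be regularly spaced")
    grid = WavelengthGrid(float(lam[0]), float(lam[-1]), float(steps[0]))
    vals = vals / vals.max()
    return EmissionTemplate(dye_id=dye_id, grid=grid, values=vals)
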