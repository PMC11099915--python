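"""Seed-reproducible synthetic hyperspectral scenes of plaque-bearing tissue.

Real inputs to this pipeline are hyperspectral micrographs of
flash-frozen brain cryosections double-stained with qFTAA and hFTAA.
No such images ship with the package, so this module generates
surrogate scenes with per-pixel ground truth: each amyloid plaque is a
compact qFTAA-rich core disk inside an hFTAA-rich corona annulus on a
dim autofluorescent background, and each mouse-model preset differs in
plaque size, number and core dye composition the way the APP23 (few
large mature-cored plaques), APPPS1 (many medium plaques) and App NL-F
(few small plaques with tiny immature cores) architectures differ.

Geometry and noise draw from separate child streams of one master seed,
so a fixed geometry can be re-rendered under fresh noise.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, asdict

import numpy as np

from .spectral_model import (
    MixWeights,
    WavelengthGrid,
    mix_spectrum,
    standard_templates,
)

__all__ = [
    "PlaqueSpec",
    "SceneSpec",
    "GroundTruth",
    "genotype_preset",
    "single_plaque_scene",
    "render_cube",
    "render_fibril_smear",
    "GENOTYPE_PRESETS",
    "FIBRIL_PRESETS",
    "LABEL_BACKGROUND",
    "LABEL_CORE",
    "LABEL_CORONA",
    "DEFAULT_UM_PER_PX",
    "DEFAULT_FIELD_SHAPE",
    "scene_to_yaml",
    "scene_from_yaml",
]

# Ground-truth pixel classes.
LABEL_BACKGROUND = 0
LABEL_CORE = 1
LABEL_CORONA = 2

#: Default pixel pitch: a 5x5 ROI then spans ~1x1 um, the ROI size used
#: in the ratiometric protocol.
DEFAULT_UM_PER_PX = 0.2
DEFAULT_FIELD_SHAPE = (512, 512)

# Default acquisition-noise model (arbitrary units).  photon_scale is
# a.u. per detected count (shot noise); read_sigma is additive Gaussian
# read noise, ~2% of the default peak plaque signal.
DEFAULT_PHOTON_SCALE = 0.25
DEFAULT_READ_SIGMA = 2.0
DEFAULT_BRIGHTNESS = 100.0
DEFAULT_BACKGROUND_LEVEL = 3.0


@dataclass(frozen=True)
class PlaqueSpec:
    """One concentric core/corona plaque in a scene."""

    center: tuple[int, int]  # (row, col), px, 0-based
    core_radius_um: float
    corona_radius_um: float
    core_weights: MixWeights
    corona_weights: MixWeights
    brightness: float = DEFAULT_BRIGHTNESS

    def __post_init__(self) -> None:
        if not 0 < self.core_radius_um < self.corona_radius_um:
            raise ValueError(
                "need 0 < core_radius_um < corona_radius_um, got "
                f"{self.core_radius_um} / {self.corona_radius_um}"
            )
        # Cores are never less qFTAA-rich than their corona.
        if self.core_weights.qftaa_fraction < self.corona_weights.qftaa_fraction - 1e-12:
            raise ValueError(
                "core qFTAA fraction must be >= corona qFTAA fraction"
            )
        if self.brightness <= 0:
            raise ValueError("brightness must be positive")


@dataclass
class SceneSpec:
    """Generative description of one synthetic brain-section field."""

    shape: tuple[int, int]
    plaques: list[PlaqueSpec]
    um_per_px: float = DEFAULT_UM_PER_PX
    background_level: float = DEFAULT_BACKGROUND_LEVEL
    read_sigma: float = DEFAULT_READ_SIGMA
    photon_scale: float = DEFAULT_PHOTON_SCALE
    genotype_label: str = ""

    def __post_init__(self) -> None:
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        if self.read_sigma < 0 or self.photon_scale < 0:
            raise ValueError("noise parameters must be nonnegative")
        h, w = self.shape
        for p in self.plaques:
            r_px = p.corona_radius_um / self.um_per_px
            r0, c0 = p.center
            if not (r_px <= r0 <= h - 1 - r_px and r_px <= c0 <= w - 1 - r_px):
                raise ValueError(
                    f"plaque at {p.center} (corona {r_px:.1f} px) does not fit "
                    f"inside a {h}x{w} field"
                )


@dataclass
class GroundTruth:
    """Per-pixel truth for a rendered scene."""

    label_map: np.ndarray  # uint8, LABEL_* codes
    plaque_map: np.ndarray  # int32, plaque index, -1 for background
    weight_q: np.ndarray
    weight_h: np.ndarray
    weight_bg: np.ndarray


# Preset parameter distributions.  Radii are um; qFTAA fractions are
# w_q/(w_q+w_h).  Values are stand-ins chosen to preserve the relative
# plaque architectures of the three mouse models: APP23 few large
# plaques with strongly qFTAA-dominated mature cores, APPPS1 many
# medium plaques with intermediate cores, App NL-F few small plaques
# with tiny, weakly qFTAA-positive cores.
GENOTYPE_PRESETS: dict[str, dict] = {
    "APP23-like": {
        "n_plaques": (2, 3),
        "corona_radius_um": (20.0, 32.0),
        "core_radius_frac": (0.35, 0.5),
        "core_qftaa_fraction": (0.50, 0.65),
        "corona_qftaa_fraction": (0.14, 0.22),
        "brightness": (80.0, 120.0),
    },
    "APPPS1-like": {
        "n_plaques": (6, 10),
        "corona_radius_um": (8.0, 15.0),
        "core_radius_frac": (0.30, 0.45),
        "core_qftaa_fraction": (0.28, 0.40),
        "corona_qftaa_fraction": (0.08, 0.14),
        "brightness": (80.0, 120.0),
    },
    "NLF-like": {
        "n_plaques": (2, 4),
        "corona_radius_um": (3.0, 8.0),
        "core_radius_frac": (0.12, 0.20),
        "core_qftaa_fraction": (0.10, 0.18),
        "corona_qftaa_fraction": (0.05, 0.10),
        "brightness": (80.0, 120.0),
    },
}

# Deposited in-vitro fibril fields: Ab40 fibrils bundle laterally and
# stain strongly with qFTAA; Ab42 fibrils stay mostly solitary and
# qFTAA-poor.
FIBRIL_PRESETS: dict[str, dict] = {
    "Ab40-like": {"qftaa_fraction": (0.38, 0.52), "n_clumps": 40},
    "Ab42-like": {"qftaa_fraction": (0.08, 0.16), "n_clumps": 40},
}


def _age_core_fraction_shift(preset: str, age_months: float) -> float:
    """Age modulation of the core qFTAA fraction (plaque-core maturation).

    Overexpressor-like presets show a sigmoidal rise of core qFTAA
    positivity with a transition at ~12 months; the knock-in-like preset
    stays flat.  Returned as an additive shift to the preset's core
    qFTAA fraction, clipped downstream to [0, 0.75].
    """
    if preset == "NLF-like":
        return 0.0
    amplitude = 0.30 if preset == "APP23-like" else 0.20
    return amplitude * (1.0 / (1.0 + np.exp(-(age_months - 12.0) / 1.5)) - 0.5)


def genotype_preset(
    name: str,
    field_shape: tuple[int, int] = DEFAULT_FIELD_SHAPE,
    seed: int = 0,
    *,
    um_per_px: float = DEFAULT_UM_PER_PX,
    age_months: float | None = None,
) -> SceneSpec:
    """Draw a scene from one of the mouse-model-like preset distributions.

    The draw is fully determined by ``(name, field_shape, seed,
    age_months)``.  ``age_months`` optionally shifts the core qFTAA
    fraction along the preset's maturation curve (rise after 12 months
    for the overexpressor-like presets, flat for NLF-like).
    """
    if name not in GENOTYPE_PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; expected one of {sorted(GENOTYPE_PRESETS)}"
        )
    p = GENOTYPE_PRESETS[name]
    rng = np.random.default_rng(
        np.random.SeedSequence([zlib.crc32(name.encode()) & 0x7FFFFFFF, seed])
    )
    h, w = field_shape
    n = int(rng.integers(p["n_plaques"][0], p["n_plaques"][1] + 1))
    shift = 0.0 if age_months is None else _age_core_fraction_shift(name, age_months)

    plaques: list[PlaqueSpec] = []
    placed: list[tuple[float, float, float]] = []  # (row, col, radius_px)
    for _ in range(n):
        corona_um = float(rng.uniform(*p["corona_radius_um"]))
        core_um = corona_um * float(rng.uniform(*p["core_radius_frac"]))
        r_px = corona_um / um_per_px
        if 2 * r_px + 2 > min(h, w):
            corona_um = (min(h, w) / 2 - 2) * um_per_px
            r_px = corona_um / um_per_px
            core_um = min(core_um, 0.5 * corona_um)
        # Prefer non-overlapping placement; fall back to overlap after
        # bounded rejection sampling so dense presets always render.
        for attempt in range(200):
            r0 = float(rng.uniform(r_px, h - 1 - r_px))
            c0 = float(rng.uniform(r_px, w - 1 - r_px))
            if all(
                np.hypot(r0 - rr, c0 - cc) >= r_px + pr for rr, cc, pr in placed
            ) or attempt == 199:
                break
        # Integer centers must stay inside the radius bound after rounding.
        r0 = float(np.clip(round(r0), int(np.ceil(r_px)), int(np.floor(h - 1 - r_px))))
        c0 = float(np.clip(round(c0), int(np.ceil(r_px)), int(np.floor(w - 1 - r_px))))
        placed.append((r0, c0, r_px))
        corona_fq = float(rng.uniform(*p["corona_qftaa_fraction"]))
        core_fq = float(rng.uniform(*p["core_qftaa_fraction"])) + shift
        core_fq = float(np.clip(core_fq, corona_fq, 0.75))
        brightness = float(rng.uniform(*p["brightness"]))
        plaques.append(
            PlaqueSpec(
                center=(int(round(r0)), int(round(c0))),
                core_radius_um=core_um,
                corona_radius_um=corona_um,
                core_weights=MixWeights(w_q=core_fq, w_h=1.0 - core_fq),
                corona_weights=MixWeights(w_q=corona_fq, w_h=1.0 - corona_fq),
                brightness=brightness,
            )
        )
    return SceneSpec(
        shape=field_shape,
        plaques=plaques,
        um_per_px=um_per_px,
        genotype_label=name,
    )


def single_plaque_scene(
    preset: str,
    seed: int,
    field_shape: tuple[int, int] = DEFAULT_FIELD_SHAPE,
    *,
    age_months: float | None = None,
) -> SceneSpec:
    """One centered plaque drawn from a preset (for per-plaque analyses)."""
    scene = genotype_preset(preset, field_shape, seed, age_months=age_months)
    plaque = scene.plaques[0]
    centered = PlaqueSpec(
        center=(field_shape[0] // 2, field_shape[1] // 2),
        core_radius_um=plaque.core_radius_um,
        corona_radius_um=plaque.corona_radius_um,
        core_weights=plaque.core_weights,
        corona_weights=plaque.corona_weights,
        brightness=plaque.brightness,
    )
    return SceneSpec(
        shape=field_shape,
        plaques=[centered],
        um_per_px=scene.um_per_px,
        genotype_label=preset,
    )


def _paint_scene(scene: SceneSpec) -> GroundTruth:
    """Rasterize plaque disks into label, plaque-id and weight maps."""
    h, w = scene.shape
    rows, cols = np.mgrid[0:h, 0:w]
    label = np.full((h, w), LABEL_BACKGROUND, dtype=np.uint8)
    plaque_map = np.full((h, w), -1, dtype=np.int32)
    wq = np.zeros((h, w))
    wh = np.zeros((h, w))
    wbg = np.full((h, w), float(scene.background_level))
    for i, p in enumerate(scene.plaques):
        d = np.hypot(rows - p.center[0], cols - p.center[1]) * scene.um_per_px
        corona = d <= p.corona_radius_um
        core = d <= p.core_radius_um
        annulus = corona & ~core
        # Later plaques overwrite earlier ones where coronas overlap.
        for mask, lab, weights in (
            (annulus, LABEL_CORONA, p.corona_weights),
            (core, LABEL_CORE, p.core_weights),
        ):
            label[mask] = lab
            plaque_map[mask] = i
            wq[mask] = p.brightness * weights.w_q
            wh[mask] = p.brightness * weights.w_h
            wbg[mask] = p.brightness * weights.w_bg
    return GroundTruth(label_map=label, plaque_map=plaque_map,
                       weight_q=wq, weight_h=wh, weight_bg=wbg)


def _apply_noise(
    noiseless: np.ndarray, read_sigma: float, photon_scale: float, rng: np.random.Generator
) -> np.ndarray:
    data = noiseless
    if photon_scale > 0:
        data = rng.poisson(noiseless / photon_scale) * photon_scale
    if read_sigma > 0:
        data = data + rng.normal(0.0, read_sigma, size=noiseless.shape)
    if photon_scale > 0 or read_sigma > 0:
        data = np.clip(data, 0.0, None)
    return data


def render_cube(
    scene: SceneSpec, grid: WavelengthGrid, seed: int = 0, *, noise: bool = True
):
    """Render a scene into a hyperspectral cube plus its ground truth.

    The noiseless spectrum of a pixel is the linear mixture of its
    weight-map endmember contributions; acquisition noise is Poisson
    shot noise (granularity ``photon_scale`` a.u./count) plus Gaussian
    read noise, clipped at zero.  Bit-identical for a fixed seed.
    """
    from .cube_io import SpectralCube  # local import to avoid a cycle

    if not grid.supports_ratiometry():
        raise ValueError("grid cannot resolve the ratiometry channels")
    truth = _paint_scene(scene)
    templates = standard_templates(grid)
    basis = np.stack(
        [templates["qFTAA"].values, templates["hFTAA"].values,
         templates["background"].values]
    )  # (3, L)
    weights = np.stack([truth.weight_q, truth.weight_h, truth.weight_bg], axis=-1)
    noiseless = weights @ basis  # (H, W, L)
    if noise:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0BE]))
        data = _apply_noise(noiseless, scene.read_sigma, scene.photon_scale, rng)
    else:
        data = noiseless
    cube = SpectralCube(
        data=data,
        grid=grid,
        meta={"genotype": scene.genotype_label, "seed": seed},
    )
    return cube, truth


def render_fibril_smear(
    condition: str,
    grid: WavelengthGrid,
    seed: int = 0,
    field_shape: tuple[int, int] = (256, 256),
    *,
    n_clumps: int | None = None,
    noise: bool = True,
):
    """Render a deposited in-vitro fibril slide as a clumped texture field.

    No core/corona geometry: fibril material clumps with a
    condition-specific qFTAA fraction (Ab40-like high, Ab42-like low) on
    the standard background, with the standard noise model.
    """
    from .cube_io import SpectralCube

    if condition not in FIBRIL_PRESETS:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of {sorted(FIBRIL_PRESETS)}"
        )
    if not grid.supports_ratiometry():
        raise ValueError("grid cannot resolve the ratiometry channels")
    p = FIBRIL_PRESETS[condition]
    n = p["n_clumps"] if n_clumps is None else n_clumps
    rng_geom = np.random.default_rng(
        np.random.SeedSequence([zlib.crc32(condition.encode()) & 0x7FFFFFFF, seed, 1])
    )
    h, w = field_shape
    rows, cols = np.mgrid[0:h, 0:w]
    brightness = np.zeros((h, w))
    fq_map = np.zeros((h, w))
    for _ in range(n):
        r0 = rng_geom.uniform(0, h - 1)
        c0 = rng_geom.uniform(0, w - 1)
        radius = rng_geom.uniform(4.0, 14.0)  # px
        amp = rng_geom.uniform(0.5, 1.0) * DEFAULT_BRIGHTNESS
        fq = rng_geom.uniform(*p["qftaa_fraction"])
        blob = amp * np.exp(-0.5 * ((rows - r0) ** 2 + (cols - c0) ** 2) / radius**2)
        take = blob > brightness
        fq_map[take] = fq
        brightness = np.maximum(brightness, blob)
    templates = standard_templates(grid)
    basis = np.stack(
        [templates["qFTAA"].values, templates["hFTAA"].values,
         templates["background"].values]
    )
    weights = np.stack(
        [brightness * fq_map, brightness * (1.0 - fq_map),
         np.full((h, w), DEFAULT_BACKGROUND_LEVEL)],
        axis=-1,
    )
    noiseless = weights @ basis
    if noise:
        rng_noise = np.random.default_rng(np.random.SeedSequence([seed, 0xF1B]))
        data = _apply_noise(noiseless, DEFAULT_READ_SIGMA, DEFAULT_PHOTON_SCALE, rng_noise)
    else:
        data = noiseless
    return SpectralCube(data=data, grid=grid, meta={"condition": condition, "seed": seed})


# -- scene (de)serialization -------------------------------------------------

def scene_to_yaml(scene: SceneSpec, path) -> None:
    import yaml

    doc = {
        "shape": list(scene.shape),
        "um_per_px": scene.um_per_px,
        "background_level": scene.background_level,
        "read_sigma": scene.read_sigma,
        "photon_scale": scene.photon_scale,
        "genotype_label": scene.genotype_label,
        "plaques": [
            {
                "center": list(p.center),
                "core_radius_um": p.core_radius_um,
                "corona_radius_um": p.corona_radius_um,
                "core_weights": asdict(p.core_weights),
                "corona_weights": asdict(p.corona_weights),
                "brightness": p.brightness,
            }
            for p in scene.plaques
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def scene_from_yaml(path) -> SceneSpec:
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    plaques = [
        PlaqueSpec(
            center=tuple(p["center"]),
            core_radius_um=p["core_radius_um"],
            corona_radius_um=p["corona_radius_um"],
            core_weights=MixWeights(**p["core_weights"]),
            corona_weights=MixWeights(**p["corona_weights"]),
            brightness=p["brightness"],
        )
        for p in doc["plaques"]
    ]
    return SceneSpec(
        shape=tuple(doc["shape"]),
        plaques=plaques,
        um_per_px=doc["um_per_px"],
        background_level=doc["background_level"],
        read_sigma=doc["read_sigma"],
        photon_scale=doc["photon_scale"],
        genotype_label=doc.get("genotype_label", ""),
    )
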