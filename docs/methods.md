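# Methods

## The measurement this package models

Luminescent conjugated oligothiophenes (LCOs) are amyloid ligands whose
emission spectrum depends on the conformation of the fibril they bind.
Co-staining brain sections with two of them — qFTAA, a short probe that
binds tightly packed bundled Aβ fibrils and emits with a single peak at
500 nm, and hFTAA, a longer probe that binds both single and bundled
fibrils and emits with double peaks at 540 and 588 nm — turns fibril
packing polymorphism into an optical readout. A hyperspectral
micrograph records a full emission spectrum per pixel; the intensity
ratios I500/I540 and I500/I588 are then surrogate markers for how
compactly the amyloid at that pixel is packed. In aged overexpressor
mouse models the compact plaque core is qFTAA-dominated (high ratio)
while the diffuse corona is hFTAA-dominated (low ratio), and the three
model genotypes (APP23, APPPS1, App NL-F) differ systematically in
plaque architecture and core maturation.

The package implements the two quantitative analyses built on that
readout, plus the statistics used to compare groups:

1. **ROI ratiometry** — four 5×5-pixel regions of interest from the
   core and four from the corona of each plaque; per-ROI channel means;
   ratios of means; per-region mean ± SEM.
2. **Whole-image pixel analysis** — Gaussian reference-interval
   filtering of the exported 500 nm and 540 nm intensity matrices,
   per-pixel ratio matrix on the surviving pixels, heatmaps, violin
   data, kernel-density curves, and pooled per-genotype mean ratios.
3. **Trend and group statistics** — ordinary least-squares cubic of
   mean ratio versus age; ordinary one-way ANOVA; unpaired two-sample
   t test; significance stars (*p<0.05 through ****p<0.0001). No
   multiple-testing correction is applied anywhere, matching the
   single-comparison reporting style of the protocol this follows; all
   p values are reported as computed.

Because no real image data ship with the package, a synthetic-scene
generator provides the study conditions and the per-pixel ground truth
that unattended testing needs.

## Spectral model

Endmember templates live on a regular wavelength grid (default 450–700
nm in 10 nm steps; a grid must resolve 500/540/588 nm within half a
step to be used for ratiometry; wavelength lookup is nearest-channel,
no interpolation, mirroring single-channel export workflows).

* **qFTAA**: one Gaussian band, center 500 nm, σ = 25 nm.
* **hFTAA**: sum of two Gaussian bands, σ = 22 nm each. Only the peak
  positions (540/588 nm) and an approximate relative height (0.85) are
  observable constraints; since overlapping Gaussians shift each
  other's maxima by several nm, the component centers and amplitudes
  are solved numerically (four conditions: value 1 at 540, value 0.85
  at 588, zero slope at both) so the *summed* template peaks exactly at
  540 and 588 nm. The solved component centers land near 537.4 and
  592.4 nm.
* **background**: linear decay from 1.0 at 450 nm to 0.3 at 700 nm — a
  purely generative stand-in for broadband tissue autofluorescence.

Band widths and the 540:588 height ratio are not published quantities;
they are package choices exposed as `dye_template` keyword arguments.
All templates are unit-max normalized and all intensities are in
arbitrary units; no photometric calibration is attempted. A pixel
spectrum is the nonnegative linear mixture w_q·T_q + w_h·T_h +
w_bg·T_bg; weights are absolute brightness contributions and are not
normalized. The qFTAA fraction f_q = w_q/(w_q+w_h) is the generative
packing parameter, and I500/I540 of a mixture increases monotonically
with it.

## Synthetic scenes

A scene is a list of concentric-disk plaques (core disk inside corona
annulus) on a dim background. Defaults:

| parameter | default | why |
|---|---|---|
| pixel pitch | 0.2 μm/px | a 5×5 ROI then spans ~1×1 μm, the ROI size of the protocol |
| field | 512×512 px (102 μm) | fits the largest preset plaques |
| plaque brightness | 80–120 a.u. | arbitrary working scale |
| background level | 3 a.u. | dim autofluorescence, ~3% of plaque signal |
| photon scale | 0.25 a.u./count | shot noise ~5% at plaque intensities |
| read sigma | 2 a.u. | ~2% of peak signal |

Noise is Poisson (on counts = intensity/photon_scale) plus Gaussian
read noise. The rendered cube is clipped at zero whenever any noise is
applied, because a physical intensity cube is nonnegative; at the
default SNR the clipping probability is negligible and the noise model
is unbiased to within Monte-Carlo error (tested). Geometry and noise
derive from separate child streams of the master seed, so a fixed
geometry can be re-rendered under fresh noise; rendering is
bit-reproducible for a fixed seed.

Genotype presets are stand-ins constrained only by the relative plaque
architectures of the three mouse models; the absolute numbers are
package choices, all exposed in `GENOTYPE_PRESETS`:

| preset | plaques/field | corona radius | core radius | core f_q | corona f_q |
|---|---|---|---|---|---|
| APP23-like | 2–3 | 20–32 μm | 35–50% of corona | 0.50–0.65 | 0.14–0.22 |
| APPPS1-like | 6–10 | 8–15 μm | 30–45% | 0.28–0.40 | 0.08–0.14 |
| NLF-like | 2–4 | 3–8 μm | 12–20% (tiny cores) | 0.10–0.18 | 0.05–0.10 |

Cores are never less qFTAA-rich than their corona (enforced
invariant). An optional `age_months` argument moves the core f_q along
a maturation curve: a logistic rise centered at 12 months (amplitude
0.30 for APP23-like, 0.20 for APPPS1-like, flat for NLF-like),
emulating the age-dependent core maturation of the overexpressor
models. Plaque placement prefers non-overlap by rejection sampling and
falls back to overlap after 200 tries (later plaques own contested
pixels). Coronas are perfect disks; real coronas are irregular, so
geometric results here say nothing about segmentation of ragged plaque
boundaries.

In-vitro fibril fields (`render_fibril_smear`) have no core/corona
geometry: Gaussian clumps of fibril material with condition-specific
qFTAA fraction (Ab40-like 0.38–0.52, reflecting laterally bundled
fibrils; Ab42-like 0.08–0.16, mostly solitary fibrils).

**What the generator does not emulate:** spatially structured
autofluorescence, optical blur/PSF, vascular amyloid, intracellular
inclusions, uneven staining, bleaching. Tests passing on these scenes
demonstrate the correctness and calibration of the *analysis*, not the
segmentation robustness one would need on real tissue.

## ROI ratiometry choices

* ROI statistic: mean intensity per channel, then ratio of means.
  Ratio of means is stabler than mean of per-pixel ratios at low
  counts; the alternative is available via `per_pixel=True`.
* Windows must be odd; 5×5 default. NLF-like cores (≤20% of a 3–8 μm
  corona radius, i.e. often under 5 px across) cannot host a 5×5
  window, so per-plaque analyses of that preset use a 3×3 window.
* Undefined ratios (denominator ≤ 0) are flagged NaN and excluded from
  summaries with a warning; never imputed.
* Automatic ROI placement (the original selection was ocular) erodes
  the region label by the window footprint, orders candidates
  row-major, and samples without replacement with a seed; a region
  with too few candidates raises `InsufficientRegionError`.
* SEM uses the sample standard deviation (ddof = 1); a single-value
  group reports SEM 0 with a warning.

## Whole-image filter choices

The kept-pixel rule is: low ≤ μ_low + k_upper_low·σ_low AND high ≥
μ_high + k_lower_high·σ_high, with μ and σ (population, ddof 0)
computed on the full image before any masking. The inequality
directions follow from what each matrix is for: high intensities in
the 500 nm matrix are bright noise (upper cutoff), low intensities in
the 540 nm matrix are dark background (lower cutoff). Decreasing
k_upper_low or increasing k_lower_high can only remove pixels
(monotone filtering, tested), and the mask is invariant under global
gain because cutoffs scale with μ and σ.

The multipliers are genuinely per-image-set configuration, not method
constants — the original workflow set them per genotype by image
outlook. The neutral defaults are k_upper_low = 3, k_lower_high = 1.
The per-preset defaults in `GENOTYPE_FILTER_DEFAULTS` reflect how the
image statistics move with plaque load: in plaque-dense overexpressor
fields σ is plaque-dominated and the 540-dim qFTAA-rich cores sit
*below* μ+1σ, so the dark cutoff drops to k = 0; in sparse NLF-like
fields σ is background-dominated and the plaques themselves are the
upper tail at 500 nm, so the bright-noise cutoff rises to k = 16 (a
saturated artifact is still orders of magnitude above it).

Density curves use a Gaussian KDE with Silverman bandwidth (numeric
override available), evaluated on a grid extending 4 bandwidths past
the data range and renormalized to integrate to 1 (trapezoid, enforced
within 1e-3). Pixels, not images, are the pooling unit for densities
and means. Degenerate pools (single pixel or zero spread) fall back to
a narrow Gaussian bump. Note that Silverman's bandwidth shrinks with
pixel count, so pooling duplicate images reproduces the curve exactly
only at a fixed bandwidth.

## Statistics choices

ANOVA is classical fixed-effects, unweighted; groups of identical
values (zero variance everywhere, zero between-group spread) are
reported as F = 0, p = 1 rather than NaN. The unpaired t test defaults
to equal variances (the "ordinary" form; Welch available via
`equal_var=False`). F = t² holds for two equal-variance groups to
1e-10 (tested). The cubic age trend is fit to per-age mean ratios, not
raw ROI values, and needs at least 4 distinct ages. Aβ42/Aβ40 content
values for the genotype scatter table are user-supplied inputs — they
come from external biochemical measurements and are not computed here.

## Problem sizes used by tests and the acceptance script

Whole-image preset comparisons use 10 images per genotype at 512×512;
per-plaque core/corona comparisons use 20 single-plaque scenes per
preset at 384×384 (large enough for the biggest APP23-like plaque);
the age series uses 2 plaques per age at 7 ages; null calibration uses
10,000 simulations at n = 8 per group; oracle-equivalence checks use
20 random 32×32 cubes. These sizes give stable orderings and
calibration estimates (pooled pixel counts are 10⁴–10⁶ per condition)
while keeping a full run in the minutes range.

## Known limitations

* Preset magnitudes are stand-ins: only orderings (APP23-like >
  APPPS1-like > NLF-like in qFTAA dominance; core > corona everywhere;
  maturation rise after 12 months) are meaningful, not the absolute
  pooled ratios.
* The filter multiplier defaults assume the generator's plaque loads;
  real image sets need their own settings, which is why they are
  configuration.
* Concentric-disk geometry makes core/corona ROI placement easier than
  on real, irregular plaques.
* The protocol concentration helper computes 263.4 nM for the hFTAA
  working solution where protocol write-ups print 262 nM (rounding in
  the stated 1.1 mM stock); the arithmetic is kept exact and the
  discrepancy documented rather than corrected.
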