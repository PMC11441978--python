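# Methods

This note documents the models implemented in `condquant`, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was
genuinely open.

## Pixel-dispersion statistics (CV and Fano)

Punctateness is quantified without detecting discrete objects. For a
nucleus with raw pixel values $x_i$ and a background level $b$ (mean
intensity of unlabeled cells, assumed spatially constant):

- sub-mean: $\mu = \bar{x} - b$
- variance: sample ($n-1$) variance $s^2$ of the **raw** pixels
- $\mathrm{CV} = s/\mu$, $\mathrm{Fano} = s^2/\mu$

Subtracting the background only from the mean is the self-consistent
reading of the constant-background model: a uniform shift leaves the
variance unchanged. The identity $\mathrm{Fano} = \mathrm{CV}^2 \mu$
holds to machine precision and is enforced at construction. Cells with
$\mu \le 0$ have CV/Fano flagged undefined and are excluded from
condition aggregates (counted in a QC log) — silently including them
would corrupt means.

The Fano number is intensity-scale dependent by design (that is the
point: it controls for expression level only in photon-like units where
a free fluorophore has Fano ≈ 1). Condition values are therefore
reported normalized by the mean Fano of a free-fluorophore reference,
whose own normalized mean is exactly 1. Normalization is performed
within an explicit user-declared batch; the package takes no position on
pooling across imaging sessions.

Statistics are computed on the segmented nuclear mask eroded by an
interior margin (`interior_margin_px`, default 2 px ≈ 2×PSF σ). The PSF
rolls intensity off across the nuclear boundary; boundary pixels would
contribute spatial variance that the Poisson free-fluorophore baseline
does not contain, biasing Fano upward for every condition. The margin
follows from the generative model (an erf-shaped edge profile decays to
<2.5% of its range 2σ inside the half-maximum contour), not from tuning.

## Segmentation

Pipeline: Gaussian smooth (σ = 1 px) → Otsu threshold on the
97th-percentile-clipped image → fill holes → drop regions below
`min_area_px` (30 px) → 8-connected labeling, regions ordered by
centroid (row-major). The percentile clip is essential for strongly
punctate nuclei: without it, bright puncta pull the Otsu threshold above
the diffuse nuclear level and the mask collapses onto the puncta
(measured: 117 of 316 true pixels retained at puncta fraction 0.6).
Clipping is quantile-based, so segmentation remains invariant to global
intensity scaling. Watershed splitting of touching nuclei is off by
default — sparse fields of well-separated yeast nuclei do not need it —
and whole-cell reporter quantification reuses the same operator with a
larger minimum area. Segmentation runs on a configured z plane or (the
default) the channel's mean projection.

Known limitation: at puncta fractions ≥ 0.6 the mask still loses the
dimmest nuclear rim (area ~20% low). Area-sensitive readouts should be
interpreted accordingly; the dispersion statistics are robust to this
because the interior margin discards the rim anyway.

## Dot-centered averaging

The locus dot is the global maximum of the smoothed (σ = 1 px) dot
channel over (z, y, x); ties break toward the lowest z, then row-major.
"Dot intensity" is the smoothed single-pixel maximum, the simplest
reading; integrated spot mass is not used. Detections failing a
peak/median prominence check (default 3.0) are excluded and logged,
mirroring the practice of analyzing only cells with a visible array dot.

Alignment is integer-pixel: averaging camera-grid images with subpixel
interpolation would blur the center-bin definition. Windows are
(2w+1)² with w = 10 px (≈ 1 µm at 0.1 µm/px); pixels falling outside an
image contribute nothing (missing-aware mean with per-pixel counts).
Line profiles are the center row (default; orientation configurable)
with SEM from per-cell values at each offset. Center enrichment between
conditions compares per-cell mean intensities within |offset| ≤ 2 px by
two-sided t-test.

## FRAP

Series are normalized to percent of the mean pre-bleach intensity (the
bleach frame index is explicit; the default protocol has 3 pre-bleach
frames, then one frame every 3 s for 270 s). The recovery model is the
single exponential $I(t) = D + (P-D)(1-e^{-kt})$ — the minimal model
consistent with summarizing recovery by one half time $t_{1/2} = \ln 2 /
k$; a two-component fit exists behind `fit_recovery_biexponential` but
is not the default. Initialization is deterministic ($D$ = first
post-bleach value, $P$ = mean of the last 5 frames, $k$ from the first
half-level crossing) with 3 seeded jittered restarts; bounds keep $k >
0$. Each replicate is fit separately and the reported half time is the
replicate mean ± SD; the fit of the replicate-averaged curve and a
model-free linear-interpolation crossing estimate are also emitted for
comparison. No acquisition-bleaching correction is applied.

## Droplets

Droplet segmentation reuses the threshold-label pipeline with a 10 px
minimum area (rejects shot-noise speckle at the generator's default
noise). Touching droplets are not split: fusion is biologically real.
The dilute phase is the complement minus a 2 px guard band (PSF leakage
otherwise inflates the dilute mean); symmetrically, in-droplet means are
measured on droplets eroded by 2 px, because rim pixels smeared toward
the dilute level otherwise bias the partition coefficient downward
(measured: 4.15 recovered for a true ratio of 5 without the margin, 4.9
with it). Partition coefficients are per droplet and pooled
(area-weighted), and are invariant to global intensity scaling.

## Synthetic-microscopy generator

The generator emulates the study conditions, not optics in general:

- Nuclei are circles (2D) or spheres sampled at z planes, diameter
  2.0 µm at 0.1 µm/px, z-step 0.4 µm, placed uniformly without overlap
  (bounded retries).
- Each nucleus carries `total_photons` (default 20 000 per channel,
  ≈ 64 photons/px across the equatorial cross-section — realistic
  confocal SNR) of which `puncta_fraction` is split equally among
  `n_puncta` isotropic Gaussian puncta (σ = 1.5 px, i.e. a visible
  radius of roughly 2–4 px; placement keeps 3σ inside the nucleus) and
  the rest is uniform over the nuclear mask. The fraction is the single
  knob that maps monotonically onto the downstream Fano number.
- The chromatin dot is a diffraction-limited Gaussian (σ = 1.2 px) in
  channel 2 only, on a diffuse nucleoplasmic background; "coupled"
  places it at the first punctum center, "independent" uniformly in the
  nucleus — reproducing the target-locus vs control-locus contrast.
- The PSF is a lateral Gaussian (σ = 1 px) applied per z plane. There is
  **no axial PSF**; puncta and dots spread across z only through a
  physical-unit Gaussian weight of their own σ, which at 0.4 µm z-steps
  confines them essentially to one plane.
- Noise: Poisson on the expected photon image and/or additive Gaussian
  read noise, then clipped at zero. Pixel units are photons, so a
  zero-puncta nucleus has per-cell Fano ≈ 1 under Poisson noise — the
  free-fluorophore baseline.
- Populations draw per-cell total intensity lognormal with CV 0.2
  (mean preserved); one seeded stream per call, with the cell index
  advancing the stream deterministically, makes every fixture
  bit-reproducible.
- FRAP series follow the single-exponential truth exactly, with
  per-frame Gaussian noise added post-bleach only (pre-bleach reference
  frames stay clean so the normalization target is unambiguous).

Not emulated: vectorial/aberrated PSFs, photobleaching during
z-acquisition, cell-cycle morphology, autofluorescence, camera gain and
offset (bit depth and gain are left to configuration). Passing tests
therefore demonstrate estimator correctness under an idealized but
fully specified imaging model; they do not certify performance on real
detector artifacts or segmentation of crowded fields.

## Recovery-experiment constructions

- **Correlation recovery.** Two channels are built as a shared punctate
  signal $S$ plus channel-independent Gaussian noise; with
  $\sigma_N = \sigma_S\sqrt{1/r - 1}$ the theoretical pixel correlation
  equals the target $r$, and a constant pedestal keeps the zero-clip
  inactive (Pearson r is offset-invariant). The construction uses a
  moderate-contrast extended pattern (fraction 0.2, σ = 3 px): the
  required noise grows with signal variance, and a high-contrast
  compact pattern would push the channel noise above the
  nucleus/background contrast, outside the regime where threshold
  segmentation is meaningful.
- **Reporter ratio.** The two conditions share a population seed, so the
  lognormal cell-to-cell factors pair off (common random numbers) and
  the recovered ratio isolates pipeline bias from sampling scatter; the
  group t-test still compares the two independent per-cell readouts.
- **Problem sizes.** Recovery experiments use 50 cells per condition for
  dispersion/correlation statistics, 100 per condition for reporter and
  dot-enrichment contrasts, 3 replicates for FRAP, and ~10 droplets per
  field — population scales comparable to the per-condition cell counts
  of the assays being emulated, and sufficient for the stated
  tolerances.

## Statistical conventions

Sample (n−1) variance throughout. Group comparisons are two-sided
two-sample t-tests, pooled-variance by default ("Student's t-test")
with Welch behind a switch; stars map p < 0.05/0.01/0.001 to */**/***.
No multiple-testing correction is applied — tables report raw p values
for single pairwise comparisons.
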