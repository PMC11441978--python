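"""Synthetic fluorescence-microscopy generator with known ground truth.

Emulates the imaging conditions of a yeast TF-condensate experiment:
~2 µm nuclei carrying a diffuse nuclear signal plus a configurable
fraction of total intensity concentrated in a few Gaussian puncta, an
optional diffraction-limited chromatin dot in a second channel (the
tetO/tetR-mCherry locus tag) whose position is either coupled to a
punctum or placed independently, lateral Gaussian PSF blur, Poisson
photon noise and/or Gaussian read noise, z-stacks at 0.4 µm spacing,
and single-exponential FRAP recovery series.

All randomness flows from a single seeded generator per call; identical
(config, seed) pairs reproduce stacks bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from condquant.image_io import ImageStack

# ---------------------------------------------------------------------------
# configuration and truth containers


@dataclass
class SceneConfig:
    """Parameters of one simulated nucleus scene.

    Defaults describe the study conditions: a 2.0 µm diameter nucleus at
    0.1 µm/px (10 px radius), 20 000 photons per nucleus per channel
    (~64 photons/px over the nuclear cross-section), PSF sigma 1 px,
    z-step 0.4 µm. ``puncta_fraction`` is the fraction of total nuclear
    photons carried by the puncta — the single knob that maps
    monotonically onto the downstream Fano number.
    """

    shape_yx: tuple[int, int] = (64, 64)
    n_z: int = 1
    pixel_size_um: float = 0.1
    z_step_um: float = 0.4
    nucleus_diameter_um: float = 2.0
    n_nuclei: int = 1
    total_photons: float = 20000.0
    n_puncta: int = 3
    puncta_fraction: float = 0.0
    puncta_sigma_px: float = 1.5
    psf_sigma_px: float = 1.0
    noise: str = "none"  # "none" | "poisson" | "gaussian" | "both"
    read_noise_sd: float = 2.0
    channel_names: tuple[str, ...] = ("gfp",)
    # chromatin-dot channel (tetO/tetR-mCherry analog), channel 2 only
    with_dot: bool = False
    dot_coupled: bool = False
    dot_photons: float = 6000.0
    dot_sigma_px: float = 1.2
    dot_channel_diffuse_photons: float = 8000.0
    # cell-to-cell lognormal scatter of total intensity (population mode)
    intensity_cv: float = 0.2

    def __post_init__(self) -> None:
        if self.puncta_fraction < 0 or self.puncta_fraction > 1:
            raise ValueError("puncta_fraction must be in [0, 1]")
        if self.total_photons <= 0:
            raise ValueError("zero nuclear intensity")
        if min(self.shape_yx) <= 0 or self.n_z < 1 or self.n_nuclei < 1:
            raise ValueError("image shape, n_z and n_nuclei must be positive")
        if self.nucleus_diameter_um <= 0 or self.pixel_size_um <= 0:
            raise ValueError("sizes must be positive")
        if self.with_dot and len(self.channel_names) < 2:
            raise ValueError("with_dot requires a second channel")

    @property
    def nucleus_radius_px(self) -> float:
        return 0.5 * self.nucleus_diameter_um / self.pixel_size_um


@dataclass
class PunctumTruth:
    center_zyx: tuple[float, float, float]
    sigma_px: float
    fraction: float


@dataclass
class NucleusTruth:
    center_zyx: tuple[float, float, float]
    radius_px: float
    mask: np.ndarray  # bool, (z, y, x)
    puncta: list[PunctumTruth]
    dot_zyx: tuple[float, float, float] | None
    total_photons: float

    @property
    def center_yx(self) -> tuple[float, float]:
        return self.center_zyx[1], self.center_zyx[2]

    @property
    def area_px(self) -> int:
        """Pixel area of the equatorial (largest) cross-section."""
        return int(self.mask.sum(axis=(1, 2)).max())


@dataclass
class SceneTruth:
    nuclei: list[NucleusTruth]
    dot_coupled: bool
    seed: int
    config: SceneConfig


@dataclass
class FrapTruth:
    """Ground truth of a simulated FRAP experiment.

    ``half_time_s`` sets the single-exponential recovery rate
    k = ln 2 / half_time; intensities are in percent of the pre-bleach
    level; ``noise_sd_pct`` is Gaussian per-frame noise in percent of
    the plateau.
    """

    half_time_s: float = 64.0
    plateau_pct: float = 80.0
    bleach_depth_pct: float = 20.0
    frame_interval_s: float = 3.0
    duration_s: float = 270.0
    n_prebleach: int = 3
    noise_sd_pct: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.half_time_s <= 0 or self.frame_interval_s <= 0:
            raise ValueError("half_time_s and frame_interval_s must be > 0")
        if not 0 <= self.bleach_depth_pct <= self.plateau_pct <= 100.0 + 1e-9:
            raise ValueError("require 0 <= bleach depth <= plateau <= 100")
        if self.n_prebleach < 1:
            raise ValueError("need at least one pre-bleach frame")

    @property
    def n_post(self) -> int:
        return int(round(self.duration_s / self.frame_interval_s))


# ---------------------------------------------------------------------------
# scene generation


def _sphere_mask(
    shape_zyx: tuple[int, int, int],
    center_zyx: tuple[float, float, float],
    radius_px: float,
    z_step_px: float,
) -> np.ndarray:
    """Boolean mask of a sphere sampled on anisotropic (z, y, x) grid."""
    nz, ny, nx = shape_zyx
    zz = (np.arange(nz) - center_zyx[0]) * z_step_px
    yy = np.arange(ny) - center_zyx[1]
    xx = np.arange(nx) - center_zyx[2]
    d2 = (
        zz[:, None, None] ** 2
        + yy[None, :, None] ** 2
        + xx[None, None, :] ** 2
    )
    return d2 <= radius_px**2


def gaussian_spot(
    shape_yx: tuple[int, int],
    center_yx: tuple[float, float],
    sigma_px: float,
    photons: float,
) -> np.ndarray:
    """Isotropic 2-D Gaussian integrating (up to truncation) to ``photons``."""
    yy = np.arange(shape_yx[0]) - center_yx[0]
    xx = np.arange(shape_yx[1]) - center_yx[1]
    g = np.exp(-(yy[:, None] ** 2 + xx[None, :] ** 2) / (2.0 * sigma_px**2))
    return photons * g / (2.0 * np.pi * sigma_px**2)


def _z_weights(n_z: int, z_center: float, sigma_um: float, z_step_um: float) -> np.ndarray:
    """Normalized Gaussian weights distributing a spot across z planes."""
    if n_z == 1:
        return np.ones(1)
    dz_um = (np.arange(n_z) - z_center) * z_step_um
    w = np.exp(-(dz_um**2) / (2.0 * sigma_um**2))
    s = w.sum()
    if s <= 0:
        w = np.zeros(n_z)
        w[int(round(np.clip(z_center, 0, n_z - 1)))] = 1.0
        return w
    return w / s


def _place_nuclei(cfg: SceneConfig, rng: np.random.Generator) -> list[tuple[float, float, float]]:
    """Draw non-overlapping nucleus centers; bounded retries then error."""
    r = cfg.nucleus_radius_px
    ny, nx = cfg.shape_yx
    margin = r + 2.0
    if ny <= 2 * margin or nx <= 2 * margin:
        raise ValueError("image too small to hold the requested nuclei")
    z_half_planes = r * cfg.pixel_size_um / cfg.z_step_um if cfg.n_z > 1 else 0.0
    z_lo = min(z_half_planes, (cfg.n_z - 1) / 2)
    z_hi = cfg.n_z - 1 - z_lo
    centers: list[tuple[float, float, float]] = []
    for _ in range(cfg.n_nuclei):
        for _attempt in range(200):
            y = rng.uniform(margin, ny - margin)
            x = rng.uniform(margin, nx - margin)
            z = rng.uniform(z_lo, z_hi) if cfg.n_z > 1 else 0.0
            if all((y - cy) ** 2 + (x - cx) ** 2 > (2 * r + 3) ** 2 for _, cy, cx in centers):
                centers.append((z, y, x))
                break
        else:
            raise ValueError("nuclei cannot be placed without overlap after bounded retries")
    return centers


def _point_in_sphere(
    rng: np.random.Generator,
    center_zyx: tuple[float, float, float],
    radius_px: float,
    z_step_px: float,
    n_z: int,
    margin_px: float,
) -> tuple[float, float, float]:
    """Uniform point inside a sphere shrunk by ``margin_px`` (rejection)."""
    r_eff = max(radius_px - margin_px, 1.0)
    while True:
        dy, dx = rng.uniform(-r_eff, r_eff, size=2)
        dz_px = rng.uniform(-r_eff, r_eff) if n_z > 1 else 0.0
        if dy**2 + dx**2 + dz_px**2 <= r_eff**2:
            z = center_zyx[0] + dz_px / z_step_px if n_z > 1 else 0.0
            return (float(np.clip(z, 0, n_z - 1)), center_zyx[1] + dy, center_zyx[2] + dx)


def simulate_nucleus_scene(
    cfg: SceneConfig, seed: int
) -> tuple[ImageStack, SceneTruth]:
    """Render one scene and return it with its generative ground truth.

    The noise-free expected image is, per nucleus and channel, a uniform
    diffuse term over the nuclear mask carrying ``1 − puncta_fraction``
    of the photons plus Gaussian puncta carrying the rest, convolved
    laterally with the Gaussian PSF; Poisson and/or Gaussian read noise
    are then applied pixel-wise.
    """
    rng = np.random.default_rng(seed)
    nz, (ny, nx) = cfg.n_z, cfg.shape_yx
    n_ch = len(cfg.channel_names)
    z_step_px = cfg.z_step_um / cfg.pixel_size_um
    expected = np.zeros((nz, n_ch, ny, nx))
    centers = _place_nuclei(cfg, rng)
    nuclei: list[NucleusTruth] = []

    for center in centers:
        mask = _sphere_mask((nz, ny, nx), center, cfg.nucleus_radius_px, z_step_px)
        n_vox = int(mask.sum())
        if n_vox == 0:
            raise ValueError("nucleus mask empty; check geometry")
        f = cfg.puncta_fraction
        n_puncta = cfg.n_puncta if f > 0 else 0
        # diffuse term in every requested channel
        diffuse = np.where(mask, (1.0 - f) * cfg.total_photons / n_vox, 0.0)
        puncta: list[PunctumTruth] = []
        puncta_img = np.zeros((nz, ny, nx))
        if n_puncta > 0:
            frac_each = f / n_puncta
            for _ in range(n_puncta):
                p = _point_in_sphere(
                    rng, center, cfg.nucleus_radius_px, z_step_px, nz,
                    margin_px=3.0 * cfg.puncta_sigma_px,
                )
                wz = _z_weights(nz, p[0], cfg.puncta_sigma_px * cfg.pixel_size_um, cfg.z_step_um)
                spot2d = gaussian_spot((ny, nx), (p[1], p[2]), cfg.puncta_sigma_px,
                                       frac_each * cfg.total_photons)
                puncta_img += wz[:, None, None] * spot2d[None]
                puncta.append(PunctumTruth(p, cfg.puncta_sigma_px, frac_each))
        expected[:, 0] += diffuse + puncta_img

        dot_zyx: tuple[float, float, float] | None = None
        if cfg.with_dot:
            # diffuse nucleoplasmic level in the dot channel
            expected[:, 1] += np.where(mask, cfg.dot_channel_diffuse_photons / n_vox, 0.0)
            if cfg.dot_coupled and puncta:
                dot_zyx = puncta[0].center_zyx
            else:
                dot_zyx = _point_in_sphere(
                    rng, center, cfg.nucleus_radius_px, z_step_px, nz,
                    margin_px=3.0 * cfg.dot_sigma_px,
                )
            wz = _z_weights(nz, dot_zyx[0], cfg.dot_sigma_px * cfg.pixel_size_um, cfg.z_step_um)
            spot2d = gaussian_spot((ny, nx), (dot_zyx[1], dot_zyx[2]),
                                   cfg.dot_sigma_px, cfg.dot_photons)
            expected[:, 1] += wz[:, None, None] * spot2d[None]
        elif n_ch > 1:
            expected[:, 1] += diffuse  # second channel mirrors channel 1 diffusely

        nuclei.append(
            NucleusTruth(center, cfg.nucleus_radius_px, mask, puncta, dot_zyx,
                         cfg.total_photons)
        )

    if cfg.psf_sigma_px > 0:
        for iz in range(nz):
            for ic in range(n_ch):
                expected[iz, ic] = gaussian_filter(
                    expected[iz, ic], cfg.psf_sigma_px, mode="constant"
                )

    pixels = _apply_noise(expected, cfg, rng)
    stack = ImageStack(pixels, cfg.pixel_size_um, cfg.z_step_um, cfg.channel_names)
    return stack, SceneTruth(nuclei, cfg.dot_coupled, seed, cfg)


def _apply_noise(expected: np.ndarray, cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    out = expected
    if cfg.noise in ("poisson", "both"):
        out = rng.poisson(out).astype(np.float64)
    elif cfg.noise not in ("none", "gaussian"):
        raise ValueError(f"unknown noise mode {cfg.noise!r}")
    if cfg.noise in ("gaussian", "both"):
        out = out + rng.normal(0.0, cfg.read_noise_sd, size=out.shape)
    return np.clip(out, 0.0, None)


def simulate_population(
    cfg: SceneConfig, n_cells: int, seed: int
) -> list[tuple[ImageStack, SceneTruth]]:
    """n_cells independent scenes from one seeded stream.

    Cell-level total intensity is drawn lognormal with mean
    ``cfg.total_photons`` and coefficient of variation
    ``cfg.intensity_cv`` (set 0 to disable). The cell index advances the
    stream deterministically, so a fixed seed reproduces the population.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    master = np.random.default_rng(seed)
    scenes = []
    for i in range(n_cells):
        cell_seed = int(master.integers(0, 2**31 - 1))
        cell_cfg = cfg
        if cfg.intensity_cv > 0:
            sigma = math.sqrt(math.log(1.0 + cfg.intensity_cv**2))
            mu = math.log(cfg.total_photons) - 0.5 * sigma**2
            total = float(np.random.default_rng(cell_seed + 1).lognormal(mu, sigma))
            cell_cfg = replace(cfg, total_photons=total)
        scenes.append(simulate_nucleus_scene(cell_cfg, cell_seed))
    return scenes


# ---------------------------------------------------------------------------
# FRAP series


def simulate_frap(truth: FrapTruth):
    """Simulate a normalized FRAP series from ground-truth kinetics.

    Pre-bleach frames sit at the 100% level; at the bleach frame the
    intensity drops to the bleach depth D and recovers as
    ``I(t) = D + (P − D)(1 − exp(−k t))`` with ``k = ln 2 / half_time``
    and t measured from the bleach frame. Gaussian noise of the stated
    SD is added per frame. Returns a :class:`condquant.frap.FrapSeries`.
    """
    from condquant.frap import normalize_frap

    rng = np.random.default_rng(truth.seed)
    n_pre, n_post = truth.n_prebleach, truth.n_post
    dt = truth.frame_interval_s
    t_post = np.arange(n_post) * dt
    k = math.log(2.0) / truth.half_time_s
    recovery = truth.bleach_depth_pct + (truth.plateau_pct - truth.bleach_depth_pct) * (
        1.0 - np.exp(-k * t_post)
    )
    series_pct = np.concatenate([np.full(n_pre, 100.0), recovery])
    if truth.noise_sd_pct > 0:
        noise = rng.normal(0.0, truth.noise_sd_pct, size=series_pct.shape)
        noise[:n_pre] = 0.0  # pre-bleach reference frames kept clean
        series_pct = series_pct + noise
    # express as raw counts so that downstream normalization is exercised
    raw = series_pct * 10.0
    times = np.arange(n_pre + n_post) * dt
    return normalize_frap(raw, bleach_index=n_pre, times=times)


# ---------------------------------------------------------------------------
# droplet fields


@dataclass
class DropletFieldConfig:
    """In vitro droplet field: bright disks on a dilute-phase background."""

    shape_yx: tuple[int, int] = (128, 128)
    n_droplets: int = 10
    radius_px_range: tuple[float, float] = (3.0, 8.0)
    dilute_level: float = 20.0
    partition_ratios: tuple[float, ...] = (5.0,)
    channel_names: tuple[str, ...] = ("mcherry",)
    psf_sigma_px: float = 1.0
    noise: str = "none"
    read_noise_sd: float = 1.0
    pixel_size_um: float = 0.1

    def __post_init__(self) -> None:
        if self.radius_px_range[0] < 2:
            raise ValueError("droplet radii must be >= 2 px")
        if any(r < 0 for r in self.partition_ratios):
            raise ValueError("partition ratios must be >= 0")
        if len(self.partition_ratios) != len(self.channel_names):
            raise ValueError("one partition ratio per channel")


@dataclass
class DropletFieldTruth:
    centers_yx: list[tuple[float, float]]
    radii_px: list[float]
    dilute_level: float
    partition_ratios: tuple[float, ...]
    seed: int


def simulate_droplet_field(
    cfg: DropletFieldConfig, seed: int
) -> tuple[ImageStack, DropletFieldTruth]:
    """Disks at ``partition_ratio × dilute_level`` on a dilute background."""
    rng = np.random.default_rng(seed)
    ny, nx = cfg.shape_yx
    rmin, rmax = cfg.radius_px_range
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    for _ in range(cfg.n_droplets):
        for _attempt in range(200):
            r = rng.uniform(rmin, rmax)
            y = rng.uniform(r + 2, ny - r - 2)
            x = rng.uniform(r + 2, nx - r - 2)
            if all(
                (y - cy) ** 2 + (x - cx) ** 2 > (r + rr + 2) ** 2
                for (cy, cx), rr in zip(centers, radii)
            ):
                centers.append((y, x))
                radii.append(r)
                break
        else:
            raise ValueError("droplet overlap after bounded retries")
    yy, xx = np.mgrid[0:ny, 0:nx]
    inside = np.zeros((ny, nx), dtype=bool)
    for (cy, cx), r in zip(centers, radii):
        inside |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    n_ch = len(cfg.channel_names)
    expected = np.zeros((1, n_ch, ny, nx))
    for ic, ratio in enumerate(cfg.partition_ratios):
        img = np.where(inside, ratio * cfg.dilute_level, cfg.dilute_level)
        if cfg.psf_sigma_px > 0:
            img = gaussian_filter(img, cfg.psf_sigma_px, mode="nearest")
        expected[0, ic] = img
    scene_cfg = SceneConfig(noise=cfg.noise, read_noise_sd=cfg.read_noise_sd)
    pixels = _apply_noise(expected, scene_cfg, rng)
    stack = ImageStack(pixels, cfg.pixel_size_um, 0.4, cfg.channel_names)
    return stack, DropletFieldTruth(centers, radii, cfg.dilute_level,
                                    cfg.partition_ratios, seed)


# ---------------------------------------------------------------------------
# two-channel co-localization scenes


def simulate_colocalized_pair(
    cfg: SceneConfig, target_r: float, shared_signal: bool, seed: int
) -> tuple[ImageStack, SceneTruth]:
    """Two channels sharing (or not) a punctate spatial signal.

    With ``shared_signal`` True, both channels equal the same noise-free
    punctate nuclear image S plus channel-independent Gaussian noise.
    The noise SD is solved analytically so that the theoretical
    pixel-wise Pearson correlation over nuclear pixels equals
    ``target_r``: ``r = Var(S) / (Var(S) + Var(N))`` hence
    ``sd_N = sd_S * sqrt(1/r − 1)``. With ``shared_signal`` False the
    second channel is an independently generated punctate pattern (the
    non-interacting control) and ``target_r`` is ignored.
    """
    if not 0 < target_r <= 1:
        raise ValueError("target_r must be in (0, 1]")
    base_cfg = replace(cfg, noise="none", channel_names=(cfg.channel_names[0],))
    stack1, truth = simulate_nucleus_scene(base_cfg, seed)
    signal = stack1.pixels[:, 0]
    rng = np.random.default_rng(seed + 1)
    if shared_signal:
        # spatial SD of the shared signal over the analyzed (interior) pixels
        mask = truth.nuclei[0].mask
        from scipy.ndimage import binary_erosion

        interior = binary_erosion(mask, structure=np.ones((1, 3, 3), bool), iterations=2)
        if not interior.any():
            interior = mask
        sd_s = float(np.std(signal[interior], ddof=1))
        sd_n = sd_s * math.sqrt(1.0 / target_r - 1.0)
        # constant pedestal keeps the zero-clip inactive; Pearson r is
        # invariant to the shared offset
        ped = 5.0 * sd_n
        ch1 = np.clip(signal + ped + rng.normal(0, sd_n, signal.shape), 0, None)
        ch2 = np.clip(signal + ped + rng.normal(0, sd_n, signal.shape), 0, None)
    else:
        stack2, _ = simulate_nucleus_scene(base_cfg, seed + 10_000_019)
        ch1, ch2 = signal, stack2.pixels[:, 0]
    pixels = np.stack([ch1, ch2], axis=1)
    names = cfg.channel_names if len(cfg.channel_names) >= 2 else ("gfp", "mcherry")
    stack = ImageStack(pixels, cfg.pixel_size_um, cfg.z_step_um, names[:2])
    return stack, truth
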