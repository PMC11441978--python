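"""Chromatin-dot detection, dot-centered averaging, and line profiles.

A tetO/tetR-mCherry locus tag renders a genomic locus a
diffraction-limited dot. Per cell, the z plane with the highest
(smoothed) dot-channel intensity defines the dot; the signal channel is
then read either at the same z or as a maximum-intensity projection
(MIP), cells are aligned on the dot, averaged across the population,
and a line profile through the center summarizes the local enrichment
of the signal around the tagged locus.

Alignment is integer-pixel: camera-grid images are averaged without
subpixel interpolation so the center bin stays sharply defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from condquant.image_io import ImageStack, RunConfig
from condquant.puncta import GroupComparison, compare_groups


@dataclass(frozen=True)
class DotDetection:
    cell_id: int
    best_z: int
    center_yx: tuple[int, int]
    peak_intensity: float
    prominence: float
    passed: bool


@dataclass(frozen=True)
class AlignedAverage:
    """Population average of dot-centered windows.

    ``average`` is (2w+1, 2w+1) with NaN where no cell contributed;
    ``counts`` holds the per-pixel contributing-cell count; ``windows``
    keeps the per-cell cropped windows (NaN-padded at image borders) so
    per-offset SEMs and per-cell center statistics remain available.
    """

    mode: str
    window_radius_px: int
    average: np.ndarray
    counts: np.ndarray
    windows: np.ndarray  # (n_cells, 2w+1, 2w+1)
    n_cells: int
    pixel_size_um: float = 0.1


@dataclass(frozen=True)
class LineProfile:
    offsets_px: np.ndarray
    offsets_um: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    orientation: str


def detect_dot(stack: ImageStack, channel: str, params: RunConfig | None = None,
               cell_id: int = 0) -> DotDetection:
    """Locate the chromatin dot as the smoothed global intensity maximum.

    After Gaussian smoothing (``params.dot_sigma_px``) the global
    maximum over (z, y, x) defines the best z and dot center; ties break
    toward the lowest z, then row-major (y, x). The detection fails the
    prominence check when peak/median falls below
    ``params.dot_min_prominence`` (or the channel is all zero).
    """
    params = params or RunConfig()
    volume = stack.channel(channel)
    smoothed = np.stack(
        [ndimage.gaussian_filter(plane, params.dot_sigma_px) for plane in volume]
    )
    flat_idx = int(np.argmax(smoothed))  # C order: lowest z, then row-major
    best_z, y, x = np.unravel_index(flat_idx, smoothed.shape)
    peak = float(smoothed[best_z, y, x])
    median = float(np.median(smoothed))
    prominence = peak / median if median > 0 else float("inf")
    passed = peak > 0 and (median == 0 or prominence >= params.dot_min_prominence)
    if peak <= 0:
        passed = False
        prominence = 0.0
    return DotDetection(cell_id, int(best_z), (int(y), int(x)), peak, prominence, passed)


def extract_same_z(stack: ImageStack, channel: str, z: int) -> np.ndarray:
    """The (channel, z) plane, unmodified."""
    return stack.plane(z, channel)


def extract_mip(stack: ImageStack, channel: str) -> np.ndarray:
    """Maximum-intensity projection: per-pixel maximum over z."""
    return stack.channel(channel).max(axis=0)


def align_and_average(
    images: list[np.ndarray],
    centers: list[tuple[int, int]],
    w: int,
    mode: str = "mip",
    pixel_size_um: float = 0.1,
) -> AlignedAverage:
    """Crop a (2w+1)² window about each center and average across cells.

    Window pixels falling outside an image contribute nothing: the mean
    is missing-aware, and the per-pixel count map records how many cells
    contributed at each offset.
    """
    if len(images) == 0:
        raise ValueError("empty input: need at least one cell")
    if len(images) != len(centers):
        raise ValueError("one center per image required")
    size = 2 * w + 1
    windows = np.full((len(images), size, size), np.nan)
    for i, (img, (cy, cx)) in enumerate(zip(images, centers)):
        img = np.asarray(img, dtype=float)
        if not (0 <= cy < img.shape[0] and 0 <= cx < img.shape[1]):
            raise ValueError(f"center {(cy, cx)} outside image {i}")
        y0, y1 = cy - w, cy + w + 1
        x0, x1 = cx - w, cx + w + 1
        sy0, sx0 = max(y0, 0), max(x0, 0)
        sy1, sx1 = min(y1, img.shape[0]), min(x1, img.shape[1])
        windows[i, sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = img[sy0:sy1, sx0:sx1]
    counts = np.sum(~np.isnan(windows), axis=0)
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN offsets
        average = np.nanmean(windows, axis=0)
    average[counts == 0] = np.nan
    return AlignedAverage(mode, w, average, counts, windows, len(images), pixel_size_um)


def line_profile(avg: AlignedAverage, orientation: str = "horizontal") -> LineProfile:
    """Center row (or column) of the averaged image, offset 0 at the dot.

    The SEM at each offset comes from the per-cell values contributing
    there (missing-aware).
    """
    w = avg.window_radius_px
    if orientation == "horizontal":
        line_mean = avg.average[w, :]
        per_cell = avg.windows[:, w, :]
    elif orientation == "vertical":
        line_mean = avg.average[:, w]
        per_cell = avg.windows[:, :, w]
    else:
        raise ValueError("orientation must be 'horizontal' or 'vertical'")
    n = np.sum(~np.isnan(per_cell), axis=0)
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(per_cell, axis=0, ddof=1)
        sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    offsets = np.arange(-w, w + 1)
    return LineProfile(
        offsets_px=offsets,
        offsets_um=offsets * avg.pixel_size_um,
        mean=np.asarray(line_mean, dtype=float),
        sem=sem,
        orientation=orientation,
    )


def per_cell_center_means(avg: AlignedAverage, center_radius_px: int = 2) -> np.ndarray:
    """Per-cell mean intensity in the |dy|,|dx| <= r window about the dot."""
    w = avg.window_radius_px
    r = center_radius_px
    block = avg.windows[:, w - r : w + r + 1, w - r : w + r + 1]
    with np.errstate(invalid="ignore"):
        return np.nanmean(block.reshape(block.shape[0], -1), axis=1)


def center_enrichment(
    avg_a: AlignedAverage,
    avg_b: AlignedAverage,
    center_radius_px: int = 2,
    equal_var: bool = True,
) -> GroupComparison:
    """Compare per-cell dot-center intensities between two conditions.

    Delegates to the standard two-sided t-test on per-cell mean
    intensities in the center window (default |offset| <= 2 px).
    """
    a = per_cell_center_means(avg_a, center_radius_px)
    b = per_cell_center_means(avg_b, center_radius_px)
    return compare_groups(a[~np.isnan(a)], b[~np.isnan(b)], equal_var=equal_var)
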