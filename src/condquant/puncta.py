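"""Per-nucleus condensate metrics and group statistics.

Punctateness of a nuclear signal is quantified without counting discrete
objects, through the dispersion of pixel intensities inside each
nucleus:

* CV = SD(pixels) / (mean(pixels) − background)
* Fano = Var(pixels) / (mean(pixels) − background)

Variance is the sample (n−1) variance of the *raw* pixel values — under
the constant-background model a uniform shift leaves the variance
unchanged, so subtracting the background only from the mean is the
self-consistent reading. The Fano number of a free fluorophore imaged
in photon units is ≈ 1 (pure Poisson statistics), which is why condition
Fano values are reported normalized to a free-fluorophore reference
whose mean is set to exactly 1.

Two-channel co-localization is the standard pixel-wise Pearson r over
nuclear pixels; group comparisons use the two-sample Student's t-test
(pooled variance by default, Welch behind a switch).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from condquant.image_io import ImageStack, RunConfig
from condquant.segmentation import NucleusRegion, extract_pixels


@dataclass(frozen=True)
class PixelStats:
    """Background-subtracted intensity statistics of one pixel set."""

    n_pixels: int
    raw_mean: float
    background_mean: float
    sub_mean: float
    variance: float
    cv: float
    fano: float
    defined: bool

    def __post_init__(self) -> None:
        if self.defined and not math.isclose(
            self.fano, self.cv**2 * self.sub_mean, rel_tol=1e-9, abs_tol=1e-12
        ):
            raise ValueError("internal inconsistency: fano != cv^2 * sub_mean")


@dataclass(frozen=True)
class NormalizedFano:
    """Per-cell Fano values scaled so the reference condition averages 1."""

    values: np.ndarray
    reference_mean_fano: float
    mean: float
    sem: float
    n: int


@dataclass(frozen=True)
class ColocalizationResult:
    cell_id: int
    n_pixels: int
    pearson_r: float
    defined: bool


@dataclass(frozen=True)
class GroupComparison:
    """Two-group comparison by two-sided Student's t-test."""

    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    n_a: int
    n_b: int
    t_statistic: float
    p_value: float
    stars: str


def compute_pixel_stats(pixels: np.ndarray, background_mean: float) -> PixelStats:
    """CV and Fano of a nuclear pixel vector.

    ``cv``/``fano`` use the background-subtracted mean in the
    denominator and the raw-pixel sample variance in the numerator.
    With a non-positive subtracted mean both are flagged undefined (NaN)
    rather than silently returned.
    """
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim != 1:
        pixels = pixels.ravel()
    if pixels.size < 2:
        raise ValueError("need at least 2 pixels for a variance")
    if background_mean < 0:
        raise ValueError("background_mean must be >= 0")
    raw_mean = float(pixels.mean())
    sub_mean = raw_mean - background_mean
    variance = float(pixels.var(ddof=1))
    if sub_mean > 0:
        cv = math.sqrt(variance) / sub_mean
        fano = variance / sub_mean
        defined = True
    else:
        cv = fano = float("nan")
        defined = False
    return PixelStats(
        n_pixels=pixels.size,
        raw_mean=raw_mean,
        background_mean=background_mean,
        sub_mean=sub_mean,
        variance=variance,
        cv=cv,
        fano=fano,
        defined=defined,
    )


def normalize_fano(condition_fanos: np.ndarray, reference_fanos: np.ndarray) -> NormalizedFano:
    """Divide per-cell Fano values by the reference condition's mean Fano.

    Applied to the reference itself, the resulting mean is exactly 1.
    """
    condition = np.asarray(condition_fanos, dtype=float)
    reference = np.asarray(reference_fanos, dtype=float)
    if reference.size == 0:
        raise ValueError("reference condition is empty")
    ref_mean = float(reference.mean())
    if not ref_mean > 0:
        raise ValueError("reference mean Fano must be positive")
    values = condition / ref_mean
    n = values.size
    sem = float(values.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    # mean as mean(condition)/ref_mean so the reference normalized against
    # itself is exactly 1.0 (x/x), not 1 up to summation order
    return NormalizedFano(values=values, reference_mean_fano=ref_mean,
                          mean=float(condition.mean() / ref_mean), sem=sem, n=n)


def pixel_colocalization(
    pixels_ch1: np.ndarray, pixels_ch2: np.ndarray, cell_id: int = 0
) -> ColocalizationResult:
    """Pixel-wise Pearson correlation between two channels of one nucleus."""
    x = np.asarray(pixels_ch1, dtype=float).ravel()
    y = np.asarray(pixels_ch2, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("channel pixel vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pixels for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return ColocalizationResult(cell_id, x.size, float("nan"), defined=False)
    r = float(stats.pearsonr(x, y).statistic)
    return ColocalizationResult(cell_id, x.size, r, defined=True)


_STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for level, label in _STAR_LEVELS:
        if p < level:
            return label
    return "ns"


def compare_groups(a: np.ndarray, b: np.ndarray, equal_var: bool = True) -> GroupComparison:
    """Two-sided two-sample t-test with the figure-caption star mapping.

    ``equal_var=True`` gives the pooled-variance Student's test;
    ``False`` gives Welch's.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    p = float(res.pvalue)
    return GroupComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sem_a=float(a.std(ddof=1) / math.sqrt(a.size)),
        sem_b=float(b.std(ddof=1) / math.sqrt(b.size)),
        n_a=a.size,
        n_b=b.size,
        t_statistic=float(res.statistic),
        p_value=p,
        stars=significance_stars(p),
    )


# ---------------------------------------------------------------------------
# convenience pipelines over segmented regions


def nucleus_stats_table(
    stack: ImageStack,
    regions: list[NucleusRegion],
    channel: str,
    background_mean: float,
    params: RunConfig | None = None,
) -> list[dict]:
    """Per-nucleus PixelStats rows; undefined cells are flagged for QC.

    Pixel vectors are taken from the region interior (eroded by
    ``params.interior_margin_px``) so PSF roll-off at the nuclear
    boundary does not inflate the spatial variance.
    """
    params = params or RunConfig()
    rows = []
    for region in regions:
        values = extract_pixels(region, stack, channel, params.interior_margin_px)
        if values.size < 2:
            continue
        s = compute_pixel_stats(values, background_mean)
        rows.append(
            {
                "cell_id": region.region_id,
                "n_pixels": s.n_pixels,
                "raw_mean": s.raw_mean,
                "sub_mean": s.sub_mean,
                "variance": s.variance,
                "cv": s.cv,
                "fano": s.fano,
                "defined": s.defined,
            }
        )
    return rows


def colocalization_table(
    stack: ImageStack,
    regions: list[NucleusRegion],
    ch1: str,
    ch2: str,
    params: RunConfig | None = None,
) -> list[ColocalizationResult]:
    """Per-cell pixel-wise Pearson r between two channels."""
    params = params or RunConfig()
    out = []
    for region in regions:
        x = extract_pixels(region, stack, ch1, params.interior_margin_px)
        y = extract_pixels(region, stack, ch2, params.interior_margin_px)
        if x.size < 3:
            continue
        out.append(pixel_colocalization(x, y, cell_id=region.region_id))
    return out
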