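"""Canned synthetic experiments: generator → pipeline → summary statistic.

Each function wires the synthetic-microscopy generator to the analysis
pipeline under the study conditions (cell counts, noise models, FRAP
protocol) and returns the recovered quantity, so estimator-recovery
checks and reproduction scripts share one code path.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from condquant.dots import (
    align_and_average,
    center_enrichment,
    detect_dot,
    extract_mip,
    line_profile,
)
from condquant.frap import FrapFit, fit_recovery
from condquant.puncta import (
    GroupComparison,
    colocalization_table,
    compare_groups,
    normalize_fano,
    nucleus_stats_table,
)
from condquant.segmentation import quantify_cells, segment_nuclei
from condquant.simulate import (
    FrapTruth,
    SceneConfig,
    simulate_colocalized_pair,
    simulate_frap,
    simulate_nucleus_scene,
    simulate_population,
)


def population_fanos(cfg: SceneConfig, n_cells: int, seed: int) -> np.ndarray:
    """Per-cell Fano numbers of a simulated population, via the full
    segmentation → pixel-extraction → statistics pipeline."""
    fanos = []
    for stack, _truth in simulate_population(cfg, n_cells, seed):
        regions = segment_nuclei(stack, cfg.channel_names[0])
        for row in nucleus_stats_table(stack, regions, cfg.channel_names[0], 0.0):
            if row["defined"]:
                fanos.append(row["fano"])
    return np.asarray(fanos)


def fano_vs_puncta_fraction(
    fractions=(0.0, 0.2, 0.4, 0.6), n_cells: int = 50, seed: int = 0
) -> dict[float, float]:
    """Mean Fano per puncta fraction on noise-free populations."""
    out = {}
    for i, f in enumerate(fractions):
        cfg = SceneConfig(puncta_fraction=f, noise="none", intensity_cv=0.0)
        out[f] = float(population_fanos(cfg, n_cells, seed + i).mean())
    return out


def poisson_baseline_fano(n_cells: int = 50, seed: int = 0) -> float:
    """Mean Fano of zero-puncta nuclei under pure Poisson noise in photon
    units — the free-fluorophore baseline, expected ≈ 1."""
    cfg = SceneConfig(puncta_fraction=0.0, noise="poisson", intensity_cv=0.2)
    return float(population_fanos(cfg, n_cells, seed).mean())


def reference_normalized_fano_mean(n_cells: int = 50, seed: int = 0) -> float:
    """Mean normalized Fano of the free-fluorophore reference condition
    normalized against itself (exactly 1 by the normalization identity)."""
    fanos = population_fanos(
        SceneConfig(puncta_fraction=0.0, noise="poisson", intensity_cv=0.2),
        n_cells,
        seed,
    )
    return float(normalize_fano(fanos, fanos).mean)


# construction for the correlation-recovery experiment: a
# moderate-contrast extended punctate pattern (fraction 0.2, sigma 3 px)
# keeps the analytically required channel noise well below the
# nucleus/background contrast so segmentation stays reliable
COLOC_SCENE = SceneConfig(
    puncta_fraction=0.2, puncta_sigma_px=3.0, channel_names=("gfp", "mcherry")
)


def colocalization_recovery(
    target_r: float, n_cells: int = 50, seed: int = 0, shared_signal: bool = True
) -> float:
    """Mean per-cell Pearson r recovered from two-channel nuclei whose
    theoretical pixel correlation is set analytically to ``target_r``."""
    rs = []
    for i in range(n_cells):
        stack, _ = simulate_colocalized_pair(COLOC_SCENE, target_r, shared_signal, seed + i)
        regions = segment_nuclei(stack, "gfp")
        for res in colocalization_table(stack, regions, "gfp", "mcherry"):
            if res.defined:
                rs.append(res.pearson_r)
    return float(np.mean(rs))


def dot_population_average(
    coupled: bool,
    n_cells: int = 100,
    seed: int = 0,
    puncta_fraction: float = 0.4,
    w: int = 10,
):
    """Detect the locus dot per cell, align GFP MIPs on it, average."""
    cfg = SceneConfig(
        n_z=10,
        puncta_fraction=puncta_fraction,
        channel_names=("gfp", "mcherry"),
        with_dot=True,
        dot_coupled=coupled,
        noise="poisson",
        intensity_cv=0.0,
    )
    images, centers = [], []
    for i in range(n_cells):
        stack, _ = simulate_nucleus_scene(cfg, seed + i)
        det = detect_dot(stack, "mcherry")
        if not det.passed:
            continue
        images.append(extract_mip(stack, "gfp"))
        centers.append(det.center_yx)
    return align_and_average(images, centers, w, mode="mip", pixel_size_um=cfg.pixel_size_um)


def dot_enrichment_experiment(
    n_cells: int = 100, seed: int = 0, puncta_fraction: float = 0.4
) -> tuple:
    """Coupled vs independent dot populations: averaged profiles and the
    center-enrichment group comparison (the locus/condensate contrast)."""
    avg_coupled = dot_population_average(True, n_cells, seed, puncta_fraction)
    avg_indep = dot_population_average(False, n_cells, seed + 1_000_000, puncta_fraction)
    profile_coupled = line_profile(avg_coupled)
    profile_indep = line_profile(avg_indep)
    comparison = center_enrichment(avg_coupled, avg_indep)
    return profile_coupled, profile_indep, comparison


def frap_recovery_experiment(
    half_time_s: float = 64.0,
    n_replicates: int = 3,
    noise_sd_pct_of_plateau: float = 2.0,
    seed: int = 0,
) -> FrapFit:
    """Fit replicate synthetic FRAP curves generated under the imaging
    protocol (bleach after 3 frames, every 3 s for 270 s)."""
    truth = FrapTruth(half_time_s=half_time_s, plateau_pct=80.0, bleach_depth_pct=20.0)
    noise_sd = noise_sd_pct_of_plateau / 100.0 * truth.plateau_pct
    reps = [
        simulate_frap(replace(truth, noise_sd_pct=noise_sd, seed=seed + i))
        for i in range(n_replicates)
    ]
    return fit_recovery(reps, seed=seed)


def reporter_ratio_experiment(
    factor: float = 1.5, n_cells: int = 100, seed: int = 0
) -> tuple[float, GroupComparison]:
    """Percent excess of hotspot over basal mean cellular fluorescence.

    The same population seed pairs the lognormal cell-to-cell intensity
    factors across conditions (common random numbers), so the recovered
    ratio isolates pipeline bias rather than sampling scatter; the
    t-test compares the per-cell means of the two groups.
    """
    basal_cfg = SceneConfig(noise="poisson", intensity_cv=0.2)
    hotspot_cfg = replace(basal_cfg, total_photons=basal_cfg.total_photons * factor)
    basal, hotspot = [], []
    for stack, _ in simulate_population(basal_cfg, n_cells, seed):
        basal += [r["sub_mean"] for r in quantify_cells(stack, "gfp", 0.0)]
    for stack, _ in simulate_population(hotspot_cfg, n_cells, seed):
        hotspot += [r["sub_mean"] for r in quantify_cells(stack, "gfp", 0.0)]
    comparison = compare_groups(np.asarray(hotspot), np.asarray(basal))
    percent_excess = 100.0 * (comparison.mean_a / comparison.mean_b - 1.0)
    return percent_excess, comparison
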