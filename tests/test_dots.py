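"""Chromatin-dot detection, MIP, dot-centered averaging, line profiles."""

import numpy as np
import pytest

from condquant.dots import (
    align_and_average,
    center_enrichment,
    detect_dot,
    extract_mip,
    extract_same_z,
    line_profile,
    per_cell_center_means,
)
from condquant.image_io import ImageStack, RunConfig
from condquant.simulate import SceneConfig, simulate_nucleus_scene


def _stack_from(volume):
    return ImageStack(np.asarray(volume, float)[:, np.newaxis], channel_names=("mcherry",))


class TestDetectDot:
    def test_delta_location(self):
        vol = np.zeros((6, 24, 24))
        vol[3, 10, 12] = 100.0
        det = detect_dot(_stack_from(vol), "mcherry")
        assert det.best_z == 3
        assert det.center_yx == (10, 12)
        assert det.passed

    def test_tie_breaks_toward_lowest_z(self):
        vol = np.zeros((6, 24, 24))
        vol[2, 10, 10] = 100.0
        vol[5, 10, 10] = 100.0
        det = detect_dot(_stack_from(vol), "mcherry")
        assert det.best_z == 2

    def test_all_zero_channel_fails(self):
        det = detect_dot(_stack_from(np.zeros((3, 16, 16))), "mcherry")
        assert not det.passed

    def test_low_prominence_fails(self):
        vol = np.full((3, 16, 16), 100.0)
        vol[1, 8, 8] = 110.0  # barely above a bright background
        det = detect_dot(_stack_from(vol), "mcherry", RunConfig(dot_min_prominence=3.0))
        assert not det.passed

    def test_synthetic_scene_center_within_one_pixel(self):
        cfg = SceneConfig(n_z=10, puncta_fraction=0.4,
                          channel_names=("gfp", "mcherry"),
                          with_dot=True, dot_coupled=False, noise="none")
        for seed in range(5):
            stack, truth = simulate_nucleus_scene(cfg, 40 + seed)
            det = detect_dot(stack, "mcherry")
            _, ty, tx = truth.nuclei[0].dot_zyx
            assert np.hypot(det.center_yx[0] - ty, det.center_yx[1] - tx) <= 1.0


class TestProjections:
    def test_same_z_identity_and_bounds(self):
        vol = np.random.default_rng(0).random((4, 8, 8))
        stack = _stack_from(vol)
        np.testing.assert_array_equal(extract_same_z(stack, "mcherry", 2), vol[2])
        with pytest.raises(IndexError):
            extract_same_z(stack, "mcherry", 4)

    def test_mip_equals_top_plane_for_increasing_stack(self):
        vol = np.stack([np.full((5, 5), z) for z in range(4)]).astype(float)
        np.testing.assert_array_equal(extract_mip(_stack_from(vol), "mcherry"), vol[3])

    def test_mip_dominates_every_plane_and_matches_bruteforce(self):
        vol = np.random.default_rng(1).random((6, 10, 10))
        stack = _stack_from(vol)
        mip = extract_mip(stack, "mcherry")
        for z in range(6):
            assert np.all(mip >= vol[z])
        brute = np.array([[vol[:, y, x].max() for x in range(10)] for y in range(10)])
        np.testing.assert_array_equal(mip, brute)


def _brute_force_average(images, centers, w):
    """Pad-and-mask oracle for align_and_average."""
    size = 2 * w + 1
    total = np.zeros((size, size))
    count = np.zeros((size, size))
    for img, (cy, cx) in zip(images, centers):
        for dy in range(-w, w + 1):
            for dx in range(-w, w + 1):
                y, x = cy + dy, cx + dx
                if 0 <= y < img.shape[0] and 0 <= x < img.shape[1]:
                    total[dy + w, dx + w] += img[y, x]
                    count[dy + w, dx + w] += 1
    with np.errstate(invalid="ignore"):
        avg = total / count
    return avg, count


class TestAlignAndAverage:
    def test_single_interior_window_is_plain_crop(self):
        img = np.random.default_rng(2).random((30, 30))
        avg = align_and_average([img], [(15, 14)], w=5)
        np.testing.assert_array_equal(avg.average, img[10:21, 9:20])
        assert np.all(avg.counts == 1)

    def test_two_deltas_align_at_origin(self):
        a = np.zeros((20, 20)); a[4, 6] = 2.0
        b = np.zeros((20, 20)); b[13, 11] = 4.0
        avg = align_and_average([a, b], [(4, 6), (13, 11)], w=3)
        assert avg.average[3, 3] == pytest.approx(3.0)
        off_center = avg.average.copy()
        off_center[3, 3] = 0.0
        assert np.nansum(off_center) == pytest.approx(0.0)

    def test_border_windows_match_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        images = [rng.random((18, 22)) for _ in range(4)]
        centers = [(2, 3), (16, 20), (9, 1), (10, 11)]  # some near borders
        avg = align_and_average(images, centers, w=5)
        brute_avg, brute_count = _brute_force_average(images, centers, 5)
        np.testing.assert_array_equal(avg.counts, brute_count)
        np.testing.assert_allclose(avg.average, brute_avg, rtol=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            align_and_average([], [], w=3)

    def test_center_outside_image_rejected(self):
        with pytest.raises(ValueError):
            align_and_average([np.zeros((5, 5))], [(9, 2)], w=2)


class TestLineProfile:
    def test_uniform_average_gives_flat_profile(self):
        img = np.full((21, 21), 4.2)
        avg = align_and_average([img], [(10, 10)], w=6)
        prof = line_profile(avg)
        assert prof.mean.size == 13
        np.testing.assert_allclose(prof.mean, 4.2)

    def test_central_peak_has_maximum_at_offset_zero(self):
        img = np.zeros((21, 21)); img[10, 10] = 9.0
        avg = align_and_average([img], [(10, 10)], w=4)
        prof = line_profile(avg)
        assert prof.offsets_px[np.argmax(prof.mean)] == 0

    def test_offsets_in_micrometres(self):
        img = np.zeros((21, 21))
        avg = align_and_average([img], [(10, 10)], w=5, pixel_size_um=0.1)
        prof = line_profile(avg)
        assert prof.offsets_um[0] == pytest.approx(-0.5)

    def test_averaging_and_profiling_commute(self):
        """Profile of the average equals the missing-aware average of
        per-cell profiles, including at partially covered offsets."""
        rng = np.random.default_rng(4)
        images = [rng.random((15, 15)) for _ in range(6)]
        centers = [(2, 2), (7, 7), (12, 12), (3, 11), (11, 3), (7, 1)]
        avg = align_and_average(images, centers, w=4)
        prof = line_profile(avg)
        per_cell_rows = avg.windows[:, 4, :]
        with np.errstate(invalid="ignore"):
            manual = np.nanmean(per_cell_rows, axis=0)
        np.testing.assert_allclose(prof.mean, manual, rtol=1e-12)


class TestCenterEnrichment:
    def test_identical_populations_show_no_enrichment(self):
        rng = np.random.default_rng(5)
        images = [rng.random((21, 21)) for _ in range(30)]
        centers = [(10, 10)] * 30
        avg_a = align_and_average(images[:15], centers[:15], w=5)
        avg_b = align_and_average(images[15:], centers[15:], w=5)
        g = center_enrichment(avg_a, avg_b)
        assert g.p_value > 0.001

    def test_single_cell_groups_rejected(self):
        img = np.zeros((11, 11))
        avg = align_and_average([img], [(5, 5)], w=3)
        with pytest.raises(ValueError):
            center_enrichment(avg, avg)

    def test_center_means_use_center_window_only(self):
        img = np.zeros((21, 21)); img[10, 10] = 25.0  # 5x5 center window
        avg = align_and_average([img], [(10, 10)], w=5)
        vals = per_cell_center_means(avg, center_radius_px=2)
        assert vals[0] == pytest.approx(1.0)  # 25 / 25 pixels
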