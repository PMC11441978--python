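"""CV/Fano statistics, normalization, co-localization, group tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from condquant.puncta import (
    colocalization_table,
    compare_groups,
    compute_pixel_stats,
    normalize_fano,
    pixel_colocalization,
    significance_stars,
)
from condquant.segmentation import segment_nuclei
from condquant.simulate import SceneConfig, simulate_colocalized_pair

finite_pixels = st.lists(
    st.floats(min_value=0.0, max_value=1e5, allow_nan=False), min_size=2, max_size=50
)


class TestComputePixelStats:
    def test_uniform_pixels(self):
        s = compute_pixel_stats(np.array([5.0, 5, 5, 5]), 0.0)
        assert (s.raw_mean, s.variance, s.cv, s.fano) == (5.0, 0.0, 0.0, 0.0)

    def test_hand_computed_example(self):
        # mean 4, sample variance ((2-4)^2+(0)^2+(2)^2)/2 = 4, cv 0.5, fano 1
        s = compute_pixel_stats(np.array([2.0, 4.0, 6.0]), 0.0)
        assert s.sub_mean == pytest.approx(4.0)
        assert s.variance == pytest.approx(4.0)
        assert s.cv == pytest.approx(0.5)
        assert s.fano == pytest.approx(1.0)

    def test_background_shifts_mean_not_variance(self):
        s = compute_pixel_stats(np.array([12.0, 14.0, 16.0]), 10.0)
        assert s.sub_mean == pytest.approx(4.0)
        assert s.variance == pytest.approx(4.0)
        assert s.cv == pytest.approx(0.5)
        assert s.fano == pytest.approx(1.0)

    def test_too_few_pixels_rejected(self):
        with pytest.raises(ValueError):
            compute_pixel_stats(np.array([1.0]), 0.0)

    def test_nonpositive_sub_mean_flagged_undefined(self):
        s = compute_pixel_stats(np.array([1.0, 2.0, 3.0]), 10.0)
        assert not s.defined
        assert math.isnan(s.cv) and math.isnan(s.fano)

    @settings(derandomize=True, max_examples=100)
    @given(pixels=finite_pixels, background=st.floats(min_value=0, max_value=10))
    def test_fano_identity_holds(self, pixels, background):
        """fano == cv^2 * sub_mean to machine precision whenever defined."""
        s = compute_pixel_stats(np.array(pixels), background)
        if s.defined:
            assert s.fano == pytest.approx(s.cv**2 * s.sub_mean, rel=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(pixels=finite_pixels, shift=st.floats(min_value=0, max_value=1e4))
    def test_cv_fano_invariant_to_matched_shift(self, pixels, shift):
        """Adding c to pixels and to the background leaves CV/Fano unchanged."""
        a = compute_pixel_stats(np.array(pixels), 0.0)
        b = compute_pixel_stats(np.array(pixels) + shift, shift)
        if a.defined and b.defined:
            assert b.cv == pytest.approx(a.cv, rel=1e-6, abs=1e-9)
            assert b.fano == pytest.approx(a.fano, rel=1e-6, abs=1e-9)


class TestNormalizeFano:
    def test_example_division(self):
        norm = normalize_fano(np.array([4.0]), np.array([1.0, 2.0, 3.0]))
        assert norm.values[0] == pytest.approx(2.0)

    def test_reference_against_itself_means_exactly_one(self):
        ref = np.array([0.8, 1.1, 1.9, 2.6])
        norm = normalize_fano(ref, ref)
        assert norm.mean == 1.0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            normalize_fano(np.array([1.0]), np.array([]))

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            normalize_fano(np.array([1.0]), np.array([1.0, -3.0]))


class TestPixelColocalization:
    def test_identity_and_antisymmetry(self):
        x = np.array([1.0, 2.0, 3.0])
        assert pixel_colocalization(x, x).pearson_r == pytest.approx(1.0)
        assert pixel_colocalization(x, x[::-1]).pearson_r == pytest.approx(-1.0)

    def test_direct_formula_example(self):
        r = pixel_colocalization(np.array([1.0, 2, 3, 4]), np.array([1.0, 3, 2, 4]))
        assert r.pearson_r == pytest.approx(0.8)

    def test_zero_variance_flagged(self):
        res = pixel_colocalization(np.array([1.0, 1, 1]), np.array([1.0, 2, 3]))
        assert not res.defined
        assert math.isnan(res.pearson_r)

    def test_length_mismatch_and_short_input_rejected(self):
        with pytest.raises(ValueError):
            pixel_colocalization(np.array([1.0, 2]), np.array([1.0, 2, 3]))
        with pytest.raises(ValueError):
            pixel_colocalization(np.array([1.0, 2]), np.array([1.0, 2]))

    @settings(derandomize=True, max_examples=50)
    @given(
        gain1=st.floats(min_value=0.01, max_value=100),
        gain2=st.floats(min_value=0.01, max_value=100),
        off1=st.floats(min_value=0, max_value=1000),
        off2=st.floats(min_value=0, max_value=1000),
    )
    def test_affine_invariance(self, gain1, gain2, off1, off2):
        rng = np.random.default_rng(42)
        x = rng.random(30)
        y = 0.5 * x + rng.random(30)
        base = pixel_colocalization(x, y).pearson_r
        scaled = pixel_colocalization(gain1 * x + off1, gain2 * y + off2).pearson_r
        assert scaled == pytest.approx(base, abs=1e-7)


class TestCompareGroups:
    def test_identical_groups(self):
        g = compare_groups(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert g.t_statistic == pytest.approx(0.0)
        assert g.p_value == pytest.approx(1.0)

    def test_matches_pooled_variance_closed_form(self):
        from scipy.stats import t as tdist

        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        g = compare_groups(a, b)
        sp2 = (2 * a.var(ddof=1) + 2 * b.var(ddof=1)) / 4  # pooled, n=3 each
        t_expected = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / 3 + 1 / 3))
        p_expected = 2 * tdist.sf(abs(t_expected), df=4)
        assert g.t_statistic == pytest.approx(t_expected)
        assert g.p_value == pytest.approx(p_expected)

    def test_star_mapping(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.2) == "ns"

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups(np.array([1.0]), np.array([1.0, 2.0]))


class TestEndToEndColocalizationContrast:
    def test_shared_pattern_exceeds_independent_pattern(self):
        """Nuclei with a shared two-channel puncta pattern show much higher
        mean per-cell pixel correlation than independently patterned ones."""
        cfg = SceneConfig(puncta_fraction=0.2, puncta_sigma_px=3.0,
                          channel_names=("gfp", "mcherry"))
        shared, independent = [], []
        for i in range(15):
            for flag, sink in ((True, shared), (False, independent)):
                stack, _ = simulate_colocalized_pair(cfg, 0.75, flag, 300 + i)
                regions = segment_nuclei(stack, "gfp")
                for res in colocalization_table(stack, regions, "gfp", "mcherry"):
                    if res.defined:
                        sink.append(res.pearson_r)
        assert np.mean(shared) > np.mean(independent) + 0.3
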