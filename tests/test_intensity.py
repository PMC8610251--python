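"""Intensity ratios, line profiles, puncta gating and association."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lysoquant.core import CellRegion
from lysoquant.intensity_metrics import (
    count_puncta,
    extract_line_profile,
    grid_line_profiles,
    line_profile_ratio,
    lysosome_associated_puncta,
    lysosome_mask_2d,
    mean_cell_intensity,
    organelle_to_cytosol_ratio,
)
from lysoquant.synthetic_scenes import (
    SceneConfig,
    generate_puncta_lysosome_scene,
    generate_puncta_scene,
)

profiles = st.lists(st.floats(1.0, 1e4, allow_nan=False), min_size=20,
                    max_size=40)


class TestLineProfileRatio:
    def test_bimodal_profile_exact(self):
        assert line_profile_ratio(np.array([100.0] * 10 + [10.0] * 10)) == 10.0

    def test_uniform_profile_is_one(self):
        assert line_profile_ratio(np.full(30, 7.0)) == 1.0

    def test_too_short_profile_rejected(self):
        with pytest.raises(ValueError):
            line_profile_ratio(np.ones(19))

    def test_non_positive_f_low_is_error_not_clamped(self):
        values = np.array([100.0] * 10 + [0.0] * 10)
        with pytest.raises(ValueError, match="F_L"):
            line_profile_ratio(values)

    @given(profiles, st.floats(0.01, 100.0))
    def test_invariant_under_positive_scaling(self, values, scale):
        values = np.asarray(values)
        assert line_profile_ratio(values * scale) == pytest.approx(
            line_profile_ratio(values), rel=1e-9)

    @given(profiles)
    def test_at_least_one_and_one_iff_constant(self, values):
        ratio = line_profile_ratio(np.asarray(values))
        assert ratio >= 1.0
        if len(set(values)) == 1:
            assert ratio == 1.0

    def test_offset_removal_increases_contrast(self):
        values = np.array([100.0] * 10 + [40.0] * 10)
        assert line_profile_ratio(values - 30.0) > line_profile_ratio(values)

    def test_width_averaging_precedes_sorting(self):
        """A 3-pixel-wide profile averages across the width first."""
        image = np.zeros((9, 30))
        image[3, :] = 90.0                  # only the central row is bright
        image[4, :] = 30.0
        image[5, :] = 30.0
        profile = extract_line_profile(image, (4, 2), (4, 26), width=3)
        assert np.allclose(profile.values, 50.0)   # (90+30+30)/3

    def test_grid_lines_avoid_nucleus_and_are_seeded(self):
        mask = np.zeros((60, 60), bool)
        mask[5:55, 5:55] = True
        nucleus = np.zeros((60, 60), bool)
        nucleus[25:40, :] = True
        cell = CellRegion("c", mask, nucleus_mask=nucleus)
        image = np.random.default_rng(0).uniform(10, 20, (60, 60))
        lines = grid_line_profiles(image, cell, k=3, seed=4)
        again = grid_line_profiles(image, cell, k=3, seed=4)
        assert len(lines) == 3
        for a, b in zip(lines, again):
            assert np.array_equal(a.values, b.values)
            assert not nucleus[int(a.start[0]), :].any()


class TestMaskRatios:
    def _cell(self, shape=(40, 40)):
        mask = np.zeros(shape, bool)
        mask[5:35, 5:35] = True
        cytosol = mask.copy()
        cytosol[15:25, 15:25] = False
        return CellRegion("c", mask, cytosol)

    def test_ratio_arithmetic(self):
        cell = self._cell()
        reference = np.full((40, 40), 10.0)
        reference[15:25, 15:25] = 100.0     # organelle mask via 2× cytosol
        marker = np.full((40, 40), 50.0)
        marker[15:25, 15:25] = 200.0
        background = np.zeros((40, 40), bool)
        background[:3, :3] = True
        marker[:3, :3] = 0.0
        result = organelle_to_cytosol_ratio(marker, reference, cell, background)
        assert result.value == pytest.approx(4.0)

    def test_uniform_marker_gives_unity(self):
        cell = self._cell()
        reference = np.full((40, 40), 10.0)
        reference[15:25, 15:25] = 100.0
        marker = np.full((40, 40), 80.0)
        background = np.zeros((40, 40), bool)
        background[:3, :3] = True
        marker[:3, :3] = 0.0
        result = organelle_to_cytosol_ratio(marker, reference, cell, background)
        assert result.value == pytest.approx(1.0)

    def test_empty_reference_mask_flagged_not_zero(self):
        cell = self._cell()
        reference = np.full((40, 40), 10.0)   # uniform: nothing above 2×
        marker = np.full((40, 40), 80.0)
        background = np.zeros((40, 40), bool)
        background[:3, :3] = True
        result = organelle_to_cytosol_ratio(marker, reference, cell, background)
        assert result.value is None

    def test_mean_cell_intensity_background_correction(self):
        cell = self._cell()
        image = np.full((40, 40), 120.0)
        background = np.zeros((40, 40), bool)
        background[:3, :3] = True
        image[:3, :3] = 20.0
        assert mean_cell_intensity(image, cell, background) == pytest.approx(100.0)
        uniform = np.full((40, 40), 20.0)
        assert mean_cell_intensity(uniform, cell, background) == 0.0


class TestPuncta:
    def test_gate_logic_counts_only_in_range_areas(self):
        """Areas {30, 60, 1200}: only the 60 μm² punctum is counted."""
        config = SceneConfig(random_seed=4, pixel_size_xy=0.2,
                             shape_xy=(1024, 1024))
        image, cell, _ = generate_puncta_scene(config, [30.0, 60.0, 1200.0])
        puncta = count_puncta(image, cell, config.pixel_size_xy,
                              threshold="cytosol", gate=(50.0, 1000.0))
        assert puncta.count == 1
        assert puncta.puncta[0].area == pytest.approx(60.0, rel=0.1)

    def test_blank_cell_counts_zero(self):
        mask = np.zeros((32, 32), bool)
        mask[4:28, 4:28] = True
        cell = CellRegion("c", mask, mask.copy())
        assert count_puncta(np.full((32, 32), 5.0), cell, 0.1,
                            threshold=10.0).count == 0

    def test_count_monotone_in_gate_bounds(self):
        config = SceneConfig(random_seed=6, pixel_size_xy=0.2,
                             shape_xy=(1024, 1024))
        areas = [30.0, 60.0, 90.0, 150.0, 400.0, 800.0, 1200.0]
        image, cell, _ = generate_puncta_scene(config, areas)
        counts = [count_puncta(image, cell, 0.2, threshold="cytosol",
                               gate=(lo, hi)).count
                  for lo, hi in [(50, 1000), (100, 1000), (50, 500), (0, 2000)]]
        base, tighter_lo, tighter_hi, widest = counts
        assert tighter_lo <= base <= widest
        assert tighter_hi <= base <= widest

    def test_truth_recovery_of_in_gate_puncta(self):
        config = SceneConfig(random_seed=8, pixel_size_xy=0.2,
                             shape_xy=(1024, 1024))
        areas = [30.0, 60.0, 80.0, 120.0, 200.0, 400.0, 900.0, 55.0, 1200.0, 45.0]
        image, cell, truth = generate_puncta_scene(config, areas)
        expected = sum(50.0 <= o.area <= 1000.0 for o in truth.objects)
        puncta = count_puncta(image, cell, 0.2, threshold="cytosol")
        assert puncta.count == expected == 7


class TestAssociation:
    def test_centroid_inside_lysosome_is_associated_at_zero_distance(self):
        from lysoquant.intensity_metrics import Punctum, PunctaSet
        lysosomes = np.zeros((20, 20), bool)
        lysosomes[8:12, 8:12] = True
        inside = PunctaSet("c", [Punctum((1.0, 1.0), 0.1, 100.0)])
        assert lysosome_associated_puncta(inside, lysosomes, 0.1,
                                          association_distance=0.0) == 1

    def test_distant_punctum_not_associated(self):
        from lysoquant.intensity_metrics import Punctum, PunctaSet
        lysosomes = np.zeros((100, 100), bool)
        lysosomes[45:55, 5:15] = True
        far = PunctaSet("c", [Punctum((6.0, 5.0), 0.1, 100.0)])  # 5 μm away
        assert lysosome_associated_puncta(far, lysosomes, 0.1,
                                          association_distance=0.5) == 0

    def test_scene_truth_recovery(self):
        """4 of 10 puncta placed on lysosome rims are found associated."""
        config = SceneConfig(random_seed=9, shape_xy=(300, 300))
        channels, cell, truth = generate_puncta_lysosome_scene(
            config, n_puncta=10, n_on_lysosome=4)
        lysosomes = lysosome_mask_2d(channels[0], cell)
        puncta = count_puncta(channels[1], cell, config.pixel_size_xy,
                              threshold="cytosol", gate=(0.05, 10.0))
        assert puncta.count == 10
        assert lysosome_associated_puncta(
            puncta, lysosomes, config.pixel_size_xy) == 4
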