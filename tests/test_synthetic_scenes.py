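"""Generator correctness: determinism, geometry conservation, ground truth."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lysoquant.core import centers_um
from lysoquant.synthetic_scenes import (
    ConstantVelocity,
    PlacementError,
    RandomWalk,
    SceneConfig,
    Stationary,
    _reflect,
    asterisk_graph,
    frames_for_duration,
    generate_filament_image,
    generate_lysosome_stack,
    generate_phagosome_scene,
    generate_timelapse,
    phagosome_ring_mask,
)


def small_config(**kw):
    kw.setdefault("random_seed", 1)
    kw.setdefault("shape_xy", (96, 96))
    kw.setdefault("n_planes", 20)
    return SceneConfig(**kw)


class TestSceneConfig:
    @pytest.mark.parametrize("bad", [
        {"pixel_size_xy": 0.0}, {"z_spacing": -0.1}, {"n_planes": 0},
        {"psf_sigma": -1.0}, {"gaussian_sd": -1.0}, {"background_level": -5.0},
        {"frame_interval": 0.0},
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            SceneConfig(**bad)

    def test_timelapse_presets_cover_acquisition_durations(self):
        # 3 min at 4 s and 6 min at 8 s both give 46 frames
        assert frames_for_duration(4.0, 180.0) == 46
        assert frames_for_duration(8.0, 360.0) == 46


class TestLysosomeStack:
    def test_determinism_bit_identical(self):
        a = generate_lysosome_stack(small_config(), spheres_per_cell=8)
        b = generate_lysosome_stack(small_config(), spheres_per_cell=8)
        assert np.array_equal(a[0].intensities, b[0].intensities)
        assert [o.center for o in a[2].objects] == [o.center for o in b[2].objects]

    def test_truth_lists_every_sphere_with_ideal_volume(self, ideal_volume):
        _, _, truth = generate_lysosome_stack(
            SceneConfig(random_seed=1), n_cells=1, spheres_per_cell=20)
        assert len(truth.objects) == 20
        for obj in truth.objects:
            assert obj.kind == "sphere"
            assert obj.radius == 0.7          # default lysosome radius
            volume = 4 / 3 * np.pi * obj.radius ** 3
            assert volume == pytest.approx(ideal_volume, rel=1e-12)

    def test_empty_scene_is_background_plus_noise_only(self):
        config = small_config(gaussian_sd=0.0, psf_sigma=0.0)
        image, cells, truth = generate_lysosome_stack(config, spheres_per_cell=0)
        assert truth.objects == []
        inside = image.intensities[:, cells[0].mask]
        assert np.all(inside == config.background_level)

    def test_noiseless_support_matches_rasterized_truth(self):
        """psf=0, no noise: above-background voxels = exact sphere geometry."""
        config = small_config(gaussian_sd=0.0, psf_sigma=0.0,
                              poisson_scaling=0.0)
        image, cells, truth = generate_lysosome_stack(config, spheres_per_cell=5)
        above = image.intensities > config.background_level
        zc, yc, xc = np.meshgrid(
            centers_um(np.arange(config.n_planes), config.z_spacing),
            centers_um(np.arange(config.shape_xy[0]), config.pixel_size_xy),
            centers_um(np.arange(config.shape_xy[1]), config.pixel_size_xy),
            indexing="ij")
        expected = np.zeros_like(above)
        for obj in truth.objects:
            cx, cy, cz = obj.center
            expected |= ((xc - cx) ** 2 + (yc - cy) ** 2 + (zc - cz) ** 2
                         <= obj.radius ** 2)
        assert np.array_equal(above, expected)

    def test_unresolvable_radius_rejected(self):
        with pytest.raises(ValueError, match="resolvable"):
            generate_lysosome_stack(small_config(), spheres_per_cell=2,
                                    radius_distribution=0.15)

    def test_placement_failure_names_cell(self):
        with pytest.raises(PlacementError, match="cell_00"):
            generate_lysosome_stack(small_config(), spheres_per_cell=500)

    def test_objects_within_bounds_and_unique_ids(self):
        config = SceneConfig(random_seed=5)
        _, _, truth = generate_lysosome_stack(config, n_cells=2,
                                              spheres_per_cell=10)
        ids = [o.id for o in truth.objects]
        assert len(set(ids)) == len(ids) == 20
        h, w = config.extent_xy
        for obj in truth.objects:
            x, y, z = obj.center
            assert 0 < x < w and 0 < y < h and 0 < z < config.depth


class TestTimelapse:
    def test_stationary_truth_constant(self):
        _, truth = generate_timelapse(small_config(), 3, Stationary(), 10)
        for obj in truth.objects:
            assert np.allclose(obj.positions, obj.positions[0])

    def test_constant_velocity_kinematics(self):
        """1.25 μm/s along +x for 10 frames at 4 s: 45 μm path and net."""
        config = SceneConfig(random_seed=2, shape_xy=(560, 560),
                             frame_interval=4.0)
        _, truth = generate_timelapse(config, 1, ConstantVelocity(1.25), 10)
        pos = truth.objects[0].positions
        steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        assert steps.sum() == pytest.approx(45.0, rel=1e-9)
        assert np.linalg.norm(pos[-1] - pos[0]) == pytest.approx(45.0, rel=1e-9)

    def test_random_walk_stays_in_frame(self):
        config = small_config()
        _, truth = generate_timelapse(config, 5, RandomWalk(1.0), 50)
        h, w = config.extent_xy
        for obj in truth.objects:
            assert np.all(obj.positions >= 0)
            assert np.all(obj.positions[:, 0] <= w)
            assert np.all(obj.positions[:, 1] <= h)

    def test_short_movies_rejected(self):
        with pytest.raises(ValueError):
            generate_timelapse(small_config(), 1, Stationary(), 1)

    @given(st.floats(-100, 100, allow_nan=False))
    def test_reflection_keeps_value_in_interval(self, value):
        assert 2.0 <= _reflect(value, 2.0, 9.0) <= 9.0


class TestFilaments:
    def test_single_branch_topology(self):
        config = small_config(gaussian_sd=0.0)
        _, truth = generate_filament_image(config, [((1.0, 3.0), (8.0, 3.0))])
        assert truth.topology.n_junctions == 0
        assert truth.topology.n_branches == 1
        assert truth.topology.mean_branch_length_um == pytest.approx(7.0)

    def test_plus_and_overlaid_x_junction_counts(self):
        config = small_config()
        plus = asterisk_graph((4.8, 4.8), [3.0] * 4, [0, 90, 180, 270])
        _, truth = generate_filament_image(config, plus)
        assert (truth.topology.n_junctions, truth.topology.n_branches) == (1, 4)
        star = asterisk_graph((4.8, 4.8), [3.0] * 8,
                              [0, 45, 90, 135, 180, 225, 270, 315])
        _, truth = generate_filament_image(config, star)
        assert (truth.topology.n_junctions, truth.topology.n_branches) == (1, 8)

    def test_zero_length_branch_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            generate_filament_image(small_config(), [((2.0, 2.0), (2.0, 2.0))])

    def test_out_of_bounds_endpoint_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            generate_filament_image(small_config(), [((1.0, 1.0), (50.0, 1.0))])


class TestPhagosomeScene:
    def test_internal_external_counts_by_construction(self):
        config = small_config()
        channels, truth = generate_phagosome_scene(config, 3, 2)
        assert len(truth.of_kind("bacterium_internal")) == 3
        assert len(truth.of_kind("bacterium_external")) == 2
        assert channels.shape[0] == 3

    def test_no_internal_bacteria_gives_background_lamp_channel(self):
        config = small_config(gaussian_sd=0.0, psf_sigma=0.0)
        channels, _ = generate_phagosome_scene(config, 0, 2)
        assert np.all(channels[2] == config.background_level)

    def test_noiseless_ring_mean_equals_requested_intensity(self):
        config = small_config(gaussian_sd=0.0, psf_sigma=0.0,
                              background_level=0.0)
        channels, truth = generate_phagosome_scene(
            config, 2, 0, lamp_ring_intensity=500.0)
        ring = phagosome_ring_mask(truth, config)
        assert channels[2][ring].mean() == pytest.approx(500.0)
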