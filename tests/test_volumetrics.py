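"""Lysosome segmentation: thresholding, labelling, watershed, metrics."""

from collections import deque

import numpy as np
import pytest

from lysoquant.core import CellRegion, VolumetricImage
from lysoquant.lysosome_volumetrics import (
    cytosolic_threshold,
    per_cell_metrics,
    segment_lysosomes,
    watershed_split,
)
from lysoquant.synthetic_scenes import SceneConfig, generate_lysosome_stack

VOXEL = (0.1, 0.1, 0.3)


def make_image(data):
    return VolumetricImage(np.asarray(data, dtype=float), VOXEL)


def full_cell(shape_zyx, cytosol=None):
    mask = np.ones(shape_zyx[1:], dtype=bool)
    return CellRegion("cell", mask,
                      cytosol if cytosol is not None else mask.copy())


class TestCytosolicThreshold:
    def test_factor_times_cytosol_mean(self):
        data = np.zeros((2, 4, 4))
        data[:, :2, :] = 50.0
        cytosol = np.zeros((4, 4), dtype=bool)
        cytosol[:2, :] = True
        cell = full_cell(data.shape, cytosol)
        assert cytosolic_threshold(make_image(data), cell) == pytest.approx(100.0)

    def test_mean_oracle_small_sample(self):
        data = np.zeros((1, 1, 3))
        data[0, 0] = [10.0, 20.0, 30.0]
        cell = full_cell(data.shape)
        assert cytosolic_threshold(make_image(data), cell, 2.0) \
            == pytest.approx(40.0)

    def test_empty_cytosol_is_error(self):
        data = np.zeros((2, 4, 4))
        cell = CellRegion("c", np.ones((4, 4), bool), np.zeros((4, 4), bool))
        with pytest.raises(ValueError, match="cytosol"):
            cytosolic_threshold(make_image(data), cell)

    def test_uniform_image_yields_zero_segments(self):
        """Strict inequality: threshold 2c on a uniform image of c keeps nothing."""
        data = np.full((4, 8, 8), 37.0)
        image = make_image(data)
        cell = full_cell(data.shape)
        thr = cytosolic_threshold(image, cell)
        assert segment_lysosomes(image, cell, thr) == []


class TestSegmentation:
    def test_recovers_all_spheres_within_volume_tolerance(self, ideal_volume):
        image, cells, truth = generate_lysosome_stack(
            SceneConfig(random_seed=11), spheres_per_cell=20)
        segments = segment_lysosomes(image, cells[0])
        assert len(segments) == 20
        for seg in segments:
            assert seg.volume == pytest.approx(ideal_volume, rel=0.15)

    def test_sub_gate_sphere_excluded(self):
        """A 0.4 μm sphere (0.268 μm³ < 0.3 μm³ gate) never counts."""
        image, cells, _ = generate_lysosome_stack(
            SceneConfig(random_seed=11), spheres_per_cell=6,
            radius_distribution=0.4)
        assert segment_lysosomes(image, cells[0]) == []

    def test_all_zero_image_gives_empty_list(self):
        data = np.zeros((4, 8, 8))
        assert segment_lysosomes(make_image(data), full_cell(data.shape),
                                 threshold=10.0) == []

    def test_raising_threshold_never_grows_segments(self):
        image, cells, _ = generate_lysosome_stack(
            SceneConfig(random_seed=3), spheres_per_cell=8)
        low = segment_lysosomes(image, cells[0], threshold=200.0,
                                min_volume=0.0, split=False)
        high = segment_lysosomes(image, cells[0], threshold=260.0,
                                 min_volume=0.0, split=False)
        assert sum(s.n_voxels for s in high) <= sum(s.n_voxels for s in low)
        low_mask = set(map(tuple, np.vstack([s.voxel_indices for s in low])))
        high_mask = set(map(tuple, np.vstack([s.voxel_indices for s in high])))
        assert high_mask <= low_mask

    def test_labels_dense_from_one(self):
        image, cells, _ = generate_lysosome_stack(
            SceneConfig(random_seed=4), spheres_per_cell=5)
        segments = segment_lysosomes(image, cells[0])
        assert [s.label for s in segments] == list(range(1, len(segments) + 1))

    def test_agrees_with_flood_fill_oracle(self):
        """26-connected labelling matches brute-force BFS on a small stack."""
        rng = np.random.default_rng(42)
        data = (rng.random((12, 16, 16)) < 0.2).astype(float)
        image = make_image(data)
        segments = segment_lysosomes(image, full_cell(data.shape),
                                     threshold=0.5, min_volume=0.0,
                                     split=False)
        ours = {frozenset(map(tuple, s.voxel_indices)) for s in segments}

        # independent BFS flood fill, 26-neighbourhood
        remaining = {tuple(p) for p in np.argwhere(data > 0.5)}
        oracle = set()
        offsets = [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1)
                   for dx in (-1, 0, 1) if (dz, dy, dx) != (0, 0, 0)]
        while remaining:
            seed = remaining.pop()
            comp = {seed}
            queue = deque([seed])
            while queue:
                z, y, x = queue.popleft()
                for dz, dy, dx in offsets:
                    q = (z + dz, y + dy, x + dx)
                    if q in remaining:
                        remaining.discard(q)
                        comp.add(q)
                        queue.append(q)
            oracle.add(frozenset(comp))
        assert ours == oracle


class TestWatershedSplit:
    def test_isolated_region_is_identity(self):
        image, cells, _ = generate_lysosome_stack(
            SceneConfig(random_seed=6), spheres_per_cell=1)
        thr = cytosolic_threshold(image, cells[0])
        region = image.intensities > thr
        labels = watershed_split(region, VOXEL)
        assert labels.max() == 1
        assert np.array_equal(labels > 0, region)

    def test_touching_pair_split_into_two(self, ideal_volume):
        image, cells, _ = generate_lysosome_stack(
            SceneConfig(random_seed=6), spheres_per_cell=2, coalesced=True,
            pair_separation=1.1)
        segments = segment_lysosomes(image, cells[0], split=True)
        assert len(segments) == 2
        for seg in segments:
            assert seg.volume == pytest.approx(ideal_volume, rel=0.20)

    def test_voxel_conservation(self):
        image, cells, _ = generate_lysosome_stack(
            SceneConfig(random_seed=8), spheres_per_cell=4, coalesced=True,
            pair_separation=1.1)
        thr = cytosolic_threshold(image, cells[0])
        region = image.intensities > thr
        labels = watershed_split(region, VOXEL)
        assert np.array_equal(labels > 0, region)
        assert int(region.sum()) == sum(
            int((labels == lab).sum()) for lab in range(1, labels.max() + 1))


class TestPerCellMetrics:
    def test_count_and_total(self):
        from lysoquant.core import OrganelleSegment
        segs = [OrganelleSegment(i, np.zeros((1, 3), int), v, (0, 0, 0), "c")
                for i, v in enumerate([1.0, 2.0, 3.0], start=1)]
        report = per_cell_metrics(segs)
        assert report.lysosome_count == 3
        assert report.total_volume == pytest.approx(6.0)

    def test_empty_report(self):
        report = per_cell_metrics([])
        assert report.lysosome_count == 0
        assert report.total_volume == 0.0

    def test_mixed_cells_rejected(self):
        from lysoquant.core import OrganelleSegment
        segs = [OrganelleSegment(1, np.zeros((1, 3), int), 1.0, (0, 0, 0), "a"),
                OrganelleSegment(2, np.zeros((1, 3), int), 1.0, (0, 0, 0), "b")]
        with pytest.raises(ValueError, match="multiple cells"):
            per_cell_metrics(segs)

    def test_truth_recovery_count(self):
        image, cells, truth = generate_lysosome_stack(
            SceneConfig(random_seed=9), spheres_per_cell=20)
        report = per_cell_metrics(segment_lysosomes(image, cells[0]))
        assert report.lysosome_count == len(truth.objects) == 20
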