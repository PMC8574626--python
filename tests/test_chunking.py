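"""Box cutting, normalization, filtering, augmentation and cropping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cryoss.chunking import (
    BOX_SIZE,
    CHUNK_SIZE,
    ROTATIONS_24,
    Box,
    apply_rotation,
    augment,
    axis_starts,
    center_crop,
    cut_boxes,
    filter_boxes,
    normalize_box,
)
from cryoss.labeling import UNASSIGNED, LabelMap
from cryoss.map_io import DensityMap


def _map_with_labels(dims, rng=None):
    rng = rng or np.random.default_rng(0)
    dmap = DensityMap(rng.random(dims).astype(np.float32))
    labels = LabelMap(rng.integers(0, 4, dims))
    return dmap, labels


class TestCutBoxes:
    @pytest.mark.parametrize(
        "dim,expected",
        [(60, [0]), (90, [0, 30]), (100, [0, 30, 40]), (61, [0, 1]), (40, [0])],
    )
    def test_axis_starts(self, dim, expected):
        assert axis_starts(dim) == expected

    @pytest.mark.parametrize("dims,count", [((60,) * 3, 1), ((90,) * 3, 8), ((100,) * 3, 27)])
    def test_box_counts(self, dims, count):
        dmap, labels = _map_with_labels(dims)
        assert len(cut_boxes(dmap, labels)) == count

    def test_small_map_padded(self):
        dmap, labels = _map_with_labels((40, 40, 40))
        boxes = cut_boxes(dmap, labels)
        assert len(boxes) == 1
        box = boxes[0]
        assert box.density.shape == (60, 60, 60)
        np.testing.assert_array_equal(box.density[:40, :40, :40], dmap.grid)
        assert np.all(box.density[40:] == 0.0)
        assert np.all(box.labels[40:] == UNASSIGNED)

    def test_box_content_matches_map_slice(self):
        dmap, labels = _map_with_labels((90, 90, 90))
        for box in cut_boxes(dmap, labels):
            sx, sy, sz = box.start_index
            np.testing.assert_array_equal(
                box.density, dmap.grid[sx : sx + 60, sy : sy + 60, sz : sz + 60]
            )

    @given(
        dims=st.tuples(*[st.integers(min_value=1, max_value=140)] * 3)
    )
    @settings(max_examples=25, deadline=None)
    def test_every_voxel_covered(self, dims):
        starts = [axis_starts(max(d, BOX_SIZE)) for d in dims]
        for d, ax in zip(dims, starts):
            covered = np.zeros(max(d, BOX_SIZE), dtype=bool)
            for s in ax:
                covered[s : s + BOX_SIZE] = True
            assert covered.all()


class TestNormalize:
    def test_clip_and_scale(self):
        d = np.zeros((60, 60, 60), dtype=np.float32)
        d[0, 0, :3] = [-1.0, 0.0, 2.0]
        out = normalize_box(Box(density=d, start_index=(0, 0, 0)))
        np.testing.assert_allclose(out.density[0, 0, :3], [0.0, 0.0, 1.0])

    def test_all_negative_becomes_zero(self):
        d = np.full((60, 60, 60), -3.0, dtype=np.float32)
        out = normalize_box(Box(density=d, start_index=(0, 0, 0)))
        assert np.all(out.density == 0.0)

    def test_idempotent(self, rng):
        d = rng.random((60, 60, 60)).astype(np.float32)
        box = Box(density=d, start_index=(0, 0, 0))
        once = normalize_box(box)
        twice = normalize_box(once)
        np.testing.assert_array_equal(once.density, twice.density)


class TestFilter:
    def _box_with_unassigned_fraction(self, frac):
        labels = np.zeros(BOX_SIZE**3, dtype=np.int64)
        n_unassigned = int(round(frac * BOX_SIZE**3))
        labels[:n_unassigned] = UNASSIGNED
        return Box(
            density=np.ones((BOX_SIZE,) * 3, dtype=np.float32),
            labels=labels.reshape((BOX_SIZE,) * 3),
            start_index=(0, 0, 0),
        )

    def test_exactly_95_percent_excluded(self):
        box = self._box_with_unassigned_fraction(0.95)
        assert box.unassigned_fraction == 0.95
        assert filter_boxes([box]) == []

    def test_fully_assigned_kept(self):
        box = self._box_with_unassigned_fraction(0.0)
        assert filter_boxes([box]) == [box]

    def test_constructed_fraction_ladder(self):
        fracs = [0.90 + 0.01 * i for i in range(10)]
        boxes = [self._box_with_unassigned_fraction(f) for f in fracs]
        survivors = filter_boxes(boxes)
        assert len(survivors) == 5
        assert all(b.unassigned_fraction < 0.95 for b in survivors)

    def test_unlabeled_box_rejected(self):
        box = Box(density=np.ones((60, 60, 60), dtype=np.float32),
                  start_index=(0, 0, 0))
        with pytest.raises(ValueError):
            filter_boxes([box])


class TestRotations:
    def test_24_distinct_proper_rotations(self):
        assert len(ROTATIONS_24) == 24
        probe = np.arange(27).reshape(3, 3, 3)
        images = {apply_rotation(probe, k).tobytes() for k in range(24)}
        assert len(images) == 24

    def test_rotation_preserves_multiset(self, rng):
        vol = rng.integers(0, 4, (6, 6, 6))
        for k in range(24):
            rotated = apply_rotation(vol, k)
            assert np.array_equal(
                np.sort(rotated.ravel()), np.sort(vol.ravel())
            )


class TestAugment:
    def _labeled_box(self, rng):
        return normalize_box(
            Box(
                density=rng.random((60, 60, 60)).astype(np.float32),
                labels=rng.integers(0, 4, (60, 60, 60)),
                start_index=(0, 0, 0),
            )
        )

    def test_deterministic_given_seed(self, rng):
        box = self._labeled_box(rng)
        a = augment(box, np.random.default_rng(42))
        b = augment(box, np.random.default_rng(42))
        np.testing.assert_array_equal(a.density, b.density)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_density_and_labels_co_transformed(self, rng):
        # mark one voxel in both arrays; they must stay aligned
        box = self._labeled_box(rng)
        box.density[33, 17, 48] = 7.0  # unique sentinel value
        box.labels[...] = 0
        box.labels[33, 17, 48] = 1
        for seed in range(40):
            chunk = augment(box, np.random.default_rng(seed))
            where_d = np.argwhere(chunk.density == 7.0)
            where_l = np.argwhere(chunk.labels == 1)
            np.testing.assert_array_equal(where_d, where_l)

    def test_rotations_and_crop_extremes_all_observed(self, rng):
        box = self._labeled_box(rng)
        g = np.random.default_rng(0)
        seen_rot = set()
        seen_offsets = set()
        for _ in range(3000):
            k = int(g.integers(0, 24))
            off = g.integers(0, BOX_SIZE - CHUNK_SIZE + 1, size=3)
            seen_rot.add(k)
            seen_offsets.update(off.tolist())
        assert seen_rot == set(range(24))
        assert {0, 20} <= seen_offsets

    def test_chunk_shape_and_range(self, rng):
        chunk = augment(self._labeled_box(rng), rng)
        assert chunk.density.shape == (40, 40, 40)
        assert chunk.density.min() >= 0.0 and chunk.density.max() <= 1.0


class TestCenterCrop:
    def test_index_bookkeeping(self):
        dims = (90, 90, 90)
        grid = np.arange(np.prod(dims), dtype=np.float32).reshape(dims)
        dmap = DensityMap(grid)
        for box in cut_boxes(dmap):
            chunk = center_crop(box)
            ox, oy, oz = chunk.origin_index
            np.testing.assert_array_equal(
                chunk.density,
                grid[ox : ox + 40, oy : oy + 40, oz : oz + 40],
            )

    def test_uniform_box_uniform_chunk(self):
        box = Box(density=np.full((60, 60, 60), 0.5, dtype=np.float32),
                  start_index=(30, 0, 30))
        chunk = center_crop(box)
        assert np.all(chunk.density == 0.5)
        assert chunk.origin_index == (40, 10, 40)
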