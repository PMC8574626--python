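"""Whole-map annotation by sliding-window prediction and stitching.

The map (already on a 1.0 A grid) is zero-padded by 15 voxels on every
face, tiled into 60^3 boxes at stride 30, and each box is normalized,
center-cropped to the 40^3 network input and classified.  Only the 30^3
cube at the center of each output chunk is kept; these cubes tile the
original map extent exactly once (the padding supplies the 15-voxel border
the crop geometry would otherwise leave uncovered, and overlapping flush
boxes near the far faces write only their not-yet-covered remainder).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chunking import BOX_SIZE, BOX_STRIDE, axis_starts, cut_boxes, normalize_box, center_crop
from .labeling import LabelMap
from .map_io import DensityMap
from .model import VoxelClassifier, forward_batch

CENTER_CUBE = 30
_PAD = (BOX_SIZE - CENTER_CUBE) // 2  # 15


@dataclass
class ProbabilityMap:
    """Per-voxel class probabilities (3, nx, ny, nz), channel order
    (Helix, Sheet, Others), aligned to a :class:`DensityMap`."""

    grid: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if self.grid.ndim != 4 or self.grid.shape[0] != 3:
            raise ValueError(f"probability grid must be (3, nx, ny, nz), got {self.grid.shape}")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.grid.shape[1:]  # type: ignore[return-value]


def _write_intervals(dim: int) -> list[tuple[int, int, int]]:
    """(box_start, write_lo, write_hi) per axis in original-map coordinates.

    Box at padded start s predicts original voxels [s, s + 30); successive
    boxes write only the remainder their predecessors did not cover, so the
    intervals partition [0, dim).
    """
    starts = axis_starts(dim + 2 * _PAD, BOX_SIZE, BOX_STRIDE)
    out = []
    covered = 0
    for s in starts:
        lo = max(s, covered)
        hi = min(s + CENTER_CUBE, dim)
        if lo < hi:
            out.append((s, lo, hi))
            covered = hi
        else:
            out.append((s, 0, 0))  # degenerate: nothing left for this box
    return out


def annotate_map(
    model: VoxelClassifier, dmap: DensityMap, batch: int = 4
) -> tuple[ProbabilityMap, LabelMap]:
    """Classify every voxel of a map; see module docstring for the tiling.

    Returns the 3-channel probability map and its argmax label map (ties
    break to the lowest channel index, i.e. Helix over Sheet over Others).
    """
    dims = dmap.dims
    if any(d < 1 for d in dims):
        raise ValueError(f"map has an empty axis: {dims}")
    padded = DensityMap(
        grid=np.pad(dmap.grid, _PAD, constant_values=0.0),
        origin=dmap.origin - _PAD * dmap.spacing,
        spacing=dmap.spacing,
    )
    boxes = cut_boxes(padded)
    intervals = [_write_intervals(d) for d in dims]
    lookup = {
        (ix[0], iy[0], iz[0]): (ix, iy, iz)
        for ix in intervals[0]
        for iy in intervals[1]
        for iz in intervals[2]
    }
    prob = np.zeros((3, *dims), dtype=np.float32)
    for start in range(0, len(boxes), batch):
        group = boxes[start : start + batch]
        chunks = [center_crop(normalize_box(b)) for b in group]
        out = forward_batch(model, np.stack([c.density for c in chunks]))
        for s, box in enumerate(group):
            ix, iy, iz = lookup[box.start_index]
            (sx, lx, hx), (sy, ly, hy), (sz, lz, hz) = ix, iy, iz
            if lx >= hx or ly >= hy or lz >= hz:
                continue
            # original coord o maps to chunk-local o - s + 5
            prob[
                :, lx:hx, ly:hy, lz:hz
            ] = out[
                s,
                :,
                lx - sx + 5 : hx - sx + 5,
                ly - sy + 5 : hy - sy + 5,
                lz - sz + 5 : hz - sz + 5,
            ]
    labels = np.argmax(prob, axis=0).astype(np.int64)
    pmap = ProbabilityMap(prob, dmap.origin.copy(), dmap.spacing.copy())
    lmap = LabelMap(labels, dmap.origin.copy(), dmap.spacing.copy())
    return pmap, lmap


def apply_threshold_mask(dmap: DensityMap, threshold: float) -> np.ndarray:
    """Boolean mask of voxels strictly above the density threshold.

    With threshold 0.0 exactly the positive-density voxels survive; voxels
    at the threshold are excluded (background is anything not clearly above
    it)."""
    return dmap.grid > threshold
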