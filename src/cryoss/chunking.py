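"""Cutting maps into overlapping boxes and network-sized chunks.

Maps are tiled into 60^3 boxes at stride 30 (with a final flush start so
the far faces are always covered); boxes are clipped at zero and scaled by
their own maximum into [0, 1]; training boxes that are >= 95% Unassigned
are dropped; augmentation applies one of the 24 proper cube rotations and
a random 40^3 crop, identically to density and labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .labeling import UNASSIGNED, LabelMap
from .map_io import DensityMap

BOX_SIZE = 60
BOX_STRIDE = 30
CHUNK_SIZE = 40
MAX_UNASSIGNED_FRAC = 0.95


@dataclass
class Box:
    """A 60^3 extraction window; ``start_index`` is its corner offset in the
    (possibly padded) map frame."""

    density: np.ndarray
    start_index: tuple[int, int, int]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.density.shape != (BOX_SIZE,) * 3:
            raise ValueError(f"box density must be {BOX_SIZE}^3, got {self.density.shape}")
        if self.labels is not None and self.labels.shape != (BOX_SIZE,) * 3:
            raise ValueError(f"box labels must be {BOX_SIZE}^3, got {self.labels.shape}")
        if any(s < 0 for s in self.start_index):
            raise ValueError(f"start_index must be >= 0, got {self.start_index}")

    @property
    def unassigned_fraction(self) -> float:
        if self.labels is None:
            raise ValueError("box carries no labels")
        return float(np.count_nonzero(self.labels == UNASSIGNED)) / self.labels.size


@dataclass
class Chunk:
    """A 40^3 network input; ``origin_index`` is the chunk corner in the map
    frame (nominal for rotated training chunks)."""

    density: np.ndarray
    origin_index: tuple[int, int, int]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.density.shape != (CHUNK_SIZE,) * 3:
            raise ValueError(
                f"chunk density must be {CHUNK_SIZE}^3, got {self.density.shape}"
            )


def axis_starts(dim: int, box: int = BOX_SIZE, stride: int = BOX_STRIDE) -> list[int]:
    """Start offsets along one axis: 0, stride, ... plus a flush final start
    ``dim - box`` when needed; [0] (with padding implied) if dim <= box."""
    if dim <= box:
        return [0]
    starts = list(range(0, dim - box + 1, stride))
    if starts[-1] != dim - box:
        starts.append(dim - box)
    return starts


def cut_boxes(
    dmap: DensityMap,
    labels: LabelMap | None = None,
    box: int = BOX_SIZE,
    stride: int = BOX_STRIDE,
) -> list[Box]:
    """Tile a map (and optional aligned label map) into overlapping boxes.

    Maps smaller than ``box`` along an axis are padded: density with zeros,
    labels with Unassigned (padding never contributes to the loss).
    """
    grid = dmap.grid
    lab = None
    if labels is not None:
        if labels.dims != dmap.dims:
            raise ValueError(
                f"label dims {labels.dims} do not match map dims {dmap.dims}"
            )
        lab = labels.grid
    pad = [(0, max(0, box - d)) for d in grid.shape]
    if any(p[1] for p in pad):
        grid = np.pad(grid, pad, constant_values=0.0)
        if lab is not None:
            lab = np.pad(lab, pad, constant_values=UNASSIGNED)

    starts = [axis_starts(d, box, stride) for d in grid.shape]
    boxes = []
    for sx in starts[0]:
        for sy in starts[1]:
            for sz in starts[2]:
                sl = (slice(sx, sx + box), slice(sy, sy + box), slice(sz, sz + box))
                boxes.append(
                    Box(
                        density=np.ascontiguousarray(grid[sl]),
                        labels=None if lab is None else np.ascontiguousarray(lab[sl]),
                        start_index=(sx, sy, sz),
                    )
                )
    return boxes


def normalize_box(box: Box) -> Box:
    """Clip density at zero, then scale by the box maximum into [0, 1].

    An all-nonpositive box becomes all zeros.  Labels are untouched.
    Idempotent.
    """
    d = np.maximum(box.density, 0.0)
    peak = float(d.max())
    if peak > 0:
        d = d / peak
    return Box(density=d, labels=box.labels, start_index=box.start_index)


def filter_boxes(
    boxes: list[Box], max_unassigned_frac: float = MAX_UNASSIGNED_FRAC
) -> list[Box]:
    """Drop boxes whose Unassigned fraction is >= the threshold (a box at
    exactly 95% is excluded).  Order of survivors is preserved."""
    for b in boxes:
        if b.labels is None:
            raise ValueError("filter_boxes requires boxes with labels")
    return [b for b in boxes if b.unassigned_fraction < max_unassigned_frac]


def _proper_rotations() -> list[tuple[tuple[int, int, int], tuple[bool, bool, bool]]]:
    """The 24 orientation-preserving cube rotations as (axis permutation,
    per-axis flip) pairs, in a fixed lexicographic order."""
    from itertools import permutations, product

    def perm_sign(p):
        sign = 1
        p = list(p)
        for i in range(3):
            for j in range(i + 1, 3):
                if p[i] > p[j]:
                    sign = -sign
        return sign

    rots = []
    for perm in permutations(range(3)):
        for flips in product((False, True), repeat=3):
            det = perm_sign(perm) * (-1) ** sum(flips)
            if det == 1:
                rots.append((perm, flips))
    assert len(rots) == 24
    return rots


ROTATIONS_24 = _proper_rotations()


def apply_rotation(volume: np.ndarray, rotation_index: int) -> np.ndarray:
    """Apply the k-th proper cube rotation to a cubic volume."""
    perm, flips = ROTATIONS_24[rotation_index]
    out = np.transpose(volume, perm)
    axes = tuple(a for a, f in enumerate(flips) if f)
    if axes:
        out = np.flip(out, axis=axes)
    return out


def augment(box: Box, rng: np.random.Generator) -> Chunk:
    """One training chunk: a random proper rotation of the box followed by a
    uniformly random 40^3 crop, applied identically to density and labels.
    Deterministic given the generator state."""
    if box.labels is None:
        raise ValueError("augment requires boxes with labels")
    k = int(rng.integers(0, 24))
    off = rng.integers(0, BOX_SIZE - CHUNK_SIZE + 1, size=3)
    sl = tuple(slice(int(o), int(o) + CHUNK_SIZE) for o in off)
    density = np.ascontiguousarray(apply_rotation(box.density, k)[sl])
    labels = np.ascontiguousarray(apply_rotation(box.labels, k)[sl])
    origin = tuple(int(s + o) for s, o in zip(box.start_index, off))
    return Chunk(density=density, labels=labels, origin_index=origin)


def center_crop(box: Box) -> Chunk:
    """The central 40^3 of a 60^3 box (corner offset (10, 10, 10))."""
    sl = (slice(10, 10 + CHUNK_SIZE),) * 3
    return Chunk(
        density=np.ascontiguousarray(box.density[sl]),
        labels=None if box.labels is None else np.ascontiguousarray(box.labels[sl]),
        origin_index=tuple(s + 10 for s in box.start_index),
    )
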