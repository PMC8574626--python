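"""Dataset-curation computations: map agreement and redundancy clustering.

Training sets of deposited maps are curated by (a) checking agreement
between a deposited map and the map simulated from its model via Pearson
cross-correlation (threshold 0.65 in practice), and (b) removing sequence
redundancy by greedy clustering of a precomputed boolean similarity matrix
(two entries are similar when any chain pair exceeds the identity cutoff;
computing the identities themselves is left to external alignment tools).
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass

import numpy as np

from .map_io import DensityMap

CC_THRESHOLD = 0.65


@dataclass
class SimilarityMatrix:
    """Symmetric boolean similarity with a true diagonal."""

    matrix: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=bool)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match {n} ids"
            )
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("similarity matrix must be symmetric")
        np.fill_diagonal(self.matrix, True)

    @classmethod
    def from_edges(
        cls, ids: list[str], edges: list[tuple[str, str]]
    ) -> "SimilarityMatrix":
        index = {x: i for i, x in enumerate(ids)}
        m = np.zeros((len(ids), len(ids)), dtype=bool)
        for a, b in edges:
            m[index[a], index[b]] = m[index[b], index[a]] = True
        return cls(m, list(ids))


def read_similarity_csv(path: str | os.PathLike) -> SimilarityMatrix:
    """Edge-list CSV: header ``id_a,id_b`` then one similar pair per row.
    Ids appearing only in one column still become items."""
    ids: list[str] = []
    seen: set[str] = set()
    edges: list[tuple[str, str]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise ValueError(f"empty similarity file {path!r}")
        for row in reader:
            if len(row) < 2:
                raise ValueError(f"{path!r}: malformed row {row!r}")
            a, b = row[0].strip(), row[1].strip()
            for x in (a, b):
                if x not in seen:
                    seen.add(x)
                    ids.append(x)
            if a != b:
                edges.append((a, b))
    return SimilarityMatrix.from_edges(ids, edges)


def cross_correlation(map_a: DensityMap, map_b: DensityMap) -> float:
    """Pearson correlation between two maps over all voxels.

    Requires identical geometry (resample first if needed); raises on
    zero-variance input, where the correlation is undefined.
    """
    if not map_a.same_geometry(map_b):
        raise ValueError("maps must share dims, origin and spacing; resample first")
    a = map_a.grid.astype(np.float64).ravel()
    b = map_b.grid.astype(np.float64).ravel()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("cross-correlation undefined for a constant map")
    return float(np.corrcoef(a, b)[0, 1])


def greedy_cluster(sim: SimilarityMatrix) -> list[tuple[str, list[str]]]:
    """Iterative largest-first clustering of a similarity matrix.

    Repeatedly pick the remaining item similar to the most remaining items
    (ties to the lowest identifier), form a cluster of it and everything
    still similar to it, and remove them.  The clusters partition the items
    and their sizes are non-increasing.
    """
    m = sim.matrix
    remaining = np.ones(len(sim.ids), dtype=bool)
    order = np.argsort(np.array(sim.ids, dtype=object))  # tie-break ranking
    rank = np.empty(len(sim.ids), dtype=int)
    rank[order] = np.arange(len(sim.ids))
    clusters = []
    while remaining.any():
        counts = (m & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        best = counts.max()
        candidates = np.flatnonzero(counts == best)
        rep = candidates[np.argmin(rank[candidates])]
        members = np.flatnonzero(m[rep] & remaining)
        clusters.append(
            (sim.ids[rep], sorted(sim.ids[i] for i in members))
        )
        remaining[members] = False
    return clusters
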