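"""Voxel-level F1 and residue-level Q3 scoring.

Voxel metrics compare predicted labels with ground truth built from the
closest C-alpha atom within 3.0 A; truth-Unassigned voxels and voxels
outside the density-threshold mask are excluded from every count.  The
overall voxel F1 reported as headline is the macro (unweighted) mean of
the three class F1 scores; the micro aggregate (plain voxel accuracy) is
reported alongside.

Residue Q3 judges each residue by the voxels within 3.0 A of its C-alpha:
the residue is correct when a strict majority of those voxels carry its
true class in the prediction.  A residue is dropped from the denominator
when any voxel center within 1.0 A of its C-alpha has density below the
threshold (or when it has no C-alpha at all).
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field

import numpy as np

from .labeling import CLASS_NAMES, HELIX, OTHERS, SHEET, UNASSIGNED, LabelMap
from .map_io import DensityMap
from .structures import SSLabel, Structure

_CLASSES = (HELIX, SHEET, OTHERS)


@dataclass
class ClassScores:
    precision: float
    recall: float
    f1: float
    support: int
    undefined: bool = False  # a denominator was empty; the score is 0 by fiat


@dataclass
class EvalReport:
    voxel: dict[str, ClassScores] = field(default_factory=dict)
    overall_voxel_f1: float = 0.0  # macro mean of class F1
    voxel_accuracy: float = 0.0  # micro aggregate
    evaluated_voxels: int = 0
    residue_q3: dict[str, float] = field(default_factory=dict)
    overall_residue_q3: float = 0.0
    evaluated_residues: int = 0
    excluded_residues: int = 0
    threshold: float = 0.0

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "voxel": {
                name: vars(scores) for name, scores in self.voxel.items()
            },
            "overall_voxel_f1": self.overall_voxel_f1,
            "voxel_accuracy": self.voxel_accuracy,
            "evaluated_voxels": self.evaluated_voxels,
            "residue_q3": self.residue_q3,
            "overall_residue_q3": self.overall_residue_q3,
            "evaluated_residues": self.evaluated_residues,
            "excluded_residues": self.excluded_residues,
        }

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_csv_row(self, path: str | os.PathLike) -> None:
        d = self.to_dict()
        flat: dict[str, object] = {
            "threshold": d["threshold"],
            "overall_voxel_f1": d["overall_voxel_f1"],
            "voxel_accuracy": d["voxel_accuracy"],
            "evaluated_voxels": d["evaluated_voxels"],
            "overall_residue_q3": d["overall_residue_q3"],
            "evaluated_residues": d["evaluated_residues"],
            "excluded_residues": d["excluded_residues"],
        }
        for name, sc in self.voxel.items():
            for k in ("precision", "recall", "f1"):
                flat[f"voxel_{k}_{name}"] = getattr(sc, k)
        for name, q in self.residue_q3.items():
            flat[f"residue_q3_{name}"] = q
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(flat))
            writer.writeheader()
            writer.writerow(flat)


def confusion_matrix(
    pred: np.ndarray, truth: np.ndarray, n_classes: int = 3
) -> np.ndarray:
    """counts[t, p] over already-masked flat label arrays."""
    return np.bincount(
        truth * n_classes + pred, minlength=n_classes * n_classes
    ).reshape(n_classes, n_classes)


def voxel_metrics(
    pred: LabelMap,
    truth: LabelMap,
    mask: np.ndarray | None = None,
) -> EvalReport:
    """Per-class precision/recall/F1 plus macro and micro aggregates.

    ``mask`` (optional boolean grid, e.g. from a density threshold) and
    truth-Unassigned voxels are excluded from all counts.  Empty
    denominators yield 0 with the ``undefined`` flag set.
    """
    if pred.dims != truth.dims:
        raise ValueError(f"geometry mismatch: pred {pred.dims} vs truth {truth.dims}")
    keep = truth.grid != UNASSIGNED
    if mask is not None:
        if mask.shape != truth.grid.shape:
            raise ValueError("mask shape does not match label grids")
        keep &= mask
    t = truth.grid[keep].astype(np.int64)
    p = pred.grid[keep].astype(np.int64)
    cm = confusion_matrix(p, t)
    report = EvalReport(evaluated_voxels=int(keep.sum()))
    f1s = []
    for c in _CLASSES:
        tp = int(cm[c, c])
        fp = int(cm[:, c].sum()) - tp
        fn = int(cm[c, :].sum()) - tp
        undef = False
        if tp + fp == 0:
            precision, undef = 0.0, True
        else:
            precision = tp / (tp + fp)
        if tp + fn == 0:
            recall, undef = 0.0, True
        else:
            recall = tp / (tp + fn)
        if precision + recall == 0:
            f1, undef = 0.0, True
        else:
            f1 = 2 * precision * recall / (precision + recall)
        report.voxel[CLASS_NAMES[c]] = ClassScores(
            precision, recall, f1, support=tp + fn, undefined=undef
        )
        f1s.append(f1)
    report.overall_voxel_f1 = float(np.mean(f1s))
    report.voxel_accuracy = float(np.trace(cm) / cm.sum()) if cm.sum() else 0.0
    return report


def _voxels_within(dmap_like, center: np.ndarray, radius: float) -> np.ndarray:
    """Flat indices of voxel centers within ``radius`` (inclusive) of a point."""
    origin, spacing = dmap_like.origin, dmap_like.spacing
    dims = dmap_like.dims
    lo = np.floor((center - radius - origin) / spacing).astype(int)
    hi = np.ceil((center + radius - origin) / spacing).astype(int)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.array(dims) - 1)
    if np.any(lo > hi):
        return np.empty((0, 3), dtype=int)
    ranges = [np.arange(lo[a], hi[a] + 1) for a in range(3)]
    idx = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    world = origin + idx * spacing
    d2 = np.sum((world - center) ** 2, axis=1)
    return idx[d2 <= radius * radius]


def residue_q3(
    pred: LabelMap,
    structure: Structure,
    density: DensityMap,
    threshold: float = 0.0,
    vote_radius: float = 3.0,
    exclusion_radius: float = 1.0,
    return_counts: bool = False,
) -> tuple:
    """Residue-level Q3 under the majority rule.

    Returns ``(per_class_q3, overall_q3, evaluated, excluded)``.  Residues
    are excluded when they lack a C-alpha or when any voxel center within
    ``exclusion_radius`` of the C-alpha has density below ``threshold``.
    Correctness requires a strict majority of the voxel centers within
    ``vote_radius`` of the C-alpha to carry the residue's true class; a
    residue with no voxels in range (or a tie) counts as incorrect.

    With ``return_counts`` the raw per-class (correct, total) tallies and
    the excluded count are returned instead, for pooling across maps.
    """
    if pred.dims != density.dims:
        raise ValueError("prediction and density grids do not align")
    evaluated = excluded = 0
    correct_c = {c: 0 for c in _CLASSES}
    total_c = {c: 0 for c in _CLASSES}
    for res in structure.residues():
        if res.ss_label == SSLabel.UNLABELED:
            raise ValueError("structure residues must carry secondary-structure labels")
        ca = res.ca
        if ca is None:
            excluded += 1
            continue
        near = _voxels_within(density, ca.coord, exclusion_radius)
        if len(near) and np.any(
            density.grid[near[:, 0], near[:, 1], near[:, 2]] < threshold
        ):
            excluded += 1
            continue
        votes_idx = _voxels_within(pred, ca.coord, vote_radius)
        truth_class = int(res.ss_label)
        evaluated += 1
        total_c[truth_class] += 1
        if len(votes_idx):
            votes = pred.grid[votes_idx[:, 0], votes_idx[:, 1], votes_idx[:, 2]]
            if np.count_nonzero(votes == truth_class) * 2 > len(votes):
                correct_c[truth_class] += 1
    if return_counts:
        return correct_c, total_c, excluded
    per_class = {
        CLASS_NAMES[c]: (correct_c[c] / total_c[c]) if total_c[c] else 0.0
        for c in _CLASSES
    }
    overall = sum(correct_c.values()) / evaluated if evaluated else 0.0
    return per_class, overall, evaluated, excluded


def evaluate_map(
    pred: LabelMap,
    truth: LabelMap,
    structure: Structure,
    density: DensityMap,
    threshold: float = 0.0,
) -> EvalReport:
    """Full voxel + residue evaluation under one density threshold."""
    mask = density.grid > threshold
    report = voxel_metrics(pred, truth, mask)
    per_class, overall, evaluated, excl = residue_q3(
        pred, structure, density, threshold
    )
    report.residue_q3 = per_class
    report.overall_residue_q3 = overall
    report.evaluated_residues = evaluated
    report.excluded_residues = excl
    report.threshold = threshold
    return report
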