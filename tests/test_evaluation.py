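"""Voxel F1 and residue Q3 against brute-force tallies."""

import numpy as np
import pytest

from cryoss.evaluation import evaluate_map, residue_q3, voxel_metrics
from cryoss.labeling import HELIX, OTHERS, SHEET, UNASSIGNED, LabelMap
from cryoss.map_io import DensityMap
from cryoss.structures import Atom, Residue, SSLabel, Structure


def _lm(grid):
    return LabelMap(np.asarray(grid, dtype=np.int64))


def brute_force_metrics(pred, truth, mask=None):
    """Independent confusion-matrix tally with explicit python loops."""
    tp = {c: 0 for c in range(3)}
    fp = {c: 0 for c in range(3)}
    fn = {c: 0 for c in range(3)}
    n_eval = correct = 0
    it = np.nditer(truth, flags=["multi_index"])
    for t in it:
        idx = it.multi_index
        t = int(t)
        if t == UNASSIGNED or (mask is not None and not mask[idx]):
            continue
        p = int(pred[idx])
        n_eval += 1
        if p == t:
            tp[t] += 1
            correct += 1
        else:
            fp[p] += 1
            fn[t] += 1
    out = {}
    for c in range(3):
        precision = tp[c] / (tp[c] + fp[c]) if tp[c] + fp[c] else 0.0
        recall = tp[c] / (tp[c] + fn[c]) if tp[c] + fn[c] else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall
            else 0.0
        )
        out[c] = (precision, recall, f1)
    return out, n_eval, (correct / n_eval if n_eval else 0.0)


class TestVoxelMetrics:
    def test_perfect_prediction(self, rng):
        truth = _lm(rng.integers(0, 4, (10, 10, 10)))
        report = voxel_metrics(truth, truth)
        for scores in report.voxel.values():
            if scores.support:
                assert scores.f1 == 1.0
        assert report.voxel_accuracy == 1.0

    def test_hand_confusion_matrix(self):
        # truth: 10 Helix + 10 Sheet; pred: 8 Helix right, 2 Helix->Sheet,
        # all Sheet right
        truth = np.array([HELIX] * 10 + [SHEET] * 10).reshape(1, 4, 5)
        pred = np.array([HELIX] * 8 + [SHEET] * 2 + [SHEET] * 10).reshape(1, 4, 5)
        report = voxel_metrics(_lm(pred), _lm(truth))
        assert abs(report.voxel["Helix"].f1 - 2 * 0.8 / 1.8) < 1e-12
        sheet_p = 10 / 12
        assert abs(
            report.voxel["Sheet"].f1 - 2 * sheet_p / (sheet_p + 1.0)
        ) < 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        truth = rng.integers(0, 4, (8, 8, 8))
        pred = rng.integers(0, 3, (8, 8, 8))
        mask = rng.random((8, 8, 8)) > 0.3
        report = voxel_metrics(_lm(pred), _lm(truth), mask)
        oracle, n_eval, accuracy = brute_force_metrics(pred, truth, mask)
        assert report.evaluated_voxels == n_eval
        assert abs(report.voxel_accuracy - accuracy) < 1e-12
        for c, name in ((0, "Helix"), (1, "Sheet"), (2, "Others")):
            assert abs(report.voxel[name].precision - oracle[c][0]) < 1e-12
            assert abs(report.voxel[name].recall - oracle[c][1]) < 1e-12
            assert abs(report.voxel[name].f1 - oracle[c][2]) < 1e-12

    def test_macro_mean_and_flags(self):
        truth = np.full((2, 2, 2), HELIX)
        pred = np.full((2, 2, 2), HELIX)
        report = voxel_metrics(_lm(pred), _lm(truth))
        # Sheet and Others never occur: flagged, scored 0, macro mean 1/3
        assert report.voxel["Sheet"].undefined
        assert abs(report.overall_voxel_f1 - 1.0 / 3.0) < 1e-12

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError):
            voxel_metrics(_lm(np.zeros((2, 2, 2))), _lm(np.zeros((3, 3, 3))))


def _structure_with_ca(positions_labels):
    st = Structure()
    for i, (pos, label) in enumerate(positions_labels, 1):
        st.add_residue(
            Residue("A", i, "ALA",
                    [Atom("CA", "C", np.asarray(pos, float), "A", i)], label)
        )
    return st


def _uniform_density(dims, value=1.0):
    return DensityMap(np.full(dims, value, dtype=np.float32))


class TestResidueQ3:
    def test_strict_majority_required(self):
        # CA at a voxel center: 7 voxel centers lie within 1 A... use 3.0 A
        # neighbourhood and craft predictions around one residue
        st = _structure_with_ca([((5.0, 5.0, 5.0), SSLabel.HELIX)])
        density = _uniform_density((11, 11, 11))
        pred_grid = np.full((11, 11, 11), SHEET, dtype=np.int64)
        # count voxels within 3 A of (5,5,5), set slightly more than half Helix
        idx = np.argwhere(np.ones((11, 11, 11), dtype=bool))
        d2 = np.sum((idx - 5) ** 2, axis=1)
        in_range = idx[d2 <= 9.0]
        n = len(in_range)
        majority = in_range[: n // 2 + 1]
        pred_grid[tuple(majority.T)] = HELIX
        _, overall, evaluated, _ = residue_q3(_lm(pred_grid), st, density, 0.0)
        assert evaluated == 1 and overall == 1.0
        # exactly half is a tie -> incorrect
        pred_grid[tuple(in_range.T)] = SHEET
        pred_grid[tuple(in_range[: n // 2].T)] = HELIX
        _, overall, _, _ = residue_q3(_lm(pred_grid), st, density, 0.0)
        assert overall == 0.0

    def test_sub_threshold_voxel_excludes_residue(self):
        st = _structure_with_ca([((5.0, 5.0, 5.0), SSLabel.HELIX),
                                 ((2.0, 2.0, 2.0), SSLabel.HELIX)])
        grid = np.full((11, 11, 11), 2.0, dtype=np.float32)
        grid[5, 5, 6] = 0.5  # 1.0 A from the first CA, below threshold 1.0
        density = DensityMap(grid)
        pred = _lm(np.full((11, 11, 11), HELIX))
        _, overall, evaluated, excluded = residue_q3(pred, st, density, 1.0)
        assert excluded == 1
        assert evaluated == 1
        assert overall == 1.0

    def test_residue_without_ca_excluded(self):
        st = _structure_with_ca([((3.0, 3.0, 3.0), SSLabel.SHEET)])
        st.add_residue(
            Residue("A", 99, "ALA",
                    [Atom("CB", "C", np.array([1.0, 1.0, 1.0]), "A", 99)],
                    SSLabel.OTHERS)
        )
        pred = _lm(np.full((7, 7, 7), SHEET))
        _, overall, evaluated, excluded = residue_q3(
            pred, st, _uniform_density((7, 7, 7)), 0.0
        )
        assert (evaluated, excluded) == (1, 1)

    def test_perfect_prediction_gives_unit_q3(self, toy_domain, toy_map):
        from cryoss.labeling import label_voxels

        truth = label_voxels(toy_map, toy_domain, atom_set="ca_only")
        per_class, overall, evaluated, _ = residue_q3(
            truth, toy_domain, toy_map, 0.0
        )
        assert evaluated > 0
        assert overall == 1.0
        for name, q3 in per_class.items():
            assert q3 in (1.0, 0.0)  # 0 only for a class with no residues

    def test_majority_matches_brute_force(self, rng):
        st = _structure_with_ca(
            [
                (rng.uniform(2, 8, 3), SSLabel(int(rng.integers(0, 3))))
                for _ in range(12)
            ]
        )
        pred_grid = rng.integers(0, 3, (11, 11, 11))
        density = _uniform_density((11, 11, 11))
        _, overall, evaluated, _ = residue_q3(_lm(pred_grid), st, density, 0.0)
        correct = 0
        for res in st.residues():
            votes = []
            for i in range(11):
                for j in range(11):
                    for k in range(11):
                        if np.sum((np.array([i, j, k]) - res.ca.coord) ** 2) <= 9.0:
                            votes.append(int(pred_grid[i, j, k]))
            wins = sum(v == int(res.ss_label) for v in votes)
            if wins * 2 > len(votes):
                correct += 1
        assert evaluated == 12
        assert abs(overall - correct / 12) < 1e-12

    def test_threshold_monotonically_shrinks_evaluation(self, toy_domain, toy_map):
        from cryoss.labeling import label_voxels

        truth = label_voxels(toy_map, toy_domain, atom_set="ca_only")
        counts = []
        for thr in (0.0, 0.05, 0.2, 1.0):
            report = evaluate_map(truth, truth, toy_domain, toy_map, thr)
            counts.append((report.evaluated_residues, report.evaluated_voxels))
        for (r_prev, v_prev), (r_next, v_next) in zip(counts, counts[1:]):
            assert r_next <= r_prev
            assert v_next <= v_prev
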