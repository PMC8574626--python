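"""Atomic model parsing, SS assignment, and synthetic structure generators."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from cryoss.structures import (
    EmptyStructureError,
    SSLabel,
    assign_secondary_structure,
    backbone_dihedrals,
    build_ideal_helix,
    build_ideal_sheet,
    build_toy_domain,
    ingest_ss_codes,
    parse_pdb,
    read_ss_codes,
    write_pdb,
)

PDB_SMALL = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.697   7.155  -4.974  1.00  0.00           C
ATOM      4  O   ALA A   1      13.560   7.331  -5.842  1.00  0.00           O
ATOM      5  N   GLY A   2      12.641   7.890  -3.864  1.00  0.00           N
ATOM      6  CA  GLY A   2      13.607   8.954  -3.611  1.00  0.00           C
ATOM      7  C   GLY A   2      13.122  10.305  -4.134  1.00  0.00           C
ATOM      8  O   GLY A   2      11.937  10.472  -4.443  1.00  0.00           O
ATOM      9  N   SER A   3      14.042  11.263  -4.227  1.00  0.00           N
ATOM     10  CA  SER A   3      13.709  12.602  -4.708  1.00  0.00           C
ATOM     11  C   SER A   3      14.529  13.681  -4.005  1.00  0.00           C
ATOM     12  O   SER A   3      15.462  13.372  -3.262  1.00  0.00           O
TER
HETATM   13  O   HOH A 101       0.000   0.000   0.000  1.00  0.00           O
END
"""

PDB_ALTLOC = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA AALA A   1       1.458   0.000   0.000  0.60  0.00           C
ATOM      3  CA BALA A   1       9.999   9.999   9.999  0.40  0.00           C
ATOM      4  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
END
"""

PDB_MULTIMODEL = """\
MODEL        1
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  N   ALA A   1       5.000   5.000   5.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       6.458   5.000   5.000  1.00  0.00           C
ATOM      3  C   ALA A   1       7.000   6.400   5.000  1.00  0.00           C
ENDMDL
END
"""


class TestParsePdb:
    def test_counts(self, tmp_path):
        p = tmp_path / "s.pdb"
        p.write_text(PDB_SMALL)
        st = parse_pdb(p)
        assert list(st.chains) == ["A"]
        assert len(st.residues()) == 3
        assert len(st.atoms()) == 12  # HETATM water ignored

    def test_altloc_highest_occupancy_wins(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(PDB_ALTLOC)
        st = parse_pdb(p)
        ca = st.residues()[0].ca
        np.testing.assert_allclose(ca.coord, [1.458, 0.0, 0.0], atol=1e-3)

    def test_first_model_only(self, tmp_path):
        p = tmp_path / "nmr.pdb"
        p.write_text(PDB_MULTIMODEL)
        st = parse_pdb(p)
        assert len(st.atoms()) == 2
        np.testing.assert_allclose(st.atoms()[0].coord, [0, 0, 0], atol=1e-3)

    def test_no_atoms_is_error(self, tmp_path):
        p = tmp_path / "none.pdb"
        p.write_text("REMARK nothing here\nEND\n")
        with pytest.raises(EmptyStructureError):
            parse_pdb(p)

    def test_write_parse_round_trip(self, tmp_path, toy_domain):
        p = tmp_path / "toy.pdb"
        write_pdb(toy_domain, p)
        back = parse_pdb(p)
        assert len(back.atoms()) == len(toy_domain.atoms())
        np.testing.assert_allclose(
            back.coords(), toy_domain.coords(), atol=1e-3
        )


class TestIngestCodes:
    @pytest.mark.parametrize(
        "code,expected",
        [
            ("H", SSLabel.HELIX),
            ("G", SSLabel.HELIX),
            ("I", SSLabel.HELIX),
            ("E", SSLabel.SHEET),
            ("B", SSLabel.SHEET),
            ("b", SSLabel.SHEET),
            ("T", SSLabel.OTHERS),
            ("C", SSLabel.OTHERS),
            ("S", SSLabel.OTHERS),
        ],
    )
    def test_code_mapping(self, code, expected):
        st = build_ideal_helix(1)
        ingest_ss_codes(st, {("A", 1): code})
        assert st.residues()[0].ss_label == expected

    def test_missing_residues_become_others(self):
        st = build_ideal_helix(3)
        ingest_ss_codes(st, {("A", 1): "H"})
        labels = [r.ss_label for r in st.residues()]
        assert labels == [SSLabel.HELIX, SSLabel.OTHERS, SSLabel.OTHERS]

    def test_idempotent(self):
        st = build_ideal_helix(4)
        codes = {("A", i): "E" for i in range(1, 5)}
        ingest_ss_codes(st, codes)
        first = [r.ss_label for r in st.residues()]
        ingest_ss_codes(st, codes)
        assert [r.ss_label for r in st.residues()] == first

    def test_code_file_round_trip(self, tmp_path):
        p = tmp_path / "codes.tsv"
        p.write_text("A:1\tH\nA:2\tb\n# comment\nB:10\tT\n")
        codes = read_ss_codes(p)
        assert codes == {("A", 1): "H", ("A", 2): "b", ("B", 10): "T"}


class TestDihedralAssigner:
    def test_ideal_helix_interior_is_helix(self):
        st = assign_secondary_structure(build_ideal_helix(12))
        labels = [r.ss_label for r in st.residues()]
        assert labels.count(SSLabel.HELIX) >= 12 - 4
        # termini have undefined phi or psi
        assert labels[0] == SSLabel.OTHERS
        assert labels[-1] == SSLabel.OTHERS

    def test_ideal_strand_interior_is_sheet(self):
        st = assign_secondary_structure(build_ideal_sheet(1, 6))
        labels = [r.ss_label for r in st.residues()]
        assert labels[1:-1] == [SSLabel.SHEET] * 4

    def test_two_residue_chain_all_others(self):
        st = assign_secondary_structure(build_ideal_helix(2))
        assert all(r.ss_label == SSLabel.OTHERS for r in st.residues())

    def test_idempotent(self, toy_domain):
        assign_secondary_structure(toy_domain)
        first = [r.ss_label for r in toy_domain.residues()]
        assign_secondary_structure(toy_domain)
        assert [r.ss_label for r in toy_domain.residues()] == first

    def test_helix_dihedrals_match_construction(self):
        chain = list(build_ideal_helix(6).chains["A"])
        for phi, psi in backbone_dihedrals(chain)[1:-1]:
            assert abs(phi - (-57.0)) < 1e-6
            assert abs(psi - (-47.0)) < 1e-6


class TestIdealHelix:
    def test_nominal_length_ten_residues(self):
        # ~1.5 A rise per residue, so a 10-residue helix spans ~15 A.
        # Rise is measured on a longer helix where the fitted axis is
        # unbiased by the partial final turn.
        z18 = build_ideal_helix(18, axis=(0, 0, 1)).coords(("CA",))[:, 2]
        rise = (z18.max() - z18.min()) / 17
        assert 1.4 < rise < 1.65
        z10 = build_ideal_helix(10, axis=(0, 0, 1)).coords(("CA",))[:, 2]
        assert abs((z10.max() - z10.min()) - 15.0) < 1.5

    def test_consecutive_ca_distances(self):
        ca = build_ideal_helix(18).coords(("CA",))
        d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        assert np.all(np.abs(d - 3.8) < 0.1)

    def test_single_residue_is_valid(self):
        st = build_ideal_helix(1)
        assert len(st.residues()) == 1
        assert st.residues()[0].ss_label == SSLabel.HELIX

    def test_invalid_length_raises(self):
        with pytest.raises(ValueError):
            build_ideal_helix(0)

    def test_axis_honoured(self):
        st = build_ideal_helix(12, origin=(1, 2, 3), axis=(1, 0, 0))
        ca = st.coords(("CA",))
        direction = ca[-1] - ca[0]
        direction /= np.linalg.norm(direction)
        assert direction[0] > 0.99
        np.testing.assert_allclose(ca[0], [1, 2, 3], atol=1e-8)


class TestIdealSheet:
    def test_two_strands_geometry(self):
        st = build_ideal_sheet(2, 6)
        assert len(st.chains) == 2
        assert len(st.residues()) == 12
        ca = st.coords(("CA",))
        inter = np.linalg.norm(ca[:6, None] - ca[None, 6:], axis=2)
        assert 4.3 < inter.min() < 5.5

    def test_single_strand(self):
        st = build_ideal_sheet(1, 5)
        assert len(st.chains) == 1
        ca = st.coords(("CA",))
        rise = np.linalg.norm(ca[-1] - ca[0]) / 4
        assert 3.0 < rise < 3.6

    def test_all_residues_labeled_sheet(self):
        st = build_ideal_sheet(3, 4)
        assert all(r.ss_label == SSLabel.SHEET for r in st.residues())

    def test_invalid_sizes_raise(self):
        with pytest.raises(ValueError):
            build_ideal_sheet(0, 5)
        with pytest.raises(ValueError):
            build_ideal_sheet(2, 1)


class TestToyDomain:
    def test_deterministic_in_seed(self):
        a = build_toy_domain(3, 4)
        b = build_toy_domain(3, 4)
        np.testing.assert_array_equal(a.coords(), b.coords())

    def test_all_classes_present(self):
        st = build_toy_domain(1, 4)
        labels = {r.ss_label for r in st.residues()}
        assert {SSLabel.HELIX, SSLabel.SHEET, SSLabel.OTHERS} <= labels

    @pytest.mark.parametrize("seed", range(1, 11))
    def test_min_inter_element_separation(self, seed):
        st = build_toy_domain(seed, 4)
        by_element = {}
        for atom in st.atoms():
            by_element.setdefault(atom.chain_id[0], []).append(atom.coord)
        keys = sorted(by_element)
        for i, ka in enumerate(keys):
            tree = cKDTree(np.array(by_element[ka]))
            for kb in keys[i + 1 :]:
                dist, _ = tree.query(np.array(by_element[kb]), k=1)
                assert dist.min() >= 3.0
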