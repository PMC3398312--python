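"""Backbone parsing, dihedral geometry, segment harvesting, superposition."""

import gemmi
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

import crossprofiler as cp
from crossprofiler.structure_io import CHAIN_BREAK_CA_CA, dihedral_angle


def wrap_diff(a, b):
    return np.abs((np.asarray(a) - np.asarray(b) + 180.0) % 360.0 - 180.0)


class TestDihedralAngle:
    def test_quarter_turn_example(self):
        pts = [np.array(p, float) for p in [(0, 0, 0), (0, 0, 1), (1, 0, 1), (1, 1, 1)]]
        assert dihedral_angle(*pts) == pytest.approx(90.0, abs=1e-9)

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.floats(-5, 5), min_size=12, max_size=12),
           st.integers(0, 2**31 - 1))
    def test_matches_gemmi_oracle(self, flat, seed):
        """Sign and magnitude agree with an independent crystallographic
        implementation on random non-degenerate quadruples."""
        pts = np.array(flat).reshape(4, 3)
        # reject near-degenerate configurations
        if min(np.linalg.norm(np.diff(pts, axis=0), axis=1)) < 1e-2:
            return
        if min(np.linalg.norm(np.cross(pts[1] - pts[0], pts[2] - pts[1])),
               np.linalg.norm(np.cross(pts[2] - pts[1], pts[3] - pts[2]))) < 1e-2:
            return
        mine = dihedral_angle(*pts)
        ref = np.degrees(gemmi.calculate_dihedral(*[gemmi.Position(*p) for p in pts]))
        assert wrap_diff(mine, ref) < 1e-6

    def test_planar_trans_is_180(self):
        # zig-zag in a plane: N-CA-C-N all coplanar, trans
        pts = [np.array(p, float) for p in
               [(0, 0, 0), (1, 1, 0), (2, 0, 0), (3, 1, 0)]]
        assert abs(dihedral_angle(*pts)) == pytest.approx(180.0, abs=1e-6)


class TestComputeDihedrals:
    def test_termini_undefined(self, helix_chain):
        phi, psi, phi_def, psi_def = cp.compute_dihedrals(helix_chain)
        assert not phi_def[0] and not psi_def[-1]
        assert phi_def[1:].all() and psi_def[:-1].all()

    def test_roundtrip_through_builder(self):
        rng = np.random.default_rng(7)
        n = 10
        phi = rng.uniform(-179.9, 180.0, n)
        psi = rng.uniform(-179.9, 180.0, n)
        chain = cp.backbone_from_dihedrals(phi, psi, "A" * n)
        p2, s2, _, _ = cp.compute_dihedrals(chain)
        assert wrap_diff(p2[1:], phi[1:]).max() < 1e-6
        assert wrap_diff(s2[:-1], psi[:-1]).max() < 1e-6

    def test_incomplete_residue_breaks_neighbours(self, helix_chain):
        helix_chain.residues[5].ca = None
        phi, psi, phi_def, psi_def = cp.compute_dihedrals(helix_chain)
        assert not phi_def[5] and not psi_def[5]
        assert not phi_def[6] and not psi_def[4]

    def test_chain_break_undefines_spanning_angles(self, helix_chain):
        shift = np.array([CHAIN_BREAK_CA_CA + 10, 0.0, 0.0])
        for r in helix_chain.residues[6:]:
            r.n = r.n + shift
            r.ca = r.ca + shift
            r.c = r.c + shift
        _, _, phi_def, psi_def = cp.compute_dihedrals(helix_chain)
        assert not phi_def[6] and not psi_def[5]
        assert phi_def[5] and psi_def[6]


class TestReadBackbone:
    def test_pdb_roundtrip_to_writer_precision(self, helix_chain):
        text = cp.chain_to_pdb(helix_chain)
        back = cp.read_backbone(text, "A", structure_id="synt")
        assert len(back) == len(helix_chain)
        assert all(r.complete for r in back.residues)
        assert back.sequence == helix_chain.sequence
        for a, b in zip(back.residues, helix_chain.residues):
            assert np.abs(a.ca - b.ca).max() < 1e-3 + 1e-9  # PDB precision

    def test_missing_atom_flags_incomplete(self, helix_chain):
        lines = [ln for ln in cp.chain_to_pdb(helix_chain).splitlines()
                 if not (" CA " in ln and ln[22:26].strip() == "2")]
        back = cp.read_backbone("\n".join(lines), "A")
        assert len(back) == len(helix_chain)
        assert not back.residues[1].complete
        assert back.residues[0].complete and back.residues[2].complete

    def test_missing_chain_raises(self, helix_chain):
        with pytest.raises(KeyError, match="chain not found"):
            cp.read_backbone(cp.chain_to_pdb(helix_chain), "Q")

    def test_empty_structure_raises(self):
        with pytest.raises(ValueError, match="empty structure"):
            cp.read_backbone("END\n", "A")

    def test_hetatm_skipped(self, helix_chain):
        text = cp.chain_to_pdb(helix_chain).replace("END", "")
        text += ("HETATM 9999  O   HOH A 999      0.000   0.000   0.000"
                 "  1.00  0.00           O\nEND\n")
        back = cp.read_backbone(text, "A")
        assert len(back) == len(helix_chain)

    def test_altloc_highest_occupancy_wins(self):
        pdb = "\n".join([
            "ATOM      1  N  AALA A   1       0.000   0.000   0.000  0.40  0.00           N",
            "ATOM      2  N  BALA A   1       9.000   0.000   0.000  0.60  0.00           N",
            "ATOM      3  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C",
            "ATOM      4  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C",
            "END",
        ])
        back = cp.read_backbone(pdb, "A")
        assert back.residues[0].n[0] == pytest.approx(9.0)


class TestResidueRange:
    def test_render_matches_field_notation(self):
        assert cp.ResidueRange("1jnr", "A", 614, 629).render() == "1jnrA:614-629"

    @pytest.mark.parametrize("text", ["1jnrA:614-629", "1kthA:16-31", "2abXB:1-9"])
    def test_roundtrip(self, text):
        assert cp.ResidueRange.parse(text).render() == text

    def test_reversed_interval_rejected(self):
        with pytest.raises(ValueError):
            cp.ResidueRange("1jnr", "A", 10, 9)


class TestExtractSegments:
    def test_window_count_on_flanked_chain(self):
        """22 complete residues; eligible interior leaves 12 L=9 windows."""
        n = 22
        rng = np.random.default_rng(3)
        chain = cp.backbone_from_dihedrals(
            rng.uniform(-179, 180, n), rng.uniform(-179, 180, n), "A" * n)
        segs = cp.extract_segments(chain, 9)
        assert len(segs) == 12
        assert [s.start for s in segs] == list(range(2, 14))

    def test_no_segment_spans_break(self):
        n = 24
        rng = np.random.default_rng(4)
        chain = cp.backbone_from_dihedrals(
            rng.uniform(-179, 180, n), rng.uniform(-179, 180, n), "A" * n)
        shift = np.array([50.0, 0.0, 0.0])
        for r in chain.residues[10:]:   # break between residues 10 and 11
            r.n = r.n + shift
            r.ca = r.ca + shift
            r.c = r.c + shift
        segs = cp.extract_segments(chain, 9)
        for s in segs:
            assert not (s.start <= 10 <= s.start + 8)

    def test_short_chain_empty(self, helix_chain):
        assert cp.extract_segments(helix_chain, 15) == []

    def test_count_monotone_under_damage(self):
        n = 30
        rng = np.random.default_rng(5)
        chain = cp.backbone_from_dihedrals(
            rng.uniform(-179, 180, n), rng.uniform(-179, 180, n), "A" * n)
        counts = []
        for kill in (None, 20, 10):
            if kill is not None:
                chain.residues[kill].c = None
            counts.append(len(cp.extract_segments(chain, 9)))
        assert counts[0] >= counts[1] >= counts[2]


class TestKabschRmsd:
    def test_identity_and_symmetry(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(16, 3))
        b = rng.normal(size=(16, 3))
        assert cp.kabsch_rmsd(a, a) == pytest.approx(0.0, abs=1e-9)
        assert cp.kabsch_rmsd(a, b) == pytest.approx(cp.kabsch_rmsd(b, a), abs=1e-9)

    def test_rigid_invariance(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(16, 3))
        rot = Rotation.random(random_state=2).as_matrix()
        moved = a @ rot.T + np.array([3.0, -7.0, 11.0])
        assert cp.kabsch_rmsd(a, moved) == pytest.approx(0.0, abs=1e-9)
        b = rng.normal(size=(16, 3))
        assert cp.kabsch_rmsd(a, b) == pytest.approx(
            cp.kabsch_rmsd(a @ rot.T + 5.0, b), abs=1e-9)

    def test_known_displacement(self):
        # two points pairs offset along z after optimal superposition:
        # construct an exactly solvable case via a pure translation + noise-free
        a = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
        b = a.copy()
        b[:, 2] += np.array([1.0, -1.0, 1.0, -1.0])  # centered distortion
        # optimal rotation cannot remove the alternating z displacement fully;
        # brute-force the optimum over many random rotations as a lower-bound check
        rmsd = cp.kabsch_rmsd(a, b)
        rng = np.random.default_rng(3)
        ac = a - a.mean(0)
        bc = b - b.mean(0)
        best = min(
            np.sqrt(np.mean(np.sum((ac - bc @ Rotation.random(random_state=int(s)).as_matrix().T) ** 2, axis=1)))
            for s in rng.integers(0, 1 << 31, size=400)
        )
        assert rmsd <= best + 1e-12

    def test_collinear_points_handled(self):
        a = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float)
        b = np.array([[0, 0, 0], [0, 1, 0], [0, 2, 0]], float)
        assert cp.kabsch_rmsd(a, b) == pytest.approx(0.0, abs=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length mismatch"):
            cp.kabsch_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))


class TestSegmentsTsv:
    def test_header_and_row_count(self, planted_population):
        segs, _ = planted_population
        text = cp.structure_io.segments_to_tsv(segs[:5])
        lines = text.strip().splitlines()
        assert len(lines) == 6
        assert lines[0].startswith("source\tchain\tstart\tend\tsequence\tphi_1")
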