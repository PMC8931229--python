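import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from loopforge.fixtures import FixtureSpec, make_fixture
from loopforge.structure import (BackboneStructure, SegmentSpec, StructureError,
                                 backbone_rmsd, coords_from_torsions,
                                 downstream_anchor_atoms, read_pdb,
                                 segment_rigid_transform, set_segment_torsions,
                                 torsions_from_coords, write_pdb)
from conftest import random_chain


class TestSegmentSpec:
    def test_parse(self):
        seg = SegmentSpec.parse("A:34-45")
        assert (seg.chain_id, seg.start, seg.end, seg.length) == ("A", 34, 45, 12)

    def test_invalid_ranges(self):
        with pytest.raises(ValueError):
            SegmentSpec("A", 10, 9)
        with pytest.raises(ValueError):
            SegmentSpec("A", 5, 6)  # length 2 < 3


class TestPdbIO:
    def test_round_trip(self, tmp_path, helix_fixture):
        st, _ = helix_fixture
        path = tmp_path / "fixture.pdb"
        write_pdb(st, path)
        back = read_pdb(path)
        assert len(back) == len(st)
        assert back.sequence == st.sequence
        assert np.allclose(back.coords, st.coords, atol=1e-3)

    def test_atom_counts(self, tmp_path):
        st = random_chain(0, n=10)
        path = tmp_path / "ten.pdb"
        write_pdb(st, path)
        back = read_pdb(path)
        assert len(back) == 10
        assert back.coords.shape == (10, 4, 3)

    def test_missing_ca_is_structured_error(self, tmp_path):
        st = random_chain(0, n=4)
        path = tmp_path / "broken.pdb"
        write_pdb(st, path)
        lines = [l for l in path.read_text().splitlines()
                 if not (" CA " in l and " A   2 " in l)]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(StructureError, match="2"):
            read_pdb(path)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("")
        with pytest.raises(StructureError):
            read_pdb(path)

    def test_terminal_missing_o_rebuilt(self, tmp_path):
        st = random_chain(1, n=5)
        path = tmp_path / "noto.pdb"
        write_pdb(st, path)
        lines = [l for l in path.read_text().splitlines()
                 if not (" O  " in l and " A   5 " in l)]
        path.write_text("\n".join(lines) + "\n")
        back = read_pdb(path)
        assert len(back) == 5
        assert np.all(np.isfinite(back.coords))


class TestTorsions:
    def test_ideal_helix_angles(self):
        n = 10
        tors = np.stack([np.full(n, -57.0), np.full(n, -47.0),
                         np.full(n, 180.0)], axis=1)
        anchor = np.array([[0.0, 0, 0], [1.329, 0, 0], [1.9, 1.3, 0.2]])
        st = BackboneStructure(coords_from_torsions(anchor, tors),
                               np.arange(1, n + 1), np.array(["A"] * n), "A" * n)
        got = torsions_from_coords(st)
        assert np.allclose(got[1:, 0], -57.0, atol=1.0)
        assert np.allclose(got[:-1, 1], -47.0, atol=1.0)

    def test_round_trip_random_chains(self):
        # forward build -> extraction recovers torsions to ~1e-6 degrees
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(25):
            n = 8
            tors = np.stack([rng.uniform(-179, 179, n), rng.uniform(-179, 179, n),
                             rng.uniform(160, 200, n)], axis=1)
            tors[:, 2] = np.where(tors[:, 2] > 180, tors[:, 2] - 360, tors[:, 2])
            anchor = np.array([[0.0, 0, 0], [1.329, 0, 0], [1.9, 1.3, 0.2]])
            st = BackboneStructure(coords_from_torsions(anchor, tors),
                                   np.arange(1, n + 1), np.array(["A"] * n), "A" * n)
            got = torsions_from_coords(st)
            dev = np.abs(((got[1:-1] - tors[1:-1]) + 180) % 360 - 180)
            worst = max(worst, float(np.max(dev)))
        assert worst < 1e-6

    def test_terminus_flagged_not_invented(self):
        st = random_chain(3, n=6)
        tors = torsions_from_coords(st)
        assert np.isnan(tors[0, 0])      # phi of first residue
        assert np.isnan(tors[-1, 1])     # psi of last residue
        assert np.all(np.isfinite(tors[1:-1]))

    def test_extended_chain_ca_distance(self):
        tors = np.full((6, 3), 180.0)
        anchor = np.array([[0.0, 0, 0], [1.329, 0, 0], [1.9, 1.3, 0.2]])
        coords = coords_from_torsions(anchor, tors)
        d = np.linalg.norm(np.diff(coords[:, 1], axis=0), axis=1)
        assert np.allclose(d, 3.80, atol=0.05)

    def test_zero_length_torsions(self):
        anchor = np.array([[0.0, 0, 0], [1.329, 0, 0], [1.9, 1.3, 0.2]])
        out = coords_from_torsions(anchor, np.zeros((0, 3)))
        assert out.shape == (0, 4, 3)

    def test_nonfinite_torsion_raises(self):
        anchor = np.array([[0.0, 0, 0], [1.329, 0, 0], [1.9, 1.3, 0.2]])
        with pytest.raises(ValueError):
            coords_from_torsions(anchor, [[np.nan, 0.0, 180.0]])

    def test_rebuild_native_segment_from_own_torsions(self, helix_fixture):
        st, seg = helix_fixture
        tors = torsions_from_coords(st, seg)
        rebuilt = set_segment_torsions(st, seg, tors)
        dev = np.max(np.linalg.norm(
            rebuilt.coords[st.segment_indices(seg)]
            - st.coords[st.segment_indices(seg)], axis=-1))
        assert dev < 0.1  # idealized-geometry deviation only


class TestBackboneRmsd:
    def test_identity(self, helix_fixture):
        st, seg = helix_fixture
        assert backbone_rmsd(st, st, seg) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_displacement(self, helix_fixture):
        st, seg = helix_fixture
        moved = st.copy()
        idx = st.segment_indices(seg)
        moved.coords[idx] += np.array([2.0, 0.0, 0.0])
        assert backbone_rmsd(moved, st, seg) == pytest.approx(2.0, abs=1e-9)

    def test_independent_formula(self):
        # direct per-atom formula on a 5-residue segment, no alignment
        st = random_chain(5, n=9)
        ref = random_chain(6, n=9)
        seg = SegmentSpec("A", 3, 7)
        got = backbone_rmsd(st, ref, seg, align_rest=False)
        idx = st.segment_indices(seg)
        diffs = (st.coords[idx] - ref.coords[idx]).reshape(-1, 3)
        expected = np.sqrt(np.mean(np.sum(diffs ** 2, axis=1)))
        assert got == pytest.approx(expected, abs=1e-6)

    def test_symmetry_without_alignment(self):
        a = random_chain(7, n=9)
        b = random_chain(8, n=9)
        seg = SegmentSpec("A", 3, 7)
        assert backbone_rmsd(a, b, seg, align_rest=False) == pytest.approx(
            backbone_rmsd(b, a, seg, align_rest=False), abs=1e-12)

    def test_numbering_mismatch(self, helix_fixture):
        st, seg = helix_fixture
        other = st.copy()
        other.resnums = other.resnums + 100
        with pytest.raises(StructureError):
            backbone_rmsd(st, other, seg)


class TestSegmentRigidTransform:
    def test_same_residue_identity(self, helix_fixture):
        st, _ = helix_fixture
        tr = segment_rigid_transform(st, 3, 3, chain_id="A")
        assert np.allclose(tr.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(tr.translation, 0.0, atol=1e-9)

    def test_global_motion_invariance(self, helix_fixture):
        st, _ = helix_fixture
        tr0 = segment_rigid_transform(st, 2, 9, chain_id="A")
        moved = st.copy()
        R = Rotation.from_euler("xyz", [20, -35, 100], degrees=True).as_matrix()
        moved.coords = st.coords @ R.T + np.array([5.0, -3.0, 1.0])
        tr1 = segment_rigid_transform(moved, 2, 9, chain_id="A")
        assert np.allclose(tr0.rotation, tr1.rotation, atol=1e-9)
        assert np.allclose(tr0.translation, tr1.translation, atol=1e-9)

    def test_forward_application_reproduces_frame(self, helix_fixture):
        from loopforge.geometry import residue_frame
        st, _ = helix_fixture
        ia, ib = st.index_of("A", 2), st.index_of("A", 9)
        tr = segment_rigid_transform(st, 2, 9, chain_id="A")
        fa = residue_frame(*st.coords[ia, :3])
        fb = residue_frame(*st.coords[ib, :3])
        assert np.allclose(fa.compose(tr).rotation, fb.rotation, atol=1e-9)
        assert np.allclose(fa.compose(tr).translation, fb.translation, atol=1e-9)


def test_downstream_anchor_reconstruction(helix_fixture):
    # breaking the junction and reconstructing must reproduce native CA/C
    st, seg = helix_fixture
    broken = set_segment_torsions(st, seg, np.full((seg.length, 3), 180.0))
    ie = st.index_of("A", seg.end)
    ca3, c3 = downstream_anchor_atoms(broken, "A", seg.end)
    assert np.linalg.norm(ca3 - st.coords[ie, 1]) < 0.05
    assert np.linalg.norm(c3 - st.coords[ie, 2]) < 0.05
    # non-segment coordinates are untouched by the rebuild
    outside = np.setdiff1d(np.arange(len(st)), st.segment_indices(seg))
    assert np.array_equal(broken.coords[outside], st.coords[outside])
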