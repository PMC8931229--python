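import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from loopforge.fixtures import FixtureSpec, make_fixture
from loopforge.scoring import (EnergyWeights, R0_CA_CA, R0_OTHER, Restraint,
                               RestraintSet, ScoreBreakdown,
                               classify_satisfaction, clash_score, rama_score,
                               read_restraints, restraint_energy,
                               restraint_satisfaction, score_structure,
                               write_restraints)
from loopforge.structure import BackboneStructure, SegmentSpec, coords_from_torsions
from conftest import random_chain


def build_chain_struct(tors):
    n = len(tors)
    anchor = np.array([[0.0, 0, 0], [1.329, 0, 0], [1.9, 1.3, 0.2]])
    return BackboneStructure(coords_from_torsions(anchor, np.asarray(tors, float)),
                             np.arange(1, n + 1), np.array(["A"] * n), "A" * n)


class TestRamaScore:
    def test_helix_scores_below_extended(self):
        n = 10
        helix = build_chain_struct([[-57.0, -47.0, 180.0]] * n)
        extended = build_chain_struct([[180.0, 180.0, 180.0]] * n)
        assert rama_score(helix) < rama_score(extended)

    def test_empty_region_zero(self, helix_fixture):
        st, _ = helix_fixture
        # region at the N-terminus: phi undefined for residue 1; a 3-residue
        # window starting there still scores its defined residues only
        assert rama_score(st) > 0

    def test_rigid_motion_invariance(self, helix_fixture):
        st, _ = helix_fixture
        moved = st.copy()
        R = Rotation.from_euler("xyz", [11, 22, 33], degrees=True).as_matrix()
        moved.coords = st.coords @ R.T + np.array([4.0, 5.0, 6.0])
        assert rama_score(moved) == pytest.approx(rama_score(st), abs=1e-9)


class TestClashScore:
    def test_extended_chain_clash_free(self):
        st = build_chain_struct([[180.0, 180.0, 180.0]] * 12)
        assert clash_score(st) == 0.0

    def test_coincident_atoms_closed_form(self):
        # two far-separated residues forced onto each other: each of the 4
        # same-name atom pairs is exactly coincident and contributes
        # ((r0 - 0)/r0)^2 = 1; the remaining cross pairs add positively
        st = build_chain_struct([[180.0, 180.0, 180.0]] * 12)
        st.coords[10] = st.coords[2]
        score = clash_score(st)
        assert score >= 4.0
        coords = st.coords.reshape(-1, 3)
        expected = 0.0
        for i in range(len(coords)):
            for j in range(i + 1, len(coords)):
                if abs(i // 4 - j // 4) < 2:
                    continue
                r0 = R0_CA_CA if (i % 4 == 1 and j % 4 == 1) else R0_OTHER
                d = np.linalg.norm(coords[i] - coords[j])
                if d < r0:
                    expected += ((r0 - d) / r0) ** 2
        assert score == pytest.approx(expected, abs=1e-9)

    def test_matches_bruteforce_pairs(self, helix_fixture):
        st, _ = helix_fixture
        squeezed = st.copy()
        squeezed.coords = squeezed.coords * 0.8  # induce clashes
        got = clash_score(squeezed)
        coords = squeezed.coords.reshape(-1, 3)
        expected = 0.0
        for i in range(len(coords)):
            for j in range(i + 1, len(coords)):
                if abs(i // 4 - j // 4) < 2:
                    continue
                r0 = R0_CA_CA if (i % 4 == 1 and j % 4 == 1) else R0_OTHER
                d = np.linalg.norm(coords[i] - coords[j])
                if d < r0:
                    expected += ((r0 - d) / r0) ** 2
        assert got == pytest.approx(expected, abs=1e-9)


class TestRestraints:
    def make_restraints(self, st, offsets=(0.0, 0.0, 0.0), k=1.0):
        rs = []
        for resnum, atom in ((10, "CA"), (11, "N"), (12, "O")):
            i = st.index_of("A", resnum)
            ideal = st.atom(i, atom) + np.asarray(offsets)
            rs.append(Restraint("A", resnum, atom, ideal, k))
        return RestraintSet(rs)

    def test_perfect_placement_zero(self, helix_fixture):
        st, _ = helix_fixture
        rset = self.make_restraints(st)
        assert restraint_energy(st, rset) == pytest.approx(0.0)
        assert restraint_satisfaction(st, rset) == pytest.approx(0.0)

    def test_displacement_closed_form(self, helix_fixture):
        st, _ = helix_fixture
        rset = self.make_restraints(st, offsets=(2.0, 0.0, 0.0), k=1.0)
        assert restraint_energy(st, rset) == pytest.approx(3 * 4.0)
        assert restraint_satisfaction(st, rset) == pytest.approx(2.0)

    def test_satisfaction_is_max_norm(self, helix_fixture):
        st, _ = helix_fixture
        i10 = st.index_of("A", 10)
        rs = RestraintSet([
            Restraint("A", 10, "CA", st.atom(i10, "CA") + [0.3, 0, 0]),
            Restraint("A", 11, "CA", st.atom(st.index_of("A", 11), "CA") + [0.7, 0, 0]),
            Restraint("A", 12, "CA", st.atom(st.index_of("A", 12), "CA") + [1.5, 0, 0]),
        ])
        assert restraint_satisfaction(st, rs) == pytest.approx(1.5)
        # adding a restraint can never decrease the max
        rs2 = RestraintSet(rs.restraints + [
            Restraint("A", 13, "CA", st.atom(st.index_of("A", 13), "CA"))])
        assert restraint_satisfaction(st, rs2) >= restraint_satisfaction(st, rs)

    def test_two_threshold_classification(self):
        assert classify_satisfaction(0.5) == "satisfied"
        assert classify_satisfaction(2.5) == "unsatisfied"
        assert classify_satisfaction(1.5) == "ambiguous"

    def test_unresolvable_selector(self, helix_fixture):
        st, _ = helix_fixture
        rs = RestraintSet([Restraint("B", 999, "CA", np.zeros(3))])
        with pytest.raises(Exception, match="999"):
            restraint_energy(st, rs)

    def test_positive_spring_required(self):
        with pytest.raises(ValueError):
            Restraint("A", 1, "CA", np.zeros(3), k=0.0)

    def test_tsv_round_trip(self, tmp_path, helix_fixture):
        st, _ = helix_fixture
        rset = self.make_restraints(st, offsets=(1.0, -2.0, 0.5), k=2.5)
        path = tmp_path / "restraints.tsv"
        write_restraints(rset, path)
        back = read_restraints(path)
        assert len(back) == len(rset)
        for a, b in zip(rset, back):
            assert (a.chain_id, a.resnum, a.atom, a.k) == (b.chain_id, b.resnum, b.atom, b.k)
            assert np.allclose(a.ideal, b.ideal, atol=1e-5)


def test_score_breakdown_exact_weighted_sum(helix_fixture):
    st, _ = helix_fixture
    w = EnergyWeights(w_rama=1.5, w_clash=7.0, w_restraint=2.0)
    sc = score_structure(st, w)
    assert sc.total == pytest.approx(
        1.5 * sc.rama + 7.0 * sc.clash + 2.0 * sc.restraint, abs=1e-9)
    assert sc.rama >= 0 and sc.clash >= 0 and sc.restraint >= 0


def test_negative_weights_rejected():
    with pytest.raises(ValueError):
        EnergyWeights(w_rama=-1.0)
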