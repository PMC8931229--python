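import numpy as np
import pytest

from loopforge.kic import (ClosureProblem, ClosureSolution, PivotSelection,
                           apply_solution, ccd_close, rama_filter,
                           select_pivots, solve_closure)
from loopforge.structure import (SegmentSpec, set_segment_torsions,
                                 torsions_from_coords)
from conftest import random_chain

SEG = SegmentSpec("A", 4, 9)


def closure_problem(seed, mid=None):
    st = random_chain(seed)
    rng = np.random.default_rng(seed + 1000)
    mid = mid if mid is not None else int(rng.integers(5, 9))
    return st, ClosureProblem.from_structure(st, SEG, PivotSelection((4, mid, 9)))


def native_pivot_torsions(st, mid):
    t = torsions_from_coords(st, SEG)
    rows = (0, mid - 4, 5)
    return np.array([[t[r, 0], t[r, 1]] for r in rows])


class TestPivotSelection:
    def test_three_increasing_required(self):
        with pytest.raises(ValueError):
            PivotSelection((4, 4, 9))
        with pytest.raises(ValueError):
            PivotSelection((4, 9))

    def test_length_three_segment_forced(self, rng):
        seg = SegmentSpec("A", 5, 7)
        p = select_pivots(seg, rng)
        assert p.pivot_resnums == (5, 6, 7)

    def test_deterministic_given_seed(self):
        seg = SegmentSpec("A", 1, 12)
        a = select_pivots(seg, np.random.default_rng(5))
        b = select_pivots(seg, np.random.default_rng(5))
        assert a == b

    def test_interior_uniformity(self):
        # middle pivot over a length-12 segment: 10 interior residues,
        # frequencies within 3 sigma of Binomial(n, 1/10)
        seg = SegmentSpec("A", 1, 12)
        rng = np.random.default_rng(0)
        n = 10000
        counts = np.zeros(13)
        for _ in range(n):
            counts[select_pivots(seg, rng).pivot_resnums[1]] += 1
        p = 1 / 10
        sigma = np.sqrt(n * p * (1 - p))
        assert np.all(counts[2:12] > n * p - 3 * sigma)
        assert np.all(counts[2:12] < n * p + 3 * sigma)
        assert counts[1] == 0 and counts[12] == 0  # ends are never middle


class TestSolveClosure:
    def test_native_among_solutions(self):
        # a problem built from an intact chain must recover the native
        # pivot torsions among its solutions
        for seed in range(5):
            st, prob = closure_problem(seed)
            nat = native_pivot_torsions(st, prob.middle_index + 4)
            sol = solve_closure(prob)
            assert len(sol) >= 1
            devs = [np.max(np.abs(((t - nat) + 180) % 360 - 180))
                    for t in sol.pivot_torsions]
            assert min(devs) < 1e-3

    def test_all_residuals_below_tolerance(self):
        st, prob = closure_problem(3)
        sol = solve_closure(prob)
        assert all(r < 1e-4 for r in sol.closure_residuals)

    def test_unreachable_anchors_empty(self):
        st, prob = closure_problem(0)
        far = prob.seed_post + np.array([50.0, 0.0, 0.0])
        moved = ClosureProblem(prob.seed_pre, far, prob.torsions,
                               prob.middle_index, prob.geometry)
        assert len(solve_closure(moved)) == 0

    def test_solution_count_bounded(self):
        counts = [len(solve_closure(closure_problem(s)[1])) for s in range(20)]
        assert max(counts) <= 16

    def test_deterministic_solution_ordering(self):
        st, prob = closure_problem(7)
        a = solve_closure(prob)
        b = solve_closure(prob)
        assert len(a) == len(b)
        for ta, tb in zip(a.pivot_torsions, b.pivot_torsions):
            assert np.array_equal(ta, tb)

    def test_nonpivot_torsions_untouched(self):
        # applying any solution changes only pivot phi/psi
        st, prob = closure_problem(2, mid=6)
        pivots = PivotSelection((4, 6, 9))
        sol = solve_closure(prob)
        before = torsions_from_coords(st, SEG)
        for k in range(len(sol)):
            new = apply_solution(st, SEG, pivots, sol, k)
            after = torsions_from_coords(new, SEG)
            nonpivot_rows = [1, 3, 4]
            dev = np.abs(((after[nonpivot_rows, :2] - before[nonpivot_rows, :2])
                          + 180) % 360 - 180)
            assert np.max(dev) < 1e-6

    def test_nonfinite_input_rejected(self):
        st, prob = closure_problem(0, mid=6)
        bad = prob.torsions.copy()
        bad[1, 0] = np.nan  # nonpivot phi (middle pivot is span index 2)
        with pytest.raises(ValueError):
            ClosureProblem(prob.seed_pre, prob.seed_post, bad,
                           prob.middle_index)

    def test_grid_oracle_small(self):
        # completeness vs the 2-degree brute-force oracle on 3 problems
        # (the acceptance suite runs 50)
        from oracle_kic import brute_force_solutions, match_solution_sets
        for seed in (0, 1, 2):
            st, prob = closure_problem(seed)
            analytic = [t.ravel() for t in solve_closure(prob).pivot_torsions]
            brute = brute_force_solutions(prob)
            ua, ub = match_solution_sets(prob, analytic, brute)
            assert ua == [] and ub == []


class TestRamaFilter:
    def _fake_solutions(self, torsion_sets):
        return ClosureSolution([np.array(t, float) for t in torsion_sets],
                               [0.0] * len(torsion_sets), None)

    def test_zero_threshold_retains_all(self):
        sols = self._fake_solutions([
            [[-63, -43], [-120, 130], [-65, 145]],
            [[150, -150], [0, 0], [90, 90]],
        ])
        kept = rama_filter(sols, "AAA", threshold=0.0)
        assert len(kept) == 2

    def test_disallowed_pivot_removed(self):
        sols = self._fake_solutions([
            [[-63, -43], [150, -150], [-65, 145]],
        ])
        assert len(rama_filter(sols, "AAA", threshold=1e-12)) == 0

    def test_allowed_solution_survives(self):
        sols = self._fake_solutions([
            [[-63, -43], [-120, 130], [-65, 145]],
        ])
        assert len(rama_filter(sols, "AAA", threshold=1e-4)) == 1

    def test_empty_input_empty_output(self):
        assert len(rama_filter(self._fake_solutions([]), "AAA")) == 0

    def test_unknown_amino_acid(self):
        with pytest.raises(ValueError):
            rama_filter(self._fake_solutions([]), "AZ1")


class TestCCD:
    def test_already_closed_unchanged(self, helix_fixture):
        st, seg = helix_fixture
        res = ccd_close(st, seg, tol=0.1)
        assert res.iterations == 0
        assert res.break_distance < 0.1
        assert np.allclose(res.structure.coords, st.coords)

    def test_break_distance_non_increasing(self, helix_fixture):
        st, seg = helix_fixture
        broken = set_segment_torsions(st, seg, np.full((seg.length, 3), 180.0))
        res = ccd_close(broken, seg, max_iters=60, tol=0.05)
        assert all(b - a > -1e-9 for a, b in zip(res.history[1:], res.history))
        assert res.break_distance < res.history[0]

    def test_ccd_modifies_many_torsions_kic_only_pivots(self, helix_fixture):
        # the key mechanistic difference between the two closure methods
        st, seg = helix_fixture
        tors0 = torsions_from_coords(st, seg)
        broken = set_segment_torsions(st, seg, np.full((seg.length, 3), 180.0))
        res = ccd_close(broken, seg, max_iters=100, tol=0.05)
        t_ccd = torsions_from_coords(res.structure, seg)
        changed_ccd = np.sum(np.abs(((t_ccd[:, :2] - 180.0) + 180) % 360 - 180)
                             > 1.0)
        assert changed_ccd > 3
        # KIC closure of the same break with native nonpivot torsions
        # proposed: only the three pivot rows change
        pivots = PivotSelection((seg.start, seg.start + 2, seg.end))
        proposal = tors0.copy()
        proposal[~np.isfinite(proposal)] = 180.0
        prob = ClosureProblem.from_structure(broken, seg, pivots,
                                             torsions=proposal)
        sol = solve_closure(prob)
        assert len(sol) > 0
        new = apply_solution(broken, seg, pivots, sol, 0)
        t_kic = torsions_from_coords(new, seg)
        changed = np.abs(((t_kic[:, :2] - proposal[:, :2]) + 180) % 360
                         - 180) > 1e-3
        changed_rows = set(np.nonzero(np.any(changed, axis=1))[0])
        assert changed_rows <= {0, 2, seg.length - 1}
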