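"""Analytic inverse-kinematic loop closure (KIC) and the CCD baseline.

Given fixed anchor atoms flanking a segment, fixed covalent geometry and
fixed nonpivot torsions, the solver finds *all* combinations of the six
pivot phi/psi torsions that exactly reconnect the chain.

Geometric reduction
-------------------
With nonpivot torsions frozen, the three pivot CA atoms form a triangle
with fixed side lengths: the first and last pivot CA are pinned by the
anchors, and the middle pivot CA moves on a circle about the line joining
them.  For each circle position the two flanking subproblems (reach the
middle CA using the first pivot's phi/psi, respectively the last pivot's
psi/phi) reduce to linear trigonometric equations with at most two
branches each, solvable in closed form.  One scalar constraint remains —
the N-CA-C bond angle at the middle pivot — and its roots along the
circle parameter are bracketed on a dense scan and polished to machine
precision.  The middle pivot's phi/psi are then read off the assembled
coordinates.  Every returned solution is re-verified by forward-building
the chain and measuring the downstream reconnection residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .geometry import (IDEAL_GEOMETRY, InternalGeometry, bond_angle,
                       build_chain, dihedral, place_atom, wrap_angle)
from .rama import RamachandranTables, default_tables
from .structure import (BackboneStructure, SegmentSpec, StructureError,
                        coords_from_torsions, downstream_anchor_atoms,
                        set_segment_torsions, torsions_from_coords)

CLOSURE_TOL = 1e-4  # A; every accepted solution must reconnect below this


class ClosureNonConvergence(RuntimeError):
    """Numerical failure while polishing a closure root (distinct from
    the geometrically meaningful 'no solutions' outcome)."""


@dataclass(frozen=True)
class PivotSelection:
    """Exactly three pivot residue numbers, strictly increasing."""

    pivot_resnums: tuple

    def __post_init__(self):
        p = tuple(int(x) for x in self.pivot_resnums)
        object.__setattr__(self, "pivot_resnums", p)
        if len(p) != 3 or not (p[0] < p[1] < p[2]):
            raise ValueError("pivots must be 3 strictly increasing residue numbers")


def select_pivots(segment: SegmentSpec, rng: np.random.Generator,
                  strategy: str = "ends-random-middle") -> PivotSelection:
    """Pick the three pivot residues of a segment.

    The first and last segment residues are always pivots (the fixed
    anchors must bound the closure problem); the middle pivot is drawn
    uniformly among interior residues.
    """
    if segment.length < 3:
        raise ValueError("segment too short for pivot selection")
    if strategy not in ("ends-random-middle", "all-random"):
        raise ValueError(f"unknown pivot strategy {strategy!r}")
    middle = int(rng.integers(segment.start + 1, segment.end))
    return PivotSelection((segment.start, middle, segment.end))


@dataclass
class ClosureProblem:
    """Fixed-anchor inverse-kinematics instance over a pivot span.

    ``torsions`` holds phi/psi/omega (degrees) for the span residues in
    order; phi/psi entries at the three pivots are ignored by the solver
    (may be NaN).  ``seed_pre`` is (C(p1-1), N(p1), CA(p1)) and
    ``seed_post`` is (N(p3+1), C(p3), CA(p3)), all fixed in space.
    """

    seed_pre: np.ndarray
    seed_post: np.ndarray
    torsions: np.ndarray
    middle_index: int  # index of the middle pivot within the span
    geometry: InternalGeometry = IDEAL_GEOMETRY
    pivot_aa: str = "AAA"

    def __post_init__(self):
        self.seed_pre = np.asarray(self.seed_pre, float)
        self.seed_post = np.asarray(self.seed_post, float)
        self.torsions = np.asarray(self.torsions, float)
        if self.seed_pre.shape != (3, 3) or self.seed_post.shape != (3, 3):
            raise ValueError("seeds must be (3, 3) atom arrays")
        if not (np.all(np.isfinite(self.seed_pre)) and np.all(np.isfinite(self.seed_post))):
            raise ValueError("non-finite anchor coordinates")
        L = len(self.torsions)
        if not (0 < self.middle_index < L - 1):
            raise ValueError("middle pivot must be interior to the span")
        nonpivot = np.ones((L, 3), bool)
        for p in (0, self.middle_index, L - 1):
            nonpivot[p, :2] = False
        nonpivot[L - 1, 2] = False  # omega of the last pivot is not used
        if not np.all(np.isfinite(self.torsions[nonpivot])):
            raise ValueError("nonpivot torsions must be fully specified and finite")

    @property
    def span_length(self) -> int:
        return len(self.torsions)

    @staticmethod
    def from_structure(structure: BackboneStructure, segment: SegmentSpec,
                       pivots: PivotSelection, torsions=None,
                       geometry: InternalGeometry = IDEAL_GEOMETRY) -> "ClosureProblem":
        """Build a closure problem from a structure's current coordinates.

        ``torsions`` (span-length x 3, degrees) overrides the current
        span torsions — this is how fragment insertions are proposed
        without touching the coordinates until a closed solution exists.
        """
        p1, p2, p3 = pivots.pivot_resnums
        if not (segment.start <= p1 < p2 < p3 <= segment.end):
            raise ValueError("pivots outside segment")
        i1 = structure.index_of(segment.chain_id, p1)
        i3 = structure.index_of(segment.chain_id, p3)
        if i1 == 0 or structure.chains[i1 - 1] != segment.chain_id:
            raise StructureError("no upstream anchor residue for closure")
        if i3 == len(structure) - 1 or structure.chains[i3 + 1] != segment.chain_id:
            raise StructureError("no downstream anchor residue for closure")
        span = SegmentSpec(segment.chain_id, p1, p3)
        if torsions is None:
            torsions = torsions_from_coords(structure, span)
        torsions = np.array(torsions, float)
        torsions[-1, 2] = 180.0 if not np.isfinite(torsions[-1, 2]) else torsions[-1, 2]
        seed_pre = np.stack([structure.atom(i1 - 1, "C"), structure.atom(i1, "N"),
                             structure.atom(i1, "CA")])
        ca3, c3 = downstream_anchor_atoms(structure, segment.chain_id, p3,
                                          geometry)
        seed_post = np.stack([structure.atom(i3 + 1, "N"), c3, ca3])
        aa = (structure.sequence[i1] + structure.sequence[structure.index_of(segment.chain_id, p2)]
              + structure.sequence[i3])
        return ClosureProblem(seed_pre, seed_post, torsions, p2 - p1, geometry, aa)


@dataclass
class ClosureSolution:
    """The set of pivot torsion assignments that close one problem."""

    pivot_torsions: list  # each item: (3, 2) array of (phi, psi) per pivot
    closure_residuals: list  # A, per solution
    problem: ClosureProblem | None = None

    def __len__(self) -> int:
        return len(self.pivot_torsions)

    def full_torsions(self, k: int) -> np.ndarray:
        """Span torsions with solution k's pivot phi/psi substituted in."""
        t = self.problem.torsions.copy()
        L = len(t)
        for row, p in enumerate((0, self.problem.middle_index, L - 1)):
            t[p, 0] = self.pivot_torsions[k][row, 0]
            t[p, 1] = self.pivot_torsions[k][row, 1]
        if not np.isfinite(t[-1, 2]):
            t[-1, 2] = 180.0
        return t


# ---------------------------------------------------------------------------
# solver internals
# ---------------------------------------------------------------------------

def _frame_from_triad(a, b, c):
    """Orthonormal frame (R, origin=b) rigid with the ordered triad a,b,c."""
    x = c - b
    x = x / np.linalg.norm(x)
    z = np.cross(a - b, x)
    nz = np.linalg.norm(z)
    if nz < 1e-10:
        raise ClosureNonConvergence("degenerate anchor triad")
    z = z / nz
    y = np.cross(z, x)
    return np.stack([x, y, z], axis=1), b


def _nerf_coeffs(a, b, c, bond, angle_deg):
    """D(chi) = c + e1*cos(chi) + e2*sin(chi) + e3 for NeRF placement."""
    theta = np.deg2rad(angle_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    e1 = bond * np.sin(theta) * m
    e2 = bond * np.sin(theta) * n
    e3 = -bond * np.cos(theta) * bc
    return e1, e2, e3


class _HalfSpan:
    """One side of the closure problem: a rigid span whose two free
    torsions are solved in closed form to land its far CA on a target."""

    def __init__(self, seed, ics, free_bond, free_angle, n_far, ca_far):
        # seed: (3,3) triad (ref, A, B); first placed atom X rotates about
        # A-B with the first free torsion; the rest of the span is rigid and
        # spins about B-X with the second free torsion.
        self.seed = seed
        self.ca0 = seed[2]
        self.e1, self.e2, self.e3 = _nerf_coeffs(seed[0], seed[1], seed[2],
                                                 free_bond, free_angle)
        self.ell = free_bond
        ref = build_chain(seed, [(free_bond, free_angle, 0.0)] + list(ics))
        self.ref_atoms = ref[3:]          # X0, then the rigid span
        R, t = _frame_from_triad(seed[1], seed[2], ref[3])
        self.local = (self.ref_atoms - t) @ R  # span atoms in triad frame
        self.n_far = n_far                # index (into ref_atoms) of junction N or C atom
        self.ca_far = ca_far              # index of the far CA
        self.local_pair = self.local[[n_far, ca_far]]
        x0 = ref[3]
        axis = x0 - self.ca0
        self.kappa = float((self.ref_atoms[ca_far] - x0) @ axis / np.linalg.norm(axis))
        self.d_virtual = float(np.linalg.norm(self.ref_atoms[ca_far] - self.ca0))

    def solve_first(self, targets):
        """Both first-torsion branches placing the far CA on (reachable)
        targets: returns (X positions (2, n, 3), infeasibility (n,)).

        Outside the reachable region the solution is clamped (delta = 0),
        which keeps the closure residual continuous across the boundary;
        clamped pseudo-solutions are eliminated later by the forward-
        rebuild verification.  ``infeasibility`` is max(|ratio| - 1, 0).
        """
        rel = targets - self.ca0
        A = rel @ self.e1
        Bc = rel @ self.e2
        C0 = self.ell ** 2 + self.kappa * self.ell - rel @ self.e3
        hyp = np.hypot(A, Bc)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = C0 / hyp
        infeas = np.maximum(np.abs(ratio) - 1.0, 0.0)
        alpha = np.arctan2(Bc, A)
        delta = np.arccos(np.clip(ratio, -1.0, 1.0))
        chis = np.stack([alpha + delta, alpha - delta])  # (2, n)
        X = (self.ca0 + np.cos(chis)[..., None] * self.e1
             + np.sin(chis)[..., None] * self.e2 + self.e3)
        return X, infeas

    def junction_atom(self, X, targets):
        """Position of the junction atom after spinning the span about
        CA0->X so the far CA lands on the target.  X, targets: (..., 3)."""
        R = self._placed(X)
        pair = np.einsum("...ij,kj->...ki", R, self.local_pair) + self.ca0
        ca = pair[..., 1, :]
        axis = X - self.ca0
        axis = axis / np.linalg.norm(axis, axis=-1, keepdims=True)
        psi = _azimuth_delta(ca - X, targets - X, axis)
        atom = pair[..., 0, :]
        return _rodrigues(atom - X, axis, psi) + X

    def assemble(self, X, target):
        """Full span atom positions (scalar case) after both rotations."""
        R = self._placed(X)
        span = (self.local @ R.T) + self.ca0
        axis = X - self.ca0
        axis = axis / np.linalg.norm(axis)
        psi = _azimuth_delta(span[self.ca_far] - X, target - X, axis)
        return _rodrigues(span - X, axis, psi) + X

    def _placed(self, X):
        """Batch frames rigid with (seed[1], seed[2], X)."""
        x = X - self.ca0
        x = x / np.sqrt(np.sum(x * x, axis=-1, keepdims=True))
        z = _cross(self.seed[1] - self.ca0, x)
        z = z / np.sqrt(np.sum(z * z, axis=-1, keepdims=True))
        y = _cross(z, x)
        return np.stack([x, y, z], axis=-1)


def _cross(a, b):
    """Manual cross product (avoids np.cross's axis-handling overhead)."""
    out = np.empty(np.broadcast_shapes(a.shape, b.shape))
    out[..., 0] = a[..., 1] * b[..., 2] - a[..., 2] * b[..., 1]
    out[..., 1] = a[..., 2] * b[..., 0] - a[..., 0] * b[..., 2]
    out[..., 2] = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    return out


def _rodrigues(v, axis, angle):
    """Rotate vectors v about unit axes by angles (all broadcastable)."""
    c = np.cos(angle)[..., None]
    s = np.sin(angle)[..., None]
    if v.ndim > axis.ndim:  # rotating a stack of atoms about one axis
        axis = axis[..., None, :]
        c = c[..., None, :] if c.ndim < v.ndim else c
        s = s[..., None, :] if s.ndim < v.ndim else s
    dot = np.sum(axis * v, axis=-1, keepdims=True)
    return v * c + _cross(axis, v) * s + axis * dot * (1 - c)


def _azimuth_delta(u, v, axis):
    """Signed rotation about axis taking u's azimuth to v's."""
    up = u - np.sum(u * axis, axis=-1, keepdims=True) * axis
    vp = v - np.sum(v * axis, axis=-1, keepdims=True) * axis
    x = np.sum(up * vp, axis=-1)
    y = np.sum(_cross(axis, up) * vp, axis=-1)
    return np.arctan2(y, x)


def _build_half_spans(problem: ClosureProblem):
    g = problem.geometry
    t = problem.torsions
    m = problem.middle_index
    L = problem.span_length
    # forward half: seed (C_pre, N0, CA0); free torsions are phi_0 (places
    # C0, the _HalfSpan "X" atom) and psi_0 (the span spin, reference 0)
    ics_f = []
    for i in range(0, m):
        psi = 0.0 if i == 0 else t[i, 1]
        ics_f.append((g.c_n, g.ang_ca_c_n, psi))        # N(i+1)
        ics_f.append((g.n_ca, g.ang_c_n_ca, t[i, 2]))   # CA(i+1)
        if i + 1 < m:
            ics_f.append((g.ca_c, g.ang_n_ca_c, t[i + 1, 0]))  # C(i+1)
    # ref_atoms layout: [C0, N1, CA1, C1, N2, CA2, ..., N_m, CA_m]
    fwd = _HalfSpan(problem.seed_pre, ics_f, g.ca_c, g.ang_n_ca_c,
                    n_far=3 * m - 2, ca_far=3 * m - 1)
    # backward half: seed (N_post, C_last, CA_last); free torsions are
    # psi_{L-1} (places N_{L-1} = "X") and phi_{L-1} (the span spin, ref 0:
    # it is the dihedral placing C_{L-2}, about the N_{L-1}-CA_{L-1} axis)
    ics_b = [(g.c_n, g.ang_c_n_ca, 0.0)]               # C(L-2), dihedral phi_{L-1}
    for j in range(L - 2, m, -1):
        ics_b.append((g.ca_c, g.ang_ca_c_n, t[j, 2]))  # CA(j), dihedral omega_j
        ics_b.append((g.n_ca, g.ang_n_ca_c, t[j, 1]))  # N(j), dihedral psi_j
        ics_b.append((g.c_n, g.ang_c_n_ca, t[j, 0]))   # C(j-1), dihedral phi_j
    ics_b.append((g.ca_c, g.ang_ca_c_n, t[m, 2]))      # CA_m, dihedral omega_m
    # ref_atoms layout: [N_{L-1}, C_{L-2}, CA_{L-2}, N_{L-2}, ..., C_m, CA_m]
    q = L - 1 - m
    bwd = _HalfSpan(problem.seed_post, ics_b, g.n_ca, g.ang_n_ca_c,
                    n_far=3 * q - 2, ca_far=3 * q - 1)
    return fwd, bwd


class _ClosureEngine:
    """Fused, batch-evaluable closure residual for one problem."""

    def __init__(self, problem: ClosureProblem):
        self.problem = problem
        self.fwd, self.bwd = _build_half_spans(problem)
        fwd, bwd = self.fwd, self.bwd
        self.ca0 = np.stack([fwd.ca0, bwd.ca0])            # (2, 3)
        self.E1 = np.stack([fwd.e1, bwd.e1])
        self.E2 = np.stack([fwd.e2, bwd.e2])
        self.E3 = np.stack([fwd.e3, bwd.e3])
        self.ell = np.array([fwd.ell, bwd.ell])
        self.kappa = np.array([fwd.kappa, bwd.kappa])
        self.refvec = np.stack([fwd.seed[1] - fwd.ca0, bwd.seed[1] - bwd.ca0])
        self.pair = np.stack([fwd.local_pair, bwd.local_pair])  # (2, 2, 3)
        self.theta_mid = problem.geometry.ang_n_ca_c
        d12, d23 = fwd.d_virtual, bwd.d_virtual
        axis = bwd.ca0 - fwd.ca0
        d13 = float(np.linalg.norm(axis))
        self.lever = d12 + d23 + d13  # conservative residual lever arm
        self.feasible = not (d13 < 1e-9 or d13 > d12 + d23 or d13 < abs(d12 - d23))
        if not self.feasible:
            return
        axis = axis / d13
        a_proj = (d13 ** 2 + d12 ** 2 - d23 ** 2) / (2 * d13)
        r_sq = d12 ** 2 - a_proj ** 2
        if r_sq <= 0:
            self.feasible = False
            return
        self.radius = np.sqrt(r_sq)
        self.center = fwd.ca0 + a_proj * axis
        u = np.cross(axis, [1.0, 0.0, 0.0])
        if np.linalg.norm(u) < 1e-6:
            u = np.cross(axis, [0.0, 1.0, 0.0])
        self.u = u / np.linalg.norm(u)
        self.v = np.cross(axis, self.u)

    def circle_point(self, sigmas):
        sigmas = np.asarray(sigmas, float)
        return (self.center + self.radius
                * (np.cos(sigmas)[..., None] * self.u
                   + np.sin(sigmas)[..., None] * self.v))

    def _junctions(self, B):
        """Junction atoms for both spans and branches: (2span, 2branch, n, 3)
        plus infeasibility (2span, n)."""
        rel = B[None] - self.ca0[:, None]                  # (2, n, 3)
        A = np.sum(rel * self.E1[:, None], axis=-1)
        Bc = np.sum(rel * self.E2[:, None], axis=-1)
        C0 = (self.ell ** 2 + self.kappa * self.ell)[:, None] \
            - np.sum(rel * self.E3[:, None], axis=-1)
        hyp = np.hypot(A, Bc)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = C0 / hyp
        infeas = np.maximum(np.abs(ratio) - 1.0, 0.0)
        alpha = np.arctan2(Bc, A)
        delta = np.arccos(np.clip(ratio, -1.0, 1.0))
        chis = np.stack([alpha + delta, alpha - delta], axis=1)  # (2, 2, n)
        X = (self.ca0[:, None, None]
             + np.cos(chis)[..., None] * self.E1[:, None, None]
             + np.sin(chis)[..., None] * self.E2[:, None, None]
             + self.E3[:, None, None])                     # (2, 2, n, 3)
        x = X - self.ca0[:, None, None]
        x = x / np.sqrt(np.sum(x * x, axis=-1, keepdims=True))
        z = _cross(self.refvec[:, None, None], x)
        z = z / np.sqrt(np.sum(z * z, axis=-1, keepdims=True))
        y = _cross(z, x)
        R = np.stack([x, y, z], axis=-1)                   # (2, 2, n, 3, 3)
        pair = np.einsum("sbnij,skj->sbnki", R, self.pair) \
            + self.ca0[:, None, None, None]                # (2, 2, n, 2, 3)
        ca = pair[..., 1, :]
        atom = pair[..., 0, :]
        psi = _azimuth_delta(ca - X, B[None, None] - X, x)
        junction = _rodrigues(atom - X, x, psi) + X        # (2, 2, n, 3)
        return junction, infeas

    def residual(self, sigmas):
        """(2, 2, n) middle-pivot angle residuals (degrees), clamped."""
        B = self.circle_point(sigmas)
        junction, _ = self._junctions(B)
        ang = bond_angle(junction[0][:, None], B[None, None],
                         junction[1][None, :])
        return ang - self.theta_mid


def solve_closure(problem: ClosureProblem, scan_points: int = 720,
                  tol: float = CLOSURE_TOL) -> ClosureSolution:
    """Find all pivot phi/psi assignments that close the chain.

    Returns a :class:`ClosureSolution` whose list is empty when the anchors
    are out of reach.  Raises :class:`ClosureNonConvergence` on numerical
    failure while recovering a polished root (distinct from 'no solutions').
    """
    engine = _ClosureEngine(problem)
    sols: list[np.ndarray] = []
    residuals: list[float] = []
    out = ClosureSolution(sols, residuals, problem)
    if not engine.feasible:
        return out  # triangle impossible: anchors unreachable

    sigma = np.linspace(-np.pi, np.pi, scan_points, endpoint=False)
    f = engine.residual(sigma)

    def branch_eval(svals, ii, jj):
        val = engine.residual(np.asarray(svals, float))
        return val[ii, jj, np.arange(len(svals))]

    roots = _find_roots(sigma, f, branch_eval)
    if roots:
        # drop clamped pseudo-roots (an arm cannot actually reach B there)
        # with one batched feasibility evaluation
        svals = np.array([r[0] for r in roots])
        _, infeas = engine._junctions(engine.circle_point(svals))
        roots = [r for k, r in enumerate(roots)
                 if infeas[0, k] <= 1e-9 and infeas[1, k] <= 1e-9]

    for s, i, j in roots:
        sol = _assemble(engine, s, i, j)
        if sol is None:
            continue  # clamped pseudo-root or out-of-tolerance: discard
        torsions, residual = sol
        if any(np.max(np.abs(wrap_angle(torsions - prev))) < 1e-4 for prev in sols):
            continue
        sols.append(torsions)
        residuals.append(residual)
    return out


def _find_roots(sigma, f, branch_eval, n_rounds: int = 5, n_sub: int = 16):
    """Root polishing on the periodic scan grid.

    Sign-change brackets from all four branch combinations are narrowed
    simultaneously by repeated vectorized subdivision (each round splits
    every bracket into ``n_sub`` pieces with a single batched residual
    evaluation, shrinking brackets by 16^9 ~ 7e10 overall); shallow
    tangential minima of |f| (double roots) are polished separately.
    Returns a sorted list of (sigma, fwd_branch, bwd_branch) triples.
    """
    n = len(sigma)
    step = 2 * np.pi / n
    a_list, ii, jj = [], [], []
    tangent_cands = []
    for i in range(2):
        for j in range(2):
            fij = f[i, j]
            fnext = np.roll(fij, -1)
            sign_change = fij * fnext < 0
            for k in np.flatnonzero(sign_change):
                a_list.append(sigma[k])
                ii.append(i)
                jj.append(j)
            for k in np.flatnonzero(fij == 0.0):
                tangent_cands.append((float(sigma[k]), i, j, True))
            absf = np.abs(fij)
            local_min = ((absf < np.roll(absf, 1)) & (absf < np.roll(absf, -1))
                         & (absf < 0.5)
                         & (np.roll(fij, 1) * np.roll(fij, -1) > 0))
            for k in np.flatnonzero(local_min):
                tangent_cands.append((float(sigma[k]), i, j, False))

    roots = []
    if a_list:
        a = np.array(a_list)
        width = np.full(len(a), step)
        ia = np.repeat(np.array(ii), 1)
        ja = np.repeat(np.array(jj), 1)
        nb = len(a)
        offs = np.arange(1, n_sub + 1) / n_sub  # interior + right edge
        fa = f[ia, ja, [int(round((x + np.pi) / step)) % n for x in a_list]]
        for _ in range(n_rounds):
            pts = a[:, None] + width[:, None] * offs[None, :]
            fv = branch_eval(pts.ravel(),
                             np.repeat(ia, n_sub),
                             np.repeat(ja, n_sub)).reshape(nb, n_sub)
            fall = np.concatenate([fa[:, None], fv], axis=1)  # (nb, n_sub+1)
            cross = fall[:, :-1] * fall[:, 1:] <= 0
            first = np.argmax(cross, axis=1)  # first sign-change subinterval
            has = cross[np.arange(nb), first]
            first = np.where(has, first, 0)
            a = a + width * first / n_sub
            fa = fall[np.arange(nb), first]
            width = width / n_sub
        for s, i, j in zip(a + 0.5 * width, ia, ja):
            roots.append((float(s), int(i), int(j)))
    for s0, i, j, exact in tangent_cands:
        if exact:
            roots.append((s0, i, j))
            continue
        res = minimize_scalar(
            lambda s: abs(float(branch_eval([s], np.array([i]), np.array([j]))[0])),
            bounds=(s0 - step, s0 + step), method="bounded",
            options={"xatol": 1e-12})
        if abs(res.fun) < 1e-7:
            roots.append((float(res.x), i, j))
    roots.sort()
    return roots


def _assemble(engine: _ClosureEngine, s, i, j):
    """Recover pivot torsions at a polished root; residual is bounded by
    the remaining angle error times a conservative lever arm."""
    problem = engine.problem
    fwd, bwd = engine.fwd, engine.bwd
    B = engine.circle_point(np.array([s]))[0]
    Xf_all, infeas_f = fwd.solve_first(B[None])
    Xb_all, infeas_b = bwd.solve_first(B[None])
    Xf, Xb = Xf_all[i, 0], Xb_all[j, 0]
    if infeas_f[0] > 1e-9 or infeas_b[0] > 1e-9:
        return None  # clamped pseudo-root: the arm cannot reach this B
    if not (np.all(np.isfinite(Xf)) and np.all(np.isfinite(Xb))):
        return None
    span_f = fwd.assemble(Xf, B)   # [C0, N1, CA1, ..., N_m, CA_m]
    span_b = bwd.assemble(Xb, B)   # [N_last, C_{L-2}, CA_{L-2}, ..., C_m, CA_m]
    m = problem.middle_index
    L = problem.span_length
    c_pre, n0, ca0 = problem.seed_pre
    n_post, c_last, ca_last = problem.seed_post
    # pivot 1
    phi0 = dihedral(c_pre, n0, ca0, span_f[0])
    n1 = span_f[1]
    psi0 = dihedral(n0, ca0, span_f[0], n1)
    # middle pivot
    n_m = span_f[fwd.n_far]
    c_m = span_b[bwd.n_far]
    c_prev = span_f[fwd.n_far - 1]   # C(m-1); equals C0 when m == 1
    n_next = span_b[bwd.n_far - 1]   # N(m+1); equals N_{L-1} when m == L-2
    phim = dihedral(c_prev, n_m, B, c_m)
    psim = dihedral(n_m, B, c_m, n_next)
    # last pivot
    n_last = span_b[0]
    c_l2 = span_b[1]
    phil = dihedral(c_l2, n_last, ca_last, c_last)
    psil = dihedral(n_last, ca_last, c_last, n_post)
    torsions = wrap_angle(np.array([[phi0, psi0], [phim, psim], [phil, psil]]))
    if not np.all(np.isfinite(torsions)):
        return None
    # residual: every constraint except the middle N-CA-C angle is exact by
    # construction, so the reconnection error of the rebuilt chain is
    # bounded by the remaining angle error times the span extent
    ang_err = abs(float(bond_angle(n_m, B, c_m)) - engine.theta_mid)
    residual = float(np.deg2rad(ang_err) * engine.lever)
    if residual > CLOSURE_TOL:
        return None  # failed polish (e.g. a near-tangent pseudo-root)
    return torsions, residual


# ---------------------------------------------------------------------------
# Ramachandran screening of pivot solutions
# ---------------------------------------------------------------------------

def rama_filter(solutions: ClosureSolution, pivot_aa: str,
                threshold: float = 1e-4,
                tables: RamachandranTables | None = None) -> ClosureSolution:
    """Retain solutions whose three pivot (phi, psi) pairs all sit at
    Ramachandran density >= threshold; order preserved."""
    if tables is None:
        tables = default_tables()
    if len(pivot_aa) != 3:
        raise ValueError("pivot_aa must give one-letter codes for the 3 pivots")
    for aa in pivot_aa:
        tables.residue_class(aa)  # raises on unknown code
    kept_t, kept_r = [], []
    for t, res in zip(solutions.pivot_torsions, solutions.closure_residuals):
        dens = [tables.density(t[k, 0], t[k, 1], pivot_aa[k]) for k in range(3)]
        if all(d >= threshold for d in dens):
            kept_t.append(t)
            kept_r.append(res)
    return ClosureSolution(kept_t, kept_r, solutions.problem)


def apply_solution(structure: BackboneStructure, segment: SegmentSpec,
                   pivots: PivotSelection, solution: ClosureSolution,
                   k: int) -> BackboneStructure:
    """Rebuild the pivot span with solution k's torsions; atoms outside the
    span are untouched."""
    p1, _, p3 = pivots.pivot_resnums
    span = SegmentSpec(segment.chain_id, p1, p3)
    return set_segment_torsions(structure, span, solution.full_torsions(k),
                                solution.problem.geometry)


# ---------------------------------------------------------------------------
# CCD baseline
# ---------------------------------------------------------------------------

@dataclass
class CCDResult:
    structure: BackboneStructure
    break_distance: float
    iterations: int
    history: list = field(default_factory=list)


def ccd_close(structure: BackboneStructure, segment: SegmentSpec,
              max_iters: int = 100, tol: float = 0.1,
              geometry: InternalGeometry = IDEAL_GEOMETRY) -> CCDResult:
    """Cyclic coordinate descent closure of the segment's downstream break.

    Sweeps every segment phi/psi torsion in order, each time applying the
    closed-form rotation that minimises the squared distance between the
    rebuilt downstream anchor image (CA, C of the last segment residue and
    the following N) and its fixed target.  The break distance is
    non-increasing across updates.
    """
    idx = structure.segment_indices(segment)
    i0, iL = idx[0], idx[-1]
    if iL + 1 >= len(structure) or structure.chains[iL + 1] != segment.chain_id:
        raise StructureError("segment needs a downstream anchor for CCD")
    g = geometry
    ca3, c3 = downstream_anchor_atoms(structure, segment.chain_id,
                                      segment.end, g)
    targets = np.stack([ca3, c3, structure.coords[iL + 1, 0]])

    tors = torsions_from_coords(structure, segment)
    tors[~np.isfinite(tors)] = 180.0

    def build(t):
        seed = np.stack([structure.atom(i0 - 1, "C"), structure.atom(i0, "N"),
                         structure.atom(i0, "CA")])
        built = coords_from_torsions(seed, t, g)
        n_img = place_atom(built[-1, 0], built[-1, 1], built[-1, 2],
                           g.c_n, g.ang_ca_c_n, t[-1, 1])
        return built, n_img

    def break_dist(built, n_img):
        # RMS deviation of the three anchor images: this is (the root of)
        # the quantity each CCD update minimizes, so it is non-increasing
        imgs = np.stack([built[-1, 1], built[-1, 2], n_img])
        return float(np.sqrt(np.mean(np.sum((imgs - targets) ** 2, axis=-1))))

    built, n_img = build(tors)
    d = break_dist(built, n_img)
    history = [d]
    it = 0
    if d < tol:
        return CCDResult(structure.copy(), d, 0, history)
    L = segment.length
    while it < max_iters and d >= tol:
        it += 1
        for ri in range(L):
            for kind in (0, 1):  # phi, psi
                built, n_img = build(tors)
                if kind == 0:
                    O, A = built[ri, 0], built[ri, 1]   # axis N->CA
                else:
                    O, A = built[ri, 1], built[ri, 2]   # axis CA->C
                ax = A - O
                ax = ax / np.linalg.norm(ax)
                imgs = np.stack([built[-1, 1], built[-1, 2], n_img])
                rel = imgs - O
                par = (rel @ ax)[:, None] * ax
                rvec = rel - par
                svec = np.cross(ax, rvec)
                frel = targets - O - par
                a = float(np.sum(frel * rvec))
                b = float(np.sum(frel * svec))
                if a == 0.0 and b == 0.0:
                    continue
                delta = np.degrees(np.arctan2(b, a))
                tors[ri, kind] = wrap_angle(tors[ri, kind] + delta)
        built, n_img = build(tors)
        d = break_dist(built, n_img)
        history.append(d)
    out = set_segment_torsions(structure, segment, tors, g)
    return CCDResult(out, d, it, history)
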