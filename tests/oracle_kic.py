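"""Independent brute-force oracle for the closure solver.

Finds all pivot-torsion solutions of a ClosureProblem by gridding the six
pivot torsions at 2-degree resolution (hierarchically, with geometric
pruning so the search is tractable) and polishing every surviving grid
basin with batched damped Gauss-Newton on the direct forward-kinematics
closure residual.  Shares only the NeRF chain-building primitive with the library;
the analytic solver itself is never invoked.
"""

from __future__ import annotations

import numpy as np

from loopforge.geometry import place_atom
from loopforge.structure import coords_from_torsions

STEP_DEG = 2.0


def residual_vector(problem, pivot_torsions):
    """9-vector of downstream reconnection deviations for given pivot
    (phi, psi) values; a true solution zeroes it."""
    t = problem.torsions.copy()
    L = len(t)
    for row, p in enumerate((0, problem.middle_index, L - 1)):
        t[p, 0] = pivot_torsions[2 * row]
        t[p, 1] = pivot_torsions[2 * row + 1]
    if not np.isfinite(t[-1, 2]):
        t[-1, 2] = 180.0
    g = problem.geometry
    built = coords_from_torsions(problem.seed_pre, t, g)
    n_post, c_last, ca_last = problem.seed_post
    n_img = place_atom(built[-1, 0], built[-1, 1], built[-1, 2],
                       g.c_n, g.ang_ca_c_n, t[-1, 1])
    return np.concatenate([built[-1, 1] - ca_last, built[-1, 2] - c_last,
                           n_img - n_post])


def closure_residual(problem, pivot_torsions) -> float:
    return float(np.max(np.abs(residual_vector(problem, pivot_torsions))))


def rebuilt_segment(problem, pivot_torsions):
    t = problem.torsions.copy()
    L = len(t)
    for row, p in enumerate((0, problem.middle_index, L - 1)):
        t[p, 0] = pivot_torsions[2 * row]
        t[p, 1] = pivot_torsions[2 * row + 1]
    if not np.isfinite(t[-1, 2]):
        t[-1, 2] = 180.0
    return coords_from_torsions(problem.seed_pre, t, problem.geometry)


def place_cone(a, b, c, bond, angle_deg, chi_grid_deg):
    """Place an atom from per-point triads over a shared grid of dihedrals.

    The NeRF frame is computed once per (a, b, c) point and the dihedral
    grid applied as a 2-term cosine expansion: (..., G, 3) output for
    (..., 3) triads and (G,) grid.  Much cheaper than full place_atom when
    only the dihedral varies.
    """
    theta = np.deg2rad(angle_deg)
    chi = np.deg2rad(np.asarray(chi_grid_deg, float))
    bc = c - b
    bc = bc / np.linalg.norm(bc, axis=-1, keepdims=True)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n, axis=-1, keepdims=True)
    mvec = np.cross(n, bc)
    e1 = bond * np.sin(theta) * mvec
    e2 = bond * np.sin(theta) * n
    e3 = c - bond * np.cos(theta) * bc
    return (e3[..., None, :] + np.cos(chi)[:, None] * e1[..., None, :]
            + np.sin(chi)[:, None] * e2[..., None, :])


def brute_force_solutions(problem, step_deg: float = STEP_DEG):
    """All closure solutions found by 2-degree gridding + local polish.

    Returns a list of polished 6-vectors (phi/psi per pivot, degrees) whose
    closure residual is below 1e-4 A, deduplicated by torsion proximity.
    """
    g = problem.geometry
    t = problem.torsions
    m = problem.middle_index
    L = len(t)
    c_pre, n0, ca0 = problem.seed_pre
    n_post, c_last, ca_last = problem.seed_post
    grid = np.arange(-179.0, 181.0, step_deg)
    G = len(grid)

    # ---- fixed rigid distances, from reference builds with arbitrary pivots
    ref = rebuilt_segment(problem, np.zeros(6))
    # distances from CA_m / C_m / N_{m+1} to CA_last are pivot-invariant
    d23 = float(np.linalg.norm(ref[m, 1] - ref[L - 1, 1]))
    d_cm = float(np.linalg.norm(ref[m, 2] - ref[L - 1, 1]))
    d_nm1 = float(np.linalg.norm(ref[m + 1, 0] - ref[L - 1, 1]))
    # per-stage acceptance bands: worst-case displacement of the checked
    # image when each already-gridded angle is within half a grid step of a
    # true solution (lever = distance from the image to the rotation axis
    # region, bounded by inter-anchor distances), plus a small margin
    half = np.deg2rad(step_deg / 2)
    d12 = float(np.linalg.norm(ref[0, 1] - ref[m, 1]))
    d_far = float(np.linalg.norm(ca_last - ca0))
    band_a = 2 * half * (d12 + 2.0) + 0.1
    band_b = half * (2 * (d12 + 2.0) + 2.0) + 0.1
    band_n = half * (2 * (d12 + 4.0) + 4.0) + 0.1
    band_c = half * (2 * (d_far + 2.0) + 2 * (d23 + 2.0)) + 0.1

    def roll_build(win, seq):
        """Rolling 3-atom window build; returns atoms of the last 3 slots."""
        a, b, c = win
        for bond, ang, dih in seq:
            a, b, c = b, c, place_atom(a, b, c, bond, ang, dih)
        return a, b, c

    # ---- stage A: (phi0, psi0) grid, build forward to N_m/CA_m
    pp, ss = np.meshgrid(grid, grid, indexing="ij")
    shape = pp.shape
    A = np.broadcast_to(c_pre, shape + (3,))
    B = np.broadcast_to(n0, shape + (3,))
    Cc = np.broadcast_to(ca0, shape + (3,))
    c0 = place_atom(A, B, Cc, g.ca_c, g.ang_n_ca_c, pp)
    n1 = place_atom(B, Cc, c0, g.c_n, g.ang_ca_c_n, ss)
    seq = []
    for i in range(0, m):
        if i > 0:
            seq.append((g.c_n, g.ang_ca_c_n, t[i, 1]))   # N(i+1)
        seq.append((g.n_ca, g.ang_c_n_ca, t[i, 2]))      # CA(i+1)
        if i + 1 < m:
            seq.append((g.ca_c, g.ang_n_ca_c, t[i + 1, 0]))  # C(i+1)
    c_prev, n_m, ca_m = roll_build((Cc, c0, n1), seq)
    # (for m == 1 the rolling window already holds (C0, N1, CA1))
    dist = np.linalg.norm(ca_m - ca_last, axis=-1)
    keep = np.abs(dist - d23) < band_a
    if not np.any(keep):
        return []
    phi0_k = pp[keep]
    psi0_k = ss[keep]
    ca_m_k = ca_m[keep]
    n_m_k = n_m[keep]
    c_prev_k = c_prev[keep]

    # ---- stage B1: phi_m grid, prune on |C_m - CA_last|
    cm = place_cone(c_prev_k, n_m_k, ca_m_k,
                    g.ca_c, g.ang_n_ca_c, grid)            # (S, G, 3)
    okB = np.abs(np.linalg.norm(cm - ca_last, axis=-1) - d_cm) < band_b
    sidx, pidx = np.nonzero(okB)
    if len(sidx) == 0:
        return []

    # ---- stage B2: psi_m grid, check CA_last reconnection (chunked)
    from loopforge.geometry import dihedral
    seq = []
    for j in range(m, L - 1):
        if j > m:
            seq.append((g.c_n, g.ang_ca_c_n, t[j, 1]))   # N(j+1)
        seq.append((g.n_ca, g.ang_c_n_ca, t[j, 2]))      # CA(j+1)
        if j + 1 < L - 1:
            seq.append((g.ca_c, g.ang_n_ca_c, t[j + 1, 0]))  # C(j+1)
    # the stretch beyond N_{m+1} is rigid relative to the triad
    # (CA_m, C_m, N_{m+1}): precompute the three needed downstream atoms
    # (C_{L-2}, N_{L-1}, CA_{L-1}) in that triad's frame from the reference
    # build, then evaluate them by one frame transform per grid triple
    def triad_frame(a, b, c):
        x = c - b
        x = x / np.linalg.norm(x, axis=-1, keepdims=True)
        z = np.cross(a - b, x)
        z = z / np.linalg.norm(z, axis=-1, keepdims=True)
        y = np.cross(z, x)
        return np.stack([x, y, z], axis=-1), b

    ref_targets = np.stack([ref[L - 2, 2] if L - 2 > m else ref[m, 2],
                            ref[L - 1, 0], ref[L - 1, 1]])
    Rref, oref = triad_frame(ref[m, 1], ref[m, 2], ref[m + 1, 0])
    local = (ref_targets - oref) @ Rref  # (3 atoms, 3)

    cands = []
    chunk = 5000
    for lo in range(0, len(sidx), chunk):
        si = sidx[lo:lo + chunk]
        pi = pidx[lo:lo + chunk]
        nn = place_cone(n_m_k[si], ca_m_k[si], cm[si, pi],
                        g.c_n, g.ang_ca_c_n, grid)          # (chunk, G, 3)
        okN = np.abs(np.linalg.norm(nn - ca_last, axis=-1) - d_nm1) < band_n
        ridx0, qidx0 = np.nonzero(okN)
        if len(ridx0) == 0:
            continue
        camg = ca_m_k[si][ridx0]
        cmg = cm[si, pi][ridx0]
        nng = nn[ridx0, qidx0]
        Rb, ob = triad_frame(camg, cmg, nng)
        imgs = np.einsum("kij,aj->kai", Rb, local) + ob[:, None, :]
        c_l2_img, n_last_img, ca_last_img = imgs[:, 0], imgs[:, 1], imgs[:, 2]
        miss = np.linalg.norm(ca_last_img - ca_last, axis=-1)
        hit = miss < band_c
        if not np.any(hit):
            continue
        ridx, qidx = ridx0[hit], qidx0[hit]
        phil = dihedral(c_l2_img[hit], n_last_img[hit], ca_last, c_last)
        psil = dihedral(n_last_img[hit],
                        np.broadcast_to(ca_last, phil.shape + (3,)),
                        np.broadcast_to(c_last, phil.shape + (3,)), n_post)
        cands.append(np.stack([phi0_k[si[ridx]], psi0_k[si[ridx]],
                               grid[pi[ridx]], grid[qidx], phil, psil], axis=1))
    if not cands:
        return []
    cands = np.concatenate(cands, axis=0)
    # collapse near-duplicate seeds: the last-pivot torsions are smooth
    # functions of the four gridded angles, so dedupe on those four, on a
    # 6-degree lattice — every residual basin keeps a representative (the
    # accepted bands guarantee the grid point nearest each true solution
    # survives, and the polisher converges from within a lattice cell)
    lattice = np.round(cands[:, :4] / 6.0)
    _, first = np.unique(lattice, axis=0, return_index=True)
    cands = cands[np.sort(first)]

    # ---- batch Levenberg-Marquardt: every candidate is followed to its
    # own local minimum of the closure residual (no greedy pruning, so no
    # basin can be missed); converged minima are then deduplicated
    X = batch_polish(problem, cands)
    R = batch_residual(problem, X)
    # exact solutions polish to ~1e-10; near-tangent local minima of the
    # residual stall around 1e-5 and are not closures
    good = np.max(np.abs(R), axis=1) <= 1e-6
    Xg = ((X[good] + 180) % 360) - 180
    if len(Xg):
        _, first = np.unique(np.round(Xg / 0.005), axis=0, return_index=True)
        Xg = Xg[np.sort(first)]
    sols: list[np.ndarray] = []
    for x in Xg:
        if not any(np.max(np.abs(((x - s) + 180) % 360 - 180)) < 0.05
                   for s in sols):
            sols.append(x)
    return sols


def batch_residual(problem, X):
    """Vectorized residual_vector for (K, 6) pivot-torsion sets -> (K, 9)."""
    t = problem.torsions
    L = len(t)
    m = problem.middle_index
    g = problem.geometry
    K = len(X)
    c_pre, n0, ca0 = problem.seed_pre
    n_post, c_last, ca_last = problem.seed_post
    phi = np.broadcast_to(t[:, 0], (K, L)).copy()
    psi = np.broadcast_to(t[:, 1], (K, L)).copy()
    omg = np.broadcast_to(np.where(np.isfinite(t[:, 2]), t[:, 2], 180.0),
                          (K, L)).copy()
    for row, p in enumerate((0, m, L - 1)):
        phi[:, p] = X[:, 2 * row]
        psi[:, p] = X[:, 2 * row + 1]
    a = np.broadcast_to(c_pre, (K, 3))
    b = np.broadcast_to(n0, (K, 3))
    c = np.broadcast_to(ca0, (K, 3))
    for i in range(L):
        a, b, c = b, c, place_atom(a, b, c, g.ca_c, g.ang_n_ca_c, phi[:, i])
        if i < L - 1:
            a, b, c = b, c, place_atom(a, b, c, g.c_n, g.ang_ca_c_n, psi[:, i])
            a, b, c = b, c, place_atom(a, b, c, g.n_ca, g.ang_c_n_ca, omg[:, i])
    # window now holds (N_{L-1}, CA_{L-1}, C_{L-1})
    n_img = place_atom(a, b, c, g.c_n, g.ang_ca_c_n, psi[:, L - 1])
    return np.concatenate([b - ca_last, c - c_last, n_img - n_post], axis=1)


def batch_polish(problem, X0, iters: int = 50, fd_step: float = 1e-5):
    """Damped Gauss-Newton on the closure residual, batched over seeds.

    Converged or hopeless seeds leave the active set so late iterations
    only refine the remaining stragglers.
    """
    X = np.array(X0, float)
    K = len(X)
    lam = np.full(K, 1e-3)
    R = batch_residual(problem, X)
    cost = np.sum(R ** 2, axis=1)
    active = np.ones(K, bool)
    for _ in range(iters):
        ai = np.flatnonzero(active)
        if len(ai) == 0:
            break
        Xa = X[ai]
        Ra = R[ai]
        J = np.empty((len(ai), Ra.shape[1], 6))
        for d in range(6):
            Xp = Xa.copy()
            Xp[:, d] += fd_step
            J[:, :, d] = (batch_residual(problem, Xp) - Ra) / fd_step
        A = np.einsum("krd,kre->kde", J, J)
        A[:, np.arange(6), np.arange(6)] += lam[ai, None] + 1e-12
        gvec = np.einsum("krd,kr->kd", J, Ra)
        delta = np.linalg.solve(A, -gvec[..., None])[..., 0]
        Xn = Xa + delta
        Rn = batch_residual(problem, Xn)
        costn = np.sum(Rn ** 2, axis=1)
        better = costn < cost[ai]
        X[ai] = np.where(better[:, None], Xn, Xa)
        R[ai] = np.where(better[:, None], Rn, Ra)
        improvement = np.where(better, cost[ai] - costn, 0.0)
        cost[ai] = np.where(better, costn, cost[ai])
        lam[ai] = np.clip(np.where(better, lam[ai] * 0.3, lam[ai] * 5.0),
                          1e-12, 1e8)
        # retire: essentially exact, or no longer making progress
        done = (cost[ai] < 1e-22) | (~better & (lam[ai] > 1e6)) \
            | (better & (improvement < 1e-26))
        active[ai[done]] = False
    return X


def match_solution_sets(problem, analytic, brute, coord_tol: float = 0.05):
    """Compare solution sets by rebuilt-segment coordinates.

    Returns (unmatched_analytic, unmatched_brute): indices in either set
    with no counterpart within coord_tol maximum atom deviation.
    """
    def coords(x):
        return rebuilt_segment(problem, np.asarray(x).ravel())

    ac = [coords(np.array(a).reshape(-1)) for a in analytic]
    bc = [coords(b) for b in brute]
    unmatched_a = []
    for i, a in enumerate(ac):
        if not any(np.max(np.linalg.norm(a - b, axis=-1)) < coord_tol for b in bc):
            unmatched_a.append(i)
    unmatched_b = []
    for j, b in enumerate(bc):
        if not any(np.max(np.linalg.norm(a - b, axis=-1)) < coord_tol for a in ac):
            unmatched_b.append(j)
    return unmatched_a, unmatched_b
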