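"""Programmatic synthetic fixtures: mini-protein backbones with known
native loop conformations, benchmark sets, and fragment-source decoys.

Fixtures are helix- (or strand-) flanked irregular loops built by
forward kinematics with ideal covalent geometry, so their torsions are
exactly recoverable; every structure is clash-free and well bent by
construction (random recipes are re-drawn under clash and span budgets,
then refined into a local optimum of the simplified energy).  Sequences
follow a fixed aperiodic pattern over an 8-letter reduced alphabet so
fragment picking has unambiguous sequence signal without biological
pretension; glycine and proline are avoided unless a recipe requests
them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .benchmark import BenchmarkCase
from .rama import default_tables
from .scoring import clash_score
from .structure import (BackboneStructure, SegmentSpec, coords_from_torsions,
                        write_pdb)

ALPHABET = "ADEFIKLS"
HELIX = (-57.0, -47.0)
STRAND = (-120.0, 130.0)

# cyclic phi/psi patterns validated to give clash-free, well-bent loops
# flanked by helices at every length 4..16
LOOP_PRESETS = {
    "irregular1": [(-90, 0), (-63, -43), (-65, 145), (-90, 0)],
    "irregular2": [(-75, -20), (-90, 0), (-140, 70), (-65, 145)],
    "turn": [(57, 47), (-140, 70), (-63, -43), (-90, 0)],
}
CLASH_BUDGET = 0.1
RETRY_CAP = 200
# real loops bend: accept a loop only if the anchor-to-anchor CA span is
# well below the maximal extension, so closure moves have geometric room
MAX_SPAN_RATIO = 0.55


@dataclass(frozen=True)
class FixtureSpec:
    loop_length: int = 6
    recipe: str = "random-rama"   # preset name or "random-rama"
    seed: int = 0
    flank_length: int = 8
    flank: str = "helix"          # or "strand"
    chain_id: str = "A"

    def __post_init__(self):
        if not (4 <= self.loop_length <= 16):
            raise ValueError("loop length must be in 4..16")
        if self.flank not in ("helix", "strand"):
            raise ValueError("flank must be 'helix' or 'strand'")
        if self.recipe != "random-rama" and self.recipe not in LOOP_PRESETS:
            raise ValueError(f"unknown loop recipe {self.recipe!r}")


_SEQ_RNG_SEED = 1729  # fixed: fixture sequences are a constant pattern


def _sequence(n: int, offset: int = 0) -> str:
    """Fixed aperiodic pattern over the reduced alphabet.

    Aperiodicity makes window alignment unambiguous, so sequence-based
    fragment ranking has signal; the pattern is constant across runs.
    """
    rng = np.random.default_rng(_SEQ_RNG_SEED + offset)
    return "".join(ALPHABET[i] for i in rng.integers(0, len(ALPHABET), n))


def chain_from_torsions(torsions, sequence, chain_id="A", start_resnum=1,
                        origin=(0.0, 0.0, 0.0)) -> BackboneStructure:
    """Build a single chain from per-residue phi/psi/omega torsions."""
    torsions = np.asarray(torsions, float)
    o = np.asarray(origin, float)
    seed = np.array([[-2.5, 1.2, 0.0], [-1.329, 0.0, 0.0], [0.0, 0.0, 0.0]]) + o
    coords = coords_from_torsions(seed, torsions)
    return BackboneStructure(coords, np.arange(start_resnum,
                                               start_resnum + len(torsions)),
                             np.array([chain_id] * len(torsions)),
                             sequence)


def _loop_torsions(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    L = spec.loop_length
    out = np.full((L, 3), 180.0)
    if spec.recipe == "random-rama":
        # sharpened draws keep fixture "natives" near Ramachandran basin
        # modes, as curated loops are, so propensity scoring favours them
        tables = default_tables()
        phi, psi = tables.sample(rng, "A", size=L, sharpen=4.0)
        out[:, 0], out[:, 1] = phi, psi
    else:
        pat = LOOP_PRESETS[spec.recipe]
        for i in range(L):
            out[i, 0], out[i, 1] = pat[i % len(pat)]
    return out


def _refine_native(st, seg, rng, n_moves: int = 60):
    """Greedy closure refinement of the fixture loop.

    Crystallographic loops sit in minima of the scoring model used to rank
    predictions; the synthetic analogue is produced by descending the
    simplified backbone energy with Ramachandran-KIC moves (accepting only
    improvements, choosing the best-scoring closure solution each move)
    until the loop is a strong local optimum.
    """
    from .kic import (ClosureProblem, apply_solution, rama_filter,
                      select_pivots, solve_closure)
    from .rama import default_tables
    from .scoring import score_structure
    from .structure import torsions_from_coords
    tables = default_tables()
    cur = st
    e_cur = score_structure(cur).total
    idx = cur.segment_indices(seg)
    for _ in range(n_moves):
        prop = torsions_from_coords(cur, seg)
        prop[~np.isfinite(prop)] = 180.0
        for k, i in enumerate(idx):
            phi, psi = tables.sample(rng, cur.sequence[i], sharpen=2.0)
            prop[k, 0], prop[k, 1] = phi, psi
            prop[k, 2] = 180.0
        pivots = select_pivots(seg, rng)
        try:
            problem = ClosureProblem.from_structure(cur, seg, pivots,
                                                    torsions=prop)
            sols = solve_closure(problem)
        except Exception:
            continue
        sols = rama_filter(sols, problem.pivot_aa)
        for k in range(len(sols)):
            cand = apply_solution(cur, seg, pivots, sols, k)
            e = score_structure(cand).total
            if e < e_cur:
                cur, e_cur = cand, e
    return cur


def make_fixture(spec: FixtureSpec):
    """Helix/strand - loop - helix/strand backbone with a known native loop.

    Returns (structure, segment).  The loop is geometrically closed (built
    as one chain), clash-free (clash_score < 0.1), well bent (anchor span
    below 55% of maximal extension) and — for random recipes — refined into
    a local optimum of the simplified backbone energy, so the native is a
    meaningful target for energy-ranked prediction.  Random recipes are
    re-drawn up to a retry cap before raising.
    """
    rng = np.random.default_rng(spec.seed)
    fl = spec.flank_length
    flank_pp = HELIX if spec.flank == "helix" else STRAND
    n = 2 * fl + spec.loop_length
    seq = _sequence(n)
    for attempt in range(RETRY_CAP):
        tors = np.full((n, 3), 180.0)
        tors[:fl, 0], tors[:fl, 1] = flank_pp
        tors[fl + spec.loop_length:, 0] = flank_pp[0]
        tors[fl + spec.loop_length:, 1] = flank_pp[1]
        tors[fl:fl + spec.loop_length] = _loop_torsions(spec, rng)
        st = chain_from_torsions(tors, seq, spec.chain_id)
        seg = SegmentSpec(spec.chain_id, fl + 1, fl + spec.loop_length)
        span = np.linalg.norm(st.coords[fl - 1, 1] - st.coords[fl + spec.loop_length, 1])
        span_ok = span < MAX_SPAN_RATIO * 3.81 * (spec.loop_length + 1)
        if clash_score(st) < CLASH_BUDGET and span_ok:
            if spec.recipe == "random-rama":
                refined = _refine_native(st, seg, rng)
                if clash_score(refined) < CLASH_BUDGET:
                    return refined, seg
                return st, seg
            return st, seg
        if spec.recipe != "random-rama":
            raise ValueError(f"preset {spec.recipe!r} is invalid at length "
                             f"{spec.loop_length} (clash or over-extended)")
    raise ValueError("could not draw a clash-free loop within the retry cap")


def make_two_segment_fixture(loop_length: int = 8, seed: int = 0):
    """Two chains whose loops interact (>= 1 inter-loop CA pair < 8 A).

    Chain B is a rotated copy of an independently drawn fixture, placed so
    the two loop centroids face each other; placement is re-drawn until the
    contact criterion holds and the complex is clash-free.
    """
    rng = np.random.default_rng(seed)
    sa, sega = make_fixture(FixtureSpec(loop_length, "random-rama",
                                        int(rng.integers(2 ** 31)),
                                        chain_id="A"))
    sb, segb = make_fixture(FixtureSpec(loop_length, "random-rama",
                                        int(rng.integers(2 ** 31)),
                                        chain_id="B"))
    ia = sa.segment_indices(sega)
    ib = sb.segment_indices(segb)
    ca_a = sa.coords[ia, 1]
    # only the rigid placement of chain B is re-drawn on failure: B is
    # rotated so its loop faces A's loop, then approaches along the loop
    # normal until first inter-chain contact (~4 A)
    from scipy.spatial.transform import Rotation
    atoms_a = sa.coords.reshape(-1, 3)
    clash_intra = clash_score(sa) + clash_score(sb)
    u_a = ca_a.mean(axis=0) - atoms_a.mean(axis=0)
    u_a = u_a / np.linalg.norm(u_a)
    cent_b = sb.coords.reshape(-1, 3).mean(axis=0)
    u_b = sb.coords[ib, 1].mean(axis=0) - cent_b
    u_b = u_b / np.linalg.norm(u_b)
    base_rot, _ = Rotation.align_vectors([-u_a], [u_b])
    for attempt in range(RETRY_CAP):
        spin = Rotation.from_rotvec(rng.uniform(0, 2 * np.pi) * u_a)
        R = (spin * base_rot).as_matrix()
        cb0 = ((sb.coords.reshape(-1, 3) - cent_b) @ R.T).reshape(sb.coords.shape)
        # start with B's loop centroid 45 A out along A's loop normal
        start = (ca_a.mean(axis=0) + 45.0 * u_a) - cb0[ib, 1].mean(axis=0)
        atoms_b0 = cb0.reshape(-1, 3) + start
        t_hit = None
        for t in np.arange(0.0, 44.0, 0.25):
            dmin_all = np.min(np.linalg.norm(
                atoms_a[:, None] - (atoms_b0[None] - t * u_a), axis=-1))
            if dmin_all < 4.1:
                t_hit = t - 0.25
                break
        if t_hit is None:
            continue
        cb = cb0 + start - t_hit * u_a
        merged = BackboneStructure(
            np.concatenate([sa.coords, cb]),
            np.concatenate([sa.resnums, sb.resnums]),
            np.concatenate([sa.chains, sb.chains]),
            sa.sequence + sb.sequence)
        dmin = np.min(np.linalg.norm(
            merged.coords[ia, 1][:, None] - merged.coords[len(sa) + ib, 1][None],
            axis=-1))
        if dmin < 8.0 and clash_score(merged) < clash_intra + 0.05:
            merged.chain_breaks = merged.detect_chain_breaks()
            return merged, [sega, segb]
    raise ValueError("could not place interacting segments within retry cap")


def make_benchmark_cases(n_cases: int, lengths=(6,), seed: int = 0,
                         n_two_segment: int = 0) -> list:
    """BenchmarkCase list with native structures and loop segments."""
    if n_cases < 1:
        raise ValueError("need at least one case")
    cases = []
    rng = np.random.default_rng(seed)
    for i in range(n_cases - n_two_segment):
        L = int(lengths[i % len(lengths)])
        st, seg = make_fixture(FixtureSpec(L, "random-rama",
                                           int(rng.integers(2 ** 31))))
        cases.append(BenchmarkCase(f"case{i:02d}", st, [seg]))
    for j in range(n_two_segment):
        st, segs = make_two_segment_fixture(
            int(lengths[j % len(lengths)]), int(rng.integers(2 ** 31)))
        cases.append(BenchmarkCase(f"pair{j:02d}", st, segs))
    return cases


def make_benchmark_set(n_cases: int, lengths, seed: int, out_dir,
                       n_two_segment: int = 0) -> Path:
    """Write native PDBs + a YAML manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cases = make_benchmark_cases(n_cases, lengths, seed, n_two_segment)
    manifest = []
    for case in cases:
        pdb = out / f"{case.case_id}.pdb"
        write_pdb(case.native, pdb)
        manifest.append({
            "case_id": case.case_id,
            "pdb": pdb.name,
            "segments": [f"{s.chain_id}:{s.start}-{s.end}" for s in case.segments],
        })
    path = out / "manifest.yaml"
    path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return path


def make_fragment_sources(n_structures: int, natives=None, seed: int = 0,
                          length: int = 30, noise_deg: float = 0.0) -> dict:
    """Decoy fragment/loophash sources, optionally with native copies.

    Returns id -> BackboneStructure.  Decoys are random-Ramachandran
    chains; each entry of ``natives`` (id -> structure) is included under
    ``native_<id>`` with independent Gaussian torsion noise of
    ``noise_deg`` degrees (0 = exact copy), so homolog inclusion/exclusion
    regimes and graded fragment degradation are both constructible.
    """
    if n_structures < 1:
        raise ValueError("need at least one source structure")
    rng = np.random.default_rng(seed)
    tables = default_tables()
    out = {}
    for i in range(n_structures):
        tors = np.full((length, 3), 180.0)
        phi, psi = tables.sample(rng, "A", size=length)
        tors[:, 0], tors[:, 1] = phi, psi
        out[f"decoy{i:02d}"] = chain_from_torsions(
            tors, _sequence(length, offset=i % len(ALPHABET)))
    for nid, st in (natives or {}).items():
        from .structure import torsions_from_coords
        tors = torsions_from_coords(st)
        tors[~np.isfinite(tors)] = 180.0
        if noise_deg > 0:
            tors[:, :2] += rng.normal(0.0, noise_deg, tors[:, :2].shape)
        out[f"native_{nid}"] = chain_from_torsions(tors, st.sequence)
    return out
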