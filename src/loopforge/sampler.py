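"""Monte Carlo loop-modeling protocol.

Each trajectory initializes the target segment (idealized extended or
randomized torsions), then runs ``outer_cycles`` x ``inner_cycles`` of
sampling moves with Metropolis acceptance on the simplified backbone
energy under a geometric temperature schedule.  Four move types are
available:

* ``fkic``  — fragment insertion at nonpivot positions + analytic KIC
  closure of the three pivots;
* ``lhkic`` — loophash query by the 6D span transform, loop application
  (optionally mutating the sequence) + KIC closure;
* ``kic``   — nonpivot torsions drawn independently from residue-class
  Ramachandran tables + KIC closure (fragment-free baseline);
* ``ccd``   — fragment insertion closed by cyclic coordinate descent
  (modifies all segment torsions; comparator baseline).

A failed move (no closure solutions, empty loophash query, CCD
non-closure) counts as a rejected Metropolis step.  The per-trajectory
record is the lowest-energy *closed* structure seen; coordinates outside
the segment are never touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fragments import (FragmentLibrary, merge_fragment_torsions,
                        pick_fragment)
from .kic import (ClosureProblem, apply_solution, ccd_close, rama_filter,
                  select_pivots, solve_closure)
from .loophash import LoopHashDB, query_loophash
from .rama import default_tables
from .scoring import (EnergyWeights, RestraintSet, ScoreBreakdown,
                      restraint_satisfaction, score_structure)
from .structure import (BackboneStructure, SegmentSpec, backbone_rmsd,
                        segment_rigid_transform, set_segment_torsions,
                        torsions_from_coords)

MODES = ("fkic", "lhkic", "kic", "ccd")


@dataclass
class SamplerConfig:
    mode: str = "fkic"
    n_models: int = 500
    outer_cycles: int = 10
    inner_cycles: int = 10
    temp_start: float = 2.0
    temp_end: float = 0.6
    seed: int = 0
    weights: EnergyWeights = field(default_factory=EnergyWeights)
    restraints: RestraintSet | None = None
    mutate_on_lhkic: bool = False
    init: str = "extended"           # or "random"
    rama_threshold: float = 1e-4
    solution_selection: str = "energy"  # or "random"
    loophash_radius: int = 1
    ccd_tol: float = 0.1
    ccd_max_iters: int = 30
    library: FragmentLibrary | dict | None = None
    db: LoopHashDB | None = None

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if self.temp_start <= 0 or self.temp_end <= 0:
            raise ValueError("temperatures must be > 0")

    def temperature(self, outer: int) -> float:
        if self.outer_cycles <= 1:
            return self.temp_start
        ratio = (self.temp_end / self.temp_start) ** (outer / (self.outer_cycles - 1))
        return self.temp_start * ratio

    def library_for(self, segment: SegmentSpec) -> FragmentLibrary:
        if isinstance(self.library, dict):
            return self.library[(segment.chain_id, segment.start, segment.end)]
        if self.library is None:
            raise ValueError("sampler mode needs a fragment library")
        return self.library


@dataclass
class ModelRecord:
    structure: BackboneStructure | None
    score: ScoreBreakdown | None
    rmsd: float | None
    restraint_satisfaction: float | None
    closure_residual: float | None
    seed: int
    stats: dict
    failed: bool = False
    move_info: dict | None = None  # proposal torsions + pivots of the
    # move that produced the recorded structure


def initialize_segment(structure: BackboneStructure, segment: SegmentSpec,
                       rng: np.random.Generator | None = None,
                       init: str = "extended") -> BackboneStructure:
    """Rebuild the segment with ideal geometry in an extended (phi/psi =
    180) or Ramachandran-randomized conformation; leaves the downstream
    junction broken for the sampler to close."""
    L = segment.length
    if init == "extended":
        tors = np.full((L, 3), 180.0)
    elif init == "random":
        if rng is None:
            raise ValueError("randomized init needs an rng")
        tables = default_tables()
        idx = structure.segment_indices(segment)
        tors = np.full((L, 3), 180.0)
        for k, i in enumerate(idx):
            phi, psi = tables.sample(rng, structure.sequence[i])
            tors[k, 0], tors[k, 1] = phi, psi
    else:
        raise ValueError(f"unknown init mode {init!r}")
    return set_segment_torsions(structure, segment, tors)


# ---------------------------------------------------------------------------
# moves: each returns (structure, closure_residual) or (None, None)
# ---------------------------------------------------------------------------

def _closure_step(structure, segment, proposed_torsions, rng, config,
                  sequence=None):
    """Common tail of every KIC-based move: pivots, closure, screening,
    random tie-break, rebuild."""
    pivots = select_pivots(segment, rng)
    seq = structure.sequence
    if sequence is not None:
        idx = structure.segment_indices(segment)
        s = list(seq)
        for k, i in enumerate(idx):
            s[i] = sequence[k]
        seq = "".join(s)
    problem = ClosureProblem.from_structure(structure, segment, pivots,
                                            torsions=proposed_torsions)
    i_mid = structure.index_of(segment.chain_id, pivots.pivot_resnums[1])
    i1 = structure.index_of(segment.chain_id, pivots.pivot_resnums[0])
    i3 = structure.index_of(segment.chain_id, pivots.pivot_resnums[2])
    pivot_aa = seq[i1] + seq[i_mid] + seq[i3]
    solutions = solve_closure(problem)
    solutions = rama_filter(solutions, pivot_aa, config.rama_threshold)
    if len(solutions) == 0:
        return None, None
    if config.solution_selection == "energy" and len(solutions) > 1:
        # greedy tie-break: rebuild every surviving solution and keep the
        # best-scoring one (the random variant matches the original
        # stochastic choice and remains available)
        best_k, best_e, best_new = 0, np.inf, None
        for k in range(len(solutions)):
            cand = apply_solution(structure, segment, pivots, solutions, k)
            e = score_structure(cand, config.weights, config.restraints).total
            if e < best_e:
                best_k, best_e, best_new = k, e, cand
        k, new = best_k, best_new
    else:
        k = int(rng.integers(len(solutions)))
        new = apply_solution(structure, segment, pivots, solutions, k)
    if sequence is not None:
        s = list(new.sequence)
        for kk, i in enumerate(new.segment_indices(segment)):
            s[i] = sequence[kk]
        new.sequence = "".join(s)
    info = {"residual": solutions.closure_residuals[k],
            "proposal": np.array(proposed_torsions, float),
            "pivots": pivots, "segment": segment}
    return new, info


def fkic_move(structure: BackboneStructure, segment: SegmentSpec,
              library: FragmentLibrary, rng: np.random.Generator,
              config: SamplerConfig):
    """Fragment pick -> torsion insertion -> KIC closure."""
    size, start, frag = pick_fragment(library, rng, target=segment)
    current = torsions_from_coords(structure, segment)
    current[~np.isfinite(current)] = 180.0
    proposed = merge_fragment_torsions(current, segment, library, start, frag)
    return _closure_step(structure, segment, proposed, rng, config)


def lhkic_move(structure: BackboneStructure, segment: SegmentSpec,
               db: LoopHashDB, rng: np.random.Generator,
               config: SamplerConfig, mutate: bool = False):
    """Loophash query by span transform -> loop application -> KIC closure."""
    tr = segment_rigid_transform(structure, segment.start - 1, segment.end + 1,
                                 chain_id=segment.chain_id)
    entries = query_loophash(db, tr, segment.length, config.loophash_radius)
    if not entries:
        return None, None
    entry = entries[int(rng.integers(len(entries)))]
    current = torsions_from_coords(structure, segment)
    current[~np.isfinite(current)] = 180.0
    proposed = current.copy()
    proposed[1:-1] = entry.torsions[1:-1]
    seq = entry.aa if mutate else None
    return _closure_step(structure, segment, proposed, rng, config, sequence=seq)


def rama_kic_move(structure: BackboneStructure, segment: SegmentSpec,
                  rng: np.random.Generator, config: SamplerConfig):
    """Nonpivot torsions from residue-class Ramachandran draws + closure."""
    tables = default_tables()
    idx = structure.segment_indices(segment)
    current = torsions_from_coords(structure, segment)
    current[~np.isfinite(current)] = 180.0
    proposed = current.copy()
    for k, i in enumerate(idx):
        phi, psi = tables.sample(rng, structure.sequence[i])
        proposed[k, 0], proposed[k, 1] = phi, psi
        proposed[k, 2] = 180.0
    return _closure_step(structure, segment, proposed, rng, config)


def ccd_move(structure: BackboneStructure, segment: SegmentSpec,
             library: FragmentLibrary, rng: np.random.Generator,
             config: SamplerConfig):
    """Fragment insertion closed by CCD (modifies all segment torsions)."""
    size, start, frag = pick_fragment(library, rng, target=segment)
    current = torsions_from_coords(structure, segment)
    current[~np.isfinite(current)] = 180.0
    proposed = merge_fragment_torsions(current, segment, library, start, frag)
    broken = set_segment_torsions(structure, segment, proposed)
    result = ccd_close(broken, segment, max_iters=config.ccd_max_iters,
                       tol=config.ccd_tol)
    if result.break_distance > config.ccd_tol:
        return None, None
    info = {"residual": result.break_distance, "proposal": proposed,
            "pivots": None, "segment": segment}
    return result.structure, info


def _do_move(structure, segment, rng, config):
    if config.mode == "fkic":
        return fkic_move(structure, segment, config.library_for(segment),
                         rng, config)
    if config.mode == "lhkic":
        if config.db is None:
            raise ValueError("lhkic mode needs a loophash database")
        return lhkic_move(structure, segment, config.db, rng, config,
                          mutate=config.mutate_on_lhkic)
    if config.mode == "kic":
        return rama_kic_move(structure, segment, rng, config)
    return ccd_move(structure, segment, config.library_for(segment), rng, config)


# ---------------------------------------------------------------------------
# protocol
# ---------------------------------------------------------------------------

def metropolis_accept(delta_e: float, temperature: float,
                      rng: np.random.Generator) -> bool:
    """Energy decreases are always accepted; increases with P = exp(-dE/T)."""
    if delta_e <= 0:
        return True
    return rng.random() < np.exp(-delta_e / temperature)

def run_trajectory(structure: BackboneStructure, segments, config: SamplerConfig,
                   seed: int, reference: BackboneStructure | None = None) -> ModelRecord:
    """One independent Metropolis trajectory; returns its best-energy model."""
    segments = [segments] if isinstance(segments, SegmentSpec) else list(segments)
    rng = np.random.default_rng(seed)
    current = structure
    for seg in segments:
        current = initialize_segment(current, seg, rng, config.init)
    e_cur = score_structure(current, config.weights, config.restraints).total
    best = None
    best_info = None
    stats = {"proposed": 0, "closed": 0, "accepted": 0}
    for outer in range(config.outer_cycles):
        T = config.temperature(outer)
        for _ in range(config.inner_cycles):
            seg = segments[int(rng.integers(len(segments)))] if len(segments) > 1 \
                else segments[0]
            stats["proposed"] += 1
            try:
                proposal, move_info = _do_move(current, seg, rng, config)
            except (ValueError, RuntimeError):
                proposal = None
            if proposal is None:
                continue  # failed move counts as a rejected step
            stats["closed"] += 1
            sc = score_structure(proposal, config.weights, config.restraints)
            if best is None or sc.total < best[0]:
                best = (sc.total, proposal, sc)
                best_info = move_info
            if metropolis_accept(sc.total - e_cur, T, rng):
                current, e_cur = proposal, sc.total
                stats["accepted"] += 1
    if best is None:
        return ModelRecord(None, None, None, None, None, seed, stats, failed=True)
    _, model, sc = best
    rmsd = None
    if reference is not None:
        rmsd = backbone_rmsd(model, reference,
                             segments if len(segments) > 1 else segments[0])
    sat = None
    if config.restraints is not None and len(config.restraints) > 0:
        sat = restraint_satisfaction(model, config.restraints)
    return ModelRecord(model, sc, rmsd, sat, best_info["residual"], seed,
                       stats, move_info=best_info)


def run_monte_carlo(structure: BackboneStructure, segment, config: SamplerConfig,
                    reference: BackboneStructure | None = None) -> list:
    """n_models independent trajectories; trajectory i uses seed + i."""
    return [run_trajectory(structure, segment, config, config.seed + i, reference)
            for i in range(config.n_models)]
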