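"""Desk-scale pull-into-place (PIP) design loop.

Three stages: (1) restrained backbone generation — the sampler runs with
harmonic coordinate restraints pulling functional atoms toward target
positions, per segment-length variant; (2) sequence adoption — segment
sequences come from the loophash entries applied during sampling
(the stand-in for rotamer-based sequence design, which needs all-atom
models); (3) unrestrained re-prediction — FKIC runs without restraint
energy and each candidate is judged by the energy gap between models
that place the restrained atoms correctly (< 1 A restraint
satisfaction) and models that do not (> 2 A); the 1-2 A band joins
neither class.  Candidates are compared only within the same length
variant, and multi-metric selection uses exact Pareto fronts with
crowding-distance subsampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .fragments import build_fragment_library
from .sampler import SamplerConfig, run_monte_carlo
from .scoring import (SATISFIED_CUTOFF, UNSATISFIED_CUTOFF, RestraintSet,
                      restraint_satisfaction)
from .structure import BackboneStructure, SegmentSpec


@dataclass
class DesignTask:
    start: BackboneStructure
    segment: SegmentSpec
    restraints: RestraintSet
    length_deltas: tuple = (0,)
    keep_per_delta: int = 10

    def __post_init__(self):
        for d in self.length_deltas:
            if self.segment.length + d < 3:
                raise ValueError(f"length delta {d} makes the segment too short")
            if d > 0:
                raise ValueError("only shortening deltas (0..-6) are supported")

    def segment_for(self, delta: int) -> SegmentSpec:
        return SegmentSpec(self.segment.chain_id, self.segment.start,
                           self.segment.end + delta)


@dataclass
class DesignCandidate:
    candidate_id: str
    model: BackboneStructure
    segment: SegmentSpec
    delta: int
    sequence: str
    metrics: dict
    stage: str = "generate"
    parent: str | None = None


def _shortened_start(task: DesignTask, delta: int) -> BackboneStructure:
    """Delete |delta| residues from the segment end (renumbering the rest)."""
    if delta == 0:
        return task.start
    st = task.start
    idx = st.segment_indices(task.segment)
    drop = set(int(i) for i in idx[delta:])
    keep = [i for i in range(len(st)) if i not in drop]
    coords = st.coords[keep]
    resnums = []
    shift = 0
    for i in keep:
        if i == idx[-1] + 1:
            shift = delta
        resnums.append(int(st.resnums[i]) + (delta if i > idx[-1] else 0))
    out = BackboneStructure(coords, np.array(resnums), st.chains[keep],
                            "".join(st.sequence[i] for i in keep))
    out.chain_breaks = out.detect_chain_breaks()
    return out


def generate_restrained_backbones(task: DesignTask, config: SamplerConfig) -> list:
    """Stage 1: restrained sampling per length delta.

    The sampler (LHKIC by default, per the supplied config) runs with the
    task's restraints active; candidates are tagged by delta and never
    ranked across deltas.
    """
    candidates = []
    for delta in task.length_deltas:
        seg = task.segment_for(delta)
        start = _shortened_start(task, delta)
        cfg = replace(config, restraints=task.restraints)
        records = run_monte_carlo(start, seg, cfg)
        for i, rec in enumerate(records):
            if rec.failed:
                continue
            seq = "".join(rec.structure.sequence[j]
                          for j in rec.structure.segment_indices(seg))
            candidates.append(DesignCandidate(
                f"d{delta}_m{i}", rec.structure, seg, delta, seq,
                metrics={
                    "total": rec.score.total,
                    "rama": rec.score.rama,
                    "clash": rec.score.clash,
                    "restraint_satisfaction":
                        restraint_satisfaction(rec.structure, task.restraints),
                }))
    return candidates


def filter_by_restraint_satisfaction(candidates, keep_n: int) -> list:
    """Keep the keep_n best-satisfying candidates within each delta
    (stable order within ties)."""
    if keep_n <= 0:
        raise ValueError("keep_n must be positive")
    out = []
    deltas = sorted({c.delta for c in candidates}, reverse=True)
    for d in deltas:
        pool = [c for c in candidates if c.delta == d]
        ranked = sorted(pool, key=lambda c: c.metrics["restraint_satisfaction"])
        out.extend(ranked[:keep_n])
    return out


def adopt_fragment_sequences(candidate: DesignCandidate) -> DesignCandidate:
    """Stage 2: the candidate keeps the segment sequence accumulated from
    loophash mutations during sampling (already stored on the model);
    returns the candidate with its sequence field synchronized."""
    seq = "".join(candidate.model.sequence[j]
                  for j in candidate.model.segment_indices(candidate.segment))
    candidate.sequence = seq
    candidate.stage = "design"
    return candidate


def pareto_select(candidates, metric_names, max_out: int | None = None) -> list:
    """Exact non-dominated set under the named metrics (all minimized).

    Ties on every metric keep both candidates.  If the front exceeds
    ``max_out`` it is subsampled by crowding distance (extremes first).
    """
    for c in candidates:
        for m in metric_names:
            if m not in c.metrics:
                raise KeyError(f"candidate {c.candidate_id} lacks metric {m!r}")
    vals = np.array([[c.metrics[m] for m in metric_names] for c in candidates])
    n = len(candidates)
    keep = []
    for i in range(n):
        dominated = False
        for j in range(n):
            if j == i:
                continue
            if np.all(vals[j] <= vals[i]) and np.any(vals[j] < vals[i]):
                dominated = True
                break
        if not dominated:
            keep.append(i)
    front = [candidates[i] for i in keep]
    if max_out is None or len(front) <= max_out:
        return front
    fv = vals[keep]
    crowd = np.zeros(len(keep))
    for m in range(fv.shape[1]):
        order = np.argsort(fv[:, m], kind="stable")
        crowd[order[0]] = crowd[order[-1]] = np.inf
        span = fv[order[-1], m] - fv[order[0], m]
        if span <= 0:
            continue
        for k in range(1, len(order) - 1):
            crowd[order[k]] += (fv[order[k + 1], m] - fv[order[k - 1], m]) / span
    pick = np.argsort(-crowd, kind="stable")[:max_out]
    return [front[int(i)] for i in sorted(pick)]


def boltzmann_select(candidates, temperature: float, n: int,
                     rng: np.random.Generator) -> list:
    """Sample n candidates without replacement with P proportional to
    exp(-E/T) on the 'total' metric."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if n > len(candidates):
        raise ValueError("cannot select more candidates than the pool holds")
    energies = np.array([c.metrics["total"] for c in candidates], float)
    remaining = list(range(len(candidates)))
    chosen = []
    for _ in range(n):
        e = energies[remaining]
        logw = -(e - e.min()) / temperature
        w = np.exp(logw)
        w = w / w.sum()
        pick = int(rng.choice(len(remaining), p=w))
        chosen.append(remaining.pop(pick))
    return [candidates[i] for i in chosen]


def score_gap(energies, satisfactions):
    """Gap = min energy of unsatisfied models minus min energy of satisfied.

    Models with satisfaction in the 1-2 A band belong to neither class.
    Returns (gap, n_satisfied, n_unsatisfied, n_ambiguous); gap is None
    when no model is satisfied and +inf when every classified model is.
    """
    sats, unsats, amb = [], [], 0
    for e, s in zip(energies, satisfactions):
        if s < SATISFIED_CUTOFF:
            sats.append(e)
        elif s > UNSATISFIED_CUTOFF:
            unsats.append(e)
        else:
            amb += 1
    if not sats:
        return None, 0, len(unsats), amb
    gap = (min(unsats) - min(sats)) if unsats else np.inf
    return float(gap), len(sats), len(unsats), amb


@dataclass
class GapReport:
    candidate_id: str
    score_gap: float | None        # min E(unsatisfied) - min E(satisfied)
    n_satisfied: int
    n_unsatisfied: int
    n_ambiguous: int
    best_model_satisfied: bool     # global minimum-energy model is satisfied
    failure: str | None = None


def predict_and_gap(candidates, task: DesignTask, config: SamplerConfig,
                    sources) -> list:
    """Stage 3: per candidate, unrestrained FKIC re-prediction + score gap.

    Restraints are used only for *measurement*: models split into
    satisfied (< 1 A) and unsatisfied (> 2 A) classes, the 1-2 A band is
    excluded, and the gap is min unsatisfied energy minus min satisfied
    energy (positive = the satisfied basin is lower).  Candidates whose
    every model is satisfied rank highest (gap +inf); candidates with no
    satisfied model are flagged failures.  Reports are sorted by gap.
    """
    reports = []
    for cand in candidates:
        lib = build_fragment_library(
            sources, cand.sequence, sizes=(3,),
            start_resnum=cand.segment.start, chain_id=cand.segment.chain_id)
        cfg = replace(config, mode="fkic", restraints=None, library=lib, db=None)
        records = run_monte_carlo(cand.model, cand.segment, cfg)
        ok = [r for r in records if not r.failed]
        energies = [r.score.total for r in ok]
        satisfactions = [restraint_satisfaction(r.structure, task.restraints)
                         for r in ok]
        gap, n_sat, n_unsat, n_amb = score_gap(energies, satisfactions)
        if gap is None:
            reports.append(GapReport(cand.candidate_id, None, 0, n_unsat,
                                     n_amb, False, failure="no satisfied models"))
            continue
        sat_min = min(e for e, s in zip(energies, satisfactions)
                      if s < SATISFIED_CUTOFF)
        reports.append(GapReport(cand.candidate_id, gap, n_sat, n_unsat, n_amb,
                                 best_model_satisfied=sat_min <= min(energies)))
    reports.sort(key=lambda r: (-np.inf if r.score_gap is None else r.score_gap),
                 reverse=True)
    return reports
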