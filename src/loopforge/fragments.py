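"""Fragment libraries: construction, picking, insertion and the chord
fragment-distance statistic.

A fragment is a run of 1, 3 or 9 consecutive residues carrying coupled
phi/psi/omega torsions (and amino-acid identities) extracted from source
structures.  Libraries group fragments into *alignment frames*: for each
start position along the query window, the candidate source windows are
ranked by a BLOSUM62 similarity sum to the query sub-sequence and the
best ``max_per_frame`` (default 200) kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from .structure import (BackboneStructure, SegmentSpec, set_segment_torsions,
                        torsions_from_coords)

FRAGMENT_SIZES = (1, 3, 9)
_BLOSUM62 = None


def _blosum62():
    global _BLOSUM62
    if _BLOSUM62 is None:
        _BLOSUM62 = substitution_matrices.load("BLOSUM62")
    return _BLOSUM62


@dataclass(frozen=True)
class Fragment:
    """A run of per-position torsions with amino-acid identities."""

    torsions: np.ndarray  # (length, 3) phi/psi/omega degrees
    aa: str
    source_id: str

    def __post_init__(self):
        t = np.asarray(self.torsions, float)
        object.__setattr__(self, "torsions", t)
        if t.ndim != 2 or t.shape[1] != 3:
            raise ValueError("fragment torsions must be (length, 3)")
        if len(self.aa) != len(t):
            raise ValueError("fragment sequence/torsion length mismatch")
        if not np.all(np.isfinite(t)):
            raise ValueError("fragment torsions must be finite")

    @property
    def length(self) -> int:
        return len(self.torsions)


@dataclass
class FragmentLibrary:
    """Frames of candidate fragments around a query window.

    ``frames[size][start]`` is the ranked fragment list for the alignment
    frame beginning at 1-based position ``start`` of the query sequence;
    ``start_resnum`` maps query position 1 to a residue number so frames
    can be laid onto a structure.
    """

    query_sequence: str
    frames: dict  # size -> {start position -> [Fragment, ...]}
    start_resnum: int = 1
    chain_id: str = "A"

    def sizes(self):
        return sorted(s for s, fr in self.frames.items() if fr)

    def frame_resnums(self, size: int, start: int):
        """Residue numbers covered by a frame."""
        r0 = self.start_resnum + start - 1
        return range(r0, r0 + size)

    def is_empty(self) -> bool:
        return not any(self.frames.get(s) for s in self.frames)


def window_similarity(window_aa: str, query_aa: str) -> float:
    """BLOSUM62 similarity sum between equal-length sequences."""
    m = _blosum62()
    if len(window_aa) != len(query_aa):
        raise ValueError("window/query length mismatch")
    return float(sum(m[a.upper(), b.upper()] for a, b in zip(window_aa, query_aa)))


def build_fragment_library(source_structures, query_sequence: str,
                           sizes=(3, 9), exclude_ids=(), max_per_frame: int = 200,
                           start_resnum: int = 1, chain_id: str = "A",
                           min_identity_exclude: float | None = None) -> FragmentLibrary:
    """Rank source windows against each query frame and keep the best.

    ``source_structures`` is a mapping id -> BackboneStructure (or an
    iterable of (id, structure) pairs).  Sources listed in ``exclude_ids``
    contribute nothing — this is how homologs are withheld.  Optionally,
    windows with sequence identity >= ``min_identity_exclude`` to the query
    window are dropped as trivial homologs.  Construction uses no RNG and
    is deterministic for fixed inputs.
    """
    if hasattr(source_structures, "items"):
        sources = list(source_structures.items())
    else:
        sources = list(source_structures)
    sizes = tuple(sorted(set(int(s) for s in sizes)))
    if not set(sizes) <= set(FRAGMENT_SIZES):
        raise ValueError(f"sizes must be a subset of {FRAGMENT_SIZES}")
    if len(query_sequence) < min(sizes):
        raise ValueError("query shorter than the smallest fragment size")
    exclude = set(exclude_ids)

    per_source = []
    for sid, st in sources:
        if sid in exclude:
            continue
        tors = torsions_from_coords(st)
        per_source.append((sid, st.sequence, tors))
    if not per_source:
        warnings.warn("all fragment sources excluded: library is empty")
    order = {sid: k for k, (sid, _, _) in enumerate(per_source)}

    frames: dict = {s: {} for s in sizes}
    for size in sizes:
        for start in range(1, len(query_sequence) - size + 2):
            qwin = query_sequence[start - 1:start - 1 + size]
            candidates = []
            for sid, seq, tors in per_source:
                for w0 in range(len(seq) - size + 1):
                    t = tors[w0:w0 + size]
                    if not np.all(np.isfinite(t[:, :2])):
                        continue  # phi/psi undefined at a terminus
                    wa = seq[w0:w0 + size]
                    if min_identity_exclude is not None:
                        ident = sum(a == b for a, b in zip(wa, qwin)) / size
                        if ident >= min_identity_exclude:
                            continue
                    t = t.copy()
                    t[~np.isfinite(t)] = 180.0  # omega at a terminus
                    candidates.append((window_similarity(wa, qwin), sid, w0, wa, t))
            # stable ranking: score desc, ties by source order then position
            candidates.sort(key=lambda c: (-c[0], order[c[1]], c[2]))
            kept = [Fragment(t, wa, sid)
                    for _, sid, _, wa, t in candidates[:max_per_frame]]
            if kept:
                frames[size][start] = kept
    return FragmentLibrary(query_sequence, frames, start_resnum, chain_id)


def pick_fragment(library: FragmentLibrary, rng: np.random.Generator,
                  target: SegmentSpec | None = None):
    """Random (size class, frame, fragment) draw, uniform at each level.

    Only frames overlapping the target segment are eligible when a target
    is given.  Returns (size, frame_start, Fragment).
    """
    sizes = library.sizes()
    if not sizes:
        raise ValueError("empty fragment library")
    eligible = {}
    for size in sizes:
        for start, frags in library.frames[size].items():
            if not frags:
                continue
            if target is not None:
                r = library.frame_resnums(size, start)
                if r.stop <= target.start or r.start > target.end:
                    continue
            eligible.setdefault(size, []).append(start)
    if not eligible:
        raise ValueError("no frames overlap the target segment")
    classes = sorted(eligible)
    size = classes[int(rng.integers(len(classes)))]
    starts = sorted(eligible[size])
    start = starts[int(rng.integers(len(starts)))]
    frags = library.frames[size][start]
    frag = frags[int(rng.integers(len(frags)))]
    return size, start, frag


def merge_fragment_torsions(torsions: np.ndarray, segment: SegmentSpec,
                            library: FragmentLibrary, frame_start: int,
                            fragment: Fragment) -> np.ndarray:
    """Apply fragment torsions to the overlapping segment positions.

    ``torsions`` is the (segment length, 3) phi/psi/omega array of the
    segment; a new array is returned with the overlapped rows replaced by
    the fragment's values (a partially overlapping frame applies only the
    overlapping positions).  Raises if the frame is disjoint.
    """
    resnums = library.frame_resnums(fragment.length, frame_start)
    lo = max(resnums.start, segment.start)
    hi = min(resnums.stop - 1, segment.end)
    if lo > hi:
        raise ValueError("fragment frame is disjoint from the segment")
    out = np.array(torsions, float)
    for r in range(lo, hi + 1):
        out[r - segment.start] = fragment.torsions[r - resnums.start]
    return out


def insert_fragment_torsions(structure: BackboneStructure, segment: SegmentSpec,
                             library: FragmentLibrary, frame_start: int,
                             fragment: Fragment) -> BackboneStructure:
    """Insert a fragment into a structure's segment by forward kinematics.

    The overlapped residues take the fragment's phi/psi/omega exactly; the
    segment is rebuilt downstream of the insertion point, which generally
    breaks the chain at the segment's downstream junction (to be closed by
    KIC or CCD).  Atoms outside the segment are untouched.
    """
    current = torsions_from_coords(structure, segment)
    current[~np.isfinite(current)] = 180.0
    merged = merge_fragment_torsions(current, segment, library, frame_start,
                                     fragment)
    return set_segment_torsions(structure, segment, merged)


# ---------------------------------------------------------------------------
# chord distance
# ---------------------------------------------------------------------------

def chord_distance_sq(theta1, theta2):
    """Squared chord distance between two angles in degrees.

    D^2 = 2 - 2 cos(theta1 - theta2): 0 when the angles match exactly,
    4 when they differ by 180 degrees.
    """
    d = np.deg2rad(np.asarray(theta1, float) - np.asarray(theta2, float))
    return 2.0 - 2.0 * np.cos(d)


def mean_fragment_distance(torsions1, torsions2) -> float:
    """Mean chord distance <D> between paired phi/psi torsion runs.

    <D> = (1/n) sum_i [ D^2(phi1_i, phi2_i)/2 + D^2(psi1_i, psi2_i)/2 ],
    ranging 0 (identical) to 4 (uniform 180-degree offset).  Inputs are
    (n, >=2) arrays whose first two columns are phi and psi in degrees.
    """
    t1 = np.atleast_2d(np.asarray(torsions1, float))
    t2 = np.atleast_2d(np.asarray(torsions2, float))
    if t1.shape[0] != t2.shape[0]:
        raise ValueError("torsion runs must have equal length")
    dphi = chord_distance_sq(t1[:, 0], t2[:, 0])
    dpsi = chord_distance_sq(t1[:, 1], t2[:, 1])
    return float(np.mean(0.5 * dphi + 0.5 * dpsi))


def best_frame_distances(library: FragmentLibrary, native_torsions: np.ndarray,
                         segment: SegmentSpec, size: int = 3) -> list:
    """Per-frame minimum <D> between any library fragment and the native
    torsions it would overlap; used for fragment-quality analyses."""
    out = []
    for start, frags in sorted(library.frames.get(size, {}).items()):
        r = library.frame_resnums(size, start)
        lo, hi = max(r.start, segment.start), min(r.stop - 1, segment.end)
        if lo > hi or not frags:
            continue
        rows = slice(lo - segment.start, hi - segment.start + 1)
        frows = slice(lo - r.start, hi - r.start + 1)
        best = min(mean_fragment_distance(f.torsions[frows], native_torsions[rows])
                   for f in frags)
        out.append(best)
    return out


# ---------------------------------------------------------------------------
# plain-text serialization
# ---------------------------------------------------------------------------

def write_fragment_library(library: FragmentLibrary, path) -> None:
    """Tab-separated dialect: header then one row per fragment position
    (size, frame start, rank, source_id, position, aa, phi, psi, omega)."""
    lines = [f"#query\t{library.query_sequence}\t{library.start_resnum}\t{library.chain_id}"]
    for size in sorted(library.frames):
        for start in sorted(library.frames[size]):
            for k, frag in enumerate(library.frames[size][start]):
                for p in range(frag.length):
                    phi, psi, om = frag.torsions[p]
                    lines.append(
                        f"{size}\t{start}\t{k}\t{frag.source_id}\t{p}\t{frag.aa[p]}"
                        f"\t{phi:.6f}\t{psi:.6f}\t{om:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_fragment_library(path) -> FragmentLibrary:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("#query"):
        raise ValueError("not a fragment library file")
    _, qseq, start_resnum, chain_id = lines[0].split("\t")
    rows: dict = {}
    for line in lines[1:]:
        if not line.strip():
            continue
        size, start, k, sid, p, aa, phi, psi, om = line.split("\t")
        key = (int(size), int(start), int(k))
        rec = rows.setdefault(key, {"sid": sid, "aa": {}, "tor": {}})
        rec["aa"][int(p)] = aa
        rec["tor"][int(p)] = (float(phi), float(psi), float(om))
    frames: dict = {}
    for (size, start, k) in sorted(rows):
        rec = rows[(size, start, k)]
        npos = len(rec["aa"])
        tors = np.array([rec["tor"][p] for p in range(npos)])
        aa = "".join(rec["aa"][p] for p in range(npos))
        frames.setdefault(size, {}).setdefault(start, []).append(
            Fragment(tors, aa, rec["sid"]))
    return FragmentLibrary(qseq, frames, int(start_resnum), chain_id)
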