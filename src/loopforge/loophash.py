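"""Loophash: a database of loop conformations keyed by the 6D rigid
transform between their bounding residues.

Every contiguous window of a requested length in every source structure
contributes one entry, keyed by the transform between the backbone
frames of the residues immediately before and after the window.  The 6D
key (3 translation components in A, 3 intrinsic z-y-x Euler angles in
degrees) is bucketed on a fixed grid — default 1.0 A per translation
axis and 15 degrees per rotation axis — and queries return all entries
within a Chebyshev bucket radius.  Bucketing is wrap-aware in the Euler
angles.  Entries store per-position phi/psi/omega torsions plus the
window's amino acids, enabling LHKIC's simultaneous structure/sequence
sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import RigidTransform
from .structure import (BackboneStructure, SegmentSpec,
                        segment_rigid_transform, set_segment_torsions,
                        torsions_from_coords)

DEFAULT_TRANS_BIN = 1.0   # A
DEFAULT_ROT_BIN = 15.0    # degrees


def transform_6d(transform: RigidTransform) -> np.ndarray:
    """(tx, ty, tz, ez, ey, ex): translation + intrinsic z-y-x Euler angles."""
    e = Rotation.from_matrix(transform.rotation).as_euler("ZYX", degrees=True)
    return np.concatenate([transform.translation, e])


@dataclass(frozen=True)
class TransformKey:
    """Bucket indices of a 6D transform (3 translation, 3 rotation)."""

    trans_bins: tuple
    rot_bins: tuple

    @staticmethod
    def from_transform(transform: RigidTransform,
                       trans_bin: float = DEFAULT_TRANS_BIN,
                       rot_bin: float = DEFAULT_ROT_BIN) -> "TransformKey":
        v = transform_6d(transform)
        tb = tuple(int(np.floor(x / trans_bin)) for x in v[:3])
        n_rot = int(round(360.0 / rot_bin))
        rb = tuple(int(np.floor(((a + 180.0) % 360.0) / rot_bin)) % n_rot
                   for a in v[3:])
        return TransformKey(tb, rb)


@dataclass(frozen=True)
class LoopEntry:
    """A stored loop: per-position torsions + sequence + provenance."""

    torsions: np.ndarray  # (length, 3) phi/psi/omega degrees
    aa: str
    source_id: str

    def __post_init__(self):
        t = np.asarray(self.torsions, float)
        object.__setattr__(self, "torsions", t)
        if not np.all(np.isfinite(t)):
            raise ValueError("loop entry torsions must be finite")
        if len(self.aa) != len(t):
            raise ValueError("loop entry sequence/torsion length mismatch")

    @property
    def length(self) -> int:
        return len(self.torsions)


@dataclass
class LoopHashDB:
    """Per-length bucketed maps TransformKey -> [LoopEntry, ...]."""

    buckets: dict = field(default_factory=dict)  # length -> {key -> [entry]}
    keys_6d: dict = field(default_factory=dict)  # length -> [(vec6, entry)]
    trans_bin: float = DEFAULT_TRANS_BIN
    rot_bin: float = DEFAULT_ROT_BIN

    def lengths(self):
        return sorted(self.buckets)

    def n_entries(self, length: int | None = None) -> int:
        lengths = [length] if length is not None else self.lengths()
        return sum(len(v) for ln in lengths
                   for v in self.buckets.get(ln, {}).values())


def build_loophash_db(source_structures, lengths,
                      trans_bin: float = DEFAULT_TRANS_BIN,
                      rot_bin: float = DEFAULT_ROT_BIN) -> LoopHashDB:
    """Index every interior window of each requested length.

    A window of length L starting at internal residue i is keyed by the
    transform between the frames of residues i-1 and i+L (both must exist
    on the same chain).  Deterministic; no RNG.
    """
    if hasattr(source_structures, "items"):
        sources = list(source_structures.items())
    else:
        sources = list(source_structures)
    lengths = sorted(set(int(x) for x in lengths))
    if any(ln < 3 for ln in lengths):
        raise ValueError("loophash window lengths must be >= 3")
    db = LoopHashDB({}, {}, trans_bin, rot_bin)
    for ln in lengths:
        db.buckets[ln] = {}
        db.keys_6d[ln] = []
    n_added = 0
    for sid, st in sources:
        tors = torsions_from_coords(st)
        for ln in lengths:
            for i0 in range(1, len(st) - ln):  # window occupies i0 .. i0+ln-1
                i_before, i_after = i0 - 1, i0 + ln
                if st.chains[i_before] != st.chains[i_after]:
                    continue
                t = tors[i0:i0 + ln].copy()
                if not np.all(np.isfinite(t[:, :2])):
                    continue
                t[~np.isfinite(t)] = 180.0
                tr = segment_rigid_transform(
                    st, int(st.resnums[i_before]), int(st.resnums[i_after]),
                    chain_id=str(st.chains[i_before]))
                key = TransformKey.from_transform(tr, trans_bin, rot_bin)
                entry = LoopEntry(t, st.sequence[i0:i0 + ln],
                                  f"{sid}:{st.resnums[i0]}")
                db.buckets[ln].setdefault(key, []).append(entry)
                db.keys_6d[ln].append((transform_6d(tr), entry))
                n_added += 1
    if n_added == 0:
        warnings.warn("no valid windows found: loophash database is empty")
    return db


def _neighbor_keys(key: TransformKey, radius: int, rot_bin: float):
    n_rot = int(round(360.0 / rot_bin))
    rng = range(-radius, radius + 1)
    for dt0 in rng:
        for dt1 in rng:
            for dt2 in rng:
                for dr0 in rng:
                    for dr1 in rng:
                        for dr2 in rng:
                            yield TransformKey(
                                (key.trans_bins[0] + dt0,
                                 key.trans_bins[1] + dt1,
                                 key.trans_bins[2] + dt2),
                                ((key.rot_bins[0] + dr0) % n_rot,
                                 (key.rot_bins[1] + dr1) % n_rot,
                                 (key.rot_bins[2] + dr2) % n_rot))


def query_loophash(db: LoopHashDB, transform: RigidTransform, length: int,
                   radius: int = 1) -> list:
    """Entries in the query bucket and all buckets within ``radius``
    Chebyshev bucket steps (rotation axes wrap)."""
    if length not in db.buckets:
        raise KeyError(f"no loophash table for length {length}")
    key = TransformKey.from_transform(transform, db.trans_bin, db.rot_bin)
    out = []
    table = db.buckets[length]
    if radius == 0:
        return list(table.get(key, []))
    for k in _neighbor_keys(key, radius, db.rot_bin):
        out.extend(table.get(k, []))
    return out


def apply_loop_entry(structure: BackboneStructure, segment: SegmentSpec,
                     entry: LoopEntry, mutate: bool = False) -> BackboneStructure:
    """Apply a stored loop's torsions between the pivots.

    ``segment`` here is the pivot span (first to last pivot, inclusive) and
    must equal the entry length; torsions are applied to the residues
    strictly between the span ends, whose phi/psi are left for KIC.  With
    ``mutate`` the span residues also adopt the entry's amino acids.  The
    chain break at the downstream junction is left for closure.
    """
    if entry.length != segment.length:
        raise ValueError(
            f"entry length {entry.length} != pivot span length {segment.length}")
    tors = torsions_from_coords(structure, segment)
    tors[~np.isfinite(tors)] = 180.0
    tors[1:-1] = entry.torsions[1:-1]
    seq = entry.aa if mutate else None
    return set_segment_torsions(structure, segment, tors, sequence=seq)


# ---------------------------------------------------------------------------
# serialization: versioned TSV
# ---------------------------------------------------------------------------

_FORMAT_VERSION = "loophash-tsv-1"


def write_loophash_db(db: LoopHashDB, path) -> None:
    lines = [f"#{_FORMAT_VERSION}\t{db.trans_bin}\t{db.rot_bin}"]
    for ln in db.lengths():
        for vec, entry in db.keys_6d[ln]:
            v = "\t".join(f"{x:.17g}" for x in vec)
            t = ";".join(",".join(f"{a:.17g}" for a in row) for row in entry.torsions)
            lines.append(f"{ln}\t{entry.source_id}\t{entry.aa}\t{v}\t{t}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_loophash_db(path) -> LoopHashDB:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith(f"#{_FORMAT_VERSION}"):
        raise ValueError("unrecognized loophash file format")
    _, tb, rb = lines[0].lstrip("#").split("\t")
    db = LoopHashDB({}, {}, float(tb), float(rb))
    for line in lines[1:]:
        if not line.strip():
            continue
        ln_s, sid, aa, *rest = line.split("\t")
        ln = int(ln_s)
        vec = np.array([float(x) for x in rest[:6]])
        tors = np.array([[float(a) for a in row.split(",")]
                         for row in rest[6].split(";")])
        entry = LoopEntry(tors, aa, sid)
        tr = RigidTransform(Rotation.from_euler("ZYX", vec[3:], degrees=True).as_matrix(),
                            vec[:3])
        key = TransformKey.from_transform(tr, db.trans_bin, db.rot_bin)
        db.buckets.setdefault(ln, {}).setdefault(key, []).append(entry)
        db.keys_6d.setdefault(ln, []).append((vec, entry))
    return db
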