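"""Backbone structure container, PDB IO and torsion-space utilities.

A :class:`BackboneStructure` holds the four backbone heavy atoms
(N, CA, C, O) of every residue, in chain order, together with residue
numbers, one-letter amino-acid codes and chain identifiers.  It is the
universal currency passed between every other module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .geometry import (IDEAL_GEOMETRY, InternalGeometry, RigidTransform,
                       bond_angle, build_chain, dihedral, frame_to_frame,
                       kabsch_superpose, place_atom, residue_frame, wrap_angle)

BACKBONE_ATOMS = ("N", "CA", "C", "O")
# C(i)-N(i+1) peptide-bond distance window used for chain-break detection
PEPTIDE_BOND = 1.33
PEPTIDE_BOND_TOL = 0.25

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class StructureError(ValueError):
    """Structured error for malformed or inconsistent backbone input."""


@dataclass(frozen=True)
class SegmentSpec:
    """A contiguous residue range on one chain, 1-based and inclusive."""

    chain_id: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if self.length < 3:
            raise ValueError("segment must span at least 3 residues")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @staticmethod
    def parse(text: str) -> "SegmentSpec":
        """Parse 'A:34-45' notation."""
        chain, _, rng = text.partition(":")
        lo, _, hi = rng.partition("-")
        return SegmentSpec(chain, int(lo), int(hi))


@dataclass
class BackboneStructure:
    """Ordered backbone (N, CA, C, O) atoms of a polypeptide.

    coords has shape (n_residues, 4, 3) with the atom axis ordered as
    ``BACKBONE_ATOMS``.  ``chain_breaks`` lists indices i where the
    C(i)-N(i+1) peptide bond is outside the accepted window.
    """

    coords: np.ndarray
    resnums: np.ndarray
    chains: np.ndarray
    sequence: str
    chain_breaks: tuple = ()
    # bookkeeping that survives segment rebuilds: maps (chain, resnum) of a
    # broken downstream junction to its pre-break (phi_next, omega) torsions
    # so closure can reconstruct the anchor-consistent target geometry
    junction_torsions: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float)
        self.resnums = np.asarray(self.resnums, int)
        self.chains = np.asarray(self.chains)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (4, 3):
            raise StructureError("coords must have shape (n, 4, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite backbone coordinates")
        n = len(self.coords)
        if not (len(self.resnums) == len(self.chains) == len(self.sequence) == n):
            raise StructureError("residue annotation lengths disagree")

    def __len__(self) -> int:
        return len(self.coords)

    def copy(self) -> "BackboneStructure":
        return BackboneStructure(self.coords.copy(), self.resnums.copy(),
                                 self.chains.copy(), self.sequence,
                                 self.chain_breaks, dict(self.junction_torsions))

    # -- residue indexing -------------------------------------------------
    def index_of(self, chain_id: str, resnum: int) -> int:
        hits = np.flatnonzero((self.chains == chain_id) & (self.resnums == resnum))
        if len(hits) == 0:
            raise StructureError(f"residue {chain_id}:{resnum} not found")
        return int(hits[0])

    def segment_indices(self, segment: SegmentSpec) -> np.ndarray:
        idx = np.array([self.index_of(segment.chain_id, r)
                        for r in range(segment.start, segment.end + 1)])
        return idx

    def atom(self, i: int, name: str) -> np.ndarray:
        return self.coords[i, BACKBONE_ATOMS.index(name)]

    def set_atom(self, i: int, name: str, xyz) -> None:
        self.coords[i, BACKBONE_ATOMS.index(name)] = xyz

    def detect_chain_breaks(self) -> tuple:
        """Indices i where residue i+1 is not peptide-bonded to residue i."""
        c = self.coords[:-1, 2]
        n = self.coords[1:, 0]
        d = np.linalg.norm(c - n, axis=-1)
        same_chain = self.chains[:-1] == self.chains[1:]
        bad = (np.abs(d - PEPTIDE_BOND) > PEPTIDE_BOND_TOL) | ~same_chain
        return tuple(int(i) for i in np.flatnonzero(bad))


# ---------------------------------------------------------------------------
# PDB IO (via gemmi)
# ---------------------------------------------------------------------------

def read_pdb(path, model_index: int = 0) -> BackboneStructure:
    """Read backbone atoms from a PDB file.

    Side chains, waters and hetero records are ignored.  A missing backbone
    atom raises a :class:`StructureError` naming the residue, except for a
    missing O at a chain terminus, which is rebuilt from ideal geometry.
    Insertion codes are unsupported and rejected.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise StructureError(f"empty or missing PDB file: {path}")
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise StructureError(f"no models in {path}")
    model = st[model_index]

    coords, resnums, chains, seq = [], [], [], []
    pending_o = []  # residue indices whose O must be rebuilt
    for chain in model:
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            if info is None or not info.is_amino_acid():
                continue
            if res.het_flag == "H" and res.name == "HOH":
                continue
            if res.seqid.icode not in (" ", "", "\x00"):
                raise StructureError(
                    f"insertion codes unsupported: {chain.name}:{res.seqid.num}{res.seqid.icode}")
            pos = {}
            for atom in res:
                if atom.name in BACKBONE_ATOMS and atom.name not in pos:
                    pos[atom.name] = [atom.pos.x, atom.pos.y, atom.pos.z]
            missing = [a for a in BACKBONE_ATOMS if a not in pos]
            if missing == ["O"]:
                pending_o.append(len(coords))
                pos["O"] = [np.nan] * 3
            elif missing:
                raise StructureError(
                    f"residue {chain.name}:{res.seqid.num} missing backbone atom(s) "
                    f"{','.join(missing)}")
            coords.append([pos[a] for a in BACKBONE_ATOMS])
            resnums.append(res.seqid.num)
            chains.append(chain.name)
            seq.append(THREE_TO_ONE.get(res.name, "X"))
    if not coords:
        raise StructureError(f"no complete backbone residues in {path}")

    coords = np.asarray(coords, float)
    # rebuild any terminal O from ideal geometry (psi taken as trans)
    for i in pending_o:
        n, ca, c = coords[i, 0], coords[i, 1], coords[i, 2]
        coords[i, 3] = place_atom(n, ca, c, IDEAL_GEOMETRY.c_o,
                                  IDEAL_GEOMETRY.ang_ca_c_o, 0.0)
    s = BackboneStructure(coords, np.asarray(resnums), np.asarray(chains),
                          "".join(seq))
    s.chain_breaks = s.detect_chain_breaks()
    return s


def write_pdb(structure: BackboneStructure, path) -> None:
    """Write minimal ATOM/TER records (occupancy 1.00, B-factor 0.00)."""
    st = gemmi.Structure()
    st.name = "loopforge"
    model = gemmi.Model("1")
    chain_order = []
    chain_map = {}
    for i in range(len(structure)):
        cid = str(structure.chains[i])
        if cid not in chain_map:
            chain_map[cid] = gemmi.Chain(cid)
            chain_order.append(cid)
        res = gemmi.Residue()
        res.name = ONE_TO_THREE.get(structure.sequence[i], "ALA")
        res.seqid = gemmi.SeqId(int(structure.resnums[i]), " ")
        for j, name in enumerate(BACKBONE_ATOMS):
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(name[0])
            atom.occ = 1.0
            atom.b_iso = 0.0
            x, y, z = structure.coords[i, j]
            atom.pos = gemmi.Position(float(x), float(y), float(z))
            res.add_atom(atom)
        chain_map[cid].add_residue(res)
    for cid in chain_order:
        model.add_chain(chain_map[cid])
    st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string()
    Path(path).write_text(doc)


# ---------------------------------------------------------------------------
# Torsions
# ---------------------------------------------------------------------------

def torsions_from_coords(structure: BackboneStructure, segment: SegmentSpec | None = None):
    """phi/psi/omega triplets (degrees) for the segment (or all residues).

    Torsions undefined at a chain terminus are returned as NaN rather than
    invented.  omega(i) is the CA(i)-C(i)-N(i+1)-CA(i+1) dihedral.
    """
    C = structure.coords
    n = len(structure)
    full = np.full((n, 3), np.nan)
    if n > 1:
        same = structure.chains[:-1] == structure.chains[1:]
        full[1:, 0] = np.where(same, dihedral(C[:-1, 2], C[1:, 0],
                                              C[1:, 1], C[1:, 2]), np.nan)
        full[:-1, 1] = np.where(same, dihedral(C[:-1, 0], C[:-1, 1],
                                               C[:-1, 2], C[1:, 0]), np.nan)
        full[:-1, 2] = np.where(same, dihedral(C[:-1, 1], C[:-1, 2],
                                               C[1:, 0], C[1:, 1]), np.nan)
    if segment is None:
        return wrap_angle(full)
    return wrap_angle(full[structure.segment_indices(segment)])


def coords_from_torsions(anchor_frame, torsions,
                         geometry: InternalGeometry = IDEAL_GEOMETRY) -> np.ndarray:
    """Forward-kinematic chain building from three seed atoms.

    anchor_frame: (3, 3) seed atoms, interpreted as the (C(0), N(1), CA(1))
    triad of the first residue to be built; torsions: (n, 3) phi/psi/omega per
    residue (degrees).  The psi/omega of the final residue place the next
    residue's N/CA so the downstream junction is well defined.

    Returns backbone coords of shape (n, 4, 3) for the n built residues.
    O atoms are placed opposite the next N (dihedral psi - 180).
    """
    torsions = np.atleast_2d(np.asarray(torsions, float))
    geometry.validate()
    if torsions.size and not np.all(np.isfinite(torsions)):
        raise ValueError("non-finite torsion passed to chain builder")
    seed = np.asarray(anchor_frame, float)
    if torsions.size == 0 or torsions.shape[0] == 0:
        return np.zeros((0, 4, 3))
    g = geometry
    ics = []
    for phi, psi, omega in torsions:
        ics.append((g.ca_c, g.ang_n_ca_c, phi))    # C(i)
        ics.append((g.c_n, g.ang_ca_c_n, psi))     # N(i+1)
        ics.append((g.n_ca, g.ang_c_n_ca, omega))  # CA(i+1)
    chain = build_chain(seed, ics)
    # chain: [C0, N1, CA1, C1, N2, CA2, C2, ...]
    nres = torsions.shape[0]
    out = np.zeros((nres, 4, 3))
    for i in range(nres):
        out[i, 0] = chain[1 + 3 * i]      # N
        out[i, 1] = chain[2 + 3 * i]      # CA
        out[i, 2] = chain[3 + 3 * i]      # C
        out[i, 3] = place_atom(out[i, 0], out[i, 1], out[i, 2],
                               g.c_o, g.ang_ca_c_o, torsions[i, 1] - 180.0)
    return out


def set_segment_torsions(structure: BackboneStructure, segment: SegmentSpec,
                         torsions, geometry: InternalGeometry = IDEAL_GEOMETRY,
                         sequence: str | None = None) -> BackboneStructure:
    """Rebuild the segment from torsions, leaving the rest untouched.

    The segment is rebuilt forward from the upstream anchor residue with the
    supplied (n_seg, 3) phi/psi/omega torsions and ideal covalent geometry,
    which generally leaves a chain break at the downstream junction (to be
    closed by KIC or CCD).  Coordinates outside the segment are bit-identical
    to the input.  ``sequence`` optionally replaces the segment sequence.
    """
    idx = structure.segment_indices(segment)
    i0 = idx[0]
    if i0 == 0 or structure.chains[i0 - 1] != segment.chain_id:
        raise StructureError("segment at N-terminus: no upstream anchor residue")
    torsions = np.asarray(torsions, float)
    if torsions.shape != (segment.length, 3):
        raise ValueError(f"expected ({segment.length}, 3) torsions, got {torsions.shape}")
    out = structure.copy()
    # capture the downstream junction torsions before the rebuild breaks it
    ie = idx[-1]
    if ie + 1 < len(structure) and structure.chains[ie + 1] == segment.chain_id:
        key = (segment.chain_id, int(structure.resnums[ie]))
        d = np.linalg.norm(structure.coords[ie, 2] - structure.coords[ie + 1, 0])
        if abs(d - PEPTIDE_BOND) <= PEPTIDE_BOND_TOL:
            C = structure.coords
            phi_next = float(dihedral(C[ie, 2], C[ie + 1, 0], C[ie + 1, 1],
                                      C[ie + 1, 2]))
            omega = float(dihedral(C[ie, 1], C[ie, 2], C[ie + 1, 0],
                                   C[ie + 1, 1]))
            out.junction_torsions[key] = (phi_next, omega)
    seed = np.stack([structure.atom(i0 - 1, "C"), structure.atom(i0, "N"),
                     structure.atom(i0, "CA")])
    built = coords_from_torsions(seed, torsions, geometry)
    # keep the anchored N/CA of the first segment residue exactly as they are
    out.coords[idx] = built
    out.coords[i0, 0] = structure.coords[i0, 0]
    out.coords[i0, 1] = structure.coords[i0, 1]
    if sequence is not None:
        if len(sequence) != segment.length:
            raise ValueError("replacement sequence length mismatch")
        s = list(out.sequence)
        for k, i in enumerate(idx):
            s[i] = sequence[k]
        out.sequence = "".join(s)
    out.chain_breaks = out.detect_chain_breaks()
    return out


def downstream_anchor_atoms(structure: BackboneStructure, chain_id: str,
                            end_resnum: int,
                            geometry: InternalGeometry = IDEAL_GEOMETRY):
    """Anchor-consistent (CA, C) of the residue ending a rebuilt span.

    When the junction C(end)-N(end+1) is intact these are the current
    coordinates.  When it is broken (extended start, mid-protocol), the
    positions are reconstructed from the fixed downstream residue with the
    junction torsions captured before the break (omega of the end residue
    and phi of the following residue), falling back to trans/extended
    values when nothing was recorded.
    """
    ie = structure.index_of(chain_id, end_resnum)
    if ie + 1 >= len(structure) or structure.chains[ie + 1] != chain_id:
        raise StructureError("no downstream anchor residue")
    C = structure.coords
    d = np.linalg.norm(C[ie, 2] - C[ie + 1, 0])
    if abs(d - PEPTIDE_BOND) <= PEPTIDE_BOND_TOL:
        return C[ie, 1].copy(), C[ie, 2].copy()
    phi_next, omega = structure.junction_torsions.get(
        (chain_id, int(end_resnum)), (180.0, 180.0))
    g = geometry
    c3 = place_atom(C[ie + 1, 2], C[ie + 1, 1], C[ie + 1, 0],
                    g.c_n, g.ang_c_n_ca, phi_next)
    ca3 = place_atom(C[ie + 1, 1], C[ie + 1, 0], c3,
                     g.ca_c, g.ang_ca_c_n, omega)
    return ca3, c3


# ---------------------------------------------------------------------------
# RMSD and rigid transforms between residues
# ---------------------------------------------------------------------------

def backbone_rmsd(model: BackboneStructure, reference: BackboneStructure,
                  segment, align_rest: bool = True,
                  atoms=BACKBONE_ATOMS) -> float:
    """Backbone heavy-atom RMSD over the segment(s).

    With ``align_rest`` the model is first superposed on the reference using
    only non-segment backbone atoms (the convention used for evaluating loop
    predictions); the RMSD is then computed over the segment N, CA, C, O
    atoms.  ``segment`` may be a single SegmentSpec or a list (multi-segment
    cases are scored jointly).
    """
    segments = [segment] if isinstance(segment, SegmentSpec) else list(segment)
    cols = [BACKBONE_ATOMS.index(a) for a in atoms]
    try:
        seg_idx = np.unique(np.concatenate(
            [model.segment_indices(s) for s in segments]))
        ref_seg_idx = np.unique(np.concatenate(
            [reference.segment_indices(s) for s in segments]))
    except StructureError as e:
        raise StructureError(f"segment residue numbering mismatch: {e}") from e
    if len(model) != len(reference) or not np.all(model.resnums == reference.resnums):
        raise StructureError("model and reference numbering disagree")
    mob = model.coords
    if align_rest:
        rest = np.setdiff1d(np.arange(len(model)), seg_idx)
        tr, _ = kabsch_superpose(model.coords[rest][:, cols].reshape(-1, 3),
                                 reference.coords[rest][:, cols].reshape(-1, 3))
        mob = tr.apply(model.coords.reshape(-1, 3)).reshape(model.coords.shape)
    d = mob[seg_idx][:, cols] - reference.coords[ref_seg_idx][:, cols]
    return float(np.sqrt(np.mean(np.sum(d.reshape(-1, 3) ** 2, axis=-1))))


def segment_rigid_transform(structure: BackboneStructure, residue_a: int,
                            residue_b: int, chain_id: str | None = None) -> RigidTransform:
    """6D rigid transform from residue_a's backbone frame to residue_b's.

    Frames have origin CA and axes built from N/CA/C; the transform is
    expressed in residue_a's local frame, making it invariant under global
    rigid motion of the structure.
    """
    if chain_id is None:
        chain_id = str(structure.chains[0])
    ia = structure.index_of(chain_id, residue_a)
    ib = structure.index_of(chain_id, residue_b)
    fa = residue_frame(structure.coords[ia, 0], structure.coords[ia, 1],
                       structure.coords[ia, 2])
    fb = residue_frame(structure.coords[ib, 0], structure.coords[ib, 1],
                       structure.coords[ib, 2])
    return frame_to_frame(fa, fb)
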