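"""Internal-coordinate math for protein backbones.

Angles are degrees at every public boundary; lengths are angstroms.
The chain builder follows the NeRF scheme: each atom is placed from the
three preceding atoms by a bond length, a bond angle and a dihedral.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation


def wrap_angle(theta):
    """Wrap angle(s) in degrees to the principal interval (-180, 180]."""
    t = -(np.mod(-np.asarray(theta, dtype=float) + 180.0, 360.0) - 180.0)
    return t


@dataclass(frozen=True)
class InternalGeometry:
    """Idealized backbone covalent geometry (lengths in A, angles in deg)."""

    n_ca: float = 1.458
    ca_c: float = 1.523
    c_n: float = 1.329
    c_o: float = 1.231
    ang_n_ca_c: float = 111.2
    ang_ca_c_n: float = 116.2
    ang_c_n_ca: float = 121.7
    ang_ca_c_o: float = 120.8

    def validate(self) -> None:
        for name, v in (("n_ca", self.n_ca), ("ca_c", self.ca_c),
                        ("c_n", self.c_n), ("c_o", self.c_o)):
            if not (0.8 < v < 2.0):
                raise ValueError(f"bond length {name}={v} outside (0.8, 2.0) A")
        for name, v in (("ang_n_ca_c", self.ang_n_ca_c),
                        ("ang_ca_c_n", self.ang_ca_c_n),
                        ("ang_c_n_ca", self.ang_c_n_ca),
                        ("ang_ca_c_o", self.ang_ca_c_o)):
            if not (80.0 < v < 160.0):
                raise ValueError(f"bond angle {name}={v} outside (80, 160) deg")


IDEAL_GEOMETRY = InternalGeometry()


def _cross3(a, b):
    out = np.empty(np.broadcast_shapes(a.shape, b.shape))
    out[..., 0] = a[..., 1] * b[..., 2] - a[..., 2] * b[..., 1]
    out[..., 1] = a[..., 2] * b[..., 0] - a[..., 0] * b[..., 2]
    out[..., 2] = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    return out


def place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float):
    """Place atom D given predecessors A-B-C (NeRF).

    |CD| = bond, angle(B,C,D) = angle_deg, dihedral(A,B,C,D) = dihedral_deg.
    Inputs may be (3,) or batched (..., 3); bond/angle/dihedral broadcast.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    theta = np.deg2rad(angle_deg)
    chi = np.deg2rad(dihedral_deg)
    bc = c - b
    bc = bc / np.sqrt(np.sum(bc * bc, axis=-1, keepdims=True))
    ab = b - a
    n = _cross3(ab, bc)
    n = n / np.sqrt(np.sum(n * n, axis=-1, keepdims=True))
    m = _cross3(n, bc)
    bond = np.asarray(bond, float)[..., None]
    ct = np.cos(theta)[..., None]
    st = np.sin(theta)[..., None]
    cx = np.cos(chi)[..., None]
    sx = np.sin(chi)[..., None]
    return c + bond * (-ct * bc + st * (cx * m + sx * n))


def dihedral(p0, p1, p2, p3):
    """Signed dihedral angle in degrees for points (..., 3)."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1n, axis=-1, keepdims=True) * b1n
    w = b2 - np.sum(b2 * b1n, axis=-1, keepdims=True) * b1n
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1n, v) * w, axis=-1)
    return np.degrees(np.arctan2(y, x))


def bond_angle(p0, p1, p2):
    """Bond angle at p1 in degrees for points (..., 3)."""
    p0, p1, p2 = (np.asarray(p, float) for p in (p0, p1, p2))
    u = p0 - p1
    v = p2 - p1
    u /= np.linalg.norm(u, axis=-1, keepdims=True)
    v /= np.linalg.norm(v, axis=-1, keepdims=True)
    return np.degrees(np.arccos(np.clip(np.sum(u * v, axis=-1), -1.0, 1.0)))


def build_chain(seed: np.ndarray, internal_coords) -> np.ndarray:
    """Sequentially place atoms after three seed atoms.

    seed: (3, 3) array of the three seed atoms in order.
    internal_coords: iterable of (bond, angle_deg, dihedral_deg); atom i is
    placed from the three atoms preceding it.

    Returns (3 + n, 3) array: seeds followed by placed atoms.
    """
    atoms = [np.asarray(seed[0], float), np.asarray(seed[1], float),
             np.asarray(seed[2], float)]
    for bond, ang, dih in internal_coords:
        if not np.isfinite(dih):
            raise ValueError("non-finite dihedral in chain build")
        atoms.append(place_atom(atoms[-3], atoms[-2], atoms[-1], bond, ang, dih))
    return np.asarray(atoms)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R @ x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, float)
        t = np.asarray(self.translation, float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3, translation length 3")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation determinant must be +1")
        if np.max(np.abs(R @ R.T - np.eye(3))) > 1e-9:
            raise ValueError("rotation must be orthonormal")

    def apply(self, pts):
        return np.asarray(pts, float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self.compose(other)).apply(x) == self.apply(other.apply(x))."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


def kabsch_superpose(mobile_coords, ref_coords):
    """Least-squares rigid superposition of paired point sets.

    Returns (RigidTransform, rmsd): the transform maps the mobile set onto the
    reference in the least-squares sense; rmsd is after superposition.
    """
    mob = np.asarray(mobile_coords, float)
    ref = np.asarray(ref_coords, float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError("paired (n, 3) coordinate arrays required")
    if mob.shape[0] < 3:
        raise ValueError("at least 3 points required for superposition")
    mc = mob.mean(axis=0)
    rc = ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - rc, mob - mc)
    R = rot.as_matrix()
    t = rc - R @ mc
    moved = mob @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=-1))))
    return RigidTransform(R, t), rmsd


def residue_frame(n, ca, c) -> RigidTransform:
    """Orthonormal backbone frame at a residue: origin CA, axes from N/CA/C.

    x along CA->N, z along the normal of the N-CA-C plane, y completing a
    right-handed set. Raises on a degenerate (collinear) triple.
    """
    n = np.asarray(n, float)
    ca = np.asarray(ca, float)
    c = np.asarray(c, float)
    x = n - ca
    nx = np.linalg.norm(x)
    z = np.cross(n - ca, c - ca)
    nz = np.linalg.norm(z)
    if nx < 1e-8 or nz < 1e-8:
        raise ValueError("degenerate residue frame: N/CA/C collinear or coincident")
    x = x / nx
    z = z / nz
    y = np.cross(z, x)
    R = np.stack([x, y, z], axis=1)  # columns: local axes in world coords
    return RigidTransform(R, ca)


def frame_to_frame(frame_a: RigidTransform, frame_b: RigidTransform) -> RigidTransform:
    """Transform expressing frame_b in frame_a coordinates (a -> b)."""
    return frame_a.inverse().compose(frame_b)
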