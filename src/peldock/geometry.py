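"""Rigid-body geometry: proper rotations, superposition, internal-coordinate atom placement.

All coordinates are in Angstrom, in the orthogonal PDB frame. Rotations are
stored as 3x3 matrices and validated to be proper (det +1) at construction;
sampling and averaging go through unit quaternions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "RigidTransform",
    "SuperpositionResult",
    "kabsch_superpose",
    "random_rotation",
    "mean_rotation",
    "place_atom",
]

_ORTHO_TOL = 1e-6


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid-body motion x -> R x + t.

    Parameters
    ----------
    rotation : (3, 3) array
        Orthonormal matrix with determinant +1. Improper rotations
        (reflections) are rejected at construction.
    translation : (3,) array
        Translation vector in Angstrom.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise ValueError("transform contains non-finite values")
        if np.abs(R @ R.T - np.eye(3)).max() > 1e-5:
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("improper rotation (reflection) rejected")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotvec(cls, rotvec, translation) -> "RigidTransform":
        return cls(Rotation.from_rotvec(np.asarray(rotvec, float)).as_matrix(),
                   translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (n, 3) array (or a single 3-vector)."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other:  (self ∘ other)(x) = self(other(x))."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def as_rotvec(self) -> np.ndarray:
        return Rotation.from_matrix(self.rotation).as_rotvec()

    # -- JSON round trip: {rotation: 9 numbers row-major, translation: 3} --

    def to_dict(self) -> dict:
        return {"rotation": [float(v) for v in self.rotation.ravel()],
                "translation": [float(v) for v in self.translation]}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["rotation"], float).reshape(3, 3),
                   np.asarray(d["translation"], float))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RigidTransform":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class SuperpositionResult:
    """Least-squares superposition of one point set onto another."""

    transform: RigidTransform
    rmsd: float
    n_atoms: int


def kabsch_superpose(movable: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Optimal proper-rotation superposition of `movable` onto `reference`.

    Returns the rigid transform T minimizing sum ||T(movable_i) - reference_i||^2
    and the residual RMSD. Requires >= 3 non-collinear point pairs of equal
    length.
    """
    mov = np.asarray(movable, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mov.shape != ref.shape:
        raise ValueError(f"length mismatch: {mov.shape} vs {ref.shape}")
    if mov.ndim != 2 or mov.shape[1] != 3 or mov.shape[0] < 3:
        raise ValueError("need >= 3 points of dimension 3")
    mov_c = mov.mean(axis=0)
    ref_c = ref.mean(axis=0)
    a = ref - ref_c
    b = mov - mov_c
    # collinear sets leave the rotation about the common axis undetermined
    if np.linalg.matrix_rank(a, tol=1e-8) < 2 or np.linalg.matrix_rank(b, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point set")
    rot, rssd = Rotation.align_vectors(a, b)
    R = rot.as_matrix()
    transform = RigidTransform(R, ref_c - R @ mov_c)
    n = mov.shape[0]
    rmsd = float(rssd) / np.sqrt(n)
    return SuperpositionResult(transform=transform, rmsd=rmsd, n_atoms=n)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via the unit-quaternion construction."""
    # Shoemake subgroup-algorithm sampling of a uniform unit quaternion
    u1, u2, u3 = rng.random(3)
    q = np.array([
        np.sqrt(1 - u1) * np.sin(2 * np.pi * u2),
        np.sqrt(1 - u1) * np.cos(2 * np.pi * u2),
        np.sqrt(u1) * np.sin(2 * np.pi * u3),
        np.sqrt(u1) * np.cos(2 * np.pi * u3),
    ])
    return Rotation.from_quat(q).as_matrix()


def mean_rotation(rotations) -> np.ndarray:
    """Quaternion average: dominant eigenvector of the quaternion outer-product sum."""
    quats = np.array([Rotation.from_matrix(np.asarray(R, float)).as_quat()
                      for R in rotations])
    if len(quats) == 0:
        raise ValueError("no rotations to average")
    # align hemispheres against the first quaternion before accumulating
    signs = np.where(quats @ quats[0] < 0, -1.0, 1.0)
    quats = quats * signs[:, None]
    M = quats.T @ quats
    _, vecs = np.linalg.eigh(M)
    q_mean = vecs[:, -1]
    return Rotation.from_quat(q_mean).as_matrix()


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom d from internal coordinates relative to the chain a-b-c.

    `bond` is |c-d|, `angle_deg` the b-c-d angle, `dihedral_deg` the a-b-c-d
    torsion. Standard NeRF construction.
    """
    a, b, c = (np.asarray(x, float) for x in (a, b, c))
    theta = np.deg2rad(angle_deg)
    chi = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ValueError("collinear reference atoms for internal-coordinate placement")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array([-bond * np.cos(theta),
                        bond * np.sin(theta) * np.cos(chi),
                        -bond * np.sin(theta) * np.sin(chi)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n
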