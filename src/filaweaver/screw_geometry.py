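"""Rigid-body superposition, screw (Chasles) algebra and helical parameters.

Any proper rigid motion is a rotation about an axis combined with a
translation along it (a *screw*).  Composing the screw that maps one
filament monomer onto the next generates the whole helix, so the screw
parameters of a monomer-monomer binding geometry determine the filament's
pitch and monomers-per-turn.  RecA filaments live in two regimes: extended
(ATP-bound, pitch roughly 85-100 A) and compressed (ADP-bound or apo,
roughly 65-85 A).

Conventions: angles are degrees in every public API (radians internally);
the canonical screw form has translation >= 0 (the axis is flipped
otherwise), with ties at zero translation broken by angle >= 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import Structure, select

__all__ = [
    "RigidTransform",
    "ScrewParams",
    "HelicalParams",
    "DegenerateFitError",
    "UndefinedHelixError",
    "superpose",
    "screw_from_transform",
    "transform_from_screw",
    "compose",
    "helical_params",
    "angle_between_axes",
]

_ANGLE_EPS_DEG = 1e-6  # below this the motion is treated as a pure translation


class DegenerateFitError(ValueError):
    """Superposition attempted on fewer than 3 non-collinear atom pairs."""


class UndefinedHelixError(ValueError):
    """Helical parameters requested for a zero-angle (non-helical) screw."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation, acting as ``x -> R x + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if not math.isclose(float(np.linalg.det(R)), 1.0, abs_tol=1e-8):
            raise ValueError("rotation matrix is not proper (det != +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def apply_structure(self, s: Structure) -> Structure:
        return s.with_coords(self.apply(s.coords()))

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return compose(self, other)

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous form."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def isclose(self, other: "RigidTransform", atol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.rotation, other.rotation, atol=atol)
            and np.allclose(self.translation, other.translation, atol=atol)
        )


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Transform applying ``b`` first, then ``a``: (a.b)(x) = a(b(x))."""
    return RigidTransform(a.rotation @ b.rotation, a.rotation @ b.translation + a.translation)


@dataclass(frozen=True)
class ScrewParams:
    """Chasles form of a rigid transform.

    ``angle_deg`` follows the right-hand rule about ``axis_direction``;
    ``translation`` is the signed advance along the axis per application.
    ``axis_point`` is any point on the axis (canonically the foot of the
    perpendicular from the origin).
    """

    axis_direction: np.ndarray
    axis_point: np.ndarray
    angle_deg: float
    translation: float

    def __post_init__(self) -> None:
        u = np.asarray(self.axis_direction, dtype=float).reshape(3)
        n = np.linalg.norm(u)
        if n < 1e-12:
            raise ValueError("zero-length screw axis")
        object.__setattr__(self, "axis_direction", u / n)
        object.__setattr__(
            self, "axis_point", np.asarray(self.axis_point, dtype=float).reshape(3)
        )

    def canonical(self) -> "ScrewParams":
        """Normal form: translation >= 0 (axis flipped otherwise); at zero
        translation, angle >= 0; axis_point perpendicular to the axis."""
        u = self.axis_direction.copy()
        ang = float(self.angle_deg)
        d = float(self.translation)
        if d < -1e-9 or (abs(d) <= 1e-9 and ang < 0):
            u, ang, d = -u, -ang, -d
        if abs(d) <= 1e-9:
            d = abs(d)
        p = self.axis_point - np.dot(self.axis_point, u) * u
        return ScrewParams(u, p, ang, d)


@dataclass(frozen=True)
class HelicalParams:
    """Helix descriptors implied by repeating a screw.

    ``monomers_per_turn`` = 360/|angle|; ``pitch`` = monomers_per_turn x
    |translation| (the axial length of one full turn).  ``handedness`` is
    right when rotation and advance share sign under the right-hand rule.
    """

    monomers_per_turn: float
    pitch: float
    handedness: str


def superpose(
    mobile: Structure,
    reference: Structure,
    match_atoms: str | set[str] = "CA",
    residue_ranges: list[tuple[int, int]] | None = None,
    exclude_ranges: list[tuple[int, int]] | None = None,
) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Atoms are matched by identical ``(residue_seq, atom_name)`` (chain ids
    are ignored, so two chains of one crystal can be compared).  The default
    atom set is C-alpha; pass ``"heavy"`` or an explicit name set otherwise.
    ``residue_ranges`` restricts the match; ``exclude_ranges`` removes
    ranges from it (used to drop flexible loops and the mobile N-terminal
    domain when comparing conformers).

    Returns the optimal transform (Kabsch) and the post-fit RMSD in A.
    """

    def _keep(a) -> bool:
        if match_atoms == "heavy":
            if a.is_hydrogen:
                return False
        elif isinstance(match_atoms, str):
            if a.atom_name != match_atoms:
                return False
        elif a.atom_name not in match_atoms:
            return False
        if residue_ranges is not None and not any(
            lo <= a.residue_seq <= hi for lo, hi in residue_ranges
        ):
            return False
        if exclude_ranges is not None and any(
            lo <= a.residue_seq <= hi for lo, hi in exclude_ranges
        ):
            return False
        return True

    mob = {(a.residue_seq, a.atom_name): a.position for a in mobile.atoms if _keep(a)}
    ref = {(a.residue_seq, a.atom_name): a.position for a in reference.atoms if _keep(a)}
    keys = [k for k in mob if k in ref]
    if len(keys) < 3:
        raise DegenerateFitError(f"only {len(keys)} matched atom pairs (need >= 3)")
    P = np.array([mob[k] for k in keys])
    Q = np.array([ref[k] for k in keys])
    Pc, Qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - Pc, Q - Qc
    if np.linalg.matrix_rank(P0, tol=1e-6) < 2:
        raise DegenerateFitError("matched atoms are collinear")
    rot, rssd = Rotation.align_vectors(Q0, P0)
    R = rot.as_matrix()
    t = Qc - R @ Pc
    rmsd = float(rssd) / math.sqrt(len(keys))
    return RigidTransform(R, t), rmsd


def screw_from_transform(t: RigidTransform) -> ScrewParams:
    """Chasles decomposition of a rigid transform into screw parameters.

    The rotation angle and axis come from the axis-angle form; the signed
    axial advance is the projection of the translation on the axis; the
    axis point solves the in-plane fixed-point equation
    ``(I - R) p = t_perp`` in the plane perpendicular to the axis.  A
    near-zero rotation falls back to the pure-translation branch (axis
    along the translation, angle 0).  Result is canonical.
    """
    rotvec = Rotation.from_matrix(t.rotation).as_rotvec()
    angle = float(np.linalg.norm(rotvec))
    if math.degrees(angle) < _ANGLE_EPS_DEG:
        tr = t.translation
        d = float(np.linalg.norm(tr))
        if d < 1e-12:
            return ScrewParams(np.array([0.0, 0.0, 1.0]), np.zeros(3), 0.0, 0.0)
        return ScrewParams(tr / d, np.zeros(3), 0.0, d).canonical()
    u = rotvec / angle
    d = float(np.dot(t.translation, u))
    t_perp = t.translation - d * u
    A = np.eye(3) - t.rotation
    # Solve A p = t_perp with p constrained to the plane through the origin
    # perpendicular to u (A is singular along u).
    M = np.vstack([A, u[None, :]])
    b = np.concatenate([t_perp, [0.0]])
    p, *_ = np.linalg.lstsq(M, b, rcond=None)
    return ScrewParams(u, p, math.degrees(angle), d).canonical()


def transform_from_screw(s: ScrewParams) -> RigidTransform:
    """Exact Rodrigues reconstruction; inverse of :func:`screw_from_transform`."""
    u = s.axis_direction
    R = Rotation.from_rotvec(u * math.radians(s.angle_deg)).as_matrix()
    t = s.translation * u + (np.eye(3) - R) @ s.axis_point
    return RigidTransform(R, t)


def helical_params(s: ScrewParams) -> HelicalParams:
    """Pitch, monomers-per-turn and handedness of the helix a screw generates."""
    s = s.canonical()
    if abs(s.angle_deg) < _ANGLE_EPS_DEG:
        raise UndefinedHelixError("zero rotation angle: helix undefined")
    mpt = 360.0 / abs(s.angle_deg)
    pitch = mpt * abs(s.translation)
    # canonical form has translation >= 0, so the sign of the angle alone
    # decides whether rotation and advance agree under the right-hand rule
    handedness = "right" if s.angle_deg > 0 else "left"
    return HelicalParams(monomers_per_turn=mpt, pitch=pitch, handedness=handedness)


def angle_between_axes(u1: np.ndarray, u2: np.ndarray) -> float:
    """Unsigned angle between two axis directions, degrees in [0, 180]."""
    u1 = np.asarray(u1, dtype=float)
    u2 = np.asarray(u2, dtype=float)
    n1, n2 = np.linalg.norm(u1), np.linalg.norm(u2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise ValueError("zero-length axis vector")
    c = float(np.clip(np.dot(u1 / n1, u2 / n2), -1.0, 1.0))
    return math.degrees(math.acos(c))
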