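"""Rigid-body pose algebra and Grood-Suntay tibiofemoral kinematics.

The tibiofemoral joint coordinate system follows the floating-axis
construction: flexion-extension about the femoral medio-lateral axis,
internal-external rotation about the tibial long axis, and ab/adduction
about the mutually perpendicular floating axis.  Sign convention (right
knee): flexion, valgus, external tibial rotation, and medial / anterior /
proximal translations of the tibia relative to the femur are positive.

Anatomical frames use column axes ``[anterior, medial, proximal]`` and must
be right-handed; left knees are handled upstream by mirroring the geometry
into this convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import SingularityError, ValidationError

#: order of the six degrees of freedom in all tabular interfaces
DOF_COLUMNS = ["FE", "VV", "IE", "AP", "ML", "IS"]

_ORTHO_TOL = 1e-9


def _check_rotation(matrix: np.ndarray, tol: float = _ORTHO_TOL) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (3, 3):
        raise ValidationError("rotation must be a 3x3 matrix")
    if not np.allclose(matrix.T @ matrix, np.eye(3), atol=tol):
        raise ValidationError("rotation matrix is not orthonormal")
    if np.linalg.det(matrix) < 0:
        raise ValidationError("rotation matrix must be proper (det = +1)")
    return matrix


@dataclass(frozen=True)
class RigidPose:
    """A proper rigid transform: world point = rotation @ local + translation (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "translation", t)

    @staticmethod
    def identity() -> "RigidPose":
        return RigidPose(np.eye(3), np.zeros(3))

    def compose(self, other: "RigidPose") -> "RigidPose":
        """self after other: (self o other)(p) = self(other(p))."""
        return RigidPose(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidPose":
        rt = self.rotation.T
        return RigidPose(rt, -rt @ self.translation)

    def transform_point(self, p) -> np.ndarray:
        return self.rotation @ np.asarray(p, dtype=float) + self.translation

    def transform_points(self, pts) -> np.ndarray:
        return np.asarray(pts, dtype=float) @ self.rotation.T + self.translation

    def rotate_vector(self, v) -> np.ndarray:
        return self.rotation @ np.asarray(v, dtype=float)

    def as_quaternion(self) -> np.ndarray:
        """Scalar-last (x, y, z, w) unit quaternion interchange form."""
        return Rotation.from_matrix(self.rotation).as_quat()

    @staticmethod
    def from_quaternion(quat, translation) -> "RigidPose":
        return RigidPose(Rotation.from_quat(quat).as_matrix(), translation)

    def almost_equal(self, other: "RigidPose", tol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.rotation, other.rotation, atol=tol)
            and np.allclose(self.translation, other.translation, atol=tol)
        )


@dataclass(frozen=True)
class Frame:
    """An anatomical frame in body coordinates.

    ``axes`` holds column unit vectors ``[anterior, medial, proximal]``
    (right-handed).
    """

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float).reshape(3))
        axes = _check_rotation(self.axes, tol=1e-8)
        object.__setattr__(self, "axes", axes)

    @staticmethod
    def world_aligned(origin=(0.0, 0.0, 0.0)) -> "Frame":
        return Frame(np.asarray(origin, dtype=float), np.eye(3))

    def world_origin(self, pose: RigidPose) -> np.ndarray:
        return pose.transform_point(self.origin)

    def world_axes(self, pose: RigidPose) -> np.ndarray:
        return pose.rotation @ self.axes


@dataclass(frozen=True)
class JointKinematics:
    """Six tibiofemoral degrees of freedom.

    Angles in degrees (flexion, valgus and external tibial rotation
    positive), translations in mm (anterior, medial, proximal positive).
    """

    FE: float
    VV: float
    IE: float
    AP: float
    ML: float
    IS: float

    def __post_init__(self):
        values = self.as_array()
        if not np.all(np.isfinite(values)):
            raise ValidationError("joint kinematics must be finite")
        for name in ("FE", "VV", "IE"):
            a = getattr(self, name)
            if not (-180.0 < a <= 180.0):
                raise ValidationError(f"angle {name}={a} outside (-180, 180]")

    def as_array(self) -> np.ndarray:
        return np.array([self.FE, self.VV, self.IE, self.AP, self.ML, self.IS], dtype=float)

    @staticmethod
    def zeros() -> "JointKinematics":
        return JointKinematics(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


def _anatomical_rotation(pose: RigidPose, frame: Frame) -> np.ndarray:
    return pose.rotation @ frame.axes


def grood_suntay(
    femur_pose: RigidPose,
    tibia_pose: RigidPose,
    femur_frame: Frame,
    tibia_frame: Frame,
    singularity_tol: float = 1e-6,
) -> JointKinematics:
    """Decompose the relative tibiofemoral pose into the six joint DOFs.

    Raises :class:`SingularityError` when the floating axis is undefined
    (ab/adduction at +/-90 deg, i.e. tibial long axis parallel to the
    femoral flexion axis).
    """
    rf = _anatomical_rotation(femur_pose, femur_frame)
    rt = _anatomical_rotation(tibia_pose, tibia_frame)

    e1 = rf[:, 1]  # femoral medio-lateral (medial +) fixed axis
    e3 = rt[:, 2]  # tibial long (proximal +) fixed axis
    floating = np.cross(e1, e3)
    norm = np.linalg.norm(floating)
    if norm < singularity_tol:
        raise SingularityError(
            "floating axis undefined: tibial long axis parallel to femoral flexion axis"
        )

    # Relative rotation in the femoral anatomical frame; the floating-axis
    # system is an intrinsic medial / floating-anterior / proximal (Y-X-Z)
    # Cardan sequence of that matrix.
    r_rel = rf.T @ rt
    a, b, c = Rotation.from_matrix(r_rel).as_euler("YXZ", degrees=True)

    offset = rt.T @ (
        tibia_frame.world_origin(tibia_pose) - femur_frame.world_origin(femur_pose)
    )
    return JointKinematics(
        FE=float(a),
        VV=float(-b),
        IE=float(-c),
        AP=float(offset[0]),
        ML=float(offset[1]),
        IS=float(offset[2]),
    )


def pose_from_kinematics(
    jk: JointKinematics,
    femur_frame: Frame | None = None,
    tibia_frame: Frame | None = None,
) -> RigidPose:
    """Relative pose of the tibial anatomical frame in the femoral one.

    Inverse of :func:`grood_suntay` on non-singular inputs:
    composing the returned pose with a femur pose and the two frames and
    decomposing again reproduces ``jk``.
    """
    if abs(abs(jk.VV) - 90.0) < 1e-9:
        raise SingularityError("joint kinematics at the VV = +/-90 deg singularity")
    r_rel = Rotation.from_euler("YXZ", [jk.FE, -jk.VV, -jk.IE], degrees=True).as_matrix()
    offset_tibial = np.array([jk.AP, jk.ML, jk.IS])
    return RigidPose(r_rel, r_rel @ offset_tibial)


def tibia_pose_from_relative(
    relative: RigidPose,
    femur_pose: RigidPose,
    femur_frame: Frame,
    tibia_frame: Frame,
) -> RigidPose:
    """Body pose of the tibia realizing ``relative`` (tibial anat in femoral anat)."""
    rf = _anatomical_rotation(femur_pose, femur_frame)
    rt_world = rf @ relative.rotation @ tibia_frame.axes.T
    origin_world = femur_frame.world_origin(femur_pose) + rf @ relative.translation
    translation = origin_world - rt_world @ tibia_frame.origin
    return RigidPose(rt_world, translation)


def laxity(series) -> pd.Series:
    """Per-DOF range (max minus min) of a kinematic series.

    Accepts a DataFrame with the DOF columns, a :class:`SquatTrace`-like
    object exposing ``.kinematics``, or a sequence of
    :class:`JointKinematics`.
    """
    if hasattr(series, "kinematics"):
        frame = series.kinematics
    elif isinstance(series, pd.DataFrame):
        frame = series
    else:
        rows = [jk.as_array() for jk in series]
        if not rows:
            raise ValidationError("empty kinematic series")
        frame = pd.DataFrame(rows, columns=DOF_COLUMNS)
    if len(frame) == 0:
        raise ValidationError("empty kinematic series")
    cols = [c for c in DOF_COLUMNS if c in frame.columns]
    if not cols:
        raise ValidationError("series has no kinematic columns")
    sub = frame[cols]
    return sub.max() - sub.min()


def kinematics_to_frame(kinematics: list[JointKinematics], t=None) -> pd.DataFrame:
    data = pd.DataFrame([jk.as_array() for jk in kinematics], columns=DOF_COLUMNS)
    if t is not None:
        data.insert(0, "t", np.asarray(t, dtype=float))
    return data


def write_trace_csv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False, float_format="%.9g")


def read_trace_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
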