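"""Rigid 3-D transforms, tracked poses, and frame chaining.

Every spatial quantity in the navigation chain lives in a named coordinate
frame (``image``, ``tracker``, ``sensor``, ``projector``, ...). The tracker
frame is the world frame; all lengths are millimetres; frames are
right-handed. Transforms are stored child -> parent (e.g. tool -> tracker),
the direction in which optical trackers report tool poses: applying a
transform maps coordinates expressed in ``from_frame`` into ``to_frame``.

Rotations are stored as 3x3 matrices. Quaternions (scalar-first
``qw, qx, qy, qz``) are accepted at I/O boundaries — the pose-stream CSV —
and converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import FrameMismatchError

#: Tolerance on R^T R = I and det R = 1 for a valid rotation.
ORTHONORMAL_TOL = 1e-9

#: Unit-norm tolerance for quaternions read from pose streams.
QUATERNION_TOL = 1e-6

POSE_CSV_COLUMNS = ["timestamp", "tool_id", "qw", "qx", "qy", "qz", "tx", "ty", "tz", "valid"]


def _check_rotation(rotation: np.ndarray) -> np.ndarray:
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got shape {rotation.shape}")
    if not np.all(np.isfinite(rotation)):
        raise ValueError("rotation contains non-finite entries")
    if not np.allclose(rotation.T @ rotation, np.eye(3), atol=ORTHONORMAL_TOL, rtol=0.0):
        raise ValueError("rotation is not orthonormal (R^T R != I)")
    if abs(np.linalg.det(rotation) - 1.0) > ORTHONORMAL_TOL:
        raise ValueError("rotation is not proper (det R != +1); reflections are not rigid")
    return rotation


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform ``p_to = R @ p_from + t`` between two named frames.

    Parameters
    ----------
    rotation
        3x3 orthonormal matrix with determinant +1.
    translation
        3-vector in mm.
    from_frame, to_frame
        Labels of the child and parent frame.
    """

    rotation: np.ndarray
    translation: np.ndarray
    from_frame: str = "world"
    to_frame: str = "world"

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))
        translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(translation)):
            raise ValueError("translation contains non-finite entries")
        object.__setattr__(self, "translation", translation)

    # -- constructors ---------------------------------------------------

    @classmethod
    def identity(cls, frame: str = "world") -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), from_frame=frame, to_frame=frame)

    @classmethod
    def from_quaternion(
        cls,
        quat_wxyz,
        translation,
        from_frame: str = "world",
        to_frame: str = "world",
    ) -> "RigidTransform":
        """Build from a scalar-first quaternion, normalizing to unit length.

        Raises ``ValueError`` if the quaternion norm deviates from 1 by more
        than ``QUATERNION_TOL`` — such values indicate corrupt pose data
        rather than rounding.
        """
        quat = np.asarray(quat_wxyz, dtype=float).reshape(4)
        norm = float(np.linalg.norm(quat))
        if abs(norm - 1.0) > QUATERNION_TOL:
            raise ValueError(f"quaternion norm {norm:.8f} deviates from 1 beyond tolerance")
        rot = Rotation.from_quat(quat / norm, scalar_first=True).as_matrix()
        return cls(rot, translation, from_frame=from_frame, to_frame=to_frame)

    # -- accessors ------------------------------------------------------

    def quaternion_wxyz(self) -> np.ndarray:
        """Scalar-first unit quaternion of the rotation (qw >= 0)."""
        q = Rotation.from_matrix(self.rotation).as_quat(scalar_first=True)
        return q if q[0] >= 0 else -q

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.reshape(-1).tolist(),  # row-major
            "translation": self.translation.tolist(),
            "from_frame": self.from_frame,
            "to_frame": self.to_frame,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            np.asarray(d["rotation"], dtype=float).reshape(3, 3),
            np.asarray(d["translation"], dtype=float),
            from_frame=d.get("from_frame", "world"),
            to_frame=d.get("to_frame", "world"),
        )


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Chain two transforms: the result maps ``b.from_frame`` -> ``a.to_frame``.

    ``apply(compose(a, b), p) == apply(a, apply(b, p))``.
    """
    if a.from_frame != b.to_frame:
        raise FrameMismatchError(
            f"cannot compose: left transform expects frame '{a.from_frame}' "
            f"but right transform produces frame '{b.to_frame}'"
        )
    return RigidTransform(
        a.rotation @ b.rotation,
        a.rotation @ b.translation + a.translation,
        from_frame=b.from_frame,
        to_frame=a.to_frame,
    )


def invert(t: RigidTransform) -> RigidTransform:
    """Inverse transform, with frames swapped."""
    rot_inv = t.rotation.T
    return RigidTransform(
        rot_inv, -rot_inv @ t.translation, from_frame=t.to_frame, to_frame=t.from_frame
    )


def apply(t: RigidTransform, points) -> np.ndarray:
    """Map one point or an (N, 3) stack of points through ``t`` (mm in, mm out)."""
    pts = np.asarray(points, dtype=float)
    if not np.all(np.isfinite(pts)):
        raise ValueError("points contain non-finite coordinates")
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if pts.shape[1] != 3:
        raise ValueError(f"points must be 3-vectors, got shape {pts.shape}")
    out = pts @ t.rotation.T + t.translation
    return out[0] if single else out


@dataclass
class Pose:
    """One tracked-tool sample: tool frame -> tracker frame at an instant."""

    tool_id: str
    transform: RigidTransform
    timestamp: float = 0.0
    valid: bool = True

    def __post_init__(self) -> None:
        if self.valid and not isinstance(self.transform, RigidTransform):
            raise TypeError("valid Pose requires a RigidTransform")


def write_pose_stream(poses: list[Pose], path) -> None:
    """Serialize poses to CSV (`timestamp,tool_id,qw,qx,qy,qz,tx,ty,tz,valid`)."""
    rows = []
    for p in poses:
        q = p.transform.quaternion_wxyz()
        t = p.transform.translation
        rows.append(
            {
                "timestamp": p.timestamp,
                "tool_id": p.tool_id,
                "qw": q[0],
                "qx": q[1],
                "qy": q[2],
                "qz": q[3],
                "tx": t[0],
                "ty": t[1],
                "tz": t[2],
                "valid": int(p.valid),
            }
        )
    pd.DataFrame(rows, columns=POSE_CSV_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def read_pose_stream(path, tracker_frame: str = "tracker") -> list[Pose]:
    """Read a pose-stream CSV; each row becomes a tool -> tracker Pose."""
    df = pd.read_csv(path)
    missing = set(POSE_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pose CSV missing columns: {sorted(missing)}")
    poses = []
    for row in df.itertuples(index=False):
        transform = RigidTransform.from_quaternion(
            (row.qw, row.qx, row.qy, row.qz),
            (row.tx, row.ty, row.tz),
            from_frame=str(row.tool_id),
            to_frame=tracker_frame,
        )
        poses.append(
            Pose(
                tool_id=str(row.tool_id),
                transform=transform,
                timestamp=float(row.timestamp),
                valid=bool(int(row.valid)),
            )
        )
    return poses
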