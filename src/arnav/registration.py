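"""Paired-point rigid registration, FRE, and pointer pivot calibration.

Registration maps the pre-operative image frame into the tracker frame by
pairing fiducial landmarks identified in both. The solver is the closed-form
least-squares rigid fit (centroid subtraction + SVD of the cross-covariance,
with a determinant guard so reflections are never returned). The fiducial
registration error (FRE) is the root-mean-square residual distance of the
paired fiducials after the fit.

Pivot calibration recovers a tracked pointer's tip offset: with the tip held
fixed in a divot while the handle is swept through orientations, the tip
offset ``b`` (tool frame) and pivot point ``p`` (tracker frame) satisfy
``R_k b + t_k = p`` for every pose ``k``; both are solved jointly by linear
least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, LabelMismatchError
from .geometry import Pose, RigidTransform, apply

#: Below this second singular value (mm) a centered point set is treated as collinear.
COLLINEAR_TOL = 1e-6

#: Pivot systems with a larger condition number are rejected as degenerate.
PIVOT_MAX_CONDITION = 1e6


@dataclass
class FiducialSet:
    """Labelled fiducial coordinates in one frame.

    At least 3 non-collinear points are required — the minimum that pins down
    a rigid transform.
    """

    labels: list[str]
    points: np.ndarray
    frame: str = "tracker"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.labels = [str(label) for label in self.labels]
        if len(self.labels) != len(self.points):
            raise ValueError("labels and points must have equal length")
        if len(self.points) < 3:
            raise DegenerateGeometryError(
                f"need at least 3 fiducials, got {len(self.points)}"
            )
        centered = self.points - self.points.mean(axis=0)
        svals = np.linalg.svd(centered, compute_uv=False)
        # Collinearity leaves only one significant singular value; planar sets
        # (second value > tol, third ~ 0) are fine for a rigid fit.
        if svals[1] <= COLLINEAR_TOL:
            raise DegenerateGeometryError(
                "fiducials are collinear (second singular value "
                f"{svals[1]:.2e} mm <= {COLLINEAR_TOL:.0e} mm)"
            )

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class RegistrationResult:
    """Rigid fit of moving onto fixed fiducials plus its residual statistics."""

    transform: RigidTransform
    fre: float
    residuals: np.ndarray  # per-fiducial residual magnitudes, mm


@dataclass
class PivotResult:
    tip_offset: np.ndarray  # tool frame, mm
    pivot_point: np.ndarray  # tracker frame, mm
    rms_residual: float


def _check_paired(moving: FiducialSet, fixed: FiducialSet) -> None:
    if len(moving) != len(fixed):
        raise LabelMismatchError(
            f"fiducial counts differ: {len(moving)} moving vs {len(fixed)} fixed"
        )
    if moving.labels != fixed.labels:
        raise LabelMismatchError(
            f"fiducial labels differ: {moving.labels} vs {fixed.labels}"
        )


def rigid_register(moving: FiducialSet, fixed: FiducialSet) -> RegistrationResult:
    """Least-squares rigid fit of ``moving`` onto ``fixed`` (label-order pairing).

    Returns the transform ``moving.frame -> fixed.frame`` minimizing the sum
    of squared pair distances, with the FRE and per-fiducial residuals.
    """
    _check_paired(moving, fixed)
    m = moving.points
    f = fixed.points
    m_bar = m.mean(axis=0)
    f_bar = f.mean(axis=0)
    h = (m - m_bar).T @ (f - f_bar)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = f_bar - rotation @ m_bar
    transform = RigidTransform(
        rotation, translation, from_frame=moving.frame, to_frame=fixed.frame
    )
    residuals = np.linalg.norm(apply(transform, m) - f, axis=1)
    return RegistrationResult(transform, float(np.sqrt(np.mean(residuals**2))), residuals)


def compute_fre(transform: RigidTransform, moving: FiducialSet, fixed: FiducialSet) -> float:
    """RMS residual distance of paired fiducials under a given transform (mm)."""
    _check_paired(moving, fixed)
    residuals = np.linalg.norm(apply(transform, moving.points) - fixed.points, axis=1)
    return float(np.sqrt(np.mean(residuals**2)))


def pivot_calibrate(poses: list[Pose]) -> PivotResult:
    """Joint least-squares estimate of pointer tip offset and pivot point.

    Stacks ``[R_k  -I] [b; p] = -t_k`` over all valid poses. Requires enough
    orientation diversity for the system to be well conditioned; a condition
    number above ``PIVOT_MAX_CONDITION`` (e.g. near-constant rotation) raises
    :class:`DegenerateGeometryError`.
    """
    valid = [p for p in poses if p.valid]
    if len(valid) < 10:
        raise DegenerateGeometryError(f"need >= 10 valid poses, got {len(valid)}")
    n = len(valid)
    a = np.zeros((3 * n, 6))
    b = np.zeros(3 * n)
    for k, pose in enumerate(valid):
        a[3 * k : 3 * k + 3, :3] = pose.transform.rotation
        a[3 * k : 3 * k + 3, 3:] = -np.eye(3)
        b[3 * k : 3 * k + 3] = -pose.transform.translation
    svals = np.linalg.svd(a, compute_uv=False)
    cond = svals[0] / svals[-1] if svals[-1] > 0 else np.inf
    if cond > PIVOT_MAX_CONDITION:
        raise DegenerateGeometryError(
            f"insufficient rotation span: pivot system condition number {cond:.2e}"
        )
    x, *_ = np.linalg.lstsq(a, b, rcond=None)
    tip_offset, pivot_point = x[:3], x[3:]
    residuals = a @ x - b
    per_pose = np.linalg.norm(residuals.reshape(n, 3), axis=1)
    return PivotResult(tip_offset, pivot_point, float(np.sqrt(np.mean(per_pose**2))))


# -- CSV interface -----------------------------------------------------------

FIDUCIAL_CSV_COLUMNS = ["label", "x_mm", "y_mm", "z_mm", "frame"]


def read_fiducials(path) -> FiducialSet:
    """Read a fiducial CSV (`label,x_mm,y_mm,z_mm,frame`); one frame per file."""
    df = pd.read_csv(path)
    missing = set(FIDUCIAL_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"fiducial CSV missing columns: {sorted(missing)}")
    frames = df["frame"].unique()
    if len(frames) != 1:
        raise ValueError(f"fiducial CSV must contain a single frame, got {list(frames)}")
    return FiducialSet(
        labels=df["label"].astype(str).tolist(),
        points=df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float),
        frame=str(frames[0]),
    )


def write_fiducials(fiducials: FiducialSet, path) -> None:
    pd.DataFrame(
        {
            "label": fiducials.labels,
            "x_mm": fiducials.points[:, 0],
            "y_mm": fiducials.points[:, 1],
            "z_mm": fiducials.points[:, 2],
            "frame": fiducials.frame,
        }
    ).to_csv(path, index=False, float_format="%.17g")
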