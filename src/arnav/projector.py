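"""Pinhole model of the tracked pico-projector.

The projector is modelled as an inverse camera: a pinhole with zero skew and
no lens distortion whose optical centre emits the image. Its pixel
convention is 0-based with the origin at the top-left pixel centre, +u right
and +v down; the projector looks along +z of its own frame, so a point at
depth z > 0 maps to ``u = fu*x/z + cu``, ``v = fv*y/z + cv``.

Calibration estimates a 3x4 projection matrix from >= 6 pixel <-> 3-D
correspondences by the normalized direct linear transform (DLT), decomposes
it into intrinsics and pose (RQ factorization), and — given the pose of the
rigidly attached tracking sensor at calibration time — stores the fixed
projector -> sensor transform. That transform is what lets the tracker's
live sensor pose drive a virtual camera that stays synchronized with the
physical projector as it is repositioned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .errors import (
    BehindProjectorError,
    DegenerateGeometryError,
    NoIntersectionError,
    OutOfBoundsError,
)
from .geometry import Pose, RigidTransform, apply, compose, invert

#: Depth below this (mm) counts as "behind the projector".
MIN_DEPTH = 1e-9

#: Rays this close to parallel with a plane do not intersect it.
PARALLEL_TOL = 1e-9

#: Centered 3-D calibration points whose smallest singular value falls below
#: this are coplanar and cannot constrain a full projection matrix.
COPLANAR_TOL = 1e-6


@dataclass(frozen=True)
class ProjectorModel:
    """Calibrated projector: pinhole intrinsics + fixed sensor mounting."""

    fu: float
    fv: float
    cu: float
    cv: float
    width: int
    height: int
    t_sensor_to_projector: RigidTransform  # maps projector-frame points -> sensor frame

    def __post_init__(self) -> None:
        if self.fu <= 0 or self.fv <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cu < self.width and 0 <= self.cv < self.height):
            raise ValueError("principal point must lie inside the image")

    def intrinsic_matrix(self) -> np.ndarray:
        return np.array(
            [[self.fu, 0.0, self.cu], [0.0, self.fv, self.cv], [0.0, 0.0, 1.0]]
        )

    def to_dict(self) -> dict:
        return {
            "fu": self.fu,
            "fv": self.fv,
            "cu": self.cu,
            "cv": self.cv,
            "width": self.width,
            "height": self.height,
            "t_sensor_to_projector": self.t_sensor_to_projector.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProjectorModel":
        return cls(
            fu=float(d["fu"]),
            fv=float(d["fv"]),
            cu=float(d["cu"]),
            cv=float(d["cv"]),
            width=int(d["width"]),
            height=int(d["height"]),
            t_sensor_to_projector=RigidTransform.from_dict(d["t_sensor_to_projector"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "ProjectorModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class Ray:
    """Half-line from ``origin`` along unit ``direction`` in a named frame."""

    origin: np.ndarray
    direction: np.ndarray
    frame: str = "tracker"

    def __post_init__(self) -> None:
        origin = np.asarray(self.origin, dtype=float).reshape(3)
        direction = np.asarray(self.direction, dtype=float).reshape(3)
        norm = np.linalg.norm(direction)
        if abs(norm - 1.0) > 1e-9:
            direction = direction / norm
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "direction", direction)


@dataclass(frozen=True)
class Plane:
    """Infinite plane through ``point`` with unit ``normal``."""

    point: np.ndarray
    normal: np.ndarray
    frame: str = "tracker"

    def __post_init__(self) -> None:
        point = np.asarray(self.point, dtype=float).reshape(3)
        normal = np.asarray(self.normal, dtype=float).reshape(3)
        normal = normal / np.linalg.norm(normal)
        object.__setattr__(self, "point", point)
        object.__setattr__(self, "normal", normal)


def default_projector_model() -> ProjectorModel:
    """Package-default pico-projector: 800x600, f = 1000 px, sensor mounted
    30 mm above the optical centre with axes aligned."""
    mount = RigidTransform(
        np.eye(3), np.array([0.0, -30.0, 0.0]), from_frame="projector", to_frame="sensor"
    )
    return ProjectorModel(
        fu=1000.0, fv=1000.0, cu=400.0, cv=300.0, width=800, height=600,
        t_sensor_to_projector=mount,
    )


# -- calibration -------------------------------------------------------------


def _normalization_2d(pts: np.ndarray) -> np.ndarray:
    centroid = pts.mean(axis=0)
    scale = np.sqrt(2.0) / np.mean(np.linalg.norm(pts - centroid, axis=1))
    t = np.diag([scale, scale, 1.0])
    t[:2, 2] = -scale * centroid
    return t


def _normalization_3d(pts: np.ndarray) -> np.ndarray:
    centroid = pts.mean(axis=0)
    scale = np.sqrt(3.0) / np.mean(np.linalg.norm(pts - centroid, axis=1))
    t = np.eye(4)
    t[:3, :3] *= scale
    t[:3, 3] = -scale * centroid
    return t


def dlt_calibrate(
    pixels,
    world_points,
    sensor_pose: Pose,
    width: int = 800,
    height: int = 600,
    refine: bool = True,
) -> tuple[ProjectorModel, float]:
    """Calibrate the projector from pixel <-> world correspondences.

    Solves the 3x4 projection matrix by the normalized DLT, decomposes it
    into zero-skew intrinsics and the world -> projector pose, then (by
    default) refines the ten free parameters by nonlinear least squares on
    the reprojection error — the linear solve minimizes algebraic error
    only. The simultaneous ``sensor_pose`` (sensor -> tracker) expresses
    the rigid projector -> sensor mounting. Returns the model and the
    reprojection RMS in pixels.
    """
    px = np.asarray(pixels, dtype=float).reshape(-1, 2)
    xyz = np.asarray(world_points, dtype=float).reshape(-1, 3)
    if len(px) != len(xyz):
        raise ValueError("pixel and world point counts differ")
    if len(px) < 6:
        raise DegenerateGeometryError(f"need >= 6 correspondences, got {len(px)}")
    centered = xyz - xyz.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[-1] / len(xyz) ** 0.5 <= COPLANAR_TOL:
        raise DegenerateGeometryError(
            "calibration points are coplanar; the projection matrix is unconstrained"
        )

    t2 = _normalization_2d(px)
    t3 = _normalization_3d(xyz)
    px_h = np.hstack([px, np.ones((len(px), 1))]) @ t2.T
    xyz_h = np.hstack([xyz, np.ones((len(xyz), 1))]) @ t3.T

    a = np.zeros((2 * len(px), 12))
    for i, (uvw, p) in enumerate(zip(px_h, xyz_h)):
        u, v = uvw[0] / uvw[2], uvw[1] / uvw[2]
        a[2 * i, 0:4] = p
        a[2 * i, 8:12] = -u * p
        a[2 * i + 1, 4:8] = p
        a[2 * i + 1, 8:12] = -v * p
    _, svals_a, vt = np.linalg.svd(a)
    if svals_a[-2] <= 1e-9 * svals_a[0]:
        raise DegenerateGeometryError("DLT system is rank deficient (degenerate geometry)")
    p_norm = vt[-1].reshape(3, 4)
    p_mat = np.linalg.inv(t2) @ p_norm @ t3

    # Fix the overall sign so points sit at positive depth.
    if np.linalg.det(p_mat[:, :3]) < 0:
        p_mat = -p_mat

    k, r = scipy.linalg.rq(p_mat[:, :3])
    signs = np.sign(np.diag(k))
    k = k * signs[np.newaxis, :]
    r = r * signs[:, np.newaxis]
    k = k / k[2, 2]
    t_vec = np.linalg.solve(k, p_mat[:, 3])

    # Zero skew is part of the model; discard the (numerically tiny) estimate.
    fu, fv = float(k[0, 0]), float(k[1, 1])
    cu, cv = float(k[0, 2]), float(k[1, 2])

    if refine:
        from scipy.optimize import least_squares
        from scipy.spatial.transform import Rotation

        def residuals(params):
            fu_, fv_, cu_, cv_ = params[:4]
            rot = Rotation.from_rotvec(params[4:7]).as_matrix()
            cam = xyz @ rot.T + params[7:]
            return np.concatenate(
                [
                    fu_ * cam[:, 0] / cam[:, 2] + cu_ - px[:, 0],
                    fv_ * cam[:, 1] / cam[:, 2] + cv_ - px[:, 1],
                ]
            )

        x0 = np.concatenate(
            [[fu, fv, cu, cv], Rotation.from_matrix(r).as_rotvec(), t_vec]
        )
        sol = least_squares(residuals, x0, method="lm")
        fu, fv, cu, cv = sol.x[:4]
        r = Rotation.from_rotvec(sol.x[4:7]).as_matrix()
        t_vec = sol.x[7:]
        k = np.array([[fu, 0.0, cu], [0.0, fv, cv], [0.0, 0.0, 1.0]])
        p_mat = k @ np.hstack([r, t_vec[:, None]])

    # r, t_vec map world -> projector; store projector -> tracker, then
    # express it relative to the sensor at calibration time.
    t_world_to_proj = RigidTransform(r, t_vec, from_frame="tracker", to_frame="projector")
    t_proj_to_world = invert(t_world_to_proj)
    t_proj_to_sensor = compose(invert(sensor_pose.transform), t_proj_to_world)
    model = ProjectorModel(
        fu=fu, fv=fv, cu=cu, cv=cv, width=width, height=height,
        t_sensor_to_projector=t_proj_to_sensor,
    )

    proj = np.hstack([xyz, np.ones((len(xyz), 1))]) @ p_mat.T
    uv = proj[:, :2] / proj[:, 2:3]
    # RMS over the u and v residual components (per-component convention).
    rms = float(np.sqrt(np.mean((uv - px) ** 2)))
    return model, rms


# -- projection and ray casting ---------------------------------------------


def _world_to_projector(model: ProjectorModel, projector_pose: Pose) -> RigidTransform:
    """tracker -> projector transform from the live sensor pose."""
    if not projector_pose.valid:
        raise ValueError("projector pose is invalid")
    t_proj_to_world = compose(projector_pose.transform, model.t_sensor_to_projector)
    return invert(t_proj_to_world)


def project_point(model: ProjectorModel, projector_pose: Pose, world_point) -> np.ndarray:
    """Pinhole projection of a world point to pixel coordinates ``(u, v)``."""
    p = apply(_world_to_projector(model, projector_pose), world_point)
    if p[2] <= MIN_DEPTH:
        raise BehindProjectorError(
            f"point at depth {p[2]:.3f} mm is behind the projector"
        )
    return np.array(
        [model.fu * p[0] / p[2] + model.cu, model.fv * p[1] / p[2] + model.cv]
    )


def cast_ray(model: ProjectorModel, projector_pose: Pose, pixel) -> Ray:
    """World-frame ray from the projector centre through a pixel."""
    u, v = float(pixel[0]), float(pixel[1])
    if not (0 <= u < model.width and 0 <= v < model.height):
        raise OutOfBoundsError(
            f"pixel ({u}, {v}) outside {model.width}x{model.height} image"
        )
    t_proj_to_world = compose(projector_pose.transform, model.t_sensor_to_projector)
    direction_proj = np.array([(u - model.cu) / model.fu, (v - model.cv) / model.fv, 1.0])
    origin = apply(t_proj_to_world, np.zeros(3))
    direction = t_proj_to_world.rotation @ direction_proj
    return Ray(origin, direction / np.linalg.norm(direction), frame=t_proj_to_world.to_frame)


def intersect(ray: Ray, surface) -> np.ndarray:
    """Nearest positive-parameter intersection of a ray with a plane or mesh.

    ``surface`` is a :class:`Plane` or an object with ``vertices`` and
    ``triangles`` (a surface mesh).
    """
    if isinstance(surface, Plane):
        denom = float(np.dot(ray.direction, surface.normal))
        if abs(denom) < PARALLEL_TOL:
            raise NoIntersectionError("ray is parallel to the plane")
        s = float(np.dot(surface.point - ray.origin, surface.normal)) / denom
        if s <= 0:
            raise NoIntersectionError("plane lies behind the ray origin")
        return ray.origin + s * ray.direction
    if hasattr(surface, "vertices") and hasattr(surface, "triangles"):
        verts = np.asarray(surface.vertices, dtype=float)
        tris = np.asarray(surface.triangles, dtype=int)
        s = _ray_triangles(ray.origin, ray.direction, verts, tris)
        if s is None:
            raise NoIntersectionError("ray does not hit the mesh")
        return ray.origin + s * ray.direction
    raise TypeError(f"unsupported surface type: {type(surface).__name__}")


def _ray_triangles(origin, direction, verts, tris) -> float | None:
    """Smallest positive ray parameter hitting any triangle (Moller-Trumbore,
    vectorized over triangles); None if there is no hit."""
    v0 = verts[tris[:, 0]]
    e1 = verts[tris[:, 1]] - v0
    e2 = verts[tris[:, 2]] - v0
    pvec = np.cross(direction, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > 1e-12
    inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    tvec = origin - v0
    u = np.einsum("ij,ij->i", tvec, pvec) * inv_det
    qvec = np.cross(tvec, e1)
    v = np.einsum("j,ij->i", direction, qvec) * inv_det
    s = np.einsum("ij,ij->i", e2, qvec) * inv_det
    eps = 1e-9
    hit = ok & (u >= -eps) & (v >= -eps) & (u + v <= 1.0 + eps) & (s > eps)
    if not hit.any():
        return None
    return float(s[hit].min())
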