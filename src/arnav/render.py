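"""The AR virtual camera: rendering plan content into the projector framebuffer.

Because the projector is tracked and calibrated, a virtual camera with the
projector's intrinsics and pose renders surgical-plan content (structure
meshes, fused image slices) so that the projected light lands on the
corresponding physical anatomy. Rendering is a software rasterizer with a
z-buffer at the projector resolution; overlays are flat-colored (no
shading), composited back-to-front with per-structure opacity, slices
first, then meshes ordered by centroid depth.

Also here: pointer-driven slice scrolling (map a tracked tip to a slice
index) and the safety-margin proximity alert.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DegenerateGeometryError, OutOfBoundsError
from .geometry import RigidTransform, Pose, apply, compose, invert
from .projector import MIN_DEPTH, ProjectorModel, _world_to_projector
from .volume import AXIS_NAMES, LabelMask, SurfaceMesh, VolumeImage, fuse_slice

ROLES = ("target", "margin", "critical", "bone")


@dataclass
class PlanStructure:
    """One overlay structure: a mesh (or bare points) with display attributes."""

    geometry: SurfaceMesh | np.ndarray
    role: str = "target"
    color: tuple[float, float, float] = (0.0, 1.0, 0.0)
    opacity: float = 1.0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if not (0.0 <= self.opacity <= 1.0):
            raise ValueError(f"opacity must be in [0, 1], got {self.opacity}")
        if not isinstance(self.geometry, SurfaceMesh):
            self.geometry = np.asarray(self.geometry, dtype=float).reshape(-1, 3)


@dataclass
class SliceDisplay:
    """A fused anatomical/functional slice placed at its true world plane."""

    anat: VolumeImage
    func: VolumeImage | None = None
    axis: object = "coronal"
    index: int = 0
    alpha: float = 0.5
    colormap: str = "hot"
    opacity: float = 1.0


@dataclass
class SurgicalPlan:
    structures: list[PlanStructure] = field(default_factory=list)
    slice_display: SliceDisplay | None = None


@dataclass
class Framebuffer:
    """Projector-resolution RGB image, values in [0, 1]."""

    data: np.ndarray  # (height, width, 3)
    background: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @classmethod
    def blank(cls, model: ProjectorModel, background=(0.0, 0.0, 0.0)) -> "Framebuffer":
        data = np.empty((model.height, model.width, 3))
        data[...] = background
        return cls(data, background)

    def save_png(self, path) -> None:
        from PIL import Image

        Image.fromarray((np.clip(self.data, 0, 1) * 255).astype(np.uint8)).save(str(path))


# -- rasterization helpers ---------------------------------------------------


def _project_vertices(model: ProjectorModel, verts_proj: np.ndarray) -> np.ndarray:
    """Pinhole-project projector-frame vertices to (u, v); depth preserved."""
    uv = np.empty((len(verts_proj), 2))
    z = verts_proj[:, 2]
    uv[:, 0] = model.fu * verts_proj[:, 0] / z + model.cu
    uv[:, 1] = model.fv * verts_proj[:, 1] / z + model.cv
    return uv


def _raster_triangle(fb, zbuf, uv, z, shade, opacity: float) -> None:
    """Rasterize one triangle with z-test and alpha blending.

    ``shade(w0, w1, w2, zi)`` returns per-pixel RGB from perspective-correct
    barycentric weights.
    """
    h, w = zbuf.shape
    xmin = max(int(np.floor(uv[:, 0].min())), 0)
    xmax = min(int(np.ceil(uv[:, 0].max())), w - 1)
    ymin = max(int(np.floor(uv[:, 1].min())), 0)
    ymax = min(int(np.ceil(uv[:, 1].max())), h - 1)
    if xmin > xmax or ymin > ymax:
        return
    area = (uv[1, 0] - uv[0, 0]) * (uv[2, 1] - uv[0, 1]) - (uv[1, 1] - uv[0, 1]) * (
        uv[2, 0] - uv[0, 0]
    )
    if abs(area) < 1e-12:
        return
    xs = np.arange(xmin, xmax + 1) + 0.0
    ys = np.arange(ymin, ymax + 1) + 0.0
    gx, gy = np.meshgrid(xs, ys)
    w0 = ((uv[1, 0] - gx) * (uv[2, 1] - gy) - (uv[1, 1] - gy) * (uv[2, 0] - gx)) / area
    w1 = ((uv[2, 0] - gx) * (uv[0, 1] - gy) - (uv[2, 1] - gy) * (uv[0, 0] - gx)) / area
    w2 = 1.0 - w0 - w1
    inside = (w0 >= 0) & (w1 >= 0) & (w2 >= 0)
    if not inside.any():
        return
    # perspective-correct interpolation in 1/z
    inv_z = w0 * (1.0 / z[0]) + w1 * (1.0 / z[1]) + w2 * (1.0 / z[2])
    zi = np.where(inv_z > 0, 1.0 / np.maximum(inv_z, 1e-30), np.inf)
    sub_z = zbuf[ymin : ymax + 1, xmin : xmax + 1]
    draw = inside & (zi < sub_z)
    if not draw.any():
        return
    rgb = shade(w0, w1, w2, zi)
    sub_fb = fb[ymin : ymax + 1, xmin : xmax + 1]
    blended = (1.0 - opacity) * sub_fb + opacity * rgb
    sub_fb[draw] = blended[draw]
    sub_z[draw] = zi[draw]


def _slice_quad(display: SliceDisplay) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """Image-frame corner coordinates and texture coords of the slice plane."""
    vol = display.anat
    ax = AXIS_NAMES.get(display.axis, display.axis)
    other = [a for a in range(3) if a != ax]
    coord = vol.origin[ax] + display.index * vol.spacing[ax]
    lo = [vol.origin[a] - 0.5 * vol.spacing[a] for a in other]
    hi = [vol.origin[a] + (vol.shape[a] - 0.5) * vol.spacing[a] for a in other]
    corners = np.zeros((4, 3))
    tex = np.zeros((4, 2))  # (row, col) into the slice array, axes in `other` order
    n0, n1 = vol.shape[other[0]], vol.shape[other[1]]
    for i, (a0, a1) in enumerate([(0, 0), (1, 0), (1, 1), (0, 1)]):
        corners[i, ax] = coord
        corners[i, other[0]] = hi[0] if a0 else lo[0]
        corners[i, other[1]] = hi[1] if a1 else lo[1]
        tex[i] = [(n0 - 0.5) if a0 else -0.5, (n1 - 0.5) if a1 else -0.5]
    return corners, tex, (n0, n1)


def render_scene(
    plan: SurgicalPlan,
    model: ProjectorModel,
    projector_pose: Pose,
    registration: RigidTransform,
    background=(0.0, 0.0, 0.0),
) -> Framebuffer:
    """Render the surgical plan as seen from the tracked projector.

    ``registration`` maps the image frame to the tracker frame; the live
    sensor pose chains content on into the projector frame, where the
    pinhole intrinsics rasterize it. Returns the framebuffer to be emitted
    by the physical projector.
    """
    if not projector_pose.valid:
        raise ValueError("projector pose is invalid")
    world_to_proj = _world_to_projector(model, projector_pose)
    image_to_proj = compose(world_to_proj, registration)

    fb = Framebuffer.blank(model, background)
    zbuf = np.full((model.height, model.width), np.inf)

    if plan.slice_display is not None:
        disp = plan.slice_display
        corners, tex, _ = _slice_quad(disp)
        if disp.func is not None:
            texture = fuse_slice(disp.anat, disp.func, disp.axis, disp.index, disp.alpha, disp.colormap)
        else:
            from .volume import _normalize, take_slice

            slab = _normalize(
                take_slice(disp.anat, disp.axis, disp.index),
                disp.anat.data.min(),
                disp.anat.data.max(),
            )
            texture = np.stack([slab] * 3, axis=-1)
        verts_p = apply(image_to_proj, corners)
        if np.all(verts_p[:, 2] > MIN_DEPTH):
            uv = _project_vertices(model, verts_p)
            z = verts_p[:, 2]
            for tri in ((0, 1, 2), (0, 2, 3)):
                idx = list(tri)

                def shade(w0, w1, w2, zi, idx=idx):
                    tz = tex[idx] / z[idx][:, None]  # tex/z per vertex
                    tr = (w0 * tz[0, 0] + w1 * tz[1, 0] + w2 * tz[2, 0]) * zi
                    tc = (w0 * tz[0, 1] + w1 * tz[1, 1] + w2 * tz[2, 1]) * zi
                    ri = np.clip(np.round(tr).astype(int), 0, texture.shape[0] - 1)
                    ci = np.clip(np.round(tc).astype(int), 0, texture.shape[1] - 1)
                    return texture[ri, ci]

                _raster_triangle(fb.data, zbuf, uv[idx], z[idx], shade, disp.opacity)

    # Meshes back-to-front by centroid depth (farthest first).
    mesh_structs = []
    for struct in plan.structures:
        if isinstance(struct.geometry, SurfaceMesh):
            verts_p = apply(image_to_proj, struct.geometry.vertices) if len(
                struct.geometry.vertices
            ) else np.zeros((0, 3))
            depth = verts_p[:, 2].mean() if len(verts_p) else np.inf
            mesh_structs.append((depth, struct, verts_p))
    mesh_structs.sort(key=lambda item: -item[0])
    for _, struct, verts_p in mesh_structs:
        uv_all = np.zeros((len(verts_p), 2))
        front = verts_p[:, 2] > MIN_DEPTH
        uv_all[front] = _project_vertices(model, verts_p[front])
        color = np.asarray(struct.color, dtype=float)
        for tri in struct.geometry.triangles:
            if not front[tri].all():
                continue
            _raster_triangle(
                fb.data,
                zbuf,
                uv_all[tri],
                verts_p[tri, 2],
                lambda w0, w1, w2, zi: np.broadcast_to(color, w0.shape + (3,)),
                struct.opacity,
            )

    # Bare point structures: one pixel each at the projected location.
    for struct in plan.structures:
        if isinstance(struct.geometry, SurfaceMesh):
            continue
        pts_p = apply(image_to_proj, struct.geometry)
        color = np.asarray(struct.color, dtype=float)
        for p in np.atleast_2d(pts_p):
            if p[2] <= MIN_DEPTH:
                continue
            u = int(round(model.fu * p[0] / p[2] + model.cu))
            v = int(round(model.fv * p[1] / p[2] + model.cv))
            if 0 <= u < model.width and 0 <= v < model.height and p[2] < zbuf[v, u]:
                fb.data[v, u] = (1 - struct.opacity) * fb.data[v, u] + struct.opacity * color
                zbuf[v, u] = p[2]
    return fb


# -- pointer interaction -----------------------------------------------------


def pointer_to_slice(
    registration: RigidTransform,
    volume: VolumeImage,
    tip,
    axis,
    clamp: bool = False,
) -> int:
    """Slice index addressed by a tracked pointer tip.

    The tip (tracker frame, mm) is mapped into the image frame and the
    nearest slice index along ``axis`` returned. Out-of-bounds tips raise
    :class:`OutOfBoundsError` unless ``clamp`` is set, in which case the
    index is clamped to the volume.
    """
    ax = AXIS_NAMES.get(axis, axis)
    tip_img = apply(invert(registration), np.asarray(tip, dtype=float))
    idx = volume.world_to_index(tip_img)
    rounded = int(round(idx[ax]))
    if clamp:
        return int(np.clip(rounded, 0, volume.shape[ax] - 1))
    if np.any(idx < -0.5) or np.any(idx > np.array(volume.shape) - 0.5):
        raise OutOfBoundsError(
            f"pointer tip (image frame {np.round(tip_img, 3)}) outside volume bounds"
        )
    return rounded


def proximity_alert(
    tip,
    margin: LabelMask,
    registration: RigidTransform,
) -> dict:
    """Safety-margin check for a tracked instrument tip.

    Returns ``{"inside": bool, "distance_to_margin": mm}`` — distance is the
    Euclidean distance-transform value to the nearest margin voxel (0 when
    inside). Tips outside the volume are measured against the nearest margin
    voxel centre directly.
    """
    if margin.data.sum() == 0:
        raise DegenerateGeometryError("safety margin mask is empty")
    tip_img = apply(invert(registration), np.asarray(tip, dtype=float))
    idx = np.round((tip_img - margin.origin) / margin.spacing).astype(int)
    shape = np.array(margin.shape)
    if np.all(idx >= 0) and np.all(idx < shape):
        if margin.data[tuple(idx)]:
            return {"inside": True, "distance_to_margin": 0.0}
        dist = ndimage.distance_transform_edt(1 - margin.data, sampling=margin.spacing)
        return {"inside": False, "distance_to_margin": float(dist[tuple(idx)])}
    voxels = np.argwhere(margin.data > 0)
    centres = margin.origin + voxels * margin.spacing
    d = float(np.linalg.norm(centres - tip_img, axis=1).min())
    return {"inside": False, "distance_to_margin": d}
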