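"""Volume images: I/O, resampling, segmentation, surfaces, fusion, NMI.

A :class:`VolumeImage` is an axis-aligned scalar grid: the world coordinate
of voxel ``(i, j, k)`` is ``origin + spacing * (i, j, k)`` (mm, voxel
centres). Oblique direction matrices are out of scope for the rigid,
scanner-aligned setting this package targets and are rejected on read.

Multimodality fusion follows the operating-room display convention: the
anatomical volume (CT/MRI) is shown in grayscale, the functional volume
(PET/SPECT) colormapped on top with adjustable opacity. Rigid multimodality
registration maximizes normalized mutual information
``NMI = (H(A) + H(B)) / H(A, B)`` over the six rigid parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage
from scipy.optimize import minimize

from .errors import (
    DegenerateGeometryError,
    GridMismatchError,
    UnsupportedImageError,
)
from .geometry import RigidTransform

MODALITIES = ("CT", "PET", "MRI", "SPECT", "synthetic")

#: Named slice axes: index into the (x, y, z) grid axes.
AXIS_NAMES = {"sagittal": 0, "coronal": 1, "axial": 2}

NMI_BINS = 64


@dataclass
class VolumeImage:
    """Gridded scalar image with world geometry."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    modality: str = "synthetic"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3-D, got {self.data.ndim}-D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite voxels")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def world_to_index(self, points) -> np.ndarray:
        """Continuous voxel indices of world points (mm)."""
        return (np.asarray(points, dtype=float) - self.origin) / self.spacing

    def index_to_world(self, indices) -> np.ndarray:
        return self.origin + np.asarray(indices, dtype=float) * self.spacing

    def same_grid(self, other: "VolumeImage", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass
class LabelMask:
    """Binary structure mask sharing a VolumeImage's grid."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    structure: str = "tumour"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.isin(np.unique(self.data), (0, 1)).all():
            raise ValueError("mask values must be 0/1")
        self.data = self.data.astype(np.uint8)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class SurfaceMesh:
    """Triangulated surface in world millimetres."""

    vertices: np.ndarray
    triangles: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=int).reshape(-1, 3)
        if len(self.triangles) and self.triangles.max() >= len(self.vertices):
            raise ValueError("triangle index out of range")

    def is_empty(self) -> bool:
        return len(self.triangles) == 0

    def save_ply(self, path) -> None:
        import trimesh

        trimesh.Trimesh(self.vertices, self.triangles, process=False).export(
            str(path), file_type="ply", encoding="ascii"
        )

    @classmethod
    def load_ply(cls, path) -> "SurfaceMesh":
        import trimesh

        m = trimesh.load_mesh(str(path), process=False)
        return cls(np.asarray(m.vertices), np.asarray(m.faces))


# -- NIfTI I/O ---------------------------------------------------------------

_SUPPORTED_DTYPES = (np.uint8, np.int16, np.int32, np.float32, np.float64)


def read_volume(path, modality: str = "synthetic") -> VolumeImage:
    """Read an axis-aligned NIfTI-1 volume.

    Files with oblique/rotated direction matrices or negative axis scales
    are rejected: the navigation chain assumes scanner-aligned grids.
    """
    try:
        img = nib.load(str(path))
    except FileNotFoundError:
        raise FileNotFoundError(f"no such volume file: {path}")
    affine = img.affine
    rot = affine[:3, :3]
    if np.any(np.abs(rot - np.diag(np.diag(rot))) > 1e-6):
        raise UnsupportedImageError(
            "NIfTI direction matrix is not axis-aligned; resample the volume "
            "to an axis-aligned grid first"
        )
    if np.any(np.diag(rot) <= 0):
        raise UnsupportedImageError("NIfTI axis scales must be positive")
    data = np.asanyarray(img.dataobj)
    if not any(np.issubdtype(data.dtype, d) for d in _SUPPORTED_DTYPES):
        raise UnsupportedImageError(f"unsupported voxel dtype {data.dtype}")
    return VolumeImage(
        data=data,
        spacing=np.diag(rot).copy(),
        origin=affine[:3, 3].copy(),
        modality=modality,
    )


def write_volume(volume: VolumeImage | LabelMask, path) -> None:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(volume.spacing)
    affine[:3, 3] = volume.origin
    nib.save(nib.Nifti1Image(volume.data, affine), str(path))


# -- resampling --------------------------------------------------------------


def resample(volume: VolumeImage, new_spacing) -> VolumeImage:
    """Trilinear resample onto a new spacing, keeping the world origin.

    Output dimensions are ``ceil(dim * spacing / new_spacing)`` so the output
    extent covers the input extent; samples beyond the input grid take the
    nearest edge value.
    """
    new_spacing = np.asarray(new_spacing, dtype=float).reshape(3)
    if np.any(new_spacing <= 0):
        raise ValueError(f"new spacing must be positive, got {new_spacing}")
    old_dims = np.array(volume.shape)
    new_dims = np.ceil(old_dims * volume.spacing / new_spacing - 1e-9).astype(int)
    grids = [np.arange(n) * new_spacing[ax] / volume.spacing[ax] for ax, n in enumerate(new_dims)]
    coords = np.meshgrid(*grids, indexing="ij")
    out = ndimage.map_coordinates(
        volume.data.astype(float), np.stack(coords), order=1, mode="nearest"
    )
    return VolumeImage(out, new_spacing, volume.origin.copy(), volume.modality)


# -- segmentation and surfaces ----------------------------------------------


def threshold_segment(
    volume: VolumeImage, low: float, high: float = math.inf, structure: str = "tumour"
) -> LabelMask:
    """Binary mask of voxels with intensity in ``[low, high]`` (e.g. HU for CT)."""
    if low > high:
        raise ValueError(f"low threshold {low} exceeds high threshold {high}")
    mask = ((volume.data >= low) & (volume.data <= high)).astype(np.uint8)
    return LabelMask(mask, volume.spacing.copy(), volume.origin.copy(), structure)


def extract_isosurface(mask: LabelMask) -> SurfaceMesh:
    """Triangulated 0.5-level surface of a mask, in world mm (marching cubes).

    An empty mask yields an empty mesh.
    """
    if mask.data.sum() == 0:
        return SurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
    from skimage import measure

    padded = np.pad(mask.data.astype(float), 1)  # close surfaces touching the border
    # A touch of smoothing moves the 0.5 level off the voxel staircase and
    # onto the true structure boundary; without it surface area is biased
    # high by the axis-aligned facets.
    padded = ndimage.gaussian_filter(padded, sigma=1.0)
    verts, faces, _, _ = measure.marching_cubes(
        padded, level=0.5, spacing=tuple(mask.spacing), allow_degenerate=False
    )
    verts = verts - mask.spacing + mask.origin
    return SurfaceMesh(verts, faces)


# -- fusion ------------------------------------------------------------------


def _build_colormaps() -> dict[str, np.ndarray]:
    """Fixed 256-entry RGB lookup tables used by the fused display."""
    t = np.linspace(0.0, 1.0, 256)
    gray = np.stack([t, t, t], axis=1)
    # hot: black -> red -> yellow -> white, piecewise linear thirds
    hot = np.stack(
        [
            np.clip(3.0 * t, 0, 1),
            np.clip(3.0 * t - 1.0, 0, 1),
            np.clip(3.0 * t - 2.0, 0, 1),
        ],
        axis=1,
    )
    # rainbow: HSV hue sweep blue (240 deg) -> red (0 deg), full saturation
    import colorsys

    rainbow = np.array([colorsys.hsv_to_rgb(2.0 / 3.0 * (1.0 - x), 1.0, 1.0) for x in t])
    # purple: black -> violet -> near-white ramp used for bone renderings
    purple = np.stack(
        [
            np.clip(1.4 * t, 0, 1) * 0.75 + np.clip(2.0 * t - 1.0, 0, 1) * 0.25,
            np.clip(2.0 * t - 1.0, 0, 1),
            np.clip(1.4 * t, 0, 1) * 0.9 + np.clip(2.0 * t - 1.0, 0, 1) * 0.1,
        ],
        axis=1,
    )
    return {"gray": gray, "hot": hot, "rainbow": rainbow, "purple": purple}


COLORMAPS = _build_colormaps()


def _normalize(slab: np.ndarray, vmin: float, vmax: float) -> np.ndarray:
    if vmax <= vmin:
        return np.zeros_like(slab, dtype=float)
    return np.clip((slab.astype(float) - vmin) / (vmax - vmin), 0.0, 1.0)


def take_slice(volume: VolumeImage, axis, index: int) -> np.ndarray:
    """Extract one 2-D slice; ``axis`` is 0/1/2 or sagittal/coronal/axial."""
    ax = AXIS_NAMES.get(axis, axis)
    if not isinstance(ax, (int, np.integer)) or not 0 <= ax <= 2:
        raise ValueError(f"axis must be 0-2 or one of {sorted(AXIS_NAMES)}, got {axis!r}")
    if not 0 <= index < volume.shape[ax]:
        raise IndexError(f"slice {index} out of range for axis {ax} (size {volume.shape[ax]})")
    return np.take(volume.data, index, axis=ax)


def fuse_slice(
    anat: VolumeImage,
    func: VolumeImage,
    axis,
    index: int,
    alpha: float = 0.5,
    colormap: str = "hot",
) -> np.ndarray:
    """Alpha-blend a colormapped functional slice over the grayscale anatomy.

    Per pixel: ``(1 - alpha) * gray(anat) + alpha * cmap(func)``. Both
    volumes are window-normalized by their own global min/max. The two
    volumes must already share a grid (resample the functional first).
    Returns an (H, W, 3) float array in [0, 1].
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if colormap not in COLORMAPS:
        raise ValueError(f"unknown colormap {colormap!r}; choose from {sorted(COLORMAPS)}")
    if not anat.same_grid(func):
        raise GridMismatchError(
            "functional volume grid differs from anatomical grid; resample the "
            "functional volume onto the anatomical grid first"
        )
    a_slab = _normalize(take_slice(anat, axis, index), anat.data.min(), anat.data.max())
    f_slab = _normalize(take_slice(func, axis, index), func.data.min(), func.data.max())
    gray = np.stack([a_slab] * 3, axis=-1)
    lut = COLORMAPS[colormap]
    colored = lut[np.round(f_slab * 255).astype(int)]
    return np.clip((1.0 - alpha) * gray + alpha * colored, 0.0, 1.0)


# -- normalized mutual information registration ------------------------------


def nmi(a: np.ndarray, b: np.ndarray, bins: int = NMI_BINS) -> float:
    """Normalized mutual information ``(H(A) + H(B)) / H(A, B)`` of two samples."""
    hist, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins)
    p = hist / hist.sum()
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ha = -np.sum(pa[pa > 0] * np.log(pa[pa > 0]))
        hb = -np.sum(pb[pb > 0] * np.log(pb[pb > 0]))
        hab = -np.sum(p[p > 0] * np.log(p[p > 0]))
    if hab == 0:
        return 2.0
    return float((ha + hb) / hab)


def _sample_moving(
    moving: VolumeImage, fixed_world: np.ndarray, params: np.ndarray, center: np.ndarray
) -> np.ndarray:
    """Sample the moving volume at fixed-grid world points mapped through the
    rigid parameters (tx,ty,tz in mm, rx,ry,rz in degrees about ``center``)."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.from_euler("xyz", params[3:], degrees=True).as_matrix()
    pts = (fixed_world - center) @ rot.T + center + params[:3]
    idx = (pts - moving.origin) / moving.spacing
    return ndimage.map_coordinates(
        moving.data.astype(float), idx.T, order=1, mode="constant", cval=np.nan
    )


def nmi_register(
    moving: VolumeImage,
    fixed: VolumeImage,
    init: RigidTransform | None = None,
    bins: int = NMI_BINS,
    max_shift: float = 6.0,
) -> tuple[RigidTransform, float]:
    """Rigid registration maximizing NMI over 6 parameters.

    Returns the resampling transform mapping fixed-frame world coordinates to
    moving-frame world coordinates (ITK convention: sample the moving image
    through it to align with the fixed image) plus the NMI at the optimum.
    Optimization is a coarse-to-fine translation grid followed by
    Nelder–Mead over all six parameters; rotations are about the fixed
    volume's world centre.
    """
    for vol in (moving, fixed):
        if np.ptp(vol.data) == 0:
            raise DegenerateGeometryError("cannot register a constant image")

    fixed_idx = np.stack(
        np.meshgrid(*[np.arange(n) for n in fixed.shape], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    fixed_world = fixed.origin + fixed_idx * fixed.spacing
    fixed_vals = fixed.data.astype(float).ravel()
    center = fixed.origin + (np.array(fixed.shape) - 1) * fixed.spacing / 2.0

    init_params = np.zeros(6)
    if init is not None:
        init_params[:3] = init.translation
        from scipy.spatial.transform import Rotation

        init_params[3:] = Rotation.from_matrix(init.rotation).as_euler("xyz", degrees=True)

    def score(params: np.ndarray) -> float:
        vals = _sample_moving(moving, fixed_world, params, center)
        inside = ~np.isnan(vals)
        if inside.sum() < 0.25 * len(vals):
            return 0.0  # negligible overlap
        return nmi(vals[inside], fixed_vals[inside], bins=bins)

    # Coarse-to-fine translation search around the initial guess.
    best = init_params.copy()
    best_score = score(best)
    step = max_shift / 3.0
    for _ in range(3):
        offsets = np.array([-step, 0.0, step])
        candidates = []
        for dx in offsets:
            for dy in offsets:
                for dz in offsets:
                    p = best.copy()
                    p[:3] += (dx, dy, dz)
                    candidates.append(p)
        for p in candidates:
            s = score(p)
            if s > best_score:
                best_score, best = s, p
        step /= 2.0

    # Explicit initial simplex: Nelder-Mead's default steps collapse for
    # near-zero parameters and would leave rotations unexplored.
    steps = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])
    simplex = np.vstack([best, best + np.diag(steps)])
    res = minimize(
        lambda p: -score(p),
        best,
        method="Nelder-Mead",
        options={
            "xatol": 1e-3,
            "fatol": 1e-9,
            "maxiter": 600,
            "initial_simplex": simplex,
        },
    )
    params = res.x if -res.fun >= best_score else best
    final_score = max(-res.fun, best_score)

    from scipy.spatial.transform import Rotation

    rot = Rotation.from_euler("xyz", params[3:], degrees=True).as_matrix()
    # world_moving = R (w - c) + c + t  for fixed-frame world point w
    translation = center + params[:3] - rot @ center
    transform = RigidTransform(rot, translation, from_frame="fixed", to_frame="moving")
    return transform, float(final_score)


# -- synthetic subject -------------------------------------------------------


@dataclass
class SubjectParams:
    """Geometry and intensity recipe for the synthetic small-animal subject.

    Defaults emulate a mouse-torso field of view at the 0.3 mm isotropic
    spacing used for navigation: an ellipsoidal soft-tissue body, two
    rod-like high-intensity "skeleton" elements, a spherical tumour, and a
    functional hotspot co-located with the tumour. Intensities are
    CT-like (HU); the functional volume is in arbitrary uptake units.
    """

    shape: tuple[int, int, int] = (64, 48, 100)
    spacing: tuple[float, float, float] = (0.3, 0.3, 0.3)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    body_center: tuple[float, float, float] | None = None  # defaults to volume centre
    body_semiaxes: tuple[float, float, float] = (8.5, 6.0, 14.0)
    rod_radius: float = 1.0
    rod_offsets: tuple[float, ...] = (-3.0, 3.0)  # x-offsets of the two skeleton rods
    tumour_center: tuple[float, float, float] | None = None
    tumour_radius: float = 4.0
    air_hu: float = -1000.0
    soft_hu: float = 40.0
    bone_hu: float = 1200.0
    tumour_hu: float = 120.0
    hotspot_intensity: float = 100.0
    func_background: float = 1.0
    noise_sigma: float = 5.0
    func_noise_sigma: float = 0.05


def make_synthetic_subject(
    seed: int = 0, params: SubjectParams | None = None
) -> dict[str, VolumeImage | LabelMask]:
    """Generate a synthetic imaging subject for end-to-end navigation tests.

    Returns ``{"ct", "functional", "tumour_mask", "bone_mask"}`` on one
    world-aligned grid. The tumour mask is exactly the voxelized tumour
    sphere and the functional hotspot is co-located with it; with
    ``noise_sigma = 0`` thresholding the CT at the tumour band reproduces the
    mask bit-exactly.
    """
    p = params or SubjectParams()
    rng = np.random.default_rng(seed)
    spacing = np.asarray(p.spacing, dtype=float)
    origin = np.asarray(p.origin, dtype=float)
    shape = tuple(p.shape)

    idx = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1)
    world = origin + idx * spacing
    extent_center = origin + (np.asarray(shape) - 1) * spacing / 2.0
    body_center = (
        np.asarray(p.body_center, dtype=float) if p.body_center is not None else extent_center
    )
    tumour_center = (
        np.asarray(p.tumour_center, dtype=float)
        if p.tumour_center is not None
        else body_center + np.array([2.0, 1.0, 5.0])
    )

    rel = (world - body_center) / np.asarray(p.body_semiaxes)
    body = (rel**2).sum(axis=-1) <= 1.0

    t_rel = (tumour_center - body_center) / np.asarray(p.body_semiaxes)
    if (t_rel**2).sum() > 1.0:
        raise ValueError("tumour sphere extends outside the body ellipsoid")
    d_tumour = np.linalg.norm(world - tumour_center, axis=-1)
    tumour = d_tumour <= p.tumour_radius
    if np.any(tumour & ~body):
        raise ValueError("tumour sphere extends outside the body ellipsoid")

    bone = np.zeros(shape, dtype=bool)
    for dx in p.rod_offsets:
        rod_axis = body_center + np.array([dx, -2.0, 0.0])
        r_xy = np.linalg.norm(world[..., :2] - rod_axis[:2], axis=-1)
        z_ok = np.abs(world[..., 2] - body_center[2]) <= 0.85 * p.body_semiaxes[2]
        bone |= (r_xy <= p.rod_radius) & z_ok & body

    ct = np.full(shape, p.air_hu)
    ct[body] = p.soft_hu
    ct[tumour] = p.tumour_hu
    ct[bone & ~tumour] = p.bone_hu
    if p.noise_sigma > 0:
        ct = ct + rng.normal(0.0, p.noise_sigma, size=shape)

    func = np.full(shape, 0.0)
    func[body] = p.func_background
    func[tumour] = p.hotspot_intensity
    if p.func_noise_sigma > 0:
        func = func + rng.normal(0.0, p.func_noise_sigma, size=shape)

    return {
        "ct": VolumeImage(ct, spacing, origin, "CT"),
        "functional": VolumeImage(func, spacing, origin, "PET"),
        "tumour_mask": LabelMask(tumour.astype(np.uint8), spacing, origin, "tumour"),
        "bone_mask": LabelMask((bone & ~tumour).astype(np.uint8), spacing, origin, "bone"),
    }
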