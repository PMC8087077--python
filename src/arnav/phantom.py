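"""In-silico checkerboard-phantom accuracy study.

The accuracy of the projector overlay is quantified on a machined
checkerboard phantom: a planar grid of conical divots at known spacing.
After fiducial registration (a subset of divots localized with the tracked
pointer), the projector is placed at a series of standoff distances and,
for every divot, the "real" location (mean of repeated tracked-pointer
localizations) is compared with the "virtual" location — the point where
the projector ray that draws the divot's virtual marker actually lands on
the physical phantom plane. The per-divot error is

    Err = || (x, y, z)_real - (x, y, z)_virtual ||

and accuracy is reported as per-distance RMS +/- SD plus an overall
aggregate (the unweighted mean of the per-distance RMS values; a pooled RMS
is also emitted).

The virtual point is computed under the *noisy tracked* projector pose but
intersected with the *true* phantom plane: that is the physical mechanism
by which tracking and registration error displace the projected image.
With all noise at zero the full chain (registration -> pose -> projection
-> ray -> plane) is exactly consistent and every error is zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError
from .geometry import Pose, RigidTransform, apply, compose, invert
from .projector import Plane, ProjectorModel, cast_ray, intersect, project_point
from .registration import FiducialSet, RegistrationResult, rigid_register
from .tracking import (
    NoiseModel,
    ToolDefinition,
    default_pointer_tool,
    default_sensor_tool,
    measure_pose,
    pointer_tip,
)

#: Protocol defaults: 3 repetitions per divot at 200/300/400 mm standoff.
DEFAULT_DISTANCES = (200.0, 300.0, 400.0)
DEFAULT_REPS = 3

#: Std dev (radians, per rotvec axis) of the random pointer tilt between
#: repeated manual localizations of the same divot.
POINTER_TILT_SIGMA = 0.15


@dataclass
class PhantomSpec:
    """Checkerboard phantom geometry.

    Defaults are the machined reference phantom: a 5x5 grid of central
    divots at 20 mm spacing over 10 mm checker squares, registered on its 4
    corner divots. ``checker_square`` and ``divot_spacing`` are independent
    (divots occupy alternating checker squares).
    """

    rows: int = 5
    cols: int = 5
    divot_spacing: float = 20.0
    checker_square: float = 10.0
    registration_divots: list[str] | None = None
    plane_pose: RigidTransform = field(
        default_factory=lambda: RigidTransform.identity("tracker")
    )

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must be at least 1x1")
        if self.divot_spacing <= 0 or self.checker_square <= 0:
            raise ValueError("spacings must be positive")
        if self.registration_divots is None:
            corners = {
                f"r0c0",
                f"r0c{self.cols - 1}",
                f"r{self.rows - 1}c0",
                f"r{self.rows - 1}c{self.cols - 1}",
            }
            self.registration_divots = sorted(corners)


@dataclass
class Phantom:
    """Generated phantom: divot coordinates in the image (CAD) frame and in
    the tracker frame, plus the physical plane."""

    spec: PhantomSpec
    labels: list[str]
    points_image: np.ndarray  # (N, 3) phantom/image frame, mm
    points_world: np.ndarray  # (N, 3) tracker frame, mm
    plane: Plane

    def divot(self, label: str) -> int:
        return self.labels.index(label)

    def registration_set(self) -> tuple[FiducialSet, np.ndarray]:
        """Image-frame registration fiducials and their true world positions."""
        labels = self.spec.registration_divots
        try:
            idx = [self.divot(lbl) for lbl in labels]
        except ValueError as exc:
            raise DegenerateGeometryError(f"unknown registration divot: {exc}")
        fids = FiducialSet(labels, self.points_image[idx], frame="image")
        return fids, self.points_world[idx]

    def checker_pattern(self, pixels_per_square: int = 10) -> np.ndarray:
        """Binary checkerboard image covering the divot grid (for display)."""
        extent = max(self.spec.rows, self.spec.cols) * self.spec.divot_spacing
        n = int(np.ceil(extent / self.spec.checker_square)) | 1
        sq = np.indices((n, n)).sum(axis=0) % 2
        return np.kron(sq, np.ones((pixels_per_square, pixels_per_square), dtype=int))


def generate_phantom(spec: PhantomSpec | None = None) -> Phantom:
    """Lay out the divot grid on the phantom plane (deterministic).

    Divots are labelled ``r{i}c{j}`` and centred on the plane origin; the
    plane pose carries the phantom into the tracker frame. The plane normal
    is the phantom +z axis.
    """
    spec = spec or PhantomSpec()
    labels, pts = [], []
    for i in range(spec.rows):
        for j in range(spec.cols):
            labels.append(f"r{i}c{j}")
            pts.append(
                [
                    (j - (spec.cols - 1) / 2.0) * spec.divot_spacing,
                    (i - (spec.rows - 1) / 2.0) * spec.divot_spacing,
                    0.0,
                ]
            )
    points_image = np.asarray(pts)
    points_world = apply(spec.plane_pose, points_image)
    plane = Plane(
        point=apply(spec.plane_pose, np.zeros(3)),
        normal=spec.plane_pose.rotation[:, 2],
        frame=spec.plane_pose.to_frame,
    )
    phantom = Phantom(spec, labels, points_image, points_world, plane)
    if len(spec.registration_divots) >= 3:
        phantom.registration_set()  # validate early (subset known, non-collinear)
    return phantom


@dataclass
class LocalizationRecord:
    """One divot localization: pointer sample, per-condition mean ("real"),
    projected landing point ("virtual"), and their distance."""

    divot_id: str
    distance_condition: float
    rep_index: int
    pointer_sample: np.ndarray
    real_point: np.ndarray
    virtual_point: np.ndarray
    err: float


@dataclass
class DistanceStats:
    rms: float
    sd: float
    n: int


@dataclass
class AccuracyReport:
    """Phantom-study summary: FRE plus per-distance and overall error."""

    fre: float
    per_distance: dict[float, DistanceStats]
    overall: tuple[float, float]  # (mean of per-distance RMS, pooled SD)
    pooled_rms: float
    n_localizations: int
    seed: int | None = None
    noise: dict | None = None

    def to_dict(self) -> dict:
        return {
            "fre_mm": self.fre,
            "per_distance_mm": {
                str(d): {"rms": s.rms, "sd": s.sd, "n": s.n}
                for d, s in sorted(self.per_distance.items())
            },
            "overall_mm": {"value": self.overall[0], "sd": self.overall[1]},
            "pooled_rms_mm": self.pooled_rms,
            "n_localizations": self.n_localizations,
            "seed": self.seed,
            "noise": self.noise,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass
class ProtocolResult:
    records: list[LocalizationRecord]
    fre: float
    registration: RegistrationResult


def localization_error(real, virtual) -> float:
    """Euclidean distance (mm) between the real and virtual divot locations."""
    real = np.asarray(real, dtype=float).reshape(3)
    virtual = np.asarray(virtual, dtype=float).reshape(3)
    if not (np.all(np.isfinite(real)) and np.all(np.isfinite(virtual))):
        raise ValueError("localization points must be finite")
    return float(np.linalg.norm(real - virtual))


def _sample_pointer_tip(
    point_world: np.ndarray,
    pointer: ToolDefinition,
    noise: NoiseModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate one manual pointer localization of a physical point."""
    tilt = Rotation.from_rotvec(rng.normal(0.0, POINTER_TILT_SIGMA, 3)).as_matrix()
    true_pose = RigidTransform(
        tilt,
        point_world - tilt @ pointer.tip_offset,
        from_frame=pointer.tool_id,
        to_frame="tracker",
    )
    pose = measure_pose(pointer, true_pose, noise, rng=rng)
    return pointer_tip(pose, pointer)


def _projector_pose_at(
    phantom: Phantom, model: ProjectorModel, distance: float
) -> RigidTransform:
    """True sensor pose with the projector centred ``distance`` mm off the
    phantom, optical axis aimed at the grid centre."""
    centre = phantom.points_world.mean(axis=0)
    normal = phantom.plane.normal
    z_axis = -normal  # projector looks along +z of its frame, toward the phantom
    x_axis = phantom.spec.plane_pose.rotation[:, 0]
    y_axis = np.cross(z_axis, x_axis)
    rot = np.column_stack([x_axis, y_axis, z_axis])
    t_proj_world = RigidTransform(
        rot, centre + distance * normal, from_frame="projector", to_frame="tracker"
    )
    return compose(t_proj_world, invert(model.t_sensor_to_projector))


def run_protocol(
    phantom: Phantom,
    projector: ProjectorModel,
    noise: NoiseModel,
    distances=DEFAULT_DISTANCES,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
    pointer_tool: ToolDefinition | None = None,
    sensor_tool: ToolDefinition | None = None,
    projector_angle_sigma_deg: float = 0.0,
) -> ProtocolResult:
    """Run the full localization protocol.

    Registration (once per run): each registration divot is localized with
    the noisy tracked pointer and the image -> tracker transform fitted; the
    FRE is recorded. Then, per standoff distance and per divot, ``reps``
    pointer localizations give the "real" point (their mean) while each
    repetition's "virtual" point is the intersection with the true phantom
    plane of the ray the physical projector emits for the divot's virtual
    marker under its freshly measured (noisy) pose.

    ``projector_angle_sigma_deg`` adds an independent orientation jitter to
    the tracked projector pose about the optical centre — a pure
    orientation-noise mode in which the projection error scales linearly
    with standoff distance.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    distances = [float(d) for d in distances]
    if any(d <= 0 for d in distances):
        raise ValueError("distances must be positive")
    pointer = pointer_tool or default_pointer_tool()
    sensor = sensor_tool or default_sensor_tool()
    rng = np.random.default_rng(seed)

    # -- registration (once per run) --
    reg_fids, reg_world = phantom.registration_set()
    sampled = np.array(
        [_sample_pointer_tip(p, pointer, noise, rng) for p in reg_world]
    )
    registration = rigid_register(
        reg_fids, FiducialSet(reg_fids.labels, sampled, frame="tracker")
    )

    records: list[LocalizationRecord] = []
    for distance in distances:
        true_sensor = _projector_pose_at(phantom, projector, distance)
        proj_centre = apply(
            compose(true_sensor, projector.t_sensor_to_projector), np.zeros(3)
        )
        for divot_idx, label in enumerate(phantom.labels):
            point_world = phantom.points_world[divot_idx]
            point_image = phantom.points_image[divot_idx]
            samples, virtuals = [], []
            for _ in range(reps):
                samples.append(_sample_pointer_tip(point_world, pointer, noise, rng))
                measured = measure_pose(sensor, true_sensor, noise, rng=rng)
                if projector_angle_sigma_deg > 0:
                    jitter = Rotation.from_rotvec(
                        rng.normal(0.0, np.deg2rad(projector_angle_sigma_deg), 3)
                    ).as_matrix()
                    r_old = measured.transform.rotation
                    t_old = measured.transform.translation
                    measured = Pose(
                        measured.tool_id,
                        RigidTransform(
                            jitter @ r_old,
                            jitter @ (t_old - proj_centre) + proj_centre,
                            from_frame=measured.transform.from_frame,
                            to_frame=measured.transform.to_frame,
                        ),
                        measured.timestamp,
                        measured.valid,
                    )
                w_est = apply(registration.transform, point_image)
                pixel = project_point(projector, measured, w_est)
                true_pose = Pose(sensor.tool_id, true_sensor)
                ray = cast_ray(projector, true_pose, pixel)
                virtuals.append(intersect(ray, phantom.plane))
            real = np.mean(samples, axis=0)
            for rep, (sample, virtual) in enumerate(zip(samples, virtuals)):
                records.append(
                    LocalizationRecord(
                        divot_id=label,
                        distance_condition=distance,
                        rep_index=rep,
                        pointer_sample=sample,
                        real_point=real,
                        virtual_point=virtual,
                        err=localization_error(real, virtual),
                    )
                )
    return ProtocolResult(records, registration.fre, registration)


def summarize(
    records: list[LocalizationRecord],
    fre: float,
    seed: int | None = None,
    noise: NoiseModel | None = None,
) -> AccuracyReport:
    """Aggregate localization records into the accuracy report.

    Per distance: RMS and SD (ddof = 1) of the error values. The overall
    value is the unweighted arithmetic mean of the per-distance RMS values;
    the overall SD is the pooled SD of all errors, and the pooled RMS over
    all errors is reported alongside.
    """
    if not records:
        raise ValueError("cannot summarize an empty record list")
    per_distance: dict[float, DistanceStats] = {}
    for d in sorted({r.distance_condition for r in records}):
        errs = np.array([r.err for r in records if r.distance_condition == d])
        sd = float(errs.std(ddof=1)) if len(errs) > 1 else 0.0
        per_distance[d] = DistanceStats(float(np.sqrt(np.mean(errs**2))), sd, len(errs))
    all_errs = np.array([r.err for r in records])
    overall_value = float(np.mean([s.rms for s in per_distance.values()]))
    overall_sd = float(all_errs.std(ddof=1)) if len(all_errs) > 1 else 0.0
    return AccuracyReport(
        fre=float(fre),
        per_distance=per_distance,
        overall=(overall_value, overall_sd),
        pooled_rms=float(np.sqrt(np.mean(all_errs**2))),
        n_localizations=len(records),
        seed=seed,
        noise=None
        if noise is None
        else {
            "marker_sigma": noise.marker_sigma,
            "pointer_extra_sigma": noise.pointer_extra_sigma,
        },
    )


def records_to_frame(records: list[LocalizationRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "divot_id": r.divot_id,
                "distance_mm": r.distance_condition,
                "rep": r.rep_index,
                "sample_x": r.pointer_sample[0],
                "sample_y": r.pointer_sample[1],
                "sample_z": r.pointer_sample[2],
                "real_x": r.real_point[0],
                "real_y": r.real_point[1],
                "real_z": r.real_point[2],
                "virtual_x": r.virtual_point[0],
                "virtual_y": r.virtual_point[1],
                "virtual_z": r.virtual_point[2],
                "err_mm": r.err,
            }
        )
    return pd.DataFrame(rows)
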