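"""Simulated infrared optical tracker.

A tracked tool is a rigid constellation of retro-reflective markers with
known coordinates in the tool frame. The simulator maps the markers through
the tool's true pose, perturbs each marker coordinate with iid Gaussian
noise, and re-estimates the pose by the same paired-point rigid fit the
registration module uses. Applying noise at the marker level (rather than
directly to poses) reproduces the physical coupling in which orientation
jitter grows with the marker-array baseline and tip error grows with the
pointer's lever arm — the mechanism behind distance-dependent projection
error.

Noise magnitudes are free simulation parameters; the default marker sigma
(0.10 mm) is typical of research-grade infrared trackers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError
from .geometry import Pose, RigidTransform, apply
from .registration import FiducialSet, rigid_register

DEFAULT_MARKER_SIGMA = 0.10  # mm, per marker axis
DEFAULT_POINTER_EXTRA_SIGMA = 0.05  # mm, additional jitter for handheld pointers


@dataclass
class ToolDefinition:
    """Marker constellation (and optional pointer tip) in the tool frame."""

    tool_id: str
    marker_positions: np.ndarray  # (M, 3) mm, M >= 3, non-collinear
    tip_offset: np.ndarray | None = None  # (3,) mm, pointer tools only

    def __post_init__(self) -> None:
        self.marker_positions = np.asarray(self.marker_positions, dtype=float).reshape(-1, 3)
        # delegate the >= 3 / non-collinear check
        FiducialSet(
            labels=[f"m{i}" for i in range(len(self.marker_positions))],
            points=self.marker_positions,
            frame=self.tool_id,
        )
        if self.tip_offset is not None:
            self.tip_offset = np.asarray(self.tip_offset, dtype=float).reshape(3)

    def to_dict(self) -> dict:
        d = {"tool_id": self.tool_id, "marker_positions": self.marker_positions.tolist()}
        if self.tip_offset is not None:
            d["tip_offset"] = self.tip_offset.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ToolDefinition":
        return cls(
            tool_id=d["tool_id"],
            marker_positions=np.asarray(d["marker_positions"], dtype=float),
            tip_offset=np.asarray(d["tip_offset"], dtype=float) if "tip_offset" in d else None,
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "ToolDefinition":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class NoiseModel:
    """Gaussian marker-measurement noise (iid per marker axis)."""

    marker_sigma: float = DEFAULT_MARKER_SIGMA
    pointer_extra_sigma: float = DEFAULT_POINTER_EXTRA_SIGMA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.marker_sigma < 0 or self.pointer_extra_sigma < 0:
            raise ValueError("noise sigmas must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def sigma_for(self, tool: ToolDefinition) -> float:
        """Effective per-axis marker sigma; pointer jitter adds in quadrature."""
        if tool.tip_offset is not None:
            return float(np.hypot(self.marker_sigma, self.pointer_extra_sigma))
        return float(self.marker_sigma)


def default_pointer_tool() -> ToolDefinition:
    """Tracked pointer: 4-marker 50 mm square, tip 150 mm down the shaft."""
    half = 25.0
    markers = np.array(
        [[-half, -half, 0.0], [half, -half, 0.0], [half, half, 0.0], [-half, half, 0.0]]
    )
    return ToolDefinition("pointer", markers, tip_offset=np.array([0.0, 0.0, -150.0]))


def default_sensor_tool() -> ToolDefinition:
    """Optical sensor attachment of the AR device: 4-marker 90 mm square.

    The reference body rides on the projector enclosure, so its baseline is
    set by the enclosure footprint (order 100 mm) rather than by a handheld
    instrument's; the wider baseline is what keeps orientation jitter low
    enough for distance-amplified projection error to stay sub-millimetre.
    """
    half = 45.0
    markers = np.array(
        [[-half, -half, 0.0], [half, -half, 0.0], [half, half, 0.0], [-half, half, 0.0]]
    )
    return ToolDefinition("sensor", markers)


def measure_pose(
    tool: ToolDefinition,
    true_pose: RigidTransform,
    noise: NoiseModel,
    rng: np.random.Generator | None = None,
    visible=None,
    timestamp: float = 0.0,
) -> Pose:
    """One noisy tracker measurement of a tool.

    Markers are mapped through ``true_pose``, perturbed by iid Gaussian
    noise, and the pose re-estimated by a rigid fit of the tool template to
    the noisy markers. Fewer than 3 visible markers yields an invalid Pose.
    """
    if rng is None:
        rng = noise.rng()
    visible = (
        np.ones(len(tool.marker_positions), dtype=bool)
        if visible is None
        else np.asarray(visible, dtype=bool)
    )
    if visible.sum() < 3:
        return Pose(tool.tool_id, RigidTransform.identity(tool.tool_id), timestamp, valid=False)
    template = tool.marker_positions[visible]
    measured = apply(true_pose, template)
    sigma = noise.sigma_for(tool)
    if sigma > 0:
        measured = measured + rng.normal(0.0, sigma, size=measured.shape)
    labels = [f"m{i}" for i in np.flatnonzero(visible)]
    result = rigid_register(
        FiducialSet(labels, template, frame=tool.tool_id),
        FiducialSet(labels, measured, frame=true_pose.to_frame),
    )
    return Pose(tool.tool_id, result.transform, timestamp, valid=True)


def pointer_tip(pose: Pose, tool: ToolDefinition) -> np.ndarray:
    """Tracker-frame tip position ``R @ tip_offset + t`` of a pointer pose."""
    if not pose.valid:
        raise ValueError("cannot compute tip from an invalid pose")
    if tool.tip_offset is None:
        raise ValueError(f"tool '{tool.tool_id}' has no tip offset")
    return apply(pose.transform, tool.tip_offset)


def simulate_frames(
    scene: list[tuple[ToolDefinition, object]],
    noise: NoiseModel,
    n_frames: int,
    frame_rate: float = 20.0,
) -> list[Pose]:
    """Simulate a multi-tool pose stream.

    ``scene`` pairs each tool with its true trajectory: either a constant
    :class:`RigidTransform` or a callable ``frame_index -> RigidTransform``.
    One Pose per tool per frame; deterministic for a given noise seed.
    """
    rng = noise.rng()
    poses: list[Pose] = []
    for frame in range(n_frames):
        timestamp = frame / frame_rate
        for tool, trajectory in scene:
            true_pose = trajectory(frame) if callable(trajectory) else trajectory
            poses.append(measure_pose(tool, true_pose, noise, rng=rng, timestamp=timestamp))
    return poses
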