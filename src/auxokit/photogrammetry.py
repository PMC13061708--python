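"""Pinhole-geometry stature estimation from image keypoints.

A levelled camera at a known height photographs the athlete standing (or
sitting) against a background wall at a known distance. Under the
fronto-parallel single-plane model — the subject in the wall plane, the
optical axis horizontal — similar triangles map a vertical pixel
separation dy to a world length dy * wall_distance / focal_length. This
module converts detected keypoints (head vertex and a floor/seat
reference) to centimetres; keypoint *detection* is consumed from upstream,
never performed here.

Image convention: origin at the top-left corner, y increasing downward,
principal point defaulting to the image centre. Lens distortion and
subject-to-wall offset are ignored by design and are the dominant known
error sources of the model.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Tuple

from .core import AuxoError, MeasurementError

__all__ = [
    "Posture",
    "CameraSetup",
    "KeypointSet",
    "CalibrationCheck",
    "vertical_extent_cm",
    "world_height_of_pixel",
    "validate_calibration",
    "DegenerateKeypointsError",
    "CalibrationError",
]


class DegenerateKeypointsError(AuxoError, ValueError):
    """Keypoints do not span a positive vertical extent."""


class CalibrationError(AuxoError, ValueError):
    """Camera calibration fields are unusable."""


class Posture(str, enum.Enum):
    STANDING = "standing"
    SITTING = "sitting"


@dataclass(frozen=True)
class CameraSetup:
    """Capture geometry: levelled camera facing a wall.

    Defaults mirror the standard capture protocol (2 m from the wall,
    lens 1 m above the floor). The focal length in pixels must be supplied
    by the caller's calibration; there is no EXIF parsing.
    """

    focal_px: float
    wall_distance_cm: float = 200.0
    camera_height_cm: float = 100.0
    principal_point_px: Tuple[float, float] = (960.0, 1280.0)
    image_size_px: Tuple[int, int] = (1920, 2560)

    def __post_init__(self) -> None:
        if self.focal_px <= 0:
            raise CalibrationError(f"focal length must be positive, got {self.focal_px}")
        if self.wall_distance_cm <= 0 or self.camera_height_cm <= 0:
            raise CalibrationError("wall distance and camera height must be positive")
        px, py = self.principal_point_px
        w, h = self.image_size_px
        if w <= 0 or h <= 0:
            raise CalibrationError("image size must be positive")
        if not (0 <= px <= w and 0 <= py <= h):
            raise CalibrationError("principal point must lie inside the image")

    @property
    def cm_per_px(self) -> float:
        """World centimetres per pixel at the wall plane."""
        return self.wall_distance_cm / self.focal_px


@dataclass(frozen=True)
class KeypointSet:
    """Head-vertex and reference keypoints for one captured image.

    For standing posture the bottom keypoint is the floor contact; for
    sitting it is the seat surface. Head must be above the reference in
    image coordinates (smaller y).
    """

    posture: Posture
    top_px: Tuple[float, float]
    bottom_px: Tuple[float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "posture", Posture(self.posture))
        if self.top_px[1] >= self.bottom_px[1]:
            raise DegenerateKeypointsError(
                f"head keypoint y={self.top_px[1]} must be above "
                f"reference y={self.bottom_px[1]} (y grows downward)"
            )


def vertical_extent_cm(kp: KeypointSet, cam: CameraSetup) -> float:
    """World length spanned by the keypoint pair, in cm.

    Similar-triangles scaling at the wall plane:
    ``(bottom_y - top_y) * wall_distance / focal``. For a standing capture
    with a floor-contact reference this is the stature estimate; for a
    sitting capture with a seat-surface reference, the sitting height.
    """
    dy = kp.bottom_px[1] - kp.top_px[1]
    return dy * cam.cm_per_px


def world_height_of_pixel(y_px: float, cam: CameraSetup) -> float:
    """Height above the floor (cm) of the wall point imaged at row ``y_px``.

    The on-axis ray (y at the principal point) hits the wall at camera
    height; rows above/below map linearly with the wall-plane scale.
    """
    return cam.camera_height_cm + (cam.principal_point_px[1] - y_px) * cam.cm_per_px


@dataclass(frozen=True)
class CalibrationCheck:
    """Result of a floor-consistency check on a standing capture."""

    residual_cm: float
    tol_cm: float
    passed: bool


def validate_calibration(
    kp: KeypointSet, cam: CameraSetup, tol_cm: float = 2.0
) -> CalibrationCheck:
    """Check that the floor-contact keypoint images the floor.

    Computes the absolute world height of the bottom keypoint (which should
    be 0 for a standing capture) and flags the session when the residual
    exceeds ``tol_cm``. A failing check indicates mis-calibration, a tilted
    camera, or a bad keypoint.
    """
    if kp.posture is not Posture.STANDING:
        raise MeasurementError(
            "calibration check requires a standing capture (floor reference)"
        )
    residual = abs(world_height_of_pixel(kp.bottom_px[1], cam))
    return CalibrationCheck(residual_cm=residual, tol_cm=tol_cm, passed=residual <= tol_cm)
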