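"""Standard-plane alignment and per-hop kinematic variables.

A raw 3D trajectory is rigidly rotated so that vertical maps to +z, the
travel direction to +x and the lateral (y) excursion of the cloaca path is
least-squares minimal; the six jump variables are then read off the aligned
cloaca path and the cloaca-to-snout body axis. The cloaca is the reference
point for velocity, distance and height (it is the ground-contact end of
the body axis); body angles use the cloaca-to-snout vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    HeadingUndefinedError,
    InsufficientFramesError,
    NoDataError,
    NoJumpDetectedError,
    ParameterError,
)
from .stereo import Trajectory3D

#: Default height (cm) above baseline that counts as airborne.
EPSILON_CM = 0.1


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector a onto unit vector b (Rodrigues)."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-15:
        if c > 0:
            return np.eye(3)
        # opposite vectors: rotate pi about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-12:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        return np.eye(3) + 2.0 * K @ K
    K = np.array([[0, -v[2], v[1]],
                  [v[2], 0, -v[0]],
                  [-v[1], v[0], 0]])
    return np.eye(3) + K + K @ K * (1.0 - c) / (np.linalg.norm(v) ** 2)


def align_trajectory(
    raw: Trajectory3D,
    vertical_axis=(0.0, 0.0, 1.0),
) -> Trajectory3D:
    """Rigidly map a trajectory into the standard (x, 0, z) jump plane.

    The known vertical direction is rotated onto +z; a rotation about z
    maps the travel direction (the least-squares jump plane fitted through
    the horizontal centroid of the cloaca path) onto +x, signed so the net
    horizontal displacement points along +x; and the trajectory is
    translated so the take-off (first-frame) cloaca sits at x = z = 0 with
    the lateral origin on the fitted plane (so the squared lateral
    coordinates of the cloaca path are least-squares minimal). For a
    planar path the take-off cloaca lands exactly at the origin. All
    inter-landmark and inter-frame distances are preserved (rotation +
    translation only).
    """
    if len(raw) < 3:
        raise ParameterError("alignment needs at least 3 frames")
    R1 = _rotation_between(np.asarray(vertical_axis, dtype=float),
                           np.array([0.0, 0.0, 1.0]))
    origin = raw.cloaca[0]
    cl = (raw.cloaca - origin) @ R1.T
    sn = (raw.snout - origin) @ R1.T
    horiz = cl[:, :2]
    net = horiz[-1] - horiz[0]
    if np.linalg.norm(net) < 1e-9:
        raise HeadingUndefinedError(
            "zero net horizontal displacement: travel heading undefined "
            "(vertical hop?)"
        )
    # heading = principal direction of the centred horizontal cloaca path,
    # i.e. the unit u maximizing sum((d_i . u)^2) == minimizing lateral SS
    centred = horiz - horiz.mean(axis=0)
    M = centred.T @ centred
    w, V = np.linalg.eigh(M)
    u = V[:, np.argmax(w)]
    if u @ net < 0:
        u = -u
    Rz = np.array([[u[0], u[1], 0.0],
                   [-u[1], u[0], 0.0],
                   [0.0, 0.0, 1.0]])
    cl = cl @ Rz.T
    sn = sn @ Rz.T
    lateral_offset = cl[:, 1].mean()
    cl[:, 1] -= lateral_offset
    sn[:, 1] -= lateral_offset
    return Trajectory3D(
        timestamps=raw.timestamps.copy(),
        snout=sn,
        cloaca=cl,
        frame_rate=raw.frame_rate,
        aligned=True,
        interpolated=raw.interpolated.copy(),
    )


def detect_takeoff_landing(
    aligned: Trajectory3D,
    epsilon: float = EPSILON_CM,
) -> tuple[int, int]:
    """Bracket the single hop in an aligned trajectory.

    The baseline is the first-frame cloaca height. Take-off is the last
    frame before the cloaca rises above baseline + epsilon and stays there
    for at least 3 frames; landing is the first frame after the apex back
    within epsilon of the baseline.
    """
    z = aligned.cloaca[:, 2]
    base = z[0]
    above = z > base + epsilon
    n = len(z)
    launch = None
    for i in range(1, n - 2):
        if above[i] and above[i + 1] and above[i + 2]:
            launch = i
            break
    if launch is None:
        raise NoJumpDetectedError(
            f"cloaca never exceeds baseline + {epsilon} cm for 3 frames"
        )
    takeoff = launch - 1
    apex = takeoff + int(np.argmax(z[takeoff:]))
    landing = None
    for i in range(apex + 1, n):
        if z[i] <= base + epsilon:
            landing = i
            break
    if landing is None:
        raise NoJumpDetectedError("cloaca never returns to baseline after the apex")
    return takeoff, landing


@dataclass
class JumpKinematics:
    """The six per-hop variables (cm, cm/s, signed degrees)."""

    mean_velocity: float
    max_velocity: float
    distance: float
    height: float
    angle_takeoff: float
    angle_landing: float
    trial_id: str | None = None
    animal_id: str | None = None

    def __post_init__(self) -> None:
        if not (self.max_velocity >= self.mean_velocity > 0):
            raise ParameterError("need max_velocity >= mean_velocity > 0")
        if self.distance < 0 or self.height < 0:
            raise ParameterError("distance and height must be non-negative")
        if abs(self.angle_takeoff) > 90 or abs(self.angle_landing) > 90:
            raise ParameterError("body angles must lie within +/-90 degrees")


def _body_elevation_deg(body_vec: np.ndarray) -> float:
    """Signed elevation of the cloaca->snout vector above the horizontal plane."""
    horiz = np.hypot(body_vec[0], body_vec[1])
    return float(np.degrees(np.arctan2(body_vec[2], horiz)))


def extract_kinematics(
    aligned: Trajectory3D,
    takeoff_frame: int,
    landing_frame: int,
    smooth: bool = False,
    trial_id: str | None = None,
    animal_id: str | None = None,
) -> JumpKinematics:
    """Six kinematic variables over the [takeoff, landing] bracket.

    Cloaca speed comes from central differences (optionally smoothed with a
    5-frame moving average); distance is the x displacement of the cloaca
    between the bracket frames; height the maximum cloaca rise above the
    take-off baseline; angles the body-axis elevations at the bracket frames.
    """
    if not 0 <= takeoff_frame < landing_frame < len(aligned):
        raise ParameterError("invalid take-off/landing bracket")
    if landing_frame - takeoff_frame + 1 < 3:
        raise InsufficientFramesError("bracket shorter than 3 frames")
    c = aligned.cloaca
    dt = 1.0 / aligned.frame_rate
    vel = np.gradient(c, dt, axis=0)          # central differences
    speed = np.linalg.norm(vel, axis=1)
    if smooth:
        kernel = np.ones(5) / 5.0
        speed = np.convolve(speed, kernel, mode="same")
    window = speed[takeoff_frame:landing_frame + 1]
    distance = float(c[landing_frame, 0] - c[takeoff_frame, 0])
    height = float(np.max(c[takeoff_frame:landing_frame + 1, 2]) - c[takeoff_frame, 2])
    return JumpKinematics(
        mean_velocity=float(window.mean()),
        max_velocity=float(window.max()),
        distance=distance,
        height=height,
        angle_takeoff=_body_elevation_deg(aligned.body_vectors[takeoff_frame]),
        angle_landing=_body_elevation_deg(aligned.body_vectors[landing_frame]),
        trial_id=trial_id,
        animal_id=animal_id,
    )


def select_best_jump(jumps: list[JumpKinematics]) -> JumpKinematics:
    """The longest hop for one animal; ties go to the earliest trial id."""
    if not jumps:
        raise NoDataError("no jumps supplied")
    return min(jumps, key=lambda j: (-j.distance, j.trial_id or ""))
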