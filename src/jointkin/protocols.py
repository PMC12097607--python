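"""Standard synthetic study conditions shared by tests, examples and the CLI.

The standard rig emulates two body-worn sensors on a knee-like hinge: a
mediolateral joint axis, sensors ~20-25 cm from the joint center along each
segment, and mounts rotated about the axis (so the axis reads as +X in both
sensor frames while the other mount angles differ).

Two motion segments make up the standard protocol:

* calibration segment — hinge flexion plus a whole-limb wobble about a second
  axis.  Both constraints need angular motion of BOTH segments: a proximal
  segment that never moves leaves its axis unidentifiable, and attitude
  variety is what the SVD route aligns.
* measurement segment — a clinical-style stationary-base flexion test,
  0 to 60 degrees at 0.5 Hz, with still padding for reference anchoring.
"""

from __future__ import annotations

import numpy as np

from .rotations import elemental_rotation
from .sim import (
    BaseWobble,
    HingeRigConfig,
    MotionProfile,
    SinusoidProfile,
)

DEG = np.pi / 180.0


def standard_rig(rate: float = 100.0) -> HingeRigConfig:
    """Knee-like two-sensor hinge rig with axis +X in both sensor frames."""
    return HingeRigConfig(
        axis=(1.0, 0.0, 0.0),
        mount1=elemental_rotation("x", 20 * DEG),
        mount2=elemental_rotation("x", -35 * DEG),
        lever1=(0.03, 0.02, 0.24),    # thigh sensor, above the joint
        lever2=(0.02, -0.03, -0.20),  # shank sensor, below the joint
        rate=rate,
    )


def calibration_motion(duration: float = 10.0) -> MotionProfile:
    """Rich excitation: flexion sinusoid plus a two-component limb wobble.

    Two wobble components about different axes make the proximal segment's
    angular velocity vary in direction — a single-axis wobble leaves that
    sensor's joint axis and lever arm unidentifiable from the kinematic
    constraints.  Frequencies divide the duration so every component starts
    and ends at rest.
    """
    return MotionProfile(
        hinge=SinusoidProfile(amp_deg=25.0, freq_hz=0.5, mean_deg=30.0),
        duration=duration,
        base=(
            BaseWobble(axis=(0.5, 0.866, 0.0),
                       profile=SinusoidProfile(amp_deg=15.0, freq_hz=0.4)),
            BaseWobble(axis=(0.45, 0.0, 0.893),
                       profile=SinusoidProfile(amp_deg=12.0, freq_hz=0.6)),
        ),
    )


def measurement_motion(duration: float = 24.0, amp_deg: float = 30.0) -> MotionProfile:
    """Stationary-base flexion test: 0 to 2*amp_deg degrees at 0.5 Hz."""
    return MotionProfile(
        hinge=SinusoidProfile(amp_deg=amp_deg, freq_hz=0.5),
        duration=duration,
        still_before=2.0,
        still_after=2.0,
    )
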