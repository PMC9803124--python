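"""Model configuration: anthropometry, chair geometry, contact material, integration.

The skeleton is a sagittal 7-segment, 9-DOF linkage (lumped torso+pelvis+head,
thighs, shanks, feet) scaled from total height/mass with standard anthropometric
coefficients (Winter's tables). The chair is a horizontal seat plane of finite
length; contact is through five spheres (toes, calcanei, pelvis).

Angle conventions
-----------------
All joint angles are zero in the upright stance pose and increase with flexion
(hip: torso pitching forward; knee: shank folding back; ankle: dorsiflexion).
The *reported* hip angle -- the one the controller thresholds, the cost rules
and the analysis chain use -- is the torso pitch with respect to vertical,
because the lumped torso+pelvis segment has no lumbar joint and the seated
torso inclination is what the initial "hip 12 deg" encodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import yaml

DEG = math.pi / 180.0

# Winter anthropometric coefficients (fractions of total height / mass).
_THIGH_LEN_F = 0.245
_SHANK_LEN_F = 0.246
_FOOT_LEN_F = 0.152
_ANKLE_HEIGHT_F = 0.039
_THIGH_MASS_F = 0.100
_SHANK_MASS_F = 0.0465
_FOOT_MASS_F = 0.0145
_THIGH_COM_F = 0.433    # from proximal joint, fraction of segment length
_SHANK_COM_F = 0.433
_THIGH_GYR_F = 0.323
_SHANK_GYR_F = 0.302


@dataclass
class ModelConfig:
    """Geometry, inertia and simulation constants for the planar STS model."""

    total_height: float = 1.80          # m
    total_mass: float = 80.0            # kg
    gravity: float = 9.81               # m/s^2

    chair_height: float = 0.45          # m, ground to seat plane
    chair_length: float = 0.54          # m, seat extent in x
    contact_sphere_radius: float = 0.04  # m

    # Initial joint angles, degrees (reported convention, see module docstring).
    initial_hip_deg: float = 12.0       # torso pitch w.r.t. vertical
    initial_knee_deg: float = 85.0
    initial_ankle_deg: float = 61.0

    # Seated pelvis-sphere clearance above the seat plane at t=0.
    pelvis_seat_clearance: float = 0.035  # m

    # Torso (lumped torso+pelvis+head) geometry relative to the hip joint.
    torso_com_height: float = 0.35      # m along torso axis above the hip
    torso_gyration: float = 0.235       # m, radius of gyration about its CoM
    pelvis_center_height: float = 0.08  # m above the hip along torso axis
    # Pelvis contact sphere offset from the hip, in the torso frame
    # (forward, up); chosen so the placed seated pose has the pelvis sphere
    # at the configured seat clearance while the heel spheres start ~4 cm
    # above the ground -- both drop together into the static sitting
    # equilibrium the rollouts start from.
    pelvis_sphere_offset: tuple[float, float] = (-0.075, -0.2615)

    # Foot geometry relative to the ankle, foot frame (forward, up).
    foot_com_offset: tuple[float, float] = (0.06, -0.035)
    toe_sphere_offset: tuple[float, float] = (0.18, -0.03)
    calcaneus_sphere_offset: tuple[float, float] = (-0.05, -0.03)
    foot_gyration: float = 0.07         # m

    # Seat x-placement: front edge this far ahead of the seated pelvis sphere.
    seat_front_margin: float = 0.15     # m

    # Contact material (Hunt-Crossley normal + regularized Coulomb friction).
    contact_stiffness: float = 1.0e6    # N/m^1.5
    contact_dissipation: float = 1.0    # s/m
    friction_coefficient: float = 0.9
    friction_vel_eps: float = 0.01      # m/s, tanh regularization scale

    # Passive joint structures: viscous damping and soft range-of-motion
    # stops (flexion-positive limits, deg, order hip/knee/ankle).
    joint_damping: float = 1.0          # N*m*s/rad
    joint_limit_stiffness: float = 200.0  # N*m/rad beyond the limit
    joint_limit_damping: float = 5.0    # N*m*s/rad beyond the limit
    joint_limits_deg: tuple[tuple[float, float], ...] = (
        (-30.0, 150.0),  # hip
        (-15.0, 140.0),  # knee
        (-40.0, 90.0),   # ankle
    )

    # Integration.
    dt: float = 1.0e-3                  # s, fixed semi-implicit step
    max_dt: float = 2.0e-3              # s, largest stable step accepted
    horizon: float = 20.0               # s, simulation cap

    # First-order low-pass cutoff for acceleration feedback channels.
    accel_filter_hz: float = 20.0

    def __post_init__(self) -> None:
        self.validate()

    # ---- derived anthropometry -------------------------------------------
    @property
    def thigh_length(self) -> float:
        return _THIGH_LEN_F * self.total_height

    @property
    def shank_length(self) -> float:
        return _SHANK_LEN_F * self.total_height

    @property
    def foot_length(self) -> float:
        return _FOOT_LEN_F * self.total_height

    @property
    def ankle_height(self) -> float:
        return _ANKLE_HEIGHT_F * self.total_height

    @property
    def thigh_mass(self) -> float:
        return _THIGH_MASS_F * self.total_mass

    @property
    def shank_mass(self) -> float:
        return _SHANK_MASS_F * self.total_mass

    @property
    def foot_mass(self) -> float:
        return _FOOT_MASS_F * self.total_mass

    @property
    def torso_mass(self) -> float:
        """Lumped torso+pelvis+head (+arms) mass: remainder of total."""
        return self.total_mass - 2.0 * (
            self.thigh_mass + self.shank_mass + self.foot_mass
        )

    @property
    def segment_masses(self) -> dict[str, float]:
        return {
            "torso": self.torso_mass,
            "thigh": self.thigh_mass,
            "shank": self.shank_mass,
            "foot": self.foot_mass,
        }

    @property
    def thigh_inertia(self) -> float:
        return self.thigh_mass * (_THIGH_GYR_F * self.thigh_length) ** 2

    @property
    def shank_inertia(self) -> float:
        return self.shank_mass * (_SHANK_GYR_F * self.shank_length) ** 2

    @property
    def foot_inertia(self) -> float:
        return self.foot_mass * self.foot_gyration**2

    @property
    def torso_inertia(self) -> float:
        return self.torso_mass * self.torso_gyration**2

    # ---- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.total_height <= 0 or self.total_mass <= 0:
            raise ValueError("total_height and total_mass must be positive")
        if self.chair_height <= 0 or self.chair_length <= 0:
            raise ValueError("chair geometry must be positive")
        if self.contact_sphere_radius <= 0:
            raise ValueError("contact_sphere_radius must be positive")
        if self.dt <= 0 or self.dt > self.max_dt:
            raise ValueError("dt must be in (0, max_dt]")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        mass_sum = self.torso_mass + 2.0 * (
            self.thigh_mass + self.shank_mass + self.foot_mass
        )
        if abs(mass_sum - self.total_mass) > 1e-9:
            raise ValueError("segment masses do not sum to total_mass")

    # ---- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        d = self.to_dict()
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = [list(x) if isinstance(x, tuple) else x for x in v]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for k in (
            "pelvis_sphere_offset",
            "foot_com_offset",
            "toe_sphere_offset",
            "calcaneus_sphere_offset",
        ):
            if k in d and isinstance(d[k], list):
                d[k] = tuple(d[k])
        if "joint_limits_deg" in d and isinstance(d["joint_limits_deg"], list):
            d["joint_limits_deg"] = tuple(tuple(x) for x in d["joint_limits_deg"])
        return cls(**d)

    # ---- initial pose (reported -> internal angles) -----------------------
    def initial_internal_angles(self) -> tuple[float, float, float, float]:
        """Return (phi_torso, theta_hip, theta_knee, theta_ankle) in radians.

        The configured initial angles are given in the reported convention:
        hip = torso pitch, knee = anatomical knee flexion, ankle = anatomical
        dorsiflexion. The seated shank inclination follows from requiring a
        physically seated thigh; the foot starts pitched toes-up so that the
        ankle angle can hold its configured value with the heel on the ground.
        """
        phi_torso = self.initial_hip_deg * DEG
        theta_knee = self.initial_knee_deg * DEG
        theta_ankle = self.initial_ankle_deg * DEG
        return phi_torso, phi_torso - self._phi_thigh0(), theta_knee, theta_ankle

    def _phi_shank0(self) -> float:
        # Seated shank inclination from vertical; 29 deg places the knee ahead
        # of the ankle as in experimental STS foot placement.
        return 29.0 * DEG

    def _phi_thigh0(self) -> float:
        return self._phi_shank0() - self.initial_knee_deg * DEG
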