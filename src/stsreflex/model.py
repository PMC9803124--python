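"""Planar 7-segment, 9-DOF musculoskeletal model with chair and sphere contact.

Generalized coordinates (all SI, radians):

    q = [x_hip, y_hip, phi_torso,
         hip_L, knee_L, ankle_L, hip_R, knee_R, ankle_R]

The root is the lumped torso+pelvis+head segment, located by the hip-joint
point and its pitch w.r.t. vertical (positive = leaning forward). Joint angles
are flexion-positive and zero in upright stance. The *reported* hip angle --
used by the controller thresholds, the cost rules and the analysis chain -- is
the torso pitch itself (see config module docstring).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .config import DEG, ModelConfig

NDOF = 9
NBODY = 7
NCONTACT = 5
MAXTERMS = 4

BODY_NAMES = ("torso", "thigh_l", "shank_l", "foot_l", "thigh_r", "shank_r", "foot_r")
CONTACT_NAMES = ("toe_l", "calcaneus_l", "toe_r", "calcaneus_r", "pelvis")


class ConfigurationError(ValueError):
    """Raised when the model geometry is inconsistent."""


class SimulationDiverged(RuntimeError):
    """Raised when forward integration produces a non-finite state."""


@dataclass
class BodyState:
    """Generalized state plus the accelerations of the last dynamics solve."""

    time: float
    q: np.ndarray
    qd: np.ndarray
    qdd: np.ndarray = field(default_factory=lambda: np.zeros(NDOF))

    def copy(self) -> "BodyState":
        return BodyState(self.time, self.q.copy(), self.qd.copy(), self.qdd.copy())

    @property
    def torso_pitch(self) -> float:
        return float(self.q[2])

    def is_symmetric(self, tol: float = 1e-12) -> bool:
        return bool(np.all(np.abs(self.q[3:6] - self.q[6:9]) <= tol)) and bool(
            np.all(np.abs(self.qd[3:6] - self.qd[6:9]) <= tol)
        )


@dataclass
class ContactPoint:
    """A sphere-on-plane contact probe (used by the standalone force op)."""

    center: tuple[float, float]
    radius: float
    plane: str = "ground"          # "ground" | "seat"
    plane_height: float = 0.0
    penetration: float = 0.0
    normal_force: float = 0.0
    tangential_force: float = 0.0


def contact_force(
    point: ContactPoint,
    velocity: tuple[float, float] = (0.0, 0.0),
    stiffness: float = 1.0e6,
    dissipation: float = 1.0,
    mu: float = 0.9,
    vel_eps: float = 0.01,
    spin: float = 0.0,
    radius_spin_arm: float | None = None,
) -> tuple[float, float]:
    """Hunt-Crossley normal force + regularized Coulomb friction for a sphere.

    Returns (normal, tangential); (0, 0) when not penetrating. The tangential
    force is bounded by mu * normal for any slip velocity.
    """
    if point.radius <= 0:
        raise ValueError("radius must be positive")
    depth = point.plane_height - (point.center[1] - point.radius)
    point.penetration = depth
    if depth <= 0.0:
        point.normal_force = 0.0
        point.tangential_force = 0.0
        return 0.0, 0.0
    fn = K.contact_normal_force(depth, -velocity[1], stiffness, dissipation)
    arm = point.radius if radius_spin_arm is None else radius_spin_arm
    v_slip = velocity[0] + spin * arm
    ft = -mu * fn * math.tanh(v_slip / vel_eps)
    point.normal_force = fn
    point.tangential_force = ft
    return fn, ft


class PlanarSTSModel:
    """Packed-array planar model; owns geometry, inertia and contact material."""

    def __init__(self, config: ModelConfig):
        self.config = config
        c = config
        self.S = np.zeros((NBODY, NDOF))
        S = self.S
        for side, (b0, j0) in enumerate(((1, 3), (4, 6))):
            for k in range(3):  # thigh, shank, foot
                S[b0 + k, 2] = 1.0
                S[b0 + k, j0] = -1.0
                if k >= 1:
                    S[b0 + k, j0 + 1] = 1.0
                if k >= 2:
                    S[b0 + k, j0 + 2] = -1.0
        S[0, 2] = 1.0

        self.mass = np.array(
            [c.torso_mass, c.thigh_mass, c.shank_mass, c.foot_mass] * 1
            + [c.thigh_mass, c.shank_mass, c.foot_mass]
        )
        self.inertia = np.array(
            [c.torso_inertia, c.thigh_inertia, c.shank_inertia, c.foot_inertia,
             c.thigh_inertia, c.shank_inertia, c.foot_inertia]
        )

        HALF_PI = 0.5 * math.pi
        lt, ls = c.thigh_length, c.shank_length
        ct_ = c.thigh_length * 0.433
        cs_ = c.shank_length * 0.433
        fcx, fcy = c.foot_com_offset

        def terms(*tt):
            n = len(tt)
            tb = np.zeros(MAXTERMS, dtype=np.int64)
            tc = np.zeros(MAXTERMS)
            td = np.zeros(MAXTERMS)
            for i, (b, coef, d) in enumerate(tt):
                tb[i], tc[i], td[i] = b, coef, d
            return n, tb, tc, td

        com_terms = [
            terms((0, c.torso_com_height, 0.0)),
            terms((1, -ct_, 0.0)),
            terms((1, -lt, 0.0), (2, -cs_, 0.0)),
            terms((1, -lt, 0.0), (2, -ls, 0.0), (3, fcy, 0.0), (3, fcx, HALF_PI)),
            terms((4, -ct_, 0.0)),
            terms((4, -lt, 0.0), (5, -cs_, 0.0)),
            terms((4, -lt, 0.0), (5, -ls, 0.0), (6, fcy, 0.0), (6, fcx, HALF_PI)),
        ]
        self.ct_n = np.array([t[0] for t in com_terms], dtype=np.int64)
        self.ct_b = np.stack([t[1] for t in com_terms])
        self.ct_c = np.stack([t[2] for t in com_terms])
        self.ct_d = np.stack([t[3] for t in com_terms])

        tx, ty = c.toe_sphere_offset
        kx, ky = c.calcaneus_sphere_offset
        px, py = c.pelvis_sphere_offset
        cp_terms = [
            terms((1, -lt, 0.0), (2, -ls, 0.0), (3, ty, 0.0), (3, tx, HALF_PI)),
            terms((1, -lt, 0.0), (2, -ls, 0.0), (3, ky, 0.0), (3, kx, HALF_PI)),
            terms((4, -lt, 0.0), (5, -ls, 0.0), (6, ty, 0.0), (6, tx, HALF_PI)),
            terms((4, -lt, 0.0), (5, -ls, 0.0), (6, ky, 0.0), (6, kx, HALF_PI)),
            terms((0, py, 0.0), (0, px, HALF_PI)),
        ]
        self.cp_n = np.array([t[0] for t in cp_terms], dtype=np.int64)
        self.cp_b = np.stack([t[1] for t in cp_terms])
        self.cp_c = np.stack([t[2] for t in cp_terms])
        self.cp_d = np.stack([t[3] for t in cp_terms])
        self.cp_body = np.array([3, 3, 6, 6, 0], dtype=np.int64)
        self.cp_radius = np.full(NCONTACT, c.contact_sphere_radius)
        self.cp_plane = np.array([0, 0, 0, 0, 1], dtype=np.int64)

        tal_terms = [
            terms((1, -lt, 0.0), (2, -ls, 0.0)),
            terms((4, -lt, 0.0), (5, -ls, 0.0)),
        ]
        self.tal_n = np.array([t[0] for t in tal_terms], dtype=np.int64)
        self.tal_b = np.stack([t[1] for t in tal_terms])
        self.tal_c = np.stack([t[2] for t in tal_terms])
        self.tal_d = np.stack([t[3] for t in tal_terms])

        self.pelvis_h = c.pelvis_center_height
        self.gravity = c.gravity
        self.seat_y = c.chair_height
        self.jnt_lo = np.array([lo for lo, _ in c.joint_limits_deg]) * DEG
        self.jnt_hi = np.array([hi for _, hi in c.joint_limits_deg]) * DEG

        # seat x-span: front edge a margin ahead of the seated pelvis sphere
        state0 = self._initial_state()
        cpx, cpy = self.point_position(state0.q, "pelvis_sphere")
        self.seat_xmax = cpx + c.seat_front_margin
        self.seat_xmin = self.seat_xmax - c.chair_length
        if cpy - c.contact_sphere_radius < self.seat_y - 1e-12:
            raise ConfigurationError("pelvis contact sphere starts below the seat plane")
        self._state0 = state0

    # ------------------------------------------------------------------
    def _initial_state(self) -> BodyState:
        c = self.config
        phi_t, th_hip, th_knee, th_ankle = c.initial_internal_angles()
        q = np.zeros(NDOF)
        q[2] = phi_t
        q[3:6] = (th_hip, th_knee, th_ankle)
        q[6:9] = (th_hip, th_knee, th_ankle)
        # vertical placement: pelvis sphere bottom at seat + clearance
        px_off, py_off = c.pelvis_sphere_offset
        sphere_dy = py_off * math.cos(phi_t) - px_off * math.sin(phi_t)
        q[1] = (
            c.chair_height + c.pelvis_seat_clearance + c.contact_sphere_radius
            - sphere_dy
        )
        # horizontal placement: ankle joint at x = 0
        phi_thigh = phi_t - th_hip
        phi_shank = phi_thigh + th_knee
        q[0] = c.thigh_length * math.sin(phi_thigh) + c.shank_length * math.sin(
            phi_shank
        )
        return BodyState(0.0, q, np.zeros(NDOF))

    def initial_state(self) -> BodyState:
        return self._state0.copy()

    def settled_state(self, n_steps: int = 3000) -> BodyState:
        """Static sitting equilibrium: the placed pose dropped onto the seat.

        The placed pose starts the pelvis sphere a small clearance above the
        seat; simulations begin from *static* sitting, so the root is settled
        under gravity with the joint angles held, and velocities are zeroed.
        The result is cached.
        """
        if getattr(self, "_settled", None) is None:
            # translation only: the configured pose (incl. torso pitch) holds
            free = np.zeros(NDOF, dtype=bool)
            free[:2] = True
            s = self.initial_state()
            for _ in range(n_steps):
                s = step_dynamics(
                    self, s, dt=self.config.dt, free_dofs=free, passive_joints=True
                )
            self._settled = BodyState(0.0, s.q.copy(), np.zeros(NDOF))
        return self._settled.copy()

    # ------------------------------------------------------------------
    def orientations(self, q: np.ndarray) -> np.ndarray:
        return K.body_orientations(self.S, np.asarray(q, dtype=float))

    def point_position(self, q: np.ndarray, name: str) -> tuple[float, float]:
        """World position of a named landmark."""
        q = np.asarray(q, dtype=float)
        phi = self.orientations(q)
        zero = np.zeros(NDOF)
        if name in ("pelvis_sphere", "toe_l", "calcaneus_l", "toe_r", "calcaneus_r"):
            idx = {
                "toe_l": 0, "calcaneus_l": 1, "toe_r": 2,
                "calcaneus_r": 3, "pelvis_sphere": 4,
            }[name]
            x, y, _, _ = K.point_pos_vel(
                q, zero, phi, np.zeros(NBODY),
                self.cp_n[idx], self.cp_b[idx], self.cp_c[idx], self.cp_d[idx],
            )
            return x, y
        if name in ("talus_l", "talus_r"):
            idx = 0 if name == "talus_l" else 1
            x, y, _, _ = K.point_pos_vel(
                q, zero, phi, np.zeros(NBODY),
                self.tal_n[idx], self.tal_b[idx], self.tal_c[idx], self.tal_d[idx],
            )
            return x, y
        if name == "torso_com":
            x, y, _, _ = K.point_pos_vel(
                q, zero, phi, np.zeros(NBODY),
                self.ct_n[0], self.ct_b[0], self.ct_c[0], self.ct_d[0],
            )
            return x, y
        if name == "pelvis":
            return (
                q[0] + self.pelvis_h * math.sin(phi[0]),
                q[1] + self.pelvis_h * math.cos(phi[0]),
            )
        raise KeyError(name)

    def reported_angles_deg(self, state: BodyState) -> dict[str, float]:
        """Hip (torso pitch), knee and ankle angles in the reported convention."""
        q = state.q
        return {
            "hip": float(q[2]) / DEG,
            "knee": 0.5 * float(q[4] + q[7]) / DEG,
            "ankle": 0.5 * float(q[5] + q[8]) / DEG,
        }

    # ------------------------------------------------------------------
    def dynamics(
        self,
        state: BodyState,
        Q_applied: np.ndarray | None = None,
        contacts: bool = True,
        gravity: float | None = None,
        passive_joints: bool = True,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Return (qdd, contact_forces[ncp, 3]) for the current state."""
        g = self.gravity if gravity is None else gravity
        Q = np.zeros(NDOF) if Q_applied is None else np.asarray(Q_applied, float).copy()
        c = self.config
        if passive_joints:
            K.joint_passive_torques(
                state.q, state.qd, self.jnt_lo, self.jnt_hi,
                c.joint_damping, c.joint_limit_stiffness, c.joint_limit_damping, Q,
            )
        forces = np.zeros((NCONTACT, 3))
        if contacts:
            c = self.config
            K.contact_forces(
                state.q, state.qd, self.S,
                self.cp_n, self.cp_b, self.cp_c, self.cp_d,
                self.cp_body, self.cp_radius, self.cp_plane,
                self.seat_y, self.seat_xmin, self.seat_xmax,
                c.contact_stiffness, c.contact_dissipation,
                c.friction_coefficient, c.friction_vel_eps,
                Q, forces,
            )
        M, h = K.dynamics_terms(
            state.q, state.qd, self.S, self.mass, self.inertia,
            self.ct_n, self.ct_b, self.ct_c, self.ct_d, g,
        )
        qdd = np.linalg.solve(M, Q - h)
        return qdd, forces

    def mechanical_energy(self, state: BodyState, gravity: float | None = None) -> float:
        """Kinetic + gravitational potential energy of all segments."""
        g = self.gravity if gravity is None else gravity
        M, _ = K.dynamics_terms(
            state.q, state.qd, self.S, self.mass, self.inertia,
            self.ct_n, self.ct_b, self.ct_c, self.ct_d, 0.0,
        )
        T = 0.5 * float(state.qd @ M @ state.qd)
        phi = self.orientations(state.q)
        V = 0.0
        zero = np.zeros(NDOF)
        for b in range(NBODY):
            _, y, _, _ = K.point_pos_vel(
                state.q, zero, phi, np.zeros(NBODY),
                self.ct_n[b], self.ct_b[b], self.ct_c[b], self.ct_d[b],
            )
            V += self.mass[b] * g * y
        return T + V


def build_model(config: ModelConfig | None = None) -> tuple[PlanarSTSModel, BodyState]:
    """Construct the planar model in its static seated start pose.

    The returned state has the configured initial joint angles, the pelvis
    contact sphere at its configured clearance above the seat plane, the heels
    at ground level and zero velocities; time is 0.
    """
    model = PlanarSTSModel(config or ModelConfig())
    return model, model.initial_state()


def step_dynamics(
    model: PlanarSTSModel,
    state: BodyState,
    joint_torques: np.ndarray | None = None,
    dt: float | None = None,
    contacts: bool = True,
    gravity: float | None = None,
    free_dofs: np.ndarray | None = None,
    passive_joints: bool = False,
) -> BodyState:
    """Advance the state by one fixed semi-implicit Euler step.

    joint_torques is either a length-6 vector of flexion-positive joint
    torques (hip_L, knee_L, ankle_L, hip_R, knee_R, ankle_R) or a full
    length-9 generalized force vector. free_dofs, if given, is a boolean mask
    selecting the coordinates allowed to accelerate (the rest are held),
    useful for reduced checks such as a single pinned segment.
    """
    dt = model.config.dt if dt is None else dt
    if dt <= 0 or dt > model.config.max_dt:
        raise ValueError("dt must be in (0, max_dt]")
    Q = np.zeros(NDOF)
    if joint_torques is not None:
        tau = np.asarray(joint_torques, dtype=float)
        if tau.shape == (6,):
            Q[3:] = tau
        elif tau.shape == (NDOF,):
            Q = tau.copy()
        else:
            raise ValueError("joint_torques must have shape (6,) or (9,)")
    if free_dofs is None:
        qdd, _ = model.dynamics(
            state, Q, contacts=contacts, gravity=gravity,
            passive_joints=passive_joints,
        )
    else:
        mask = np.asarray(free_dofs, dtype=bool)
        g = model.gravity if gravity is None else gravity
        c = model.config
        if passive_joints:
            K.joint_passive_torques(
                state.q, state.qd, model.jnt_lo, model.jnt_hi,
                c.joint_damping, c.joint_limit_stiffness,
                c.joint_limit_damping, Q,
            )
        forces = np.zeros((NCONTACT, 3))
        if contacts:
            K.contact_forces(
                state.q, state.qd, model.S,
                model.cp_n, model.cp_b, model.cp_c, model.cp_d,
                model.cp_body, model.cp_radius, model.cp_plane,
                model.seat_y, model.seat_xmin, model.seat_xmax,
                c.contact_stiffness, c.contact_dissipation,
                c.friction_coefficient, c.friction_vel_eps,
                Q, forces,
            )
        M, h = K.dynamics_terms(
            state.q, state.qd, model.S, model.mass, model.inertia,
            model.ct_n, model.ct_b, model.ct_c, model.ct_d, g,
        )
        rhs = (Q - h)[mask]
        qdd = np.zeros(NDOF)
        qdd[mask] = np.linalg.solve(M[np.ix_(mask, mask)], rhs)
    if not np.all(np.isfinite(qdd)):
        raise SimulationDiverged(f"non-finite accelerations at t={state.time}")
    # kick, then drift with the velocity midpoint (2nd-order positions)
    q = state.q + dt * (state.qd + 0.5 * dt * qdd)
    qd = state.qd + dt * qdd
    if not np.all(np.isfinite(q)):
        raise SimulationDiverged(f"non-finite state at t={state.time}")
    return BodyState(state.time + dt, q, qd, qdd)
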