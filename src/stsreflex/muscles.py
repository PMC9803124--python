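"""Symmetric Hill-type muscle-tendon channels with rigid tendons.

Each channel represents one functional muscle group per side, acting through
constant (posture-averaged) moment arms on the hip, knee and ankle joints.
Moment arms are stored extension-positive. The normalized fiber length is

    L_m = 1 + sum_j r_{m,j} * theta_j / s_m

with theta_j the flexion-positive joint angles (zero at upright stance) and
s_m an effective excursion scale: extensors stretch as joints flex. The scale
absorbs tendon compliance and moment-arm variation, keeping L_m in a
physiological band over the STS range.

Force: F = F_max * (a * f_L(L) * f_V(v) + f_P(L)), with a Gaussian
force-length curve, a Hill force-velocity curve (zero force at the maximal
shortening rate, ~1.8 F_max eccentric plateau) and a quadratic passive
element engaging beyond optimal length.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import _kernels as K

JOINT_NAMES = ("hip", "knee", "ankle")

A_MIN = 0.01          # activation floor used by the dynamics
FL_GAMMA = 0.2025     # Gaussian force-length width^2 ((L-1)^2 scale)
FP_K = 4.0            # passive quadratic stiffness beyond the slack length 1.2


@dataclass(frozen=True)
class MuscleChannel:
    """One symmetric muscle-tendon actuator (identical on both sides)."""

    name: str
    moment_arms: tuple[float, float, float]  # (hip, knee, ankle), m, extension +
    f_max: float                              # N
    excursion_scale: float = 0.25             # m per unit normalized length
    v_max: float = 10.0                       # excursion-scale units / s
    tau_act: float = 0.015                    # s
    tau_deact: float = 0.05                   # s

    def __post_init__(self):
        if all(r == 0.0 for r in self.moment_arms):
            raise ValueError(f"{self.name}: needs a nonzero moment arm")
        if self.tau_act <= 0 or self.tau_deact <= 0:
            raise ValueError(f"{self.name}: time constants must be positive")
        if self.f_max < 0 or self.excursion_scale <= 0 or self.v_max <= 0:
            raise ValueError(f"{self.name}: invalid Hill parameters")


@dataclass
class MuscleState:
    """Activation and normalized fiber kinematics of one channel."""

    activation: float = A_MIN
    fiber_length: float = 1.0     # normalized, 1 = optimal
    fiber_velocity: float = 0.0   # normalized / s, > 0 lengthening

    def __post_init__(self):
        if not (A_MIN - 1e-12 <= self.activation <= 1.0 + 1e-12):
            raise ValueError("activation outside [a_min, 1]")
        if self.fiber_length <= 0:
            raise ValueError("fiber length must be positive")


def default_channels() -> list[MuscleChannel]:
    """Nine symmetric channels approximating the STS-relevant muscle groups.

    GLU gluteus maximus/medius, ILPSO iliacus+psoas (vestibular reflexes
    disabled in phase 1), RF rectus femoris (biarticular, the phase-1 torso
    flexor), VAS vasti, HAMS biarticular hamstrings, BFSH biceps femoris short
    head, GAS gastrocnemius, SOL soleus, TA tibialis anterior.
    """
    return [
        MuscleChannel("GLU", (0.062, 0.0, 0.0), 1900.0),
        MuscleChannel("ILPSO", (-0.050, 0.0, 0.0), 1500.0),
        MuscleChannel("RF", (-0.040, 0.048, 0.0), 1200.0),
        MuscleChannel("VAS", (0.0, 0.045, 0.0), 5000.0),
        MuscleChannel("HAMS", (0.060, -0.030, 0.0), 2200.0),
        MuscleChannel("BFSH", (0.0, -0.030, 0.0), 550.0),
        MuscleChannel("GAS", (0.0, -0.020, 0.050), 1600.0, excursion_scale=0.20),
        MuscleChannel("SOL", (0.0, 0.0, 0.050), 3600.0, excursion_scale=0.20),
        MuscleChannel("TA", (0.0, 0.0, -0.040), 900.0, excursion_scale=0.20),
    ]


def channel_names(channels: list[MuscleChannel]) -> list[str]:
    return [ch.name for ch in channels]


# ---------------------------------------------------------------------------
# packed arrays for the kernels
# ---------------------------------------------------------------------------
def pack_channels(channels: list[MuscleChannel]):
    C = len(channels)
    arms = np.zeros((C, 3))
    fmax = np.zeros(C)
    sexc = np.zeros(C)
    vmax = np.zeros(C)
    ta = np.zeros(C)
    td = np.zeros(C)
    for i, ch in enumerate(channels):
        arms[i] = ch.moment_arms
        fmax[i] = ch.f_max
        sexc[i] = ch.excursion_scale
        vmax[i] = ch.v_max
        ta[i] = ch.tau_act
        td[i] = ch.tau_deact
    return arms, fmax, sexc, vmax, ta, td


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------
def activation_dynamics(
    stimulation: float, state: MuscleState, dt: float, channel: MuscleChannel
) -> MuscleState:
    """First-order excitation-activation coupling (exact exponential step)."""
    a = K.activation_step(
        state.activation, stimulation, dt, channel.tau_act, channel.tau_deact
    )
    a = min(1.0, max(A_MIN, a))
    return replace(state, activation=a)


def muscle_force(state: MuscleState, channel: MuscleChannel) -> float:
    """Hill force (N) for the given state; >= 0 always."""
    return float(
        K.muscle_force_kernel(
            state.activation,
            state.fiber_length,
            state.fiber_velocity,
            channel.f_max,
            FL_GAMMA,
            channel.v_max,
            FP_K,
        )
    )


def fiber_state(
    channel: MuscleChannel, joint_angles: np.ndarray, joint_velocities: np.ndarray
) -> tuple[float, float]:
    """(L_m, v_m) from flexion-positive joint angles (hip, knee, ankle), rad."""
    r = np.asarray(channel.moment_arms)
    L = 1.0 + float(r @ np.asarray(joint_angles)) / channel.excursion_scale
    v = float(r @ np.asarray(joint_velocities)) / channel.excursion_scale
    return L, v


def apply_muscle_torques(
    states: list[MuscleState],
    channels: list[MuscleChannel],
    body_state,
) -> np.ndarray:
    """Flexion-positive joint torques (hip_L, knee_L, ankle_L, hip_R, ...).

    The same activation drives both sides; forces are evaluated per side at
    that side's joint angles.
    """
    tau = np.zeros(6)
    q = body_state.q
    qd = body_state.qd
    for side in range(2):
        sl = slice(3 + 3 * side, 6 + 3 * side)
        for st, ch in zip(states, channels):
            L, v = fiber_state(ch, q[sl], qd[sl])
            f = muscle_force(replace(st, fiber_length=L, fiber_velocity=v), ch)
            for j in range(3):
                r = ch.moment_arms[j]
                if r != 0.0:
                    tau[3 * side + j] -= r * f
    return tau


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------
_CSV_COLS = [
    "name", "arm_hip", "arm_knee", "arm_ankle", "f_max",
    "excursion_scale", "v_max", "tau_act", "tau_deact",
]


def channels_to_csv(channels: list[MuscleChannel], path_or_buf) -> None:
    rows = [
        {
            "name": ch.name,
            "arm_hip": ch.moment_arms[0],
            "arm_knee": ch.moment_arms[1],
            "arm_ankle": ch.moment_arms[2],
            "f_max": ch.f_max,
            "excursion_scale": ch.excursion_scale,
            "v_max": ch.v_max,
            "tau_act": ch.tau_act,
            "tau_deact": ch.tau_deact,
        }
        for ch in channels
    ]
    pd.DataFrame(rows, columns=_CSV_COLS).to_csv(path_or_buf, index=False)


def channels_from_csv(path_or_buf) -> list[MuscleChannel]:
    df = pd.read_csv(path_or_buf)
    return [
        MuscleChannel(
            name=str(r["name"]),
            moment_arms=(float(r["arm_hip"]), float(r["arm_knee"]), float(r["arm_ankle"])),
            f_max=float(r["f_max"]),
            excursion_scale=float(r["excursion_scale"]),
            v_max=float(r["v_max"]),
            tau_act=float(r["tau_act"]),
            tau_deact=float(r["tau_deact"]),
        )
        for _, r in df.iterrows()
    ]
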