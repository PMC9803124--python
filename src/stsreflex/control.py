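"""Phase-dependent reflex controller: stimulation law, routing, phase machine.

The stimulation of channel m in phase n is

    A_m = A0_{m,n} + sum_s k_{s,m,n} (x_s - x_ref)  +  k_l,m (L_m - L0_m)

clamped to [a_min, 1]. The routed signals x_s are phase-dependent (vestibular
torso kinematics; torso+pelvis in the final phase); position-type signals have
a per-phase optimizable reference subtracted. The muscle-length reflex gains
are shared across phases. In the flexion-momentum phase only the rectus
femoris receives vestibular terms.

The phase machine is non-returning: flexion momentum -> momentum transfer at
hip > 77 deg; (4-phase only) -> extension when the torso CoM passes the feet
with non-positive forward velocity and a forward-leaning shank; -> stabilization
at knee <= 5 deg and hip <= 0 deg. The 2-phase controller merges everything
after the first transition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels as K
from ._kernels import (
    FB_ALPHA, FB_AX, FB_AY, FB_OMEGA, FB_PAX, FB_PPX, FB_PVX, FB_PX, FB_PY,
    FB_THETA, FB_VX, FB_VY, N_FB,
)
from .config import DEG

CONTROLLER_TYPES = ("4phase", "2phase")

_SIGNALS_VESTIBULAR = ("theta_torso", "omega_torso", "alpha_torso")
_SIGNALS_TRANSLATION = (
    "p_torso_x", "p_torso_y", "v_torso_x", "v_torso_y", "a_torso_x", "a_torso_y"
)
_SIGNALS_STABILIZATION = (
    "p_torso_x", "p_pelvis_x", "v_torso_x", "v_pelvis_x", "a_torso_x", "a_pelvis_x"
)

#: default per-class optimization bounds (lo, hi)
DEFAULT_BOUNDS = {
    "klen": (0.0, 3.0),
    "L0": (0.5, 1.5),
    "tonic": (0.01, 1.0),
    "pref_theta": (-0.5, 1.6),
    "pref_pos": (-0.5, 1.5),
    "k_theta_p": (-4.0, 4.0),
    "k_theta_v": (-2.0, 2.0),
    "k_theta_a": (-0.5, 0.5),
    "k_pos": (-8.0, 8.0),
    "k_vel": (-4.0, 4.0),
    "k_acc": (-1.0, 1.0),
}

_GAIN_CLASSES_VEST = ("k_theta_p", "k_theta_v", "k_theta_a")
_GAIN_CLASSES_TRANS = ("k_pos", "k_pos", "k_vel", "k_vel", "k_acc", "k_acc")


def n_phases(controller_type: str) -> int:
    if controller_type not in CONTROLLER_TYPES:
        raise ValueError(f"unknown controller type {controller_type!r}")
    return 4 if controller_type == "4phase" else 2


@dataclass
class PhaseState:
    """Current modelled phase with entry times; non-decreasing by contract."""

    phase: int = 1
    entry_times: list = field(default_factory=lambda: [0.0, None, None, None])

    def advance_to(self, phase: int, time: float) -> "PhaseState":
        if phase < self.phase:
            raise ValueError("phase machine cannot go backwards")
        new = PhaseState(phase, list(self.entry_times))
        if phase != self.phase:
            new.entry_times[phase - 1] = time
        return new


class BodyFeedback:
    """Named view over the feedback channel vector consumed by the controller."""

    _NAMES = {
        "theta_torso": FB_THETA, "omega_torso": FB_OMEGA, "alpha_torso": FB_ALPHA,
        "p_torso_x": FB_PX, "p_torso_y": FB_PY, "v_torso_x": FB_VX,
        "v_torso_y": FB_VY, "a_torso_x": FB_AX, "a_torso_y": FB_AY,
        "p_pelvis_x": FB_PPX, "v_pelvis_x": FB_PVX, "a_pelvis_x": FB_PAX,
        "theta_hip": FB_THETA, "omega_hip": FB_OMEGA,
        "theta_knee": K.FB_KNEE, "omega_knee": K.FB_KNEEVEL,
        "theta_ankle": K.FB_ANKLE, "omega_ankle": K.FB_ANKLEVEL,
        "theta_shank_x": K.FB_SHANK_X, "p_feet_x": K.FB_FEET_X,
        "v_talus_y": K.FB_VTALUS_Y, "v_toes_x": K.FB_VTOES_X,
        "v_toes_y": K.FB_VTOES_Y, "p_talus_x": K.FB_PTALUS_X,
        "p_toes_x": K.FB_PTOES_X, "p_pelvis_y": K.FB_PPY,
    }

    def __init__(self, array: np.ndarray):
        array = np.asarray(array, dtype=float)
        if array.shape != (N_FB,):
            raise ValueError(f"feedback vector must have length {N_FB}")
        self.array = array

    def __getattr__(self, name):
        idx = BodyFeedback._NAMES.get(name)
        if idx is None:
            raise AttributeError(name)
        return float(self.array[idx])

    def __getitem__(self, name: str) -> float:
        return float(self.array[self._NAMES[name]])

    def is_finite(self) -> bool:
        return bool(np.all(np.isfinite(self.array)))


def derive_feedback(model, state) -> BodyFeedback:
    """Assemble the controller/cost feedback channels from a BodyState.

    Acceleration channels come from the accelerations of the state's last
    dynamics evaluation (state.qdd), unfiltered.
    """
    fb = np.zeros(N_FB)
    filt = np.zeros(4)
    K.assemble_feedback(
        state.q, state.qd, state.qdd, model.S,
        model.ct_n, model.ct_b, model.ct_c, model.ct_d, model.pelvis_h,
        model.cp_n, model.cp_b, model.cp_c, model.cp_d,
        model.tal_n, model.tal_b, model.tal_c, model.tal_d,
        filt, 1.0, fb,
    )
    return BodyFeedback(fb)


def route_feedback(phase: PhaseState | int, controller_type: str) -> tuple[str, ...]:
    """Ordered routed-signal names for the given phase (Table-2 routing)."""
    p = phase.phase if isinstance(phase, PhaseState) else int(phase)
    np_ = n_phases(controller_type)
    if not 1 <= p <= np_:
        raise ValueError(f"phase {p} invalid for {controller_type}")
    if p == 1:
        return _SIGNALS_VESTIBULAR
    if controller_type == "4phase" and p == 4:
        return _SIGNALS_STABILIZATION
    return _SIGNALS_TRANSLATION


# ---------------------------------------------------------------------------
# parameter container + flat-vector codec
# ---------------------------------------------------------------------------
class ParamLayout:
    """Deterministic flat-vector layout for a controller's parameters.

    Order: k_l per channel; L0 per channel; then per phase: tonic A0 per
    channel, position reference(s), vestibular gains (phase 1: the rectus
    femoris' 3 gains; later phases: 6 gains per channel, channel-major).
    """

    def __init__(self, controller_type: str, channel_names: list[str], rf_index: int):
        self.controller_type = controller_type
        self.channel_names = list(channel_names)
        self.rf_index = rf_index
        self.n_channels = len(channel_names)
        self.entries: list[tuple[str, str]] = []  # (label, class)
        C = self.n_channels
        names = self.channel_names
        for m in range(C):
            self.entries.append((f"klen[{names[m]}]", "klen"))
        for m in range(C):
            self.entries.append((f"L0[{names[m]}]", "L0"))
        for p in range(1, n_phases(controller_type) + 1):
            sig = route_feedback(p, controller_type)
            for m in range(C):
                self.entries.append((f"A0[p{p},{names[m]}]", "tonic"))
            if p == 1:
                self.entries.append((f"ref[p{p},{sig[0]}]", "pref_theta"))
                for k in range(3):
                    self.entries.append(
                        (f"k[p{p},{names[rf_index]},{sig[k]}]", _GAIN_CLASSES_VEST[k])
                    )
            else:
                self.entries.append((f"ref[p{p},{sig[0]}]", "pref_pos"))
                self.entries.append((f"ref[p{p},{sig[1]}]", "pref_pos"))
                for m in range(C):
                    for k in range(6):
                        self.entries.append(
                            (f"k[p{p},{names[m]},{sig[k]}]", _GAIN_CLASSES_TRANS[k])
                        )

    @property
    def n_params(self) -> int:
        return len(self.entries)

    @staticmethod
    def expected_size(controller_type: str, n_channels: int) -> int:
        """Closed-form parameter count for C channels."""
        C = n_channels
        if controller_type == "4phase":
            return 24 * C + 10
        return 10 * C + 6

    def default_bounds(self, overrides: dict | None = None):
        b = dict(DEFAULT_BOUNDS)
        if overrides:
            b.update(overrides)
        lo = np.array([b[cls][0] for _, cls in self.entries])
        hi = np.array([b[cls][1] for _, cls in self.entries])
        return lo, hi

    def describe(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["parameter", "class"])


@dataclass
class ControllerParams:
    """Reflex gain sets for every phase plus the shared length reflex.

    Arrays are sized for 4 phases; the 2-phase controller uses rows 0..1.
    Gains beyond a phase's routed-signal count are ignored by the law.
    """

    controller_type: str
    channel_names: list[str]
    rf_index: int
    G: np.ndarray          # (4, C, 6) vestibular gains
    A0: np.ndarray         # (4, C) tonic
    pref: np.ndarray       # (4, 2) position references
    klen: np.ndarray       # (C,) length-reflex gain, shared across phases
    L0: np.ndarray         # (C,) length-reflex offset
    hip_up_deg: float = 77.0
    knee_ext_deg: float = 5.0
    hip_ext_deg: float = 0.0

    @classmethod
    def zeros(cls, controller_type: str, channel_names: list[str], rf_index: int):
        C = len(channel_names)
        return cls(
            controller_type, list(channel_names), rf_index,
            np.zeros((4, C, 6)), np.zeros((4, C)), np.zeros((4, 2)),
            np.zeros(C), np.ones(C),
        )

    @property
    def layout(self) -> ParamLayout:
        return ParamLayout(self.controller_type, self.channel_names, self.rf_index)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def thresholds_rad(self) -> tuple[float, float, float]:
        return (
            self.hip_up_deg * DEG,
            self.knee_ext_deg * DEG,
            self.hip_ext_deg * DEG,
        )

    def to_gain_table(self) -> pd.DataFrame:
        """Labeled long-format table (phase, channel, signal, value)."""
        rows = []
        for p in range(1, n_phases(self.controller_type) + 1):
            sig = route_feedback(p, self.controller_type)
            for m, name in enumerate(self.channel_names):
                rows.append((p, name, "tonic", self.A0[p - 1, m]))
                if p == 1 and m != self.rf_index:
                    continue
                for k, s in enumerate(sig):
                    rows.append((p, name, s, self.G[p - 1, m, k]))
        for m, name in enumerate(self.channel_names):
            rows.append((0, name, "k_length", self.klen[m]))
            rows.append((0, name, "L0", self.L0[m]))
        return pd.DataFrame(rows, columns=["phase", "channel", "signal", "value"])


def pack_params(params: ControllerParams) -> np.ndarray:
    """Flatten a ControllerParams to its layout's parameter vector."""
    layout = params.layout
    C = params.n_channels
    out = np.empty(layout.n_params)
    i = 0
    out[i : i + C] = params.klen
    i += C
    out[i : i + C] = params.L0
    i += C
    for p in range(1, n_phases(params.controller_type) + 1):
        out[i : i + C] = params.A0[p - 1]
        i += C
        if p == 1:
            out[i] = params.pref[0, 0]
            i += 1
            out[i : i + 3] = params.G[0, params.rf_index, :3]
            i += 3
        else:
            out[i : i + 2] = params.pref[p - 1]
            i += 2
            out[i : i + 6 * C] = params.G[p - 1].reshape(-1)
            i += 6 * C
    assert i == layout.n_params
    return out


def unpack_params(vector: np.ndarray, layout: ParamLayout) -> ControllerParams:
    """Inverse of pack_params; raises on a length mismatch."""
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (layout.n_params,):
        raise ValueError(
            f"parameter vector length {vector.shape} does not match layout "
            f"({layout.n_params})"
        )
    C = layout.n_channels
    params = ControllerParams.zeros(
        layout.controller_type, layout.channel_names, layout.rf_index
    )
    i = 0
    params.klen[:] = vector[i : i + C]
    i += C
    params.L0[:] = vector[i : i + C]
    i += C
    for p in range(1, n_phases(layout.controller_type) + 1):
        params.A0[p - 1] = vector[i : i + C]
        i += C
        if p == 1:
            params.pref[0, 0] = vector[i]
            i += 1
            params.G[0, layout.rf_index, :3] = vector[i : i + 3]
            i += 3
        else:
            params.pref[p - 1] = vector[i : i + 2]
            i += 2
            params.G[p - 1] = vector[i : i + 6 * C].reshape(C, 6)
            i += 6 * C
    return params


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------
def compute_stimulation(
    feedback: BodyFeedback,
    muscle_states: list,
    params: ControllerParams,
    phase: PhaseState | int,
    a_min: float = 0.01,
) -> np.ndarray:
    """Stimulation per channel, clamped to [a_min, 1]."""
    if not feedback.is_finite():
        raise ValueError("non-finite feedback")
    p = phase.phase if isinstance(phase, PhaseState) else int(phase)
    C = params.n_channels
    if len(muscle_states) != C:
        raise ValueError("one MuscleState per channel required")
    Lm = np.array([st.fiber_length for st in muscle_states])
    out = np.zeros(C)
    K.stimulation_kernel(
        feedback.array, Lm, params.G, params.A0, params.pref,
        params.klen, params.L0, p, n_phases(params.controller_type),
        params.rf_index, a_min, out,
    )
    return out


def advance_phase(
    feedback: BodyFeedback,
    phase: PhaseState,
    controller_type: str,
    time: float = 0.0,
    thresholds: tuple[float, float, float] | None = None,
) -> PhaseState:
    """Apply the non-returning transition rules; at most one step per call."""
    if thresholds is None:
        thresholds = (77.0 * DEG, 5.0 * DEG, 0.0)
    new_phase = K.phase_transition(
        phase.phase, feedback.array, n_phases(controller_type), *thresholds
    )
    return phase.advance_to(int(new_phase), time)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------
def params_to_json(params: ControllerParams, path) -> None:
    layout = params.layout
    obj = {
        "controller_type": params.controller_type,
        "channel_names": params.channel_names,
        "rf_index": params.rf_index,
        "thresholds_deg": [params.hip_up_deg, params.knee_ext_deg, params.hip_ext_deg],
        "vector": pack_params(params).tolist(),
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)


def params_from_json(path) -> ControllerParams:
    with open(path) as fh:
        obj = json.load(fh)
    layout = ParamLayout(
        obj["controller_type"], obj["channel_names"], int(obj["rf_index"])
    )
    params = unpack_params(np.array(obj["vector"]), layout)
    thr = obj.get("thresholds_deg")
    if thr:
        params.hip_up_deg, params.knee_ext_deg, params.hip_ext_deg = thr
    return params
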