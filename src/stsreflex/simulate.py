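"""Forward rollout of the reflex-controlled model.

Couples the planar dynamics, the Hill-type channels and the phase-dependent
reflex law in a single fixed-step loop (compiled when numba is available) and
returns a tidy trajectory table plus the cost report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels as K
from .config import DEG
from .control import ControllerParams, n_phases
from .cost import CostConfig, CostReport, finalize, rule_names
from .model import NDOF, PlanarSTSModel
from .muscles import A_MIN, FL_GAMMA, FP_K, MuscleChannel, pack_channels

#: hip-height / torso-pitch limits beyond which the rollout counts as a fall
FALL_HIP_Y = 0.25       # m
FALL_PITCH = 2.0        # rad, torso well past horizontal


@dataclass
class SimulationResult:
    """Trajectory + cost of one controller rollout."""

    frame: pd.DataFrame
    cost: CostReport
    phase_entry_times: list
    termination: str
    t_end: float
    record_dt: float

    @property
    def completed(self) -> bool:
        return self.termination == "completed"

    def trajectory(self):
        from .analysis import Trajectory

        return Trajectory(self.frame, self.record_dt)


def run_rollout(
    model: PlanarSTSModel,
    channels: list[MuscleChannel],
    params: ControllerParams,
    horizon: float | None = None,
    dt: float | None = None,
    record_hz: float = 100.0,
    cost_config: CostConfig | None = None,
) -> SimulationResult:
    """Simulate the seated model under the reflex controller.

    The rollout is deterministic given (model, channels, params). Horizon
    defaults to the model config's (20 s); the cost's termination penalty is
    always referenced to the cost config's horizon so short rollouts remain
    comparable.
    """
    cfg = model.config
    dt = cfg.dt if dt is None else dt
    horizon = cfg.horizon if horizon is None else horizon
    ctrl_phases = n_phases(params.controller_type)
    cost_cfg = cost_config or CostConfig(
        controller_type=params.controller_type, horizon=horizon
    )
    arms, fmax, sexc, vmax, tau_a, tau_d = pack_channels(channels)
    C = len(channels)
    rf_idx = params.rf_index

    nsteps = max(1, int(round(horizon / dt)))
    stride = max(1, int(round(1.0 / (record_hz * dt))))
    nrec_max = nsteps // stride + 1
    rec_t = np.zeros(nrec_max)
    rec_q = np.zeros((nrec_max, NDOF))
    rec_qd = np.zeros((nrec_max, NDOF))
    rec_act = np.zeros((nrec_max, C))
    rec_stim = np.zeros((nrec_max, C))
    rec_seat = np.zeros(nrec_max)
    rec_ground = np.zeros(nrec_max)
    rec_fb = np.zeros((nrec_max, K.N_FB))
    rec_phase = np.zeros(nrec_max, dtype=np.int64)
    phase_entry = np.zeros(4)
    n_rules = len(rule_names(params.controller_type))
    cost_acc = np.zeros(n_rules + 1)

    state0 = model.settled_state()  # static sitting equilibrium
    alpha_f = dt / (dt + 1.0 / (2.0 * math.pi * cfg.accel_filter_hz))
    thr = params.thresholds_rad()

    n_rec, t_end, term = K.rollout(
        model.S, model.mass, model.inertia,
        model.ct_n, model.ct_b, model.ct_c, model.ct_d, model.gravity,
        model.cp_n, model.cp_b, model.cp_c, model.cp_d,
        model.cp_body, model.cp_radius, model.cp_plane,
        model.seat_y, model.seat_xmin, model.seat_xmax,
        cfg.contact_stiffness, cfg.contact_dissipation,
        cfg.friction_coefficient, cfg.friction_vel_eps,
        model.tal_n, model.tal_b, model.tal_c, model.tal_d, model.pelvis_h,
        arms, fmax, sexc, vmax, tau_a, tau_d, A_MIN, FL_GAMMA, FP_K,
        model.jnt_lo, model.jnt_hi, cfg.joint_damping,
        cfg.joint_limit_stiffness, cfg.joint_limit_damping,
        ctrl_phases, params.G, params.A0, params.pref,
        params.klen, params.L0, rf_idx,
        thr[0], thr[1], thr[2],
        cost_cfg.a_threshold, cost_cfg.violation_cap,
        cost_cfg.weights, cost_cfg.k_fall, cost_cfg.horizon,
        state0.q, state0.qd, dt, nsteps, stride, alpha_f,
        FALL_HIP_Y, FALL_PITCH,
        rec_t, rec_q, rec_qd, rec_act, rec_stim, rec_seat, rec_ground,
        rec_fb, rec_phase, phase_entry, cost_acc,
    )

    entry = [t if t >= 0 else None for t in phase_entry[:ctrl_phases]]
    report = finalize(
        cost_acc, params.controller_type, int(term), float(t_end), entry, cost_cfg
    )
    frame = _build_frame(
        rec_t[:n_rec], rec_q[:n_rec], rec_qd[:n_rec], rec_act[:n_rec],
        rec_stim[:n_rec], rec_seat[:n_rec], rec_ground[:n_rec],
        rec_fb[:n_rec], rec_phase[:n_rec], channels,
    )
    return SimulationResult(
        frame, report, entry, report.termination, float(t_end), stride * dt
    )


_Q_NAMES = [
    "q_hip_x", "q_hip_y", "q_pitch",
    "q_hip_l", "q_knee_l", "q_ankle_l", "q_hip_r", "q_knee_r", "q_ankle_r",
]


def _build_frame(t, q, qd, act, stim, seat, ground, fb, phase, channels):
    data = {"time": t}
    # reported angle channels (deg)
    data["hip_deg"] = fb[:, K.FB_THETA] / DEG
    data["knee_deg"] = fb[:, K.FB_KNEE] / DEG
    data["ankle_deg"] = fb[:, K.FB_ANKLE] / DEG
    data["shank_x_deg"] = fb[:, K.FB_SHANK_X] / DEG
    data["seat_force_N"] = seat
    data["ground_force_N"] = ground
    for i, ch in enumerate(channels):
        data[f"act_{ch.name}"] = act[:, i]
    for i, ch in enumerate(channels):
        data[f"stim_{ch.name}"] = stim[:, i]
    data["phase"] = phase
    for j, name in enumerate(_Q_NAMES):
        data[name] = q[:, j]
    for j, name in enumerate(_Q_NAMES):
        data["d" + name] = qd[:, j]
    data["p_torso_x"] = fb[:, K.FB_PX]
    data["p_torso_y"] = fb[:, K.FB_PY]
    data["v_torso_x"] = fb[:, K.FB_VX]
    data["a_torso_x"] = fb[:, K.FB_AX]
    return pd.DataFrame(data)
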