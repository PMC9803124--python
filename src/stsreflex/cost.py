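"""Phase-dependent composite cost for controller optimization.

Every rule is a penalized predicate over the body feedback (thresholds from
the controllers' design tables); a violated predicate contributes

    weight * (excess beyond threshold)^2 * dt

per step, the quadratic excess giving the evolutionary search a graded signal.
There is deliberately no effort/energy term. Early termination (fall or
numerical divergence) adds K_fall * (horizon - t_end).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels as K
from .control import BodyFeedback, PhaseState, n_phases

#: rule ids, in kernel accumulator order
RULE_NAMES_4P = (
    "p1_suboptimal_acceleration",
    "p1_feet_movement",
    "p2_pelvis_backwards",
    "p2_talus_lift",
    "p2_toes_forward",
    "p2_hip_overextension",
    "p2_knee_overextension",
    "p2_torso_falling",
    "p3_torso_falling",
    "p3_torso_over_toes",
    "p3_talus_lift",
    "p3_toes_lift",
    "p3_hip_overextension",
    "p3_pelvis_backwards",
    "p4_torso_falling",
    "p4_talus_lift",
    "p4_toes_lift",
    "p4_pelvis_behind_talus",
    "p4_torso_over_toes",
    "p4_hip_range",
)
RULE_NAMES_2P = (
    "p1_suboptimal_acceleration",
    "p1_feet_movement",
    "m_torso_backwards",      # condition hip > 44 deg
    "m_pelvis_backwards",     # condition hip > 44 deg
    "m_hip_extension_progress",   # condition 8 < hip < 77 deg
    "m_knee_extension_progress",  # condition 8 < hip < 77 deg
    "m_hip_range",            # condition hip <= 8 deg
    "m_knee_flexion",         # condition hip <= 8 deg
    "m_torso_falling",
    "m_knee_overextension",
    "m_talus_lift",
    "m_toes_lift",
)

#: forward-acceleration thresholds for the flexion-momentum subtask, m/s^2
A_THRESH = {"4phase": 1.2, "2phase": 0.8}


def rule_names(controller_type: str) -> tuple[str, ...]:
    return RULE_NAMES_4P if controller_type == "4phase" else RULE_NAMES_2P


@dataclass
class CostConfig:
    """Weights and termination penalty; thresholds are the published values."""

    controller_type: str = "2phase"
    weights: np.ndarray | None = None
    k_fall: float = 50.0          # penalty per second of unsimulated time
    horizon: float = 20.0         # s, reference horizon for the penalty
    violation_cap: float = 2.0    # saturation of each rule's excess measure

    def __post_init__(self):
        n = len(rule_names(self.controller_type))
        if self.weights is None:
            # Default weights shape the search landscape so that completing
            # the task < lingering anywhere < falling, while each rule's
            # capped rate stays below the fall-penalty rate (living is never
            # costlier than dying early).
            self.weights = np.ones(n)
            self.weights[0] = 10.0  # flexion-momentum acceleration drive
            if self.controller_type == "2phase":
                names = rule_names("2phase")
                self.weights[names.index("m_hip_extension_progress")] = 50.0
                self.weights[names.index("m_knee_extension_progress")] = 10.0
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (n,):
                raise ValueError(f"expected {n} weights")
        if np.any(self.weights < 0) or self.k_fall < 0:
            raise ValueError("weights must be non-negative")

    @property
    def a_threshold(self) -> float:
        return A_THRESH[self.controller_type]


@dataclass
class CostReport:
    """Outcome of one rollout evaluation."""

    total: float
    components: dict[str, float]
    termination: str              # completed | fell | diverged
    phase_entry_times: list
    t_end: float

    def to_frame(self) -> pd.DataFrame:
        rows = [{"component": k, "value": v} for k, v in self.components.items()]
        rows.append({"component": "total", "value": self.total})
        return pd.DataFrame(rows)


def evaluate_step(
    feedback: BodyFeedback,
    phase: PhaseState | int,
    controller_type: str,
    dt: float,
    config: CostConfig | None = None,
    accumulator: np.ndarray | None = None,
) -> np.ndarray:
    """Per-rule penalty increments for one step (returns the accumulator).

    With accumulator=None a fresh zero array (one slot per rule, plus one for
    the termination penalty) is used, so the return value holds just this
    step's increments.
    """
    cfg = config or CostConfig(controller_type=controller_type)
    p = phase.phase if isinstance(phase, PhaseState) else int(phase)
    n = len(rule_names(controller_type))
    if accumulator is None:
        accumulator = np.zeros(n + 1)
    if controller_type == "4phase":
        K.cost_step_4p(
            feedback.array, p, dt, cfg.a_threshold, cfg.violation_cap,
            cfg.weights, accumulator,
        )
    else:
        K.cost_step_2p(
            feedback.array, p, dt, cfg.a_threshold, cfg.violation_cap,
            cfg.weights, accumulator,
        )
    return accumulator


_RULE_CONDITIONS = {
    "p1_suboptimal_acceleration": "a_torso,x <= a_threshold (1.2 / 0.8 m/s^2)",
    "p1_feet_movement": "v_toes,y > 0.2 m/s",
    "p2_pelvis_backwards": "v_pelvis,x <= 0 m/s",
    "p2_talus_lift": "v_talus,y > 0.1 m/s",
    "p2_toes_forward": "v_toes,x > 0.15 m/s",
    "p2_hip_overextension": "hip < -11 deg",
    "p2_knee_overextension": "knee < 0 deg",
    "p2_torso_falling": "p_torso,y < p_pelvis,y",
    "p3_torso_falling": "p_torso,y < p_pelvis,y",
    "p3_torso_over_toes": "p_torso,x > p_toes,x",
    "p3_talus_lift": "v_talus,y > 0.1 m/s",
    "p3_toes_lift": "v_toes,y > 0.15 m/s",
    "p3_hip_overextension": "hip < -11 deg",
    "p3_pelvis_backwards": "v_pelvis,x <= 0 m/s",
    "p4_torso_falling": "p_torso,y < p_pelvis,y",
    "p4_talus_lift": "v_talus,y > 0.1 m/s",
    "p4_toes_lift": "v_toes,y > 0.3 m/s",
    "p4_pelvis_behind_talus": "p_pelvis,x < p_talus,x",
    "p4_torso_over_toes": "p_torso,x > p_toes,x",
    "p4_hip_range": "|hip| > 8 deg",
    "m_torso_backwards": "v_torso,x <= 0 m/s  [while hip > 44 deg]",
    "m_pelvis_backwards": "v_pelvis,x <= 0 m/s  [while hip > 44 deg]",
    "m_hip_extension_progress": "hip extension < 10 deg/s  [8 < hip < 77 deg]",
    "m_knee_extension_progress": "knee flexing  [8 < hip < 77 deg]",
    "m_hip_range": "hip < -8 deg  [while hip <= 8 deg]",
    "m_knee_flexion": "knee >= 11 deg  [while hip <= 8 deg]",
    "m_torso_falling": "p_torso,y < p_pelvis,y",
    "m_knee_overextension": "knee < -15 deg",
    "m_talus_lift": "v_talus,y > 0.1 m/s",
    "m_toes_lift": "v_toes,y > 0.3 m/s",
}


def rule_table(controller_type: str, config: CostConfig | None = None) -> pd.DataFrame:
    """Auditable table of the penalty rules: name, penalized condition, weight."""
    cfg = config or CostConfig(controller_type=controller_type)
    names = rule_names(controller_type)
    return pd.DataFrame(
        {
            "rule": names,
            "penalized_condition": [_RULE_CONDITIONS[n] for n in names],
            "weight": cfg.weights,
        }
    )


TERMINATION_NAMES = {
    K.TERM_COMPLETED: "completed",
    K.TERM_FELL: "fell",
    K.TERM_DIVERGED: "diverged",
}


def finalize(
    accumulator: np.ndarray,
    controller_type: str,
    termination: int | str,
    t_end: float,
    phase_entry_times: list,
    config: CostConfig | None = None,
) -> CostReport:
    """Assemble a CostReport, adding the early-termination penalty if needed."""
    cfg = config or CostConfig(controller_type=controller_type)
    names = rule_names(controller_type)
    acc = np.asarray(accumulator, dtype=float)
    if acc.shape not in ((len(names),), (len(names) + 1,)):
        raise ValueError("accumulator size does not match the rule table")
    if isinstance(termination, int):
        termination = TERMINATION_NAMES[termination]
    components = {name: float(acc[i]) for i, name in enumerate(names)}
    term_pen = float(acc[len(names)]) if acc.shape[0] == len(names) + 1 else 0.0
    if termination != "completed" and term_pen == 0.0:
        term_pen = cfg.k_fall * max(0.0, cfg.horizon - t_end)
    components["termination_penalty"] = term_pen
    total = float(sum(components.values()))
    return CostReport(total, components, termination, list(phase_entry_times), t_end)
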