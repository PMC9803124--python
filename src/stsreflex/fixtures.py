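"""Synthetic STS reference traces.

The experimental recordings behind the STS study are not deposited; this
module generates surrogate traces with the statistical structure the analysis
chain assumes: minimum-jerk joint excursions from the seated pose (hip 12,
knee 85, ankle 61 deg) to upright 0 deg, a seat force that decays to exactly
0 N at the planted lift-off instant, a ground force complementarily rising to
body weight, a shank-inclination minimum at the planted momentum-transfer
instant, and muscle-activation bursts at plausible cycle positions. Phase-end
targets are user-set, never hard-coded results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import Trajectory

_DEFAULT_NOISE: dict[str, float] = {}

ACT_CHANNELS = ("SOL", "GAS", "TA", "VAS", "RF", "BF", "GLU")
# (center %, width %, peak) of each activation burst within the STS cycle
_ACT_SHAPE = {
    "SOL": (70.0, 18.0, 0.55),
    "GAS": (65.0, 20.0, 0.45),
    "TA": (25.0, 15.0, 0.60),
    "VAS": (50.0, 15.0, 0.85),
    "RF": (30.0, 14.0, 0.70),
    "BF": (55.0, 20.0, 0.50),
    "GLU": (48.0, 16.0, 0.80),
}


@dataclass
class FixtureSpec:
    """Targets and scales for one synthetic STS trace."""

    liftoff_pct: float = 35.0        # % of the STS cycle
    momentum_transfer_pct: float = 51.0
    cycle_duration: float = 2.0      # s, start to extension end
    standing_tail: float = 5.0       # s simulated after extension end
    start_angles_deg: tuple[float, float, float] = (12.0, 85.0, 61.0)
    hip_peak_deg: float = 80.0       # torso lean at lift-off
    body_weight: float = 80.0 * 9.81  # N
    seat_share: float = 0.75         # fraction of BW on the seat when seated
    sample_hz: float = 250.0
    noise: dict = field(default_factory=dict)  # channel -> std dev
    # residual hip-extension creep after the cycle (the hips keep extending
    # very slowly while standing); its initial acceleration A/tau^2 sits
    # between the extension and stabilization detection thresholds, which is
    # what separates those two events on a simulated-style trace
    settle_amp_deg: float = 0.0012
    settle_tau: float = 0.5          # s
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.liftoff_pct < self.momentum_transfer_pct < 100.0:
            raise ValueError("need 0 < liftoff% < momentum-transfer% < 100")
        if self.cycle_duration <= 0 or self.standing_tail < 0:
            raise ValueError("durations must be positive")


def _minjerk(s: np.ndarray) -> np.ndarray:
    """Minimum-jerk unit profile on s in [0, 1] (clamped outside)."""
    s = np.clip(s, 0.0, 1.0)
    return s**3 * (10.0 - 15.0 * s + 6.0 * s * s)


def _segment(t, t0, t1, v0, v1):
    """Minimum-jerk move from v0 at t0 to v1 at t1, held outside."""
    if t1 <= t0:
        return np.where(t < t0, v0, v1)
    return v0 + (v1 - v0) * _minjerk((t - t0) / (t1 - t0))


def generate_sts_trace(spec: FixtureSpec) -> Trajectory:
    """Build one synthetic STS trajectory from a FixtureSpec (seeded)."""
    rng = np.random.default_rng(spec.seed)
    dt = 1.0 / spec.sample_hz
    T = spec.cycle_duration
    t_lift = spec.liftoff_pct / 100.0 * T
    t_mt = spec.momentum_transfer_pct / 100.0 * T
    t_total = T + spec.standing_tail
    n = int(round(t_total / dt)) + 1
    t = np.arange(n) * dt

    hip0, knee0, ankle0 = spec.start_angles_deg
    # hip: lean to the peak by lift-off, then descend to 0 at extension end
    hip = np.where(
        t < t_lift,
        _segment(t, 0.0, t_lift, hip0, spec.hip_peak_deg),
        _segment(t, t_lift, T, spec.hip_peak_deg, 0.0),
    )
    # residual extension creep after the cycle end
    tail = t >= T
    hip = hip + np.where(
        tail,
        spec.settle_amp_deg * np.exp(-(t - T) / spec.settle_tau),
        0.0,
    )
    knee = _segment(t, t_lift, T, knee0, 0.0)
    # ankle: dorsiflexion bump peaking at momentum transfer, then extension
    ankle = np.where(
        t < t_mt,
        _segment(t, t_lift * 0.5, t_mt, ankle0, ankle0 + 5.0),
        _segment(t, t_mt, T, ankle0 + 5.0, 0.0),
    )
    # shank inclination w.r.t. +x: dips to its minimum exactly at t_mt
    shank0 = 90.0 - (90.0 - ankle0) * 0.5   # nominal seated inclination
    shank_min = shank0 - 6.0
    shank = np.where(
        t < t_mt,
        _segment(t, t_lift * 0.5, t_mt, shank0, shank_min),
        _segment(t, t_mt, T, shank_min, 90.0),
    )
    # seat force: smooth decay reaching exactly 0 N at lift-off
    seat = np.where(
        t < t_lift,
        spec.seat_share * spec.body_weight * (1.0 - _minjerk(t / max(t_lift, dt))),
        0.0,
    )
    ground = spec.body_weight - seat

    pct = np.clip(t / T * 100.0, 0.0, 100.0)
    data = {
        "time": t,
        "hip_deg": hip,
        "knee_deg": knee,
        "ankle_deg": ankle,
        "shank_x_deg": shank,
        "seat_force_N": seat,
        "ground_force_N": ground,
    }
    for name in ACT_CHANNELS:
        c, w, peak = _ACT_SHAPE[name]
        burst = 0.1 + (peak - 0.1) * np.exp(-0.5 * ((pct - c) / w) ** 2)
        data[f"act_{name}"] = np.where(tail, 0.1, burst)

    for ch, sd in spec.noise.items():
        if ch not in data or ch == "time":
            raise KeyError(f"unknown noise channel {ch!r}")
        data[ch] = data[ch] + rng.normal(0.0, sd, size=n)
    # keep the seat-force zero-crossing exact despite noise
    if "seat_force_N" in spec.noise:
        data["seat_force_N"] = np.where(
            t >= t_lift, 0.0, np.maximum(data["seat_force_N"], 1e-9)
        )
    for name in ACT_CHANNELS:
        data[f"act_{name}"] = np.clip(data[f"act_{name}"], 0.0, 1.0)

    return Trajectory(pd.DataFrame(data), dt)


def generate_degenerate_traces() -> dict[str, tuple[Trajectory, dict]]:
    """Pathological traces paired with their expected detector outcome."""
    base = FixtureSpec()
    out: dict[str, tuple[Trajectory, dict]] = {}

    traj = generate_sts_trace(base)
    df = traj.frame.copy()
    df["seat_force_N"] = 100.0  # never reaches 0 N
    out["seat_never_zero"] = (
        Trajectory(df, traj.dt),
        {"liftoff": None, "reason": "missing liftoff"},
    )

    df = traj.frame.copy()
    df["hip_deg"] = 12.0  # constant hip: extension never detectable
    out["constant_hip"] = (
        Trajectory(df, traj.dt),
        {"extension": None, "reason": "missing extension"},
    )

    # passing trace clipped right after stabilization: fails only standing
    short = FixtureSpec(standing_tail=2.5)
    out["short_standing"] = (
        generate_sts_trace(short),
        {"reason": "standing < 3 s"},
    )
    return out
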