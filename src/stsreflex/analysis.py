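"""STS measurement chain: kinematic phase detection, success classification,
cycle length-normalization, cross-correlation and run aggregation.

Kinematic phase-end events (simulated-trace rules):

* flexion momentum ends at lift-off -- the first sample where the vertical
  seat force reaches 0 N;
* momentum transfer ends at the minimum of the shank inclination w.r.t. the
  positive x axis;
* extension ends when the magnitude of the hip extension acceleration first
  drops below 0.0065 deg/s^2 (downward crossing, after momentum transfer);
* stabilization ends at the analogous 0.0015 deg/s^2 crossing;
* standing lasts until the end of the trace.

For experimental-style traces lift-off is the minimum of the seat-force first
derivative, momentum transfer ends at maximum dorsiflexion and extension at
the 0.0065 deg/s crossing of the hip extension *velocity*; the stabilization
event is not applied.

A cycle is successful when all phases occur in order, extension lasts at most
1 s and standing (stabilization end to trace end) lasts at least 3 s. Cycles
are resampled to 100 points between the start and the extension end (0-100 %
of the STS cycle).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _sig

EXT_ACC_THRESH = 0.0065    # deg/s^2, simulated-trace extension end
STAB_ACC_THRESH = 0.0015   # deg/s^2, simulated-trace stabilization end
EXT_VEL_THRESH = 0.0065    # deg/s, experimental-trace extension end
R_MATCH = 0.7              # cross-correlation acceptance (strict >)
N_CYCLE = 100


# ---------------------------------------------------------------------------
@dataclass
class Trajectory:
    """Uniformly sampled STS time-series table.

    Canonical columns: time, hip_deg (torso-pitch convention), knee_deg,
    ankle_deg, shank_x_deg, seat_force_N, ground_force_N and any number of
    act_<muscle> activation columns in [0, 1].
    """

    frame: pd.DataFrame
    dt: float | None = None

    def __post_init__(self):
        if "time" not in self.frame.columns:
            raise ValueError("trajectory needs a 'time' column")
        t = np.asarray(self.frame["time"], dtype=float)
        if len(t) < 2:
            raise ValueError("trajectory too short")
        steps = np.diff(t)
        if self.dt is None:
            self.dt = float(np.median(steps))
        if np.any(np.abs(steps - self.dt) > 1e-6 + 1e-3 * self.dt):
            raise ValueError("trajectory must be uniformly sampled")

    @property
    def time(self) -> np.ndarray:
        return np.asarray(self.frame["time"], dtype=float)

    @property
    def n(self) -> int:
        return len(self.frame)

    def channel(self, name: str) -> np.ndarray:
        return np.asarray(self.frame[name], dtype=float)

    def activation_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c.startswith("act_")]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        return cls(pd.read_csv(path))


@dataclass
class PhaseBoundaries:
    """Detected kinematic phase-end sample indices/times (None = not found)."""

    liftoff: int | None = None
    momentum_transfer: int | None = None
    extension: int | None = None
    stabilization: int | None = None
    end: int = 0
    times: dict = field(default_factory=dict)

    def ordered_indices(self) -> list[int]:
        return [
            i
            for i in (
                self.liftoff, self.momentum_transfer, self.extension,
                self.stabilization,
            )
            if i is not None
        ]

    def all_present(self) -> bool:
        return None not in (
            self.liftoff, self.momentum_transfer, self.extension, self.stabilization
        )

    def is_ordered(self) -> bool:
        idx = self.ordered_indices()
        return all(a < b for a, b in zip(idx, idx[1:]))


def _smooth(x: np.ndarray, dt: float, cutoff_hz: float) -> np.ndarray:
    fs = 1.0 / dt
    if cutoff_hz <= 0 or cutoff_hz >= 0.5 * fs or len(x) < 15:
        return x.astype(float)
    b, a = _sig.butter(2, cutoff_hz / (0.5 * fs))
    return _sig.filtfilt(b, a, x)


def _crossing_below(
    mag: np.ndarray, thresh: float, start: int, sustain: int = 3
) -> int | None:
    """First sustained downward crossing of mag below thresh after start.

    The detector arms once the magnitude is at/above the threshold, and fires
    at the first index where it stays below for `sustain` consecutive samples
    (clipped at the end of the record). Sustaining distinguishes genuine
    stillness from the single-sample zero grazes that any acceleration signal
    produces at its inflection points. If the signal never reaches the
    threshold after start, no event is reported.
    """
    n = len(mag)
    armed = mag[start] >= thresh
    i = start + 1
    while i < n:
        if mag[i] >= thresh:
            armed = True
            i += 1
            continue
        if armed:
            j = min(i + sustain, n)
            if np.all(mag[i:j] < thresh):
                return i
        i += 1
    return None


def detect_phases(
    traj: Trajectory, mode: str = "simulated", smooth_hz: float = 0.0
) -> PhaseBoundaries:
    """Locate the kinematic phase-end events of one STS trace."""
    if mode not in ("simulated", "experimental"):
        raise ValueError("mode must be 'simulated' or 'experimental'")
    t = traj.time
    dt = traj.dt
    n = traj.n
    b = PhaseBoundaries(end=n - 1)
    hip = _smooth(traj.channel("hip_deg"), dt, smooth_hz)
    ext_vel = -np.gradient(hip, dt)       # extension-positive, deg/s
    ext_acc = np.gradient(ext_vel, dt)    # deg/s^2

    if mode == "simulated":
        seat = traj.channel("seat_force_N")
        # arm once the seat is loaded (the model may start just above it)
        loaded = np.flatnonzero(seat > 1.0)
        if loaded.size:
            hit = np.flatnonzero(seat[loaded[0] :] <= 0.0)
            if hit.size:
                b.liftoff = int(loaded[0] + hit[0])
    else:
        seat = _smooth(traj.channel("seat_force_N"), dt, smooth_hz)
        dseat = np.gradient(seat, dt)
        b.liftoff = int(np.argmin(dseat))

    if b.liftoff is not None:
        if mode == "simulated":
            shank = traj.channel("shank_x_deg")
            b.momentum_transfer = b.liftoff + int(np.argmin(shank[b.liftoff :]))
        else:
            ankle = traj.channel("ankle_deg")
            b.momentum_transfer = b.liftoff + int(np.argmax(ankle[b.liftoff :]))

    if b.momentum_transfer is not None and b.momentum_transfer < n - 1:
        if mode == "simulated":
            b.extension = _crossing_below(
                np.abs(ext_acc), EXT_ACC_THRESH, b.momentum_transfer
            )
        else:
            b.extension = _crossing_below(
                np.abs(ext_vel), EXT_VEL_THRESH, b.momentum_transfer
            )

    if mode == "simulated" and b.extension is not None and b.extension < n - 1:
        b.stabilization = _crossing_below(
            np.abs(ext_acc), STAB_ACC_THRESH, b.extension
        )

    for name in ("liftoff", "momentum_transfer", "extension", "stabilization"):
        idx = getattr(b, name)
        b.times[name] = float(t[idx]) if idx is not None else None
    b.times["end"] = float(t[-1])
    return b


def check_success(
    boundaries: PhaseBoundaries,
    horizon: float | None = None,
    max_extension_s: float = 1.0,
    min_standing_s: float = 3.0,
) -> tuple[bool, list[str]]:
    """Classify an STS execution; returns (success, failure reasons)."""
    reasons: list[str] = []
    for name in ("liftoff", "momentum_transfer", "extension", "stabilization"):
        if boundaries.times.get(name) is None:
            reasons.append(f"missing {name}")
    if reasons:
        return False, reasons
    if not boundaries.is_ordered():
        return False, ["phases out of order"]
    t = boundaries.times
    ext_duration = t["extension"] - t["momentum_transfer"]
    if ext_duration > max_extension_s:
        reasons.append(f"extension > {max_extension_s:g} s")
    end = horizon if horizon is not None else t["end"]
    standing = end - t["stabilization"]
    if standing < min_standing_s:
        reasons.append(f"standing < {min_standing_s:g} s")
    return not reasons, reasons


# ---------------------------------------------------------------------------
@dataclass
class STSCycle:
    """A 100-point, length-normalized STS cycle."""

    channels: pd.DataFrame            # 100 rows
    boundaries_pct: dict              # phase-end positions in cycle %
    duration: float                   # s, start to extension end

    def channel(self, name: str) -> np.ndarray:
        return np.asarray(self.channels[name], dtype=float)


def normalize_cycle(traj: Trajectory, boundaries: PhaseBoundaries) -> STSCycle:
    """Resample every channel to 100 points over [start, extension end]."""
    if boundaries.extension is None:
        raise ValueError("cannot normalize: extension end not detected")
    t = traj.time
    t0, t1 = t[0], t[boundaries.extension]
    if t1 <= t0:
        raise ValueError("degenerate cycle span")
    tn = np.linspace(t0, t1, N_CYCLE)
    cols = {}
    for c in traj.frame.columns:
        if c == "time":
            continue
        arr = traj.channel(c)
        cols[c] = np.interp(tn, t, arr)
    pct = {}
    for name in ("liftoff", "momentum_transfer", "extension"):
        ti = boundaries.times.get(name)
        pct[name] = None if ti is None else 100.0 * (ti - t0) / (t1 - t0)
    return STSCycle(pd.DataFrame(cols), pct, float(t1 - t0))


# ---------------------------------------------------------------------------
@dataclass
class CrossCorrelation:
    r: float
    lag_pct: int
    matched: bool

    def __iter__(self):
        return iter((self.r, self.lag_pct, self.matched))


def cross_correlate(
    sim: np.ndarray, ref: np.ndarray, max_lag: int = 50
) -> CrossCorrelation:
    """Maximum Pearson correlation over cycle-percentage lags.

    Positive lag means the simulated waveform trails the reference by that
    many cycle percent. Ties resolve to the smallest |lag|. A zero-variance
    input yields r = nan (undefined, never silently 0).
    """
    x = np.asarray(sim, dtype=float)
    y = np.asarray(ref, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("channels must be 1-D arrays of equal length")
    n = x.size
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return CrossCorrelation(math.nan, 0, False)
    best_r = -np.inf
    best_lag = 0
    for a in range(max_lag + 1):
        for lag in ({a, -a} if a else {0}):
            if lag >= 0:
                xs, ys = x[lag:], y[: n - lag]
            else:
                xs, ys = x[: n + lag], y[-lag:]
            if xs.size < 3 or np.std(xs) == 0.0 or np.std(ys) == 0.0:
                continue
            r = float(np.corrcoef(xs, ys)[0, 1])
            if r > best_r:
                best_r = r
                best_lag = lag
    if not np.isfinite(best_r):
        return CrossCorrelation(math.nan, 0, False)
    return CrossCorrelation(best_r, best_lag, best_r > R_MATCH)


# ---------------------------------------------------------------------------
@dataclass
class CycleStats:
    mean: pd.DataFrame
    std: pd.DataFrame
    boundary_pct_mean: dict
    boundary_pct_std: dict
    n_runs: int


def aggregate_runs(cycles: list[STSCycle]) -> CycleStats:
    """Pointwise mean +/- std across runs, plus phase-percentage statistics."""
    if not cycles:
        raise ValueError("need at least one cycle")
    cols = list(cycles[0].channels.columns)
    for c in cycles[1:]:
        if list(c.channels.columns) != cols:
            raise ValueError("cycles have mismatched channels")
    stack = np.stack([c.channels.to_numpy(dtype=float) for c in cycles])
    mean = pd.DataFrame(stack.mean(axis=0), columns=cols)
    std = pd.DataFrame(stack.std(axis=0, ddof=0), columns=cols)
    bmean, bstd = {}, {}
    for name in ("liftoff", "momentum_transfer", "extension"):
        vals = [c.boundaries_pct.get(name) for c in cycles]
        vals = [v for v in vals if v is not None]
        if vals:
            bmean[name] = float(np.mean(vals))
            bstd[name] = float(np.std(vals, ddof=0))
        else:
            bmean[name] = None
            bstd[name] = None
    return CycleStats(mean, std, bmean, bstd, len(cycles))
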