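"""High-level modelling interface.

`ReflexSTS` bundles the planar musculoskeletal model, the muscle channel set
and a reflex-controller layout; `fit()` runs the CMA-ES protocol against the
phase-dependent cost and returns a `ReflexSTSResults` carrying the per-run
records, success classification and cycle statistics, with a `summary()`
table in the style of statistical modelling packages.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .analysis import (
    STSCycle, aggregate_runs, check_success, detect_phases, normalize_cycle,
)
from .config import ModelConfig
from .control import (
    ControllerParams, ParamLayout, pack_params, unpack_params,
)
from .cost import CostConfig
from .model import PlanarSTSModel
from .muscles import MuscleChannel, channel_names, default_channels
from .optimize import OptimizationConfig, RunRecord, records_to_frame, run_cmaes
from .simulate import SimulationResult, run_rollout


def load_demo_params(name: str = "demo_2phase.json") -> ControllerParams:
    """Packaged reference controller parameter set.

    Obtained with this package's own scaled-down optimization protocol
    (hand-initialized reflex gains refined by seeded CMA-ES) and frozen for
    reproducible demonstrations and tests.
    """
    from importlib import resources

    from .control import params_from_json

    path = resources.files("stsreflex").joinpath("data", name)
    with resources.as_file(path) as p:
        return params_from_json(p)


class ReflexSTS:
    """Reflex-controlled sit-to-stand model.

    Parameters
    ----------
    config
        Musculoskeletal/scene configuration; defaults to the 1.80 m / 80 kg
        reference body on a 0.45 m chair.
    controller_type
        "4phase" or "2phase".
    channels
        Muscle channel set; defaults to the nine symmetric STS groups.
    bounds_overrides
        Optional per-class optimization bound overrides.
    """

    def __init__(
        self,
        config: ModelConfig | None = None,
        controller_type: str = "2phase",
        channels: list[MuscleChannel] | None = None,
        cost_config: CostConfig | None = None,
        bounds_overrides: dict | None = None,
    ):
        self.config = config or ModelConfig()
        self.model = PlanarSTSModel(self.config)
        self.channels = channels if channels is not None else default_channels()
        self.controller_type = controller_type
        names = channel_names(self.channels)
        if "RF" not in names:
            raise ValueError("the channel set must include an RF channel")
        self.rf_index = names.index("RF")
        self.layout = ParamLayout(controller_type, names, self.rf_index)
        self.bounds = self.layout.default_bounds(bounds_overrides)
        self.cost_config = cost_config or CostConfig(controller_type=controller_type)

    # ------------------------------------------------------------------
    @property
    def n_params(self) -> int:
        return self.layout.n_params

    def params_from_vector(self, vector: np.ndarray) -> ControllerParams:
        return unpack_params(vector, self.layout)

    def zero_params(self) -> ControllerParams:
        return ControllerParams.zeros(
            self.controller_type, self.layout.channel_names, self.rf_index
        )

    def simulate(
        self,
        params: ControllerParams | np.ndarray,
        horizon: float | None = None,
        dt: float | None = None,
        record_hz: float = 100.0,
    ) -> SimulationResult:
        """Deterministic rollout of a parameter set from the seated pose."""
        if not isinstance(params, ControllerParams):
            params = self.params_from_vector(np.asarray(params, dtype=float))
        return run_rollout(
            self.model, self.channels, params,
            horizon=horizon, dt=dt, record_hz=record_hz,
            cost_config=self.cost_config,
        )

    def objective(self, vector: np.ndarray, horizon: float | None = None) -> float:
        """Cost of one parameter vector (deterministic; divergence-safe)."""
        try:
            res = self.simulate(vector, horizon=horizon)
        except Exception:
            return 1e9
        total = res.cost.total
        if not np.isfinite(total):
            return 1e9
        return float(total)

    # ------------------------------------------------------------------
    def fit(
        self,
        runs: int = 10,
        max_generations: int = 10000,
        popsize: int | None = None,
        seed: int = 0,
        horizon: float | None = None,
        sigma0: float = 0.2,
        stagnation_generations: int | None = None,
        x0: np.ndarray | None = None,
        map_fn=map,
    ) -> "ReflexSTSResults":
        """Optimize the reflex gains with independent CMA-ES runs."""
        horizon = self.config.horizon if horizon is None else horizon
        x0n = None
        if x0 is not None:
            lo, hi = self.bounds
            x0n = (np.asarray(x0, dtype=float) - lo) / (hi - lo)
        opt_cfg = OptimizationConfig(
            controller_type=self.controller_type,
            runs=runs,
            max_generations=max_generations,
            popsize=popsize,
            sigma0=sigma0,
            horizon=horizon,
            seed=seed,
            stagnation_generations=stagnation_generations,
            x0_normalized=x0n,
        )
        records = run_cmaes(
            lambda v: self.objective(v, horizon=horizon),
            self.bounds,
            opt_cfg,
            map_fn=map_fn,
        )
        return ReflexSTSResults(self, records, horizon)


@dataclass
class RunAnalysis:
    record: RunRecord
    simulation: SimulationResult
    success: bool
    reasons: list
    cycle: STSCycle | None


class ReflexSTSResults:
    """Fit outcome: per-run optimization records + STS cycle analyses."""

    def __init__(self, sts: ReflexSTS, records: list[RunRecord], horizon: float):
        self.model = sts
        self.records = records
        self.horizon = horizon
        self.analyses: list[RunAnalysis] = []
        for rec in records:
            sim = sts.simulate(rec.best_vector, horizon=horizon)
            boundaries = detect_phases(sim.trajectory())
            ok, reasons = check_success(boundaries, horizon=sim.t_end)
            cycle = None
            if boundaries.extension is not None:
                cycle = normalize_cycle(sim.trajectory(), boundaries)
            rec.success = ok
            rec.phase_entry_times = sim.phase_entry_times
            self.analyses.append(RunAnalysis(rec, sim, ok, reasons, cycle))

    # ------------------------------------------------------------------
    @property
    def n_success(self) -> int:
        return sum(a.success for a in self.analyses)

    @property
    def best_index(self) -> int:
        return int(np.argmin([r.best_cost for r in self.records]))

    @property
    def best_record(self) -> RunRecord:
        return self.records[self.best_index]

    def successful_cycles(self) -> list[STSCycle]:
        return [a.cycle for a in self.analyses if a.success and a.cycle is not None]

    def aggregate(self):
        cycles = self.successful_cycles()
        if not cycles:
            raise ValueError("no successful cycles to aggregate")
        return aggregate_runs(cycles)

    def to_frame(self) -> pd.DataFrame:
        df = records_to_frame(self.records)
        df["liftoff_pct"] = [
            (a.cycle.boundaries_pct["liftoff"] if a.cycle else np.nan)
            for a in self.analyses
        ]
        df["momentum_transfer_pct"] = [
            (a.cycle.boundaries_pct["momentum_transfer"] if a.cycle else np.nan)
            for a in self.analyses
        ]
        return df

    def summary(self) -> str:
        buf = io.StringIO()
        m = self.model
        buf.write("Reflex STS controller fit\n")
        buf.write("=" * 60 + "\n")
        buf.write(f"controller type:      {m.controller_type}\n")
        buf.write(f"muscle channels:      {len(m.channels)} per side\n")
        buf.write(f"parameters:           {m.n_params}\n")
        buf.write(f"simulation horizon:   {self.horizon:g} s\n")
        buf.write(f"independent runs:     {len(self.records)}\n")
        buf.write(f"successful STS:       {self.n_success} / {len(self.records)}\n")
        buf.write("-" * 60 + "\n")
        df = self.to_frame()
        buf.write(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
        buf.write("\n")
        cycles = self.successful_cycles()
        if cycles:
            stats = aggregate_runs(cycles)
            buf.write("-" * 60 + "\n")
            buf.write("phase-end cycle percentages (successful runs, mean +/- std):\n")
            for name, label in (
                ("liftoff", "flexion momentum"),
                ("momentum_transfer", "momentum transfer"),
                ("extension", "extension"),
            ):
                mu = stats.boundary_pct_mean[name]
                sd = stats.boundary_pct_std[name]
                if mu is not None:
                    buf.write(f"  {label:<20s} {mu:6.2f} +/- {sd:.2f} %\n")
        return buf.getvalue()
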