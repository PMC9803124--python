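"""CMA-ES search protocol over controller parameters.

Mirrors the published optimization setup: a number of independent runs
(default 10) with distinct seeds, an iteration (generation) cap (default
10000) and a fixed simulation horizon (default 20 s). The search operates in
box-normalized coordinates (each parameter mapped to [0, 1] from its
class-specific bounds), with sigma0 expressed in those units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cmaes import CMAResult, minimize


@dataclass
class OptimizationConfig:
    controller_type: str = "2phase"
    runs: int = 10
    max_generations: int = 10000
    max_evaluations: int | None = None
    popsize: int | None = None
    sigma0: float = 0.2              # in normalized [0, 1] parameter units
    horizon: float = 20.0            # s
    seed: int = 0
    stagnation_generations: int | None = None
    x0_normalized: np.ndarray | None = None

    def __post_init__(self):
        if self.runs < 1 or self.max_generations < 1:
            raise ValueError("runs and max_generations must be >= 1")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")

    def run_seeds(self) -> list[int]:
        seeds = [self.seed + 1000 * i for i in range(self.runs)]
        if len(set(seeds)) != len(seeds):
            raise ValueError("run seeds must be distinct")
        return seeds


@dataclass
class RunRecord:
    """Outcome of one independent CMA-ES run."""

    seed: int
    best_vector: np.ndarray          # natural (denormalized) units
    best_cost: float
    cost_trace: list                 # best-so-far per generation
    generations: int
    evaluations: int
    stop_reason: str
    success: bool | None = None      # filled by the analysis chain
    phase_entry_times: list | None = None

    def __post_init__(self):
        tr = np.asarray(self.cost_trace, dtype=float)
        if tr.size and np.any(np.diff(tr) > 1e-12):
            raise ValueError("best-so-far cost trace must be non-increasing")


def run_cmaes(
    objective,
    bounds: tuple[np.ndarray, np.ndarray],
    config: OptimizationConfig,
    map_fn=map,
    callback=None,
) -> list[RunRecord]:
    """Execute the independent-runs CMA-ES protocol.

    objective is called with a parameter vector in natural units; bounds are
    (lo, hi) arrays in the same units. Each run is reproducible from its seed.
    """
    lo = np.asarray(bounds[0], dtype=float)
    hi = np.asarray(bounds[1], dtype=float)
    if lo.shape != hi.shape or np.any(hi <= lo):
        raise ValueError("invalid bounds")
    span = hi - lo

    def to_natural(y: np.ndarray) -> np.ndarray:
        return lo + np.clip(y, 0.0, 1.0) * span

    def wrapped(y: np.ndarray) -> float:
        return float(objective(to_natural(y)))

    max_gens = config.max_generations
    records: list[RunRecord] = []
    for seed in config.run_seeds():
        gens = max_gens
        if config.max_evaluations is not None:
            from .cmaes import default_popsize

            lam = config.popsize or default_popsize(lo.size)
            gens = min(gens, max(1, config.max_evaluations // lam))
        x0 = (
            np.full(lo.size, 0.5)
            if config.x0_normalized is None
            else np.asarray(config.x0_normalized, dtype=float)
        )
        res: CMAResult = minimize(
            wrapped,
            x0,
            config.sigma0,
            popsize=config.popsize,
            max_generations=gens,
            seed=seed,
            bounds=(np.zeros(lo.size), np.ones(lo.size)),
            stagnation_generations=config.stagnation_generations,
            map_fn=map_fn,
            callback=callback,
        )
        records.append(
            RunRecord(
                seed=seed,
                best_vector=to_natural(res.xbest),
                best_cost=res.fbest,
                cost_trace=list(res.history),
                generations=res.generations,
                evaluations=res.evaluations,
                stop_reason=res.stop_reason,
            )
        )
    return records


def records_to_frame(records: list[RunRecord]) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(records):
        rows.append(
            {
                "run": i,
                "seed": r.seed,
                "best_cost": r.best_cost,
                "generations": r.generations,
                "evaluations": r.evaluations,
                "stop_reason": r.stop_reason,
                "success": r.success,
            }
        )
    return pd.DataFrame(rows)
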