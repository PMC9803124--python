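"""Covariance Matrix Adaptation Evolution Strategy (CMA-ES).

Standard (mu/mu_w, lambda) CMA-ES with rank-1 and rank-mu covariance updates
and cumulative step-size adaptation, after Hansen's reference description.
Deterministic for a fixed seed. Box constraints are handled by evaluating a
projected (clipped) candidate plus a small quadratic out-of-bounds penalty,
which keeps the sampling distribution unconstrained while selection pulls the
population back into the box.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass
class CMAResult:
    xbest: np.ndarray
    fbest: float
    history: list            # best-so-far cost per generation (non-increasing)
    generations: int
    evaluations: int
    stop_reason: str


def default_popsize(n: int) -> int:
    return 4 + int(3 * math.log(n))


class CMAES:
    """Ask/tell CMA-ES minimizer."""

    def __init__(
        self,
        x0: np.ndarray,
        sigma0: float,
        popsize: int | None = None,
        seed: int = 0,
        bounds: tuple[np.ndarray, np.ndarray] | None = None,
        bound_penalty: float = 1.0,
    ):
        self.mean = np.asarray(x0, dtype=float).copy()
        self.n = self.mean.size
        self.sigma = float(sigma0)
        self.lam = popsize or default_popsize(self.n)
        if self.lam < 2:
            raise ValueError("population size must be >= 2")
        self.rng = np.random.default_rng(seed)
        self.bounds = bounds
        self.bound_penalty = bound_penalty

        n, lam = self.n, self.lam
        self.mu = lam // 2
        w = np.log((lam + 1) / 2.0) - np.log(np.arange(1, self.mu + 1))
        self.weights = w / w.sum()
        self.mueff = 1.0 / np.sum(self.weights**2)

        self.cc = (4 + self.mueff / n) / (n + 4 + 2 * self.mueff / n)
        self.cs = (self.mueff + 2) / (n + self.mueff + 5)
        self.c1 = 2.0 / ((n + 1.3) ** 2 + self.mueff)
        self.cmu = min(
            1 - self.c1,
            2 * (self.mueff - 2 + 1 / self.mueff) / ((n + 2) ** 2 + self.mueff),
        )
        self.damps = 1 + 2 * max(0.0, math.sqrt((self.mueff - 1) / (n + 1)) - 1) + self.cs
        self.chin = math.sqrt(n) * (1 - 1.0 / (4 * n) + 1.0 / (21 * n * n))

        self.pc = np.zeros(n)
        self.ps = np.zeros(n)
        self.C = np.eye(n)
        self.B = np.eye(n)
        self.D = np.ones(n)
        self.invsqrtC = np.eye(n)
        self._eigen_stale = 0
        # lazy eigendecomposition cadence (generations)
        self._eigen_every = max(1, int(1.0 / ((self.c1 + self.cmu) * n * 10.0)))
        self.generation = 0
        self.evaluations = 0

    # ------------------------------------------------------------------
    def _update_eigen(self) -> None:
        if self._eigen_stale < self._eigen_every and self.generation > 0:
            self._eigen_stale += 1
            return
        self._eigen_stale = 1
        self.C = np.triu(self.C) + np.triu(self.C, 1).T
        d2, self.B = np.linalg.eigh(self.C)
        self.D = np.sqrt(np.maximum(d2, 1e-30))
        self.invsqrtC = (self.B / self.D) @ self.B.T

    def ask(self) -> np.ndarray:
        """Sample lambda candidates, shape (lam, n)."""
        self._update_eigen()
        z = self.rng.standard_normal((self.lam, self.n))
        y = z * self.D  # scale
        self._y = y @ self.B.T
        return self.mean + self.sigma * self._y

    def repair(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Project candidates into the box; return (projected, penalties)."""
        if self.bounds is None:
            return X, np.zeros(X.shape[0])
        lo, hi = self.bounds
        Xr = np.clip(X, lo, hi)
        pen = self.bound_penalty * np.sum((X - Xr) ** 2, axis=1)
        return Xr, pen

    def tell(self, X: np.ndarray, f: np.ndarray) -> None:
        """Rank candidates by f and update mean, paths, C, sigma."""
        f = np.asarray(f, dtype=float)
        order = np.argsort(f, kind="stable")
        sel = order[: self.mu]
        yw = self.weights @ self._y[sel]
        self.mean = self.mean + self.sigma * yw

        self.ps = (1 - self.cs) * self.ps + math.sqrt(
            self.cs * (2 - self.cs) * self.mueff
        ) * (self.invsqrtC @ yw)
        hsig = float(
            np.linalg.norm(self.ps)
            / math.sqrt(1 - (1 - self.cs) ** (2 * (self.generation + 1)))
            / self.chin
            < 1.4 + 2.0 / (self.n + 1)
        )
        self.pc = (1 - self.cc) * self.pc + hsig * math.sqrt(
            self.cc * (2 - self.cc) * self.mueff
        ) * yw

        artmp = self._y[sel]
        self.C = (
            (1 - self.c1 - self.cmu) * self.C
            + self.c1
            * (
                np.outer(self.pc, self.pc)
                + (1 - hsig) * self.cc * (2 - self.cc) * self.C
            )
            + self.cmu * (artmp.T * self.weights) @ artmp
        )
        self.sigma *= math.exp(
            (self.cs / self.damps) * (np.linalg.norm(self.ps) / self.chin - 1)
        )
        self.generation += 1
        self.evaluations += len(f)


def minimize(
    func,
    x0: np.ndarray,
    sigma0: float,
    popsize: int | None = None,
    max_generations: int = 1000,
    seed: int = 0,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
    ftol_target: float | None = None,
    stagnation_generations: int | None = None,
    map_fn=map,
    callback=None,
) -> CMAResult:
    """Minimize func with CMA-ES.

    func is called on one candidate vector at a time (through map_fn, which
    may parallelize within a generation; the reduction is order-preserving so
    results are independent of evaluation order). The best-so-far history is
    non-increasing by construction.
    """
    es = CMAES(x0, sigma0, popsize=popsize, seed=seed, bounds=bounds)
    fbest = math.inf
    xbest = np.asarray(x0, dtype=float).copy()
    history: list[float] = []
    stop = "max_generations"
    since_improvement = 0
    for gen in range(max_generations):
        X = es.ask()
        Xr, pen = es.repair(X)
        f_raw = np.fromiter(map_fn(func, Xr), dtype=float, count=es.lam)
        f = f_raw + pen
        es.tell(X, f)
        i = int(np.argmin(f_raw))
        improved = f_raw[i] < fbest
        if improved:
            fbest = float(f_raw[i])
            xbest = Xr[i].copy()
            since_improvement = 0
        else:
            since_improvement += 1
        history.append(fbest)
        if callback is not None:
            callback(es, fbest, xbest)
        if ftol_target is not None and fbest <= ftol_target:
            stop = "ftol_target"
            break
        if (
            stagnation_generations is not None
            and since_improvement >= stagnation_generations
        ):
            stop = "stagnation"
            break
        if es.sigma < 1e-16:
            stop = "sigma_collapse"
            break
    return CMAResult(xbest, fbest, history, es.generation, es.evaluations, stop)
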