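"""Sparrow search algorithm (SSA), a population metaheuristic.

The population is split by fitness rank into producers (discoverers) who
explore, and scroungers who follow the best producer; each iteration a
random subset ("scouts", the danger-aware fraction) is additionally
relocated relative to the global best. The producer update switches between
a contracting exponential walk (safe, alarm value below the safety
threshold) and a Gaussian step (alarmed). Positions are clipped to the box
bounds and the best-so-far solution is tracked, so the fitness history is
monotone nonincreasing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SsaConfig", "ssa_optimize"]


@dataclass(frozen=True)
class SsaConfig:
    """Defaults: population 10, 20 iterations, 70% discoverers, 20% scouts,
    alert (safety) value 0.6."""

    pop_size: int = 10
    n_iter: int = 20
    discoverer_frac: float = 0.70
    scout_frac: float = 0.20
    alert_value: float = 0.60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("population must hold at least 2 sparrows")
        if self.n_iter < 0:
            raise ValueError("n_iter must be >= 0")
        for name in ("discoverer_frac", "scout_frac", "alert_value"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")


def _evaluate(fitness, X: np.ndarray) -> np.ndarray:
    F = np.empty(X.shape[0])
    for i, x in enumerate(X):
        f = float(fitness(x))
        if not np.isfinite(f):
            raise ValueError(f"non-finite fitness at position {x.tolist()}")
        F[i] = f
    return F


def ssa_optimize(fitness, dim: int, bounds, config: SsaConfig | None = None,
                 init: np.ndarray | None = None
                 ) -> tuple[np.ndarray, float, np.ndarray]:
    """Minimize ``fitness`` over a box; returns (best_x, best_f, history).

    ``bounds`` is a (low, high) pair of scalars or length-``dim`` arrays.
    ``history`` holds the best-so-far fitness after initialization and after
    each iteration (length n_iter + 1), monotone nonincreasing. ``init``
    optionally seeds the first population member.
    """
    config = config or SsaConfig()
    lo = np.broadcast_to(np.asarray(bounds[0], float), (dim,)).copy()
    hi = np.broadcast_to(np.asarray(bounds[1], float), (dim,)).copy()
    if not np.all(np.isfinite(lo)) or not np.all(np.isfinite(hi)) or np.any(lo >= hi):
        raise ValueError("bounds must be finite with low < high")
    rng = np.random.default_rng(config.seed)
    pop, T = config.pop_size, config.n_iter

    X = rng.uniform(lo, hi, size=(pop, dim))
    if init is not None:
        X[0] = np.clip(np.asarray(init, float), lo, hi)
    F = _evaluate(fitness, X)
    ib = int(np.argmin(F))
    best_x, best_f = X[ib].copy(), float(F[ib])
    history = [best_f]

    n_prod = max(1, int(round(config.discoverer_frac * pop)))
    n_scout = max(1, int(round(config.scout_frac * pop)))

    for t in range(1, T + 1):
        order = np.argsort(F)
        Xn = X.copy()
        worst = X[order[-1]]
        alarm = rng.random()
        # producers: contract toward the origin of their own scale when safe,
        # take a Gaussian step when the alarm exceeds the safety threshold
        for rank in range(n_prod):
            i = order[rank]
            if alarm < config.alert_value:
                alpha = rng.random() or 1e-12
                Xn[i] = X[i] * np.exp(-(rank + 1) / (alpha * T))
            else:
                Xn[i] = X[i] + rng.normal() * np.ones(dim)
        # scroungers: the hungrier half scatters, the rest follow the best producer
        x_prod = X[order[0]]
        for rank in range(n_prod, pop):
            i = order[rank]
            if rank + 1 > pop / 2:
                q = rng.normal()
                Xn[i] = q * np.exp((worst - X[i]) / (rank + 1) ** 2)
            else:
                step = np.abs(X[i] - x_prod) * rng.choice([-1.0, 1.0], size=dim)
                Xn[i] = x_prod + step / dim
        # scouts: a random danger-aware fraction moves relative to the best
        for i in rng.choice(pop, size=n_scout, replace=False):
            if F[i] > best_f:
                Xn[i] = best_x + rng.normal() * np.abs(X[i] - best_x)
            else:
                k = rng.uniform(-1, 1)
                denom = (F[i] - F[order[-1]]) + 1e-50
                Xn[i] = X[i] + k * np.abs(X[i] - worst) / denom if denom != 0 else X[i]
        X = np.clip(Xn, lo, hi)
        F = _evaluate(fitness, X)
        ib = int(np.argmin(F))
        if F[ib] < best_f:
            best_x, best_f = X[ib].copy(), float(F[ib])
        history.append(best_f)
    return best_x, best_f, np.asarray(history)
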