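"""SSA-optimized BP network: metaheuristic search over initial weights.

The sparrow search algorithm explores the flattened initial weight/bias
vector of the network; each candidate is scored by the validation MSE of a
Levenberg-Marquardt refinement (an inner 4:1 split of the training data,
refinement budget equal to a plain training run). The seeded random
initialization that plain training would use is a member of the initial
population, and the final model is chosen elitistically: both the SSA
winner and the plain initialization are trained to completion with a
1000-epoch budget and the one with the lower inner-validation MSE is
returned, so the optimizer can refine but never degrade the baseline. With
``n_iter=0`` the optimizer degenerates to plain training from the seeded
random initialization.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .neural import BpConfig, BpModel, bp_predict, bp_train, n_params
from .ssa import SsaConfig, ssa_optimize

__all__ = ["ssa_bp_train", "inner_validation_split"]


def inner_validation_split(n: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """The seeded 4:1 (train, validation) index split used for the SSA fitness."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = max(1, int(np.floor(n / 5 + 0.5)))
    return perm[n_val:], perm[:n_val]

_FITNESS_EPOCHS = 100
_FINAL_EPOCHS = 1000
_WEIGHT_BOUND = 1.0


def ssa_bp_train(X: np.ndarray, y: np.ndarray,
                 bp_config: BpConfig | None = None,
                 ssa_config: SsaConfig | None = None) -> BpModel:
    """Train a BP network from an SSA-optimized initial weight vector."""
    bp_config = bp_config or BpConfig()
    ssa_config = ssa_config or SsaConfig()
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    n, d = X.shape
    p = n_params(d, bp_config.n_hidden)
    final_cfg = replace(bp_config, max_epochs=_FINAL_EPOCHS)

    if ssa_config.n_iter == 0:
        return bp_train(X, y, final_cfg)

    tr, val = inner_validation_split(n, bp_config.seed)
    fit_cfg = replace(bp_config, max_epochs=_FITNESS_EPOCHS)

    def fitness(theta: np.ndarray) -> float:
        m = bp_train(X[tr], y[tr], fit_cfg, theta0=theta)
        pred = bp_predict(m, X[val])
        return float(np.mean((y[val] - pred) ** 2))

    seed_init = np.random.default_rng(bp_config.seed).uniform(-0.5, 0.5, p)
    best_theta, _, _ = ssa_optimize(
        fitness, p, (-_WEIGHT_BOUND, _WEIGHT_BOUND), ssa_config, init=seed_init
    )

    def val_of(model: BpModel) -> float:
        return float(np.mean((y[val] - bp_predict(model, X[val])) ** 2))

    candidates = [bp_train(X, y, final_cfg, theta0=best_theta),
                  bp_train(X, y, final_cfg)]
    return min(candidates, key=val_of)
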