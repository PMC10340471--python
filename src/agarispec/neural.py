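"""Three-layer feedforward regression network trained by Levenberg-Marquardt.

The architecture mirrors the classic MATLAB setup for small chemometric
problems: one hidden layer of tanh ("tansig") units, a linear ("purelin")
output, inputs min-max scaled to [-1, 1] per feature, target standardized
for training. Training is damped Gauss-Newton on the full Jacobian
("trainlm"): exact for these network sizes (<= tens of hidden units, a few
hundred samples) and far faster than first-order descent. When the
parameter count exceeds the sample count the normal equations are solved in
sample space via the push-through identity, so full-spectrum inputs (311
bands) remain cheap.

Stopping: target MSE reached (on the standardized scale), epoch budget
exhausted, or the damping factor overflowing (no descent direction left).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .spectra import r2_score

__all__ = ["BpConfig", "BpModel", "bp_train", "bp_predict", "bp_scan_hidden",
           "n_params"]


@dataclass(frozen=True)
class BpConfig:
    """Training settings: tanh hidden layer (5-10 units), linear output,
    learning rate 0.1, target MSE 0.001, 100-epoch budget.

    ``val_fraction``/``max_fail`` implement the MATLAB-toolbox-style early
    stopping: a held-out slice of the training data is monitored and
    training stops after ``max_fail`` consecutive epochs without a new best
    validation error, returning the best-validation weights. Set
    ``val_fraction=0`` for pure LM descent on all samples.
    """

    n_hidden: int = 8
    lr: float = 0.1               # kept for fidelity; LM adapts its own damping
    max_epochs: int = 100
    goal_mse: float = 1e-3
    val_fraction: float = 0.2
    max_fail: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hidden < 1:
            raise ValueError("need at least one hidden unit")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")
        if not (0 <= self.val_fraction < 1):
            raise ValueError("val_fraction must lie in [0, 1)")


@dataclass
class BpModel:
    W1: np.ndarray                 # (hidden, inputs)
    b1: np.ndarray                 # (hidden,)
    w2: np.ndarray                 # (hidden,)
    b2: float
    x_min: np.ndarray
    x_max: np.ndarray
    y_mean: float
    y_sd: float
    config: BpConfig
    history: list = field(default_factory=list)  # (epoch, training mse)


def n_params(n_inputs: int, n_hidden: int) -> int:
    return n_hidden * n_inputs + n_hidden + n_hidden + 1


def _unpack(theta: np.ndarray, d: int, h: int):
    W1 = theta[: h * d].reshape(h, d)
    b1 = theta[h * d: h * d + h]
    w2 = theta[h * d + h: h * d + 2 * h]
    b2 = theta[-1]
    return W1, b1, w2, b2


def _scale_x(X, x_min, x_max):
    rng = np.where(x_max > x_min, x_max - x_min, 1.0)
    return 2.0 * (X - x_min) / rng - 1.0


def _forward(theta, Xs, d, h):
    W1, b1, w2, b2 = _unpack(theta, d, h)
    Z = np.tanh(Xs @ W1.T + b1)
    return Z @ w2 + b2, Z


def _jacobian(theta, Xs, Z, d, h):
    _, _, w2, _ = _unpack(theta, d, h)
    S = (1.0 - Z ** 2) * w2            # (n, h): d yhat / d b1
    JW1 = np.einsum("nj,nk->njk", S, Xs).reshape(Xs.shape[0], h * d)
    ones = np.ones((Xs.shape[0], 1))
    return np.hstack([JW1, S, Z, ones])


def _lm_step(J, r, mu):
    n, p = J.shape
    if p <= n:
        A = J.T @ J + mu * np.eye(p)
        return -np.linalg.solve(A, J.T @ r)
    A = J @ J.T + mu * np.eye(n)       # push-through: work in sample space
    return -J.T @ np.linalg.solve(A, r)


def bp_train(X: np.ndarray, y: np.ndarray, config: BpConfig | None = None,
             theta0: np.ndarray | None = None) -> BpModel:
    """Fit the network; deterministic for a fixed config seed and data."""
    config = config or BpConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, d = X.shape
    h = config.n_hidden
    x_min, x_max = X.min(axis=0), X.max(axis=0)
    y_mean = float(y.mean())
    y_sd = float(y.std()) or 1.0
    Xs = _scale_x(X, x_min, x_max)
    ys = (y - y_mean) / y_sd

    p = n_params(d, h)
    if theta0 is None:
        theta = np.random.default_rng(config.seed).uniform(-0.5, 0.5, p)
    else:
        theta = np.asarray(theta0, dtype=float).copy()
        if theta.shape != (p,):
            raise ValueError(f"theta0 must have {p} entries for this architecture")

    # early-stopping split of the fitting data (toolbox-style dividerand)
    if config.val_fraction > 0 and n >= 10:
        perm = np.random.default_rng(config.seed + 1).permutation(n)
        n_val = max(1, int(round(n * config.val_fraction)))
        val_idx, fit_idx = perm[:n_val], perm[n_val:]
    else:
        val_idx, fit_idx = None, np.arange(n)
    Xf, yf = Xs[fit_idx], ys[fit_idx]

    yhat, Z = _forward(theta, Xf, d, h)
    mse = float(np.mean((yhat - ys[fit_idx]) ** 2))
    history = [(0, mse)]

    def val_mse(th):
        pred, _ = _forward(th, Xs[val_idx], d, h)
        return float(np.mean((pred - ys[val_idx]) ** 2))

    best_theta = theta.copy()
    best_val = val_mse(theta) if val_idx is not None else np.inf
    fails = 0
    mu = 1e-3
    for epoch in range(1, config.max_epochs + 1):
        if mse <= config.goal_mse:
            break
        r = yhat - yf
        J = _jacobian(theta, Xf, Z, d, h)
        accepted = False
        while mu <= 1e10:
            delta = _lm_step(J, r, mu)
            cand = theta + delta
            yhat_c, Z_c = _forward(cand, Xf, d, h)
            mse_c = float(np.mean((yhat_c - yf) ** 2))
            if not np.isfinite(mse_c):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            if mse_c < mse:
                theta, yhat, Z, mse = cand, yhat_c, Z_c, mse_c
                mu = max(mu / 10.0, 1e-12)
                accepted = True
                break
            mu *= 10.0
        history.append((epoch, mse))
        if val_idx is not None:
            v = val_mse(theta)
            if v < best_val:
                best_val, best_theta, fails = v, theta.copy(), 0
            else:
                fails += 1
                if fails >= config.max_fail:
                    break
        if not accepted:      # damping overflow: no descent direction
            break
    if val_idx is not None:
        theta = best_theta
    W1, b1, w2, b2 = _unpack(theta, d, h)
    return BpModel(W1.copy(), b1.copy(), w2.copy(), float(b2),
                   x_min, x_max, y_mean, y_sd, config, history)


def bp_predict(model: BpModel, X: np.ndarray) -> np.ndarray:
    """Predict targets in original units; a pure function of (model, X)."""
    Xs = _scale_x(np.atleast_2d(np.asarray(X, float)), model.x_min, model.x_max)
    Z = np.tanh(Xs @ model.W1.T + model.b1)
    return (Z @ model.w2 + model.b2) * model.y_sd + model.y_mean


def _first_argmax(scores: list[float]) -> int:
    """Index of the maximum; the earliest (smallest size) wins exact ties."""
    best, best_i = -np.inf, 0
    for i, s in enumerate(scores):
        if s > best:
            best, best_i = s, i
    return best_i


def bp_scan_hidden(X: np.ndarray, y: np.ndarray,
                   hidden_sizes=range(5, 11),
                   config: BpConfig | None = None,
                   seed: int | None = None) -> tuple[BpModel, dict[int, float]]:
    """Pick the hidden-layer size with the best held-out R2, then refit on all data.

    An inner 4:1 split of the provided data serves as the validation set.
    Returns the refitted model and the per-size validation scores.
    """
    config = config or BpConfig()
    seed = config.seed if seed is None else seed
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = max(1, int(np.floor(n / 5 + 0.5)))
    val, tr = perm[:n_val], perm[n_val:]

    sizes = list(hidden_sizes)
    scores = []
    for h in sizes:
        m = bp_train(X[tr], y[tr], replace(config, n_hidden=h))
        pred = bp_predict(m, X[val])
        if np.ptp(y[val]) == 0:
            scores.append(-float(np.mean((y[val] - pred) ** 2)))
        else:
            scores.append(r2_score(y[val], pred))
    best_h = sizes[_first_argmax(scores)]
    model = bp_train(X, y, replace(config, n_hidden=best_h))
    return model, dict(zip(sizes, scores))
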