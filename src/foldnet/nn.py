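"""From-scratch 4-32-1 sigmoid feedforward network predicting MMSE.

Architecture: y = b + c . sigmoid(k + W x) — a linear output on top of a
32-unit sigmoid hidden layer over the four panel log-expression values.
Parameters are trained by per-sample stochastic gradient descent on the
squared error, in a seeded shuffled order each epoch, so identical seed and
data give bitwise-identical parameters.  Inputs are normalized per feature
(min-max to [0, 1] by default, fit on the training samples only); the output
layer stays linear.

Evaluation reports Pearson r (with two-sided p) and Spearman r between the
predicted and true MMSE; predictions are clipped to the valid MMSE range
[0, 30] for reporting, with the unclipped values retained.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "NNParams",
    "TrainConfig",
    "Normalizer",
    "RegressionEval",
    "FitResult",
    "init_params",
    "nn_forward",
    "nn_gradients",
    "nn_train",
    "nn_evaluate",
    "split_train_test",
]


@dataclass
class NNParams:
    """Weights of the 4-32-1 network: W (32x4), hidden biases k (32),
    output weights c (32) and output bias b."""

    W: np.ndarray
    k: np.ndarray
    c: np.ndarray
    b: float

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.k = np.asarray(self.k, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        h, d = self.W.shape
        if self.k.shape != (h,) or self.c.shape != (h,):
            raise ValueError("parameter shapes inconsistent with W")
        if not (
            np.all(np.isfinite(self.W))
            and np.all(np.isfinite(self.k))
            and np.all(np.isfinite(self.c))
            and np.isfinite(self.b)
        ):
            raise ValueError("non-finite network parameters")


@dataclass
class TrainConfig:
    learning_rate: float = 0.01
    epochs: int = 2000
    seed: int = 0
    hidden: int = 32
    normalization: str = "minmax"  # or "zscore"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.epochs < 1:
            raise ValueError("learning_rate must be > 0 and epochs >= 1")
        if self.normalization not in ("minmax", "zscore"):
            raise ValueError("normalization must be 'minmax' or 'zscore'")


@dataclass
class Normalizer:
    """Per-feature normalization with statistics fit on training data only."""

    kind: str
    a: np.ndarray  # min (minmax) or mean (zscore)
    b: np.ndarray  # range or sd; zero-spread features map to 0

    @classmethod
    def fit(cls, X: np.ndarray, kind: str = "minmax") -> "Normalizer":
        X = np.asarray(X, dtype=float)
        if kind == "minmax":
            a = X.min(axis=0)
            b = X.max(axis=0) - a
        else:
            a = X.mean(axis=0)
            b = X.std(axis=0, ddof=0)
        return cls(kind=kind, a=a, b=np.where(b == 0, 1.0, b))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.a) / self.b


def _sigmoid(v: np.ndarray) -> np.ndarray:
    out = np.empty_like(v)
    pos = v >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-v[pos]))
    ev = np.exp(v[~pos])
    out[~pos] = ev / (1.0 + ev)
    return out


def init_params(n_in: int = 4, hidden: int = 32, seed: int = 0) -> NNParams:
    """Seeded uniform(-r, r) weights with r = sqrt(6 / (fan_in + fan_out));
    biases start at zero."""
    rng = np.random.default_rng(seed)
    rw = np.sqrt(6.0 / (n_in + hidden))
    rc = np.sqrt(6.0 / (hidden + 1))
    return NNParams(
        W=rng.uniform(-rw, rw, size=(hidden, n_in)),
        k=np.zeros(hidden),
        c=rng.uniform(-rc, rc, size=hidden),
        b=0.0,
    )


def nn_forward(params: NNParams, x: np.ndarray) -> float | np.ndarray:
    """y = b + c . sigmoid(k + W x); accepts a single 4-vector or an (n, 4)
    batch of normalized inputs."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.shape[1] != params.W.shape[1]:
        raise ValueError(f"input dimension {X.shape[1]} != {params.W.shape[1]}")
    A = _sigmoid(X @ params.W.T + params.k)
    y = params.b + A @ params.c
    return float(y[0]) if single else y


def nn_gradients(
    params: NNParams, x: np.ndarray, target: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Analytic gradient of the per-sample squared error (y - t)^2 with
    respect to (W, k, c, b)."""
    x = np.asarray(x, dtype=float)
    v = params.k + params.W @ x
    a = _sigmoid(v)
    y = params.b + params.c @ a
    dy = 2.0 * (y - target)
    dc = dy * a
    db = dy
    dv = dy * params.c * a * (1.0 - a)
    dW = np.outer(dv, x)
    dk = dv
    return dW, dk, dc, float(db)


@dataclass
class FitResult:
    params: NNParams
    normalizer: Normalizer
    loss_trace: np.ndarray  # mean squared error after each epoch
    config: TrainConfig


def nn_train(X: np.ndarray, y: np.ndarray, config: TrainConfig | None = None) -> FitResult:
    """Per-sample SGD on squared error over seeded shuffled epochs."""
    config = config or TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y) or len(X) < 2:
        raise ValueError("need >= 2 (input, target) training pairs")
    norm = Normalizer.fit(X, config.normalization)
    Xn = norm.transform(X)
    params = init_params(X.shape[1], config.hidden, config.seed)
    rng = np.random.default_rng(config.seed + 1)
    lr = config.learning_rate
    trace = np.empty(config.epochs)
    for epoch in range(config.epochs):
        for i in rng.permutation(len(Xn)):
            dW, dk, dc, db = nn_gradients(params, Xn[i], y[i])
            params.W -= lr * dW
            params.k -= lr * dk
            params.c -= lr * dc
            params.b -= lr * db
        pred = nn_forward(params, Xn)
        mse = float(np.mean((pred - y) ** 2))
        trace[epoch] = mse
        if not np.isfinite(mse):
            raise FloatingPointError(
                f"training diverged at epoch {epoch}; try a smaller learning rate"
            )
    logger.info("trained %d epochs, final MSE %.4g", config.epochs, trace[-1])
    return FitResult(params=params, normalizer=norm, loss_trace=trace, config=config)


@dataclass
class RegressionEval:
    predicted: np.ndarray  # unclipped network outputs
    predicted_clipped: np.ndarray  # clipped to [0, 30] for reporting
    true: np.ndarray
    pearson_r: float
    pearson_p: float
    spearman_r: float
    mse: float


def nn_evaluate(fit: FitResult, X: np.ndarray, y: np.ndarray) -> RegressionEval:
    """Predict on held-out pairs and correlate with the true MMSE."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < 3:
        raise ValueError("need >= 3 test pairs")
    pred = np.asarray(nn_forward(fit.params, fit.normalizer.transform(X)), dtype=float)
    if np.ptp(pred) == 0 or np.ptp(y) == 0:
        warnings.warn("degenerate (constant) predictions or targets; correlation set to 0")
        r, p, rho = 0.0, 1.0, 0.0
    else:
        r, p = stats.pearsonr(pred, y)
        rho = stats.spearmanr(pred, y).statistic
    return RegressionEval(
        predicted=pred,
        predicted_clipped=np.clip(pred, 0.0, 30.0),
        true=y,
        pearson_r=float(r),
        pearson_p=float(p),
        spearman_r=float(rho),
        mse=float(np.mean((pred - y) ** 2)),
    )


def split_train_test(
    n: int, test_size: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded shuffle; the last ``test_size`` shuffled indices are held out."""
    if not (0 < test_size < n):
        raise ValueError("test_size must be in (0, n)")
    order = np.random.default_rng(seed).permutation(n)
    return np.sort(order[:-test_size]), np.sort(order[-test_size:])
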