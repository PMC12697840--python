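"""Single-hidden-layer feed-forward network trained by full-batch Adam.

The network is y_hat = W2 sigma(W1 z + b1) + b2, a scalar-output MLP on
PC scores, minimising mean squared error.  Calibration sets in this
problem are tens of samples, so gradients are full batch and everything is
plain numpy: training a few thousand epochs on a 100 x 26 score matrix is
a fraction of a second and bit-reproducible for a fixed seed.

Weights are initialised from a symmetric uniform distribution with
Glorot-style fan scaling, U(-a, a) with a = sqrt(6 / (fan_in + fan_out)).
Adam runs with learning rate 1e-3, beta1 = 0.9, beta2 = 0.999,
epsilon = 1e-8 unless overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ANNConfig", "MLPParams", "train_mlp", "mlp_forward", "ACTIVATIONS"]


def _tanh(x):
    return np.tanh(x)


def _tanh_grad(x, a):
    return 1.0 - a**2


def _relu(x):
    return np.maximum(x, 0.0)


def _relu_grad(x, a):
    return (x > 0).astype(float)


def _leaky_relu(x, slope=0.01):
    return np.where(x > 0, x, slope * x)


def _leaky_relu_grad(x, a, slope=0.01):
    return np.where(x > 0, 1.0, slope)


def _swish(x):
    s = 1.0 / (1.0 + np.exp(-x))
    return x * s


def _swish_grad(x, a):
    s = 1.0 / (1.0 + np.exp(-x))
    return s + x * s * (1.0 - s)


#: activation name -> (function, derivative wrt pre-activation)
ACTIVATIONS = {
    "tanh": (_tanh, _tanh_grad),
    "relu": (_relu, _relu_grad),
    "leaky_relu": (_leaky_relu, _leaky_relu_grad),
    "swish": (_swish, _swish_grad),
}


@dataclass
class ANNConfig:
    """Hyperparameters of one network (hidden width, activation, epochs)."""

    n_neurons: int = 10
    activation: str = "tanh"
    epochs: int = 3000
    learning_rate: float = 1e-3
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self):
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.activation not in ACTIVATIONS:
            raise ValueError(
                f"unknown activation {self.activation!r}; "
                f"choose from {sorted(ACTIVATIONS)}"
            )


@dataclass
class MLPParams:
    """Weights and biases of the fitted network."""

    W1: np.ndarray  # (k, h)
    b1: np.ndarray  # (h,)
    W2: np.ndarray  # (h,)
    b2: float
    activation: str
    loss_trace: np.ndarray = field(default=None)


def _init_params(k: int, h: int, seed: int, activation: str) -> MLPParams:
    rng = np.random.default_rng(seed)
    a1 = np.sqrt(6.0 / (k + h))
    a2 = np.sqrt(6.0 / (h + 1))
    return MLPParams(
        W1=rng.uniform(-a1, a1, size=(k, h)),
        b1=np.zeros(h),
        W2=rng.uniform(-a2, a2, size=h),
        b2=0.0,
        activation=activation,
    )


def mlp_forward(params: MLPParams, Z: np.ndarray) -> np.ndarray:
    """Network output for each row of Z (scaled-target units)."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[1] != params.W1.shape[0]:
        raise ValueError(
            f"scores have {Z.shape[1]} columns, network expects {params.W1.shape[0]}"
        )
    act, _ = ACTIVATIONS[params.activation]
    H = act(Z @ params.W1 + params.b1)
    return H @ params.W2 + params.b2


def train_mlp(Z: np.ndarray, y: np.ndarray, cfg: ANNConfig) -> MLPParams:
    """Fit the network to (Z, y) by full-batch Adam on the MSE loss."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, k = Z.shape
    if y.size != n:
        raise ValueError("row count of Z must match y")
    p = _init_params(k, cfg.n_neurons, cfg.seed, cfg.activation)
    act, act_grad = ACTIVATIONS[cfg.activation]

    theta = [p.W1, p.b1, p.W2, np.array(p.b2, dtype=float)]
    m = [np.zeros_like(t) for t in theta]
    v = [np.zeros_like(t) for t in theta]
    lr, b1c, b2c, eps = cfg.learning_rate, cfg.beta1, cfg.beta2, cfg.eps
    trace = np.empty(cfg.epochs)

    for t in range(1, cfg.epochs + 1):
        pre = Z @ theta[0] + theta[1]
        H = act(pre)
        yhat = H @ theta[2] + theta[3]
        err = yhat - y
        loss = float(np.mean(err**2))
        if not np.isfinite(loss):
            raise FloatingPointError(f"loss became non-finite at epoch {t}")
        trace[t - 1] = loss

        g_out = 2.0 * err / n  # dLoss/dyhat
        gW2 = H.T @ g_out
        gb2 = np.array(np.sum(g_out))
        gH = np.outer(g_out, theta[2]) * act_grad(pre, H)
        gW1 = Z.T @ gH
        gb1 = gH.sum(axis=0)
        grads = [gW1, gb1, gW2, gb2]

        for i in range(4):
            m[i] = b1c * m[i] + (1 - b1c) * grads[i]
            v[i] = b2c * v[i] + (1 - b2c) * grads[i] ** 2
            mhat = m[i] / (1 - b1c**t)
            vhat = v[i] / (1 - b2c**t)
            theta[i] = theta[i] - lr * mhat / (np.sqrt(vhat) + eps)

    return MLPParams(
        W1=theta[0], b1=theta[1], W2=theta[2], b2=float(theta[3]),
        activation=cfg.activation, loss_trace=trace,
    )
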