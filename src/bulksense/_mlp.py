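"""Minimal single-hidden-layer perceptron classifier.

Supports the five hidden activations the benchmark protocol explores —
linear, exponential, logistic, sine, tanh — including the two
(exponential, sine) that mainstream libraries do not ship.  The output
unit is logistic, the loss is mean binary cross-entropy with a small L2
penalty for stability, and the weights are optimized with L-BFGS using
analytic gradients.  Inputs are standardized internally.  The
exponential activation clips its argument to [-30, 30] so e^x cannot
overflow; within that band the derivative equals the activation itself.
"""
from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

_EXP_CLIP = 30.0

_ACTS = {
    "linear": (lambda z: z, lambda z, a: np.ones_like(z)),
    "exponential": (
        lambda z: np.exp(np.clip(z, -_EXP_CLIP, _EXP_CLIP)),
        lambda z, a: np.where(np.abs(z) < _EXP_CLIP, a, 0.0),
    ),
    "logistic": (
        lambda z: 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500))),
        lambda z, a: a * (1.0 - a),
    ),
    "sine": (np.sin, lambda z, a: np.cos(z)),
    "tanh": (np.tanh, lambda z, a: 1.0 - a**2),
}


class SmallMLP:
    """One-hidden-layer binary classifier with a configurable activation."""

    def __init__(
        self,
        hidden: int,
        activation: str = "tanh",
        alpha: float = 1e-4,
        max_iter: int = 300,
        random_state: int = 0,
    ) -> None:
        if activation not in _ACTS:
            raise ValueError(f"unknown activation {activation!r}; choose from {sorted(_ACTS)}")
        if hidden < 1:
            raise ValueError("hidden must be >= 1")
        self.hidden = hidden
        self.activation = activation
        self.alpha = alpha
        self.max_iter = max_iter
        self.random_state = random_state
        self.converged_: bool | None = None

    # parameter vector layout: W1 (d*h), b1 (h), W2 (h), b2 (1)
    def _unpack(self, theta: np.ndarray, d: int):
        h = self.hidden
        i = 0
        W1 = theta[i : i + d * h].reshape(d, h); i += d * h
        b1 = theta[i : i + h]; i += h
        W2 = theta[i : i + h]; i += h
        b2 = theta[i]
        return W1, b1, W2, b2

    def _loss_grad(self, theta: np.ndarray, X: np.ndarray, y: np.ndarray):
        n, d = X.shape
        act, dact = _ACTS[self.activation]
        W1, b1, W2, b2 = self._unpack(theta, d)
        Z = X @ W1 + b1
        A = act(Z)
        logit = A @ W2 + b2
        p = 1.0 / (1.0 + np.exp(-np.clip(logit, -500, 500)))
        eps = 1e-12
        loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
        loss += 0.5 * self.alpha * (np.sum(W1**2) + np.sum(W2**2))

        dlogit = (p - y) / n
        gW2 = A.T @ dlogit + self.alpha * W2
        gb2 = dlogit.sum()
        dA = np.outer(dlogit, W2)
        dZ = dA * dact(Z, A)
        gW1 = X.T @ dZ + self.alpha * W1
        gb1 = dZ.sum(axis=0)
        grad = np.concatenate([gW1.ravel(), gb1, gW2, [gb2]])
        return loss, grad

    def fit(self, X, y) -> "SmallMLP":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self._mu = X.mean(axis=0)
        self._sd = X.std(axis=0)
        self._sd[self._sd == 0] = 1.0
        Xs = (X - self._mu) / self._sd

        d = Xs.shape[1]
        h = self.hidden
        rng = np.random.default_rng(self.random_state)
        theta0 = rng.normal(scale=0.5, size=d * h + h + h + 1)
        res = minimize(
            self._loss_grad,
            theta0,
            args=(Xs, y),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.max_iter},
        )
        self._theta = res.x
        self.converged_ = bool(res.success)
        self.loss_ = float(res.fun)
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Xs = (X - self._mu) / self._sd
        act, _ = _ACTS[self.activation]
        W1, b1, W2, b2 = self._unpack(self._theta, Xs.shape[1])
        logit = act(Xs @ W1 + b1) @ W2 + b2
        return 1.0 / (1.0 + np.exp(-np.clip(logit, -500, 500)))

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)
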