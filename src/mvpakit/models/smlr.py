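"""Sparse multinomial logistic regression (SMLR) via proximal gradient descent.

Minimizes the L1-penalized softmax objective

    f(W) = (1/n) * sum_i -log softmax(x_i W)[y_i]  +  lambda * sum_jk |W_jk|

over an augmented weight matrix W of shape (d + 1, K) whose first row is the
(unpenalized) bias.  The optimizer is ISTA with backtracking line search;
soft-thresholding drives many weights exactly to zero, which is the point of
the "sparse" in SMLR: surviving weights identify the informative features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SMLRResult", "smlr_fit", "smlr_objective", "softmax_scores"]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _augment(X: np.ndarray) -> np.ndarray:
    return np.hstack([np.ones((X.shape[0], 1)), X])


def smlr_objective(W: np.ndarray, X: np.ndarray, y: np.ndarray, lam: float) -> float:
    """Penalized objective at W (shape (d+1, K), bias row first, unpenalized)."""
    Xb = _augment(np.asarray(X, dtype=float))
    logits = Xb @ W
    logits = logits - logits.max(axis=1, keepdims=True)
    log_norm = np.log(np.exp(logits).sum(axis=1))
    nll = float(np.mean(log_norm - logits[np.arange(len(y)), y]))
    return nll + lam * float(np.abs(W[1:]).sum())


@dataclass
class SMLRResult:
    W: np.ndarray  # (d + 1, K), row 0 = bias
    objective: float
    n_iter: int
    converged: bool


def smlr_fit(
    X: np.ndarray,
    y: np.ndarray,
    lam: float = 0.1,
    max_iter: int = 2000,
    tol: float = 1e-9,
) -> SMLRResult:
    """Fit SMLR weights by ISTA with backtracking.

    Convergence is declared when the objective decrease over one accepted
    step falls below ``tol``.  Non-convergence at ``max_iter`` sets
    ``converged=False`` on the result rather than raising.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    K = int(y.max()) + 1
    Xb = _augment(X)
    d1 = Xb.shape[1]
    W = np.zeros((d1, K))
    onehot = np.zeros((n, K))
    onehot[np.arange(n), y] = 1.0

    def smooth(Wm):
        logits = Xb @ Wm
        shifted = logits - logits.max(axis=1, keepdims=True)
        log_norm = np.log(np.exp(shifted).sum(axis=1))
        return float(np.mean(log_norm - shifted[np.arange(n), y]))

    def grad(Wm):
        p = _softmax(Xb @ Wm)
        return Xb.T @ (p - onehot) / n

    def prox(Wm, t):
        out = np.sign(Wm) * np.maximum(np.abs(Wm) - t * lam, 0.0)
        out[0] = Wm[0]  # bias row unpenalized
        return out

    f = smooth(W)
    obj = f + lam * float(np.abs(W[1:]).sum())
    step = 1.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        g = grad(W)
        # backtracking on the quadratic majorization of the smooth part
        while True:
            W_new = prox(W - step * g, step)
            delta = W_new - W
            f_new = smooth(W_new)
            bound = f + float(np.sum(g * delta)) + float(np.sum(delta * delta)) / (2 * step)
            if f_new <= bound + 1e-12:
                break
            step *= 0.5
            if step < 1e-12:
                W_new, f_new = W, f
                break
        obj_new = f_new + lam * float(np.abs(W_new[1:]).sum())
        decrease = obj - obj_new
        W, f, obj = W_new, f_new, obj_new
        if 0 <= decrease < tol:
            converged = True
            break
        step = min(step * 2.0, 1e6)  # allow step to grow back
    return SMLRResult(W=W, objective=obj, n_iter=it, converged=converged)


def softmax_scores(W: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Per-class softmax probabilities under fitted SMLR weights."""
    return _softmax(_augment(np.asarray(X, dtype=float)) @ W)
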