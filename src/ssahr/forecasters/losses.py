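"""Training losses: supervised MSE is computed inline by the trainer; this
module holds the physics (Taylor-consistency) penalty and the composite
weighting used by the physics-informed family."""

from __future__ import annotations

import numpy as np


def physics_loss(predictions: np.ndarray, context: np.ndarray, dt: float = 1.0) -> float:
    """Smoothness residual penalising implausible HR acceleration.

    Forms the sequence ``[x_{T-1}, x_T, p_1, ..., p_h]`` from the last two
    observed context values and the ``h`` forecast steps, and returns the
    mean squared second-order finite difference ``(s_{j+1} - 2 s_j +
    s_{j-1}) / dt^2`` over the ``h`` differences that involve at least one
    forecast value (junction + interior).

    Accepts a single forecast ``(h,)`` with context ``(w,)``, or a batch
    ``(B, h)`` with context ``(B, w)``.
    """
    p = np.atleast_2d(np.asarray(predictions, dtype=float))
    c = np.atleast_2d(np.asarray(context, dtype=float))
    if c.shape[1] < 2:
        raise ValueError("context must provide at least the last two observed values")
    s = np.concatenate([c[:, -2:], p], axis=1)
    d2 = (s[:, 2:] - 2.0 * s[:, 1:-1] + s[:, :-2]) / dt**2
    return float(np.mean(d2**2))


def physics_loss_grad(
    predictions: np.ndarray, context: np.ndarray, dt: float = 1.0
) -> np.ndarray:
    """Gradient of :func:`physics_loss` w.r.t. the (batched) predictions."""
    p = np.atleast_2d(np.asarray(predictions, dtype=float))
    c = np.atleast_2d(np.asarray(context, dtype=float))
    s = np.concatenate([c[:, -2:], p], axis=1)
    d2 = (s[:, 2:] - 2.0 * s[:, 1:-1] + s[:, :-2]) / dt**2
    scale = 2.0 / (d2.size * dt**2)
    ds = np.zeros_like(s)
    ds[:, 2:] += scale * d2
    ds[:, 1:-1] -= 2.0 * scale * d2
    ds[:, :-2] += scale * d2
    grad = ds[:, 2:]
    if np.asarray(predictions).ndim == 1:
        return grad[0]
    return grad


def composite_loss(lc: float, lp: float, alpha: float, beta: float) -> float:
    """Weighted total loss ``alpha * Lc + beta * Lp``."""
    if alpha < 0 or beta < 0:
        raise ValueError("loss weights must be nonnegative")
    return alpha * lc + beta * lp
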