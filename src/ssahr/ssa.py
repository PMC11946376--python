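"""Singular Spectrum Analysis: embedding, SVD decomposition, grouping,
diagonal-averaging reconstruction, and linear-recurrence forecasting.

The pipeline follows the classical four stages:

1. *Embedding* — a length-``L`` sliding window turns the series into an
   ``L x K`` Hankel trajectory matrix (``K = N - L + 1``).
2. *Decomposition* — SVD of the trajectory matrix into eigentriples
   ``(sigma_i, u_i, v_i)``.
3. *Grouping* — partition of the retained eigentriples into a deterministic
   set (trend + periodic structure) and a residual set.
4. *Reconstruction* — diagonal (anti-diagonal) averaging of the grouped
   rank-one matrices back to a series.

Extrapolation of the deterministic part uses recurrent (LRR) forecasting:
the deterministic subspace yields coefficients ``a_1..a_{L-1}`` such that
``x_t = sum_j a_j x_{t-j}`` for any series lying in that subspace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TrajectoryMatrix",
    "SSADecomposition",
    "LinearRecurrence",
    "embed",
    "hankelize",
    "decompose",
    "group",
    "reconstruct",
    "fit_recurrence",
    "forecast_recurrence",
    "ssa_forecast",
]

#: Relative singular-value threshold below which eigentriples are dropped.
RANK_TOL = 1e-12

#: Verticality tolerance: nu^2 must stay below ``1 - VERTICALITY_TOL``.
VERTICALITY_TOL = 1e-10


@dataclass(frozen=True)
class TrajectoryMatrix:
    """Hankel trajectory matrix of a series (entry ``(i, j) = s[i + j]``)."""

    values: np.ndarray  # (L, K)
    L: int
    K: int
    source_n: int

    def __post_init__(self) -> None:
        if self.values.shape != (self.L, self.K):
            raise ValueError("trajectory matrix shape mismatch")
        if self.K != self.source_n - self.L + 1:
            raise ValueError("K must equal N - L + 1")


@dataclass
class SSADecomposition:
    """Eigentriples of a trajectory matrix plus a deterministic/residual split.

    Eigentriple indices are 0-based internally; exported summaries report
    them 1-based following SSA convention.
    """

    singular_values: np.ndarray      # (d,) nonincreasing, nonnegative
    left_vectors: np.ndarray         # (L, d)
    right_vectors: np.ndarray        # (K, d)
    window: int
    source_n: int
    deterministic_set: tuple[int, ...] = ()
    residual_set: tuple[int, ...] = ()

    @property
    def d(self) -> int:
        return int(self.singular_values.size)

    @property
    def energy_fractions(self) -> np.ndarray:
        """Normalised sigma^2 contributions of each eigentriple."""
        e = self.singular_values**2
        return e / e.sum()

    def summary(self) -> dict:
        """JSON-ready decomposition summary (1-based eigentriple indices)."""
        return {
            "window": self.window,
            "n": self.source_n,
            "singular_values": [float(s) for s in self.singular_values],
            "energy_fractions": [float(f) for f in self.energy_fractions],
            "deterministic_set": [i + 1 for i in self.deterministic_set],
            "residual_set": [i + 1 for i in self.residual_set],
        }


@dataclass(frozen=True)
class LinearRecurrence:
    """Coefficients ``a_1..a_{L-1}`` of ``x_t = sum_j a_j x_{t-j}``.

    ``coefficients[j]`` multiplies the value ``j + 1`` steps back.
    ``verticality`` is ``nu^2``, the squared norm of the last coordinates of
    the deterministic left singular vectors; forecasting requires
    ``nu^2 < 1``.
    """

    coefficients: np.ndarray  # (L - 1,), lag order 1..L-1
    verticality: float


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def embed(series: np.ndarray, L: int) -> TrajectoryMatrix:
    """Build the Hankel trajectory matrix with window length ``L``.

    Requires ``2 <= L <= N - 1``.
    """
    s = np.asarray(series, dtype=float).ravel()
    n = s.size
    if not 2 <= L <= n - 1:
        raise ValueError(f"window L={L} outside admissible range [2, {n - 1}]")
    K = n - L + 1
    X = np.lib.stride_tricks.sliding_window_view(s, K)[:L].copy()
    return TrajectoryMatrix(values=X, L=L, K=K, source_n=n)


def hankelize(M: np.ndarray, n: int) -> np.ndarray:
    """Diagonal averaging: project an ``L x K`` matrix to a length-``n`` series.

    Averages the anti-diagonals ``i + j = t``; for a Hankel matrix this is
    the exact inverse of :func:`embed`.
    """
    L, K = M.shape
    if L + K - 1 != n:
        raise ValueError("matrix shape incompatible with series length")
    sums = np.zeros(n)
    counts = np.zeros(n)
    for i in range(L):
        sums[i : i + K] += M[i]
        counts[i : i + K] += 1.0
    return sums / counts


def decompose(X: TrajectoryMatrix) -> SSADecomposition:
    """SVD of the trajectory matrix, dropping near-null directions.

    Eigentriples with ``sigma / sigma_1 < 1e-12`` are discarded.  The
    grouping starts empty; apply :func:`group` before forecasting.
    """
    U, s, Vt = np.linalg.svd(X.values, full_matrices=False)
    if s.size == 0 or s[0] == 0.0:
        keep = np.array([0]) if s.size else np.array([], dtype=int)
    else:
        keep = np.flatnonzero(s / s[0] >= RANK_TOL)
    return SSADecomposition(
        singular_values=s[keep],
        left_vectors=U[:, keep],
        right_vectors=Vt[keep].T,
        window=X.L,
        source_n=X.source_n,
    )


def group(
    dec: SSADecomposition, criterion: str = "energy_fraction", param: float | int = 0.9
) -> SSADecomposition:
    """Partition eigentriples into deterministic and residual sets.

    ``energy_fraction``: deterministic set is the smallest prefix
    ``{1..r}`` whose cumulative sigma^2 energy reaches ``param``.
    ``leading_r``: deterministic set is the first ``param`` eigentriples.
    """
    d = dec.d
    if d < 1:
        raise ValueError("decomposition has no eigentriples")
    if criterion == "energy_fraction":
        frac = float(param)
        if not 0.0 < frac <= 1.0:
            raise ValueError(f"energy fraction must be in (0, 1], got {frac}")
        cum = np.cumsum(dec.energy_fractions)
        r = int(np.searchsorted(cum, frac - 1e-15)) + 1
        r = min(r, d)
    elif criterion == "leading_r":
        r = int(param)
        if not 1 <= r <= d:
            raise ValueError(f"leading_r must be in [1, {d}], got {r}")
    else:
        raise ValueError(f"unknown grouping criterion {criterion!r}")
    return replace_grouping(dec, tuple(range(r)), tuple(range(r, d)))


def replace_grouping(
    dec: SSADecomposition, det: tuple[int, ...], res: tuple[int, ...]
) -> SSADecomposition:
    out = SSADecomposition(
        singular_values=dec.singular_values,
        left_vectors=dec.left_vectors,
        right_vectors=dec.right_vectors,
        window=dec.window,
        source_n=dec.source_n,
        deterministic_set=det,
        residual_set=res,
    )
    return out


def reconstruct(dec: SSADecomposition, subset) -> np.ndarray:
    """Series reconstructed from the eigentriples in ``subset`` (0-based).

    An empty subset yields a zero series of the source length (documented
    degenerate case, not an error).
    """
    subset = tuple(subset)
    if not set(subset) <= set(range(dec.d)):
        raise ValueError("subset contains unknown eigentriple indices")
    if not subset:
        return np.zeros(dec.source_n)
    idx = list(subset)
    M = (dec.left_vectors[:, idx] * dec.singular_values[idx]) @ dec.right_vectors[:, idx].T
    return hankelize(M, dec.source_n)


# ---------------------------------------------------------------------------
# Forecasting
# ---------------------------------------------------------------------------

def fit_recurrence(dec: SSADecomposition) -> LinearRecurrence:
    """Linear-recurrence coefficients from the deterministic left vectors.

    With ``pi_i`` the last coordinate of deterministic vector ``U_i`` and
    ``U_i^nabla`` its first ``L - 1`` coordinates,

    ``a = (1 / (1 - nu^2)) * sum_i pi_i U_i^nabla``,  ``nu^2 = sum_i pi_i^2``.

    ``a`` is returned in lag order (``a_1`` = one step back).
    """
    if not dec.deterministic_set:
        raise ValueError("deterministic set is empty; call group() first")
    U = dec.left_vectors[:, list(dec.deterministic_set)]
    pi = U[-1, :]
    nu2 = float(pi @ pi)
    if nu2 >= 1.0 - VERTICALITY_TOL:
        raise ValueError(f"non-forecastable grouping: verticality nu^2={nu2:.6g}")
    head = U[:-1, :]  # chronological coordinates 0..L-2
    r_chrono = head @ pi / (1.0 - nu2)  # weight for value at lag L-1-j
    coeffs = r_chrono[::-1].copy()      # reindex to lag order 1..L-1
    if not np.all(np.isfinite(coeffs)):
        raise ValueError("non-finite recurrence coefficients")
    return LinearRecurrence(coefficients=coeffs, verticality=nu2)


def forecast_recurrence(
    lrr: LinearRecurrence, history: np.ndarray, horizon: int
) -> np.ndarray:
    """Iterate the recurrence ``horizon`` steps beyond ``history``.

    ``history`` must supply at least ``L - 1`` values in chronological order.
    """
    p = lrr.coefficients.size
    hist = np.asarray(history, dtype=float).ravel()
    if hist.size < p:
        raise ValueError(f"history must contain at least {p} values")
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    buf = hist[-p:].copy()
    out = np.empty(horizon)
    for t in range(horizon):
        nxt = float(lrr.coefficients @ buf[::-1])
        out[t] = nxt
        buf = np.roll(buf, -1)
        buf[-1] = nxt
    return out


def default_window(n: int) -> int:
    """Default SSA window: ``min(N // 2, 60)`` (~1 minute at 1 Hz)."""
    return max(2, min(n // 2, 60))


def ssa_forecast(
    series: np.ndarray,
    L: int | None = None,
    horizon: int = 10,
    criterion: str = "energy_fraction",
    param: float | int = 0.9,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, SSADecomposition, LinearRecurrence]:
    """Full SSA fit + deterministic extrapolation.

    Returns ``(deterministic_fit, deterministic_forecast, residual_series,
    decomposition, recurrence)`` where ``deterministic_fit + residual_series``
    equals ``series`` exactly and the forecast iterates the fitted
    recurrence ``horizon`` steps from the end of the deterministic fit.
    """
    s = np.asarray(series, dtype=float).ravel()
    if L is None:
        L = default_window(s.size)
    dec = group(decompose(embed(s, L)), criterion, param)
    det_fit = reconstruct(dec, dec.deterministic_set)
    residual = s - det_fit
    lrr = fit_recurrence(dec)
    det_forecast = forecast_recurrence(lrr, det_fit, horizon)
    return det_fit, det_forecast, residual, dec, lrr
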