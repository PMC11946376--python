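"""Hybrid forecasting: SSA deterministic extrapolation + neural residual.

The target HR channel is decomposed by SSA on the training segment; the
deterministic part is extrapolated with the fitted linear recurrence, while
a neural forecaster learns the residual (with optional auxiliary BR/RR
predictors).  The final forecast is the elementwise sum of both parts on
the original bpm scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import ssa
from .forecasters import ForecasterSpec, make_windows, train
from .forecasters.nets import build_core
from .signal_io import CHANNELS, PhysioSeries

DEFAULT_CLAMP = (25.0, 230.0)


@dataclass(frozen=True)
class HybridSpec:
    """Configuration of one hybrid (SSA + residual learner) forecaster."""

    residual_spec: ForecasterSpec = field(default_factory=ForecasterSpec)
    ssa_window: int | None = None          # None -> min(N // 2, 60)
    grouping_criterion: str = "energy_fraction"
    grouping_param: float | int = 0.9
    predictors: tuple[str, ...] = ("HR",)
    lookback: int = 30
    horizon: int = 10
    clamp: tuple[float, float] | None = DEFAULT_CLAMP


@dataclass
class ForecastResult:
    """Per-horizon forecast with the SSA and residual parts kept separable.

    ``combined[i] == deterministic_part[i] + residual_part[i]`` exactly;
    when output clamping is active the residual part absorbs the clip so
    the identity still holds bit-exactly.
    """

    deterministic_part: np.ndarray
    residual_part: np.ndarray
    combined: np.ndarray
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "deterministic_part": [float(v) for v in self.deterministic_part],
            "residual_part": [float(v) for v in self.residual_part],
            "combined": [float(v) for v in self.combined],
            "provenance": self.provenance,
        }


@dataclass
class FittedHybrid:
    spec: HybridSpec
    decomposition: ssa.SSADecomposition
    recurrence: ssa.LinearRecurrence
    deterministic_fit: np.ndarray          # over the training segment
    residual_model: object                 # TrainedForecaster
    channel_stats: dict[str, tuple[float, float]]  # per-predictor (mean, std)
    train_matrix_tail: np.ndarray          # last lookback rows, normalised


def _stats(x: np.ndarray) -> tuple[float, float]:
    sd = float(np.std(x))
    return float(np.mean(x)), sd if sd > 0 else 1.0


def _predictor_order(predictors) -> tuple[str, ...]:
    return tuple(c for c in CHANNELS if c in set(predictors))


def _normalised_matrix(
    channels: dict[str, np.ndarray],
    order: tuple[str, ...],
    stats: dict[str, tuple[float, float]],
) -> np.ndarray:
    cols = [(channels[c] - stats[c][0]) / stats[c][1] for c in order]
    return np.stack(cols, axis=1)


def hybrid_fit(spec: HybridSpec, train_series: PhysioSeries) -> FittedHybrid:
    """Fit SSA on the training HR channel and a residual forecaster on
    ``HR - deterministic_fit`` (auxiliary predictors enter normalised only).
    """
    order = _predictor_order(spec.predictors)
    if "HR" not in order:
        raise ValueError("predictors must include HR")
    hr = train_series.channels["HR"]
    n = hr.size
    L = spec.ssa_window or ssa.default_window(n)
    if n < max(L + 1, spec.lookback + 1 + 1):
        raise ValueError("training segment too short for SSA and windowing")

    det_fit, _, residual, dec, lrr = ssa.ssa_forecast(
        hr, L=L, horizon=1,
        criterion=spec.grouping_criterion, param=spec.grouping_param,
    )
    if float(np.std(residual)) < 1e-10:
        warnings.warn("degenerate residual (~0); residual model will learn a zero map")

    work = {"HR": residual}
    for c in order:
        if c != "HR":
            work[c] = train_series.channels[c]
    stats = {c: _stats(work[c]) for c in order}
    norm_mat = _normalised_matrix(work, order, stats)

    norm_series = PhysioSeries(
        session_id=train_series.session_id + ":residual",
        channels={c: norm_mat[:, i] for i, c in enumerate(order)},
    )
    data = make_windows(norm_series, order, lookback=spec.lookback, horizon=1)
    model = train(spec.residual_spec, data)
    return FittedHybrid(
        spec=spec,
        decomposition=dec,
        recurrence=lrr,
        deterministic_fit=det_fit,
        residual_model=model,
        channel_stats=stats,
        train_matrix_tail=norm_mat[-spec.lookback :].copy(),
    )


def _recursive_batch(model, windows: np.ndarray, steps: int) -> np.ndarray:
    """Batched iterated one-step forecasting (persistence for aux channels)."""
    core = build_core(model.spec, len(model.channel_names), model.lookback, 1)
    cur = windows.copy()
    hr_idx = model.hr_index
    out = np.empty((cur.shape[0], steps))
    for t in range(steps):
        yhat, _ = core.forward(model.parameters, cur)
        out[:, t] = yhat[:, 0]
        new_rows = cur[:, -1, :].copy()
        new_rows[:, hr_idx] = out[:, t]
        cur = np.concatenate([cur[:, 1:, :], new_rows[:, None, :]], axis=1)
    return out


def _combine(det: np.ndarray, resid: np.ndarray, clamp) -> tuple[np.ndarray, np.ndarray]:
    combined = det + resid
    if clamp is not None:
        combined = np.clip(combined, clamp[0], clamp[1])
    return combined, combined - det


def hybrid_predict(fit: FittedHybrid, horizon: int | None = None) -> ForecastResult:
    """Forecast ``horizon`` steps past the end of the training segment."""
    h = horizon or fit.spec.horizon
    det = ssa.forecast_recurrence(fit.recurrence, fit.deterministic_fit, h)
    resid_norm = _recursive_batch(fit.residual_model, fit.train_matrix_tail[None], h)[0]
    mu, sd = fit.channel_stats["HR"]
    resid = resid_norm * sd + mu
    combined, resid_adj = _combine(det, resid, fit.spec.clamp)
    return ForecastResult(
        deterministic_part=det,
        residual_part=resid_adj,
        combined=combined,
        provenance={
            "kind": "hybrid",
            "residual_family": fit.spec.residual_spec.family,
            **(
                {
                    "ssa_window": fit.decomposition.window,
                    "deterministic_set": [
                        i + 1 for i in fit.decomposition.deterministic_set
                    ],
                }
                if fit.decomposition is not None
                else {}
            ),
        },
    )


def hybrid_forecast_matrix(
    fit: FittedHybrid, test_series: PhysioSeries
) -> tuple[np.ndarray, np.ndarray]:
    """Rolling h-step forecasts over a held-out test segment.

    The deterministic part is the training recurrence rolled forward across
    the entire test span once (strict train/test firewall: no refitting).
    Observed test residuals are actual HR minus that rollout.  Returns
    ``(predictions, truth)`` matrices shaped (windows, horizon), on the bpm
    scale.
    """
    spec = fit.spec
    w, h = spec.lookback, spec.horizon
    hr_test = test_series.channels["HR"]
    m = hr_test.size
    if m < w + h:
        raise ValueError(f"test segment needs at least {w + h} samples")
    det_roll = ssa.forecast_recurrence(fit.recurrence, fit.deterministic_fit, m)
    resid_obs = hr_test - det_roll

    order = fit.residual_model.channel_names
    work = {"HR": resid_obs}
    for c in order:
        if c != "HR":
            work[c] = test_series.channels[c]
    norm_mat = _normalised_matrix(work, order, fit.channel_stats)

    count = m - w - h + 1
    windows = np.stack([norm_mat[i : i + w] for i in range(count)])
    resid_norm = _recursive_batch(fit.residual_model, windows, h)
    mu, sd = fit.channel_stats["HR"]
    resid_pred = resid_norm * sd + mu

    det_mat = np.stack([det_roll[i + w : i + w + h] for i in range(count)])
    truth = np.stack([hr_test[i + w : i + w + h] for i in range(count)])
    combined, _ = _combine(det_mat, resid_pred, spec.clamp)
    return combined, truth


# ---------------------------------------------------------------------------
# Standalone counterpart (same interface, no SSA stage) for comparisons
# ---------------------------------------------------------------------------

@dataclass
class FittedStandalone:
    spec: HybridSpec                        # ssa fields ignored
    model: object
    channel_stats: dict[str, tuple[float, float]]


def standalone_fit(spec: HybridSpec, train_series: PhysioSeries) -> FittedStandalone:
    """Train one forecaster family directly on (normalised) raw channels."""
    order = _predictor_order(spec.predictors)
    stats = {c: _stats(train_series.channels[c]) for c in order}
    norm_mat = _normalised_matrix(train_series.channels, order, stats)
    norm_series = PhysioSeries(
        session_id=train_series.session_id + ":norm",
        channels={c: norm_mat[:, i] for i, c in enumerate(order)},
    )
    data = make_windows(norm_series, order, lookback=spec.lookback, horizon=1)
    model = train(spec.residual_spec, data)
    return FittedStandalone(spec=spec, model=model, channel_stats=stats)


def standalone_forecast_matrix(
    fit: FittedStandalone, test_series: PhysioSeries
) -> tuple[np.ndarray, np.ndarray]:
    """Rolling h-step recursive forecasts of the standalone model."""
    spec = fit.spec
    w, h = spec.lookback, spec.horizon
    order = fit.model.channel_names
    norm_mat = _normalised_matrix(test_series.channels, order, fit.channel_stats)
    hr_test = test_series.channels["HR"]
    m = hr_test.size
    if m < w + h:
        raise ValueError(f"test segment needs at least {w + h} samples")
    count = m - w - h + 1
    windows = np.stack([norm_mat[i : i + w] for i in range(count)])
    pred_norm = _recursive_batch(fit.model, windows, h)
    mu, sd = fit.channel_stats["HR"]
    pred = pred_norm * sd + mu
    if spec.clamp is not None:
        pred = np.clip(pred, spec.clamp[0], spec.clamp[1])
    truth = np.stack([hr_test[i + w : i + w + h] for i in range(count)])
    return pred, truth
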