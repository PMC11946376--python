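"""Seeded training loop (Adam), prediction, recursive multi-step
forecasting, and directory save/load for trained forecasters."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .losses import physics_loss, physics_loss_grad
from .nets import build_core
from .specs import ForecasterSpec, WindowDataset


class _Adam:
    def __init__(self, params: dict, lr: float, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for k in params:
            gk = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * gk
            self.v[k] = b2 * self.v[k] + (1 - b2) * gk * gk
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainedForecaster:
    """Fitted state of one forecaster: spec, weights, loss history."""

    spec: ForecasterSpec
    parameters: dict[str, np.ndarray]
    training_curve: list[float]
    lookback: int
    horizon: int
    channel_names: tuple[str, ...]
    pinn_curves: dict[str, list[float]] = field(default_factory=dict)
    normalization_params: dict | None = None

    @property
    def hr_index(self) -> int:
        return self.channel_names.index("HR")


def train(spec: ForecasterSpec, data: WindowDataset) -> TrainedForecaster:
    """Train one forecaster on a window dataset.

    Deterministic given ``spec.seed``: weight initialisation and batch
    shuffling consume a single seeded generator, so identical spec + data
    reproduce the training curve bit-for-bit.  The supervised loss is MSE;
    the PINN family adds ``pinn_beta`` times the Taylor-consistency penalty
    (recorded separately per epoch, and skipped entirely in the update when
    ``pinn_beta == 0`` so the trajectory matches the plain LSTM's).

    Raises on divergence (non-finite loss) advising a smaller learning rate.
    """
    X, y = data.inputs, data.targets
    n = X.shape[0]
    if n == 0:
        raise ValueError("empty window dataset")
    core = build_core(spec, len(data.channel_names), data.lookback, data.horizon)
    rng = np.random.default_rng(spec.seed)
    params = core.init(rng)
    opt = _Adam(params, spec.learning_rate)
    is_pinn = spec.family == "PINN"
    alpha = spec.pinn_alpha if is_pinn else 1.0
    beta = spec.pinn_beta if is_pinn else 0.0
    hr_idx = data.channel_names.index("HR")
    context = X[:, -2:, hr_idx] if data.lookback >= 2 else None

    curve: list[float] = []
    lc_curve: list[float] = []
    lp_curve: list[float] = []
    for _epoch in range(spec.epochs):
        order = rng.permutation(n)
        tot_lc = tot_lp = 0.0
        for start in range(0, n, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            Xb, yb = X[idx], y[idx]
            yhat, cache = core.forward(params, Xb)
            err = yhat - yb
            lc = float(np.mean(err**2))
            dY = (2.0 * alpha / err.size) * err
            lp = 0.0
            if is_pinn and context is not None:
                ctx_b = context[idx]
                lp = physics_loss(yhat, ctx_b)
                if beta > 0.0:
                    dY = dY + beta * physics_loss_grad(yhat, ctx_b)
            if not np.isfinite(lc) or lc > 1e12:
                raise ValueError(
                    "training diverged (non-finite loss); try a smaller learning rate"
                )
            grads = core.backward(params, cache, dY)
            opt.step(params, grads)
            tot_lc += lc * idx.size
            tot_lp += lp * idx.size
        curve.append((alpha * tot_lc + beta * tot_lp) / n)
        lc_curve.append(tot_lc / n)
        lp_curve.append(tot_lp / n)

    pinn_curves = {"Lc": lc_curve, "Lp": lp_curve} if is_pinn else {}
    return TrainedForecaster(
        spec=spec,
        parameters=params,
        training_curve=curve,
        lookback=data.lookback,
        horizon=data.horizon,
        channel_names=data.channel_names,
        pinn_curves=pinn_curves,
    )


def predict(model: TrainedForecaster, inputs: np.ndarray) -> np.ndarray:
    """Forward pass on a batch of windows ``(n, lookback, channels)``.

    Pure function of (model, inputs); an empty batch yields an empty
    prediction array.
    """
    inputs = np.asarray(inputs, dtype=float)
    if inputs.ndim != 3 or inputs.shape[1:] != (
        model.lookback,
        len(model.channel_names),
    ):
        raise ValueError(
            f"expected input shape (n, {model.lookback}, "
            f"{len(model.channel_names)}), got {inputs.shape}"
        )
    if inputs.shape[0] == 0:
        return np.empty((0, model.horizon))
    core = build_core(
        model.spec, len(model.channel_names), model.lookback, model.horizon
    )
    Y, _ = core.forward(model.parameters, inputs)
    return Y


def forecast_recursive(
    model: TrainedForecaster, window: np.ndarray, steps: int
) -> np.ndarray:
    """Iterated one-step forecasting over ``steps`` future samples.

    The predicted HR value is fed back into the window; auxiliary channels
    are held at their last observed value (persistence), which is adequate
    at the 1 Hz / short-horizon scale this package targets.
    """
    if model.horizon != 1:
        raise ValueError("recursive forecasting requires a one-step model")
    cur = np.asarray(window, dtype=float).copy()
    if cur.shape != (model.lookback, len(model.channel_names)):
        raise ValueError("window shape mismatch")
    hr_idx = model.hr_index
    core = build_core(
        model.spec, len(model.channel_names), model.lookback, model.horizon
    )
    out = np.empty(steps)
    for t in range(steps):
        yhat, _ = core.forward(model.parameters, cur[None])
        out[t] = yhat[0, 0]
        new_row = cur[-1].copy()
        new_row[hr_idx] = out[t]
        cur = np.vstack([cur[1:], new_row])
    return out


# ---------------------------------------------------------------------------
# Persistence: JSON manifest + little-endian float64 weight blob
# ---------------------------------------------------------------------------

def save_forecaster(model: TrainedForecaster, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    blobs = []
    offset = 0
    for name in sorted(model.parameters):
        arr = np.ascontiguousarray(model.parameters[name], dtype="<f8")
        manifest.append({"name": name, "shape": list(arr.shape), "offset": offset})
        blobs.append(arr.tobytes())
        offset += arr.size
    meta = {
        "spec": model.spec.to_dict(),
        "lookback": model.lookback,
        "horizon": model.horizon,
        "channel_names": list(model.channel_names),
        "training_curve": model.training_curve,
        "pinn_curves": model.pinn_curves,
        "weights": {"dtype": "<f8", "manifest": manifest},
    }
    (directory / "model.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    (directory / "weights.bin").write_bytes(b"".join(blobs))


def load_forecaster(directory: str | Path) -> TrainedForecaster:
    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text())
    raw = np.frombuffer((directory / "weights.bin").read_bytes(), dtype="<f8")
    params = {}
    for entry in meta["weights"]["manifest"]:
        shape = tuple(entry["shape"])
        size = int(np.prod(shape)) if shape else 1
        params[entry["name"]] = (
            raw[entry["offset"] : entry["offset"] + size].reshape(shape).copy()
        )
    return TrainedForecaster(
        spec=ForecasterSpec(**meta["spec"]),
        parameters=params,
        training_curve=list(meta["training_curve"]),
        lookback=int(meta["lookback"]),
        horizon=int(meta["horizon"]),
        channel_names=tuple(meta["channel_names"]),
        pinn_curves={k: list(v) for k, v in meta.get("pinn_curves", {}).items()},
    )
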