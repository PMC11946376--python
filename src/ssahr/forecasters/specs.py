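"""Forecaster configuration and supervised window construction."""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from ..signal_io import CHANNELS, PhysioSeries

FAMILIES = ("RNN", "LSTM", "CNN1D", "PINN")


@dataclass(frozen=True)
class ForecasterSpec:
    """Configuration of one forecaster family.

    ``hidden_units`` applies to the recurrent families (and the PINN's LSTM
    base); ``filters``/``kernel_size``/``elu_alpha`` to the 1D CNN.
    ``pinn_alpha``/``pinn_beta`` weight the supervised and physics terms of
    the PINN composite loss; with ``pinn_beta == 0`` the PINN training
    trajectory is identical to the plain LSTM's for the same seed.
    """

    family: str = "LSTM"
    hidden_units: int = 32
    conv_layers: int = 2
    filters: int = 16
    kernel_size: int = 5
    elu_alpha: float = 1.0
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 32
    seed: int = 0
    pinn_alpha: float = 1.0
    pinn_beta: float = 0.1

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if min(self.hidden_units, self.filters, self.kernel_size,
               self.conv_layers, self.batch_size) < 1:
            raise ValueError("all architecture sizes must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.family == "PINN":
            if self.pinn_alpha <= 0:
                raise ValueError("pinn_alpha must be > 0")
            if self.pinn_beta < 0:
                raise ValueError("pinn_beta must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class WindowDataset:
    """Sliding supervised windows: ``inputs`` (n, lookback, channels) and
    ``targets`` (n, horizon) future HR values."""

    inputs: np.ndarray
    targets: np.ndarray
    lookback: int
    horizon: int
    channel_names: tuple[str, ...]

    @property
    def n_windows(self) -> int:
        return int(self.inputs.shape[0])


def make_windows(
    series: PhysioSeries,
    predictors=("HR",),
    lookback: int = 30,
    horizon: int = 1,
) -> WindowDataset:
    """Build stride-1 sliding windows from a session.

    The target channel is always HR; predictors follow the configured
    combination in canonical channel order.  A length-``N`` series yields
    ``N - lookback - horizon + 1`` windows.
    """
    preds = tuple(c for c in CHANNELS if c in set(predictors))
    if not preds:
        raise ValueError("at least one predictor channel required")
    missing = [c for c in preds if c not in series.channels]
    if missing:
        raise ValueError(f"predictor channels missing from series: {missing}")
    if "HR" not in series.channels:
        raise ValueError("series must contain an HR channel (forecast target)")
    n = series.n
    need = lookback + horizon
    if n < need:
        raise ValueError(
            f"series length {n} < lookback + horizon = {need} samples required"
        )
    mat = np.stack([series.channels[c] for c in preds], axis=1)  # (N, C)
    hr = series.channels["HR"]
    count = n - lookback - horizon + 1
    idx = np.arange(count)
    inputs = np.stack([mat[i : i + lookback] for i in idx])
    targets = np.stack([hr[i + lookback : i + lookback + horizon] for i in idx])
    return WindowDataset(
        inputs=inputs,
        targets=targets,
        lookback=lookback,
        horizon=horizon,
        channel_names=preds,
    )
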