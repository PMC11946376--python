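"""Read, validate, preprocess and write 1 Hz cardiorespiratory session records.

A session record holds up to three channels sampled once per second:

``HR``
    heart rate in beats per minute,
``BR``
    breathing rate in breaths per minute,
``RR``
    beat-to-beat (RR) intervals in milliseconds.

Files are plain delimited text with a header row; the canonical column
names are ``time_s``, ``hr_bpm``, ``br_rpm`` and ``rr_ms``, but arbitrary
layouts are supported through an explicit column mapping.

Preprocessing follows two configurable outlier policies (hard physiological
bounds, or a Hampel filter on a rolling median) with replacement by linear
interpolation, clipping, or removal, plus per-channel z-score normalisation
with population standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CHANNELS",
    "CANONICAL_COLUMNS",
    "DEFAULT_BOUNDS",
    "PhysioSeries",
    "PreprocessPolicy",
    "NormalizationRecord",
    "read_session",
    "write_session",
    "remove_outliers",
    "normalize",
    "denormalize",
]

#: Canonical channel order for every ``PhysioSeries``.
CHANNELS = ("HR", "BR", "RR")

#: Channel name -> canonical file column.
CANONICAL_COLUMNS = {"HR": "hr_bpm", "BR": "br_rpm", "RR": "rr_ms"}

#: Default physiological plausibility bounds per channel.
DEFAULT_BOUNDS = {
    "HR": (25.0, 230.0),   # bpm
    "BR": (4.0, 70.0),     # breaths/min
    "RR": (260.0, 2400.0), # ms
}


@dataclass
class PhysioSeries:
    """One session's multichannel 1 Hz record.

    Parameters
    ----------
    session_id : str
        Identifier of the recording session.
    channels : dict
        Mapping of channel name (subset of ``CHANNELS``) to a 1-D float
        array.  All channels must have equal length ``n >= 1``.
    sport : str, optional
        Free-text sport/activity label.
    t0 : float
        Time offset of the first sample in seconds.
    sample_rate : float
        Always 1 Hz; kept explicit so the invariant is checkable.
    preprocessing_log : list
        Descriptors of preprocessing steps applied so far (dicts).
    metadata : dict
        Free-form extras (e.g. ground-truth info for synthetic sessions).
    """

    session_id: str
    channels: dict[str, np.ndarray]
    sport: str | None = None
    t0: float = 0.0
    sample_rate: float = 1.0
    preprocessing_log: list[dict] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sample_rate != 1.0:
            raise ValueError("sample_rate must be 1 Hz; resampling is unsupported")
        if not self.channels:
            raise ValueError("PhysioSeries requires at least one channel")
        ordered: dict[str, np.ndarray] = {}
        for name in CHANNELS:
            if name in self.channels:
                ordered[name] = np.asarray(self.channels[name], dtype=float)
        unknown = set(self.channels) - set(CHANNELS)
        if unknown:
            raise ValueError(f"unknown channel names: {sorted(unknown)}")
        lengths = {name: arr.size for name, arr in ordered.items()}
        if len(set(lengths.values())) != 1:
            raise ValueError(f"channels have unequal lengths: {lengths}")
        n = next(iter(lengths.values()))
        if n < 1:
            raise ValueError("channels must contain at least one sample")
        self.channels = ordered

    @property
    def n(self) -> int:
        """Sample count shared by all channels."""
        return next(iter(self.channels.values())).size

    @property
    def time(self) -> np.ndarray:
        return self.t0 + np.arange(self.n, dtype=float)

    def copy(self) -> "PhysioSeries":
        return PhysioSeries(
            session_id=self.session_id,
            channels={k: v.copy() for k, v in self.channels.items()},
            sport=self.sport,
            t0=self.t0,
            sample_rate=self.sample_rate,
            preprocessing_log=[dict(e) for e in self.preprocessing_log],
            metadata=dict(self.metadata),
        )

    def slice(self, start: int, stop: int, session_suffix: str = "") -> "PhysioSeries":
        """Chronological sub-record ``[start:stop)`` sharing the time base."""
        out = self.copy()
        out.channels = {k: v[start:stop].copy() for k, v in self.channels.items()}
        out.t0 = self.t0 + start
        if session_suffix:
            out.session_id = f"{self.session_id}{session_suffix}"
        return out


@dataclass(frozen=True)
class PreprocessPolicy:
    """Outlier handling policy.

    ``physio_bounds`` flags samples outside per-channel hard bounds;
    ``hampel`` flags samples deviating from a centred rolling median by more
    than ``hampel_k`` scaled MADs.  Flagged samples are replaced by linear
    interpolation, clipped to the nearest bound, or dropped.
    """

    outlier_method: str = "physio_bounds"  # or "hampel"
    bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    hampel_window: int = 11
    hampel_k: float = 3.0
    replacement: str = "interpolate"  # or "clip", "drop"
    normalization: str = "zscore"  # or "none"

    def __post_init__(self) -> None:
        if self.outlier_method not in ("physio_bounds", "hampel"):
            raise ValueError(f"unknown outlier_method {self.outlier_method!r}")
        if self.replacement not in ("interpolate", "clip", "drop"):
            raise ValueError(f"unknown replacement {self.replacement!r}")
        if self.normalization not in ("zscore", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.hampel_window < 3 or self.hampel_window % 2 == 0:
            raise ValueError("hampel_window must be odd and >= 3")
        if self.hampel_k <= 0:
            raise ValueError("hampel_k must be positive")


@dataclass
class NormalizationRecord:
    """Per-channel (mean, population std) pairs that invert ``normalize``."""

    params: dict[str, tuple[float, float]]

    def to_dict(self) -> dict:
        return {k: [float(m), float(s)] for k, (m, s) in self.params.items()}


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_session(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = ",",
    session_id: str | None = None,
    sport: str | None = None,
) -> PhysioSeries:
    """Read one session from a delimited text file.

    Parameters
    ----------
    path : path-like
        File with a header row and one row per second.
    column_map : mapping, optional
        Channel name (``HR``/``BR``/``RR``) -> column name in the file.
        Defaults to the canonical names (``hr_bpm`` etc.); channels whose
        column is absent are simply omitted (and recorded in the log),
        but at least one mapped channel must resolve.
    delimiter : str
        Field separator.

    Raises
    ------
    ValueError
        On empty files, zero resolvable channels, or non-numeric values
        (the error names the offending data row).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no data rows") from None
    if df.empty:
        raise ValueError(f"{path}: no data rows")

    if column_map is None:
        column_map = CANONICAL_COLUMNS
    channels: dict[str, np.ndarray] = {}
    missing: list[str] = []
    for name in CHANNELS:
        col = column_map.get(name)
        if col is None or col not in df.columns:
            if name in column_map:
                missing.append(name)
            continue
        values = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(values) & df[col].notna().to_numpy())
        if bad.size:
            raise ValueError(
                f"{path}: unparseable value in column {col!r} at data row {int(bad[0])}"
            )
        if np.isnan(values).any():
            raise ValueError(
                f"{path}: missing value in column {col!r} at data row "
                f"{int(np.flatnonzero(np.isnan(values))[0])}"
            )
        channels[name] = values
    if not channels:
        raise ValueError(f"{path}: no mapped channels present in file")

    t0 = 0.0
    if "time_s" in df.columns:
        t0 = float(df["time_s"].iloc[0])

    series = PhysioSeries(
        session_id=session_id or path.stem,
        channels=channels,
        sport=sport,
        t0=t0,
    )
    if missing:
        series.preprocessing_log.append(
            {"step": "read_session", "missing_channels": sorted(missing)}
        )
    return series


def write_session(series: PhysioSeries, path: str | Path, delimiter: str = ",") -> None:
    """Write a session using the canonical column layout (round-trips exactly)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data: dict[str, np.ndarray] = {"time_s": series.time}
    for name, arr in series.channels.items():
        data[CANONICAL_COLUMNS[name]] = arr
    # shortest-repr floats + round_trip parsing keep write/read bit-exact
    pd.DataFrame(data).to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# Outlier removal
# ---------------------------------------------------------------------------

def _hampel_flags(x: np.ndarray, window: int, k: float) -> np.ndarray:
    s = pd.Series(x)
    med = s.rolling(window, center=True, min_periods=1).median()
    abs_dev = (s - med).abs()
    # 1.4826 scales MAD to a Gaussian sigma
    mad = abs_dev.rolling(window, center=True, min_periods=1).median()
    sigma = 1.4826 * mad.to_numpy()
    return abs_dev.to_numpy() > k * np.maximum(sigma, 1e-12)


def _replace(
    x: np.ndarray, flags: np.ndarray, replacement: str, bounds: tuple[float, float]
) -> np.ndarray:
    if not flags.any():
        return x
    if replacement == "clip":
        return np.clip(x, bounds[0], bounds[1])
    if replacement == "drop":
        return x[~flags]
    # linear interpolation over flagged samples; edges extend nearest good value
    good = np.flatnonzero(~flags)
    if good.size == 0:
        raise ValueError("channel entirely outlying")
    out = x.copy()
    bad = np.flatnonzero(flags)
    out[bad] = np.interp(bad, good, x[good])
    return out


def remove_outliers(series: PhysioSeries, policy: PreprocessPolicy | None = None) -> PhysioSeries:
    """Flag and replace outliers per channel according to ``policy``.

    Returns a new series; the flagged counts and indices are appended to the
    preprocessing log.  Length is unchanged for ``interpolate``/``clip``
    replacement.  ``drop`` removes flagged rows across *all* channels to keep
    channels aligned.

    Raises
    ------
    ValueError
        If every sample of a channel is flagged, or if the series is shorter
        than the Hampel window when that method is selected.
    """
    policy = policy or PreprocessPolicy()
    if policy.outlier_method == "hampel" and series.n < policy.hampel_window:
        raise ValueError(
            f"series length {series.n} < hampel_window {policy.hampel_window}"
        )
    out = series.copy()
    all_flags = np.zeros(series.n, dtype=bool)
    log_entry: dict = {"step": "remove_outliers", "method": policy.outlier_method,
                       "replacement": policy.replacement, "channels": {}}
    for name, x in series.channels.items():
        bounds = tuple(policy.bounds.get(name, DEFAULT_BOUNDS[name]))
        if policy.outlier_method == "physio_bounds":
            flags = (x < bounds[0]) | (x > bounds[1])
        else:
            flags = _hampel_flags(x, policy.hampel_window, policy.hampel_k)
        if flags.all():
            raise ValueError(f"channel {name} entirely outlying")
        if policy.replacement == "drop":
            all_flags |= flags
        else:
            out.channels[name] = _replace(x, flags, policy.replacement, bounds)
        log_entry["channels"][name] = {
            "flagged": int(flags.sum()),
            "indices": [int(i) for i in np.flatnonzero(flags)],
        }
    if policy.replacement == "drop" and all_flags.any():
        keep = ~all_flags
        out.channels = {k: v[keep].copy() for k, v in out.channels.items()}
    out.preprocessing_log.append(log_entry)
    return out


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------

def normalize(
    series: PhysioSeries, record: NormalizationRecord | None = None
) -> tuple[PhysioSeries, NormalizationRecord]:
    """Z-score each channel with the population-std convention.

    If ``record`` is given, its stored parameters are applied (so test data
    can be transformed with training statistics); otherwise parameters are
    estimated from ``series``.

    Raises
    ------
    ValueError
        If a channel is constant ("zero variance channel").
    """
    out = series.copy()
    if record is None:
        params: dict[str, tuple[float, float]] = {}
        for name, x in series.channels.items():
            mu = float(np.mean(x))
            sd = float(np.std(x))  # population std (ddof=0)
            if sd == 0.0:
                raise ValueError(f"zero variance channel {name}")
            params[name] = (mu, sd)
        record = NormalizationRecord(params)
    for name, x in out.channels.items():
        mu, sd = record.params[name]
        out.channels[name] = (x - mu) / sd
    out.preprocessing_log.append(
        {"step": "normalize", "params": record.to_dict()}
    )
    return out, record


def denormalize(series: PhysioSeries, record: NormalizationRecord) -> PhysioSeries:
    """Invert :func:`normalize` exactly (within floating-point rounding)."""
    out = series.copy()
    for name, x in out.channels.items():
        mu, sd = record.params[name]
        out.channels[name] = x * sd + mu
    out.preprocessing_log.append({"step": "denormalize"})
    return out
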