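"""Evaluation protocol: MAE, chronological 80:20 split, per-horizon error
curves, input-combination study, standalone-vs-hybrid comparison and the
high-risk (90th-percentile error) subset analysis.

All MAEs are reported on the denormalised bpm scale.  Reports are pure
functions of (data, config, seeds): identical inputs produce identical
JSON byte streams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .forecasters import FAMILIES
from .hybrid import (
    HybridSpec,
    hybrid_fit,
    hybrid_forecast_matrix,
    standalone_fit,
    standalone_forecast_matrix,
)
from .signal_io import PhysioSeries, PreprocessPolicy, remove_outliers

INPUT_COMBOS: dict[str, tuple[str, ...]] = {
    "HR": ("HR",),
    "HR+BR": ("HR", "BR"),
    "HR+RR": ("HR", "RR"),
    "HR+BR+RR": ("HR", "BR", "RR"),
}


def mae(y: Sequence[float], yhat: Sequence[float]) -> float:
    """Mean absolute error ``(1/n) sum |y_i - yhat_i|``."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("mae of empty sequences is undefined")
    if y.size != yhat.size:
        raise ValueError(f"length mismatch: {y.size} vs {yhat.size}")
    return float(np.mean(np.abs(y - yhat)))


def split_series(
    series: PhysioSeries, train_fraction: float = 0.8
) -> tuple[PhysioSeries, PhysioSeries]:
    """Chronological split: train = first ``floor(train_fraction * N)``
    samples, test = remainder.  No shuffling."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n_train = int(np.floor(series.n * train_fraction))
    if n_train < 1 or n_train >= series.n:
        raise ValueError(f"split leaves an empty segment (N={series.n})")
    return series.slice(0, n_train, ":train"), series.slice(n_train, series.n, ":test")


def horizon_curve(predictions: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """MAE per forecast step: entry ``k`` is the MAE of the (k+1)-step-ahead
    predictions over all windows."""
    predictions = np.asarray(predictions, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if predictions.shape != truth.shape or predictions.ndim != 2:
        raise ValueError("predictions and truth must share shape (windows, horizon)")
    return np.mean(np.abs(predictions - truth), axis=0)


def high_risk_comparison(
    standalone_errors: Sequence[float],
    hybrid_errors: Sequence[float],
    percentile: float = 90.0,
) -> dict:
    """Compare paired per-sample errors on the standalone model's worst tail.

    Membership: samples whose standalone error is >= the linear-interpolation
    ``percentile`` quantile of the standalone errors.  Both models' MAE on
    that subset is reported unconditionally.
    """
    s = np.asarray(standalone_errors, dtype=float).ravel()
    h = np.asarray(hybrid_errors, dtype=float).ravel()
    if s.size == 0:
        raise ValueError("empty error arrays")
    if s.size != h.size:
        raise ValueError("error arrays must be paired (equal length)")
    threshold = float(np.percentile(s, percentile))  # linear interpolation
    members = np.flatnonzero(s >= threshold)
    return {
        "percentile": float(percentile),
        "threshold": threshold,
        "member_indices": [int(i) for i in members],
        "n_members": int(members.size),
        "standalone_mae": float(np.mean(s[members])),
        "hybrid_mae": float(np.mean(h[members])),
    }


@dataclass
class EvalReport:
    """JSON-serialisable evaluation report (deterministic byte stream)."""

    config: dict
    results: dict

    def to_json(self) -> str:
        return json.dumps(
            {"config": self.config, "results": self.results},
            indent=2,
            sort_keys=True,
        )


# ---------------------------------------------------------------------------
# Session-level drivers
# ---------------------------------------------------------------------------

def _prepare(series: PhysioSeries, policy: PreprocessPolicy | None) -> PhysioSeries:
    return remove_outliers(series, policy or PreprocessPolicy())


def evaluate_session(
    series: PhysioSeries,
    spec: HybridSpec,
    mode: str = "hybrid",
    train_fraction: float = 0.8,
    policy: PreprocessPolicy | None = None,
) -> dict:
    """Preprocess, split, fit and score one session.

    Returns test MAE, the per-horizon-step curve and per-window mean
    absolute errors, all on the bpm scale.
    """
    if mode not in ("hybrid", "standalone"):
        raise ValueError(f"unknown mode {mode!r}")
    clean = _prepare(series, policy)
    train_part, test_part = split_series(clean, train_fraction)
    if mode == "hybrid":
        fit = hybrid_fit(spec, train_part)
        pred, truth = hybrid_forecast_matrix(fit, test_part)
    else:
        fit = standalone_fit(spec, train_part)
        pred, truth = standalone_forecast_matrix(fit, test_part)
    abs_err = np.abs(pred - truth)
    return {
        "mae": float(np.mean(abs_err)),
        "curve": [float(v) for v in horizon_curve(pred, truth)],
        "per_window_mae": abs_err.mean(axis=1),
        "n_windows": int(pred.shape[0]),
        "n_train": train_part.n,
        "n_test": test_part.n,
    }


def _spec_for(
    family: str,
    predictors: tuple[str, ...],
    base: HybridSpec,
    seed: int,
) -> HybridSpec:
    rspec = replace(base.residual_spec, family=family, seed=seed)
    return replace(base, residual_spec=rspec, predictors=predictors)


def standalone_vs_hybrid_study(
    sessions: Sequence[PhysioSeries],
    families: Sequence[str] = FAMILIES,
    base_spec: HybridSpec | None = None,
    train_fraction: float = 0.8,
    percentile: float = 90.0,
    seed: int = 0,
    policy: PreprocessPolicy | None = None,
) -> EvalReport:
    """Paired comparison of each family against its SSA-hybrid counterpart.

    Each session is scored with both the standalone and the hybrid variant
    of every family (same residual-net seed per pairing); per-window errors
    are pooled across sessions for the high-risk subset analysis.
    """
    base = base_spec or HybridSpec()
    results: dict = {}
    for family in families:
        per_session = {"standalone": [], "hybrid": []}
        curves = {"standalone": [], "hybrid": []}
        pooled = {"standalone": [], "hybrid": []}
        for i, session in enumerate(sessions):
            spec = _spec_for(family, base.predictors, base, seed + i)
            for mode in ("standalone", "hybrid"):
                out = evaluate_session(
                    session, spec, mode=mode,
                    train_fraction=train_fraction, policy=policy,
                )
                per_session[mode].append(out["mae"])
                curves[mode].append(out["curve"])
                pooled[mode].append(out["per_window_mae"])
        pooled_s = np.concatenate(pooled["standalone"])
        pooled_h = np.concatenate(pooled["hybrid"])
        results[family] = {
            "standalone_mae": float(np.mean(per_session["standalone"])),
            "hybrid_mae": float(np.mean(per_session["hybrid"])),
            "per_session_standalone": [float(v) for v in per_session["standalone"]],
            "per_session_hybrid": [float(v) for v in per_session["hybrid"]],
            "curve_standalone": [float(v) for v in np.mean(curves["standalone"], axis=0)],
            "curve_hybrid": [float(v) for v in np.mean(curves["hybrid"], axis=0)],
            "high_risk": high_risk_comparison(pooled_s, pooled_h, percentile),
        }
    config = {
        "families": list(families),
        "n_sessions": len(sessions),
        "train_fraction": train_fraction,
        "percentile": percentile,
        "seed": seed,
        "predictors": list(base.predictors),
        "lookback": base.lookback,
        "horizon": base.horizon,
        "residual_spec": base.residual_spec.to_dict(),
    }
    return EvalReport(config=config, results=results)


def input_combination_study(
    sessions: Sequence[PhysioSeries],
    families: Sequence[str] = FAMILIES,
    combos: dict[str, tuple[str, ...]] | None = None,
    base_spec: HybridSpec | None = None,
    mode: str = "hybrid",
    train_fraction: float = 0.8,
    seed: int = 0,
    policy: PreprocessPolicy | None = None,
) -> EvalReport:
    """Full factorial family x input-combination grid of test MAEs.

    Every session must contain all channels referenced by any combination;
    the report flags the best (lowest mean MAE) combination per family.
    """
    combos = combos or INPUT_COMBOS
    needed = {c for chans in combos.values() for c in chans}
    for session in sessions:
        missing = needed - set(session.channels)
        if missing:
            raise ValueError(
                f"session {session.session_id!r} missing channels {sorted(missing)}"
            )
    base = base_spec or HybridSpec()
    results: dict = {}
    for family in families:
        row: dict = {}
        for combo_name, predictors in combos.items():
            maes = []
            for i, session in enumerate(sessions):
                spec = _spec_for(family, predictors, base, seed + i)
                out = evaluate_session(
                    session, spec, mode=mode,
                    train_fraction=train_fraction, policy=policy,
                )
                maes.append(out["mae"])
            row[combo_name] = {
                "mae": float(np.mean(maes)),
                "per_session": [float(v) for v in maes],
            }
        best = min(row, key=lambda k: row[k]["mae"])
        results[family] = {"combos": row, "best_combo": best}
    config = {
        "families": list(families),
        "combos": {k: list(v) for k, v in combos.items()},
        "mode": mode,
        "n_sessions": len(sessions),
        "train_fraction": train_fraction,
        "seed": seed,
        "lookback": base.lookback,
        "horizon": base.horizon,
        "residual_spec": base.residual_spec.to_dict(),
    }
    return EvalReport(config=config, results=results)


def paired_difference_interval(
    a: Sequence[float], b: Sequence[float], confidence: float = 0.95
) -> dict:
    """t-based confidence interval for the mean of paired differences a - b."""
    from scipy import stats as _st

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired samples of equal length >= 2 required")
    d = a - b
    m = float(np.mean(d))
    se = float(np.std(d, ddof=1) / np.sqrt(d.size))
    if se == 0.0:
        lo = hi = m
    else:
        tcrit = float(_st.t.ppf(0.5 + confidence / 2.0, d.size - 1))
        lo, hi = m - tcrit * se, m + tcrit * se
    return {"mean": m, "low": lo, "high": hi, "covers_zero": bool(lo <= 0.0 <= hi)}


def plot_horizon_curves(report: EvalReport, out_path: str) -> None:
    """MAE-vs-horizon figure, one line per family (and variant if present)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for family, res in sorted(report.results.items()):
        for key, style in (("curve_standalone", "--"), ("curve_hybrid", "-"),
                           ("curve", "-")):
            if key in res:
                steps = np.arange(1, len(res[key]) + 1)
                label = family if key == "curve" else f"{family} ({key.split('_')[1]})"
                ax.plot(steps, res[key], style, label=label)
    ax.set_xlabel("forecast step (s)")
    ax.set_ylabel("MAE (bpm)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
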