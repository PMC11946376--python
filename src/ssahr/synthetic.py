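"""Seeded synthetic cardiorespiratory sessions.

Each session mimics the statistical structure of 1 Hz chest-strap
recordings during exercise:

* a slow exercise-intensity HR trend (rest / ramp / interval templates),
* a respiratory sinus arrhythmia (RSA) oscillation in HR phase-locked to
  the instantaneous breathing rate,
* AR(1) heart-rate noise,
* RR intervals reciprocal to instantaneous HR plus Gaussian variability,
* occasional outlier spikes (HR tripled or RR driven negative) mimicking
  sensor glitches.

The generator exposes its ground-truth components (deterministic part,
noise series, injected-outlier indices) so preprocessing recall and
parameter-recovery tests have an exact reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .signal_io import PhysioSeries

INTENSITY_PROFILES = ("rest", "ramp", "interval_training")


@dataclass(frozen=True)
class SessionModel:
    """Parameters of one synthetic session."""

    duration: int = 1800            # seconds
    hr_baseline: float = 70.0       # bpm
    intensity_profile: str = "rest"
    intensity_amplitude: float = 20.0  # bpm swing of the exercise trend
    rsa_coupling: float = 2.5       # bpm amplitude of the RSA oscillation
    br_mean: float = 15.0           # breaths/min
    br_drift_amplitude: float = 3.0  # breaths/min slow sinusoidal drift
    br_noise_sd: float = 0.2        # breaths/min white jitter
    hrv_sd: float = 40.0            # ms RR variability
    ar1_phi: float = 0.6            # HR noise autocorrelation
    noise_sd: float = 1.5           # bpm stationary sd of the AR(1) noise
    outlier_rate: float = 0.002     # per-sample spike probability
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration < 10:
            raise ValueError("duration must be >= 10 s")
        if self.intensity_profile not in INTENSITY_PROFILES:
            raise ValueError(
                f"unknown intensity_profile {self.intensity_profile!r}"
            )
        if not 0.0 <= self.ar1_phi < 1.0:
            raise ValueError("ar1_phi must be in [0, 1)")
        if self.rsa_coupling < 0 or self.noise_sd < 0 or self.hrv_sd < 0:
            raise ValueError("amplitudes and noise scales must be nonnegative")
        if not 0.0 <= self.outlier_rate < 1.0:
            raise ValueError("outlier_rate must be in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


def _intensity(model: SessionModel, t: np.ndarray) -> np.ndarray:
    a = model.intensity_amplitude
    n = t.size
    if model.intensity_profile == "rest":
        return np.zeros(n)
    if model.intensity_profile == "ramp":
        # monotone piecewise-linear warm-up: 0 -> a across the session
        return a * t / max(n - 1, 1)
    # interval_training: smooth 5-minute on/off bursts
    return 0.5 * a * (1.0 - np.cos(2.0 * np.pi * t / 300.0))


def generate_session(
    model: SessionModel, session_id: str | None = None, with_truth: bool = False
):
    """Generate one seeded session as a :class:`PhysioSeries`.

    With ``with_truth=True`` also returns a dict holding the noise-free
    deterministic HR, the AR(1) noise series, the breathing phase, and the
    indices of injected outliers per channel.
    """
    rng = np.random.default_rng(model.seed)
    n = int(model.duration)
    t = np.arange(n, dtype=float)

    br_clean = (
        model.br_mean
        + model.br_drift_amplitude * np.sin(2.0 * np.pi * t / 600.0
                                            + rng.uniform(0, 2 * np.pi))
    )
    br = br_clean + rng.normal(0.0, model.br_noise_sd, n)
    br = np.maximum(br, 4.0)

    # breathing phase integrates the instantaneous rate (breaths/s -> rad)
    phase = 2.0 * np.pi * np.cumsum(br_clean / 60.0)
    deterministic = (
        model.hr_baseline + _intensity(model, t) + model.rsa_coupling * np.sin(phase)
    )

    # stationary AR(1): innovations scaled so the marginal sd is noise_sd
    noise = np.zeros(n)
    if model.noise_sd > 0:
        innov_sd = model.noise_sd * np.sqrt(1.0 - model.ar1_phi**2)
        eps = rng.normal(0.0, innov_sd, n)
        noise[0] = rng.normal(0.0, model.noise_sd)
        for i in range(1, n):
            noise[i] = model.ar1_phi * noise[i - 1] + eps[i]
    hr = deterministic + noise

    rr = 60000.0 / hr + rng.normal(0.0, model.hrv_sd, n)

    hr_out_idx: list[int] = []
    rr_out_idx: list[int] = []
    if model.outlier_rate > 0:
        spikes = rng.random(n) < model.outlier_rate
        which = rng.random(n) < 0.5
        for i in np.flatnonzero(spikes):
            if which[i]:
                hr[i] *= 3.0  # dropout-style HR spike
                hr_out_idx.append(int(i))
            else:
                rr[i] = -abs(rr[i])  # corrupted RR sample
                rr_out_idx.append(int(i))

    series = PhysioSeries(
        session_id=session_id or f"synthetic-{model.seed}",
        sport="synthetic",
        channels={"HR": hr, "BR": br, "RR": rr},
        metadata={
            "model": model.to_dict(),
            "injected_outliers": {"HR": hr_out_idx, "RR": rr_out_idx},
        },
    )
    if with_truth:
        truth = {
            "deterministic_hr": deterministic,
            "noise": noise,
            "breathing_phase": phase,
            "injected_outliers": {"HR": hr_out_idx, "RR": rr_out_idx},
        }
        return series, truth
    return series


@dataclass
class CohortManifest:
    """Session-id -> generating parameters, JSON round-trippable."""

    master_seed: int
    sessions: dict[str, dict] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"master_seed": self.master_seed, "sessions": self.sessions},
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "CohortManifest":
        obj = json.loads(text)
        return cls(master_seed=obj["master_seed"], sessions=obj["sessions"])


def generate_cohort(
    n_sessions: int,
    parameter_ranges: dict[str, tuple[float, float]] | None = None,
    master_seed: int = 0,
    base_model: SessionModel | None = None,
) -> tuple[list[PhysioSeries], CohortManifest]:
    """Generate ``n_sessions`` sessions with per-session parameters drawn
    uniformly from ``parameter_ranges`` (field name -> (lo, hi)).

    Per-session seeds derive from ``master_seed`` via ``SeedSequence.spawn``
    so sessions are independent and the whole cohort reproducible.
    """
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    parameter_ranges = parameter_ranges or {}
    for name, rng_pair in parameter_ranges.items():
        if len(rng_pair) != 2 or rng_pair[1] < rng_pair[0]:
            raise ValueError(f"invalid range for {name}: {rng_pair}")
    base = base_model or SessionModel()
    ss = np.random.SeedSequence(master_seed)
    child_seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(n_sessions + 1)]
    draw_rng = np.random.default_rng(child_seeds[-1])

    sessions = []
    manifest = CohortManifest(master_seed=master_seed)
    for i in range(n_sessions):
        overrides = {
            name: float(draw_rng.uniform(lo, hi))
            for name, (lo, hi) in sorted(parameter_ranges.items())
        }
        fields = base.to_dict()
        fields.update(overrides)
        fields["seed"] = child_seeds[i]
        model = SessionModel(**fields)
        sid = f"session-{i:03d}"
        sessions.append(generate_session(model, session_id=sid))
        manifest.sessions[sid] = model.to_dict()
    return sessions, manifest
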