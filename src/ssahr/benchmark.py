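"""Default synthetic benchmark configuration.

One place defines the cohort and model settings used by the CLI benchmark,
the acceptance tests and the acceptance report, so "the default benchmark"
means the same thing everywhere: 10 sessions of 15 minutes with a warm-up
trend, RSA periodicity locked to a drifting breathing rate, AR(1) noise and
occasional sensor spikes; compact forecasters sized for CPU training.
"""

from __future__ import annotations

from ssahr.forecasters import ForecasterSpec
from ssahr.hybrid import HybridSpec
from ssahr.signal_io import PreprocessPolicy
from ssahr.synthetic import SessionModel, generate_cohort

#: Per-session parameter ranges for the default cohort.
DEFAULT_RANGES = {
    "rsa_coupling": (2.0, 4.0),
    "hr_baseline": (60.0, 90.0),
    "intensity_amplitude": (10.0, 20.0),
}

DEFAULT_DURATION = 900  # seconds per session
DEFAULT_N_SESSIONS = 10


def default_cohort(
    master_seed: int = 0,
    n_sessions: int = DEFAULT_N_SESSIONS,
    rsa_coupling: float | None = None,
    duration: int = DEFAULT_DURATION,
):
    """The default benchmark cohort (ramp trend + RSA + AR(1) noise).

    ``rsa_coupling`` pins the coupling to a single value (e.g. 0 for the
    null, uncoupled cohort) instead of drawing it from the default range.
    """
    ranges = dict(DEFAULT_RANGES)
    base = SessionModel(duration=duration, intensity_profile="ramp")
    if rsa_coupling is not None:
        ranges.pop("rsa_coupling")
        base = SessionModel(
            duration=duration, intensity_profile="ramp", rsa_coupling=rsa_coupling
        )
    sessions, manifest = generate_cohort(
        n_sessions, ranges, master_seed=master_seed, base_model=base
    )
    return sessions, manifest


def null_cohort(
    master_seed: int = 0,
    n_sessions: int = DEFAULT_N_SESSIONS,
    duration: int = DEFAULT_DURATION,
):
    """Uncoupled control cohort: RSA coupling 0 and auxiliary channels
    taken from *different* sessions, so BR/RR carry no information about HR.

    Generates ``2 * n_sessions`` sessions and grafts each even session's
    BR/RR onto the following odd session's HR.
    """
    raw, manifest = default_cohort(
        master_seed=master_seed, n_sessions=2 * n_sessions,
        rsa_coupling=0.0, duration=duration,
    )
    sessions = []
    for i in range(n_sessions):
        host, donor = raw[2 * i], raw[2 * i + 1]
        host.channels["BR"] = donor.channels["BR"].copy()
        host.channels["RR"] = donor.channels["RR"].copy()
        host.metadata["aux_donor"] = donor.session_id
        sessions.append(host)
    return sessions, manifest


def default_spec(
    predictors=("HR", "BR", "RR"),
    epochs: int = 30,
    horizon: int = 10,
) -> HybridSpec:
    """Compact forecaster settings sized for single-CPU benchmark runs."""
    return HybridSpec(
        residual_spec=ForecasterSpec(
            hidden_units=16,
            filters=8,
            learning_rate=5e-3,
            epochs=epochs,
            batch_size=64,
        ),
        predictors=tuple(predictors),
        lookback=30,
        horizon=horizon,
    )


def default_policy() -> PreprocessPolicy:
    """Hampel outlier policy: catches in-range sensor spikes that hard
    physiological bounds miss."""
    return PreprocessPolicy(outlier_method="hampel")
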