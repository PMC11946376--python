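# ssahr

Hybrid SSA + neural-network short-horizon heart-rate forecasting from 1 Hz
wearable cardiorespiratory signals (heart rate, breathing rate, RR
intervals).

The package decomposes the HR channel with Singular Spectrum Analysis
(Hankel embedding → SVD → deterministic/residual grouping → diagonal
averaging), extrapolates the deterministic part with linear-recurrence
forecasting, and trains a neural forecaster (RNN, LSTM, 1D CNN, or a
physics-informed LSTM variant) on the residual — optionally with BR and RR
as auxiliary predictors.  An evaluation layer provides the MAE-per-horizon
protocol, an input-combination study, a standalone-vs-hybrid comparison and
a 90th-percentile high-risk subset analysis, all exercisable end-to-end on
a seeded synthetic cohort that mimics the statistical structure of
chest-strap exercise recordings (intensity trend, respiratory sinus
arrhythmia phase-locked to breathing, AR(1) noise, sensor spikes).

The neural forecasters are plain NumPy with hand-written backprop (verified
against finite differences in the test suite), so no deep-learning
framework is required and training is bit-for-bit reproducible from a seed.

## Library layout

| module | contents |
| --- | --- |
| `ssahr.signal_io` | `PhysioSeries`, CSV read/write, outlier policies (physiological bounds / Hampel), z-score normalisation |
| `ssahr.ssa` | embedding, SVD decomposition, grouping, diagonal-averaging reconstruction, linear-recurrence forecasting |
| `ssahr.forecasters` | window construction, the four network families, training (Adam), prediction, recursive multi-step forecasting, save/load |
| `ssahr.hybrid` | SSA + residual-learner composition and its standalone counterpart |
| `ssahr.evaluation` | MAE, chronological split, horizon curves, input-combination and standalone-vs-hybrid studies, high-risk comparison |
| `ssahr.synthetic` | seeded session/cohort generator with ground-truth components |
| `ssahr.benchmark` | the default benchmark cohort/spec shared by tests and the CLI |
| `ssahr.cli` | `ssahr` command-line interface |

## CLI

```bash
ssahr simulate  --config cfg.yaml --out runs/sim            # synthetic cohort -> CSV + manifest
ssahr decompose --input session.csv --out runs/dec          # SSA summary JSON
ssahr train     --config cfg.yaml --input session.csv --out runs/model
ssahr predict   --model runs/model --out runs/fc            # ForecastResult JSON
ssahr benchmark --config cfg.yaml --out runs/bench --seed 1 # studies + figure
```

Example config:

```yaml
simulate:
  n_sessions: 10
  duration: 900
  parameter_ranges: {rsa_coupling: [2.0, 4.0]}
ssa: {window: 60, criterion: energy_fraction, param: 0.9}
forecaster: {family: LSTM, hidden_units: 16, epochs: 30, learning_rate: 0.005}
predictors: [HR, BR, RR]
lookback: 30
horizon: 10
train_fraction: 0.8
assert_claims: true
```

With `assert_claims: true`, `ssahr benchmark` exits non-zero unless the
hybrid variants are at least as accurate as their standalone counterparts
and the full input set is at least as accurate as HR alone.

## Data format

Sessions are delimited text with a header row, one row per second:
`time_s, hr_bpm, br_rpm, rr_ms` (other layouts via an explicit column
mapping).  Sampling is fixed at 1 Hz; resampling is out of scope.
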