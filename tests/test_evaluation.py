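import json

import numpy as np
import pytest

from ssahr import benchmark, evaluation
from ssahr.evaluation import (
    high_risk_comparison,
    horizon_curve,
    input_combination_study,
    mae,
    paired_difference_interval,
    split_series,
    standalone_vs_hybrid_study,
)
from ssahr.signal_io import PhysioSeries


class TestMae:
    def test_identical_is_zero(self):
        assert mae([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_hand_arithmetic(self):
        assert mae([1, 2], [2, 4]) == pytest.approx(1.5)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=20), rng.normal(size=20)
        assert mae(a, b) == mae(b, a)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            mae([1, 2], [1])

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mae([], [])


class TestSplit:
    def _series(self, n):
        return PhysioSeries("x", channels={"HR": np.arange(n, dtype=float) + 60})

    def test_default_80_20(self):
        tr, te = split_series(self._series(100))
        assert (tr.n, te.n) == (80, 20)

    def test_floor_behaviour(self):
        tr, te = split_series(self._series(10), 0.8)
        assert (tr.n, te.n) == (8, 2)

    def test_partition_and_chronology(self):
        s = self._series(57)
        tr, te = split_series(s, 0.8)
        assert tr.n + te.n == 57
        joined = np.concatenate([tr.channels["HR"], te.channels["HR"]])
        np.testing.assert_array_equal(joined, s.channels["HR"])

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            split_series(self._series(10), 1.0)


class TestHorizonCurve:
    def test_perfect_predictions_zero_curve(self):
        truth = np.random.default_rng(0).normal(size=(8, 5))
        np.testing.assert_array_equal(horizon_curve(truth, truth), np.zeros(5))

    def test_first_entry_matches_one_step_mae(self):
        rng = np.random.default_rng(1)
        pred, truth = rng.normal(size=(9, 4)), rng.normal(size=(9, 4))
        curve = horizon_curve(pred, truth)
        assert curve[0] == pytest.approx(mae(truth[:, 0], pred[:, 0]))

    def test_ar1_analytic_error_growth(self):
        # Oracle: for AR(1) x_t = phi x_{t-1} + e_t with stationary sd s, the
        # optimal k-step predictor is phi^k x_t and its error is Gaussian with
        # sd s*sqrt(1 - phi^(2k)), hence MAE = sqrt(2/pi)*sd.  Monte Carlo
        # over 50 seeded series must match that closed form.
        phi, s_sd, h, n = 0.8, 1.0, 6, 400
        curves = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = np.zeros(n)
            x[0] = rng.normal(0, s_sd)
            innov = rng.normal(0, s_sd * np.sqrt(1 - phi**2), n)
            for t in range(1, n):
                x[t] = phi * x[t - 1] + innov[t]
            starts = np.arange(0, n - h)
            pred = np.stack([x[i] * phi ** np.arange(1, h + 1) for i in starts])
            truth = np.stack([x[i + 1 : i + 1 + h] for i in starts])
            curves.append(horizon_curve(pred, truth))
        observed = np.mean(curves, axis=0)
        expected = np.sqrt(2 / np.pi) * s_sd * np.sqrt(1 - phi ** (2 * np.arange(1, h + 1)))
        np.testing.assert_allclose(observed, expected, rtol=0.05)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            horizon_curve(np.zeros((3, 4)), np.zeros((3, 5)))


class TestHighRisk:
    def test_linear_interpolation_quantile_oracle(self):
        # percentile 90 of 1..10 (linear interpolation) is 9.1 -> only the
        # sample with error 10 is a member
        s = np.arange(1.0, 11.0)
        h = np.ones(10)
        out = high_risk_comparison(s, h, 90)
        assert out["threshold"] == pytest.approx(9.1)
        assert out["member_indices"] == [9]
        assert out["standalone_mae"] == pytest.approx(10.0)

    def test_all_equal_everyone_is_member(self):
        out = high_risk_comparison(np.full(5, 2.0), np.zeros(5), 90)
        assert out["n_members"] == 5

    def test_hybrid_reported_even_when_worse(self):
        out = high_risk_comparison([1.0, 10.0], [5.0, 50.0], 90)
        assert out["hybrid_mae"] > out["standalone_mae"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            high_risk_comparison([], [], 90)

    def test_unpaired_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            high_risk_comparison([1.0], [1.0, 2.0], 90)


class TestPairedInterval:
    def test_zero_difference_covers_zero(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        out = paired_difference_interval(a, a)
        assert out["covers_zero"]

    def test_large_systematic_difference_excludes_zero(self):
        rng = np.random.default_rng(0)
        a = rng.normal(10, 0.1, 20)
        b = rng.normal(0, 0.1, 20)
        assert not paired_difference_interval(a, b)["covers_zero"]


@pytest.fixture(scope="module")
def tiny_cohort():
    sessions, _ = benchmark.default_cohort(master_seed=5, n_sessions=2,
                                           duration=400)
    return sessions


@pytest.fixture(scope="module")
def tiny_spec():
    return benchmark.default_spec(epochs=4)


class TestStudies:
    def test_grid_shape_and_best_flag(self, tiny_cohort, tiny_spec):
        combos = {"HR": ("HR",), "HR+BR": ("HR", "BR")}
        rep = input_combination_study(
            tiny_cohort, ("RNN",), combos, tiny_spec,
            policy=benchmark.default_policy(),
        )
        assert set(rep.results["RNN"]["combos"]) == {"HR", "HR+BR"}
        assert rep.results["RNN"]["best_combo"] in combos

    def test_missing_channel_names_session(self, tiny_spec):
        bad = PhysioSeries("nochan", channels={"HR": np.arange(100.0) + 70})
        with pytest.raises(ValueError, match="nochan"):
            input_combination_study([bad], ("RNN",), None, tiny_spec)

    def test_study_report_deterministic_bytes(self, tiny_cohort, tiny_spec):
        kw = dict(
            families=("RNN",), base_spec=tiny_spec, seed=3,
            policy=benchmark.default_policy(),
        )
        r1 = standalone_vs_hybrid_study(tiny_cohort, **kw)
        r2 = standalone_vs_hybrid_study(tiny_cohort, **kw)
        assert r1.to_json().encode() == r2.to_json().encode()

    def test_report_fields(self, tiny_cohort, tiny_spec):
        rep = standalone_vs_hybrid_study(
            tiny_cohort, ("RNN",), tiny_spec, seed=3,
            policy=benchmark.default_policy(),
        )
        res = rep.results["RNN"]
        assert len(res["curve_hybrid"]) == tiny_spec.horizon
        assert all(v >= 0 for v in res["curve_hybrid"])
        assert all(np.isfinite(res["curve_standalone"]))
        hr = res["high_risk"]
        assert hr["percentile"] == 90.0
        parsed = json.loads(rep.to_json())
        assert parsed["config"]["train_fraction"] == 0.8

    def test_plot_writes_file(self, tiny_cohort, tiny_spec, tmp_path):
        rep = standalone_vs_hybrid_study(
            tiny_cohort, ("RNN",), tiny_spec, seed=3,
            policy=benchmark.default_policy(),
        )
        out = tmp_path / "curves.png"
        evaluation.plot_horizon_curves(rep, str(out))
        assert out.stat().st_size > 0
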