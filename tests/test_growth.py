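"""Growth screen: log-phase detection, exponential fits, normalization."""

import math

import numpy as np
import pandas as pd
import pytest

from pufstress import (
    GrowthCurve,
    GrowthDesign,
    GrowthRateModel,
    aggregate_replicates,
    detect_log_phase,
    fit_growth_rate,
    normalize_growth,
    read_plate_timeseries,
    simulate_plate,
)

TOY_OD = [0.04, 0.05, 0.06, 0.08, 0.12, 0.20, 0.35, 0.60, 0.90, 1.10, 1.15, 1.16]


def make_curve(od, times=None, well="w1"):
    od = np.asarray(od, dtype=float)
    if times is None:
        times = np.arange(len(od)) * 15.0
    return GrowthCurve(well_id=well, strain="s", condition="none",
                       times=np.asarray(times, float), od=od)


class TestDetectLogPhase:
    def test_hand_scanned_window(self):
        # max 1.16, half-max 0.58: readings 0.06..0.35 qualify -> [2, 7)
        assert detect_log_phase(make_curve(TOY_OD)) == (2, 7)

    def test_all_below_floor(self):
        assert detect_log_phase(make_curve([0.01, 0.02, 0.03, 0.055])) is None

    def test_truncates_at_sixth_decrease(self):
        # jittered rise with 6 downward steps before reaching half-max
        od = [0.06, 0.08, 0.07, 0.10, 0.09, 0.13, 0.12, 0.16, 0.15,
              0.20, 0.19, 0.25, 0.24, 0.33, 0.40, 2.0]
        window = detect_log_phase(make_curve(od))
        # decreases at pairs ending at indices 2,4,6,8,10,12; 6th at index 12
        assert window == (0, 12)

    def test_window_start_stable_under_extension(self):
        base = make_curve(TOY_OD)
        w1 = detect_log_phase(base)
        extended = make_curve(TOY_OD + [1.16, 1.17])
        w2 = detect_log_phase(extended)
        assert w1[0] == w2[0]

    def test_window_satisfies_both_rules(self):
        curve = make_curve(TOY_OD)
        start, end = detect_log_phase(curve)
        inside = curve.od[start:end]
        assert np.all(inside > 0.055)
        assert np.all(inside < curve.od.max() / 2)


class TestFitGrowthRate:
    def test_exact_exponential(self):
        times = np.arange(6) * 15.0
        od = 0.06 * 2 ** (times / 60.0)  # doubles every 60 min
        fit = fit_growth_rate(make_curve(od, times), (0, 6))
        assert fit.valid
        assert fit.slope == pytest.approx(math.log(2), rel=1e-12)
        assert fit.doubling_time == pytest.approx(60.0, rel=1e-12)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.rmse == pytest.approx(0.0, abs=1e-12)

    def test_two_point_window_invalid(self):
        fit = fit_growth_rate(make_curve(TOY_OD), (2, 4))
        assert not fit.valid
        assert "too short" in fit.reason

    def test_r2_gate_rejects_noisy_fit(self, rng):
        # scale residuals so that R^2 lands below the 0.9 gate
        times = np.arange(12) * 15.0
        log_od = math.log(0.06) + math.log(2) / 60.0 * times
        resid = rng.normal(0, 1, 12)
        resid -= np.polyval(np.polyfit(times, resid, 1), times)  # orthogonal
        sst = np.sum((log_od - log_od.mean()) ** 2)
        resid *= math.sqrt(0.15 / 0.85 * sst / np.sum(resid**2))  # r2 = 0.85
        fit = fit_growth_rate(make_curve(np.exp(log_od + resid), times), (0, 12))
        assert fit.r2 == pytest.approx(0.85, abs=1e-6)
        assert not fit.valid

    def test_matches_normal_equations_oracle(self, rng):
        times = np.arange(10) * 15.0
        od = np.exp(np.linspace(-3, -1, 10) + rng.normal(0, 0.01, 10))
        fit = fit_growth_rate(make_curve(od, times), (0, 10))
        # closed-form OLS via the normal equations on ln(OD) vs hours
        X = np.column_stack([np.ones(10), times / 60.0])
        beta = np.linalg.solve(X.T @ X, X.T @ np.log(od))
        assert fit.slope == pytest.approx(beta[1], rel=1e-10)


class TestNormalizeGrowth:
    def fit_with_doubling(self, doubling_min):
        mu = 60.0 * math.log(2) / doubling_min
        times = np.arange(6) * 15.0
        od = 0.06 * np.exp(mu / 60.0 * times)
        return fit_growth_rate(make_curve(od, times), (0, 6))

    @pytest.mark.parametrize(
        "treated_dt, untreated_dt, expected",
        [(120, 60, 0.5), (60, 60, 1.0), (45, 60, pytest.approx(4 / 3))],
    )
    def test_rate_ratios(self, treated_dt, untreated_dt, expected):
        rate = normalize_growth(self.fit_with_doubling(treated_dt),
                                self.fit_with_doubling(untreated_dt))
        assert rate == pytest.approx(expected)

    def test_invalid_fit_propagates_reason(self):
        bad = fit_growth_rate(make_curve(TOY_OD), (2, 4))
        with pytest.raises(ValueError, match="too short"):
            normalize_growth(bad, self.fit_with_doubling(60))

    def test_scale_invariance(self):
        # multiplying all OD by a constant, or rescaling time units,
        # leaves the normalized rate unchanged
        times = np.arange(8) * 15.0
        od_t = 0.06 * np.exp(0.4 / 60.0 * times)
        od_u = 0.06 * np.exp(0.6 / 60.0 * times)
        base = normalize_growth(
            fit_growth_rate(make_curve(od_t, times), (0, 8)),
            fit_growth_rate(make_curve(od_u, times), (0, 8)),
        )
        scaled = normalize_growth(
            fit_growth_rate(make_curve(3.7 * od_t, times), (0, 8)),
            fit_growth_rate(make_curve(3.7 * od_u, times), (0, 8)),
        )
        assert scaled == pytest.approx(base, rel=1e-12)
        assert base == pytest.approx(0.4 / 0.6, rel=1e-10)


class TestAggregateReplicates:
    def test_three_identical(self):
        agg = aggregate_replicates([0.5, 0.5, 0.5])
        assert (agg.normalized_rate, agg.sd, agg.n, agg.low_n) == (0.5, 0.0, 3, False)

    def test_two_values_sample_sd(self):
        agg = aggregate_replicates([0.4, 0.6])
        assert agg.normalized_rate == pytest.approx(0.5)
        assert agg.sd == pytest.approx(math.sqrt(0.02), rel=1e-12)  # 0.1414...
        assert agg.n == 2 and agg.low_n

    def test_single_value(self):
        agg = aggregate_replicates([1.0])
        assert (agg.normalized_rate, agg.sd, agg.n, agg.low_n) == (1.0, 0.0, 1, True)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            aggregate_replicates([])


class TestPlateIO:
    def write_plate(self, tmp_path, rows):
        path = tmp_path / "plate.csv"
        pd.DataFrame(rows, columns=["well", "time_min", "od"]).to_csv(path, index=False)
        return path

    def test_parse_two_wells(self, tmp_path):
        rows = [(w, t, 0.1 + 0.01 * t / 15) for w in ("A1", "A2") for t in range(0, 60, 15)]
        layout = {"A1": ("WT", "none"), "A2": ("WT", "CaCl2")}
        curves = read_plate_timeseries(self.write_plate(tmp_path, rows), layout)
        assert len(curves) == 2 and all(len(c) == 4 for c in curves)

    def test_shuffled_rows_sorted(self, tmp_path, rng):
        rows = [("A1", t, 0.05 + 0.002 * t) for t in range(0, 120, 15)]
        shuffled = [rows[i] for i in rng.permutation(len(rows))]
        layout = {"A1": ("WT", "none")}
        a = read_plate_timeseries(self.write_plate(tmp_path, rows), layout)[0]
        b = read_plate_timeseries(self.write_plate(tmp_path, shuffled), layout)[0]
        np.testing.assert_array_equal(a.times, b.times)
        np.testing.assert_array_equal(a.od, b.od)

    def test_unknown_well_skipped(self, tmp_path, caplog):
        rows = [("Z9", t, 0.1) for t in range(0, 60, 15)]
        with caplog.at_level("WARNING"):
            curves = read_plate_timeseries(self.write_plate(tmp_path, rows), {})
        assert curves == [] and "Z9" in caplog.text


class TestRecoveryFromSimulatedCurves:
    """Fits on simulated curves recover the design growth rate."""

    def test_noiseless_recovery_within_one_percent(self):
        # capacity far above the half-max window cap keeps the window
        # inside the exponential region
        d = GrowthDesign(noise_cv=0.0, mu_per_hour=0.6, capacity=100.0,
                         duration_hours=7.0, seed=5)
        fit = GrowthRateModel(simulate_plate({"A1": d})[0]).fit()
        assert fit.valid
        assert fit.slope == pytest.approx(0.6, rel=0.01)

    def test_noisy_recovery_within_fifteen_percent(self):
        rel_errs = []
        for seed in range(5):
            d = GrowthDesign(noise_cv=0.02, mu_per_hour=0.6, capacity=100.0,
                             duration_hours=7.0, seed=seed)
            fit = GrowthRateModel(simulate_plate({"A1": d})[0]).fit()
            assert fit.valid
            rel_errs.append(abs(fit.slope - 0.6) / 0.6)
        assert max(rel_errs) < 0.15
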