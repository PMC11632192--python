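"""Per-session endpoints: sleepiness, SOL, fits, microsleeps, KSS, table."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mwtbio.epochs import LOG_FLOOR, EpochSeries
from mwtbio.session_metrics import (
    KSSSeries,
    MicrosleepEvent,
    SOLResult,
    compile_endpoints,
    fit_log_trajectory,
    interpolate_kss,
    microsleep_metrics,
    score_sol,
    sleepiness_from_hypnodensity,
)

CENSORED_40 = SOLResult(sol_min=40.0, censored=True)


class TestSleepinessScore:
    @pytest.mark.parametrize(
        "row, expected",
        [
            ((0.7, 0.2, 0.1, 0, 0), 0.3),
            ((1, 0, 0, 0, 0), 0.0),
            ((0.0, 0.25, 0.25, 0.25, 0.25), 1.0),
        ],
    )
    def test_equals_one_minus_wake(self, row, expected):
        series = sleepiness_from_hypnodensity(np.array([row], dtype=float))
        assert series.values[0] == pytest.approx(expected)

    def test_bad_row_sum_names_the_row(self):
        h = np.array([[0.5, 0.5, 0, 0, 0], [0.2, 0.2, 0.2, 0.2, 0.1]])
        with pytest.raises(ValueError, match="row 1"):
            sleepiness_from_hypnodensity(h)

    @given(
        st.lists(
            st.lists(st.floats(0.01, 1.0), min_size=5, max_size=5),
            min_size=1,
            max_size=20,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_bounded_in_unit_interval(self, raw):
        h = np.array(raw)
        h = h / h.sum(axis=1, keepdims=True)
        series = sleepiness_from_hypnodensity(h)
        assert np.all((series.values >= 0) & (series.values <= 1))
        assert np.allclose(series.values, 1.0 - h[:, 0])


class TestScoreSOL:
    def test_triple_n1_clause(self):
        stages = ["W", "W", "N1", "N1", "N1"] + ["W"] * 10
        res = score_sol(stages, 40.0)
        assert (res.sol_min, res.onset_epoch, res.censored) == (1.0, 2, False)

    def test_single_deep_epoch_clause(self):
        res = score_sol(["W", "N1", "W", "N2", "W"], 40.0)
        assert (res.sol_min, res.onset_epoch) == (1.5, 3)

    def test_all_wake_censored(self):
        res = score_sol(["W"] * 80, 40.0)
        assert res.censored and res.sol_min == 40.0 and res.onset_epoch is None

    def test_matches_brute_force_oracle_on_random_hypnograms(self):
        """1000 random hypnograms against an independent vectorized scan."""
        rng = np.random.default_rng(2024)
        stages_pool = np.array(["W", "N1", "N2", "N3", "REM"], dtype=object)
        for _ in range(1000):
            n = int(rng.integers(1, 81))
            stages = rng.choice(stages_pool, size=n, p=[0.55, 0.3, 0.07, 0.04, 0.04])
            # oracle: vectorized candidate onsets, min over both clauses
            is_n1 = stages == "N1"
            deep = np.isin(stages, ("N2", "N3", "REM"))
            triple = (
                np.flatnonzero(is_n1[:-2] & is_n1[1:-1] & is_n1[2:])
                if n >= 3
                else np.array([], dtype=int)
            )
            candidates = np.concatenate([triple, np.flatnonzero(deep)])
            res = score_sol(stages, 40.0)
            if candidates.size:
                e = int(candidates.min())
                assert (res.onset_epoch, res.sol_min, res.censored) == (e, 0.5 * e, False)
            else:
                assert res.censored and res.sol_min == 40.0

    def test_empty_hypnogram_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            score_sol([], 40.0)

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError, match="N4"):
            score_sol(["W", "N4"], 40.0)


class TestTrajectoryFit:
    def test_exact_recovery_on_noiseless_log_linear_series(self):
        t = (np.arange(80) + 0.5) * 0.25
        series = EpochSeries(values=np.exp(-2.0 + 0.05 * t), epoch_len=15.0)
        fit = fit_log_trajectory(series, CENSORED_40)
        assert fit.slope == pytest.approx(0.05, abs=1e-12)
        assert fit.intercept == pytest.approx(-2.0, abs=1e-12)

    def test_constant_series(self):
        series = EpochSeries(values=np.full(40, 0.5), epoch_len=15.0)
        fit = fit_log_trajectory(series, CENSORED_40)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(math.log(0.5))
        assert fit.average == pytest.approx(0.5)

    def test_zero_series_hits_the_log_floor(self):
        series = EpochSeries(values=np.zeros(40), epoch_len=15.0)
        fit = fit_log_trajectory(series, CENSORED_40)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(math.log(LOG_FLOOR))

    def test_window_ends_at_sleep_onset(self):
        t = (np.arange(80) + 0.5) * 0.25
        values = np.exp(-2.0 + 0.05 * t)
        values[40:] = 5e-4  # garbage after onset must not affect the fit
        series = EpochSeries(values=values, epoch_len=15.0)
        sol = SOLResult(sol_min=10.0, censored=False, onset_epoch=20)
        fit = fit_log_trajectory(series, sol)
        assert fit.n_epochs_used == 40
        assert fit.slope == pytest.approx(0.05, abs=1e-12)

    def test_too_few_epochs_invalid(self):
        series = EpochSeries(values=np.full(3, 0.5), epoch_len=15.0)
        fit = fit_log_trajectory(series, CENSORED_40)
        assert not fit.valid and math.isnan(fit.slope)

    @given(st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance(self, c):
        """Scaling the series by c shifts intercept by ln c, slope unchanged."""
        t = (np.arange(40) + 0.5) * 0.25
        base = np.exp(-3.0 + 0.08 * t)
        f1 = fit_log_trajectory(EpochSeries(values=base, epoch_len=15.0), CENSORED_40)
        f2 = fit_log_trajectory(
            EpochSeries(values=c * base, epoch_len=15.0), CENSORED_40
        )
        assert f2.slope == pytest.approx(f1.slope, abs=1e-9)
        assert f2.intercept - f1.intercept == pytest.approx(math.log(c), abs=1e-9)


class TestMicrosleepMetrics:
    def test_no_events_reported_as_zero(self):
        m = microsleep_metrics([], 40.0)
        assert (m.rate, m.mean_duration_s, m.n_events) == (0.0, 0.0, 0)

    def test_rate_and_mean_duration(self):
        events = [MicrosleepEvent(10.0 * i, 3.0 + i) for i in range(5)]
        m = microsleep_metrics(events, 10.0)
        assert m.rate == pytest.approx(0.25)  # 5 events / 20 epochs
        assert m.mean_duration_s == pytest.approx(5.0)

    def test_duration_bounds_enforced(self):
        with pytest.raises(ValueError, match=r"\[3.0, 15.0\)"):
            MicrosleepEvent(onset_s=0.0, duration_s=15.0)
        with pytest.raises(ValueError):
            MicrosleepEvent(onset_s=0.0, duration_s=2.9)

    def test_partial_epoch_excluded_from_denominator(self):
        events = [MicrosleepEvent(1.0, 4.0)]
        m = microsleep_metrics(events, 10.4)  # floor(20.8) = 20 epochs
        assert m.rate == pytest.approx(1 / 20)

    def test_pre_sol_denominator_switch(self):
        events = [MicrosleepEvent(1.0, 4.0), MicrosleepEvent(100.0, 4.0)]
        m = microsleep_metrics(events, 40.0, denominator="pre_sol", sol_min=5.0)
        assert m.rate == pytest.approx(2 / 10)


class TestKSS:
    def test_linear_interpolation(self):
        kss = KSSSeries(times=["09:50", "10:50"], scores=[7, 5])
        assert interpolate_kss(kss, "10:20") == pytest.approx(6.0)

    def test_exact_match_returns_measurement(self):
        kss = KSSSeries(times=["09:00", "11:00"], scores=[4, 8])
        assert interpolate_kss(kss, "11:00") == 8.0

    def test_no_extrapolation(self):
        kss = KSSSeries(times=["10:00", "12:00"], scores=[4, 6])
        assert math.isnan(interpolate_kss(kss, "09:30"))
        assert math.isnan(interpolate_kss(kss, "12:30"))

    def test_validation(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            KSSSeries(times=["10:00", "10:00"], scores=[4, 5])
        with pytest.raises(ValueError, match=r"\[1, 9\]"):
            KSSSeries(times=["10:00", "11:00"], scores=[4, 11])


class TestCompileEndpoints:
    def test_siesta_flag_and_eligibility(self, small_endpoints):
        tab = small_endpoints
        assert (tab.loc[tab.session_time == "14:00", "isSiesta"] == 1).all()
        assert (tab.loc[tab.session_time != "14:00", "isSiesta"] == 0).all()
        assert tab.slope_analysis_eligible.equals(tab.sol_min > 1.0)

    def test_inverse_sol_on_censored_sessions(self, small_endpoints):
        censored = small_endpoints[small_endpoints.sol_censored]
        assert len(censored) > 0
        assert np.allclose(censored.inverse_sol, 1.0 / 40.0)

    def test_all_ten_endpoints_present(self, small_endpoints):
        for col in (
            "sol_min",
            "microsleep_rate",
            "microsleep_duration",
            "sleepiness_avg",
            "sleepiness_slope",
            "sleepiness_intercept",
            "theta_alpha_avg",
            "theta_alpha_slope",
            "theta_alpha_intercept",
            "kss",
        ):
            assert col in small_endpoints.columns

    def test_kss_interpolated_within_span(self, small_endpoints):
        assert small_endpoints.kss.notna().all()
        assert small_endpoints.kss.between(1, 9).all()

    def test_threshold_crossing_identity_noiseless(self):
        """1/SOL proportional to slope b across a noiseless slope ladder."""
        from mwtbio.simstudy import (
            SimSessionConfig,
            TrajectoryParams,
            simulate_session,
        )

        # gentle slopes so the 30-s scoring grid resolves the crossing time
        slopes = np.linspace(0.04, 0.15, 12)
        inv_sol, est = [], []
        for b in slopes:
            rec, _ = simulate_session(
                TrajectoryParams(-2.0, float(b), 0.0), SimSessionConfig(seed=0)
            )
            series = sleepiness_from_hypnodensity(rec.hypnodensity)
            fit = fit_log_trajectory(series, rec.sol)
            if fit.valid and not rec.sol.censored:
                inv_sol.append(1.0 / rec.sol.sol_min)
                est.append(fit.slope)
        r = np.corrcoef(est, inv_sol)[0, 1]
        assert r >= 0.99
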