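"""CP/W' estimators: exact recovery, OLS oracles, hyperbolic NLS, prediction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cpdomains.critpower import (
    CriticalPowerModel,
    PredictiveTrial,
    fit_all,
    fit_hyperbolic,
    fit_inverse_time,
    fit_two_point,
    fit_work_time,
    predict_tlim,
)
from cpdomains.errors import (
    InsufficientDataError,
    InvalidInputError,
    SingularFitError,
)

CP_TRUE, WP_TRUE = 200.0, 20000.0
TIMES = np.array([200.0, 300.0, 420.0])
POWERS = CP_TRUE + WP_TRUE / TIMES  # exact hyperbola

# group-mean trials: powers at 95/100/110% of PPO 274 W, printed mean times
GROUP_TRIALS = [
    PredictiveTrial(260.3, 424.0),
    PredictiveTrial(274.0, 310.0),
    PredictiveTrial(301.4, 223.0),
]


def ols_oracle(x, y):
    """Closed-form simple OLS via the normal equations, with classic SEs."""
    x, y = np.asarray(x), np.asarray(y)
    n = x.size
    sxx = np.sum((x - x.mean()) ** 2)
    slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    s2 = np.sum(resid**2) / (n - 2)
    se_slope = np.sqrt(s2 / sxx)
    se_intercept = np.sqrt(s2 * (1.0 / n + x.mean() ** 2 / sxx))
    r2 = 1 - np.sum(resid**2) / np.sum((y - y.mean()) ** 2)
    return slope, intercept, se_slope, se_intercept, r2


class TestExactRecovery:
    @pytest.mark.parametrize("method", ["work_time", "inverse_time", "hyperbolic"])
    def test_noiseless_trials_recover_truth(self, method):
        res = CriticalPowerModel(POWERS, TIMES).fit(method)
        assert res.cp_W == pytest.approx(CP_TRUE, rel=1e-6)
        assert res.w_prime_J == pytest.approx(WP_TRUE, rel=1e-6)
        assert res.r2 == pytest.approx(1.0, abs=1e-9)

    def test_two_point_recovers_truth(self):
        res = fit_two_point(
            PredictiveTrial(POWERS[0], TIMES[0]), PredictiveTrial(POWERS[2], TIMES[2])
        )
        assert res.cp_W == pytest.approx(CP_TRUE, rel=1e-6)
        assert res.w_prime_J == pytest.approx(WP_TRUE, rel=1e-6)
        assert res.bse is None and res.r2 is None


class TestLinearModelsAgainstOracle:
    def test_work_time_matches_normal_equations(self):
        res = fit_work_time(GROUP_TRIALS)
        t = np.array([tr.tlim_s for tr in GROUP_TRIALS])
        w = np.array([tr.work_J for tr in GROUP_TRIALS])
        slope, intercept, se_slope, se_intercept, r2 = ols_oracle(t, w)
        assert res.cp_W == pytest.approx(slope, rel=1e-10)
        assert res.w_prime_J == pytest.approx(intercept, rel=1e-10)
        assert res.se_cp_W == pytest.approx(se_slope, rel=1e-8)
        assert res.se_wp_J == pytest.approx(se_intercept, rel=1e-8)
        assert res.r2 == pytest.approx(r2, rel=1e-10)

    def test_inverse_time_matches_normal_equations(self):
        res = fit_inverse_time(GROUP_TRIALS)
        x = np.array([1.0 / tr.tlim_s for tr in GROUP_TRIALS])
        p = np.array([tr.power_W for tr in GROUP_TRIALS])
        slope, intercept, se_slope, se_intercept, r2 = ols_oracle(x, p)
        assert res.cp_W == pytest.approx(intercept, rel=1e-10)
        assert res.w_prime_J == pytest.approx(slope, rel=1e-10)
        assert res.se_cp_W == pytest.approx(se_intercept, rel=1e-8)
        assert res.see_cp_pct == pytest.approx(100 * se_intercept / intercept, rel=1e-8)
        assert res.r2 == pytest.approx(r2, rel=1e-10)

    def test_two_trials_directed_to_two_point(self):
        with pytest.raises(InsufficientDataError, match="two_point"):
            fit_work_time(GROUP_TRIALS[:2])

    def test_identical_times_singular(self):
        trials = [PredictiveTrial(p, 300.0) for p in (260.0, 280.0, 300.0)]
        with pytest.raises(SingularFitError):
            fit_work_time(trials)


class TestHyperbolic:
    def grid_oracle(self, trials, cp_grid):
        """Best objective over a CP grid with closed-form W' per CP."""
        P = np.array([tr.power_W for tr in trials])
        t = np.array([tr.tlim_s for tr in trials])
        best = np.inf
        for cp in cp_grid:
            x = 1.0 / (P - cp)
            wp = np.sum(t * x) / np.sum(x * x)
            best = min(best, float(np.sum((t - wp * x) ** 2)))
        return best

    def test_objective_beats_fine_grid_search(self, rng):
        t_noisy = TIMES * rng.lognormal(0.0, 0.05, size=3)
        trials = [PredictiveTrial(p, tt) for p, tt in zip(POWERS, t_noisy)]
        res = fit_hyperbolic(trials)
        obj = float(
            np.sum((t_noisy - res.w_prime_J / (POWERS - res.cp_W)) ** 2)
        )
        grid = np.arange(100.0, POWERS.min() - 1.0, 0.01)
        oracle = self.grid_oracle(trials, grid)
        assert obj <= oracle * (1 + 1e-6)

    def test_equal_powers_singular(self):
        trials = [PredictiveTrial(300.0, t) for t in (200.0, 300.0, 400.0)]
        with pytest.raises(SingularFitError):
            fit_hyperbolic(trials)

    def test_power_domain_axis_matches_inverse_time(self):
        # power-domain hyperbolic residuals are linear in 1/t, so the
        # optimum coincides with the inverse-time OLS solution
        res_p = fit_hyperbolic(GROUP_TRIALS, residual_axis="power")
        res_l = fit_inverse_time(GROUP_TRIALS)
        assert res_p.cp_W == pytest.approx(res_l.cp_W, rel=1e-6)
        assert res_p.w_prime_J == pytest.approx(res_l.w_prime_J, rel=1e-6)


class TestTwoPoint:
    def test_hand_solved_group_mean_pair(self):
        a, b = PredictiveTrial(260.3, 424.0), PredictiveTrial(301.4, 223.0)
        cp_hand = (b.work_J - a.work_J) / (b.tlim_s - a.tlim_s)
        wp_hand = a.work_J - cp_hand * a.tlim_s
        res = fit_two_point(a, b)
        assert res.cp_W == pytest.approx(cp_hand, rel=1e-12)
        assert res.w_prime_J == pytest.approx(wp_hand, rel=1e-12)
        # sanity: roughly CP ~214.5 W and W' ~19.3 kJ on this pair
        assert res.cp_W == pytest.approx(214.7, abs=0.5)
        assert res.w_prime_kJ == pytest.approx(19.3, abs=0.2)

    @given(
        st.floats(120.0, 350.0),
        st.floats(5000.0, 35000.0),
        st.floats(120.0, 400.0),
        st.floats(60.0, 110.0),
    )
    def test_work_time_and_inverse_time_forms_identical(self, cp, wp, t1, dt):
        t2 = t1 + dt
        a = PredictiveTrial(cp + wp / t1, t1)
        b = PredictiveTrial(cp + wp / t2, t2)
        r1 = fit_two_point(a, b, form="work_time")
        r2 = fit_two_point(a, b, form="inverse_time")
        assert r1.cp_W == pytest.approx(r2.cp_W, rel=1e-9)
        assert r1.w_prime_J == pytest.approx(r2.w_prime_J, rel=1e-9)

    def test_interpolation_returns_trial_time_exactly(self):
        a, b = PredictiveTrial(260.3, 424.0), PredictiveTrial(301.4, 223.0)
        res = fit_two_point(a, b)
        assert res.predict(a.power_W) == pytest.approx(a.tlim_s, rel=1e-12)
        assert res.predict(b.power_W) == pytest.approx(b.tlim_s, rel=1e-12)

    def test_identical_trials_rejected(self):
        a = PredictiveTrial(260.3, 424.0)
        with pytest.raises(InvalidInputError):
            fit_two_point(a, a)

    def test_equal_times_singular(self):
        with pytest.raises(SingularFitError):
            fit_two_point(PredictiveTrial(260.0, 300.0), PredictiveTrial(280.0, 300.0))


class TestPrediction:
    def test_forced_value(self):
        res = fit_work_time(
            [PredictiveTrial(p, t) for p, t in zip(POWERS, TIMES)]
        )
        assert predict_tlim(res, 300.0) == pytest.approx(200.0, rel=1e-6)

    def test_group_mean_anchor(self):
        # CP 213 W, W' 19400 J at P 344 W -> 19400/131 ~ 148.1 s
        from cpdomains.critpower import CriticalPowerResults

        res = CriticalPowerResults(
            model=CriticalPowerModel(POWERS, TIMES),
            method="hyperbolic", cp_W=213.0, w_prime_J=19400.0,
        )
        assert res.predict(344.0) == pytest.approx(19400.0 / 131.0, rel=1e-12)
        assert res.predict(344.0) == pytest.approx(148.1, abs=0.05)

    @given(st.floats(0.1, 200.0), st.floats(0.1, 200.0))
    def test_strictly_decreasing_in_power(self, d1, d2):
        res = fit_two_point(
            PredictiveTrial(POWERS[0], TIMES[0]), PredictiveTrial(POWERS[2], TIMES[2])
        )
        p1 = res.cp_W + min(d1, d2)
        p2 = res.cp_W + min(d1, d2) + max(d1, d2)
        assert res.predict(p1) > res.predict(p2)

    def test_at_or_below_cp_rejected(self):
        res = fit_work_time([PredictiveTrial(p, t) for p, t in zip(POWERS, TIMES)])
        with pytest.raises(InvalidInputError):
            res.predict(res.cp_W)

    def test_unbounded_near_asymptote(self):
        res = fit_two_point(
            PredictiveTrial(POWERS[0], TIMES[0]), PredictiveTrial(POWERS[2], TIMES[2])
        )
        assert res.predict(res.cp_W + 1e-9) > 1e10


class TestModelSurface:
    def test_from_dataframe_roundtrip(self):
        import pandas as pd

        df = pd.DataFrame({"power_W": POWERS, "tlim_s": TIMES})
        res = CriticalPowerModel.from_dataframe(df).fit("work_time")
        assert res.cp_W == pytest.approx(CP_TRUE, rel=1e-6)

    def test_fit_all_returns_four_models(self):
        out = fit_all([PredictiveTrial(p, t) for p, t in zip(POWERS, TIMES)])
        assert set(out) == {"work_time", "inverse_time", "hyperbolic", "two_point"}

    def test_summary_mentions_estimates(self):
        res = fit_hyperbolic([PredictiveTrial(p, t) for p, t in zip(POWERS, TIMES)])
        text = res.summary()
        assert "CP (W)" in text and "W' (kJ)" in text and "R²" in text
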