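"""Synthetic cohort generator: sampling, trial/trace simulation, study replica."""

import numpy as np
import pandas as pd
import pytest

from cpdomains.breath import peak_15s
from cpdomains.cohort import (
    AthleteProfile,
    CohortConfig,
    deterministic_ppo,
    run_study,
    sample_cohort,
    simulate_breath_series,
    simulate_incremental,
    simulate_tlim,
)
from cpdomains.errors import InvalidInputError, ProtocolFailureError


def make_profile(**kw):
    defaults = dict(
        cp_W=213.0, w_prime_J=19400.0, vo2max_l_min=3.75,
        vo2_baseline_l_min=0.9, tau_primary_s=25.0, sc_delay_s=60.0,
        sc_gain_l_min_per_W=8e-4, body_mass_kg=77.8, i_high_true_W=350.0,
        extreme_shortfall_k=0.5, tlim_noise_cv=0.0, vo2_noise_sd_l_min=0.0,
        vo2_day_cv=0.0,
    )
    defaults.update(kw)
    return AthleteProfile(**defaults)


class TestSampleCohort:
    def test_same_seed_identical_cohorts(self):
        cfg = CohortConfig(seed=42, n=6)
        assert sample_cohort(cfg) == sample_cohort(cfg)

    def test_zero_sds_give_identical_athletes(self):
        cfg = CohortConfig(
            seed=1, n=4,
            cp_W=(213.0, 0.0), w_prime_J=(19400.0, 0.0),
            vo2max_l_min=(3.75, 0.0), vo2_baseline_l_min=(0.9, 0.0),
            tau_primary_s=(25.0, 0.0), sc_delay_s=(60.0, 0.0),
            sc_gain_l_min_per_W=(8e-4, 0.0), body_mass_kg=(77.8, 0.0),
            i_high_ratio=(1.27, 0.0),
        )
        athletes = sample_cohort(cfg)
        assert len(set(athletes)) == 1

    def test_large_cohort_mean_cp_within_two_percent(self):
        cfg = CohortConfig(seed=7, n=5000)
        cps = np.array([a.cp_W for a in sample_cohort(cfg)])
        assert abs(cps.mean() - 213.0) / 213.0 < 0.02

    def test_invalid_size_rejected(self):
        with pytest.raises(InvalidInputError):
            CohortConfig(n=0)


class TestSimulateTlim:
    def test_noiseless_hyperbola(self):
        ath = make_profile(extreme_shortfall_k=0.0)
        assert simulate_tlim(ath, 300.0) == pytest.approx(
            19400.0 / (300.0 - 213.0), rel=1e-12
        )

    def test_shortfall_shortens_extreme_bouts(self):
        ath = make_profile(extreme_shortfall_k=0.5)
        p = 380.0  # above the true boundary of 350 W
        hyper = 19400.0 / (p - 213.0)
        expected = hyper * (1 - 0.5 * (p - 350.0) / 350.0)
        assert simulate_tlim(ath, p) == pytest.approx(expected, rel=1e-12)
        assert simulate_tlim(ath, p) < hyper

    def test_mean_overestimation_matches_monte_carlo_of_stated_formula(self):
        ath = make_profile(extreme_shortfall_k=0.5, tlim_noise_cv=0.05)
        p = ath.i_high_true_W * 1.04
        rng = np.random.default_rng(5)
        actual = np.array([simulate_tlim(ath, p, rng) for _ in range(2000)])
        predicted = 19400.0 / (p - 213.0)  # severe-domain hyperbola
        # independent Monte Carlo of the same expression
        rng2 = np.random.default_rng(99)
        sigma = np.sqrt(np.log1p(0.05**2))
        short = predicted * (1 - 0.5 * (p - ath.i_high_true_W) / ath.i_high_true_W)
        oracle = short * rng2.lognormal(-0.5 * sigma**2, sigma, 5000)
        bias = predicted - actual.mean()
        assert bias > 0
        assert actual.mean() == pytest.approx(oracle.mean(), rel=0.01)

    def test_subcritical_power_rejected(self):
        with pytest.raises(InvalidInputError):
            simulate_tlim(make_profile(), 213.0)


class TestSimulateBreathSeries:
    def test_severe_noiseless_attains_vo2max(self):
        ath = make_profile()
        for p, tlim in ((260.0, 420.0), (340.0, 155.0), (350.0, 140.0)):
            s = simulate_breath_series(ath, p, tlim)
            assert peak_15s(s).value_l_min == pytest.approx(3.75, abs=1e-9)

    def test_extreme_noiseless_stays_below(self):
        ath = make_profile()
        s = simulate_breath_series(ath, 380.0, 100.0)
        assert peak_15s(s).value_l_min <= 3.75 - 0.25 + 1e-9

    def test_sc_disabled_matches_monoexponential_closed_form(self):
        ath = make_profile(sc_gain_l_min_per_W=0.0)
        s = simulate_breath_series(ath, 300.0, 240.0)
        amp = min(0.0103 * 300.0, 0.92 * (3.75 - 0.9))
        expected = 0.9 + amp * (1 - np.exp(-s.time_s / 25.0))
        assert np.allclose(s.vo2_l_min, expected, atol=1e-9)

    def test_inconsistent_profile_rejected(self):
        with pytest.raises(InvalidInputError):
            make_profile(vo2_baseline_l_min=4.0)

    def test_noise_is_reproducible(self):
        ath = make_profile(vo2_noise_sd_l_min=0.2)
        a = simulate_breath_series(ath, 300.0, 200.0, np.random.default_rng(3))
        b = simulate_breath_series(ath, 300.0, 200.0, np.random.default_rng(3))
        assert np.array_equal(a.vo2_l_min, b.vo2_l_min)


class TestSimulateIncremental:
    def test_supra_cp_depletion_conserves_w_prime(self):
        ath = make_profile()
        res = simulate_incremental(ath)
        spent = sum(
            (p - ath.cp_W) * d for p, d in res.stages if p > ath.cp_W
        )
        assert spent == pytest.approx(ath.w_prime_J, rel=1e-9)

    def test_ppo_matches_stagewise_hand_ledger(self):
        # cp 213, w' 19400, mass 77.8: inc 38.9 W; supra-CP stages 6..8:
        # 233.4 W drains 3672 J, 272.3 W drains 10674 J, remainder 5054 J
        # at 311.2 W lasts 51.466 s -> PPO = 272.3 + 38.9 * 51.466/180
        ppo, stages, supra = deterministic_ppo(213.0, 19400.0, 77.8)
        drain6 = (6 * 38.9 - 213.0) * 180.0
        drain7 = (7 * 38.9 - 213.0) * 180.0
        dur8 = (19400.0 - drain6 - drain7) / (8 * 38.9 - 213.0)
        ppo_hand = 7 * 38.9 + 38.9 * dur8 / 180.0
        assert ppo == pytest.approx(ppo_hand, rel=1e-12)
        assert stages[-1][1] == pytest.approx(dur8, rel=1e-12)

    def test_unreachable_cp_fails_protocol(self):
        with pytest.raises(ProtocolFailureError):
            deterministic_ppo(5000.0, 19400.0, 77.8)

    def test_vo2peak_attains_vo2max_noiselessly(self):
        res = simulate_incremental(make_profile())
        assert res.vo2peak.value_l_min == pytest.approx(3.75, abs=1e-9)


class TestRunStudy:
    def test_noiseless_null_system_has_zero_bias_everywhere(self):
        cfg = CohortConfig(
            seed=3, n=6, extreme_shortfall_k=0.0, tlim_noise_cv=0.0,
            vo2_noise_sd_l_min=0.0, vo2_day_cv=0.0,
        )
        res = run_study(cfg)
        assert not res.manifest["excluded"]
        # every model recovers the truth ...
        assert np.allclose(res.fits["cp_W"], res.fits["cp_true_W"], rtol=1e-6)
        assert np.allclose(res.fits["w_prime_J"], res.fits["w_prime_true_J"], rtol=1e-6)
        # ... so predictions equal actual times at both intensities
        assert np.allclose(res.predictions["predicted_s"],
                           res.predictions["actual_s"], rtol=1e-6)
        raw = res.agreement[res.agreement["mode"] == "raw"]
        assert np.allclose(raw["bias"], 0.0, atol=1e-6)
        assert not (raw["heteroscedastic"] == True).any()  # noqa: E712

    def test_same_seed_byte_identical_bundle(self, tmp_path):
        cfg = CohortConfig(seed=9, n=5)
        a, b = run_study(cfg), run_study(cfg)
        for name in ("cohort", "trials", "fits", "boundary", "predictions", "agreement"):
            pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))
        a.to_dir(tmp_path / "x")
        b.to_dir(tmp_path / "y")
        for f in sorted((tmp_path / "x").iterdir()):
            assert f.read_bytes() == (tmp_path / "y" / f.name).read_bytes()

    def test_study_tables_are_structured_like_the_report(self):
        from cpdomains.report import model_estimates_table, prediction_agreement_table

        res = run_study(CohortConfig(seed=2, n=8))
        t1 = model_estimates_table(res.fits)
        assert set(t1.columns) <= {"work_time", "inverse_time", "hyperbolic", "two_point"}
        t2 = prediction_agreement_table(res.predictions, res.agreement)
        assert {"i_high", "i_high_plus5"} == set(t2["intensity"])
        assert "cp" in res.anova and "tlim_i_high" in res.anova
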