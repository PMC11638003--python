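"""Estimator tests: exact round trips on noiseless data, Monte-Carlo
calibration of reported uncertainties, and the global ODE fit."""

import numpy as np
import pandas as pd
import pytest

from phypif import estimators as est
from phypif.hydrodynamics import water_viscosity
from phypif.model import RateConstants, SystemComposition, TimeTrace
from phypif.synthetic import PRESETS, GeneratorSpec, generate


class TestMonoexponential:
    def test_noiseless_round_trip(self):
        t = np.arange(0.0, 2.0, 0.02)
        y = 0.4 + 0.6 * np.exp(-5.2 * t)
        fit = est.fit_monoexponential(TimeTrace(t, y))
        assert fit.k1 == pytest.approx(5.2, rel=1e-8)
        assert fit.F0 == pytest.approx(0.4, rel=1e-8)

    def test_constant_trace_flagged(self):
        t = np.arange(0.0, 1.0, 0.1)
        fit = est.fit_monoexponential(TimeTrace(t, np.full_like(t, 2.0)))
        assert fit.F1 == 0.0
        assert "constant-signal" in fit.flags

    def test_monte_carlo_rate_and_error_calibration(self):
        """Over 300 seeded replicates at 2% noise the mean estimate stays
        within 1% of truth and the reported asymptotic standard error
        matches the empirical scatter."""
        ks, ses = [], []
        for seed in range(300):
            ds = generate(GeneratorSpec("photoconversion_trace",
                                        noise_sd=0.02, seed=seed))
            fit = est.fit_monoexponential(ds.data)
            ks.append(fit.k1)
            ses.append(fit.stderr["k1"])
        ks, ses = np.array(ks), np.array(ses)
        assert np.mean(ks) == pytest.approx(2.4, rel=0.01)
        assert 0.7 < np.std(ks) / np.mean(ses) < 1.3


class TestBiexponential:
    def test_noiseless_round_trip_and_slow_phase_flag(self):
        t = np.arange(0.0, 40.0, 0.2)
        y = 0.2 + 0.3 * np.exp(-1.0 * t) + 0.6 * np.exp(-0.1 * t)
        fit = est.fit_biexponential(TimeTrace(t, y))
        assert fit.k1 == pytest.approx(1.0, rel=1e-6)
        assert fit.k2 == pytest.approx(0.1, rel=1e-6)
        assert fit.k1 > fit.k2
        assert fit.slower_phase_dominant is True

    def test_nested_model_limit(self):
        """With a vanishing second amplitude the biexponential fit
        reproduces the monoexponential prediction."""
        t = np.arange(0.0, 5.0, 0.05)
        y = 1.0 - 0.5 * np.exp(-2.0 * t)
        mono = est.fit_monoexponential(TimeTrace(t, y))
        bi = est.fit_biexponential(TimeTrace(t, y))
        assert np.max(np.abs(bi.predict(t) - mono.predict(t))) < 1e-8

    def test_dark_recovery_arrhenius_consistency(self):
        """Dark-recovery-style biexponential data whose slow rate speeds
        up 10-fold over 15 K yields an activation energy on the
        10^5 J mol^-1 scale."""
        temps = np.array([288.15, 295.15, 303.15])
        e_a = np.log(10.0) * est.R_GAS / (1 / temps[0] - 1 / temps[-1])
        assert 0.5e5 < e_a < 2e5  # order-of-magnitude design check
        a = 1e-5 / np.exp(-e_a / (est.R_GAS * temps[0]))
        slow = []
        for T in temps:
            k2 = a * np.exp(-e_a / (est.R_GAS * T))
            t = np.linspace(0, 5 / k2, 400)
            y = 0.1 + 0.2 * np.exp(-20 * k2 * t) + 0.7 * np.exp(-k2 * t)
            fit = est.fit_biexponential(TimeTrace(t, y))
            assert fit.slower_phase_dominant
            slow.append(fit.k2)
        arr = est.fit_arrhenius(pd.DataFrame({"T_K": temps, "k_s": slow}))
        assert arr.E_A == pytest.approx(e_a, rel=0.01)


class TestConsecutive:
    def test_noiseless_round_trip(self):
        t = np.arange(0.0, 60.0, 0.05)
        y = est.consecutive_signal(t, 1.0, 0.86, 2.4, 0.11)
        fit = est.fit_consecutive(TimeTrace(t, y), k_q_fixed=2.4)
        assert fit.k_o == pytest.approx(0.11, rel=1e-8)

    def test_slow_limit_matches_delayed_monoexponential(self):
        """For k_o << k_q the late-time decay is monoexponential in k_o."""
        t = np.arange(0.0, 60.0, 0.1)
        y = est.consecutive_signal(t, 1.0, 0.86, 2.4, 0.05)
        mono = est.fit_monoexponential(TimeTrace(t, y).window(t_min=2.0))
        assert mono.k1 == pytest.approx(0.05, rel=0.01)

    def test_identifiability_warning_near_kq(self):
        """A downstream rate close to the fixed photoreversion rate is
        only a lower bound on the true speed and must be flagged."""
        t = np.arange(0.0, 10.0, 0.05)
        y = est.consecutive_signal(t, 1.0, 0.86, 2.4, 2.5)
        fit = est.fit_consecutive(TimeTrace(t, y), k_q_fixed=2.4)
        assert fit.k_o == pytest.approx(2.5, rel=1e-6)
        assert "identifiability" in fit.flags

    def test_singular_point_continuity(self):
        t = np.linspace(0.0, 3.0, 50)
        near = est.consecutive_signal(t, 1.0, 0.5, 2.0, 2.0 + 1e-7)
        at = est.consecutive_signal(t, 1.0, 0.5, 2.0, 2.0)
        assert np.max(np.abs(near - at)) < 1e-6


class TestPseudoFirstOrder:
    def test_exact_line_with_pfr_correction(self):
        """The printed slope/intercept map to the corrected bimolecular
        rate constant and a consistent K_d."""
        conc = np.array([0.5, 1.0, 1.5, 2.0]) * 1e-6
        table = pd.DataFrame({"concentration_M": conc,
                              "k_obs_s": 4.4e5 * conc + 0.11})
        fit = est.fit_pseudo_first_order(table, pfr_fraction=0.73)
        assert fit.k_a_corrected == pytest.approx(4.4e5 / 0.73, rel=1e-10)
        assert fit.k_a_corrected == pytest.approx(6.1e5, rel=0.02)
        assert fit.k_d == pytest.approx(0.11, rel=1e-10)
        assert fit.K_d * fit.k_a_corrected == pytest.approx(fit.k_d)
        assert fit.K_d == pytest.approx(183e-9, rel=0.02)

    def test_unit_pfr_fraction_is_identity(self):
        conc = np.array([1.0, 2.0, 3.0]) * 1e-6
        table = pd.DataFrame({"concentration_M": conc,
                              "k_obs_s": 2e5 * conc + 0.2})
        fit = est.fit_pseudo_first_order(table, pfr_fraction=1.0)
        assert fit.k_a_corrected == pytest.approx(fit.k_a)

    def test_flat_rates_mark_association_unresolved(self, rng):
        """Concentration-independent observable rates (the Pr-state
        situation) leave the association unresolved and report the mean
        rate as the dissociation rate."""
        conc = np.array([0.5, 1.0, 1.5, 2.0]) * 1e-6
        k_obs = 2.5 + rng.normal(0, 0.02, size=4)
        table = pd.DataFrame({"concentration_M": conc, "k_obs_s": k_obs})
        fit = est.fit_pseudo_first_order(table)
        assert "association-unresolved" in fit.flags
        assert fit.k_d == pytest.approx(np.mean(k_obs))


class TestIsotherm:
    def test_pfr_correction_scales_kd(self):
        """An apparent 180 nM affinity against total receptor maps to
        ~131 nM against the photoactivated fraction."""
        ds = generate(GeneratorSpec("titration", noise_sd=0.0, seed=0))
        fit = est.fit_isotherm(ds.data, pfr_fraction=0.73)
        assert fit.K_d == pytest.approx(0.73 * 180e-9, rel=1e-6)
        assert fit.K_d == pytest.approx(130e-9, rel=0.02)

    def test_uncorrected_fit_returns_apparent_kd(self):
        ds = generate(GeneratorSpec("titration", noise_sd=0.0, seed=0))
        fit = est.fit_isotherm(ds.data, correct=False)
        assert fit.K_d == pytest.approx(180e-9, rel=1e-6)

    def test_noisy_ensemble_recovery(self):
        kds = []
        for seed in range(50):
            ds = generate(GeneratorSpec("titration", noise_sd=0.03,
                                        seed=seed))
            kds.append(est.fit_isotherm(ds.data, pfr_fraction=0.73).K_d)
        assert np.median(kds) == pytest.approx(0.73 * 180e-9, rel=0.1)

    def test_out_of_range_kd_flagged(self):
        conc = np.linspace(1e-6, 2e-6, 6)
        signal = 1.0 - 0.1 * conc / (conc + 5e-5)  # K_d far above range
        table = pd.DataFrame({"concentration_M": conc, "signal": signal})
        fit = est.fit_isotherm(table, correct=False)
        assert "extrapolation" in fit.flags


class TestArrhenius:
    def test_noiseless_round_trip(self):
        T = np.array([288.15, 295.15, 303.15])
        a, e_a = 3e17, 7.1e4
        table = pd.DataFrame({"T_K": T,
                              "k_s": a * np.exp(-e_a / (est.R_GAS * T))})
        fit = est.fit_arrhenius(table)
        assert fit.E_A == pytest.approx(7.1e4, rel=1e-10)
        nl = est.fit_arrhenius(table, method="nonlinear")
        assert nl.E_A == pytest.approx(7.1e4, rel=1e-6)

    def test_temperature_independent_rates(self):
        table = pd.DataFrame({"T_K": [288.15, 295.15, 303.15],
                              "k_s": [0.5, 0.5, 0.5]})
        assert est.fit_arrhenius(table).E_A == pytest.approx(0.0, abs=1e-8)

    def test_viscosity_correction_removes_diffusive_activation(self):
        """Association rates that scale with water fluidity carry an
        apparent activation energy; referring them to constant viscosity
        removes it."""
        T = np.array([288.15, 291.15, 295.15, 299.15, 303.15])
        eta = np.array([water_viscosity(x) for x in T])
        k_diff = 1e5 * eta[0] / eta
        raw = est.fit_arrhenius(pd.DataFrame({"T_K": T, "k_s": k_diff}))
        corrected = est.fit_arrhenius(
            pd.DataFrame({"T_K": T, "k_s": k_diff * eta / eta[0]}))
        assert raw.E_A > 1e4
        assert abs(corrected.E_A) < 1e-6 * raw.E_A

    def test_nonpositive_rates_rejected(self):
        table = pd.DataFrame({"T_K": [288.0, 295.0, 303.0],
                              "k_s": [0.1, -0.2, 0.3]})
        with pytest.raises(est.FitError):
            est.fit_arrhenius(table)


class TestTwoStateMelt:
    def test_noiseless_round_trip(self):
        ds = generate(GeneratorSpec("melt_curve", noise_sd=0.0, seed=0))
        fit = est.fit_two_state_melt(ds.data)
        assert fit.T_m_celsius == pytest.approx(49.9, abs=1e-6)
        assert fit.dH == pytest.approx(3e5, rel=1e-5)

    def test_midpoint_signal_is_baseline_average(self):
        """At T = T_m half the molecules are unfolded, so the signal sits
        midway between the two baselines."""
        from phypif.estimators import melt_signal
        tm = 323.05
        val = melt_signal(np.array([tm]), 3e5, tm, -20.0, 0.01, -5.0, 0.0)
        folded = -20.0 + 0.01 * tm
        unfolded = -5.0
        assert val[0] == pytest.approx(0.5 * (folded + unfolded))

    def test_no_transition_flagged(self):
        T = np.linspace(288.0, 363.0, 40)
        table = pd.DataFrame({"T_K": T, "signal": -10 + 0.001 * T})
        fit = est.fit_two_state_melt(table)
        assert "no-transition" in fit.flags

    def test_noisy_recovery_precision(self):
        tms = []
        for seed in range(20):
            ds = generate(GeneratorSpec("melt_curve", noise_sd=0.01,
                                        seed=seed))
            tms.append(est.fit_two_state_melt(ds.data).T_m_celsius)
        tms = np.array(tms)
        assert np.mean(tms) == pytest.approx(49.9, abs=0.1)
        # scatter comparable to the ~0.2 C experimental uncertainty
        assert np.std(tms) < 0.2


@pytest.fixture(scope="module")
def four_intensity_traces():
    traces = {}
    for i, inten in enumerate((1.0, 10.0, 30.0, 69.0)):
        ds = generate(GeneratorSpec(
            "association_trace", noise_sd=0.01, seed=50 + i,
            params={"intensity_mW_cm2": inten, "pulse_s": 20.0,
                    "t_max_s": 40.0}))
        traces[inten] = ds.data
    return traces


class TestGlobalFit:

    def test_four_intensity_parameter_recovery(self, four_intensity_traces,
                                               standard_composition):
        """The shared-parameter ODE fit across 1/10/30/69 mW cm^-2
        recovers all four rate parameters within 10% from a start
        displaced by factors of 2-3."""
        truth = PRESETS["P6A"]
        init = RateConstants.from_calibration(
            total_rate=7.0, k_aFR=3e5, k_dFR=0.3, k_dR=1.0)
        res = est.global_fit_interaction(
            four_intensity_traces, init, standard_composition,
            light_duration=20.0)
        assert res.success
        assert res.k_p_ref == pytest.approx(7.3, rel=0.10)
        assert res.k_aFR == pytest.approx(truth.k_aFR, rel=0.10)
        assert res.k_dFR == pytest.approx(truth.k_dFR, rel=0.10)
        assert res.k_dR == pytest.approx(truth.k_dR, rel=0.10)

    def test_conventional_model_fails_on_attenuated_data(
            self, four_intensity_traces, standard_composition):
        """The reduced scheme without photoconversion of the bound
        complex cannot reproduce the fluence-dependent attenuation: its
        residuals are an order of magnitude larger."""
        init = RateConstants.from_calibration(
            total_rate=7.0, k_aFR=3e5, k_dFR=0.3, k_dR=1.0)
        full = est.global_fit_interaction(
            four_intensity_traces, init, standard_composition,
            light_duration=20.0)
        reduced = est.global_fit_interaction(
            four_intensity_traces, init, standard_composition,
            light_duration=20.0, model="conventional")
        assert reduced.rss >= 10.0 * full.rss

    def test_attenuation_free_data_yield_small_kdr(self,
                                                   standard_composition):
        """Data generated without Pr-state dissociation show no
        fluence-dependent amplitude loss and fit with k_dR near zero.

        k_dR is identified only through the attenuation it would cause,
        so on attenuation-free data the estimate is limited by the noise
        floor; it must land an order of magnitude below the 2.5 s^-1
        recovered from attenuated data."""
        traces = {}
        for i, inten in enumerate((1.0, 10.0, 69.0)):
            ds = generate(GeneratorSpec(
                "association_trace", noise_sd=0.005, seed=80 + i,
                params={"intensity_mW_cm2": inten, "pulse_s": 20.0,
                        "t_max_s": 30.0, "k_dR": 0.0}))
            traces[inten] = ds.data
        init = RateConstants.from_calibration(
            total_rate=10.0, k_aFR=6e5, k_dFR=0.1, k_dR=0.5)
        res = est.global_fit_interaction(
            traces, init, standard_composition, light_duration=20.0)
        assert res.k_dR < 0.25  # vs 2.5 when attenuation is present


class TestAssociationSeries:
    def test_noiseless_series_recovers_corrected_rate(self):
        traces = {}
        for conc in (500e-9, 1000e-9, 1500e-9, 2000e-9):
            ds = generate(GeneratorSpec(
                "association_trace", noise_sd=0.0, seed=0,
                params={"receptor_M": conc, "pulse_s": 0.5,
                        "t_max_s": 20.0}))
            traces[conc] = ds.data
        fit = est.fit_association_series(traces, pfr_fraction=0.73)
        assert fit.k_a_corrected == pytest.approx(6.1e5, rel=0.08)
        assert fit.K_d == pytest.approx(183e-9, rel=0.25)
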