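"""Restricted/repetitive-behaviour submodels: entropy-driven stereotypies,
bout process, sameness distress, interests and cumulative sensory load."""

import dataclasses
import math

import numpy as np
import pytest
from scipy.integrate import quad

from asdyn import (EntropySignal, InterestParams, InterestTerm, MovementParams,
                   RoutineParams, SensoryStimulusParams, cumulative_impact,
                   deviation_distress, effective_amplitude,
                   equifinality_profiles, habituation_rate, interest_engagement,
                   movement_intensity, simulate_bouts, total_sameness,
                   total_sensory_load)


class TestEffectiveAmplitude:
    def test_zero_entropy_silences(self):
        assert effective_amplitude(MovementParams(), 0.0) == 0.0

    def test_half_saturation(self):
        p = MovementParams(Gamma_max=0.8, k_H=2.5)
        assert effective_amplitude(p, 2.5) == pytest.approx(0.4, abs=1e-14)

    def test_hand_evaluation_with_engagement(self):
        p = MovementParams(Gamma_max=1.0, k_H=2.0, k_engage=1.0)
        assert effective_amplitude(p, 6.0, E_engage=0.5) == pytest.approx(0.5, abs=1e-14)

    def test_saturation_limit(self):
        p = MovementParams(Gamma_max=1.3, k_H=2.0, k_engage=0.7, k_alt=0.4)
        E, Phi = 0.5, 0.3
        limit = p.Gamma_max / (1 + p.k_engage * E + p.k_alt * Phi)
        # deficit from the limit is Gamma * k_H/(H + k_H), so ~1e-6 relative
        # at H = 1e6 k_H and below 1e-9 absolute by H = 1e10 k_H
        assert effective_amplitude(p, 1e6 * p.k_H, E, Phi) == pytest.approx(limit, rel=2e-6)
        assert effective_amplitude(p, 1e10 * p.k_H, E, Phi) == pytest.approx(limit, abs=1e-9)

    def test_negative_entropy_rejected(self):
        with pytest.raises(ValueError):
            effective_amplitude(MovementParams(), -1.0)


class TestMovementIntensity:
    def test_zero_amplitude_returns_baseline(self):
        p = MovementParams(M0=0.7, Gamma_max=0.0)
        sig = EntropySignal.constant(np.linspace(0, 2, 10), 4.0)
        assert movement_intensity(p, sig, 1.3) == pytest.approx(0.7)

    def test_sine_maximum(self):
        p = MovementParams(M0=0.5, Gamma_max=1.0, k_H=2.0, omega=math.pi, phi=0.0)
        sig = EntropySignal.constant(np.linspace(0, 2, 100), 2.0)  # Gamma_eff = 0.5
        assert movement_intensity(p, sig, 0.5) == pytest.approx(0.5 + 0.5, abs=1e-12)

    def test_mean_over_period_is_baseline(self):
        p = MovementParams(M0=0.6, Gamma_max=1.0, k_H=2.0, omega=2 * math.pi, phi=0.3)
        t = np.linspace(0, 1, 4001)  # one period
        sig = EntropySignal.constant(t, 3.0)
        m = movement_intensity(p, sig, t)
        assert np.trapezoid(m, t) == pytest.approx(0.6, abs=1e-6)


class TestBoutProcess:
    def test_zero_rate_yields_empty_sequence(self):
        sig = EntropySignal.constant(np.linspace(0, 10, 11), 3.0)
        bouts = simulate_bouts(MovementParams(), sig, rate_scale=0.0, seed=1)
        assert len(bouts) == 0

    def test_seed_determinism(self):
        sig = EntropySignal.constant(np.linspace(0, 20, 21), 4.0)
        b1 = simulate_bouts(MovementParams(), sig, 3.0, seed=7)
        b2 = simulate_bouts(MovementParams(), sig, 3.0, seed=7)
        assert np.array_equal(b1.onsets, b2.onsets)
        assert np.array_equal(b1.durations, b2.durations)

    def test_homogeneous_mean_count_matches_poisson(self):
        # constant entropy H = k_H makes lambda = rate_scale / 2; pick 2 /h over 50 h
        p = MovementParams(k_H=2.0)
        sig = EntropySignal.constant(np.linspace(0, 50, 51), 2.0)
        counts = [len(simulate_bouts(p, sig, 4.0, seed=s)) for s in range(200)]
        expected = 2.0 * 50
        se = math.sqrt(expected / 200)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_rate_ratio_tracks_entropy(self):
        p = MovementParams(k_H=2.0)
        t = np.linspace(0, 50, 51)
        n1 = np.mean([len(simulate_bouts(p, EntropySignal.constant(t, 1.0), 3.0, seed=s))
                      for s in range(200)])
        n2 = np.mean([len(simulate_bouts(p, EntropySignal.constant(t, 6.0), 3.0, seed=s))
                      for s in range(200)])
        ratio_expected = (1.0 / 3.0) / (6.0 / 8.0)
        assert n1 / n2 == pytest.approx(ratio_expected, rel=0.1)

    def test_bouts_do_not_overlap(self):
        sig = EntropySignal.constant(np.linspace(0, 30, 31), 5.0)
        b = simulate_bouts(MovementParams(), sig, 5.0,
                           duration_dist={"kind": "exponential", "scale": 0.5}, seed=3)
        ends = b.onsets + b.durations
        assert np.all(ends[:-1] <= b.onsets[1:] + 1e-12)

    def test_bad_duration_spec_rejected(self):
        sig = EntropySignal.constant(np.linspace(0, 10, 11), 3.0)
        with pytest.raises(ValueError):
            simulate_bouts(MovementParams(), sig, 1.0,
                           duration_dist={"kind": "lognormal", "sd_log": -1}, seed=0)


class TestSamenessDistress:
    def test_midpoint_at_threshold(self):
        r = RoutineParams(s_max=0.9, theta=0.3)
        assert deviation_distress(r, 0.3) == pytest.approx(0.45, abs=1e-12)

    def test_asymptote(self):
        r = RoutineParams(s_max=0.7, r_base=5.0, pi_precision=2.0)
        assert deviation_distress(r, 1e6) == pytest.approx(0.7, abs=1e-12)

    def test_steepness_calibration_by_bisection(self):
        # solve for the baseline steepness giving distress 0.85 at deviation 0.6
        lo, hi = 1e-6, 100.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            r = RoutineParams(s_max=0.9, r_base=mid, pi_precision=4.0, theta=0.3)
            if deviation_distress(r, 0.6) < 0.85:
                lo = mid
            else:
                hi = mid
        assert lo == pytest.approx(2.36, abs=0.01)
        r = RoutineParams(s_max=0.9, r_base=lo, pi_precision=4.0, theta=0.3)
        assert deviation_distress(r, 0.6) == pytest.approx(0.85, abs=1e-6)

    def test_monotone_in_deviation_precision_and_severity(self, rng):
        for _ in range(50):
            r = RoutineParams(s_max=rng.uniform(0.3, 1), r_base=rng.uniform(0.5, 5),
                              pi_precision=rng.uniform(0.5, 5), theta=rng.uniform(0.1, 0.5))
            d = rng.uniform(r.theta + 0.01, 2.0)
            assert deviation_distress(r, d + 0.05) > deviation_distress(r, d)
            steeper = dataclasses.replace(r, pi_precision=r.pi_precision * 2)
            assert deviation_distress(steeper, d) > deviation_distress(r, d)
            bigger = dataclasses.replace(r, s_max=r.s_max * 1.5)
            assert deviation_distress(bigger, d) > deviation_distress(r, d)

    def test_midpoint_slope_is_analytic(self):
        r = RoutineParams(s_max=0.8, r_base=3.0, pi_precision=2.0, theta=0.4)
        h = 1e-6
        slope = (deviation_distress(r, 0.4 + h) - deviation_distress(r, 0.4 - h)) / (2 * h)
        assert slope == pytest.approx(0.8 * 6.0 / 4, rel=1e-6)


class TestTotalSameness:
    def test_singleton_reduces_to_single_routine(self):
        r = RoutineParams()
        assert total_sameness([r], [0.7]) == pytest.approx(deviation_distress(r, 0.7))

    def test_no_deviation_floor(self):
        routines = [RoutineParams(s_max=0.9, r_base=5.0, pi_precision=2.0, theta=0.3),
                    RoutineParams(s_max=0.5, r_base=8.0, pi_precision=2.0, theta=0.2)]
        expected = sum(r.s_max / (1 + math.exp(r.r_base * r.pi_precision * r.theta))
                       for r in routines)
        got = total_sameness(routines, [r.x_expected for r in routines])
        assert got == pytest.approx(expected, abs=1e-12)
        assert got < 0.1  # near zero for steep curves

    def test_permutation_invariance(self):
        routines = [RoutineParams(s_max=0.9), RoutineParams(s_max=0.4, theta=0.1)]
        states = [0.5, 0.2]
        assert total_sameness(routines, states) == pytest.approx(
            total_sameness(routines[::-1], states[::-1]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            total_sameness([RoutineParams()], [0.1, 0.2])


class TestEquifinality:
    @pytest.mark.parametrize("target,ref", [(0.5, 0.4), (0.85, 0.6), (0.3, 1.0)])
    def test_three_routes_hit_anchor_and_differ_off_anchor(self, target, ref):
        routes = equifinality_profiles(target, ref)
        assert len(routes) == 3
        vals_half = []
        for r in routes:
            assert deviation_distress(r, ref) == pytest.approx(target, abs=1e-6)
            vals_half.append(deviation_distress(r, ref / 2))
        assert max(vals_half) - min(vals_half) > 1e-3  # distinct response curves

    def test_vignette_regime_present(self):
        routes = equifinality_profiles(0.85, 0.6)
        precisions = {r.label: r.pi_precision for r in routes}
        assert precisions["high_precision"] > precisions["low_threshold"]

    def test_infeasible_target_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            equifinality_profiles(1.2, 0.6)


class TestInterestEngagement:
    def test_fresh_interest_adds_full_intensity(self):
        p = InterestParams(I0=0.3, interests=[InterestTerm(b_base=0.5, R_int=2.0, R_norm=1.0)])
        assert interest_engagement(p, 0.0) == pytest.approx(0.3 + 1.0, abs=1e-12)

    def test_perfect_prediction_never_decays(self):
        p = InterestParams(I0=0.1, interests=[InterestTerm(b_base=0.6, P_acc=1.0)])
        assert interest_engagement(p, 500.0) == pytest.approx(0.1 + 0.6, abs=1e-12)

    def test_direct_evaluation(self):
        p = InterestParams(I0=0.2, interests=[InterestTerm(
            b_base=0.8, R_int=1.0, R_norm=1.0, lambda_base=0.2, P_acc=0.5)])
        expected = 0.2 + 0.8 * math.exp(-1.0)  # lambda = 0.1, dt = 10
        assert interest_engagement(p, 10.0) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.49430, abs=5e-6)

    def test_decays_to_floor(self):
        p = InterestParams(I0=0.25, interests=[InterestTerm(lambda_base=0.5, P_acc=0.0)])
        assert interest_engagement(p, 1e4) == pytest.approx(0.25, abs=1e-12)

    def test_unacquired_interest_contributes_nothing(self):
        p = InterestParams(I0=0.2, interests=[InterestTerm(t_acquired=24.0)])
        assert interest_engagement(p, 12.0) == pytest.approx(0.2)


class TestHabituationRate:
    def test_identity_case(self):
        p = SensoryStimulusParams(delta_base=0.1, gaba_ratio=1.0, k_sens=0.5)
        assert habituation_rate(p, 0.0) == pytest.approx(0.1)

    def test_sensitisation_regime(self):
        p = SensoryStimulusParams(delta_base=0.1, gaba_ratio=0.5, k_sens=0.2)
        assert habituation_rate(p, 0.5) == pytest.approx(-0.05, abs=1e-14)

    def test_non_increasing_in_arousal(self):
        p = SensoryStimulusParams(delta_base=0.2, k_sens=0.3)
        xs = np.linspace(0, 2, 20)
        rates = habituation_rate(p, xs)
        assert np.all(np.diff(rates) <= 0)


class TestCumulativeImpact:
    def test_empty_exposure(self):
        assert cumulative_impact(0.9, 0.4, 0.0) == 0.0

    def test_habituation_failure_is_linear(self):
        # the worked scenario's arithmetic: 0.8 * 90 = 72
        assert cumulative_impact(0.8, 0.0, 90.0) == pytest.approx(72.0, abs=1e-12)
        assert cumulative_impact(0.8, 0.0, 45.0) == pytest.approx(36.0, abs=1e-12)

    def test_closed_forms(self):
        assert cumulative_impact(1.0, 0.5, 2.0) == pytest.approx(2 * (1 - math.exp(-1)), abs=1e-12)
        assert cumulative_impact(0.5, -0.2, 3.0) == pytest.approx(2.5 * (math.exp(0.6) - 1), abs=1e-12)

    def test_quadrature_oracle(self):
        for sigma in (0.1, 0.8, 2.0):
            for delta in (-0.5, -0.1, 0.0, 0.1, 0.5):
                for T in (0.5, 2.0, 10.0):
                    ref, _ = quad(lambda t: sigma * math.exp(-delta * t), 0, T,
                                  epsabs=1e-13, epsrel=1e-13)
                    assert cumulative_impact(sigma, delta, T) == pytest.approx(ref, abs=1e-8)

    def test_regime_ordering_and_bound(self):
        sigma, T = 0.7, 4.0
        p_neg = cumulative_impact(sigma, -0.3, T)
        p_zero = cumulative_impact(sigma, 0.0, T)
        p_pos = cumulative_impact(sigma, 0.3, T)
        assert p_neg > p_zero > p_pos
        assert cumulative_impact(sigma, 0.3, 1e6) <= sigma / 0.3 + 1e-9

    def test_branch_continuity(self):
        eps = 1e-8
        for sigma in (0.1, 1.0, 3.0):
            for T in (0.5, 5.0, 50.0):
                p0 = cumulative_impact(sigma, 0.0, T)
                above = cumulative_impact(sigma, eps * (1 + 1e-3), T)
                below = cumulative_impact(sigma, -eps * (1 + 1e-3), T)
                assert abs(above - p0) < 1e-6 * sigma * T
                assert abs(below - p0) < 1e-6 * sigma * T

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            cumulative_impact(1.0, 0.1, -1.0)


class TestTotalSensoryLoad:
    def test_empty_and_singleton_and_additivity(self):
        assert total_sensory_load([]) == 0.0
        p = SensoryStimulusParams(sigma=0.6, delta_base=0.1)
        one = total_sensory_load([(p, 2.0, 0.0)])
        assert one == pytest.approx(cumulative_impact(0.6, 0.1, 2.0))
        assert total_sensory_load([(p, 2.0, 0.0)] * 2) == pytest.approx(2 * one)

    def test_lagged_arousal_enters_rate(self):
        p = SensoryStimulusParams(sigma=0.6, delta_base=0.1, k_sens=0.4)
        calm = total_sensory_load([(p, 3.0, 0.0)])
        aroused = total_sensory_load([(p, 3.0, 1.0)])
        assert aroused > calm  # arousal impairs habituation
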