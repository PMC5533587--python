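"""Survival estimator, bi-exponential fit, classification, association, bleaching."""

import dataclasses

import numpy as np
import pytest

from slbkin.survival_stats import (
    SurvivalCurve,
    classify_modes,
    compute_survival,
    estimate_association,
    fit_biexponential,
    fit_bleaching,
)
from slbkin.synthetic_trajectories import (
    GroundTruthKinetics,
    ImagingConfig,
    TrajectorySet,
    simulate_trajectories,
)
from conftest import make_set, make_trajectory
from oracles import survival_window_enumeration


def synth_curve(times, p1, k1, k2, dt=0.02):
    t = np.asarray(times, dtype=float)
    p = p1 * np.exp(-k1 * t) + (1 - p1) * np.exp(-k2 * t)
    lags = np.arange(1, len(t) + 1)
    return SurvivalCurve(
        lags=lags, times=t, p_survival=p,
        n_windows=np.full(len(t), 100), n_start=np.array([]), dt=dt,
    )


class TestComputeSurvival:
    def test_empty_set_rejected(self):
        ts = make_set([])
        with pytest.raises(ValueError):
            compute_survival(ts)

    def test_jmax_beyond_movie_truncated_with_warning(self):
        ts = make_set([(1, 5)], n_frames=10)
        with pytest.warns(UserWarning):
            curve = compute_survival(ts, j_max=50)
        assert curve.lags.max() <= 10

    def test_full_movie_trajectory_survives_every_lag(self):
        m = 20
        ts = make_set([(1, m)], n_frames=m)
        curve = compute_survival(ts)
        np.testing.assert_allclose(curve.p_survival, 1.0)
        assert len(curve.lags) == m

    def test_single_frame_trajectories_drop_at_lag_two(self):
        ts = make_set([(3, 1), (7, 1), (9, 1)], n_frames=12)
        curve = compute_survival(ts)
        assert curve.p_survival[0] == 1.0
        assert curve.p_survival[1] == 0.0

    def test_hand_built_example_matches_enumeration(self):
        starts, lengths, m = [1, 3, 5], [2, 4, 1], 8
        ts = make_set(list(zip(starts, lengths)), n_frames=m)
        curve = compute_survival(ts)
        expected = survival_window_enumeration(starts, lengths, m)
        mask = ~np.isnan(expected)
        got = np.full(m, np.nan)
        got[curve.lags - 1] = curve.p_survival
        np.testing.assert_allclose(got[mask], expected[mask], atol=1e-12)

    def test_random_instances_match_enumeration_oracle(self):
        # the estimator must agree with brute-force window enumeration on
        # random small movies (200 cases)
        rng = np.random.default_rng(1234)
        for _ in range(200):
            m = int(rng.integers(3, 51))
            n = int(rng.integers(1, 21))
            starts = rng.integers(1, m + 1, size=n)
            lengths = np.minimum(
                rng.integers(1, m + 1, size=n), m - starts + 1
            )
            ts = make_set(list(zip(starts, lengths)), n_frames=m)
            curve = compute_survival(ts)
            expected = survival_window_enumeration(starts, lengths, m)
            got = np.full(m, np.nan)
            got[curve.lags - 1] = curve.p_survival
            mask = ~np.isnan(expected)
            np.testing.assert_allclose(got[mask], expected[mask], atol=1e-12)
            assert np.all(np.isnan(got[~mask]))

    def test_lag_one_is_exactly_one_and_curve_monotone_early(self):
        ts = make_set([(1, 10), (4, 6), (8, 3), (2, 2)], n_frames=16)
        curve = compute_survival(ts)
        assert curve.p_survival[0] == 1.0
        assert curve.times[0] == 0.0
        assert np.all(curve.p_survival >= 0) and np.all(curve.p_survival <= 1)

    def test_pooled_movies_equal_concatenated_counts(self):
        a = make_set([(1, 5), (3, 8)], n_frames=20)
        b = make_set([(2, 4), (10, 6)], n_frames=20)
        pooled = compute_survival([a, b])
        merged = make_set([(1, 5), (3, 8), (2, 4), (10, 6)], n_frames=20)
        single = compute_survival(merged)
        np.testing.assert_allclose(pooled.p_survival, single.p_survival)


class TestBiExponentialFit:
    def test_too_short_curve_rejected(self):
        curve = synth_curve(np.arange(5) * 0.02, 0.5, 5.0, 0.5)
        with pytest.raises(ValueError):
            fit_biexponential(curve)

    def test_degenerate_single_exponential_recovered(self):
        t = np.arange(0, 10, 0.02)
        curve = synth_curve(t, 1.0, 2.0, 0.1)  # P2 = 0: pure k = 2
        fit = fit_biexponential(curve)
        assert fit.P1 == pytest.approx(1.0, abs=1e-6)
        assert fit.fast_rate == pytest.approx(2.0, abs=1e-6)
        assert fit.effectively_single

    def test_noiseless_mixture_round_trip(self):
        t = np.arange(0.02, 20.0, 0.02)
        curve = synth_curve(t, 0.9, 14.0, 0.081)
        fit = fit_biexponential(curve, min_window_support=0.0)
        assert fit.P1 == pytest.approx(0.9, rel=1e-4)
        assert fit.k_off1 == pytest.approx(14.0, rel=1e-4)
        assert fit.k_off2 == pytest.approx(0.081, rel=1e-4)
        assert not fit.effectively_single

    def test_scale_equivariance(self):
        t = np.arange(0.02, 20.0, 0.02)
        c = 4.0
        fit_a = fit_biexponential(synth_curve(t, 0.7, 8.0, 0.2))
        fit_b = fit_biexponential(synth_curve(t * c, 0.7, 8.0 / c, 0.2 / c, dt=0.02 * c))
        assert fit_b.k_off1 == pytest.approx(fit_a.k_off1 / c, rel=1e-6)
        assert fit_b.k_off2 == pytest.approx(fit_a.k_off2 / c, rel=1e-6)

    def test_slow_rate_near_window_limit_flagged(self):
        t = np.arange(0.02, 5.0, 0.02)
        curve = synth_curve(t, 0.6, 10.0, 0.1)  # 1/t_max = 0.2 > 0.1
        fit = fit_biexponential(curve)
        assert fit.k_off2_near_window_limit

    def test_fast_rate_unbiased_when_resolved_by_frame_rate(self):
        # k_off1 * dt = 0.2 < 0.5: recovery bias must stay below 5%
        truth = GroundTruthKinetics(
            k1=30.0, k_off1=10.0, k2=0.0, k_off2=0.0, f1=1.0, f2=0.0
        )
        cfg = ImagingConfig(seed=77, n_frames=5000, dt=0.02, bleach_rate=0.0)
        ts = simulate_trajectories(truth, cfg)
        fit = fit_biexponential(compute_survival(ts))
        assert abs(fit.fast_rate - 10.0) / 10.0 < 0.05


class TestClassification:
    def test_lifetimes_straddling_cutoff(self):
        cfg = ImagingConfig(seed=0, dt=0.02, n_frames=100)
        short = make_trajectory(0, 1, 5)    # 0.10 s -> Dynamic
        long = make_trajectory(1, 1, 50)    # 1.0 s -> Stable
        pops = classify_modes(TrajectorySet([short, long], cfg), cutoff=0.25)
        assert pops.P1 == pytest.approx(0.5)
        assert pops.n_total == 2

    def test_tie_at_cutoff_counts_as_dynamic(self):
        cfg = ImagingConfig(seed=0, dt=0.01, n_frames=100)
        tie = make_trajectory(0, 1, 25)  # exactly 0.25 s
        pops = classify_modes(TrajectorySet([tie], cfg), cutoff=0.25)
        assert pops.P1 == 1.0

    def test_empty_set_rejected(self):
        cfg = ImagingConfig(seed=0, n_frames=100)
        with pytest.raises(ValueError):
            classify_modes(TrajectorySet([], cfg))

    def test_classifier_tracks_truth_labels(self):
        # 92% Dynamic arrivals, well-separated dwells: classified fraction
        # within 3 percentage points of the truth-label fraction
        truth = GroundTruthKinetics(
            k1=4.5, k_off1=14.0, k2=0.45, k_off2=0.081, f1=23 / 43, f2=20 / 43, conc=5.0
        )
        cfg = ImagingConfig(seed=42, n_frames=2000, bleach_rate=0.0)
        ts = simulate_trajectories(truth, cfg)
        truth_frac = np.mean([tr.arrival_mode == "Dynamic" for tr in ts])
        pops = classify_modes(ts, cutoff=0.25)
        assert abs(pops.P1 - truth_frac) < 0.03

    def test_stable_fraction_monotone_in_generator_mix(self):
        # sweep the Stable arrival share: classified P2 must not decrease
        p2s = []
        for f2 in (0.05, 0.25, 0.5, 0.75, 0.95):
            f1 = 1 - f2
            truth = GroundTruthKinetics(
                k1=2.0, k_off1=14.0, k2=2.0, k_off2=0.081, f1=f1, f2=f2, conc=5.0
            )
            cfg = ImagingConfig(seed=99, n_frames=2000, bleach_rate=0.0)
            pops = classify_modes(simulate_trajectories(truth, cfg), cutoff=0.25)
            p2s.append(pops.P2)
        assert all(b > a for a, b in zip(p2s, p2s[1:]))


class TestAssociation:
    @staticmethod
    def poisson_set(rate_per_s, seed, n_frames=2000, dt=0.02, lifetime_frames=3):
        rng = np.random.default_rng(seed)
        T = n_frames * dt
        n = rng.poisson(rate_per_s * T)
        starts = np.sort(rng.integers(1, n_frames + 1, size=n))
        cfg = ImagingConfig(seed=seed, dt=dt, n_frames=n_frames)
        trajs = [
            make_trajectory(i, int(s), min(lifetime_frames, n_frames - int(s) + 1))
            for i, s in enumerate(starts)
        ]
        return TrajectorySet(trajs, cfg)

    def test_homogeneous_poisson_slope_recovered(self):
        ts = self.poisson_set(5.0, seed=5)
        rates = estimate_association(ts, conc=1.0)
        n = len(ts)
        se = np.sqrt(n) / (ts.config.n_frames * ts.config.dt)  # Poisson count error
        assert abs(rates.k1_app - 5.0) < 3 * se
        assert not rates.k1_wide_error

    def test_no_stable_arrivals_flagged(self):
        ts = self.poisson_set(5.0, seed=6, lifetime_frames=2)
        rates = estimate_association(ts, conc=1.0)
        assert rates.k2_app == 0.0
        assert rates.k2_wide_error

    def test_concentration_normalization(self):
        # doubling conc at fixed truth leaves k_app unchanged within error
        truth = GroundTruthKinetics(
            k1=4.0, k_off1=5.0, k2=0.4, k_off2=0.1, f1=0.9, f2=0.1, conc=1.0
        )
        cfg = ImagingConfig(seed=13, n_frames=2000)
        r1 = estimate_association(simulate_trajectories(truth, cfg), conc=1.0)
        truth2 = dataclasses.replace(truth, conc=2.0)
        cfg2 = ImagingConfig(seed=14, n_frames=2000)
        r2 = estimate_association(simulate_trajectories(truth2, cfg2), conc=2.0)
        tol = 3 * np.hypot(r1.slope_se[0], r2.slope_se[0]) + 0.05 * r1.k1_app
        assert abs(r1.k1_app - r2.k1_app) < tol

    def test_positive_concentration_required(self):
        ts = self.poisson_set(5.0, seed=7)
        with pytest.raises(ValueError):
            estimate_association(ts, conc=0.0)


class TestBleaching:
    def test_exact_decay_round_trip(self):
        t = np.arange(0, 400.0, 1.0)
        res = fit_bleaching(t, 100.0 * np.exp(-0.005 * t))
        assert res.bleach_rate == pytest.approx(0.005, abs=1e-6)

    def test_noisy_decay_within_five_percent(self, rng):
        t = np.arange(0, 400.0, 1.0)
        y = 100.0 * np.exp(-0.005 * t) * (1 + rng.normal(0, 0.01, len(t)))
        res = fit_bleaching(t, y)
        assert res.bleach_rate == pytest.approx(0.005, rel=0.05)

    def test_constant_trace_means_no_bleaching(self):
        t = np.arange(0, 100.0, 1.0)
        res = fit_bleaching(t, np.full(len(t), 7.0))
        assert res.bleach_rate == 0.0

    def test_increasing_trace_rejected(self):
        t = np.arange(0, 100.0, 1.0)
        with pytest.raises(ValueError):
            fit_bleaching(t, 1.0 + 0.01 * t)

    def test_ratio_against_slow_dissociation(self):
        t = np.arange(0, 400.0, 1.0)
        curve_t = np.arange(0.02, 20.0, 0.02)
        fit = fit_biexponential(synth_curve(curve_t, 0.9, 14.0, 0.081))
        res = fit_bleaching(t, np.exp(-0.005 * t), biexp=fit)
        assert res.ratio_to_koff2 == pytest.approx(0.005 / fit.k_off2, rel=1e-6)
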