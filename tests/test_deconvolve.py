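"""FFBS deconvolution: exact conditional path sampling and interval statistics."""

import numpy as np
import pytest
from scipy.linalg import expm

from promcycle.model import PromoterCycleModel
from promcycle.likelihood import (LatticeTruncation, build_propagator,
                                  choose_truncation, dataset_loglikelihood,
                                  stationary_lattice_distribution)
from promcycle.deconvolve import (deconvolve_dataset, ffbs_sample,
                                  interval_statistics, TrajectoryPosterior)
from promcycle.noise import stationary_mrna_distribution
from promcycle.simulate import (CalibrationModel, generate_cohort,
                                sample_trace, simulate_ssa)


@pytest.fixture(scope="module")
def pin_model():
    """Fast, high-copy protein so a noiseless signal identifies p exactly."""
    return PromoterCycleModel(1, (1 / 45.0,), off_rate=1 / 8, k_m=0.3,
                              k_p=2.0, gamma_m=0.05, gamma_p=1.0)


class TestFFBS:
    def test_noiseless_signal_pins_protein_path(self, small_model,
                                                noiseless_calibration):
        traj = simulate_ssa(small_model, 300.0, seed=60)
        sig = sample_trace(traj, 5.0, noiseless_calibration, seed=61)
        trunc = choose_truncation(small_model, 1e-4)
        g, m, p = ffbs_sample(sig, 5.0, small_model, noiseless_calibration,
                              trunc, seed=62, n_draws=3)
        assert np.all(p == sig[None, :].astype(int))

    def test_path_frequencies_match_enumerated_conditional(self):
        """10^4 draws on a 3-step trace vs the exhaustively summed conditional."""
        model = PromoterCycleModel(1, (1 / 45.0,), off_rate=1 / 8, k_m=0.2,
                                   k_p=0.1, gamma_m=0.1, gamma_p=0.5)
        trunc = LatticeTruncation(m_max=1, p_max=1, eps=1e-2)
        calib = CalibrationModel(var_floor=0.25)
        prop = build_propagator(model, 5.0, trunc)
        stationary = stationary_lattice_distribution(prop)
        signal = np.array([0.2, 0.9, 0.1])
        n = prop.n
        P = prop.P
        pe = np.stack([np.exp(calib.log_emission(s, np.arange(2)))
                       for s in signal])[:, prop.p_of_state]
        # exhaustive joint over all n^3 paths
        joint = {}
        for x0 in range(n):
            for x1 in range(n):
                for x2 in range(n):
                    w = (stationary[x0] * pe[0, x0] * P[x0, x1] * pe[1, x1]
                         * P[x1, x2] * pe[2, x2])
                    if w > 0:
                        joint[(x0, x1, x2)] = w
        Z = sum(joint.values())
        n_draws = 10_000
        g, m, p = ffbs_sample(signal, 5.0, model, calib, trunc, seed=63,
                              propagator=prop, stationary=stationary,
                              n_draws=n_draws)
        nM, nP = trunc.m_max + 1, trunc.p_max + 1
        states = (g * nM + m) * nP + p
        counts = {}
        for path in map(tuple, states):
            counts[path] = counts.get(path, 0) + 1
        for path, w in joint.items():
            prob = w / Z
            if prob < 5e-4:
                continue
            se = np.sqrt(prob * (1 - prob) / n_draws)
            freq = counts.get(path, 0) / n_draws
            assert abs(freq - prob) < 4 * se + 1e-3

    def test_seeds_differ_but_marginals_agree(self, small_model,
                                              noisy_calibration):
        traj = simulate_ssa(small_model, 400.0, seed=64)
        sig = sample_trace(traj, 5.0, noisy_calibration, seed=65)
        trunc = choose_truncation(small_model, 1e-3)
        prop = build_propagator(small_model, 5.0, trunc)
        stationary = stationary_lattice_distribution(prop)
        g1, _, _ = ffbs_sample(sig, 5.0, small_model, noisy_calibration, trunc,
                               seed=1, propagator=prop, stationary=stationary,
                               n_draws=400)
        g2, _, _ = ffbs_sample(sig, 5.0, small_model, noisy_calibration, trunc,
                               seed=2, propagator=prop, stationary=stationary,
                               n_draws=400)
        assert not np.array_equal(g1, g2)
        p_on1 = (g1 == 0).mean(axis=0)
        p_on2 = (g2 == 0).mean(axis=0)
        assert np.abs(p_on1 - p_on2).max() < 0.12  # ~4 sigma at 400 draws


@pytest.fixture(scope="module")
def cohort_posterior(small_model, noisy_calibration):
    ds = generate_cohort(small_model, n_cells=16, duration=1440.0, dt=5.0,
                         calibration=noisy_calibration, seed=66)
    post = deconvolve_dataset(ds, small_model, noisy_calibration,
                              n_samples=40, seed=67)
    return ds, post


class TestDeconvolveDataset:
    def test_pooled_mrna_histogram_matches_stationary_law(self, small_model,
                                                          cohort_posterior):
        _, post = cohort_posterior
        pooled = post.pooled_mrna_histogram()
        pmf = stationary_mrna_distribution(small_model)
        k = min(len(pooled), len(pmf))
        tv = 0.5 * (np.abs(pooled[:k] - pmf[:k]).sum()
                    + pooled[k:].sum() + pmf[k:].sum())
        assert tv < 0.05

    def test_activity_fraction_matches_duty_cycle(self, small_model,
                                                  cohort_posterior):
        _, post = cohort_posterior
        expected = small_model.tau_a / (small_model.tau_a
                                        + small_model.silent_period)
        assert post.activity_fraction() == pytest.approx(expected, abs=0.03)

    def test_single_sample_gives_one_path_per_cell(self, small_model,
                                                   noisy_calibration):
        ds = generate_cohort(small_model, n_cells=2, duration=200.0, dt=5.0,
                             calibration=noisy_calibration, seed=68)
        post = deconvolve_dataset(ds, small_model, noisy_calibration,
                                  n_samples=1, seed=69)
        assert all(g.shape[0] == 1 for g in post.g_paths)

    def test_shared_propagator_reproduces_likelihood(self, small_model,
                                                     noisy_calibration,
                                                     cohort_posterior):
        """Filter/smoother consistency: the posterior's propagator is the
        likelihood's operator."""
        ds, post = cohort_posterior
        trunc = post.propagator.trunc
        stationary = stationary_lattice_distribution(post.propagator)
        ll_shared = dataset_loglikelihood(ds, small_model, noisy_calibration,
                                          trunc, post.propagator, stationary)
        ll_fresh = dataset_loglikelihood(ds, small_model, noisy_calibration,
                                         trunc)
        assert ll_shared == pytest.approx(ll_fresh, abs=1e-8)

    def test_posterior_predictive_signal(self, noisy_calibration,
                                         cohort_posterior):
        """Averaging emission means over paths reproduces the observed signal
        up to the emission noise scale."""
        ds, post = cohort_posterior
        for i in range(post.n_cells):
            implied = noisy_calibration.mean(post.p_paths[i].mean(axis=0))
            resid = ds.signals[i] - implied
            # residuals stay on the emission-noise scale (sd 0.5 gray levels)
            assert np.abs(resid.mean()) < 0.15
            assert resid.std() < 3.0 * np.sqrt(noisy_calibration.var_floor)


class TestIntervalStatistics:
    def _posterior_from_paths(self, g_paths, dt, model):
        # minimal posterior wrapper around hand-made activity paths
        trunc = LatticeTruncation(m_max=0, p_max=0, eps=1e-2)
        from dataclasses import replace
        silent_model = replace(model, k_m=0.0)
        prop = build_propagator(silent_model, dt, trunc)
        return TrajectoryPosterior(
            g_paths=g_paths, m_paths=[np.zeros_like(g) for g in g_paths],
            p_paths=[np.zeros_like(g) for g in g_paths],
            p_on=[(g == 0).mean(axis=0) for g in g_paths],
            mrna_histograms=[np.ones(1) for _ in g_paths], dt=dt,
            n_samples=g_paths[0].shape[0], model=model, propagator=prop)

    def test_constant_on_path_has_no_silent_intervals(self, telegraph):
        g = np.zeros((1, 50), dtype=int)
        post = self._posterior_from_paths([g], 5.0, telegraph)
        stats = interval_statistics(post)
        assert stats["silent_durations"].size == 0
        assert stats["active_durations"].size == 0  # single censored run
        assert stats["n_censored"] == 1
        assert stats["empty"]

    def test_peaked_versus_exponential_silent_intervals(self, noisy_calibration):
        """N=6 cycles produce lower silent-interval CV than matched N=1, and
        the deconvolved mean silent duration recovers T.

        The active time (20 min) is kept well above the sampling interval
        (2.5 min): active periods shorter than one interval are invisible on
        the grid and would merge adjacent silent intervals.
        """
        kw = dict(off_rate=1 / 20, k_m=0.15, k_p=0.2, gamma_m=0.05, gamma_p=0.2)
        m1 = PromoterCycleModel(1, (1 / 90.0,), **kw)
        m6 = PromoterCycleModel.equal_steps(6, 90.0, **kw)
        cvs = {}
        for name, model in (("n1", m1), ("n6", m6)):
            ds = generate_cohort(model, n_cells=24, duration=1440.0, dt=2.5,
                                 calibration=noisy_calibration, seed=70)
            post = deconvolve_dataset(ds, model, noisy_calibration,
                                      n_samples=8, seed=71)
            stats = interval_statistics(post)
            cvs[name] = stats["silent_cv"]
            assert stats["silent_mean"] == pytest.approx(90.0, rel=0.10)
        assert cvs["n6"] < cvs["n1"]
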