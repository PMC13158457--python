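"""Tests for the heteroscedastic Bayesian stage."""

import numpy as np
import pytest
from scipy import stats

from adhesiokin import (AdhesionDataset, MCMCConfig, NoiseParams,
                        PosteriorSamples, PriorSpec, SigmaCurve, SLSParams,
                        convergence_diagnostics, empirical_sd_curve,
                        hetero_sigma, log_likelihood, log_prior,
                        posterior_predictive, sample_posterior, sls_mean)
from adhesiokin.bayes import _lognorm_trunc0


def _flat_sigma(value: float) -> SigmaCurve:
    return SigmaCurve(knot_times=np.array([0.0, 100.0]),
                      knot_sds=np.array([value, value]),
                      window_width=2.0, floor=min(value, 1.0))


class TestEmpiricalSdCurve:
    def test_zero_spread_is_floored(self):
        data = AdhesionDataset(condition="c",
                               times=np.repeat([2.0, 4.0, 6.0], 3),
                               forces=np.full(9, 10.0))
        curve = empirical_sd_curve(data, floor=1.0)
        assert np.all(curve(np.array([2.0, 3.0, 6.0])) == 1.0)

    def test_linear_interpolation_between_windows(self):
        """Window SDs 5 at t=2 and 15 at t=4 interpolate to 10 at t=3."""
        data = AdhesionDataset(
            condition="c",
            times=np.array([2.0, 2.0, 2.0, 4.0, 4.0, 4.0]),
            forces=np.array([95.0, 100.0, 105.0, 185.0, 200.0, 215.0]),
        )
        curve = empirical_sd_curve(data, window_width=1.0, floor=0.5)
        assert curve(2.0) == pytest.approx(5.0)
        assert curve(4.0) == pytest.approx(15.0)
        assert curve(3.0) == pytest.approx(10.0)
        # constant extrapolation beyond the observed range
        assert curve(0.0) == pytest.approx(5.0)
        assert curve(10.0) == pytest.approx(15.0)

    def test_sparse_window_falls_back_to_global_sd(self):
        data = AdhesionDataset(
            condition="c",
            times=np.array([2.0, 4.0, 4.0, 4.0]),
            forces=np.array([50.0, 180.0, 200.0, 220.0]),
        )
        curve = empirical_sd_curve(data, window_width=1.0, floor=0.5)
        assert curve(2.0) == pytest.approx(np.std(data.forces, ddof=1))

    def test_tracks_generating_sd_on_large_simulation(self):
        """With many replicates the window SD recovers the generating
        sigma(t) = 0.05 * mu(t) + 5 within 20% at observed times."""
        rng = np.random.default_rng(0)
        params = SLSParams(F0=30.0, Fmax=300.0, tau=3.7)
        times = np.repeat([2.0, 4.0, 6.0, 8.0, 10.0], 1000)
        mu = sls_mean(params, times)
        sd_true = 0.05 * mu + 5.0
        data = AdhesionDataset(condition="c", times=times,
                               forces=np.abs(mu + sd_true * rng.standard_normal(times.size)))
        curve = empirical_sd_curve(data, window_width=2.0, floor=1.0)
        for t in (2.0, 4.0, 6.0, 8.0, 10.0):
            truth = 0.05 * sls_mean(params, t) + 5.0
            assert curve(t) == pytest.approx(truth, rel=0.2)


class TestHeteroSigma:
    def test_linear_combination(self):
        assert hetero_sigma(NoiseParams(0.05, 1.0), 200.0, 10.0) == pytest.approx(20.0)

    def test_zero_proportional_term(self):
        assert hetero_sigma(NoiseParams(0.0, 2.0), 500.0, 7.0) == pytest.approx(14.0)

    def test_rejects_negative_inputs(self):
        with pytest.raises(ValueError):
            hetero_sigma(NoiseParams(0.1, 1.0), -1.0, 5.0)
        with pytest.raises(ValueError):
            NoiseParams(-0.1, 1.0)

    def test_degenerate_noise_rejected_by_likelihood(self):
        """gamma_mu = gamma_sigma = 0 gives sigma = 0: the likelihood must
        reject the state with -inf rather than evaluate a degenerate normal."""
        data = AdhesionDataset(condition="c", times=np.array([2.0]),
                               forces=np.array([100.0]))
        ll = log_likelihood(SLSParams(10.0, 100.0, 3.0), NoiseParams(0.0, 0.0),
                            data, _flat_sigma(5.0))
        assert ll == -np.inf


class TestLogDensities:
    def test_single_observation_at_mean_unit_sd(self):
        params = SLSParams(F0=50.0, Fmax=350.0, tau=3.0)
        t = np.array([3.0])
        data = AdhesionDataset(condition="c", times=t,
                               forces=np.asarray(sls_mean(params, t)))
        # gamma_mu = 0, gamma_sigma = 1, sigma_l = 1 -> sigma = 1
        ll = log_likelihood(params, NoiseParams(0.0, 1.0), data, _flat_sigma(1.0))
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    def test_additivity_over_duplicated_observations(self):
        params = SLSParams(F0=50.0, Fmax=350.0, tau=3.0)
        one = AdhesionDataset(condition="c", times=np.array([4.0]),
                              forces=np.array([210.0]))
        two = AdhesionDataset(condition="c", times=np.array([4.0, 4.0]),
                              forces=np.array([210.0, 210.0]))
        noise = NoiseParams(0.05, 1.0)
        sig = _flat_sigma(8.0)
        assert log_likelihood(params, noise, two, sig) == pytest.approx(
            2.0 * log_likelihood(params, noise, one, sig), abs=1e-12)

    def test_three_observation_scipy_oracle(self):
        """Hand-assembled sum of scipy normal log-densities to 1e-10."""
        params = SLSParams(F0=20.0, Fmax=250.0, tau=4.0)
        noise = NoiseParams(0.1, 1.5)
        times = np.array([2.0, 5.0, 9.0])
        forces = np.array([100.0, 180.0, 260.0])
        data = AdhesionDataset(condition="c", times=times, forces=forces)
        sig = _flat_sigma(6.0)
        mu = sls_mean(params, times)
        sd = noise.gamma_mu * mu + noise.gamma_sigma * sig(times)
        expected = float(np.sum(stats.norm.logpdf(forces, mu, sd)))
        assert log_likelihood(params, noise, data, sig) == pytest.approx(
            expected, abs=1e-10)

    def test_prior_support_truncation(self):
        assert _lognorm_trunc0(-1.0, 30.0, 300.0) == -np.inf
        assert _lognorm_trunc0(-0.1, 3.7, 1.0) == -np.inf

    def test_prior_density_scipy_oracle(self):
        """log_prior at the prior centers (noise scales at 1) matches an
        independently composed scipy density sum to 1e-10."""
        priors = PriorSpec(F0_star=30.0, Fmax_star=300.0, tau_star=3.7)
        params = SLSParams(F0=30.0, Fmax=300.0, tau=3.7)
        noise = NoiseParams(1.0, 1.0)
        a0 = (0.0 - 30.0) / 300.0
        at = (0.0 - 3.7) / 1.0
        expected = (
            stats.norm.logpdf(300.0, 300.0, 300.0)
            + stats.truncnorm.logpdf(30.0, a0, np.inf, 30.0, 300.0)
            + stats.truncnorm.logpdf(3.7, at, np.inf, 3.7, 1.0)
            + 2.0 * stats.halfcauchy.logpdf(1.0, scale=3.0)
        )
        assert log_prior(params, noise, priors) == pytest.approx(
            float(expected), abs=1e-10)

    def test_halfnormal_scale_option(self):
        priors = PriorSpec(F0_star=30.0, Fmax_star=300.0, tau_star=3.7,
                           tau_prior="halfnormal_scale")
        params = SLSParams(F0=30.0, Fmax=300.0, tau=0.5)
        noise = NoiseParams(1.0, 1.0)
        lp = log_prior(params, noise, priors)
        expected_tau = stats.halfnorm.logpdf(0.5, scale=1.0)
        base = PriorSpec(F0_star=30.0, Fmax_star=300.0, tau_star=3.7)
        delta = lp - log_prior(params, noise, base)
        at = (0.0 - 3.7) / 1.0
        trunc_tau = stats.truncnorm.logpdf(0.5, at, np.inf, 3.7, 1.0)
        assert delta == pytest.approx(float(expected_tau - trunc_tau), abs=1e-10)


class TestSamplePosterior:
    def test_support_and_reproducibility(self, mild_dataset):
        from adhesiokin import fit_sls

        priors = PriorSpec.from_fit(fit_sls(mild_dataset))
        cfg = MCMCConfig(chains=2, warmup=150, draws=150, seed=5)
        post = sample_posterior(mild_dataset, priors, cfg)
        assert post.n_total == 300
        assert np.all(post.pooled("F0") >= 0)
        assert np.all(post.pooled("tau") > 0)
        assert np.all(post.pooled("gamma_mu") >= 0)
        assert np.all(post.pooled("gamma_sigma") >= 0)
        post2 = sample_posterior(mild_dataset, priors, cfg)
        np.testing.assert_array_equal(post.draws["Fmax"], post2.draws["Fmax"])

    def test_requires_three_distinct_times(self):
        data = AdhesionDataset(condition="c", times=np.array([2.0, 2.0, 4.0]),
                               forces=np.array([10.0, 12.0, 30.0]))
        with pytest.raises(ValueError):
            sample_posterior(data, PriorSpec(10.0, 100.0, 3.0),
                             MCMCConfig(chains=2, warmup=50, draws=50, seed=0))

    def test_doubling_data_concentrates_posterior(self, fibroblast_mild):
        """Replicating every observation sharpens the likelihood, shrinking
        the posterior SDs of F0 and Fmax (averaged over seeds)."""
        from adhesiokin import SimConfig, fit_sls, simulate_dataset

        ratios = []
        for seed in range(3):
            data = simulate_dataset(fibroblast_mild,
                                    SimConfig(seed=60 + seed, n_replicates=5))
            doubled = AdhesionDataset(
                condition=data.condition,
                times=np.concatenate([data.times, data.times]),
                forces=np.concatenate([data.forces, data.forces]),
            )
            cfg = MCMCConfig(chains=2, warmup=200, draws=200, seed=seed)
            priors = PriorSpec.from_fit(fit_sls(data))
            p1 = sample_posterior(data, priors, cfg)
            p2 = sample_posterior(doubled, PriorSpec.from_fit(fit_sls(doubled)),
                                  cfg)
            for name in ("F0", "Fmax"):
                ratios.append(p2.pooled(name).std() / p1.pooled(name).std())
        assert np.mean(ratios) < 1.0


class TestConvergenceDiagnostics:
    def _samples(self, arr_by_chain: np.ndarray) -> PosteriorSamples:
        return PosteriorSamples(draws={"x": arr_by_chain})

    def test_iid_chains_converge(self):
        rng = np.random.default_rng(0)
        diag = convergence_diagnostics(self._samples(rng.standard_normal((4, 500))))
        assert diag["x"]["rhat"] < 1.01

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.standard_normal(500),
                           10.0 + rng.standard_normal(500)])
        diag = convergence_diagnostics(self._samples(chains))
        assert diag["x"]["rhat"] > 1.5

    def test_iid_ess_concentration(self):
        rng = np.random.default_rng(2)
        diag = convergence_diagnostics(self._samples(rng.standard_normal((4, 500))))
        assert 1500 <= diag["x"]["ess_bulk"] <= 2500

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            convergence_diagnostics(self._samples(np.zeros((1, 100))))


def _samples_from_params(F0, Fmax, tau, gamma_mu=0.0, gamma_sigma=1.0):
    def arr(v):
        return np.atleast_2d(np.asarray(v, dtype=float))

    n = arr(F0).shape[1]
    return PosteriorSamples(draws={
        "F0": arr(F0), "Fmax": arr(Fmax), "tau": arr(tau),
        "gamma_mu": arr(np.broadcast_to(gamma_mu, n).copy()),
        "gamma_sigma": arr(np.broadcast_to(gamma_sigma, n).copy()),
    })


class TestPosteriorPredictive:
    def test_far_from_boundary_mean(self):
        """A single draw at mu = 500, sigma = 50: truncation at zero is a
        10-sigma event, so the predictive mean equals mu to 1e-6."""
        samples = _samples_from_params([500.0], [500.0], [3.0])
        summary = posterior_predictive(samples, [5.0], _flat_sigma(50.0))
        assert summary.mean[0] == pytest.approx(500.0, abs=1e-6)
        assert summary.sd[0] == pytest.approx(50.0, rel=1e-6)

    def test_half_normal_limit(self):
        """mu = 0, sigma = 1 truncated at zero is a standard half-normal
        with mean sqrt(2/pi)."""
        samples = _samples_from_params([0.0], [0.0], [3.0])
        summary = posterior_predictive(samples, [5.0], _flat_sigma(1.0))
        assert summary.mean[0] == pytest.approx(np.sqrt(2.0 / np.pi), abs=1e-9)

    def test_mixture_against_rejection_sampling_oracle(self):
        """Predictive mean and 90% band of a 100-draw mixture agree with a
        large rejection-sampling simulation."""
        rng = np.random.default_rng(3)
        F0 = rng.uniform(0.0, 60.0, 100)
        Fmax = rng.uniform(200.0, 400.0, 100)
        tau = rng.uniform(2.0, 6.0, 100)
        gmu = rng.uniform(0.0, 0.2, 100)
        samples = _samples_from_params(F0, Fmax, tau, gamma_mu=gmu)
        sig = _flat_sigma(25.0)
        t_star = 4.0
        summary = posterior_predictive(samples, [t_star], sig)

        mu = F0 + (Fmax - F0) * (1.0 - np.exp(-t_star / tau))
        sd = gmu * mu + 1.0 * sig(t_star)
        n_per = 20_000
        draws = rng.normal(mu[:, None], sd[:, None], size=(100, n_per))
        for _ in range(200):
            neg = draws < 0
            if not neg.any():
                break
            draws[neg] = rng.normal(
                np.broadcast_to(mu[:, None], draws.shape)[neg],
                np.broadcast_to(sd[:, None], draws.shape)[neg])
        pool = draws.ravel()
        se = pool.std() / np.sqrt(200.0)  # generous MC allowance
        assert summary.mean[0] == pytest.approx(pool.mean(), abs=4 * se)
        assert summary.pred_lower[0] == pytest.approx(
            np.quantile(pool, 0.05), abs=5 * se)
        assert summary.pred_upper[0] == pytest.approx(
            np.quantile(pool, 0.95), abs=5 * se)

    def test_band_ordering_invariants(self):
        """On a posterior-like cloud (parameter spread small next to the
        observation noise) the 90% prediction band brackets the mean and
        contains the 95% credible band of the mean curve."""
        rng = np.random.default_rng(4)
        samples = _samples_from_params(
            np.clip(rng.normal(20.0, 3.0, 200), 0.0, None),
            rng.normal(300.0, 12.0, 200),
            np.clip(rng.normal(3.7, 0.25, 200), 0.5, None),
            gamma_mu=rng.uniform(0.05, 0.1, 200))
        grid = np.linspace(0.0, 10.0, 25)
        s = posterior_predictive(samples, grid, _flat_sigma(20.0))
        assert np.all(s.pred_lower <= s.mean + 1e-9)
        assert np.all(s.mean <= s.pred_upper + 1e-9)
        assert np.all(s.pred_lower <= s.cred_lower + 1e-9)
        assert np.all(s.cred_upper <= s.pred_upper + 1e-9)
        assert np.all(s.pred_lower >= 0.0)

    def test_empty_grid_rejected(self):
        samples = _samples_from_params([10.0], [100.0], [3.0])
        with pytest.raises(ValueError):
            posterior_predictive(samples, [], _flat_sigma(10.0))
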