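"""Likelihood algebra, the Metropolis sampler (toy-target calibration,
determinism), convergence diagnostics, posterior summaries and the
stepping-stone evidence estimator against an analytic oracle."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

import hcgate as hg
from hcgate.bayes import (
    PARAM_NAMES,
    _DEFAULT_SCALES,
    log_prior_u,
    params_to_vector,
    sample_prior_u,
    stepping_stone,
    vector_to_params,
)
from hcgate.errors import InvalidArgumentError


def exact_dataset(params, sd=1.0):
    """Dataset whose observations equal the model predictions exactly."""
    V = np.arange(20.0, -61.0, -10.0)
    po = hg.open_probability(params, V, 0.0)
    gv = hg.GVCurve(V, po / po.max(), np.full(V.size, sd))
    ca = np.logspace(-2, 0.5, 6)
    curves = []
    for vt in (0.0, -30.0):
        rel = hg.open_probability(params, vt, ca) / hg.open_probability(params, vt, 0.0)
        curves.append(hg.InhibitionCurve(vt, ca, rel, np.full(ca.size, sd)))
    return hg.Dataset(gv, curves)


class TestLogLikelihood:
    def test_zero_residuals_unit_sd(self, mlv):
        data = exact_dataset(mlv, sd=1.0)
        n = data.n_points
        assert hg.log_likelihood(mlv, data) == pytest.approx(
            -0.5 * n * np.log(2 * np.pi)
        )

    def test_doubling_sds_gaussian_algebra(self, mlv):
        other = mlv.replace(Kd=2.0)
        d1 = exact_dataset(mlv, sd=0.05)
        d2 = exact_dataset(mlv, sd=0.10)
        n = d1.n_points
        ll1, ll2 = hg.log_likelihood(other, d1), hg.log_likelihood(other, d2)
        resid_term = ll1 + 0.5 * n * np.log(2 * np.pi * 0.05**2)
        assert ll2 == pytest.approx(
            -0.5 * n * np.log(2 * np.pi * 0.10**2) + resid_term / 4.0
        )

    def test_truth_beats_distorted_affinity(self, mlv, default_study):
        ll_true = hg.log_likelihood(mlv, default_study.data)
        ll_off = hg.log_likelihood(mlv.replace(Kd=9.6), default_study.data)
        assert ll_true - ll_off > 10.0


class TestMetropolis:
    def gaussian_target(self):
        cov = np.array([[1.0, 0.6], [0.6, 2.0]])
        mean = np.array([1.0, -2.0])
        rv = multivariate_normal(mean=mean, cov=cov)
        return mean, cov, lambda x: rv.logpdf(x)

    def test_recovers_toy_gaussian_moments(self):
        mean, cov, logp = self.gaussian_target()
        rng = np.random.default_rng(0)
        samples, _, rate = hg.metropolis_sample(
            logp, np.zeros(2), np.array([0.5, 0.5]), 30000, rng, adapt_steps=5000
        )
        kept = samples[5000:]
        n_eff = kept.shape[0] / 20.0  # generous autocorrelation allowance
        mc_se = np.sqrt(np.diag(cov) / n_eff)
        assert np.all(np.abs(kept.mean(axis=0) - mean) < 3 * mc_se)
        assert np.allclose(np.cov(kept, rowvar=False), cov, rtol=0.10, atol=0.05)
        assert 0.0 < rate < 1.0

    def test_seeded_chain_is_bit_identical(self, default_study, mlv):
        priors = hg.default_priors()
        runs = [
            hg.run_metropolis(default_study.data, priors, mlv, 1500, seed=3)
            for _ in range(2)
        ]
        assert np.array_equal(runs[0].samples, runs[1].samples)
        assert np.array_equal(runs[0].log_post, runs[1].log_post)

    def test_init_outside_prior_support_rejected(self, default_study, mlv):
        priors = hg.default_priors()
        with pytest.raises(InvalidArgumentError):
            hg.run_metropolis(
                default_study.data, priors, mlv.replace(V1=500.0), 1500, seed=0
            )


class TestDiagnostics:
    def test_chains_from_same_distribution_pass(self):
        rng = np.random.default_rng(1)
        chains = [rng.normal(0, 1, (4000, 3)) for _ in range(3)]
        out = hg.convergence_diagnostics(chains)
        assert out["pass"] and np.all(out["rhat"] < 1.05)

    def test_stuck_chain_fails(self):
        rng = np.random.default_rng(2)
        chains = [rng.normal(0, 1, (2000, 2)) for _ in range(2)]
        chains.append(np.full((2000, 2), 5.0))
        out = hg.convergence_diagnostics(chains)
        assert not out["pass"] and out["rhat"].max() > 1.1

    def test_identical_chains_statistic_near_one(self):
        rng = np.random.default_rng(3)
        base = rng.normal(0, 1, (3000, 2))
        out = hg.convergence_diagnostics([base, base.copy(), base.copy()])
        assert np.all(out["rhat"] <= 1.01)

    def test_requires_two_chains(self):
        with pytest.raises(InvalidArgumentError):
            hg.convergence_diagnostics([np.zeros((100, 2))])


class TestPosteriorSummary:
    def test_iid_gaussian_quantiles(self):
        rng = np.random.default_rng(4)
        n = 60000
        samples = rng.normal(2.0, 0.5, (n, 1))
        chain = hg.Chain(samples, -0.5 * ((samples[:, 0] - 2) / 0.5) ** 2, 0.3, 0)
        s = hg.posterior_summary(chain, burn_in_fraction=0.0)
        assert s.lo95[0] == pytest.approx(2.0 - 1.96 * 0.5, abs=0.02)
        assert s.hi95[0] == pytest.approx(2.0 + 1.96 * 0.5, abs=0.02)
        assert s.sd[0] == pytest.approx(0.5, rel=0.02)
        assert s.mlv[0] == pytest.approx(2.0, abs=0.05)

    def test_constant_chain_zero_width_interval(self):
        samples = np.full((500, 2), 3.0)
        chain = hg.Chain(samples, np.zeros(500), 0.5, 0)
        s = hg.posterior_summary(chain)
        assert np.all(s.lo95 == s.hi95)


class TestRecoveryCalibration:
    def test_informative_study_covers_truth(self, mlv):
        # calibration check of the whole inference stack: with
        # informative noise the 95% intervals cover nearly all of the
        # 13 generating parameters and the chains converge
        noise = hg.NoiseSpec(rel_current_sd=0.005, tau_log_sd=0.02)
        study = hg.make_study(noise=noise, seed=2)
        priors = hg.default_priors()
        rng = np.random.default_rng(2)
        chains = []
        for _ in range(3):
            jit = {
                n: float(getattr(mlv, n) * rng.lognormal(0, 0.05))
                for n in ("A0", "B0", "C0", "D0", "Kd")
            }
            chains.append(
                hg.run_metropolis(
                    study.data, priors, mlv.replace(**jit), 6000,
                    int(rng.integers(2**31)),
                )
            )
        summ = hg.posterior_summary(chains)
        truth = params_to_vector(mlv)
        inside = sum(
            1 for j in range(len(PARAM_NAMES))
            if summ.lo95[j] <= truth[j] <= summ.hi95[j]
        )
        assert inside >= 11
        i = summ.names.index("Kd")
        assert summ.lo95[i] <= mlv.Kd <= summ.hi95[i]


class TestEvidence:
    @staticmethod
    def conjugate_toy(seed=3):
        # scalar mean with N(0,1) prior, five N(mu, 0.5) observations:
        # the marginal likelihood is a closed-form Gaussian density
        rng = np.random.default_rng(seed)
        y = rng.normal(0.7, 0.5, 5)
        s = 0.5

        def loglik(x):
            return float(-0.5 * np.sum((y - x[0]) ** 2 / s**2 + np.log(2 * np.pi * s**2)))

        def logprior(x):
            return float(-0.5 * (x[0] ** 2 + np.log(2 * np.pi)))

        def sample_prior(r):
            return np.array([r.normal()])

        Sigma = s**2 * np.eye(y.size) + np.ones((y.size, y.size))
        log_z = multivariate_normal(mean=np.zeros(y.size), cov=Sigma).logpdf(y)
        return loglik, sample_prior, logprior, log_z

    def test_matches_analytic_conjugate_evidence(self):
        loglik, sample_prior, logprior, truth = self.conjugate_toy()
        lz, se, unstable = stepping_stone(
            loglik, sample_prior, logprior, np.array([0.5]),
            np.random.default_rng(0), n_rungs=16, steps_per_rung=500,
        )
        assert not unstable
        assert abs(lz - truth) < max(3 * se, 0.15)

    def test_estimator_consistent_across_seeds(self):
        loglik, sample_prior, logprior, truth = self.conjugate_toy()
        lzs, ses = [], []
        for seed in (0, 1, 2):
            lz, se, _ = stepping_stone(
                loglik, sample_prior, logprior, np.array([0.5]),
                np.random.default_rng(seed), n_rungs=16, steps_per_rung=500,
            )
            lzs.append(lz)
            ses.append(se)
        spread = max(lzs) - min(lzs)
        assert spread < 2 * (max(ses) + max(ses))

    def test_identical_models_even_odds(self):
        loglik, sample_prior, logprior, _ = self.conjugate_toy()
        evs = []
        for seed in (5, 6):
            lz, se, _ = stepping_stone(
                loglik, sample_prior, logprior, np.array([0.5]),
                np.random.default_rng(seed), n_rungs=16, steps_per_rung=500,
            )
            evs.append(hg.ModelEvidence(lz, se, 6))
        ratio = hg.odds_ratio(evs[0], evs[1])
        band = np.exp(4 * (evs[0].se + evs[1].se))
        assert 1.0 / band < ratio < band


def test_prior_support_and_sampling_round_trip():
    priors = hg.default_priors()
    rng = np.random.default_rng(0)
    for _ in range(200):
        u = sample_prior_u(priors, rng)
        assert np.isfinite(log_prior_u(u, priors))
    # a point outside any one bound has zero density
    u = sample_prior_u(priors, rng)
    u[PARAM_NAMES.index("V1")] = 101.0
    assert log_prior_u(u, priors) == -np.inf


def test_parameter_vector_round_trip(mlv):
    v = params_to_vector(mlv)
    back = vector_to_params(v, mlv.m)
    assert back == mlv
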