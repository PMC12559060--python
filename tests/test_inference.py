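"""Sampler correctness: TMCMC, latent updates, diagnostics, IRMCMC."""

import numpy as np
import pytest
from scipy import stats

from marapop.inference import (
    IPMModel,
    MCMCConfig,
    PriorSpec,
    effective_sample_size,
    gelman_rubin,
    initial_params,
    irmcmc_weights,
    ks_prior_posterior,
    posterior_summary,
    run_mcmc,
    tmcmc_update,
    update_latent_states,
)
from marapop.states import N_COMP, p_col
from marapop.vitalrates import BLOCK_SIZES, VitalRateCoefficients


def zero_coeffs():
    return VitalRateCoefficients(
        **{f"gamma{b}": np.zeros(s) for b, s in BLOCK_SIZES.items()}
    )


class TestTMCMC:
    def test_recovers_2d_gaussian_moments(self):
        """Sampling a standard 2-D normal: moments within 0.05."""
        rng = np.random.default_rng(17)

        def log_target(x):
            return -0.5 * float(x @ x)

        x = np.zeros(2)
        draws = np.empty((100000, 2))
        for i in range(100000):
            x, _ = tmcmc_update(x, 1.2, log_target, rng)
            draws[i] = x
        assert np.all(np.abs(draws.mean(axis=0)) < 0.05)
        assert np.all(np.abs(draws.std(axis=0) - 1.0) < 0.05)

    def test_zero_delta_always_accepted(self):
        rng = np.random.default_rng(0)
        accepted = [
            tmcmc_update(np.zeros(3), 0.5, lambda x: 0.0, rng)[1]
            for _ in range(50)
        ]
        assert all(accepted)

    def test_proposal_is_involution(self):
        """Flipping every sign maps the proposal back to the start."""
        rng = np.random.default_rng(1)
        eps = abs(rng.standard_normal())
        signs = rng.choice([-1.0, 1.0], size=4)
        x = rng.standard_normal(4)
        prop = x + signs * 0.3 * eps
        back = prop + (-signs) * 0.3 * eps
        np.testing.assert_allclose(back, x)


class TestSiteDelta:
    def test_matches_full_log_joint_recompute(self, small_dataset,
                                              small_model, small_params):
        """Incremental deltas equal the brute-force joint difference."""
        model = small_model
        params = small_params
        traj = small_dataset.truth_traj.copy()
        rates = model.all_rates(params.coeffs)
        lj0 = model.log_joint(params, traj)
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(150):
            c = int(rng.integers(0, N_COMP))
            t = int(rng.integers(0, model.T + 1))
            d = int(rng.integers(-4, 5)) or 1
            dll = model.site_delta(c, np.array([t]), np.array([d]), traj,
                                   params, rates)[0]
            traj2 = traj.copy()
            traj2[t, c] += d
            full = (model.log_joint(params, traj2) - lj0
                    if np.all(traj2[t] >= 0) else -np.inf)
            if np.isinf(dll) and np.isinf(full):
                continue
            assert dll == pytest.approx(full, abs=1e-8)
            checked += 1
        assert checked > 50

    def test_numba_and_python_sweeps_identical(self, small_dataset,
                                               small_model, small_params):
        from marapop import _fastsweep

        if not _fastsweep.HAVE_NUMBA:
            return  # reference path is then the only path
        model = small_model
        rates = model.all_rates(small_params.coeffs)
        a = small_dataset.truth_traj.copy()
        b = small_dataset.truth_traj.copy()
        update_latent_states(a, model, small_params, rates,
                             np.random.default_rng(33))
        update_latent_states(b, model, small_params, rates,
                             np.random.default_rng(33), force_python=True)
        np.testing.assert_array_equal(a, b)

    def test_sweep_preserves_feasibility(self, small_dataset, small_model,
                                         small_params):
        model = small_model
        rates = model.all_rates(small_params.coeffs)
        traj = small_dataset.truth_traj.copy()
        rng = np.random.default_rng(5)
        for _ in range(5):
            update_latent_states(traj, model, small_params, rates, rng)
        assert np.isfinite(model.log_joint(small_params, traj))
        assert np.all(traj >= 0)


class TestLogJoint:
    def test_decomposition_identity(self, small_dataset, small_model,
                                    small_params):
        """log_joint equals the sum of its separately computed factors."""
        model = small_model
        traj = small_dataset.truth_traj
        g = model.group_lls(small_params, traj)
        total = (model.log_prior(small_params)
                 + sum(v for k, v in g.items() if k != "aerial")
                 + float(np.sum(g["aerial"])))
        assert model.log_joint(small_params, traj) == pytest.approx(
            total, abs=1e-10
        )

    def test_infeasible_trajectory_is_minus_inf(self, small_dataset,
                                                small_model, small_params):
        traj = small_dataset.truth_traj.copy()
        traj[3, 5] = traj[2, 4] + 10  # cohort gains animals from nowhere
        assert small_model.log_joint(small_params, traj) == -np.inf

    def test_prior_support(self, small_model, small_params):
        p = small_params.copy()
        if len(p.K):
            p.K[0] = 0.9
            assert small_model.log_prior(p) == -np.inf
        p = small_params.copy()
        p.sigma_sq[0] = -1.0
        assert small_model.log_prior(p) == -np.inf

    def test_gamma_prior_density_oracle(self, small_model, small_params):
        got = small_model.log_prior(small_params)
        manual = 0.0
        for b in ("R", "Q", "H", "A", "S"):
            manual += stats.norm.logpdf(
                small_params.coeffs.block(b), 0.0, 100.0
            ).sum()
        if len(small_params.K):
            manual += (-2.0 * np.log(small_params.K)).sum()
        v = small_params.sigmaT_sq
        s2 = small_model.prior.sigmaT_prior_scale ** 2
        manual += -np.log1p(v / s2) - 0.5 * np.log(v)
        assert got == pytest.approx(manual, rel=1e-12)


class TestTinyModelExactness:
    """The latent sampler must match the exhaustively enumerated posterior
    on a miniature two-month model."""

    @staticmethod
    def _tiny_model():
        import pandas as pd

        from marapop.covariates import CovariateTable
        from marapop.observation import AerialObservation  # noqa: F401
        from marapop.synthetic import ScenarioConfig, generate_climate, \
            population_index
        from marapop.covariates import build_covariate_table
        from marapop.vitalrates import PredationConfig

        cfg = ScenarioConfig(T=2)
        clim = generate_climate(cfg)
        pop = population_index(cfg, 2.0)
        tab = build_covariate_table(clim, pop, range(0, 3))
        ground = np.array([[1, 0, 0, 3, 0], [0, 0, 0, 2, 0]])
        init_means = np.zeros(N_COMP)
        init_means[p_col(11)] = 1.5
        init_means[p_col(12)] = 1.0
        prior = PriorSpec(init_state_var=0.6)
        model = IPMModel(ground, [], tab, PredationConfig(), prior,
                         init_means)
        return model

    @staticmethod
    def _tiny_params(model):
        params = initial_params(model, zero_coeffs(), np.random.default_rng(0))
        params.sigma_sq = np.full(5, 2.0)
        return params

    def _enumerate_posterior(self, model, params, rates):
        """Brute-force joint over the reachable tiny state space, using
        scipy.stats densities (independent of the package kernels)."""
        saf = rates["saf"]
        sq = rates["sq"]
        r = rates["r"]
        sig = params.sigma_sq
        n_obs = model.ground[:, 0]
        f_obs = model.ground[:, 3]
        iv = model.prior.init_state_var
        mu11 = model.init_means[p_col(11)]
        mu12 = model.init_means[p_col(12)]

        def nb(count, mean, s2):
            if mean <= 0:
                return 1.0 if count == 0 else 0.0
            a = mean * mean / s2
            b = (mean / s2) / (1.0 + mean / s2)
            return stats.nbinom.pmf(count, a, b)

        cap = 7
        states = {}
        total = 0.0
        for p11_0 in range(cap):
            for p12_0 in range(cap):
                pool0 = p11_0 + p12_0
                pri = (stats.norm.pdf(p11_0, mu11, np.sqrt(iv))
                       * stats.norm.pdf(p12_0, mu12, np.sqrt(iv)))
                for n0 in range(pool0 + 1):
                    # N(0) also feeds the (empty) next-month survivor
                    # classes: P(1,1) = 0 and G(1,2) = 0
                    w0 = (pri * stats.binom.pmf(n0, pool0, r[0])
                          * (1.0 - saf[1]) ** n0 * (1.0 - sq[1]) ** n0)
                    for p12_1 in range(pool0 - n0 + 1):
                        w1 = w0 * stats.binom.pmf(p12_1, pool0 - n0, saf[1])
                        for n1 in range(p12_1 + 1):
                            w2 = (w1 * stats.binom.pmf(n1, p12_1, r[1])
                                  * (1.0 - saf[2]) ** n1
                                  * (1.0 - sq[2]) ** n1
                                  * nb(n_obs[0], n1, sig[0])
                                  * nb(f_obs[0], p12_1, sig[3]))
                            for p12_2 in range(p12_1 - n1 + 1):
                                w3 = w2 * stats.binom.pmf(
                                    p12_2, p12_1 - n1, saf[2]
                                )
                                for n2 in range(p12_2 + 1):
                                    w = (w3
                                         * stats.binom.pmf(n2, p12_2, r[2])
                                         * nb(n_obs[1], n2, sig[0])
                                         * nb(f_obs[1], p12_2, sig[3]))
                                    key = (n1, p12_1)
                                    states[key] = states.get(key, 0.0) + w
                                    total += w
        return {k: v / total for k, v in states.items()}

    def test_sampler_matches_enumeration(self):
        model = self._tiny_model()
        params = self._tiny_params(model)
        rates = model.all_rates(params.coeffs)
        exact = self._enumerate_posterior(model, params, rates)

        comps = np.array([0, p_col(11), p_col(12)])
        traj = np.zeros((3, N_COMP), dtype=np.int64)
        traj[:, p_col(12)] = [2, 2, 2]
        traj[0, p_col(11)] = 1
        rng = np.random.default_rng(11)
        step = np.full(N_COMP, 1.0)
        counts = {}
        n_sweeps = 40000
        burn = 2000
        for i in range(n_sweeps + burn):
            update_latent_states(traj, model, params, rates, rng,
                                 step_means=step, components=comps)
            if i >= burn:
                key = (int(traj[1, 0]), int(traj[1, p_col(12)]))
                counts[key] = counts.get(key, 0) + 1
        freq = {k: v / n_sweeps for k, v in counts.items()}
        # compare the joint distribution of (N(1), P12(1))
        tv = 0.5 * sum(
            abs(freq.get(k, 0.0) - p)
            for k, p in exact.items()
        ) + 0.5 * sum(v for k, v in freq.items() if k not in exact)
        assert tv < 0.05

    def test_infeasible_proposals_rejected(self):
        """P(11) at month 1 can only be 0 (no P(10) ancestors exist)."""
        model = self._tiny_model()
        params = self._tiny_params(model)
        rates = model.all_rates(params.coeffs)
        traj = np.zeros((3, N_COMP), dtype=np.int64)
        traj[:, p_col(12)] = [2, 2, 2]
        rng = np.random.default_rng(3)
        for _ in range(200):
            update_latent_states(
                traj, model, params, rates, rng,
                components=np.array([p_col(11)]),
            )
        assert traj[1, p_col(11)] == 0
        assert traj[2, p_col(11)] == 0


class TestRunMCMC:
    def test_deterministic_given_seed(self, small_model, small_dataset):
        cfg = MCMCConfig(n_iter=60, n_burnin=20, thin=10, seed=44)
        a = run_mcmc(small_model, cfg, small_dataset.truth.coeffs)
        b = run_mcmc(small_model, cfg, small_dataset.truth.coeffs)
        for blk in a.free_blocks:
            np.testing.assert_array_equal(a.draws[blk], b.draws[blk])
        np.testing.assert_array_equal(a.B, b.B)

    def test_draw_shapes_match_config(self, small_model, small_dataset):
        cfg = MCMCConfig(n_iter=60, n_burnin=10, thin=10, seed=2)
        chain = run_mcmc(small_model, cfg, small_dataset.truth.coeffs)
        assert chain.n_kept == 6
        assert chain.draws["R"].shape == (6, 9)
        assert chain.B.shape == (6, small_model.T + 1)
        assert np.all(np.isfinite(chain.log_joint))
        assert np.all(chain.K > 1.0)
        assert np.all(chain.sigma_sq > 0)


class TestSummaries:
    def test_constant_chain_zero_width(self):
        m, lo, hi = posterior_summary(np.full(100, 3.3))
        assert m == lo == hi == pytest.approx(3.3)

    def test_quantile_oracle(self, rng):
        draws = rng.standard_normal(5001)
        m, lo, hi = posterior_summary(draws)
        s = np.sort(draws)
        assert lo == pytest.approx(np.quantile(s, 0.025))
        assert hi == pytest.approx(np.quantile(s, 0.975))

    def test_known_normal_quantiles(self, rng):
        draws = rng.standard_normal(10000)
        _, lo, hi = posterior_summary(draws)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_empty_chain_raises(self):
        with pytest.raises(ValueError):
            posterior_summary(np.zeros(0))


class TestDiagnostics:
    def test_rhat_identical_chains(self, rng):
        x = rng.standard_normal(500)
        assert gelman_rubin([x, x.copy()]) == pytest.approx(1.0, abs=0.03)

    def test_rhat_null_simulation(self, rng):
        chains = [rng.standard_normal(2000) for _ in range(4)]
        assert gelman_rubin(chains) == pytest.approx(1.0, abs=0.01)

    def test_rhat_detects_shifted_means(self, rng):
        a = rng.standard_normal(500)
        b = rng.standard_normal(500) + 5.0
        assert gelman_rubin([a, b]) > 2.0

    def test_rhat_needs_two_chains(self, rng):
        with pytest.raises(ValueError):
            gelman_rubin([rng.standard_normal(100)])

    def test_ess_iid(self, rng):
        x = rng.standard_normal(20000)
        assert effective_sample_size(x) == pytest.approx(20000, rel=0.1)

    def test_ess_ar1_closed_form(self, rng):
        """AR(1) with rho = 0.9: ESS ~= n (1-rho)/(1+rho)."""
        rho = 0.9
        n = 40000
        x = np.empty(n)
        x[0] = rng.standard_normal()
        eps = rng.standard_normal(n) * np.sqrt(1 - rho**2)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + eps[i]
        expected = n * (1 - rho) / (1 + rho)
        assert effective_sample_size(x) == pytest.approx(expected, rel=0.2)

    def test_ess_never_exceeds_length(self, rng):
        for _ in range(5):
            x = rng.standard_normal(200)
            assert 0 < effective_sample_size(x) <= 200

    def test_ks_null_calibration(self, rng):
        rejections = 0
        reps = 200
        for _ in range(reps):
            a = rng.standard_normal(300)
            b = rng.standard_normal(300)
            _, p = ks_prior_posterior(a, b)
            rejections += p < 0.05
        assert rejections / reps < 0.12

    def test_ks_disjoint_supports(self, rng):
        a = rng.uniform(0, 1, 200)
        b = rng.uniform(5, 6, 200)
        stat, p = ks_prior_posterior(a, b)
        assert stat == 1.0
        assert p < 1e-10

    def test_ks_statistic_matches_ecdf_oracle(self, rng):
        a = rng.standard_normal(80)
        b = rng.standard_normal(120) + 0.3
        stat, _ = ks_prior_posterior(a, b)
        grid = np.concatenate([a, b])
        ecdf_a = np.array([(a <= g).mean() for g in grid])
        ecdf_b = np.array([(b <= g).mean() for g in grid])
        assert stat == pytest.approx(np.max(np.abs(ecdf_a - ecdf_b)))


class TestIRMCMC:
    def test_identical_dataset_uniform_weights(self, small_dataset,
                                               small_model):
        cfg = MCMCConfig(n_iter=200, n_burnin=50, thin=10, seed=9,
                         pool_size=10)
        chain = run_mcmc(small_model, cfg, small_dataset.truth.coeffs)
        w = irmcmc_weights(chain, small_model)
        np.testing.assert_allclose(w, 1.0 / len(w), rtol=1e-10)

    def test_all_infinite_weights_error(self, small_dataset, small_model):
        cfg = MCMCConfig(n_iter=100, n_burnin=20, thin=10, seed=9,
                         pool_size=5)
        chain = run_mcmc(small_model, cfg, small_dataset.truth.coeffs)
        chain.pool["loglik"] = np.full_like(chain.pool["loglik"], np.nan)
        with pytest.raises(ValueError, match="full MCMC"):
            irmcmc_weights(chain, small_model)
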