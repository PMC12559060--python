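"""State vector, monthly transitions, their exact log-pmf, Leslie/Kalman."""

import itertools

import numpy as np
import pytest

from marapop.states import (
    IDX_FA,
    IDX_MA,
    IDX_MB,
    IDX_N,
    N_COMP,
    StateVector,
    derived_totals,
    g_col,
    initial_state_means,
    kalman_loglik,
    leslie_matrix,
    observation_matrix,
    p_col,
    process_covariance,
    round_feasible_initial_state,
    simulate_transition,
    transition_logpmf,
)
from marapop.vitalrates import VitalRates


def make_rates(r=0.0, s_q=1.0, s_h=1.0, s_a_f=1.0, s_a_m=1.0, phi=1.0):
    return VitalRates(*(np.asarray(v, dtype=float)
                        for v in (r, s_q, s_h, s_a_f, s_a_m, phi)))


def random_state(rng, scale=20):
    y = rng.integers(0, scale, size=N_COMP)
    pool = y[p_col(11)] + y[p_col(12)]
    y[IDX_N] = min(y[IDX_N], pool)
    return StateVector(y)


class TestDerivedTotals:
    def test_zero_state(self):
        assert derived_totals(StateVector(np.zeros(N_COMP, dtype=int))) == \
            (0, 0, 0, 0, 0)

    def test_unit_cohorts(self):
        Y = StateVector.from_components(G=np.ones(18, dtype=int))
        Q, H, F, M, B = derived_totals(Y)
        assert (Q, H) == (5, 13)
        assert B == 18

    def test_summation_oracle(self, rng):
        Y = random_state(rng)
        Q, H, F, M, B = derived_totals(Y)
        y = Y.y
        assert Q == y[1:6].sum()
        assert H == y[6:19].sum()
        assert F == y[19:31].sum() + y[IDX_FA]
        assert M == y[IDX_MA] + y[IDX_MB]
        assert B == Q + H + F + M + y[IDX_N]


class TestSimulateTransition:
    def test_deterministic_conveyor(self, rng):
        """All survivals 1, phi 1, r 0: every cohort shifts exactly."""
        prev = random_state(rng)
        rates = make_rates()
        nxt = simulate_transition(prev, rates, rng)
        # juvenile conveyor
        assert nxt.y[g_col(2)] == prev.N
        for k in range(3, 20):
            assert nxt.y[g_col(k)] == prev.y[g_col(k - 1)]
        # recruitment: all of G19 becomes female (phi = 1)
        assert nxt.Fa == prev.y[g_col(19)]
        assert nxt.Ma == 0
        assert nxt.Mb == prev.Ma + prev.Mb
        assert nxt.N == 0

    def test_conveyor_conserves_totals(self, rng):
        prev = random_state(rng)
        nxt = simulate_transition(prev, make_rates(), rng)
        # no births, no deaths: every animal moves somewhere
        assert nxt.B == prev.B

    def test_zero_birth_rate(self, rng):
        prev = random_state(rng)
        for _ in range(10):
            nxt = simulate_transition(
                prev, make_rates(r=0.0, s_q=0.7, s_h=0.8, s_a_f=0.9,
                                 s_a_m=0.9, phi=0.5), rng
            )
            assert nxt.N == 0

    def test_infeasible_origin_rejected(self):
        y = np.zeros(N_COMP, dtype=int)
        y[IDX_N] = 5  # newborns without enough conceivable females
        y = StateVector.__new__(StateVector)  # bypass invariant for the check
        object.__setattr__(y, "y", np.zeros(N_COMP, dtype=np.int64))
        y.y[IDX_N] = 5
        with pytest.raises(ValueError, match="infeasible"):
            simulate_transition(y, make_rates(), np.random.default_rng(0))

    def test_monte_carlo_mean_matches_leslie(self, rng):
        """E[Y_3] from simulation matches L^3 Y_0 within 3 SE."""
        rates = make_rates(r=0.4, s_q=0.9, s_h=0.95, s_a_f=0.98,
                           s_a_m=0.97, phi=0.6)
        y0 = np.full(N_COMP, 40, dtype=np.int64)
        y0[IDX_N] = 20
        Y0 = StateVector(y0)
        n_rep = 10000
        acc = np.zeros((n_rep, N_COMP))
        for i in range(n_rep):
            Y = Y0
            for _ in range(3):
                Y = simulate_transition(Y, rates, rng)
            acc[i] = Y.y
        L = leslie_matrix(rates)
        expected = L @ L @ L @ y0.astype(float)
        se = acc.std(axis=0, ddof=1) / np.sqrt(n_rep)
        np.testing.assert_array_less(
            np.abs(acc.mean(axis=0) - expected), 3.0 * se + 1e-9
        )


class TestTransitionLogpmf:
    def test_conveyor_has_probability_one(self, rng):
        prev = random_state(rng)
        nxt = simulate_transition(prev, make_rates(), rng)
        # exact up to the 1e-12 probability clamp accumulated over the trials
        assert transition_logpmf(prev, nxt, make_rates()) == \
            pytest.approx(0.0, abs=1e-6)

    def test_infeasible_successor(self, rng):
        prev = random_state(rng)
        rates = make_rates(r=0.2, s_q=0.9, s_h=0.9, s_a_f=0.9, s_a_m=0.9,
                           phi=0.5)
        nxt = simulate_transition(prev, rates, rng)
        bad = nxt.y.copy()
        bad[g_col(5)] = prev.y[g_col(4)] + 1  # more survivors than trials
        assert transition_logpmf(prev, StateVector(bad), rates) == -np.inf

    def test_exhaustive_enumeration_sums_to_one(self):
        """exp(logpmf) is a proper pmf over all successors of a tiny state."""
        y = np.zeros(N_COMP, dtype=np.int64)
        y[IDX_N] = 1
        y[g_col(2)] = 1
        y[g_col(19)] = 2
        y[p_col(3)] = 1
        y[p_col(10)] = 1
        y[p_col(11)] = 1
        y[p_col(12)] = 1
        y[IDX_FA] = 1
        y[IDX_MA] = 1
        prev = StateVector(y)
        rates = make_rates(r=0.35, s_q=0.8, s_h=0.7, s_a_f=0.9, s_a_m=0.85,
                           phi=0.6)
        # successor support ranges implied by the trial counts
        ranges = {
            "P1": range(0, 2),       # Bin(N=1)
            "P4": range(0, 3),       # Bin(P3+Fa=2)
            "P11": range(0, 2),      # Bin(P10=1)
            "P12": range(0, 2),      # Bin(P11+P12-N=1)
            "G2": range(0, 2),       # Bin(N=1)
            "G3": range(0, 2),       # Bin(G2=1)
            "FaMa": [(a, b) for a in range(3) for b in range(3) if a + b <= 2],
            "Mb": range(0, 2),       # Bin(Ma+Mb=1)
        }
        total = 0.0
        for p1, p4, p11, p12, g2, g3, (fa, ma), mb in itertools.product(
            ranges["P1"], ranges["P4"], ranges["P11"], ranges["P12"],
            ranges["G2"], ranges["G3"], ranges["FaMa"], ranges["Mb"],
        ):
            base = np.zeros(N_COMP, dtype=np.int64)
            base[p_col(1)] = p1
            base[p_col(4)] = p4
            base[p_col(11)] = p11
            base[p_col(12)] = p12
            base[g_col(2)] = g2
            base[g_col(3)] = g3
            base[IDX_FA] = fa
            base[IDX_MA] = ma
            base[IDX_MB] = mb
            for n_new in range(0, p11 + p12 + 1):
                base[IDX_N] = n_new
                total += np.exp(transition_logpmf(prev, StateVector(base),
                                                  rates))
        assert total == pytest.approx(1.0, abs=1e-10)


class TestInitialState:
    def test_multiplication_and_conservation(self):
        props = {"newborn": 0.1, "quarter": 0.2, "half": 0.2,
                 "adult_female": 0.4, "adult_male": 0.1}
        mu = initial_state_means(props, 4000.0)
        assert mu[IDX_N] == pytest.approx(400.0)
        assert mu[19:31].sum() == pytest.approx(1600.0)
        assert mu.sum() == pytest.approx(4000.0)

    def test_uniform_split_within_quarters(self):
        props = {"newborn": 0.0, "quarter": 0.5, "half": 0.0,
                 "adult_female": 0.5, "adult_male": 0.0}
        mu = initial_state_means(props, 1000.0)
        np.testing.assert_allclose(mu[1:6], 100.0)

    def test_bad_proportions(self):
        with pytest.raises(ValueError, match="sum to 1"):
            initial_state_means(
                {"newborn": 0.5, "quarter": 0.2, "half": 0.2,
                 "adult_female": 0.4, "adult_male": 0.1}, 100.0
            )

    def test_rounding_respects_feasibility(self):
        mu = np.zeros(N_COMP)
        mu[IDX_N] = 50.0  # more newborns than conceivable females
        Y = round_feasible_initial_state(mu)
        assert Y.N <= Y.conceivable()


class TestLeslieMatrix:
    def test_conveyor_is_permutation_like(self):
        L = leslie_matrix(make_rates())
        assert np.all(np.isin(L, [0.0, 1.0, -1.0]))
        # juvenile rows shift exactly
        assert L[g_col(2), IDX_N] == 1.0
        for k in range(3, 20):
            assert L[g_col(k), g_col(k - 1)] == 1.0
        assert L[IDX_N].sum() == 0.0  # r = 0

    def test_newborn_row_structure(self):
        rates = make_rates(r=0.3, s_a_f=0.9)
        L = leslie_matrix(rates)
        assert L[IDX_N, p_col(10)] == pytest.approx(0.3 * 0.9)
        assert L[IDX_N, p_col(11)] == pytest.approx(0.3 * 0.9)
        assert L[IDX_N, p_col(12)] == pytest.approx(0.3 * 0.9)
        assert L[IDX_N, IDX_N] == pytest.approx(-0.3 * 0.9)

    def test_dominant_eigenvalue_matches_long_run_growth(self):
        rates = make_rates(r=0.5, s_q=0.9, s_h=0.95, s_a_f=0.98,
                           s_a_m=0.97, phi=0.6)
        L = leslie_matrix(rates)
        lam = np.max(np.abs(np.linalg.eigvals(L)))
        mu = np.full(N_COMP, 100.0)
        for _ in range(400):
            mu = L @ mu
            mu_prev_total = mu.sum()
        growth = (L @ mu).sum() / mu_prev_total
        assert growth == pytest.approx(lam, rel=1e-6)


class TestKalman:
    @staticmethod
    def _toy_inputs(T=3, seed=0):
        rng = np.random.default_rng(seed)
        rates = VitalRates(
            r=np.full(T + 1, 0.3), s_q=np.full(T + 1, 0.9),
            s_h=np.full(T + 1, 0.95), s_a_f=np.full(T + 1, 0.97),
            s_a_m=np.full(T + 1, 0.96), phi=np.full(T + 1, 0.6),
        )
        mu0 = np.full(N_COMP, 50.0)
        sigma_sq = np.array([50.0, 100.0, 100.0, 200.0, 200.0])
        ground = rng.poisson(50.0, size=(T, 5)).astype(float) * np.array(
            [1, 5, 13, 13, 2]
        )
        return rates, mu0, sigma_sq, ground

    @staticmethod
    def _rates_at(rates, t):
        return VitalRates(*(np.asarray(getattr(rates, f))[t]
                            for f in ("r", "s_q", "s_h", "s_a_f", "s_a_m",
                                      "phi")))

    def test_matches_direct_mvn_marginalization(self):
        """KF log-likelihood equals the joint-normal density on a T=3 toy."""
        from scipy.stats import multivariate_normal

        T = 3
        rates, mu0, sigma_sq, ground = self._toy_inputs(T)
        var0 = 500.0
        got = kalman_loglik(
            VitalRates(*(np.asarray(getattr(rates, f))[1:]
                         for f in ("r", "s_q", "s_h", "s_a_f", "s_a_m",
                                   "phi"))),
            ground, sigma_sq, mu0, var0=var0,
        )
        # direct construction of the joint normal of the stacked observations:
        # propagate marginal means/covariances, then the cross blocks
        # Cov(Y_s, Y_t) = Cov(Y_s, Y_{t-1}) L_t' for t > s
        H = observation_matrix()
        mus, covs, Ls = [], [], []
        m = mu0.copy()
        P = np.eye(N_COMP) * var0
        mu_det = mu0.copy()
        for t in range(1, T + 1):
            rt = self._rates_at(rates, t)
            L = leslie_matrix(rt)
            Q = process_covariance(rt, mu_det)
            mu_det = L @ mu_det
            m = L @ m
            P = L @ P @ L.T + Q
            Ls.append(L)
            mus.append(m.copy())
            covs.append(P.copy())
        big = np.zeros((5 * T, 5 * T))
        for s in range(T):
            cross = covs[s]
            for t in range(s, T):
                if t > s:
                    cross = cross @ Ls[t].T
                block = H @ cross @ H.T
                big[5 * s:5 * s + 5, 5 * t:5 * t + 5] = block
                big[5 * t:5 * t + 5, 5 * s:5 * s + 5] = block.T
        for t in range(T):
            # observation variance evaluated on the deterministic mean path
            # (identical to the marginal mean here, since the prior mean is
            # mu0 and both propagate through the same L's)
            R = np.diag(np.maximum(H @ mus[t], 0.0) + sigma_sq)
            big[5 * t:5 * t + 5, 5 * t:5 * t + 5] += R
        mean_stack = np.concatenate([H @ mus[t] for t in range(T)])
        expected = multivariate_normal.logpdf(
            ground.reshape(-1), mean=mean_stack, cov=big, allow_singular=False
        )
        assert got == pytest.approx(expected, abs=1e-6)

    def test_moving_observation_away_decreases_loglik(self):
        T = 3
        rates, mu0, sigma_sq, ground = self._toy_inputs(T)
        sl = VitalRates(*(np.asarray(getattr(rates, f))[1:]
                          for f in ("r", "s_q", "s_h", "s_a_f", "s_a_m",
                                    "phi")))
        base = kalman_loglik(sl, ground, sigma_sq, mu0)
        worse = ground.copy()
        worse[-1, 3] += 2000.0
        assert kalman_loglik(sl, worse, sigma_sq, mu0) < base

    def test_aerial_observation_enters(self):
        T = 3
        rates, mu0, sigma_sq, ground = self._toy_inputs(T)
        sl = VitalRates(*(np.asarray(getattr(rates, f))[1:]
                          for f in ("r", "s_q", "s_h", "s_a_f", "s_a_m",
                                    "phi")))
        base = kalman_loglik(sl, ground, sigma_sq, mu0)
        with_aerial = kalman_loglik(
            sl, ground, sigma_sq, mu0,
            aerial=[(2, 4000.0, 300.0)], K=2.0, sigma_psi_sq=10000.0,
        )
        assert with_aerial != base
        assert np.isfinite(with_aerial)
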