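"""Latent state vector, stochastic monthly transitions and their log-pmf.

The population is tracked at monthly resolution in 34 integer components:

====  =========  ====================================================
cols  name       meaning
====  =========  ====================================================
0     N          newborns, age [0, 1) months
1-18  G(2..19)   juvenile cohorts, cohort k holds ages [k-1, k)
19-30 P(1..12)   adult females that last gave birth l months ago
                 (l = 12 means >= 12, i.e. available to conceive)
31    Fa         adult females newly recruited this month
32    Ma         adult males newly recruited this month
33    Mb         surviving (previously recruited) adult males
====  =========  ====================================================

Quarters are cohorts 2..6, half-yearlings 7..19.  Only females in P(11) and
P(12) can conceive (11-month cycle: 8 months gestation + 3 lactation), so
births this month are Binomial(P(t,11) + P(t,12), r(t)) *after* the adult
female classes have been advanced — the within-month order is: adult female
survival, recruitment and male survival, juvenile cohort advancement, births.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._dists import binom_logpmf, trinomial_logpmf, clamp_prob
from .vitalrates import VitalRates

N_COMP = 34
IDX_N = 0
IDX_G = slice(1, 19)    # G(2)..G(19)
IDX_P = slice(19, 31)   # P(1)..P(12)
IDX_FA = 31
IDX_MA = 32
IDX_MB = 33

COMPONENT_NAMES = (
    ["N"]
    + [f"G{k}" for k in range(2, 20)]
    + [f"P{l}" for l in range(1, 13)]
    + ["Fa", "Ma", "Mb"]
)


def g_col(k: int) -> int:
    """Array column of cohort G(k), k = 2..19."""
    if not 2 <= k <= 19:
        raise ValueError("cohort index k must be in 2..19")
    return k - 1


def p_col(l: int) -> int:
    """Array column of pregnancy class P(l), l = 1..12."""
    if not 1 <= l <= 12:
        raise ValueError("pregnancy class l must be in 1..12")
    return 18 + l


@dataclass(frozen=True)
class StateVector:
    """One month's latent population; a thin view over a 34-vector."""

    y: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.y)
        if arr.shape != (N_COMP,):
            raise ValueError(f"state vector must have shape ({N_COMP},)")
        if np.any(arr < 0):
            raise ValueError("state components must be non-negative")
        object.__setattr__(self, "y", arr.astype(np.int64))

    @classmethod
    def from_components(cls, N=0, G=None, P=None, Fa=0, Ma=0, Mb=0) -> "StateVector":
        y = np.zeros(N_COMP, dtype=np.int64)
        y[IDX_N] = N
        if G is not None:
            y[IDX_G] = np.asarray(G, dtype=np.int64)
        if P is not None:
            y[IDX_P] = np.asarray(P, dtype=np.int64)
        y[IDX_FA] = Fa
        y[IDX_MA] = Ma
        y[IDX_MB] = Mb
        return cls(y)

    @property
    def N(self) -> int:
        return int(self.y[IDX_N])

    @property
    def G(self) -> np.ndarray:
        return self.y[IDX_G]

    @property
    def P(self) -> np.ndarray:
        return self.y[IDX_P]

    @property
    def Fa(self) -> int:
        return int(self.y[IDX_FA])

    @property
    def Ma(self) -> int:
        return int(self.y[IDX_MA])

    @property
    def Mb(self) -> int:
        return int(self.y[IDX_MB])

    @property
    def Q(self) -> int:
        return int(self.G[:5].sum())  # cohorts 2..6

    @property
    def H(self) -> int:
        return int(self.G[5:].sum())  # cohorts 7..19

    @property
    def F(self) -> int:
        return int(self.P.sum()) + self.Fa

    @property
    def M(self) -> int:
        return self.Ma + self.Mb

    @property
    def B(self) -> int:
        return self.N + self.Q + self.H + self.F + self.M

    def conceivable(self) -> int:
        """Females available to conceive: P(11) + P(12)."""
        return int(self.y[p_col(11)] + self.y[p_col(12)])

    def is_feasible_origin(self) -> bool:
        """Whether a transition out of this state is well-defined."""
        return self.N <= self.conceivable()


def derived_totals(Y: StateVector):
    """(Q, H, F, M, B) class totals of a state vector."""
    return Y.Q, Y.H, Y.F, Y.M, Y.B


def class_totals(traj: np.ndarray) -> np.ndarray:
    """(T+1, 5) array of (N, Q, H, F, M) for a (T+1, 34) trajectory."""
    traj = np.asarray(traj)
    N = traj[..., IDX_N]
    Q = traj[..., 1:6].sum(axis=-1)
    H = traj[..., 6:19].sum(axis=-1)
    F = traj[..., IDX_P].sum(axis=-1) + traj[..., IDX_FA]
    M = traj[..., IDX_MA] + traj[..., IDX_MB]
    return np.stack([N, Q, H, F, M], axis=-1)


def simulate_transition(prev: StateVector, rates: VitalRates, rng) -> StateVector:
    """Draw the next month's state given the previous one.

    Within-month order: (a) adult female classes, (b) adult recruitment and
    male survival, (c) juvenile cohorts, (d) births from the updated
    conceivable pool.
    """
    if not prev.is_feasible_origin():
        raise ValueError(
            f"infeasible origin: N = {prev.N} exceeds P(11)+P(12) = {prev.conceivable()}"
        )
    r = float(rates.r)
    s_q = float(rates.s_q)
    s_h = float(rates.s_h)
    saf = float(rates.s_a_f)
    sam = float(rates.s_a_m)
    phi = float(rates.phi)

    y = np.zeros(N_COMP, dtype=np.int64)
    # (a) adult females
    y[p_col(1)] = rng.binomial(prev.N, saf)
    for l in (2, 3):
        y[p_col(l)] = rng.binomial(prev.y[p_col(l - 1)], saf)
    y[p_col(4)] = rng.binomial(prev.y[p_col(3)] + prev.Fa, saf)
    for l in range(5, 12):
        y[p_col(l)] = rng.binomial(prev.y[p_col(l - 1)], saf)
    y[p_col(12)] = rng.binomial(prev.conceivable() - prev.N, saf)
    # (b) recruitment into adulthood and male survival
    p1, p2 = phi * saf, (1.0 - phi) * sam
    fa, ma, _ = rng.multinomial(prev.y[g_col(19)], [p1, p2, 1.0 - p1 - p2])
    y[IDX_FA] = fa
    y[IDX_MA] = ma
    y[IDX_MB] = rng.binomial(prev.Ma + prev.Mb, sam)
    # (c) juvenile cohorts
    y[g_col(2)] = rng.binomial(prev.N, s_q)
    for k in range(3, 7):
        y[g_col(k)] = rng.binomial(prev.y[g_col(k - 1)], s_q)
    for k in range(7, 20):
        y[g_col(k)] = rng.binomial(prev.y[g_col(k - 1)], s_h)
    # (d) births from the updated conceivable pool
    y[IDX_N] = rng.binomial(int(y[p_col(11)] + y[p_col(12)]), r)
    return StateVector(y)


def transition_logpmf(prev: StateVector, nxt: StateVector, rates: VitalRates) -> float:
    """Exact log-probability of one monthly transition; -inf if infeasible."""
    pv, nx = prev.y, nxt.y
    r = clamp_prob(float(rates.r))
    s_q = clamp_prob(float(rates.s_q))
    s_h = clamp_prob(float(rates.s_h))
    saf = clamp_prob(float(rates.s_a_f))
    sam = clamp_prob(float(rates.s_a_m))
    phi = clamp_prob(float(rates.phi))

    terms = []
    terms.append(binom_logpmf(nx[p_col(1)], pv[IDX_N], saf))
    for l in (2, 3):
        terms.append(binom_logpmf(nx[p_col(l)], pv[p_col(l - 1)], saf))
    terms.append(binom_logpmf(nx[p_col(4)], pv[p_col(3)] + pv[IDX_FA], saf))
    for l in range(5, 12):
        terms.append(binom_logpmf(nx[p_col(l)], pv[p_col(l - 1)], saf))
    terms.append(
        binom_logpmf(nx[p_col(12)], pv[p_col(11)] + pv[p_col(12)] - pv[IDX_N], saf)
    )
    terms.append(
        trinomial_logpmf(nx[IDX_FA], nx[IDX_MA], pv[g_col(19)],
                         phi * saf, (1.0 - phi) * sam)
    )
    terms.append(binom_logpmf(nx[IDX_MB], pv[IDX_MA] + pv[IDX_MB], sam))
    terms.append(binom_logpmf(nx[g_col(2)], pv[IDX_N], s_q))
    for k in range(3, 7):
        terms.append(binom_logpmf(nx[g_col(k)], pv[g_col(k - 1)], s_q))
    for k in range(7, 20):
        terms.append(binom_logpmf(nx[g_col(k)], pv[g_col(k - 1)], s_h))
    terms.append(binom_logpmf(nx[IDX_N], nx[p_col(11)] + nx[p_col(12)], r))
    total = float(np.sum(terms))
    return total


def initial_state_means(june_proportions: dict, aerial_total_t0: float) -> np.ndarray:
    """Real-valued mean initial state from class proportions and a total.

    ``june_proportions`` has keys ``newborn``, ``quarter``, ``half``,
    ``adult_female``, ``adult_male`` summing to 1.  The quarter mean is split
    uniformly over G(2..6), half-yearlings over G(7..19), adult females over
    P(1..12); adult males go to Mb (none are recruited "this month" at t=0).
    """
    keys = ("newborn", "quarter", "half", "adult_female", "adult_male")
    props = np.array([june_proportions[k] for k in keys], dtype=float)
    if np.any(props < 0):
        raise ValueError("proportions must be non-negative")
    if abs(props.sum() - 1.0) > 1e-6:
        raise ValueError(f"proportions must sum to 1, got {props.sum():.6f}")
    n_mean, q_mean, h_mean, f_mean, m_mean = props * float(aerial_total_t0)
    mu = np.zeros(N_COMP, dtype=float)
    mu[IDX_N] = n_mean
    mu[1:6] = q_mean / 5.0
    mu[6:19] = h_mean / 13.0
    mu[IDX_P] = f_mean / 12.0
    mu[IDX_MB] = m_mean
    return mu


def round_feasible_initial_state(mu: np.ndarray) -> StateVector:
    """Round mean initial state to integers, enforcing N <= P(11)+P(12)."""
    y = np.rint(np.asarray(mu)).astype(np.int64)
    y = np.maximum(y, 0)
    pool = y[p_col(11)] + y[p_col(12)]
    if y[IDX_N] > pool:
        y[IDX_N] = pool
    return StateVector(y)


def leslie_matrix(rates: VitalRates) -> np.ndarray:
    """Expected one-month projection matrix L with E[Y_t | Y_{t-1}] = L Y_{t-1}.

    Built as the composition of the within-month stages: stage 1 advances
    every component except N, stage 2 draws newborns from the *updated*
    conceivable pool, so the N row carries r*s_a_f on the P(10..12) columns
    and -r*s_a_f on the N column (a generalized Leslie form with a negative
    entry).
    """
    r = float(rates.r)
    s_q = float(rates.s_q)
    s_h = float(rates.s_h)
    saf = float(rates.s_a_f)
    sam = float(rates.s_a_m)
    phi = float(rates.phi)

    L1 = np.zeros((N_COMP, N_COMP))
    L1[p_col(1), IDX_N] = saf
    for l in (2, 3):
        L1[p_col(l), p_col(l - 1)] = saf
    L1[p_col(4), p_col(3)] = saf
    L1[p_col(4), IDX_FA] = saf
    for l in range(5, 12):
        L1[p_col(l), p_col(l - 1)] = saf
    L1[p_col(12), p_col(11)] = saf
    L1[p_col(12), p_col(12)] = saf
    L1[p_col(12), IDX_N] = -saf
    L1[IDX_FA, g_col(19)] = phi * saf
    L1[IDX_MA, g_col(19)] = (1.0 - phi) * sam
    L1[IDX_MB, IDX_MA] = sam
    L1[IDX_MB, IDX_MB] = sam
    L1[g_col(2), IDX_N] = s_q
    for k in range(3, 7):
        L1[g_col(k), g_col(k - 1)] = s_q
    for k in range(7, 20):
        L1[g_col(k), g_col(k - 1)] = s_h

    L2 = np.eye(N_COMP)
    L2[IDX_N, IDX_N] = 0.0
    L2[IDX_N, p_col(11)] = r
    L2[IDX_N, p_col(12)] = r
    return L2 @ L1


def _stage_covariances(rates: VitalRates, mu_prev: np.ndarray):
    """Process noise of the two within-month stages at a mean state.

    Binomial/multinomial variances are evaluated with trial counts set to
    the (clamped non-negative) mean of the conditioning state, which makes
    the approximating model linear-Gaussian.
    """
    r = float(rates.r)
    s_q = float(rates.s_q)
    s_h = float(rates.s_h)
    saf = float(rates.s_a_f)
    sam = float(rates.s_a_m)
    phi = float(rates.phi)
    m = np.maximum(np.asarray(mu_prev, dtype=float), 0.0)

    Q1 = np.zeros((N_COMP, N_COMP))

    def bv(n, p):
        return max(n, 0.0) * p * (1.0 - p)

    Q1[p_col(1), p_col(1)] = bv(m[IDX_N], saf)
    for l in (2, 3):
        Q1[p_col(l), p_col(l)] = bv(m[p_col(l - 1)], saf)
    Q1[p_col(4), p_col(4)] = bv(m[p_col(3)] + m[IDX_FA], saf)
    for l in range(5, 12):
        Q1[p_col(l), p_col(l)] = bv(m[p_col(l - 1)], saf)
    Q1[p_col(12), p_col(12)] = bv(
        m[p_col(11)] + m[p_col(12)] - m[IDX_N], saf
    )
    n19 = max(m[g_col(19)], 0.0)
    p1, p2 = phi * saf, (1.0 - phi) * sam
    Q1[IDX_FA, IDX_FA] = n19 * p1 * (1.0 - p1)
    Q1[IDX_MA, IDX_MA] = n19 * p2 * (1.0 - p2)
    Q1[IDX_FA, IDX_MA] = Q1[IDX_MA, IDX_FA] = -n19 * p1 * p2
    Q1[IDX_MB, IDX_MB] = bv(m[IDX_MA] + m[IDX_MB], sam)
    Q1[g_col(2), g_col(2)] = bv(m[IDX_N], s_q)
    for k in range(3, 7):
        Q1[g_col(k), g_col(k)] = bv(m[g_col(k - 1)], s_q)
    for k in range(7, 20):
        Q1[g_col(k), g_col(k)] = bv(m[g_col(k - 1)], s_h)

    mu1 = leslie_stage1_mean(rates, m)
    Q2 = np.zeros((N_COMP, N_COMP))
    pool = max(mu1[p_col(11)] + mu1[p_col(12)], 0.0)
    Q2[IDX_N, IDX_N] = pool * r * (1.0 - r)
    return Q1, Q2


def leslie_stage1_mean(rates: VitalRates, mu_prev: np.ndarray) -> np.ndarray:
    """Mean state after stage 1 (everything except births)."""
    L = leslie_matrix(rates)
    # stage-1 mean equals the full projection except for the N entry, which
    # stage 2 overwrites; reconstruct it by zeroing r.
    zero_r = VitalRates(
        r=np.asarray(0.0), s_q=rates.s_q, s_h=rates.s_h,
        s_a_f=rates.s_a_f, s_a_m=rates.s_a_m, phi=rates.phi,
    )
    return leslie_matrix(zero_r) @ np.asarray(mu_prev, dtype=float)


def process_covariance(rates: VitalRates, mu_prev: np.ndarray) -> np.ndarray:
    """One-step process covariance of the linear-Gaussian approximation."""
    Q1, Q2 = _stage_covariances(rates, mu_prev)
    r = float(rates.r)
    L2 = np.eye(N_COMP)
    L2[IDX_N, IDX_N] = 0.0
    L2[IDX_N, p_col(11)] = r
    L2[IDX_N, p_col(12)] = r
    return L2 @ Q1 @ L2.T + Q2


# observation matrix mapping the 34-vector to the five observed class totals
def observation_matrix() -> np.ndarray:
    H = np.zeros((5, N_COMP))
    H[0, IDX_N] = 1.0
    H[1, 1:6] = 1.0
    H[2, 6:19] = 1.0
    H[3, IDX_P] = 1.0
    H[3, IDX_FA] = 1.0
    H[4, IDX_MA] = 1.0
    H[4, IDX_MB] = 1.0
    return H


def kalman_loglik(
    rates_seq,
    ground,
    sigma_sq,
    mu0: np.ndarray,
    var0: float = 20000.0,
    aerial=None,
    K: float | None = None,
    sigma_psi_sq: float | None = None,
) -> float:
    """Log-likelihood of the linear-Gaussian (Leslie/Kalman) approximation.

    Parameters
    ----------
    rates_seq : VitalRates with array fields of length T (months 1..T).
    ground : (T, 5) array of observed class counts for months 1..T.
    sigma_sq : length-5 observation variance offsets (class variance is
        predicted mean + sigma_i^2, evaluated along the deterministic mean
        trajectory so the model stays exactly linear-Gaussian).
    mu0, var0 : prior mean vector and isotropic variance of the initial state.
    aerial : optional list of (month t, psi, se) ecosystem totals; each adds
        one observation row K * total(Y_t) with variance se^2 + sigma_psi_sq.
    """
    ground = np.asarray(ground, dtype=float)
    T = ground.shape[0]
    sigma_sq = np.asarray(sigma_sq, dtype=float)
    Hc = observation_matrix()
    aerial_by_t = {}
    if aerial is not None:
        for (ta, psi, se) in aerial:
            aerial_by_t[int(ta)] = (float(psi), float(se))

    m = np.asarray(mu0, dtype=float).copy()
    P = np.eye(N_COMP) * float(var0)
    mu_det = m.copy()  # deterministic mean trajectory for variance evaluation
    ll = 0.0
    for t in range(1, T + 1):
        rt = rates_seq.at(t - 1)
        L = leslie_matrix(rt)
        Q = process_covariance(rt, mu_det)
        mu_det = L @ mu_det
        m = L @ m
        P = L @ P @ L.T + Q
        # observation stack for month t
        rows = [Hc]
        preds = Hc @ mu_det
        obs = [ground[t - 1]]
        rvar = [np.maximum(preds, 0.0) + sigma_sq]
        if t in aerial_by_t:
            psi, se = aerial_by_t[t]
            row = np.full((1, N_COMP), float(K))
            rows.append(row)
            obs.append(np.array([psi]))
            rvar.append(np.array([se ** 2 + float(sigma_psi_sq)]))
        Ht = np.vstack(rows)
        zt = np.concatenate(obs)
        Rt = np.diag(np.concatenate(rvar))
        v = zt - Ht @ m
        S = Ht @ P @ Ht.T + Rt
        sign, logdet = np.linalg.slogdet(S)
        if sign <= 0:
            raise np.linalg.LinAlgError(
                f"innovation covariance not positive definite at month {t}"
            )
        sol = np.linalg.solve(S, v)
        ll += -0.5 * (len(zt) * np.log(2.0 * np.pi) + logdet + v @ sol)
        Kg = P @ Ht.T @ np.linalg.inv(S)
        m = m + Kg @ v
        P = (np.eye(N_COMP) - Kg @ Ht) @ P
        P = 0.5 * (P + P.T)
    return float(ll)
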