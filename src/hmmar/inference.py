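"""Variational-Bayes inference for the HMM with MAR observation models.

The generative model: a first-order Markov chain over ``K`` hidden states;
given state ``k``, each sample is Gaussian around a linear prediction from
lagged samples (the state's MAR coefficients ``W^(k)``).  Coefficients carry
a two-level automatic-relevance-determination (ARD) prior — a Gamma
precision per channel pair (spatial sparsity) times a Gamma precision per
lag (spectral sparsity) — noise precisions are Gamma (diagonal covariance)
or Wishart (full), and the transition matrix rows and initial distribution
are Dirichlet.

All priors are conjugate, so inference alternates closed-form coordinate
updates: a weighted Bayesian regression per state for the coefficients, a
forward-backward pass for the state time courses, Dirichlet count updates
for the transitions, and the variational free energy (negative evidence
bound, lower is better) for monitoring and model selection.  The free
energy is guaranteed non-increasing over cycles up to round-off.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Optional

import numpy as np
from scipy.special import digamma, gammaln, multigammaln

from .datatypes import TimeSeriesData
from .model import (
    ClampingPlan,
    HMMMARConfig,
    InvalidConfigurationError,
    LagSet,
    build_design,
    fit_global_mar,
)

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))


class NumericalFailureError(RuntimeError):
    pass


class FitFailureError(RuntimeError):
    pass


class InitializationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Containers


@dataclass
class StateTimeCourse:
    """Per-sample state responsibilities and pairwise transition marginals.

    ``gamma[t, k]`` is the posterior probability of state ``k`` at sample
    ``t`` (rows sum to one).  ``xi`` holds one ``K x K`` joint marginal per
    within-segment transition, concatenated over segments in order;
    ``xi_from`` gives the absolute sample index each transition starts at.
    """

    gamma: np.ndarray
    xi: Optional[np.ndarray] = None
    xi_from: Optional[np.ndarray] = None
    hard_path: Optional[np.ndarray] = None

    @property
    def n_states(self) -> int:
        return self.gamma.shape[1]

    def hard(self) -> np.ndarray:
        """Most-probable state per sample (argmax of gamma, low index wins ties)."""
        if self.hard_path is not None:
            return self.hard_path
        return np.argmax(self.gamma, axis=1)

    def occupancy(self) -> np.ndarray:
        """Fraction of total soft mass per state."""
        return self.gamma.mean(axis=0)


@dataclass
class StatePosterior:
    """Posterior factors of one state's observation model."""

    W_mean: np.ndarray  # (p, N) posterior mean, clamped entries at fixed values
    W_cov: list  # per channel (n_free_j, n_free_j); single joint matrix if full noise
    free_cols: list  # per channel: integer index of free regressors
    # diagonal noise: Gamma(shape, rate) per channel
    noise_shape: Optional[np.ndarray] = None
    noise_rate: Optional[np.ndarray] = None
    # full noise: Wishart(dof, scale) on the precision, E[Omega] = dof * inv(scale)
    wishart_dof: Optional[float] = None
    wishart_scale: Optional[np.ndarray] = None
    sigma_shape: Optional[np.ndarray] = None  # (N, N) connection ARD
    sigma_rate: Optional[np.ndarray] = None
    alpha_shape: Optional[np.ndarray] = None  # (L,) lag ARD
    alpha_rate: Optional[np.ndarray] = None


@dataclass
class HMMMARPosterior:
    """Full posterior over states, noise, ARD and Markov-chain parameters."""

    states: list[StatePosterior]
    trans_counts: np.ndarray  # (K, K) Dirichlet counts per row
    init_counts: np.ndarray  # (K,)
    lagset: LagSet
    n_channels: int

    @property
    def K(self) -> int:
        return len(self.states)

    def transition_matrix(self) -> np.ndarray:
        """Posterior-mean transition probabilities."""
        return self.trans_counts / self.trans_counts.sum(axis=1, keepdims=True)

    def expected_noise_covariance(self, k: int) -> np.ndarray:
        st = self.states[k]
        if st.noise_shape is not None:
            return np.diag(st.noise_rate / np.maximum(st.noise_shape - 1, 1e-12))
        return st.wishart_scale / max(st.wishart_dof - self.n_channels - 1, 1e-12)

    def expected_noise_precision(self, k: int) -> np.ndarray:
        st = self.states[k]
        if st.noise_shape is not None:
            return np.diag(st.noise_shape / st.noise_rate)
        return st.wishart_dof * np.linalg.inv(st.wishart_scale)


@dataclass
class FitResult:
    """Converged fit: posterior, state time courses, free-energy trace."""

    posterior: HMMMARPosterior
    stc: StateTimeCourse
    free_energy_trace: np.ndarray
    config: HMMMARConfig
    restart_id: int
    seed: int
    converged: bool
    low_occupancy_states: list[int] = field(default_factory=list)

    @property
    def free_energy(self) -> float:
        return float(self.free_energy_trace[-1])


# ---------------------------------------------------------------------------
# Design cache


class _Design:
    """Precomputed regression quantities shared across VB cycles."""

    def __init__(self, data: TimeSeriesData, config: HMMMARConfig):
        self.config = config
        lagset = config.lagset
        N = data.n_channels
        L = len(lagset)
        self.intercept = config.observation == "gaussian-envelope"
        X, Y, idx = build_design(data, lagset)
        if self.intercept:
            X = np.concatenate([X, np.ones((X.shape[0], 1))], axis=1)
        self.X, self.Y, self.target_idx = X, Y, idx
        self.N, self.L = N, L
        self.p = X.shape[1]
        plan = config.clamping or ClampingPlan.free(N)
        mask = plan.free_mask(N, L) if L else np.zeros((0, N), bool)
        if self.intercept:
            mask = np.concatenate([mask, np.ones((1, N), bool)])
        self.free_mask = mask  # (p, N)
        fixed = plan.fixed_values(N, L) if L else np.zeros((0, N))
        if self.intercept:
            fixed = np.concatenate([fixed, np.zeros((1, N))])
        self.fixed_W = fixed
        self.fixed_pred = X @ fixed  # (n_targets, N)
        self.free_cols = [np.flatnonzero(mask[:, j]) for j in range(N)]
        # map regressor row -> (lag index, source channel); intercept -> (-1, -1)
        lag_of = np.repeat(np.arange(L), N)
        src_of = np.tile(np.arange(N), L)
        if self.intercept:
            lag_of = np.concatenate([lag_of, [-1]])
            src_of = np.concatenate([src_of, [-1]])
        self.lag_of, self.src_of = lag_of, src_of
        self.data_var = float(np.var(data.values))
        self.segments = data.segments
        self.T = data.n_samples


# ---------------------------------------------------------------------------
# Initialization


def initialize(
    data: TimeSeriesData, config: HMMMARConfig, seed: int | None = None
) -> StateTimeCourse:
    """Initial state time course from windowed MAR fits clustered by k-means.

    Short ridge-regularised MAR models are fitted in non-overlapping windows
    and their coefficient vectors clustered into ``K`` groups; window
    members seed soft responsibilities (0.9 for the winning state).  The
    scheme is deterministic given ``seed``.
    """
    from sklearn.cluster import KMeans

    config.validate(data.n_channels)
    seed = config.training.seed if seed is None else seed
    K = config.K
    T = data.n_samples
    if K == 1:
        return StateTimeCourse(gamma=np.ones((T, 1)))
    lagset = config.lagset
    P = lagset.P if len(lagset) else 1
    win = max(config.training.init_window_factor * P, 2 * data.n_channels + 2)
    if T <= P * K:
        raise InitializationError(
            f"series too short to initialise {K} states at order {P}"
        )
    X, Y, idx = build_design(data, lagset) if len(lagset) else (None, None, None)
    if X is None:
        # Gaussian observations: cluster windowed means/log-variances
        feats, owners = [], []
        for a, b in data.segments:
            for s in range(a, b - win + 1, win):
                seg = data.values[s : s + win]
                feats.append(np.concatenate([seg.mean(0), np.log(seg.var(0) + 1e-12)]))
                owners.append((s, s + win))
        feats = np.asarray(feats)
    else:
        feats, owners = [], []
        n = X.shape[0]
        p = X.shape[1]
        for s in range(0, n - win + 1, win):
            Xw, Yw = X[s : s + win], Y[s : s + win]
            coef = np.linalg.solve(
                Xw.T @ Xw + 1e-3 * win * np.eye(p), Xw.T @ Yw
            )
            feats.append(coef.ravel())
            owners.append((idx[s], idx[min(s + win, n) - 1] + 1))
        feats = np.asarray(feats)
    if feats.shape[0] < K:
        raise InitializationError("not enough windows to seed all states")
    km = KMeans(n_clusters=K, n_init=5, random_state=seed % (2**32))
    labels = km.fit_predict(feats)
    gamma = np.full((T, K), 1.0 / K)
    soft_win = 0.9
    soft_rest = (1.0 - soft_win) / max(K - 1, 1)
    for (a, b), lab in zip(owners, labels):
        gamma[a:b] = soft_rest
        gamma[a:b, lab] = soft_win
    return StateTimeCourse(gamma=gamma)


# ---------------------------------------------------------------------------
# Observation-model update


def _symmetrise_sigma(shape: np.ndarray, rate: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return 0.5 * (shape + shape.T), 0.5 * (rate + rate.T)


def update_observation_model(
    data: TimeSeriesData,
    stc: StateTimeCourse,
    posterior: Optional[HMMMARPosterior],
    config: HMMMARConfig,
    design: Optional[_Design] = None,
) -> HMMMARPosterior:
    """Conjugate updates of coefficients, noise and ARD precisions.

    Each state solves a responsibility-weighted Bayesian regression over its
    free coefficients with prior precision ``E[sigma_ij] * E[alpha_l]``, then
    refreshes the Gamma (or Wishart) noise posterior and the two ARD Gamma
    posteriors.  Clamped coefficients keep their fixed values with zero
    posterior variance.
    """
    design = design or _Design(data, config)
    K = config.K
    N, L, p = design.N, design.L, design.p
    pri = config.priors
    gamma_t = stc.gamma[design.target_idx]  # (n, K)
    X, Y = design.X, design.Y
    Yc = Y - design.fixed_pred

    # current ARD expectations (prior means on the first pass)
    def ard_expectations(st: Optional[StatePosterior]):
        if st is None or st.sigma_shape is None:
            E_sig = np.full((N, N), pri.sigma_shape / pri.sigma_rate)
            E_alp = np.full((max(L, 1),), pri.alpha_shape / pri.alpha_rate)
        else:
            E_sig = st.sigma_shape / st.sigma_rate
            E_alp = st.alpha_shape / st.alpha_rate
        return E_sig, E_alp

    def noise_expectation(st: Optional[StatePosterior]) -> np.ndarray:
        if st is None:
            return np.full(N, 1.0 / max(design.data_var, 1e-12)) if (
                config.noise_cov == "diagonal"
            ) else np.eye(N) / max(design.data_var, 1e-12)
        if config.noise_cov == "diagonal":
            return st.noise_shape / st.noise_rate
        return st.wishart_dof * np.linalg.inv(st.wishart_scale)

    intercept_prec = 1e-3

    new_states: list[StatePosterior] = []
    pooled_noise_stats = []  # for shared noise
    for k in range(K):
        st_prev = posterior.states[k] if posterior is not None else None
        E_sig, E_alp = ard_expectations(st_prev)
        if config.symmetric_sigma:
            E_sig = 0.5 * (E_sig + E_sig.T)
        E_om = noise_expectation(st_prev)
        g = gamma_t[:, k]
        Xg = X * g[:, None]
        XtGX = Xg.T @ X  # (p, p)
        XtGY = Xg.T @ Yc  # (p, N)
        sum_g = float(g.sum())

        prior_prec_full = np.empty((p, N))
        for j in range(N):
            pr = np.where(
                design.lag_of >= 0,
                E_sig[np.maximum(design.src_of, 0), j]
                * E_alp[np.maximum(design.lag_of, 0)],
                intercept_prec,
            )
            prior_prec_full[:, j] = pr

        W_mean = design.fixed_W.copy()
        W_cov: list = []
        if config.noise_cov == "diagonal":
            for j in range(N):
                cols = design.free_cols[j]
                if cols.size == 0:
                    W_cov.append(np.zeros((0, 0)))
                    continue
                prec = np.diag(prior_prec_full[cols, j]) + E_om[j] * XtGX[
                    np.ix_(cols, cols)
                ]
                try:
                    cov = np.linalg.inv(prec)
                except np.linalg.LinAlgError as exc:
                    raise NumericalFailureError(
                        f"state {k} channel {j}: singular coefficient precision"
                    ) from exc
                mean = cov @ (E_om[j] * XtGY[cols, j])
                W_mean[cols, j] = mean
                W_cov.append(cov)
        else:
            free_idx = [design.free_cols[j] for j in range(N)]
            sizes = [c.size for c in free_idx]
            tot = sum(sizes)
            prec = np.zeros((tot, tot))
            rhs = np.zeros(tot)
            offs = np.cumsum([0] + sizes)
            for j in range(N):
                cj = free_idx[j]
                prec[offs[j] : offs[j + 1], offs[j] : offs[j + 1]] += np.diag(
                    prior_prec_full[cj, j]
                )
                for j2 in range(N):
                    c2 = free_idx[j2]
                    prec[offs[j] : offs[j + 1], offs[j2] : offs[j2 + 1]] += (
                        E_om[j, j2] * XtGX[np.ix_(cj, c2)]
                    )
                rhs[offs[j] : offs[j + 1]] = (XtGY @ E_om[:, j])[cj]
            try:
                cov = np.linalg.inv(prec)
            except np.linalg.LinAlgError as exc:
                raise NumericalFailureError(
                    f"state {k}: singular joint coefficient precision"
                ) from exc
            mean = cov @ rhs
            for j in range(N):
                W_mean[free_idx[j], j] = mean[offs[j] : offs[j + 1]]
            W_cov = [cov, offs, free_idx]

        # --- noise update ---
        resid = Yc - X @ (W_mean - design.fixed_W)
        if config.noise_cov == "diagonal":
            noise_shape = np.full(N, pri.noise_shape) + 0.5 * sum_g
            noise_rate = np.full(N, pri.noise_rate)
            for j in range(N):
                cols = design.free_cols[j]
                quad = float(np.sum(g * resid[:, j] ** 2))
                if cols.size:
                    quad += float(
                        np.sum(XtGX[np.ix_(cols, cols)] * W_cov[j])
                    )
                noise_rate[j] += 0.5 * quad
            wis_dof = wis_scale = None
        else:
            cov, offs, free_idx = W_cov
            E_rr = (resid * g[:, None]).T @ resid
            for j in range(N):
                for j2 in range(N):
                    blk = cov[offs[j] : offs[j + 1], offs[j2] : offs[j2 + 1]]
                    E_rr[j, j2] += float(
                        np.sum(XtGX[np.ix_(free_idx[j], free_idx[j2])] * blk.T)
                    )
            dof0 = pri.wishart_dof if pri.wishart_dof else N + 1
            scale0 = (
                pri.wishart_scale
                if pri.wishart_scale is not None
                else np.eye(N) * design.data_var
            )
            wis_dof = dof0 + sum_g
            wis_scale = scale0 + 0.5 * (E_rr + E_rr.T)
            noise_shape = noise_rate = None
        pooled_noise_stats.append((sum_g, noise_rate, wis_scale))

        # --- ARD updates ---
        if L:
            # second moments of free coefficients
            M2 = np.zeros((p, N))
            if config.noise_cov == "diagonal":
                for j in range(N):
                    cols = design.free_cols[j]
                    if cols.size:
                        M2[cols, j] = W_mean[cols, j] ** 2 + np.diag(W_cov[j])
            else:
                cov, offs, free_idx = W_cov
                dvar = np.diag(cov)
                for j in range(N):
                    M2[free_idx[j], j] = (
                        W_mean[free_idx[j], j] ** 2 + dvar[offs[j] : offs[j + 1]]
                    )
            lagmask = design.lag_of >= 0
            sigma_shape = np.full((N, N), pri.sigma_shape)
            sigma_rate = np.full((N, N), pri.sigma_rate)
            alpha_shape = np.full(L, pri.alpha_shape)
            alpha_rate = np.full(L, pri.alpha_rate)
            free2 = design.free_mask & lagmask[:, None]
            for j in range(N):
                rows = np.flatnonzero(free2[:, j])
                if rows.size == 0:
                    continue
                src = design.src_of[rows]
                lag = design.lag_of[rows]
                np.add.at(sigma_shape[:, j], src, 0.5)
                np.add.at(sigma_rate[:, j], src, 0.5 * E_alp[lag] * M2[rows, j])
            if config.symmetric_sigma:
                sigma_shape, sigma_rate = _symmetrise_sigma(sigma_shape, sigma_rate)
            # alpha update must see the refreshed sigma expectations, or the
            # sigma*alpha scale ambiguity makes the pair see-saw and the free
            # energy lose its descent guarantee
            E_sig = sigma_shape / sigma_rate
            if config.symmetric_sigma:
                E_sig = 0.5 * (E_sig + E_sig.T)
            for j in range(N):
                rows = np.flatnonzero(free2[:, j])
                if rows.size == 0:
                    continue
                src = design.src_of[rows]
                lag = design.lag_of[rows]
                np.add.at(alpha_shape, lag, 0.5)
                np.add.at(alpha_rate, lag, 0.5 * E_sig[src, j] * M2[rows, j])
        else:
            sigma_shape = sigma_rate = None
            alpha_shape = alpha_rate = None

        new_states.append(
            StatePosterior(
                W_mean=W_mean,
                W_cov=W_cov,
                free_cols=design.free_cols,
                noise_shape=noise_shape,
                noise_rate=noise_rate,
                wishart_dof=wis_dof,
                wishart_scale=wis_scale,
                sigma_shape=sigma_shape,
                sigma_rate=sigma_rate,
                alpha_shape=alpha_shape,
                alpha_rate=alpha_rate,
            )
        )

    if config.noise_shared and K > 1:
        if config.noise_cov == "diagonal":
            shape = np.full(N, pri.noise_shape) + 0.5 * sum(
                s for s, _, _ in pooled_noise_stats
            )
            rate = np.full(N, pri.noise_rate) + sum(
                (r - pri.noise_rate) for _, r, _ in pooled_noise_stats
            )
            for st in new_states:
                st.noise_shape, st.noise_rate = shape, rate
        else:
            dof0 = pri.wishart_dof if pri.wishart_dof else N + 1
            scale0 = (
                pri.wishart_scale
                if pri.wishart_scale is not None
                else np.eye(N) * design.data_var
            )
            dof = dof0 + sum(s for s, _, _ in pooled_noise_stats)
            scale = scale0 + sum((sc - scale0) for _, _, sc in pooled_noise_stats)
            for st in new_states:
                st.wishart_dof, st.wishart_scale = dof, scale

    trans = posterior.trans_counts if posterior is not None else np.full(
        (K, K), pri.dirichlet_trans
    )
    init = posterior.init_counts if posterior is not None else np.full(
        K, pri.dirichlet_init
    )
    return HMMMARPosterior(
        states=new_states,
        trans_counts=trans,
        init_counts=init,
        lagset=config.lagset,
        n_channels=N,
    )


# ---------------------------------------------------------------------------
# Expected log-likelihood and forward-backward


def _expected_loglik(
    posterior: HMMMARPosterior, config: HMMMARConfig, design: _Design
) -> np.ndarray:
    """E[log p(y_t | x_t=k)] for every valid target sample, (n, K)."""
    X, Y = design.X, design.Y
    N = design.N
    n = X.shape[0]
    p = design.p
    K = posterior.K
    ll = np.empty((n, K))
    diag_noise = config.noise_cov == "diagonal"
    if diag_noise:
        # one GEMM for all residuals and one for all quadratic-form factors
        W_cat = np.concatenate([st.W_mean for st in posterior.states], axis=1)
        resid_all = Y[:, None, :] - (X @ W_cat).reshape(n, K, N)
        blocks = []
        width = np.zeros((K, N), dtype=int)
        for k, st in enumerate(posterior.states):
            E_om = st.noise_shape / st.noise_rate
            for j in range(N):
                cols = st.free_cols[j]
                if cols.size == 0:
                    continue
                Lc = np.linalg.cholesky(st.W_cov[j] + 1e-14 * np.eye(cols.size))
                B = np.zeros((p, cols.size))
                B[cols] = Lc * np.sqrt(E_om[j])
                blocks.append(B)
                width[k, j] = cols.size
        quad_cov = np.zeros((n, K, N))
        if blocks:
            Q = X @ np.concatenate(blocks, axis=1)
            Q *= Q
            off = 0
            for k in range(K):
                for j in range(N):
                    w = width[k, j]
                    if w:
                        quad_cov[:, k, j] = Q[:, off : off + w].sum(axis=1)
                        off += w
        for k, st in enumerate(posterior.states):
            E_om = st.noise_shape / st.noise_rate
            E_logom = digamma(st.noise_shape) - np.log(st.noise_rate)
            acc = 0.5 * float(np.sum(E_logom)) - 0.5 * N * _LOG2PI
            quad = resid_all[:, k] ** 2 @ E_om + quad_cov[:, k].sum(axis=1)
            ll[:, k] = acc - 0.5 * quad
        return ll
    # full (Wishart) noise covariance
    for k, st in enumerate(posterior.states):
        resid = Y - X @ st.W_mean
        E_om = st.wishart_dof * np.linalg.inv(st.wishart_scale)
        _, logdetB = np.linalg.slogdet(st.wishart_scale)
        E_logdet = (
            float(np.sum(digamma(0.5 * (st.wishart_dof - np.arange(N)))))
            + N * np.log(2.0)
            - logdetB
        )
        quad = np.einsum("ti,ij,tj->t", resid, E_om, resid)
        cov, offs, free_idx = st.W_cov
        for j in range(N):
            for j2 in range(N):
                blk = cov[offs[j] : offs[j + 1], offs[j2] : offs[j2 + 1]]
                if blk.size:
                    quad += E_om[j, j2] * np.einsum(
                        "ti,ij,tj->t", X[:, free_idx[j]], blk, X[:, free_idx[j2]]
                    )
        ll[:, k] = 0.5 * E_logdet - 0.5 * N * _LOG2PI - 0.5 * quad
    return ll


def _expected_log_transition(
    posterior: HMMMARPosterior,
) -> tuple[np.ndarray, np.ndarray]:
    tc = posterior.trans_counts
    log_A = digamma(tc) - digamma(tc.sum(axis=1, keepdims=True))
    ic = posterior.init_counts
    log_pi = digamma(ic) - digamma(ic.sum())
    return log_A, log_pi


def infer_state_timecourses(
    data: TimeSeriesData,
    posterior: HMMMARPosterior,
    config: HMMMARConfig,
    design: Optional[_Design] = None,
    return_evidence: bool = False,
):
    """Forward-backward smoothing of the hidden state chain per segment.

    Emission evidence is the expected log likelihood under the coefficient
    and noise posteriors; transition and initial probabilities enter through
    their expected logs (geometric-mean parametrisation of variational HMM
    inference).  The first ``P`` samples of each segment, which lack a full
    lag window, receive uniform emission evidence.  Returns normalised
    ``gamma`` and pairwise marginals ``xi``; with ``return_evidence`` also
    the per-segment log normalisation sum (the chain's contribution to the
    evidence bound).
    """
    design = design or _Design(data, config)
    K = posterior.K
    T = design.T
    ll_valid = _expected_loglik(posterior, config, design)
    ll = np.zeros((T, K))
    ll[design.target_idx] = ll_valid
    log_A, log_pi = _expected_log_transition(posterior)
    A = np.exp(log_A)
    pi = np.exp(log_pi)

    gamma = np.empty((T, K))
    xi_full = np.zeros((max(T - 1, 0), K, K))
    xi_mask = np.zeros(max(T - 1, 0), bool)
    logZ = 0.0
    # batch the recursion over segments of equal length (e.g. equal trials)
    by_len: dict[int, list[tuple[int, int]]] = {}
    for seg in design.segments:
        by_len.setdefault(seg[1] - seg[0], []).append(seg)
    for Ls, segs in by_len.items():
        starts = np.array([a for a, _ in segs])
        llseg = np.stack([ll[a:b] for a, b in segs])  # (S, Ls, K)
        shift = llseg.max(axis=2)
        e = np.exp(llseg - shift[..., None])
        S = len(segs)
        alpha = np.empty((S, Ls, K))
        c = np.empty((S, Ls))
        af = pi[None] * e[:, 0]
        c[:, 0] = af.sum(axis=1)
        if not np.all(np.isfinite(c[:, 0])) or np.any(c[:, 0] <= 0):
            raise NumericalFailureError("forward pass underflow at segment start")
        alpha[:, 0] = af / c[:, 0, None]
        for t in range(1, Ls):
            af = (alpha[:, t - 1] @ A) * e[:, t]
            c[:, t] = af.sum(axis=1)
            if not np.all(np.isfinite(c[:, t])) or np.any(c[:, t] <= 0):
                raise NumericalFailureError(f"forward pass underflow at offset {t}")
            alpha[:, t] = af / c[:, t, None]
        beta = np.empty((S, Ls, K))
        beta[:, -1] = 1.0
        for t in range(Ls - 2, -1, -1):
            beta[:, t] = ((e[:, t + 1] * beta[:, t + 1]) @ A.T) / c[:, t + 1, None]
        g = alpha * beta
        g /= g.sum(axis=2, keepdims=True)
        for i, (a, b) in enumerate(segs):
            gamma[a:b] = g[i]
        if Ls > 1:
            xi = (
                alpha[:, :-1, :, None]
                * A[None, None]
                * (e[:, 1:] * beta[:, 1:])[:, :, None, :]
                / c[:, 1:, None, None]
            )
            xi /= xi.sum(axis=(2, 3), keepdims=True)
            for i, (a, b) in enumerate(segs):
                xi_full[a : b - 1] = xi[i]
                xi_mask[a : b - 1] = True
        logZ += float(np.sum(np.log(c)) + np.sum(shift))
    xi_from = np.flatnonzero(xi_mask)
    xi = xi_full[xi_from]
    stc = StateTimeCourse(gamma=gamma, xi=xi, xi_from=xi_from)
    if return_evidence:
        return stc, logZ
    return stc


def viterbi_path(
    data: TimeSeriesData,
    posterior: HMMMARPosterior,
    config: HMMMARConfig,
    design: Optional[_Design] = None,
) -> np.ndarray:
    """Most probable joint state sequence (per segment) under expected logs."""
    design = design or _Design(data, config)
    K = posterior.K
    T = design.T
    ll = np.zeros((T, K))
    ll[design.target_idx] = _expected_loglik(posterior, config, design)
    log_A, log_pi = _expected_log_transition(posterior)
    path = np.empty(T, dtype=int)
    for a, b in design.segments:
        Ls = b - a
        delta = log_pi + ll[a]
        back = np.empty((Ls, K), dtype=int)
        for t in range(1, Ls):
            cand = delta[:, None] + log_A
            back[t] = np.argmax(cand, axis=0)
            delta = cand[back[t], np.arange(K)] + ll[a + t]
        path[b - 1] = int(np.argmax(delta))
        for t in range(Ls - 1, 0, -1):
            path[a + t - 1] = back[t, path[a + t]]
    return path


# ---------------------------------------------------------------------------
# Transition update


def update_transition_model(
    stc: StateTimeCourse, config: HMMMARConfig, posterior: HMMMARPosterior,
    segments: list[tuple[int, int]],
) -> HMMMARPosterior:
    """Dirichlet count updates from pairwise marginals and segment starts."""
    K = config.K
    pri = config.priors
    trans = np.full((K, K), pri.dirichlet_trans)
    if stc.xi is not None and stc.xi.size:
        trans = trans + stc.xi.sum(axis=0)
    init = np.full(K, pri.dirichlet_init)
    for a, _ in segments:
        init = init + stc.gamma[a]
    posterior.trans_counts = trans
    posterior.init_counts = init
    return posterior


# ---------------------------------------------------------------------------
# Free energy


def _kl_gamma(a: np.ndarray, b: np.ndarray, a0: float, b0: float) -> float:
    """KL( Gamma(a, b) || Gamma(a0, b0) ), shape/rate parametrisation."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    val = (
        (a - a0) * digamma(a)
        - gammaln(a)
        + gammaln(a0)
        + a0 * (np.log(b) - np.log(b0))
        + a * (b0 - b) / b
    )
    return float(np.sum(val))


def _kl_dirichlet(c: np.ndarray, c0: np.ndarray) -> float:
    c = np.asarray(c, float)
    c0 = np.asarray(c0, float)
    cs, c0s = c.sum(), c0.sum()
    return float(
        gammaln(cs)
        - gammaln(c0s)
        - np.sum(gammaln(c) - gammaln(c0))
        + np.sum((c - c0) * (digamma(c) - digamma(cs)))
    )


def _kl_wishart(dof1: float, S1: np.ndarray, dof0: float, S0: np.ndarray) -> float:
    """KL( W(dof1, S1^{-1}) || W(dof0, S0^{-1}) ) with rate-style scales."""
    N = S1.shape[0]
    V1 = np.linalg.inv(S1)
    _, ld1 = np.linalg.slogdet(V1)
    _, ld0 = np.linalg.slogdet(S0)
    ld0 = -ld0  # logdet of V0 = S0^{-1}
    E_logdet = (
        float(np.sum(digamma(0.5 * (dof1 - np.arange(N)))))
        + N * np.log(2.0)
        + ld1
    )
    return float(
        0.5 * (dof1 - dof0) * E_logdet
        + 0.5 * dof1 * (np.trace(S0 @ V1) - N)
        - 0.5 * dof1 * ld1
        + 0.5 * dof0 * ld0
        - 0.5 * (dof1 - dof0) * N * np.log(2.0)
        + multigammaln(0.5 * dof0, N)
        - multigammaln(0.5 * dof1, N)
    )


def _kl_coefficients(
    st: StatePosterior, config: HMMMARConfig, design: _Design, pri
) -> float:
    """E_q[log q(W) - log p(W | sigma, alpha)] for one state."""
    N, L = design.N, design.L
    intercept_prec = 1e-3
    if st.sigma_shape is not None:
        E_sig = st.sigma_shape / st.sigma_rate
        E_logsig = digamma(st.sigma_shape) - np.log(st.sigma_rate)
        E_alp = st.alpha_shape / st.alpha_rate
        E_logalp = digamma(st.alpha_shape) - np.log(st.alpha_rate)
    total = 0.0
    if config.noise_cov == "diagonal":
        covs = [(st.W_cov[j], st.free_cols[j], j) for j in range(N)]
    else:
        cov, offs, free_idx = st.W_cov
        covs = [
            (cov[offs[j] : offs[j + 1], offs[j] : offs[j + 1]], free_idx[j], j)
            for j in range(N)
        ]
        # diagonal blocks give the marginal second moments; the entropy term
        # below uses the full joint covariance
    for covj, cols, j in covs:
        if cols.size == 0:
            continue
        m2 = st.W_mean[cols, j] ** 2 + np.diag(covj)
        lag = design.lag_of[cols]
        src = design.src_of[cols]
        is_lag = lag >= 0
        E_prec = np.full(cols.size, intercept_prec)
        E_logprec = np.full(cols.size, np.log(intercept_prec))
        if st.sigma_shape is not None and np.any(is_lag):
            E_prec[is_lag] = E_sig[src[is_lag], j] * E_alp[lag[is_lag]]
            E_logprec[is_lag] = E_logsig[src[is_lag], j] + E_logalp[lag[is_lag]]
        cross = 0.5 * np.sum(-E_logprec + E_prec * m2) + 0.5 * cols.size * _LOG2PI
        total += float(cross)
    # entropy of q(W)
    if config.noise_cov == "diagonal":
        for covj, cols, j in covs:
            if cols.size == 0:
                continue
            sign, ld = np.linalg.slogdet(covj)
            total -= 0.5 * (cols.size * (1.0 + _LOG2PI) + ld)
    else:
        cov = st.W_cov[0]
        if cov.size:
            sign, ld = np.linalg.slogdet(cov)
            total -= 0.5 * (cov.shape[0] * (1.0 + _LOG2PI) + ld)
    return total


def compute_free_energy(
    data: TimeSeriesData,
    posterior: HMMMARPosterior,
    stc: StateTimeCourse,
    config: HMMMARConfig,
    design: Optional[_Design] = None,
    logZ: Optional[float] = None,
) -> float:
    """Variational free energy (negative evidence lower bound; lower is better).

    Computed as the sum of KL divergences of every posterior factor against
    its prior, minus the log normalisation of the forward pass run with
    expected-log parameters (which bundles the expected log likelihood, the
    chain prior and the chain entropy).
    """
    design = design or _Design(data, config)
    if logZ is None:
        _, logZ = infer_state_timecourses(
            data, posterior, config, design=design, return_evidence=True
        )
    pri = config.priors
    K = posterior.K
    N = design.N
    kl = 0.0
    # transition + initial Dirichlets
    kl += _kl_dirichlet(posterior.init_counts, np.full(K, pri.dirichlet_init))
    for k in range(K):
        kl += _kl_dirichlet(
            posterior.trans_counts[k], np.full(K, pri.dirichlet_trans)
        )
    shared_counted = False
    for k, st in enumerate(posterior.states):
        kl += _kl_coefficients(st, config, design, pri)
        if st.sigma_shape is not None:
            plan = config.clamping or ClampingPlan.free(N)
            plan.validate(N, design.L)
            sel = plan.state == "free"
            if config.symmetric_sigma:
                sel = np.triu(sel)  # shared (i,j)/(j,i) posterior counted once
            kl += _kl_gamma(
                st.sigma_shape[sel], st.sigma_rate[sel], pri.sigma_shape, pri.sigma_rate
            )
            kl += _kl_gamma(st.alpha_shape, st.alpha_rate, pri.alpha_shape, pri.alpha_rate)
        if config.noise_cov == "diagonal":
            if not config.noise_shared or not shared_counted:
                kl += _kl_gamma(
                    st.noise_shape, st.noise_rate, pri.noise_shape, pri.noise_rate
                )
                shared_counted = True
        else:
            dof0 = pri.wishart_dof if pri.wishart_dof else N + 1
            scale0 = (
                pri.wishart_scale
                if pri.wishart_scale is not None
                else np.eye(N) * design.data_var
            )
            if not config.noise_shared or not shared_counted:
                kl += _kl_wishart(st.wishart_dof, st.wishart_scale, dof0, scale0)
                shared_counted = True
    return kl - logZ


# ---------------------------------------------------------------------------
# Fit driver


def _run_cycles(
    data: TimeSeriesData,
    config: HMMMARConfig,
    design: _Design,
    stc: StateTimeCourse,
    posterior: Optional[HMMMARPosterior],
    max_cycles: int,
) -> tuple[HMMMARPosterior, StateTimeCourse, list, bool]:
    trace: list[float] = []
    converged = False
    prev_F = np.inf
    for cycle in range(max_cycles):
        posterior = update_observation_model(data, stc, posterior, config, design)
        posterior = update_transition_model(stc, config, posterior, design.segments)
        stc, logZ = infer_state_timecourses(
            data, posterior, config, design=design, return_evidence=True
        )
        F = compute_free_energy(data, posterior, stc, config, design=design, logZ=logZ)
        trace.append(F)
        logger.debug("cycle %d: free energy %.6f", cycle, F)
        if np.isfinite(prev_F):
            rel = abs(prev_F - F) / max(abs(F), 1e-300)
            if rel < config.training.tol:
                converged = True
                break
        prev_F = F
    return posterior, stc, trace, converged


def _fit_once(
    data: TimeSeriesData,
    config: HMMMARConfig,
    seed: int,
    design: _Design,
    max_cycles: Optional[int] = None,
) -> tuple[HMMMARPosterior, StateTimeCourse, np.ndarray, bool]:
    stc = initialize(data, config, seed=seed)
    posterior, stc, trace, converged = _run_cycles(
        data, config, design, stc, None,
        config.training.max_cycles if max_cycles is None else max_cycles,
    )
    return posterior, stc, np.asarray(trace), converged


def fit(
    data: TimeSeriesData, config: HMMMARConfig, envelope_applied: bool = False
) -> FitResult:
    """Fit the model by variational Bayes with restarts.

    Cycles observation-model, transition and state-time-course updates until
    the relative free-energy change drops below tolerance; across restarts
    (different initialisation seeds) the lowest-free-energy solution wins.
    States whose total occupancy falls below 1e-3 of the series length are
    reported in ``low_occupancy_states`` but never deleted.

    For the Gaussian-envelope observation model pass data through
    :func:`~hmmar.spectral.hilbert_envelope` first (``fit`` does this
    automatically unless ``envelope_applied``).
    """
    config.validate(data.n_channels)
    if config.observation == "gaussian-envelope" and not envelope_applied:
        from .spectral import hilbert_envelope

        data = hilbert_envelope(data)
    design = _Design(data, config)
    tr_cfg = config.training
    best = None
    errors = []
    probe = min(tr_cfg.restart_cycles, tr_cfg.max_cycles)
    for r in range(tr_cfg.n_restarts):
        seed = tr_cfg.seed + r
        try:
            # probe each restart briefly; only the best basin is run to
            # convergence below
            cycles = tr_cfg.max_cycles if tr_cfg.n_restarts == 1 else probe
            posterior, stc, trace, converged = _fit_once(
                data, config, seed, design, max_cycles=cycles
            )
        except (NumericalFailureError, InitializationError) as exc:
            logger.warning("restart %d failed: %s", r, exc)
            errors.append(exc)
            continue
        if best is None or trace[-1] < best[2][-1]:
            best = (posterior, stc, list(trace), converged, r, seed)
    if best is None:
        raise FitFailureError(f"all restarts failed numerically: {errors}")
    posterior, stc, trace, converged, r, seed = best
    if tr_cfg.n_restarts > 1 and not converged and len(trace) < tr_cfg.max_cycles:
        posterior, stc, more, converged = _run_cycles(
            data, config, design, stc, posterior,
            tr_cfg.max_cycles - len(trace),
        )
        trace = trace + more
    trace = np.asarray(trace)
    occ = stc.gamma.sum(axis=0) / design.T
    low = [int(k) for k in np.flatnonzero(occ < 1e-3)]
    if low:
        logger.info("states with negligible occupancy: %s", low)
    return FitResult(
        posterior=posterior,
        stc=stc,
        free_energy_trace=trace,
        config=config,
        restart_id=r,
        seed=seed,
        converged=converged,
        low_occupancy_states=low,
    )


def select_num_states(
    data: TimeSeriesData, config: HMMMARConfig, K_candidates: list[int]
) -> dict:
    """Fit per candidate K (shared seeds) and rank by converged free energy.

    Returns ``{"free_energy": {K: F}, "results": {K: FitResult}, "best_K": K}``;
    per-K failures are recorded, not fatal (unless all fail).
    """
    if not K_candidates:
        raise InvalidConfigurationError("K_candidates must be non-empty")
    table: dict[int, float] = {}
    results: dict[int, FitResult] = {}
    failures: dict[int, str] = {}
    for K in K_candidates:
        cfg_k = replace(config, K=K)
        try:
            res = fit(data, cfg_k)
        except FitFailureError as exc:
            failures[K] = str(exc)
            continue
        table[K] = res.free_energy
        results[K] = res
    if not table:
        raise FitFailureError(f"every candidate K failed: {failures}")
    best_K = min(table, key=table.get)
    return {
        "free_energy": table,
        "results": results,
        "best_K": best_K,
        "failures": failures,
    }


def make_variant(
    config: HMMMARConfig,
    variant: Literal["full", "ar-only", "cross-only", "gaussian-envelope"],
    data: Optional[TimeSeriesData] = None,
) -> HMMMARConfig:
    """Derive the restricted observation-model variants.

    ``ar-only`` clamps cross-channel coefficients to zero so the power
    spectra alone drive the state transitions; ``cross-only`` pins the
    self-coefficients at their global maximum-likelihood values (requires
    ``data``) so functional connectivity alone drives the transitions;
    ``gaussian-envelope`` drops the lags entirely and models the Hilbert
    amplitude envelope with state-specific Gaussians.
    """
    if variant == "full":
        return replace(config, clamping=None, observation="mar")
    if variant == "ar-only":
        n = data.n_channels if data is not None else None
        if n is None:
            raise InvalidConfigurationError("ar-only variant needs data for N")
        return replace(
            config, clamping=ClampingPlan.diagonal_only(n), observation="mar"
        )
    if variant == "cross-only":
        if data is None:
            raise InvalidConfigurationError("cross-only variant needs data")
        W_glob, _ = fit_global_mar(data, config.lagset)
        return replace(
            config,
            clamping=ClampingPlan.cross_only(data.n_channels, W_glob),
            observation="mar",
        )
    if variant == "gaussian-envelope":
        empty = LagSet(lags=(), P=0, P0=0, Q="uniform")
        return replace(
            config, lagset=empty, clamping=None, observation="gaussian-envelope"
        )
    raise InvalidConfigurationError(f"unknown variant {variant!r}")
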