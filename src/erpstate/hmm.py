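"""Multivariate-Gaussian-emission hidden Markov model.

The model: a hidden K-state first-order Markov chain S_1..S_T with initial
distribution ``pi`` and transition matrix ``A``; given S_t = k the observed
M-channel vector Y_t is drawn from N(mu_k, Sigma_k).  The state covariance
Sigma_k is interpreted as the functional-connectivity pattern of state k.

Fitting is maximum-likelihood EM (Baum-Welch) over several random restarts,
keeping the restart with the highest final log-likelihood.  Multiple
observation sequences (one per subject) share parameters; the chain restarts
at ``pi`` at each sequence boundary rather than splicing sequences together.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from ._kernels import forward_backward_kernel, viterbi_kernel

logger = logging.getLogger(__name__)

__all__ = [
    "HMMParams",
    "PosteriorSet",
    "FitResult",
    "emission_loglik",
    "forward_backward",
    "viterbi",
    "fit_hmm",
    "fc_matrix",
]


@dataclass
class HMMParams:
    """Parameters of a Gaussian-emission HMM.

    pi : (K,) initial state distribution
    A : (K, K) row-stochastic transition matrix
    mu : (K, M) state mean vectors
    Sigma : (K, M, M) state covariance matrices
    """

    pi: np.ndarray
    A: np.ndarray
    mu: np.ndarray
    Sigma: np.ndarray

    @property
    def K(self) -> int:
        return self.pi.shape[0]

    @property
    def M(self) -> int:
        return self.mu.shape[1]

    def validate(self, atol: float = 1e-8) -> None:
        K, M = self.K, self.M
        if self.A.shape != (K, K) or self.mu.shape != (K, M) or self.Sigma.shape != (K, M, M):
            raise ValueError("inconsistent parameter shapes")
        if not np.isclose(self.pi.sum(), 1.0, atol=atol):
            raise ValueError("pi must sum to 1")
        if not np.allclose(self.A.sum(axis=1), 1.0, atol=atol):
            raise ValueError("A rows must sum to 1")
        for k in range(K):
            if not np.allclose(self.Sigma[k], self.Sigma[k].T, atol=atol):
                raise ValueError(f"Sigma[{k}] is not symmetric")


@dataclass
class PosteriorSet:
    """E-step quantities: per-sequence posteriors and pooled transition counts."""

    gammas: list[np.ndarray]  # per sequence, (T_j, K), rows sum to 1
    xi_sum: np.ndarray  # (K, K) expected transition counts pooled over sequences
    loglik: float  # total log P(Y) in nats


@dataclass
class FitResult:
    params: HMMParams
    posteriors: PosteriorSet
    paths: list[np.ndarray]  # Viterbi path per sequence, values 0..K-1
    loglik_trace: np.ndarray  # winning restart's per-iteration log-likelihood
    restart_index: int
    seed_used: int
    restart_logliks: np.ndarray = field(default=None)  # final loglik per restart


def emission_loglik(Y: np.ndarray, params: HMMParams) -> np.ndarray:
    """Log N(Y_t; mu_k, Sigma_k) for every time point and state.

    Y is (M, T) with channels on the first axis; the result is (T, K).
    Computed through a Cholesky factorization of each Sigma_k.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[0] != params.M:
        raise ValueError(f"Y must be (M={params.M}, T); got {Y.shape}")
    X = Y.T  # (T, M)
    T, M = X.shape
    out = np.empty((T, params.K))
    for k in range(params.K):
        try:
            L = linalg.cholesky(params.Sigma[k], lower=True)
        except linalg.LinAlgError as exc:
            raise FloatingPointError(
                f"Sigma[{k}] is not positive definite"
            ) from exc
        dev = X - params.mu[k]
        z = linalg.solve_triangular(L, dev.T, lower=True)
        maha = np.einsum("ij,ij->j", z, z)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        out[:, k] = -0.5 * (M * np.log(2.0 * np.pi) + logdet + maha)
    return out


def _shift_exp(logB: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """exp(logB - rowmax) plus the per-row shifts, for underflow-safe scaling."""
    shift = np.max(logB, axis=1)
    if not np.all(np.isfinite(shift)):
        raise FloatingPointError("a time point has no state with finite emission likelihood")
    return np.exp(logB - shift[:, None]), shift


def forward_backward(logB: np.ndarray, pi: np.ndarray, A: np.ndarray) -> PosteriorSet:
    """Exact smoothing for one sequence from emission log-likelihoods.

    Scaled (per-step normalized) recursions, stable for T up to at least 1e5.
    Returns posteriors gamma (T, K), pooled pairwise expected transition
    counts xi_sum (K, K) and the sequence log-likelihood.
    """
    logB = np.asarray(logB, dtype=float)
    pi = np.asarray(pi, dtype=float)
    A = np.asarray(A, dtype=float)
    if logB.ndim != 2 or logB.shape[1] != pi.shape[0] or A.shape != (pi.shape[0],) * 2:
        raise ValueError("inconsistent shapes for logB, pi, A")
    B, shift = _shift_exp(logB)
    gamma, xi_sum, log_c, ok = forward_backward_kernel(B, pi, A)
    if not ok:
        raise FloatingPointError("zero total likelihood at some time point")
    return PosteriorSet(gammas=[gamma], xi_sum=xi_sum, loglik=float(log_c + shift.sum()))


def viterbi(logB: np.ndarray, pi: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Most probable joint state path (0-based); ties go to the lower state index."""
    logB = np.asarray(logB, dtype=float)
    with np.errstate(divide="ignore"):
        log_pi = np.log(np.asarray(pi, dtype=float))
        log_A = np.log(np.asarray(A, dtype=float))
    path, score = viterbi_kernel(logB, log_pi, log_A)
    if not np.isfinite(score):
        raise FloatingPointError("no path with finite probability")
    return path


def viterbi_score(logB: np.ndarray, pi: np.ndarray, A: np.ndarray) -> tuple[np.ndarray, float]:
    """Viterbi path together with its joint log-probability."""
    logB = np.asarray(logB, dtype=float)
    with np.errstate(divide="ignore"):
        log_pi = np.log(np.asarray(pi, dtype=float))
        log_A = np.log(np.asarray(A, dtype=float))
    path, score = viterbi_kernel(logB, log_pi, log_A)
    return path, float(score)


def fc_matrix(params: HMMParams, k: int, kind: str = "covariance") -> np.ndarray:
    """State k's functional-connectivity matrix: its covariance, or the
    corresponding correlation matrix (unit diagonal)."""
    if not 0 <= k < params.K:
        raise ValueError(f"state index {k} out of range 0..{params.K - 1}")
    S = params.Sigma[k]
    if kind == "covariance":
        return S.copy()
    if kind == "correlation":
        d = np.diag(S)
        if np.any(d <= 0):
            raise ValueError(f"state {k} has a zero-variance channel; correlation undefined")
        C = S / np.sqrt(np.outer(d, d))
        np.fill_diagonal(C, 1.0)
        return C
    raise ValueError("kind must be 'covariance' or 'correlation'")


def _as_sequences(obs) -> list[np.ndarray]:
    seqs = [np.asarray(Y, dtype=float) for Y in obs]
    if not seqs:
        raise ValueError("no observation sequences")
    M = seqs[0].shape[0]
    for i, Y in enumerate(seqs):
        if Y.ndim != 2 or Y.shape[0] != M:
            raise ValueError(f"sequence {i} has shape {Y.shape}; expected ({M}, T_j)")
        if Y.shape[1] < 2:
            raise ValueError(f"sequence {i} is shorter than 2 samples")
    return seqs


def _m_step(Xcat, gammas, xi_sum, seq_starts, K, ridge):
    """Pooled M-step from responsibilities; returns HMMParams."""
    G = np.concatenate(gammas, axis=0)  # (T_total, K)
    Nk = G.sum(axis=0)
    M = Xcat.shape[1]
    mu = (G.T @ Xcat) / Nk[:, None]
    Sigma = np.empty((K, M, M))
    for k in range(K):
        dev = Xcat - mu[k]
        w = G[:, k]
        Sigma[k] = (dev * w[:, None]).T @ dev / Nk[k]
        Sigma[k] = 0.5 * (Sigma[k] + Sigma[k].T)
        Sigma[k] += ridge * max(np.mean(np.diag(Sigma[k])), 1e-12) * np.eye(M)
    A = xi_sum / np.maximum(xi_sum.sum(axis=1, keepdims=True), 1e-300)
    pi = np.mean([g[0] for g in gammas], axis=0)
    pi = pi / pi.sum()
    return HMMParams(pi=pi, A=A, mu=mu, Sigma=Sigma), Nk


def _e_step(Xcat, seq_starts, params):
    """Forward-backward over every sequence, with emissions evaluated once
    on the pooled samples.  Returns (gammas, xi_sum, total loglik)."""
    logB_cat = emission_loglik(Xcat.T, params)
    gammas = []
    xi_sum = np.zeros((params.K, params.K))
    ll = 0.0
    for i in range(len(seq_starts) - 1):
        logB = logB_cat[seq_starts[i]: seq_starts[i + 1]]
        post = forward_backward(logB, params.pi, params.A)
        gammas.append(post.gammas[0])
        xi_sum += post.xi_sum
        ll += post.loglik
    return gammas, xi_sum, ll


def fit_hmm(
    obs,
    K: int,
    n_restarts: int = 20,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
    ridge: float = 1e-6,
    init_params: HMMParams | None = None,
) -> FitResult:
    """Baum-Welch EM over multiple sequences with multi-restart selection.

    obs : iterable of (M, T_j) arrays, one per subject/sequence.
    Each restart initializes from random responsibilities drawn with
    ``seed + restart_index``; the restart with the highest final
    log-likelihood wins.  ``init_params`` replaces the random initialization
    (then a single restart is run) -- useful for controlled experiments.

    Covariance updates carry a ridge of ``ridge * mean(diag)`` to keep the
    M-step positive definite.  A state whose pooled responsibility falls
    below one sample-equivalent is re-initialized once per restart; a second
    collapse abandons that restart.
    """
    seqs = _as_sequences(obs)
    M = seqs[0].shape[0]
    T_total = sum(Y.shape[1] for Y in seqs)
    if K < 1:
        raise ValueError("K must be >= 1")
    if T_total < 10 * K * M:
        raise ValueError(
            f"only {T_total} samples for K={K}, M={M}; need at least {10 * K * M} "
            "for an identifiable fit"
        )
    Xcat = np.concatenate([Y.T for Y in seqs], axis=0)
    seq_lens = [Y.shape[1] for Y in seqs]
    seq_starts = np.cumsum([0] + seq_lens)

    if init_params is not None:
        n_restarts = 1

    best = None
    restart_logliks = np.full(n_restarts, -np.inf)
    for r in range(n_restarts):
        rng = np.random.default_rng(seed + r)
        if init_params is not None:
            params = HMMParams(
                pi=init_params.pi.copy(),
                A=init_params.A.copy(),
                mu=init_params.mu.copy(),
                Sigma=init_params.Sigma.copy(),
            )
        else:
            # random-responsibility init: Dirichlet(1) row per pooled sample
            G0 = rng.dirichlet(np.ones(K), size=T_total)
            gammas0 = [G0[seq_starts[i]: seq_starts[i + 1]] for i in range(len(seqs))]
            xi0 = np.full((K, K), (T_total - len(seqs)) / (K * K))
            params, _ = _m_step(Xcat, gammas0, xi0, seq_starts, K, ridge)
        trace = []
        reinit_used = False
        aborted = False
        prev_ll = -np.inf
        for it in range(max_iter):
            try:
                gammas, xi_sum, ll = _e_step(Xcat, seq_starts, params)
            except FloatingPointError as exc:
                logger.warning("restart %d aborted at iteration %d: %s", r, it, exc)
                aborted = True
                break
            trace.append(ll)
            params, Nk = _m_step(Xcat, gammas, xi_sum, seq_starts, K, ridge)
            collapsed = np.where(Nk < 1.0)[0]
            if collapsed.size:
                if reinit_used:
                    warnings.warn(
                        f"restart {r}: state(s) {collapsed.tolist()} collapsed twice; "
                        "abandoning this restart",
                        RuntimeWarning,
                    )
                    aborted = True
                    break
                reinit_used = True
                for k in collapsed:
                    t0 = rng.integers(T_total)
                    params.mu[k] = Xcat[t0]
                    params.Sigma[k] = np.cov(Xcat.T) + ridge * np.eye(M)
            if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * abs(prev_ll):
                break
            prev_ll = ll
        if aborted or not trace:
            continue
        restart_logliks[r] = trace[-1]
        if best is None or trace[-1] > best[0]:
            best = (trace[-1], params, np.array(trace), r)

    if best is None:
        raise RuntimeError("all EM restarts failed")

    _, params, trace, r_best = best
    gammas, xi_sum, ll = _e_step(Xcat, seq_starts, params)
    logB_cat = emission_loglik(Xcat.T, params)
    paths = [
        viterbi(logB_cat[seq_starts[i]: seq_starts[i + 1]], params.pi, params.A)
        for i in range(len(seqs))
    ]
    return FitResult(
        params=params,
        posteriors=PosteriorSet(gammas=gammas, xi_sum=xi_sum, loglik=ll),
        paths=paths,
        loglik_trace=trace,
        restart_index=r_best,
        seed_used=seed,
        restart_logliks=restart_logliks,
    )
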