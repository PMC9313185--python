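"""HMM inference against brute-force enumeration and closed forms."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from erpstate.hmm import (
    HMMParams,
    emission_loglik,
    fc_matrix,
    fit_hmm,
    forward_backward,
    viterbi,
    viterbi_score,
)
from erpstate.synth import build_ground_truth, sample_raw_sequences

from conftest import random_hmm_params


# ---------------------------------------------------------------- oracles
def enumerate_posteriors(logB, pi, A):
    """Exhaustive sum over all K^T paths: loglik, marginals, best path."""
    T, K = logB.shape
    with np.errstate(divide="ignore"):
        log_pi, log_A = np.log(pi), np.log(A)
    total = -np.inf
    gamma = np.zeros((T, K))
    best_score, best_path = -np.inf, None
    scores = {}
    for path in itertools.product(range(K), repeat=T):
        s = log_pi[path[0]] + logB[0, path[0]]
        for t in range(1, T):
            s += log_A[path[t - 1], path[t]] + logB[t, path[t]]
        scores[path] = s
        total = np.logaddexp(total, s)
        if s > best_score:
            best_score, best_path = s, path
    for path, s in scores.items():
        w = np.exp(s - total)
        for t, k in enumerate(path):
            gamma[t, k] += w
    return total, gamma, best_score, np.array(best_path)


# ---------------------------------------------------------------- emissions
def test_emission_standard_normal_at_mean():
    p = HMMParams(
        pi=np.array([1.0]), A=np.array([[1.0]]),
        mu=np.zeros((1, 1)), Sigma=np.ones((1, 1, 1)),
    )
    ll = emission_loglik(np.zeros((1, 1)), p)
    assert np.isclose(ll[0, 0], -0.5 * np.log(2 * np.pi))


def test_emission_diagonal_factorizes():
    rng = np.random.default_rng(0)
    var = np.array([2.0, 0.5])
    p = HMMParams(
        pi=np.array([1.0]), A=np.array([[1.0]]),
        mu=np.array([[0.3, -0.2]]), Sigma=np.diag(var)[None],
    )
    Y = rng.normal(size=(2, 6))
    ll = emission_loglik(Y, p)
    uni = sum(
        sps.norm.logpdf(Y[i], loc=p.mu[0, i], scale=np.sqrt(var[i])) for i in range(2)
    )
    assert np.allclose(ll[:, 0], uni, atol=1e-12)


def test_emission_matches_explicit_inverse():
    rng = np.random.default_rng(1)
    p = random_hmm_params(rng, K=2, M=3)
    Y = rng.normal(size=(3, 5))
    ll = emission_loglik(Y, p)
    for k in range(2):
        Sinv = np.linalg.inv(p.Sigma[k])
        _, logdet = np.linalg.slogdet(p.Sigma[k])
        for t in range(5):
            d = Y[:, t] - p.mu[k]
            ref = -0.5 * (3 * np.log(2 * np.pi) + logdet + d @ Sinv @ d)
            assert abs(ll[t, k] - ref) < 1e-10


# ---------------------------------------------------------- forward-backward
@pytest.mark.parametrize("K,T,seed", [(1, 4, 0), (2, 5, 1), (3, 5, 2), (2, 6, 3)])
def test_forward_backward_matches_enumeration(K, T, seed):
    rng = np.random.default_rng(seed)
    p = random_hmm_params(rng, K, M=2)
    Y = rng.normal(size=(2, T))
    logB = emission_loglik(Y, p)
    post = forward_backward(logB, p.pi, p.A)
    ll_ref, gamma_ref, _, _ = enumerate_posteriors(logB, p.pi, p.A)
    assert abs(post.loglik - ll_ref) < 1e-10
    assert np.allclose(post.gammas[0], gamma_ref, atol=1e-10)
    assert np.allclose(post.gammas[0].sum(axis=1), 1.0, atol=1e-10)
    # pooled pairwise counts account for every transition
    assert np.isclose(post.xi_sum.sum(), T - 1, atol=1e-8)


def test_forward_backward_single_state_and_absorbing():
    rng = np.random.default_rng(4)
    logB = rng.normal(size=(7, 1))
    post = forward_backward(logB, np.array([1.0]), np.array([[1.0]]))
    assert np.allclose(post.gammas[0], 1.0)
    assert np.isclose(post.loglik, logB.sum())

    # 2-state absorbing chain started in state 0 never leaves it
    p = random_hmm_params(np.random.default_rng(5), 2, 2)
    logB = emission_loglik(np.random.default_rng(6).normal(size=(2, 6)), p)
    post = forward_backward(logB, np.array([1.0, 0.0]), np.eye(2))
    assert np.allclose(post.gammas[0][:, 0], 1.0, atol=1e-12)


def test_forward_backward_long_sequence_no_underflow():
    rng = np.random.default_rng(7)
    p = random_hmm_params(rng, 3, 2)
    Y = rng.normal(size=(2, 100_000))
    logB = emission_loglik(Y, p)
    post = forward_backward(logB, p.pi, p.A)
    assert np.isfinite(post.loglik)
    assert np.allclose(post.gammas[0].sum(axis=1), 1.0, atol=1e-9)


def test_forward_backward_matches_hmmlearn():
    """Independent cross-check of the sequence log-likelihood."""
    hmmlearn = pytest.importorskip("hmmlearn.hmm")
    rng = np.random.default_rng(8)
    p = random_hmm_params(rng, 3, 4)
    Y = rng.normal(size=(4, 200))
    post = forward_backward(emission_loglik(Y, p), p.pi, p.A)
    m = hmmlearn.GaussianHMM(n_components=3, covariance_type="full", init_params="")
    m.startprob_, m.transmat_, m.means_, m.covars_ = p.pi, p.A, p.mu, p.Sigma
    assert abs(post.loglik - m.score(Y.T)) < 1e-8


# ------------------------------------------------------------------ viterbi
@pytest.mark.parametrize("seed", range(10))
def test_viterbi_matches_enumeration(seed):
    rng = np.random.default_rng(100 + seed)
    K = int(rng.integers(1, 4))
    T = int(rng.integers(2, 7))
    p = random_hmm_params(rng, K, M=2)
    logB = emission_loglik(rng.normal(size=(2, T)), p)
    path, score = viterbi_score(logB, p.pi, p.A)
    _, _, best_score, best_path = enumerate_posteriors(logB, p.pi, p.A)
    assert abs(score - best_score) < 1e-10
    assert np.array_equal(path, best_path)


def test_viterbi_recovers_well_separated_states():
    truth = build_ground_truth(3, 4, seed=9, mu_scale=10.0)
    obs, paths = sample_raw_sequences(truth, 1, 500, seed=10)
    p = HMMParams(pi=truth.pi, A=truth.A, mu=truth.mu, Sigma=truth.Sigma)
    decoded = viterbi(emission_loglik(obs[0], p), p.pi, p.A)
    assert np.array_equal(decoded, paths[0])


def test_viterbi_tie_breaks_to_lower_state():
    # two identical states: every step ties; the all-zeros path must win
    p = HMMParams(
        pi=np.array([0.5, 0.5]),
        A=np.full((2, 2), 0.5),
        mu=np.zeros((2, 1)),
        Sigma=np.ones((2, 1, 1)),
    )
    path = viterbi(emission_loglik(np.zeros((1, 5)), p), p.pi, p.A)
    assert np.array_equal(path, np.zeros(5, dtype=int))


# ----------------------------------------------------------------- fitting
def test_fit_single_state_closed_form():
    rng = np.random.default_rng(11)
    seqs = [rng.normal(size=(3, 50)) for _ in range(4)]
    res = fit_hmm(seqs, K=1, n_restarts=1, seed=0, ridge=0.0)
    X = np.concatenate([s.T for s in seqs])
    assert np.allclose(res.params.mu[0], X.mean(axis=0), atol=1e-8)
    assert np.allclose(res.params.Sigma[0], np.cov(X.T, bias=True), atol=1e-8)


def test_em_monotone_loglik():
    rng = np.random.default_rng(12)
    truth = build_ground_truth(3, 3, seed=12)
    obs, _ = sample_raw_sequences(truth, 2, 150, seed=13)
    res = fit_hmm(obs, K=3, n_restarts=2, seed=1, max_iter=40)
    tr = res.loglik_trace
    assert np.all(np.diff(tr) >= -1e-7 * np.abs(tr[:-1]))


def test_fit_permutation_equivariant():
    """Permuting the initial parameters permutes the fitted parameters."""
    rng = np.random.default_rng(14)
    truth = build_ground_truth(3, 3, seed=14)
    obs, _ = sample_raw_sequences(truth, 2, 200, seed=15)
    init = random_hmm_params(rng, 3, 3)
    perm = np.array([2, 0, 1])
    init_p = HMMParams(
        pi=init.pi[perm],
        A=init.A[np.ix_(perm, perm)],
        mu=init.mu[perm],
        Sigma=init.Sigma[perm],
    )
    r1 = fit_hmm(obs, K=3, seed=0, max_iter=15, init_params=init)
    r2 = fit_hmm(obs, K=3, seed=0, max_iter=15, init_params=init_p)
    assert np.allclose(r2.params.mu, r1.params.mu[perm], atol=1e-6)
    assert np.allclose(r2.params.A, r1.params.A[np.ix_(perm, perm)], atol=1e-6)


def test_fit_guards_insufficient_data():
    with pytest.raises(ValueError, match="identifiable"):
        fit_hmm([np.zeros((4, 20))], K=4, seed=0)


def test_gamma_rows_and_transition_counts(truth48):
    obs, _ = sample_raw_sequences(truth48, 3, 120, seed=16)
    res = fit_hmm(obs, K=2, n_restarts=1, seed=2, max_iter=10)
    for g in res.posteriors.gammas:
        assert np.allclose(g.sum(axis=1), 1.0, atol=1e-10)
    total_transitions = sum(Y.shape[1] - 1 for Y in obs)
    assert np.isclose(res.posteriors.xi_sum.sum(), total_transitions, atol=1e-6)


# --------------------------------------------------------------- fc_matrix
def test_fc_matrix_forms():
    S = np.array([[4.0, 2.0], [2.0, 1.0 + 1e-9]])
    p = HMMParams(
        pi=np.array([1.0]), A=np.array([[1.0]]), mu=np.zeros((1, 2)), Sigma=S[None],
    )
    assert np.allclose(fc_matrix(p, 0, "covariance"), S)
    C = fc_matrix(p, 0, "correlation")
    assert np.allclose(np.diag(C), 1.0, atol=1e-12)
    assert np.isclose(C[0, 1], 2.0 / np.sqrt(4.0 * (1.0 + 1e-9)))
    with pytest.raises(ValueError):
        fc_matrix(p, 1)
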