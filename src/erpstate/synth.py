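"""Synthetic two-condition ERP study generator with known hidden-state truth.

Emulates the statistical structure a state-based dynamic-connectivity
analysis assumes in multichannel ERP data:

* a hidden K-state Markov chain per subject whose states carry distinct
  channel covariance (connectivity) patterns — one diagonal-dominant
  "weak connectivity" state and one high-off-diagonal "strong connectivity"
  state;
* time-inhomogeneous dynamics: the strong state is favoured before a split
  time and the weak state after it, with the post-split bias depending on
  the viewing condition ("comfort" vs "discomfort");
* an ERP component effect: one condition's trial-average template is
  shifted on a channel subset inside a post-stimulus latency window;
* trials = template + white noise; the pre-stimulus baseline is noise only,
  so baseline correction and trial averaging are exercised meaningfully.

This reproduces the structure the downstream pipeline estimates, not EEG
physiology (no artifacts, no volume conduction, no realistic montage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from ._kernels import markov_sample_kernel
from .erp import EpochSet
from .io import TrialDataset

__all__ = [
    "ComponentEffect",
    "GroundTruthModel",
    "SynthConfig",
    "build_ground_truth",
    "sample_state_sequence",
    "sample_subject_data",
    "sample_raw_sequences",
    "generate_study",
    "CONDITIONS",
]

CONDITIONS = ("comfort", "discomfort")


@dataclass(frozen=True)
class ComponentEffect:
    """Additive ERP amplitude shift on a channel subset inside a latency window."""

    channels: tuple[int, ...] = (1, 3, 5)
    start_ms: float = 90.0
    end_ms: float = 130.0
    amplitude: float = 2.0
    condition: str = "discomfort"


@dataclass(frozen=True)
class SynthConfig:
    """Study-level simulation settings.

    Defaults mirror the emulated recording protocol: 512 Hz sampling,
    epochs from -200 ms to +3000 ms around stimulus onset, a 1100 ms
    early/late boundary, and 37 subjects per condition pair.
    """

    n_subjects: int = 37
    n_trials: int = 50
    fs: float = 512.0
    epoch_start_ms: float = -200.0
    epoch_end_ms: float = 3000.0
    split_ms: float = 1100.0
    noise_sd: float = 1.0
    subject_jitter: float = 200.0
    smooth_len: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not (self.epoch_start_ms < 0 < self.split_ms < self.epoch_end_ms):
            raise ValueError("need epoch_start_ms < 0 < split_ms < epoch_end_ms")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_pre(self) -> int:
        """Pre-stimulus samples in an epoch."""
        return int(round(-self.epoch_start_ms * self.fs / 1000.0))

    @property
    def n_post(self) -> int:
        """Post-stimulus samples in an epoch (the hidden chain's length)."""
        return int(round(self.epoch_end_ms * self.fs / 1000.0))


@dataclass(frozen=True)
class GroundTruthModel:
    """Generative model shared by all synthetic subjects (states 0-indexed)."""

    K: int
    M: int
    pi: np.ndarray  # (K,)
    A: np.ndarray  # (K, K) baseline transition matrix
    mu: np.ndarray  # (K, M)
    Sigma: np.ndarray  # (K, M, M)
    weak_state: int
    strong_state: int
    late_bias: dict = field(default_factory=lambda: {"comfort": 1.0, "discomfort": 2.5})
    early_bias: float = 2.0
    component_effect: ComponentEffect = field(default_factory=ComponentEffect)

    def validate(self) -> None:
        if abs(self.pi.sum() - 1.0) > 1e-12:
            raise ValueError("pi must sum to 1")
        if np.max(np.abs(self.A.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("A rows must sum to 1")
        for k in range(self.K):
            if not np.allclose(self.Sigma[k], self.Sigma[k].T):
                raise ValueError(f"Sigma[{k}] not symmetric")
            if np.linalg.eigvalsh(self.Sigma[k])[0] <= 0:
                raise ValueError(f"Sigma[{k}] not positive definite")
        if _mean_abs_offdiag(_corr(self.Sigma[self.weak_state])) >= _mean_abs_offdiag(
            _corr(self.Sigma[self.strong_state])
        ):
            raise ValueError("weak state must have smaller mean |off-diagonal| correlation")
        if any(b < 1.0 for b in self.late_bias.values()):
            raise ValueError("late_bias entries must be >= 1")


def _corr(S: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


def _mean_abs_offdiag(C: np.ndarray) -> float:
    M = C.shape[0]
    off = C[~np.eye(M, dtype=bool)]
    return float(np.mean(np.abs(off)))


def build_ground_truth(
    K: int,
    M: int,
    seed: int,
    *,
    self_stick: float = 0.92,
    mu_scale: float = 2.0,
    weak_shrink: float = 0.1,
    strong_blend: float = 0.8,
    strong_rho: float = 0.7,
    late_bias: dict | None = None,
    early_bias: float = 2.0,
    component_effect: ComponentEffect | None = None,
) -> GroundTruthModel:
    """Construct a deterministic ground-truth model from a seed.

    State covariances are built from random Wishart-style correlation
    matrices: the weak state's off-diagonal entries are shrunk toward 0,
    the strong state is blended toward an equicorrelation matrix (rho =
    ``strong_rho``), and each is finalized through its eigendecomposition
    Q diag(lam) Q^T + eps*I with eps = 1e-6 * mean(lam), guaranteeing
    positive definiteness.  State means are i.i.d. N(0, mu_scale^2) draws,
    which sets the state separation of the simulated signals.
    """
    if K < 2 or M < 2:
        raise ValueError("need K >= 2 and M >= 2")
    rng = np.random.default_rng(seed)
    pi = np.full(K, 1.0 / K)
    A = np.full((K, K), (1.0 - self_stick) / (K - 1))
    np.fill_diagonal(A, self_stick)
    mu = rng.normal(0.0, mu_scale, size=(K, M))

    weak_state, strong_state = K - 1, 1 % K  # mirrors "state 4 weak, state 2 strong"
    if weak_state == strong_state:
        strong_state = 0
    Sigma = np.empty((K, M, M))
    eye = np.eye(M)
    # Sign-balanced rank-one structure: strong |correlations| of mixed sign,
    # so the pattern is not a pure common-mode signal and survives average
    # re-referencing (which removes the across-channel mean).
    signs = np.ones(M)
    signs[: M // 2] = -1.0
    rng.shuffle(signs)
    equi = (1.0 - strong_rho) * eye + strong_rho * np.outer(signs, signs)
    for k in range(K):
        W = rng.normal(size=(M, M))
        C = _corr(W @ W.T / M + 1e-3 * eye)
        if k == weak_state:
            C = eye + weak_shrink * (C - eye)
        elif k == strong_state:
            C = (1.0 - strong_blend) * C + strong_blend * equi
        lam, Q = np.linalg.eigh(C)
        lam = np.maximum(lam, 1e-8)
        Sigma[k] = Q @ np.diag(lam) @ Q.T + 1e-6 * lam.mean() * eye
        Sigma[k] = 0.5 * (Sigma[k] + Sigma[k].T)

    truth = GroundTruthModel(
        K=K,
        M=M,
        pi=pi,
        A=A,
        mu=mu,
        Sigma=Sigma,
        weak_state=weak_state,
        strong_state=strong_state,
        late_bias=dict(late_bias) if late_bias is not None else {"comfort": 1.0, "discomfort": 2.5},
        early_bias=early_bias,
        component_effect=(
            component_effect
            if component_effect is not None
            else ComponentEffect(channels=tuple(range(1, M, 2))[:3])
        ),
    )
    eff = truth.component_effect
    if eff is not None and eff.channels and max(eff.channels) >= M:
        raise ValueError("component_effect channel index out of range")
    truth.validate()
    return truth


def _bias_column(A: np.ndarray, col: int, factor: float) -> np.ndarray:
    B = A.copy()
    B[:, col] *= factor
    return B / B.sum(axis=1, keepdims=True)


def sample_state_sequence(
    truth: GroundTruthModel,
    condition: str,
    T: int,
    fs: float,
    split_ms: float,
    seed: int,
    t_origin_ms: float = 0.0,
    A: np.ndarray | None = None,
) -> np.ndarray:
    """Sample the hidden path (length T, values 0..K-1) for one epoch.

    The chain is time-inhomogeneous: before the split the strong-state
    column of the transition matrix is multiplied by ``early_bias``, after
    it the weak-state column by ``late_bias[condition]`` (rows renormalized).
    Sample times are t_origin_ms + index * 1000 / fs; "late" means strictly
    greater than split_ms.  ``A`` overrides the baseline transition matrix
    (used for per-subject perturbed chains).
    """
    if condition not in truth.late_bias:
        raise ValueError(f"unknown condition {condition!r}; known: {sorted(truth.late_bias)}")
    if T < 1:
        raise ValueError("T must be >= 1")
    base = truth.A if A is None else A
    A_early = _bias_column(base, truth.strong_state, truth.early_bias)
    A_late = _bias_column(base, truth.weak_state, truth.late_bias[condition])
    times = t_origin_ms + np.arange(T) * 1000.0 / fs
    late_mask = times > split_ms
    rng = np.random.default_rng(seed)
    s0 = int(rng.choice(truth.K, p=truth.pi))
    u = rng.random(max(T - 1, 1))
    path = markov_sample_kernel(
        np.cumsum(A_early, axis=1),
        np.cumsum(A_late, axis=1),
        late_mask,
        s0,
        u,
    )
    return path


def _draw_state_emissions(truth: GroundTruthModel, path: np.ndarray, rng) -> np.ndarray:
    """(T, M) draws x_t ~ N(mu[s_t], Sigma[s_t]), vectorized per state."""
    T = path.shape[0]
    z = rng.standard_normal((T, truth.M))
    X = np.empty((T, truth.M))
    for k in range(truth.K):
        idx = path == k
        if not np.any(idx):
            continue
        L = np.linalg.cholesky(truth.Sigma[k])
        X[idx] = truth.mu[k] + z[idx] @ L.T
    return X


def sample_subject_data(
    truth: GroundTruthModel,
    path: np.ndarray,
    config: SynthConfig,
    condition: str,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """ERP template (M, T_total) and trial stack (n_trials, M, T_total).

    The post-onset template is a per-time-point draw from the active state's
    Gaussian, smoothed with a short moving average (``config.smooth_len``
    samples); the component effect adds its amplitude to its channels inside
    its window for its condition.  Pre-onset samples are 0 in the template,
    so each trial's baseline is pure noise.
    """
    path = np.asarray(path)
    if path.shape[0] != config.n_post:
        raise ValueError(
            f"path length {path.shape[0]} != post-onset epoch length {config.n_post}"
        )
    if path.min() < 0 or path.max() >= truth.K:
        raise ValueError("path contains a state index outside 0..K-1")
    rng = np.random.default_rng(seed)
    X = _draw_state_emissions(truth, path, rng)
    if config.smooth_len > 1:
        X = uniform_filter1d(X, size=config.smooth_len, axis=0, mode="nearest")
    eff = truth.component_effect
    if eff is not None and condition == eff.condition:
        t_ms = np.arange(config.n_post) * 1000.0 / config.fs
        win = (t_ms >= eff.start_ms) & (t_ms < eff.end_ms)
        for ch in eff.channels:
            X[win, ch] += eff.amplitude
    T_total = config.n_pre + config.n_post
    template = np.zeros((truth.M, T_total))
    template[:, config.n_pre:] = X.T
    trials = template[None, :, :] + rng.normal(
        0.0, config.noise_sd, size=(config.n_trials, truth.M, T_total)
    )
    return template, trials


def sample_raw_sequences(
    truth: GroundTruthModel,
    n_seq: int,
    T: int,
    seed: int,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Unsmoothed draws straight from the homogeneous hidden Markov model.

    Returns (observations, paths): n_seq sequences of shape (M, T) with
    emissions N(mu_k, Sigma_k) under the baseline transition matrix, no
    period biases and no temporal smoothing.  This is the generative match
    to the fitting model, used for parameter-recovery experiments.
    """
    ss = np.random.SeedSequence(seed)
    obs, paths = [], []
    for child in ss.spawn(n_seq):
        rng = np.random.default_rng(child)
        path = np.empty(T, dtype=np.int64)
        path[0] = rng.choice(truth.K, p=truth.pi)
        cum = np.cumsum(truth.A, axis=1)
        u = rng.random(T - 1)
        for t in range(1, T):
            path[t] = np.searchsorted(cum[path[t - 1]], u[t - 1], side="right")
        X = _draw_state_emissions(truth, path, rng)
        obs.append(X.T)
        paths.append(path)
    return obs, paths


def generate_study(
    config: SynthConfig, truth: GroundTruthModel
) -> tuple[TrialDataset, dict]:
    """Full two-condition multi-subject dataset plus its ground truth.

    Per-subject transition matrices are Dirichlet perturbations of the
    baseline rows (concentration ``config.subject_jitter``); each subject
    keeps the same matrix under both conditions so condition contrasts are
    purely the late-period bias.  Returns (dataset, truth_bundle) where the
    bundle holds per-subject paths and transition matrices for recovery
    tests.  Fully reproducible from ``config.seed``.
    """
    root = np.random.SeedSequence(config.seed)
    subj_ss = root.spawn(config.n_subjects)
    channels = [f"ch{i:02d}" for i in range(truth.M)]
    subjects = [f"s{i:02d}" for i in range(config.n_subjects)]
    epochs = {}
    paths = {}
    A_subject = {}
    for i, (subj, ss) in enumerate(zip(subjects, subj_ss)):
        rng = np.random.default_rng(ss)
        A_s = np.vstack(
            [rng.dirichlet(config.subject_jitter * row) for row in truth.A]
        )
        A_subject[subj] = A_s
        for cond in CONDITIONS:
            path_seed, data_seed = rng.integers(2**31, size=2)
            path = sample_state_sequence(
                truth,
                cond,
                config.n_post,
                config.fs,
                config.split_ms,
                int(path_seed),
                A=A_s,
            )
            _, trials = sample_subject_data(truth, path, config, cond, int(data_seed))
            epochs[(subj, cond)] = EpochSet(
                subject=subj,
                condition=cond,
                trials=trials,
                fs=config.fs,
                t0_ms=config.epoch_start_ms,
                channels=list(channels),
            )
            paths[(subj, cond)] = path
    dataset = TrialDataset(
        fs=config.fs,
        t0_ms=config.epoch_start_ms,
        channels=list(channels),
        subjects=subjects,
        conditions=list(CONDITIONS),
        epochs=epochs,
    )
    bundle = {"truth": truth, "paths": paths, "A_subject": A_subject, "config": config}
    return dataset, bundle
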