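"""Synthetic multivariate Gaussian timeseries with known dynamic correlations.

Observations at each timepoint are drawn independently from a zero-mean
multivariate Gaussian, s_t ~ N(0, Σ_t), where the covariance timecourse Σ_t
follows one of four temporal regimes:

``constant``
    one random covariance Σ = CCᵀ (C i.i.d. standard normal) for all t;
``random``
    a fresh independently drawn covariance at every timepoint;
``ramping``
    Σ_t = (1 − t/(T−1))·Σ_start + (t/(T−1))·Σ_end, a linear blend of two
    random anchors (t ∈ [0..T−1]);
``event``
    ``n_events`` random covariances, each held constant over a block of
    T/n_events consecutive samples (long stable epochs separated by sudden
    state switches).

Ground truth is stored as the *correlation* normalization D^(−1/2) Σ_t
D^(−1/2) of each covariance, vectorized (upper triangle + diagonal), since
recovery is always scored against correlation matrices.

Higher-order datasets lift the order-1 correlation timecourse to order n by
repeated Kronecker self-products (m_{j+1} = m_j ⊗ m_j, applied per timepoint)
and then sample backward: a draw from N(0, m_j) is reshaped to a square
matrix, symmetrized by reflecting its upper triangle onto the lower one,
PSD-repaired (eigenvalues clipped at 1e−10, diagonal re-unitized), and used
as the covariance for the next draw down; the order-1 draw is the
observation itself.  The generation noise therefore propagates from higher
orders down to lower ones.

Multi-participant groups share a single stimulus-driven covariance
timecourse (and, for order > 1, the shared template chain); each
participant's observations are drawn independently from it.

All generators are bit-reproducible from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dyncorr import Timeseries, vec_length

__all__ = [
    "RegimeSpec",
    "SyntheticDataset",
    "random_covariance",
    "cov_to_corr",
    "psd_repair",
    "generate_first_order",
    "generate_higher_order",
    "generate",
    "generate_group",
    "CATEGORIES",
]

CATEGORIES = ("constant", "random", "ramping", "event")

#: defaults matching the study conditions: first-order sims use K=50, T=300;
#: higher-order sims use K=10, T=300; the event regime uses 5 events.
FIRST_ORDER_K = 50
HIGHER_ORDER_K = 10
DEFAULT_T = 300
DEFAULT_N_EVENTS = 5


@dataclass(frozen=True)
class RegimeSpec:
    """Temporal regime and dimensions of a simulated dataset."""

    category: str
    K: int
    T: int = DEFAULT_T
    order: int = 1
    n_events: int = DEFAULT_N_EVENTS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r}; expected one of {CATEGORIES}"
            )
        if self.K < 2 or self.T < 2:
            raise ValueError("need K >= 2 and T >= 2")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.category == "event" and self.T % self.n_events != 0:
            raise ValueError(
                f"T={self.T} must be divisible by n_events={self.n_events}"
            )


@dataclass
class SyntheticDataset:
    """Observations plus per-order ground-truth correlation timecourses.

    ``truth[j-1]`` is the T × ((S²−S)/2+S) vectorized order-j correlation
    timecourse, S = K^(2^(j−1)).
    """

    observations: Timeseries
    truth: list[np.ndarray]
    regime: RegimeSpec
    seed: int

    @property
    def order(self) -> int:
        return len(self.truth)


def random_covariance(K: int, rng: np.random.Generator) -> np.ndarray:
    """Random Gram covariance Σ = CCᵀ with C entries i.i.d. standard normal."""
    C = rng.standard_normal((K, K))
    return C @ C.T


def cov_to_corr(S: np.ndarray) -> np.ndarray:
    """Correlation normalization D^(−1/2) S D^(−1/2)."""
    d = np.sqrt(np.diag(S))
    if np.any(d <= 0):
        raise ValueError("covariance has non-positive diagonal entries")
    R = S / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return np.clip(0.5 * (R + R.T), -1.0, 1.0)


def psd_repair(S: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    """Clip eigenvalues at ``floor`` and re-unitize the diagonal.

    Returns a valid correlation matrix (symmetric, PSD, unit diagonal).
    """
    S = 0.5 * (S + S.T)
    vals, vecs = np.linalg.eigh(S)
    vals = np.clip(vals, floor, None)
    R = (vecs * vals) @ vecs.T
    return cov_to_corr(R)


def _cov_timecourse(spec: RegimeSpec, rng: np.random.Generator) -> np.ndarray:
    """T × K × K covariance timecourse for the regime (pre-normalization)."""
    K, T = spec.K, spec.T
    if spec.category == "constant":
        S = random_covariance(K, rng)
        return np.broadcast_to(S, (T, K, K)).copy()
    if spec.category == "random":
        return np.stack([random_covariance(K, rng) for _ in range(T)])
    if spec.category == "ramping":
        S0 = random_covariance(K, rng)
        S1 = random_covariance(K, rng)
        w = np.arange(T) / (T - 1)
        return (1.0 - w)[:, None, None] * S0 + w[:, None, None] * S1
    # event: piecewise-constant blocks
    block = T // spec.n_events
    mats = [random_covariance(K, rng) for _ in range(spec.n_events)]
    return np.stack([mats[t // block] for t in range(T)])


def _block_key(spec: RegimeSpec, t: int) -> int:
    """Cache key identifying which timepoints share a covariance factorization."""
    if spec.category == "constant":
        return 0
    if spec.category == "event":
        return t // (spec.T // spec.n_events)
    return t  # ramping / random: unique per timepoint


def _chol(S: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        jitter = 1e-10 * max(1.0, float(np.trace(S)) / S.shape[0])
        return np.linalg.cholesky(S + jitter * np.eye(S.shape[0]))


def _first_order_truth(spec: RegimeSpec, covs: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(spec.K)
    return np.stack([cov_to_corr(covs[t])[iu] for t in range(spec.T)])


def _sample_first_order(
    spec: RegimeSpec, covs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    obs = np.empty((spec.T, spec.K))
    chols: dict[int, np.ndarray] = {}
    for t in range(spec.T):
        key = _block_key(spec, t)
        if key not in chols:
            chols[key] = _chol(covs[t])
        obs[t] = chols[key] @ rng.standard_normal(spec.K)
    return obs


def generate_first_order(spec: RegimeSpec) -> SyntheticDataset:
    """Simulate a first-order dataset: s_t ~ N(0, Σ_t) independently per t."""
    if spec.order != 1:
        raise ValueError("generate_first_order requires order=1")
    rng = np.random.default_rng(spec.seed)
    covs = _cov_timecourse(spec, rng)
    obs = _sample_first_order(spec, covs, rng)
    return SyntheticDataset(
        observations=Timeseries(obs, order=0),
        truth=[_first_order_truth(spec, covs)],
        regime=spec,
        seed=spec.seed,
    )


def _higher_order_truth(
    spec: RegimeSpec, covs: np.ndarray
) -> tuple[list[np.ndarray], dict[int, list[np.ndarray]]]:
    """Vectorized truth streams for orders 1..n plus per-block template chains."""
    n = spec.order
    truth = [
        np.empty((spec.T, vec_length(spec.K ** (2 ** (j - 1)))))
        for j in range(1, n + 1)
    ]
    chains: dict[int, list[np.ndarray]] = {}
    for t in range(spec.T):
        key = _block_key(spec, t)
        if key not in chains:
            m = cov_to_corr(covs[t])
            chain = [m]
            for _ in range(n - 1):
                m = np.kron(m, m)
                chain.append(m)
            chains[key] = chain
        for j, mj in enumerate(chains[key], start=1):
            truth[j - 1][t] = mj[np.triu_indices(mj.shape[0])]
    return truth, chains


def _sample_backward(
    spec: RegimeSpec,
    chains: dict[int, list[np.ndarray]],
    top_chols: dict[int, np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    """Walk each timepoint's template chain backward to an order-0 observation."""
    n = spec.order
    obs = np.empty((spec.T, spec.K))
    for t in range(spec.T):
        key = _block_key(spec, t)
        if key not in top_chols:
            # the Kronecker lift of a PSD correlation matrix is PSD; the repair
            # only guards numerically tiny negative eigenvalues
            top_chols[key] = _chol(psd_repair(chains[key][-1]))
        cur_chol = top_chols[key]
        for j in range(n, 0, -1):
            v = cur_chol @ rng.standard_normal(cur_chol.shape[0])
            if j == 1:
                obs[t] = v
                break
            s = int(round(np.sqrt(v.size)))
            V = v.reshape(s, s)  # row-major, matching the kron index order
            V = np.triu(V) + np.triu(V, 1).T  # reflect upper triangle down
            cur_chol = _chol(psd_repair(V))
    return obs


def generate_higher_order(
    spec: RegimeSpec, max_matrix_side: int = 2048
) -> SyntheticDataset:
    """Simulate a dataset with known correlations at orders 1..spec.order.

    The order-1 correlation timecourse is lifted to order n by per-timepoint
    Kronecker self-products and observations are sampled backward down the
    chain (see module docstring).  Requires K^(2^(n−1)) ≤ ``max_matrix_side``.
    """
    n = spec.order
    if n < 2:
        return generate_first_order(spec)
    side = spec.K ** (2 ** (n - 1))
    if side > max_matrix_side:
        raise MemoryError(
            f"order-{n} truth matrices would be {side}x{side} "
            f"(> max_matrix_side={max_matrix_side})"
        )
    rng = np.random.default_rng(spec.seed)
    covs = _cov_timecourse(spec, rng)
    truth, chains = _higher_order_truth(spec, covs)
    obs = _sample_backward(spec, chains, {}, rng)
    return SyntheticDataset(
        observations=Timeseries(obs, order=0),
        truth=truth,
        regime=spec,
        seed=spec.seed,
    )


def generate(spec: RegimeSpec, max_matrix_side: int = 2048) -> SyntheticDataset:
    """Dispatch on ``spec.order``."""
    if spec.order == 1:
        return generate_first_order(spec)
    return generate_higher_order(spec, max_matrix_side=max_matrix_side)


def generate_group(
    spec: RegimeSpec,
    P: int,
    noise_sd: float = 1.0,
    max_matrix_side: int = 2048,
) -> tuple[list[Timeseries], list[np.ndarray]]:
    """Simulate P participants sharing one stimulus-driven signal timecourse.

    A single stimulus-driven timeseries s_t is drawn from the regime's
    covariance timecourse (through the full backward-sampling chain when
    ``spec.order`` > 1) and every participant observes it through independent
    additive white noise:

        x_t^p = s_t + noise_sd · ε_t^p,   ε_t^p ~ N(0, I_K) i.i.d.

    The stimulus-driven correlation structure is therefore identical across
    participants while the observation noise is participant-independent —
    the premise under which the leave-one-out DISFC average isolates
    stimulus-driven correlations.  ``noise_sd`` is in units of the signal's
    per-feature standard deviation (the truth timecourses are correlation
    matrices, so signal features have unit variance); ``noise_sd=0`` gives
    identical (noiseless) participants.

    Returns ``(members, truth)`` with truth in the per-order layout of
    :class:`SyntheticDataset`.
    """
    if P < 2:
        raise ValueError("need P >= 2 participants")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(spec.seed)
    covs = _cov_timecourse(spec, rng)

    if spec.order == 1:
        truth = [_first_order_truth(spec, covs)]
        # draw the shared signal from the correlation-normalized covariance so
        # noise_sd is on the signal's own per-feature scale
        corr_covs = np.stack([cov_to_corr(covs[t]) for t in range(spec.T)])
        signal = _sample_first_order(spec, corr_covs, rng)
    else:
        side = spec.K ** (2 ** (spec.order - 1))
        if side > max_matrix_side:
            raise MemoryError(
                f"order-{spec.order} truth matrices would be {side}x{side} "
                f"(> max_matrix_side={max_matrix_side})"
            )
        truth, chains = _higher_order_truth(spec, covs)
        signal = _sample_backward(spec, chains, {}, rng)

    members = [
        Timeseries(
            signal + noise_sd * rng.standard_normal(signal.shape), order=0
        )
        for _ in range(P)
    ]
    return members, truth
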