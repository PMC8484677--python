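"""Static and kernel-based dynamic correlations, plus symmetric-matrix vectorization.

The instantaneous correlation at timepoint ``t`` between columns ``i`` and ``j``
of a T × K timeseries ``X`` replaces the global column means of the Pearson
formula with kernel-weighted means centered on ``t``:

.. math::

    \\tilde{X}_{\\kappa_t}(\\cdot,k) = \\sum_{\\tau=1}^T \\kappa_t(\\tau) X(\\tau,k)

Two estimator variants are provided behind ``mode``:

``as_printed`` (default)
    The kernel enters only through the weighted mean; the cross-product and
    squared-deviation sums run unweighted over all τ.  This variant is defined
    for every kernel family including the Dirac δ (where the "mean" is the
    observation at ``t`` itself) and is used for all recovery analyses.

``fully_weighted``
    The conventional weighted Pearson correlation: the kernel weights also
    multiply the cross-product and variance sums.  Undefined (0/0) for an
    exact Dirac δ and can produce negative "variances" under the signed
    mexican-hat kernel; both conditions raise.

Both variants reduce exactly to the static Pearson correlation under the
uniform kernel.  Timepoints are reported 1-based throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernels import KernelSpec, kernel_matrix

__all__ = [
    "Timeseries",
    "static_corr",
    "dynamic_corr",
    "dynamic_xcorr",
    "vectorize_corr",
    "devectorize_corr",
    "vec_length",
    "vec_dim",
    "MODES",
    "VARIANCE_FLOOR",
]

MODES = ("as_printed", "fully_weighted")

#: variance sums below this raise rather than emitting NaN correlations
VARIANCE_FLOOR = 1e-12


@dataclass
class Timeseries:
    """A T × K multivariate timeseries of order-``n`` features.

    ``order`` 0 is raw data; order ``n`` holds (projected) nth-order dynamic
    correlations between the columns of the order-0 data.
    """

    values: np.ndarray
    order: int = 0
    feature_labels: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("Timeseries values must be a 2-D (T x K) matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Timeseries values must be finite")
        if self.feature_labels is not None and len(self.feature_labels) != self.K:
            raise ValueError("feature_labels length must equal K")

    @property
    def T(self) -> int:
        return self.values.shape[0]

    @property
    def K(self) -> int:
        return self.values.shape[1]


def _asarray(X) -> np.ndarray:
    if isinstance(X, Timeseries):
        return X.values
    A = np.asarray(X, dtype=float)
    if A.ndim != 2:
        raise ValueError("expected a 2-D (T x K) matrix")
    return A


# ---------------------------------------------------------------------------
# vectorization of symmetric matrices (the M operator and its inverse)
# ---------------------------------------------------------------------------

def vec_length(K: int) -> int:
    """Length of the vectorized upper triangle + diagonal of a K × K matrix."""
    return (K * K - K) // 2 + K


def vec_dim(length: int) -> int:
    """Recover K from a vectorized length, erroring if no integer K fits."""
    K = int((np.sqrt(8 * length + 1) - 1) / 2)
    if vec_length(K) != length:
        raise ValueError(
            f"length {length} is not of the form (K^2 - K)/2 + K for integer K"
        )
    return K


def vectorize_corr(S: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Extract the upper triangle + diagonal of symmetric ``S`` in row-major order."""
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.allclose(S, S.T, atol=tol, rtol=0.0):
        raise ValueError(f"matrix is not symmetric within {tol}")
    iu = np.triu_indices(S.shape[0])
    return S[iu]


def devectorize_corr(v: np.ndarray) -> np.ndarray:
    """Rebuild the symmetric K × K matrix whose upper triangle + diagonal is ``v``."""
    v = np.asarray(v, dtype=float).ravel()
    K = int((np.sqrt(8 * v.size + 1) - 1) / 2)
    if vec_length(K) != v.size:
        raise ValueError(
            f"length {v.size} is not of the form (K^2 - K)/2 + K for integer K"
        )
    S = np.zeros((K, K))
    iu = np.triu_indices(K)
    S[iu] = v
    S = S + S.T - np.diag(np.diag(S))
    return S


# ---------------------------------------------------------------------------
# static and dynamic correlation estimators
# ---------------------------------------------------------------------------

def static_corr(X) -> np.ndarray:
    """Pearson correlation matrix between the columns of ``X`` (T ≥ 2)."""
    A = _asarray(X)
    T, K = A.shape
    if T < 2:
        raise ValueError("need at least 2 timepoints to compute correlations")
    var = A.var(axis=0)
    bad = np.where(var <= VARIANCE_FLOOR)[0]
    if bad.size:
        raise ValueError(f"zero-variance column(s): {bad.tolist()}")
    C = np.corrcoef(A, rowvar=False)
    return np.clip(np.atleast_2d(C), -1.0, 1.0)


def _check_mode(mode: str) -> None:
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")


def dynamic_xcorr(A, B, spec: KernelSpec, mode: str = "as_printed") -> np.ndarray:
    """Per-timepoint kernel-based cross-correlations between columns of A and B.

    Returns a T × K_A × K_B array; entry ``(t, i, j)`` is the instantaneous
    correlation at (1-based) timepoint ``t+1`` between column ``i`` of ``A``
    and column ``j`` of ``B``.  Generally non-symmetric even for K_A == K_B.
    """
    _check_mode(mode)
    A = _asarray(A)
    B = _asarray(B)
    if A.shape[0] != B.shape[0]:
        raise ValueError("A and B must share the number of timepoints")
    T = A.shape[0]
    if T < 2:
        raise ValueError("need at least 2 timepoints")

    W = kernel_matrix(spec, T)
    MA = W @ A  # T x K_A weighted means
    MB = W @ B

    if mode == "as_printed":
        # cross-products and variances are unweighted sums about the weighted mean:
        #   C_t = A'B - sA mB' - mA sB' + T mA mB'
        G = A.T @ B
        sA = A.sum(axis=0)
        sB = B.sum(axis=0)
        GA = A.T @ A
        GB = B.T @ B
        out = np.empty((T, A.shape[1], B.shape[1]))
        for t in range(T):
            mA, mB = MA[t], MB[t]
            C = G - np.outer(sA, mB) - np.outer(mA, sB) + T * np.outer(mA, mB)
            vA = np.diag(GA) - 2.0 * sA * mA + T * mA**2
            vB = np.diag(GB) - 2.0 * sB * mB + T * mB**2
            _check_variance(vA, spec, t)
            _check_variance(vB, spec, t)
            out[t] = C / np.sqrt(np.outer(vA, vB))
        return np.clip(out, -1.0, 1.0)

    # fully weighted: the kernel enters every sum
    out = np.empty((T, A.shape[1], B.shape[1]))
    for t in range(T):
        w = W[t]
        dA = A - MA[t]
        dB = B - MB[t]
        C = dA.T @ (w[:, None] * dB)
        vA = np.einsum("t,tk,tk->k", w, dA, dA)
        vB = np.einsum("t,tk,tk->k", w, dB, dB)
        _check_variance(vA, spec, t, fully_weighted=True)
        _check_variance(vB, spec, t, fully_weighted=True)
        out[t] = C / np.sqrt(np.outer(vA, vB))
    return np.clip(out, -1.0, 1.0)


def _check_variance(v: np.ndarray, spec: KernelSpec, t: int, fully_weighted=False) -> None:
    if np.min(v) <= VARIANCE_FLOOR:
        hint = (
            "use mode='as_printed' or a wider kernel"
            if fully_weighted
            else "the column may be constant"
        )
        raise ValueError(
            f"effective variance below floor ({VARIANCE_FLOOR}) at timepoint "
            f"{t + 1} under kernel {spec.label}; {hint}"
        )


def dynamic_corr(X, spec: KernelSpec, mode: str = "as_printed") -> np.ndarray:
    """Per-timepoint kernel-based correlations between the columns of ``X``.

    Returns a T × ((K²−K)/2 + K) matrix; row ``t`` is the vectorized upper
    triangle + diagonal of the instantaneous correlation matrix at ``t``.
    """
    _check_mode(mode)
    A = _asarray(X)
    T, K = A.shape
    R = dynamic_xcorr(A, A, spec, mode=mode)
    iu = np.triu_indices(K)
    out = np.empty((T, vec_length(K)))
    for t in range(T):
        # symmetrize away roundoff before extracting the triangle
        S = 0.5 * (R[t] + R[t].T)
        out[t] = S[iu]
    return out
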