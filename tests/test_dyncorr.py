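"""Static/dynamic correlation estimators and symmetric-matrix vectorization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hocorr.dyncorr import (
    devectorize_corr,
    dynamic_corr,
    dynamic_xcorr,
    static_corr,
    vec_length,
    vectorize_corr,
)
from hocorr.kernels import KernelSpec, evaluate_kernel

UNIFORM = KernelSpec("uniform")
DELTA = KernelSpec("dirac_delta")


# ---------------------------------------------------------------------------
# static Pearson correlation
# ---------------------------------------------------------------------------

def pearson_oracle(x, y):
    """Term-by-term evaluation of the textbook Pearson formula."""
    T = len(x)
    mx = sum(x) / T
    my = sum(y) / T
    num = sum((x[t] - mx) * (y[t] - my) for t in range(T))
    vx = sum((x[t] - mx) ** 2 for t in range(T))
    vy = sum((y[t] - my) ** 2 for t in range(T))
    return num / np.sqrt(vx * vy)


def test_static_corr_identical_and_negated_columns():
    x = np.array([1.0, 3.0, 2.0, 5.0])
    X = np.column_stack([x, x, -x])
    C = static_corr(X)
    assert C[0, 1] == pytest.approx(1.0)
    assert C[0, 2] == pytest.approx(-1.0)
    np.testing.assert_allclose(np.diag(C), 1.0)


def test_static_corr_matches_direct_formula_oracle():
    X = np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 4.0]])
    expected = pearson_oracle(X[:, 0], X[:, 1])
    assert expected == pytest.approx(6.0 / np.sqrt(84.0))  # frozen closed form
    C = static_corr(X)
    assert C[0, 1] == pytest.approx(expected, abs=1e-12)
    assert C[1, 0] == pytest.approx(expected, abs=1e-12)


def test_static_corr_zero_variance_column_names_offender():
    X = np.column_stack([np.arange(4.0), np.full(4, 7.0)])
    with pytest.raises(ValueError, match="1"):
        static_corr(X)


# ---------------------------------------------------------------------------
# vectorization operator M and its inverse
# ---------------------------------------------------------------------------

def test_vec_length_and_identity_example():
    assert vec_length(3) == 6
    np.testing.assert_array_equal(vectorize_corr(np.eye(2)), [1.0, 0.0, 1.0])
    np.testing.assert_array_equal(devectorize_corr([1.0, 0.0, 1.0]), np.eye(2))


@settings(max_examples=30, derandomize=True)
@given(K=st.integers(min_value=1, max_value=8), seed=st.integers(0, 100))
def test_vectorize_devectorize_round_trip(K, seed):
    r = np.random.default_rng(seed)
    A = r.standard_normal((K, K))
    S = 0.5 * (A + A.T)
    np.testing.assert_allclose(devectorize_corr(vectorize_corr(S)), S, atol=1e-14)


def test_vectorize_rejects_asymmetric_devectorize_rejects_bad_length():
    with pytest.raises(ValueError):
        vectorize_corr(np.array([[0.0, 1.0], [0.5, 0.0]]))
    with pytest.raises(ValueError):
        devectorize_corr(np.arange(5.0))  # 5 != (K^2-K)/2 + K for any K


# ---------------------------------------------------------------------------
# dynamic correlations
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("mode", ["as_printed", "fully_weighted"])
def test_uniform_kernel_recovers_static_pearson(mode, rng):
    X = rng.standard_normal((40, 5))
    Y = dynamic_corr(X, UNIFORM, mode=mode)
    ref = vectorize_corr(static_corr(X))
    np.testing.assert_allclose(Y, np.tile(ref, (40, 1)), atol=1e-12)


def test_perfectly_correlated_pair_is_one_at_every_timepoint(rng):
    x = rng.standard_normal(30)
    X = np.column_stack([x, 2.0 * x + 3.0, rng.standard_normal(30)])
    for spec in (DELTA, KernelSpec("laplace", 5.0)):
        Y = dynamic_corr(X, spec)
        # pair (0,1) sits at vectorized position 1 for K=3
        np.testing.assert_allclose(Y[:, 1], 1.0, atol=1e-10)


def test_as_printed_matches_literal_sum_oracle():
    """Kernel-weighted mean, unweighted product/variance sums, evaluated longhand."""
    X = np.array(
        [[0.3, -1.2], [1.1, 0.4], [-0.5, 0.9], [0.2, -0.3], [1.4, 0.8], [-0.9, 0.1]]
    )
    spec = KernelSpec("gaussian", 2.0)
    t = 3  # 1-based center
    kappa = evaluate_kernel(spec, t, 6).weights
    mu = [sum(kappa[tau] * X[tau, k] for tau in range(6)) for k in range(2)]
    num = sum((X[tau, 0] - mu[0]) * (X[tau, 1] - mu[1]) for tau in range(6))
    v0 = sum((X[tau, 0] - mu[0]) ** 2 for tau in range(6))
    v1 = sum((X[tau, 1] - mu[1]) ** 2 for tau in range(6))
    expected = num / np.sqrt(v0 * v1)

    Y = dynamic_corr(X, spec, mode="as_printed")
    assert Y[t - 1, 1] == pytest.approx(expected, abs=1e-12)


def test_fully_weighted_matches_weighted_pearson_oracle():
    X = np.array(
        [[0.3, -1.2], [1.1, 0.4], [-0.5, 0.9], [0.2, -0.3], [1.4, 0.8], [-0.9, 0.1]]
    )
    spec = KernelSpec("laplace", 3.0)
    t = 4
    w = evaluate_kernel(spec, t, 6).weights
    mu = w @ X
    d = X - mu
    num = sum(w[tau] * d[tau, 0] * d[tau, 1] for tau in range(6))
    den = np.sqrt(
        sum(w[tau] * d[tau, 0] ** 2 for tau in range(6))
        * sum(w[tau] * d[tau, 1] ** 2 for tau in range(6))
    )
    Y = dynamic_corr(X, spec, mode="fully_weighted")
    assert Y[t - 1, 1] == pytest.approx(num / den, abs=1e-12)


def test_dirac_fully_weighted_raises_with_guidance(rng):
    X = rng.standard_normal((10, 3))
    with pytest.raises(ValueError, match="as_printed"):
        dynamic_corr(X, DELTA, mode="fully_weighted")


def test_bounded_and_unit_diagonal_for_nonnegative_kernels(rng):
    X = rng.standard_normal((25, 4))
    for spec in (KernelSpec("gaussian", 3.0), KernelSpec("laplace", 8.0), DELTA):
        Y = dynamic_corr(X, spec)
        assert np.all(Y >= -1.0) and np.all(Y <= 1.0)
        diag_cols = [0, 4, 7, 9]  # diagonal positions for K=4 vectorization
        np.testing.assert_allclose(Y[:, diag_cols], 1.0, atol=1e-12)


def test_shift_and_positive_scale_invariance(rng):
    X = rng.standard_normal((20, 3))
    X2 = X.copy()
    X2[:, 0] = 2.5 * X2[:, 0] - 7.0
    spec = KernelSpec("gaussian", 5.0)
    for mode in ("as_printed", "fully_weighted"):
        np.testing.assert_allclose(
            dynamic_corr(X, spec, mode=mode),
            dynamic_corr(X2, spec, mode=mode),
            atol=1e-10,
        )


def test_xcorr_self_equals_dynamic_corr(rng):
    X = rng.standard_normal((15, 3))
    spec = KernelSpec("laplace", 4.0)
    R = dynamic_xcorr(X, X, spec)
    Y = dynamic_corr(X, spec)
    iu = np.triu_indices(3)
    for t in range(15):
        np.testing.assert_allclose(0.5 * (R[t] + R[t].T)[iu], Y[t], atol=1e-12)


def test_xcorr_column_permutation_equivariance(rng):
    A = rng.standard_normal((18, 4))
    perm = [2, 0, 3, 1]
    spec = KernelSpec("gaussian", 6.0)
    R1 = dynamic_xcorr(A, A[:, perm], spec)
    R0 = dynamic_xcorr(A, A, spec)
    np.testing.assert_allclose(R1, R0[:, :, perm], atol=1e-12)


def test_uniform_xcorr_static_oracle(rng):
    A = rng.standard_normal((6, 2))
    B = rng.standard_normal((6, 2))
    R = dynamic_xcorr(A, B, UNIFORM)
    for i in range(2):
        for j in range(2):
            expected = pearson_oracle(A[:, i], B[:, j])
            np.testing.assert_allclose(R[:, i, j], expected, atol=1e-12)


def test_mismatched_lengths_raise(rng):
    with pytest.raises(ValueError):
        dynamic_xcorr(rng.standard_normal((5, 2)), rng.standard_normal((6, 2)), UNIFORM)
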