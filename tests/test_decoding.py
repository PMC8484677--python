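"""Group splitting, the correlation classifier, weight optimization, decoding runs."""

import numpy as np
import pytest

from hocorr.decoding import (
    compare_feature_sets,
    decode_matrix,
    decode_pair,
    optimize_weights,
    run_decoding,
    split_groups,
)
from hocorr.kernels import KernelSpec
from hocorr.synth import RegimeSpec, generate_group


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def test_split_sizes_even_and_odd():
    s = split_groups(10, seed=0)
    assert len(s.train) == len(s.test) == 5
    s7 = split_groups(7, seed=1)
    assert sorted([len(s7.train), len(s7.test)]) == [3, 4]


def test_split_disjoint_covering_and_nested():
    s = split_groups(9, seed=3)
    assert sorted(np.concatenate([s.train, s.test]).tolist()) == list(range(9))
    assert sorted(np.concatenate([s.train1, s.train2]).tolist()) == sorted(s.train.tolist())
    assert abs(len(s.train1) - len(s.train2)) <= 1


def test_split_deterministic_and_validated():
    a, b = split_groups(8, seed=5), split_groups(8, seed=5)
    np.testing.assert_array_equal(a.train, b.train)
    np.testing.assert_array_equal(a.train1, b.train1)
    with pytest.raises(ValueError):
        split_groups(3, seed=0)


# ---------------------------------------------------------------------------
# the correlation classifier
# ---------------------------------------------------------------------------

def test_self_decoding_with_distinct_rows_is_perfect(rng):
    F = rng.standard_normal((12, 6))
    assert decode_pair([F], [F.copy()], [1.0]) == 1.0


def test_random_features_decode_at_chance_via_permutation_oracle():
    """Mean accuracy over many i.i.d.-feature draws approaches 1/T."""
    r = np.random.default_rng(99)
    T = 25
    accs = [
        decode_pair([r.standard_normal((T, 8))], [r.standard_normal((T, 8))], [1.0])
        for _ in range(400)
    ]
    # chance band: mean of 400 x (2 directions) binomial(T, 1/T)/T draws
    assert abs(np.mean(accs) - 1.0 / T) < 3.0 * np.sqrt(1.0 / T / (400 * 2 * T))


def test_decode_pair_matches_exhaustive_argmax_oracle():
    template = np.array(
        [[1.0, 0.0, 2.0], [0.0, 1.0, -1.0], [2.0, 2.0, 0.0], [-1.0, 0.5, 0.5]]
    )
    decode = np.array(
        [[0.9, 0.1, 1.8], [0.1, 1.2, -0.9], [1.9, 2.2, 0.2], [-0.8, 0.4, 0.6]]
    )
    lam = decode_matrix(template, decode)
    correct_fwd = sum(
        int(np.argmax(lam[:, c]) == c) for c in range(4)
    ) / 4.0
    correct_bwd = sum(
        int(np.argmax(lam.T[:, c]) == c) for c in range(4)
    ) / 4.0
    expected = 0.5 * (correct_fwd + correct_bwd)
    assert decode_pair([template], [decode], [1.0]) == pytest.approx(expected)


def test_decode_pair_invariant_to_common_column_permutation(rng):
    A, B = rng.standard_normal((10, 5)), rng.standard_normal((10, 5))
    perm = [3, 1, 4, 0, 2]
    w = [1.0]
    assert decode_pair([A], [B], w) == decode_pair([A[:, perm]], [B[:, perm]], w)


def test_decode_matrix_validation(rng):
    with pytest.raises(ValueError):
        decode_matrix(rng.standard_normal((5, 3)), rng.standard_normal((6, 3)))
    with pytest.raises(ValueError, match="constant"):
        decode_matrix(np.ones((5, 3)), rng.standard_normal((5, 3)))
    with pytest.raises(ValueError):
        decode_matrix(rng.standard_normal((1, 3)), rng.standard_normal((1, 3)))


# ---------------------------------------------------------------------------
# weight optimization
# ---------------------------------------------------------------------------

def test_single_order_weights_are_trivial(rng):
    F = rng.standard_normal((8, 4))
    np.testing.assert_array_equal(optimize_weights([F], [F.copy()], 0), [1.0])


def test_optimizer_prefers_informative_order_and_beats_uniform():
    """Order 0 is pure noise; order 1 is shared signal: grid-search oracle check."""
    r = np.random.default_rng(17)
    T = 30
    signal = r.standard_normal((T, 6))
    feats1 = [r.standard_normal((T, 6)), signal + 0.2 * r.standard_normal((T, 6))]
    feats2 = [r.standard_normal((T, 6)), signal + 0.2 * r.standard_normal((T, 6))]
    phi = optimize_weights(feats1, feats2, 1)
    assert phi[1] > phi[0]
    assert phi.min() >= 0.0
    assert phi.sum() == pytest.approx(1.0, abs=1e-8)
    acc_opt = decode_pair(feats1, feats2, phi)
    acc_uni = decode_pair(feats1, feats2, [0.5, 0.5])
    assert acc_opt >= acc_uni
    # grid-search oracle over the 2-simplex at resolution 0.01: the optimizer
    # should land within reach of the best grid plateau
    grid = [
        decode_pair(feats1, feats2, [1.0 - w, w]) for w in np.arange(0.0, 1.0001, 0.01)
    ]
    assert acc_opt >= max(grid) - 0.05


def test_optimizer_requires_matching_orders(rng):
    F = rng.standard_normal((8, 4))
    with pytest.raises(ValueError):
        optimize_weights([F], [F], 1)


# ---------------------------------------------------------------------------
# full decoding runs
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def signal_group():
    return generate_group(
        RegimeSpec("random", K=8, T=40, seed=21), P=8, noise_sd=0.5
    )[0]


def test_run_decoding_bookkeeping(signal_group):
    bank = [KernelSpec("laplace", 5.0), KernelSpec("gaussian", 5.0)]
    res = run_decoding(signal_group, n_max=2, kernel_bank=bank, folds=3, seed=0)
    assert len(res.records) == 3 * 2 * 3  # folds x kernels x (orders 0..2)
    assert res.chance == pytest.approx(1.0 / 40)
    np.testing.assert_allclose(
        res.records["relative_accuracy"],
        res.records["accuracy"] - 1.0 / 40,
        atol=1e-12,
    )
    assert res.records["accuracy"].between(0, 1).all()


def test_run_decoding_reproducible(signal_group):
    bank = [KernelSpec("laplace", 5.0)]
    a = run_decoding(signal_group, 1, kernel_bank=bank, folds=2, seed=7)
    b = run_decoding(signal_group, 1, kernel_bank=bank, folds=2, seed=7)
    np.testing.assert_array_equal(
        a.records["accuracy"].to_numpy(), b.records["accuracy"].to_numpy()
    )


def test_noiseless_shared_signal_decodes_perfectly():
    members, _ = generate_group(
        RegimeSpec("random", K=8, T=40, seed=5), P=8, noise_sd=0.0
    )
    res = run_decoding(
        members, 0, kernel_bank=[KernelSpec("laplace", 5.0)], folds=2, seed=0
    )
    assert res.summary["mean_accuracy"].iloc[0] > 0.95


def test_pure_noise_group_decodes_at_chance():
    r = np.random.default_rng(31)
    members = [r.standard_normal((40, 8)) for _ in range(8)]
    res = run_decoding(
        members, 1, kernel_bank=[KernelSpec("laplace", 5.0)], folds=4, seed=2
    )
    # chance is 1/40; the fold-mean should sit well below any real signal level
    assert res.summary["mean_accuracy"].max() < 0.15


def test_compare_feature_sets_statistics(signal_group):
    res = run_decoding(
        signal_group,
        n_max=1,
        kernel_bank=[KernelSpec("laplace", 5.0)],
        folds=4,
        seed=3,
    )
    out = compare_feature_sets(res)
    assert out["t"].shape == (2, 2)
    assert np.allclose(np.diag(out["t"]), 0.0)
    assert out["mean_weights"].sum() == pytest.approx(1.0, abs=1e-6)
    # identical distributions -> t=0, p=1 on the diagonal comparison of a set
    # with itself; sign convention: uniformly greater accuracies give t > 0
    import pandas as pd

    rec = res.records.copy()
    rec_boost = rec.copy()
    rec_boost.loc[rec_boost["max_order"] == 1, "accuracy"] += 0.2
    res2 = type(res)(
        records=rec_boost,
        weights=res.weights,
        summary=res.summary,
        chance=res.chance,
        T=res.T,
        seed=res.seed,
    )
    out2 = compare_feature_sets(res2)
    assert out2["t"].loc[1, 0] > 0


def test_paired_t_matches_closed_form():
    from scipy import stats as spstats

    a = np.array([0.40, 0.42, 0.39, 0.45, 0.41, 0.44, 0.38, 0.43, 0.40, 0.46])
    b = np.array([0.35, 0.40, 0.36, 0.41, 0.39, 0.40, 0.37, 0.39, 0.38, 0.42])
    d = a - b
    t_closed = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
    t_lib, _ = spstats.ttest_rel(a, b)
    assert t_lib == pytest.approx(t_closed, abs=1e-12)
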