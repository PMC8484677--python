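"""Across-participant temporal decoding from order-stacked DISFC features.

Participants are split into a template group and a to-be-decoded group.  For
each feature order, the per-timepoint rows of the two groups' feature
matrices are correlated to form a timepoints × timepoints decode matrix Λ;
a weighted average Λ = Σ_i φ_i Λ_i over orders 0..n combines the feature
sets, each decode timepoint is labeled with the template timepoint whose row
correlates most strongly, and the accuracy is the proportion of correctly
labeled timepoints averaged over both group-role assignments.  Chance is 1/T
and the relative accuracy is accuracy − 1/T.

The per-order weights φ (nonnegative, summing to 1) are optimized on a
nested split of the training group.  Raw decoding accuracy is piecewise
constant in φ, so the optimizer ascends a differentiable surrogate — the
softmax probability mass (temperature 0.1) assigned to the correct template
timepoint, averaged over timepoints and both directions — over softmax-
reparameterized weights with multiple starts (uniform plus each simplex
vertex), and the candidate with the highest *true* accuracy is kept.  The
uniform start is always among the candidates, so optimized training weights
never decode worse than uniform ones.

Order-0 group features are the elementwise mean timeseries across the
group's participants; order-n features (n ≥ 1) are the group DISFC of the
members' order-(n−1) streams, which are themselves computed with Dirac-δ
kernels below the top order so temporal blur enters only once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .dyncorr import Timeseries, _asarray, dynamic_corr
from .isfc import disfc
from .kernels import KernelSpec, default_kernel_bank
from .projection import ProjectionSpec, centrality_project, pca_apply, pca_fit

__all__ = [
    "GroupSplit",
    "DecodeResult",
    "split_groups",
    "decode_matrix",
    "decode_pair",
    "optimize_weights",
    "participant_order_streams",
    "group_order_features",
    "run_decoding",
    "compare_feature_sets",
]

DELTA = KernelSpec("dirac_delta")
SOFTMAX_TEMPERATURE = 0.1


@dataclass(frozen=True)
class GroupSplit:
    """Outer train/test partition plus the nested halves of the training set."""

    train: np.ndarray
    test: np.ndarray
    train1: np.ndarray
    train2: np.ndarray
    seed: int | None = None


def split_groups(P: int, seed) -> GroupSplit:
    """Seeded random partition of P participants with the ±1 size rule."""
    if P < 4:
        raise ValueError("need P >= 4 so the training set can be halved")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(P)
    cut = P // 2 + (int(rng.integers(2)) if P % 2 else 0)
    train, test = np.sort(perm[:cut]), np.sort(perm[cut:])
    inner = rng.permutation(train.size)
    icut = train.size // 2 + (int(rng.integers(2)) if train.size % 2 else 0)
    train1, train2 = np.sort(train[inner[:icut]]), np.sort(train[inner[icut:]])
    return GroupSplit(
        train=train,
        test=test,
        train1=train1,
        train2=train2,
        seed=seed if isinstance(seed, int) else None,
    )


def decode_matrix(template: np.ndarray, decode: np.ndarray) -> np.ndarray:
    """Λ: Pearson correlation between each template row and each decode row."""
    A = np.asarray(template, dtype=float)
    B = np.asarray(decode, dtype=float)
    if A.shape != B.shape:
        raise ValueError("template and decode features must share shape")
    if A.shape[0] < 2:
        raise ValueError("need at least 2 timepoints to decode")
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    na = np.linalg.norm(Ac, axis=1)
    nb = np.linalg.norm(Bc, axis=1)
    if np.any(na < 1e-14) or np.any(nb < 1e-14):
        raise ValueError("degenerate features: a timepoint row is constant")
    return (Ac / na[:, None]) @ (Bc / nb[:, None]).T


def _direction_accuracy(lam: np.ndarray) -> float:
    """Proportion of columns whose argmax row (ties -> lowest index) is correct."""
    labels = np.argmax(lam, axis=0)
    return float(np.mean(labels == np.arange(lam.shape[1])))


def _combined(lams: list[np.ndarray], weights: np.ndarray) -> np.ndarray:
    out = np.zeros_like(lams[0])
    for w, lam in zip(weights, lams):
        out += w * lam
    return out


def _accuracy(lams: list[np.ndarray], weights: np.ndarray) -> float:
    lam = _combined(lams, weights)
    return 0.5 * (_direction_accuracy(lam) + _direction_accuracy(lam.T))


def _soft_accuracy(lams, weights, temperature=SOFTMAX_TEMPERATURE) -> float:
    lam = _combined(lams, weights)
    total = 0.0
    for L in (lam, lam.T):
        z = L / temperature
        z = z - z.max(axis=0, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=0, keepdims=True)
        total += float(np.mean(np.diag(p)))
    return total / 2.0


def decode_pair(template_feats, decode_feats, weights) -> float:
    """Decoding accuracy for weighted per-order features, both directions averaged.

    ``template_feats``/``decode_feats`` are per-order lists of T × D_i feature
    matrices (matched orders and T); ``weights`` is a simplex vector, one
    entry per order.
    """
    weights = np.asarray(weights, dtype=float)
    if len(template_feats) != len(decode_feats) or len(weights) != len(template_feats):
        raise ValueError("feature lists and weights must have matching lengths")
    lams = [decode_matrix(a, b) for a, b in zip(template_feats, decode_feats)]
    return _accuracy(lams, weights)


def optimize_weights(feats1, feats2, n: int | None = None) -> np.ndarray:
    """Optimize simplex weights φ_0..φ_n to maximize between-half decoding accuracy.

    ``feats1``/``feats2`` are per-order feature lists for the two training
    halves (orders 0..n).  Returns the feasible weight vector with the highest
    true (unsmoothed) accuracy among all optimizer candidates.
    """
    if n is None:
        n = len(feats1) - 1
    if len(feats1) < n + 1 or len(feats2) < n + 1:
        raise ValueError(f"need feature sets for all orders 0..{n}")
    if n == 0:
        return np.array([1.0])
    lams = [decode_matrix(a, b) for a, b in zip(feats1[: n + 1], feats2[: n + 1])]
    m = n + 1

    def softmax(theta):
        z = theta - theta.max()
        e = np.exp(z)
        return e / e.sum()

    def neg_surrogate(theta):
        return -_soft_accuracy(lams, softmax(theta))

    # multi-start: uniform, each vertex, and a fixed battery of seeded random
    # simplex points (the true accuracy surface is plateaued; cheap candidate
    # evaluation matters more than gradient steps)
    rng = np.random.default_rng(0)
    starts = [np.zeros(m)] + [8.0 * e for e in np.eye(m)]
    candidates = [softmax(s) for s in starts]
    candidates += list(rng.dirichlet(np.ones(m), size=64))
    for s in starts + [np.log(c + 1e-12) for c in candidates[m + 1 : m + 9]]:
        res = optimize.minimize(neg_surrogate, s, method="L-BFGS-B")
        candidates.append(softmax(res.x))
    scores = [_accuracy(lams, w) for w in candidates]
    best = candidates[int(np.argmax(scores))]
    best = np.clip(best, 0.0, None)
    return best / best.sum()


# ---------------------------------------------------------------------------
# feature construction
# ---------------------------------------------------------------------------

def participant_order_streams(
    members,
    n_max: int,
    mode: str = "as_printed",
    proj: str = "pca",
) -> list[list[np.ndarray]]:
    """Per-order low-dimensional streams X_0..X_{n_max−1} for every participant.

    Orders below the top are computed with a Dirac-δ kernel; for PCA, one
    embedding per order is fitted on the row-stacked δ-kernel correlation
    streams of *all* members so every participant (and later every group)
    shares a common space.  Returns ``streams[order][participant]``.
    """
    cur = [_asarray(m) for m in members]
    K = cur[0].shape[1]
    streams = [cur]
    for _ in range(1, n_max):
        # the Dirac-delta steps always use the as_printed estimator (the
        # fully weighted variant is a 0/0 for a one-hot kernel)
        ys = [dynamic_corr(x, DELTA, mode="as_printed") for x in cur]
        if proj == "pca":
            spec = pca_fit(ys, K)
            cur = [pca_apply(spec, y) for y in ys]
        elif proj == "eigenvector_centrality":
            cur = [centrality_project(y) for y in ys]
        else:
            raise ValueError(f"unknown projection method {proj!r}")
        streams.append(cur)
    return streams


def group_order_features(
    streams: list[list[np.ndarray]],
    indices: np.ndarray,
    n_max: int,
    analysis_spec: KernelSpec,
    mode: str = "as_printed",
) -> list[np.ndarray]:
    """Per-order feature matrices for one group of participants.

    Order 0 is the group-mean timeseries; order i ≥ 1 is the group DISFC of
    the members' order-(i−1) streams under the analysis kernel.
    """
    feats = [np.mean([streams[0][p] for p in indices], axis=0)]
    for i in range(1, n_max + 1):
        members = [streams[i - 1][p] for p in indices]
        feats.append(disfc(members, analysis_spec, mode=mode))
    return feats


@dataclass
class DecodeResult:
    """Accuracies, optimized weights and summaries from a decoding run."""

    records: pd.DataFrame  # fold, kernel, max_order, accuracy, relative_accuracy
    weights: pd.DataFrame  # fold, kernel, max_order, order, phi
    summary: pd.DataFrame  # per max_order, kernel-bank-averaged mean + 95% CI
    chance: float
    T: int
    seed: int


def run_decoding(
    group,
    n_max: int,
    kernel_bank: list[KernelSpec] | None = None,
    folds: int = 10,
    seed: int = 0,
    mode: str = "as_printed",
    proj: str = "pca",
) -> DecodeResult:
    """Full decoding analysis over folds × kernel bank × max feature order.

    For each of ``folds`` random group assignments and each analysis kernel,
    per-order features are built for the nested training halves (to optimize
    the order weights φ) and for the outer train/test groups (to evaluate);
    accuracies are summarized per max order after averaging over the kernel
    bank (the robustness average).
    """
    members = [_asarray(m) for m in group]
    P = len(members)
    T = members[0].shape[0]
    chance = 1.0 / T
    if kernel_bank is None:
        kernel_bank = default_kernel_bank()

    streams = participant_order_streams(members, max(n_max, 1), mode=mode, proj=proj)
    rng = np.random.default_rng(seed)
    fold_seeds = rng.integers(0, 2**31 - 1, size=folds)

    rec_rows, weight_rows = [], []
    for fold in range(folds):
        split = split_groups(P, int(fold_seeds[fold]))
        for spec in kernel_bank:
            f1 = group_order_features(streams, split.train1, n_max, spec, mode)
            f2 = group_order_features(streams, split.train2, n_max, spec, mode)
            ftr = group_order_features(streams, split.train, n_max, spec, mode)
            fte = group_order_features(streams, split.test, n_max, spec, mode)
            for n in range(n_max + 1):
                phi = optimize_weights(f1[: n + 1], f2[: n + 1], n)
                acc = decode_pair(ftr[: n + 1], fte[: n + 1], phi)
                rec_rows.append(
                    {
                        "fold": fold,
                        "kernel": spec.label,
                        "max_order": n,
                        "accuracy": acc,
                        "relative_accuracy": acc - chance,
                    }
                )
                for i, w in enumerate(phi):
                    weight_rows.append(
                        {
                            "fold": fold,
                            "kernel": spec.label,
                            "max_order": n,
                            "order": i,
                            "phi": w,
                        }
                    )

    records = pd.DataFrame(rec_rows)
    weights = pd.DataFrame(weight_rows)

    # robustness average over the kernel bank, then fold-level summary
    per_fold = (
        records.groupby(["fold", "max_order"])["accuracy"].mean().reset_index()
    )
    rows = []
    for n, sub in per_fold.groupby("max_order"):
        a = sub["accuracy"].to_numpy()
        mean = a.mean()
        if a.size > 1:
            sem = a.std(ddof=1) / np.sqrt(a.size)
            tcrit = stats.t.ppf(0.975, df=a.size - 1)
        else:
            sem, tcrit = 0.0, 0.0
        rows.append(
            {
                "max_order": n,
                "mean_accuracy": mean,
                "ci_low": mean - tcrit * sem,
                "ci_high": mean + tcrit * sem,
                "mean_relative_accuracy": mean - chance,
            }
        )
    summary = pd.DataFrame(rows)
    return DecodeResult(
        records=records, weights=weights, summary=summary, chance=chance, T=T, seed=seed
    )


def compare_feature_sets(result: DecodeResult):
    """Pairwise paired t-tests between max-order feature sets, plus mean weights.

    Returns a dict with square DataFrames ``t`` and ``p`` (feature set i vs j
    across folds on kernel-averaged accuracies), a ``vs_rest`` frame comparing
    each feature set against the mean of all others, and ``mean_weights`` —
    the average optimized weight per order in the full (highest max-order)
    decoder.
    """
    per_fold = (
        result.records.groupby(["fold", "max_order"])["accuracy"]
        .mean()
        .unstack("max_order")
    )
    if per_fold.shape[0] < 2:
        raise ValueError("need at least 2 folds to compare feature sets")
    orders = list(per_fold.columns)
    m = len(orders)
    tmat = pd.DataFrame(np.zeros((m, m)), index=orders, columns=orders)
    pmat = pd.DataFrame(np.ones((m, m)), index=orders, columns=orders)
    for i in orders:
        for j in orders:
            if i == j:
                continue
            a, b = per_fold[i].to_numpy(), per_fold[j].to_numpy()
            if np.allclose(a, b):
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_rel(a, b)
            tmat.loc[i, j], pmat.loc[i, j] = t, p

    vs_rows = []
    for i in orders if m >= 2 else []:
        rest = per_fold[[j for j in orders if j != i]].mean(axis=1)
        a, b = per_fold[i].to_numpy(), rest.to_numpy()
        if np.allclose(a, b):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(a, b)
        vs_rows.append({"max_order": i, "t": t, "p": p})

    n_full = result.weights["max_order"].max()
    mean_weights = (
        result.weights[result.weights["max_order"] == n_full]
        .groupby("order")["phi"]
        .mean()
    )
    return {
        "t": tmat,
        "p": pmat,
        "vs_rest": pd.DataFrame(vs_rows),
        "mean_weights": mean_weights,
    }
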