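"""Low-dimensional projections of vectorized correlation streams.

A T × ((K²−K)/2+K) correlation stream is mapped back onto a T × K feature
matrix in one of two ways:

- **PCA** — a single linear embedding fitted on the row-stacked streams of all
  participants in an analysis set, so every group shares one space.  Scores
  approximately preserve (and can invert back to) the correlation patterns.
- **Eigenvector centrality** — each timepoint's correlation matrix is turned
  into a nonnegative weight matrix and each feature is scored by the principal
  eigenvector: a node is central when it is strongly connected to other
  central nodes.  This keeps the original feature identities but discards the
  activity patterns themselves.

Correlations are signed but eigenvector centrality needs nonnegative weights;
by default the absolute correlation is used as the edge weight (so the
Perron–Frobenius theorem guarantees a nonnegative principal eigenvector).  A
shifted alternative, (1+r)/2, is available behind ``weight_transform``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.decomposition import PCA

from .dyncorr import devectorize_corr, vec_dim

__all__ = [
    "ProjectionSpec",
    "pca_fit",
    "pca_apply",
    "pca_invert",
    "centrality_project",
    "eigenvector_centrality",
    "graph_project",
    "GRAPH_MEASURES",
    "register_graph_measure",
]


@dataclass
class ProjectionSpec:
    """A fitted (PCA) or parameter-free (centrality) projection onto K dims."""

    method: str  # "pca" | "eigenvector_centrality"
    n_components: int
    mean_: np.ndarray | None = field(default=None, repr=False)
    components_: np.ndarray | None = field(default=None, repr=False)  # K x D, orthonormal rows


def _stack(streams) -> np.ndarray:
    mats = [np.asarray(s, dtype=float) for s in streams]
    D = mats[0].shape[1]
    if any(m.shape[1] != D for m in mats):
        raise ValueError("all streams must share the vectorized dimension")
    return np.vstack(mats)


def pca_fit(streams, K: int) -> ProjectionSpec:
    """Fit one shared top-K PCA embedding on row-stacked correlation streams.

    Component signs are made deterministic by flipping each component so its
    largest-magnitude loading is positive.
    """
    Y = _stack(streams if isinstance(streams, (list, tuple)) else [streams])
    n, D = Y.shape
    if K > min(n, D):
        raise ValueError(
            f"K={K} exceeds the available rank min(rows={n}, dim={D})"
        )
    model = PCA(n_components=K, svd_solver="full")
    model.fit(Y)
    comps = model.components_.copy()
    for i in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    return ProjectionSpec(
        method="pca", n_components=K, mean_=model.mean_, components_=comps
    )


def pca_apply(spec: ProjectionSpec, Y) -> np.ndarray:
    """Project a stream onto the fitted components; returns T × K scores."""
    if spec.method != "pca" or spec.components_ is None:
        raise ValueError("spec is not a fitted PCA projection")
    Y = np.asarray(Y, dtype=float)
    if Y.shape[1] != spec.components_.shape[1]:
        raise ValueError(
            f"stream has dimension {Y.shape[1]}, "
            f"spec was fitted on {spec.components_.shape[1]}"
        )
    return (Y - spec.mean_) @ spec.components_.T


def pca_invert(spec: ProjectionSpec, scores) -> np.ndarray:
    """Back-project T × K scores to the vectorized-correlation space."""
    if spec.method != "pca" or spec.components_ is None:
        raise ValueError("spec is not a fitted PCA projection")
    return np.asarray(scores, dtype=float) @ spec.components_ + spec.mean_


# ---------------------------------------------------------------------------
# graph-measure projections (η : symmetric K×K matrix -> K-vector)
# ---------------------------------------------------------------------------

def eigenvector_centrality(S: np.ndarray, weight_transform: str = "abs") -> np.ndarray:
    """Principal-eigenvector centrality of a signed symmetric weight matrix.

    The matrix is made nonnegative (``abs`` of the entries by default, or the
    shift (1+r)/2), and the eigenvector of the largest eigenvalue is returned
    with unit Euclidean norm and nonnegative orientation.  Exactly tied
    dominant eigenvalues are broken deterministically by projecting the
    all-ones vector onto the tied eigenspace.
    """
    S = np.asarray(S, dtype=float)
    if weight_transform == "abs":
        A = np.abs(S)
    elif weight_transform == "shift":
        A = (1.0 + S) / 2.0
    else:
        raise ValueError(f"unknown weight_transform {weight_transform!r}")
    vals, vecs = np.linalg.eigh(A)
    top = vals[-1]
    tied = vals >= top - 1e-12 * max(1.0, abs(top))
    if tied.sum() > 1:
        # deterministic tie-break: component of the all-ones vector in the
        # dominant eigenspace (equivalent to power iteration started at 1)
        basis = vecs[:, tied]
        v = basis @ (basis.T @ np.ones(A.shape[0]))
        if np.linalg.norm(v) < 1e-12:
            v = vecs[:, -1]
    else:
        v = vecs[:, -1]
    v = v / np.linalg.norm(v)
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    v = np.clip(v, 0.0, None)  # remove roundoff negatives (Perron-Frobenius)
    return v / np.linalg.norm(v)


GRAPH_MEASURES: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "eigenvector_centrality": eigenvector_centrality,
}


def register_graph_measure(name: str, fn: Callable[[np.ndarray], np.ndarray]) -> None:
    """Register a plug-in graph measure η mapping a symmetric K×K matrix to a K-vector."""
    GRAPH_MEASURES[name] = fn


def graph_project(Y, measure: str = "eigenvector_centrality", **kwargs) -> np.ndarray:
    """Apply a registered graph measure to each devectorized row of a stream."""
    Y = np.asarray(Y, dtype=float)
    fn = GRAPH_MEASURES[measure]
    K = vec_dim(Y.shape[1])
    out = np.empty((Y.shape[0], K))
    for t in range(Y.shape[0]):
        out[t] = fn(devectorize_corr(Y[t]), **kwargs) if kwargs else fn(devectorize_corr(Y[t]))
    return out


def centrality_project(Y, weight_transform: str = "abs") -> np.ndarray:
    """Per-timepoint eigenvector centrality of a vectorized correlation stream."""
    Y = np.asarray(Y, dtype=float)
    K = vec_dim(Y.shape[1])
    out = np.empty((Y.shape[0], K))
    for t in range(Y.shape[0]):
        out[t] = eigenvector_centrality(
            devectorize_corr(Y[t]), weight_transform=weight_transform
        )
    return out
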