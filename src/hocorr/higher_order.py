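"""Recursive estimation of order-0 … order-n dynamic correlation features.

Each recursion step maps a T × K order-n timeseries X_n to the T × K order-
(n+1) timeseries X_{n+1} = project(dynamic_corr(X_n)): the kernel-based
correlation stream (T × (K²−K)/2+K) is computed and immediately projected
back onto K dimensions, so the stored representation of orders 0..n occupies
exactly (n+1)·T·K values — linear in n, instead of the O(T·K^(2^n)) that the
unprojected correlations would require.

Two stepping conventions are supported.  In ``decode_mode`` the intermediate
orders 1..n−1 are computed with a Dirac δ kernel and only the final step uses
the analysis kernel, so temporal blurring is applied exactly once regardless
of the target order (otherwise higher orders would be blurred n times and a
timepoint decoder would be biased against them).  With ``decode_mode=False``
the analysis kernel is used at every step.

The recovery benchmarks use a separate *unprojected* recursion (see
:mod:`hocorr.recovery`) that stays in the exact correlation space so the
order-n estimates can be scored entry-by-entry against simulated ground
truth; that route is exponential in n and only feasible for small K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dyncorr import Timeseries, _asarray, dynamic_corr
from .kernels import KernelSpec
from .projection import ProjectionSpec, centrality_project, pca_apply, pca_fit

__all__ = ["OrderStack", "step", "build_stack"]

DELTA = KernelSpec("dirac_delta")


@dataclass
class OrderStack:
    """Per-order T × K feature matrices X_0..X_n plus the specs that built them."""

    orders: list[Timeseries]
    kernels: list[KernelSpec] = field(default_factory=list)  # kernel used per step
    projections: list[ProjectionSpec | None] = field(default_factory=list)
    mode: str = "as_printed"

    @property
    def n_max(self) -> int:
        return len(self.orders) - 1

    @property
    def n_stored_values(self) -> int:
        return int(sum(x.values.size for x in self.orders))

    def __getitem__(self, n: int) -> Timeseries:
        return self.orders[n]


def _project(Y: np.ndarray, method, K: int) -> tuple[np.ndarray, ProjectionSpec | None]:
    """Project a correlation stream to K columns; fit PCA here if not prefitted."""
    if isinstance(method, ProjectionSpec):
        if method.method == "pca":
            return pca_apply(method, Y), method
        method = method.method
    if method == "pca":
        spec = pca_fit([Y], K)
        return pca_apply(spec, Y), spec
    if method == "eigenvector_centrality":
        return centrality_project(Y), ProjectionSpec("eigenvector_centrality", K)
    raise ValueError(f"unknown projection method {method!r}")


def step(X_n, spec: KernelSpec, mode: str = "as_printed", proj="pca") -> Timeseries:
    """One recursion step: X_{n+1} = project(dynamic_corr(X_n, spec, mode))."""
    order = X_n.order if isinstance(X_n, Timeseries) else 0
    A = _asarray(X_n)
    Y = dynamic_corr(A, spec, mode=mode)
    Z, _ = _project(Y, proj, A.shape[1])
    return Timeseries(Z, order=order + 1)


def build_stack(
    X_0,
    n_max: int,
    analysis_spec: KernelSpec,
    mode: str = "as_printed",
    proj="pca",
    decode_mode: bool = False,
    fitted_projections: list[ProjectionSpec] | None = None,
) -> OrderStack:
    """Compute the order stack X_0..X_{n_max}.

    ``fitted_projections`` optionally supplies a prefitted projection per step
    (e.g. PCA specs fitted on pooled δ-kernel streams across participants);
    otherwise each step fits its own projection on its own stream.  Order 0 is
    passed through untouched.
    """
    if n_max < 0:
        raise ValueError("n_max must be >= 0")
    A = _asarray(X_0)
    orders = [Timeseries(A.copy(), order=0)]
    kernels: list[KernelSpec] = []
    projections: list[ProjectionSpec | None] = []
    cur = A
    for j in range(1, n_max + 1):
        spec = analysis_spec if (not decode_mode or j == n_max) else DELTA
        Y = dynamic_corr(cur, spec, mode=mode)
        proj_j = (
            fitted_projections[j - 1]
            if fitted_projections is not None
            else proj
        )
        cur, used = _project(Y, proj_j, A.shape[1])
        orders.append(Timeseries(cur, order=j))
        kernels.append(spec)
        projections.append(used)
    return OrderStack(orders=orders, kernels=kernels, projections=projections, mode=mode)
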