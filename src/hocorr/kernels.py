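"""Kernel functions for weighting timepoints in instantaneous-correlation estimates.

A kernel :math:`\\kappa_t(\\tau)` centered on timepoint ``t`` assigns each
observed timepoint ``τ ∈ [1..T]`` a weight describing how much it contributes
to the correlation estimate at ``t``.  Five families are supported:

- ``uniform`` — every timepoint weighted equally (dynamic estimates reduce to
  the static Pearson correlation);
- ``dirac_delta`` — all mass on the center timepoint (infinitely narrow);
- ``gaussian`` — Gaussian density centered on ``t``; ``width`` is the variance σ²;
- ``laplace`` — Laplace density centered on ``t``; ``width`` is the scale b;
- ``mexican_hat`` — Ricker wavelet centered on ``t``; ``width`` is the scale σ.
  The wavelet contrasts local against surrounding activity, so its weights
  carry negative side lobes.

Weights are evaluated on the observed range ``[1..T]`` (truncated) and then
normalized.  The nonnegative families are normalized to sum to exactly 1, so
the kernel-weighted mean is a proper weighted average; edge timepoints get
renormalized one-sided windows.  The mexican-hat raw weights nearly cancel
when summed (the truncated discrete Ricker sum is ~0 for interior centers),
so that family is normalized by the sum of absolute weights instead, which
preserves its shape and scale without dividing by a vanishing quantity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KernelSpec",
    "KernelWeights",
    "evaluate_kernel",
    "kernel_matrix",
    "default_kernel_bank",
    "FAMILIES",
]

FAMILIES = ("uniform", "dirac_delta", "gaussian", "laplace", "mexican_hat")

#: families whose width parameter is meaningful
_WIDTH_FAMILIES = ("gaussian", "laplace", "mexican_hat")


@dataclass(frozen=True)
class KernelSpec:
    """A kernel family plus its width parameter.

    ``width`` maps to the parameter conventional for each family: σ² for
    ``gaussian``, the scale b for ``laplace``, and σ for ``mexican_hat``.
    It is ignored by ``uniform`` and ``dirac_delta``.
    """

    family: str
    width: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown kernel family {self.family!r}; expected one of {FAMILIES}"
            )
        if self.family in _WIDTH_FAMILIES:
            if self.width is None or not np.isfinite(self.width) or self.width <= 0:
                raise ValueError(
                    f"kernel family {self.family!r} requires a positive width, "
                    f"got {self.width!r}"
                )

    @property
    def label(self) -> str:
        if self.family in _WIDTH_FAMILIES:
            return f"{self.family}({self.width:g})"
        return self.family


@dataclass(frozen=True)
class KernelWeights:
    """Normalized per-timepoint weights for a kernel centered on ``center``.

    ``center`` is 1-based, matching the τ ∈ [1..T] convention used throughout.
    """

    center: int
    weights: np.ndarray


def _raw_profile(spec: KernelSpec, t: int, T: int) -> np.ndarray:
    tau = np.arange(1, T + 1, dtype=float)
    d = tau - t
    if spec.family == "uniform":
        return np.ones(T)
    if spec.family == "dirac_delta":
        w = np.zeros(T)
        w[t - 1] = 1.0
        return w
    if spec.family == "gaussian":
        # width is the variance sigma^2
        return np.exp(-(d**2) / (2.0 * spec.width))
    if spec.family == "laplace":
        return np.exp(-np.abs(d) / spec.width)
    # mexican hat (Ricker wavelet), width is sigma
    x2 = (d / spec.width) ** 2
    return (1.0 - x2) * np.exp(-x2 / 2.0)


def evaluate_kernel(spec: KernelSpec, t: int, T: int) -> KernelWeights:
    """Evaluate ``spec`` centered on 1-based timepoint ``t`` over ``τ ∈ [1..T]``.

    Returns normalized weights: nonnegative families sum to 1 exactly;
    ``mexican_hat`` weights have unit L1 norm (their plain sum nearly cancels).
    """
    if T < 1:
        raise ValueError("series length T must be >= 1")
    if not 1 <= t <= T:
        raise ValueError(f"kernel center t={t} outside [1..{T}]")
    w = _raw_profile(spec, t, T)
    if spec.family == "mexican_hat":
        denom = np.abs(w).sum()
    else:
        denom = w.sum()
    if not np.isfinite(denom) or abs(denom) < 1e-300:
        raise ValueError(f"degenerate kernel weights for {spec.label} at t={t}")
    return KernelWeights(center=t, weights=w / denom)


def kernel_matrix(spec: KernelSpec, T: int) -> np.ndarray:
    """T × T matrix whose row ``t-1`` holds the weights of the kernel centered on t."""
    return np.vstack([evaluate_kernel(spec, t, T).weights for t in range(1, T + 1)])


def default_kernel_bank() -> list[KernelSpec]:
    """The default analysis bank: {gaussian, laplace, mexican_hat} × widths {5, 10, 20, 50}."""
    return [
        KernelSpec(family, float(width))
        for family in ("gaussian", "laplace", "mexican_hat")
        for width in (5, 10, 20, 50)
    ]
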