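"""Dynamic inter-subject functional connectivity (DISFC).

Given observation matrices X^1..X^P from P participants experiencing the same
stimulus, the stimulus-driven correlation structure at each timepoint is
estimated by correlating each participant's features against the leave-one-out
average of everyone else's, Fisher z-transforming, averaging the symmetrized
z-maps across participants, and mapping back to correlation units:

    C̄(t) = M( R( (1/2P) Σ_p [ Z(Y^p(t))ᵀ + Z(Y^p(t)) ] ) )

where Y^p(t) is the kernel-based cross-correlation matrix at t between
participant p and the leave-one-out mean, Z/R are the Fisher transform and its
inverse, and M vectorizes the upper triangle + diagonal.  Because the
participant-specific noise is independent across individuals, only correlation
structure time-locked to the shared stimulus survives the average.

Diagonal entries of Y^p are cross-correlations with the leave-one-out mean and
are generally < 1; they pass through untouched (no re-unitization).
"""

from __future__ import annotations

import numpy as np

from .dyncorr import Timeseries, _asarray, dynamic_xcorr, vec_length
from .kernels import KernelSpec

__all__ = ["fisher_z", "inv_fisher_z", "loo_average", "disfc", "CLIP"]

#: correlations are clipped to ±(1 − CLIP_EPS) before the Fisher transform
CLIP_EPS = 1e-10
CLIP = 1.0 - CLIP_EPS


def fisher_z(r):
    """Fisher z-transform, z = ½·log((1+r)/(1−r)); input clipped to ±(1−1e−10)."""
    r = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("fisher_z requires finite input")
    return np.arctanh(np.clip(r, -CLIP, CLIP))


def inv_fisher_z(z):
    """Inverse Fisher transform, r = (exp(2z) − 1)/(exp(2z) + 1) = tanh(z)."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("inv_fisher_z requires finite input")
    return np.tanh(z)


def _group_values(group) -> list[np.ndarray]:
    members = [_asarray(m) for m in group]
    if len(members) < 2:
        raise ValueError("need at least 2 participants")
    shape = members[0].shape
    for i, m in enumerate(members[1:], start=2):
        if m.shape != shape:
            raise ValueError(
                f"participant {i} has shape {m.shape}, expected {shape}"
            )
    return members


def loo_average(group, p: int) -> np.ndarray:
    """Elementwise mean of all members except (0-based) member ``p``."""
    members = _group_values(group)
    if not 0 <= p < len(members):
        raise IndexError(f"participant index {p} out of range [0..{len(members) - 1}]")
    rest = [m for q, m in enumerate(members) if q != p]
    return np.mean(rest, axis=0)


def disfc(group, spec: KernelSpec, mode: str = "as_printed") -> np.ndarray:
    """DISFC stream for a participant group.

    Returns a T × ((K²−K)/2 + K) matrix; each row devectorizes to the
    symmetric stimulus-driven correlation matrix at that timepoint.

    ``group`` is a sequence of T × K arrays (or :class:`Timeseries`) sharing
    T and K exactly; P ≥ 2 is required for the leave-one-out average.
    """
    members = _group_values(group)
    P = len(members)
    T, K = members[0].shape

    zsum = np.zeros((T, K, K))
    for p, Xp in enumerate(members):
        loo = loo_average(members, p)
        Yp = dynamic_xcorr(Xp, loo, spec, mode=mode)  # T x K x K
        Zp = fisher_z(Yp)
        zsum += Zp + np.transpose(Zp, (0, 2, 1))

    R = inv_fisher_z(zsum / (2.0 * P))  # symmetric by construction
    iu = np.triu_indices(K)
    out = np.empty((T, vec_length(K)))
    for t in range(T):
        out[t] = R[t][iu]
    return out
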