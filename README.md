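# hocorr

Kernel-based estimation of **dynamic, arbitrarily high-order correlations**
in multivariate timeseries — with matched synthetic-data simulators,
recovery benchmarks, and an across-participant temporal decoder.

Functional brain networks (and many other coupled systems) reconfigure from
moment to moment. Sliding-window correlations capture some of this, but they
impose a window, and they stop at pairwise (first-order) structure. `hocorr`
implements a framework for researchers in network neuroscience and systems
biology who want timepoint-resolved estimates of:

- **order 1** — dynamic correlations between features,
- **order 2** — correlations between patterns of correlation (homologous
  subgraphs behaving alike),
- **order n** — recursively, homologies between order-(n−1) dynamics.

## The estimator

For a T × K timeseries **X**, a kernel κ_t weights every observed timepoint
by its relevance to time *t*, giving a kernel-weighted mean
μ̃_k(t) = Σ_τ κ_t(τ) X(τ,k) and the instantaneous correlation

    corr_t(i, j) = Σ_τ (X(τ,i) − μ̃_i(t)) (X(τ,j) − μ̃_j(t))
                   ───────────────────────────────────────────
                   √( Σ_τ (X(τ,i) − μ̃_i(t))² · Σ_τ (X(τ,j) − μ̃_j(t))² )

Kernel families: uniform (recovers the static Pearson correlation exactly),
Dirac δ, Gaussian, Laplace, and Mexican hat. A fully weighted variant
(kernel inside every sum) is available behind `mode="fully_weighted"`.

Around this core the package provides:

- **DISFC** — dynamic inter-subject functional connectivity: each
  participant's features are correlated against the leave-one-out group
  average and combined through Fisher z-averaging, isolating stimulus-driven
  structure: C̄(t) = M(R((1/2P) Σ_p [Z(Y^p(t))ᵀ + Z(Y^p(t))])).
- **Order recursion** — each T × ((K²−K)/2+K) correlation stream is projected
  back to T × K (PCA or per-timepoint eigenvector centrality), so estimating
  orders 0..n needs only (n+1)·T·K values instead of O(T·K^(2^n)). Storing
  15th-order correlations of 700 nodes conventionally would take
  700³⁰/2 ≈ 1.13×10⁸⁵ numbers; the recursion stores 16 ordinary matrices.
- **Simulators** — multivariate Gaussian timeseries with known dynamic
  correlations under four regimes (constant, random, ramping, event), plus
  Kronecker-lifted higher-order structure and multi-participant groups
  sharing a stimulus-driven signal.
- **Recovery benchmarks** — per-timepoint correlation between recovered and
  true correlations, summarized across replicates with 95% CIs.
- **Temporal decoding** — an across-participant correlation classifier over
  weighted blends of feature orders, with simplex-constrained weight
  optimization, repeated random group assignments, kernel-bank robustness
  averaging, and paired-t feature-set comparisons.

See `docs/methods.md` for conventions, numerical choices, and limitations.

## Worked example

```python
import numpy as np
from hocorr import (KernelSpec, RegimeSpec, generate_first_order,
                    recovery_timecourse, generate_group, run_decoding)

# 1. Simulate an event-structured dataset (50 features, 300 timepoints,
#    5 covariance regimes) and ask how well two kernels recover the truth.
ds = generate_first_order(RegimeSpec("event", K=50, T=300, seed=0))
for spec in (KernelSpec("dirac_delta"), KernelSpec("laplace", 20.0)):
    res = recovery_timecourse(ds, spec)
    print(f"{spec.label:>12}: mean recovery r = {res.mean:.3f}")

# 2. Simulate 8 participants sharing a stimulus-driven covariance timecourse
#    and decode held-out participants' timepoints from DISFC features.
members, _ = generate_group(RegimeSpec("random", K=10, T=100, seed=0), P=8)
out = run_decoding(members, n_max=2, kernel_bank=[KernelSpec("laplace", 10.0)],
                   folds=10, seed=0)
print(out.summary.round(3).to_string(index=False))
```

Output:

```
 dirac_delta: mean recovery r = 0.175
 laplace(20): mean recovery r = 0.323
 max_order  mean_accuracy  ci_low  ci_high  mean_relative_accuracy
         0          0.678   0.645    0.710                   0.668
         1          0.682   0.649    0.714                   0.672
         2          0.682   0.650    0.714                   0.672
```

The width-20 Laplace kernel, which pools over nearby timepoints, recovers
the piecewise-stable event correlations almost twice as well as the
single-timepoint δ kernel (r = 0.32 vs 0.18). In the decoding run, held-out
timepoints are identified with ≈68% accuracy against a 1% chance level —
the participants share only their correlation *structure* plus a common
signal, and the classifier finds it at every feature order.

The same pipeline is scriptable from the shell:

```bash
hocorr simulate --category event --K 50 --T 300 --reps 20 --seed 0 --out sim/
hocorr recover  --categories constant,random,ramping,event \
                --kernels laplace:5,laplace:10,laplace:20,laplace:50 \
                --reps 20 --seed 0 --out rec/
hocorr decode   group_dir/ --orders 2 --folds 10 --bank default --seed 0 --out dec/
```

Every stage writes a `manifest.json` with its resolved configuration, and
all randomness derives from `--seed`.

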