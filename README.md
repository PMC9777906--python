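# hivecrit

Tools for asking whether a collectively behaving animal group — a honey-bee
colony tracked inside its hive — operates near a critical point, by comparing
the statistical signatures of its activity with the two-dimensional Ising
model at, below, and above its critical temperature.

The package is aimed at researchers in collective behavior and systems
neuroscience who want a tested, reusable implementation of the full analysis
chain:

1. **Trajectories → activity.** Raw detections `(individual_id, timestamp,
   x, y)` are resampled by linear interpolation to a uniform grid, inactive
   individuals are filtered out, and each individual's activity is measured
   by its per-interval "kinetic energy" `K(t) = Δx² + Δy²` (a massless
   proxy). The hive-level series is the mean over individuals.
2. **Ising simulation.** Metropolis dynamics on an `L × L` torus
   (`J = k_B = 1`, no field): each step is `N = L²` random single-site flip
   attempts accepted with probability `min(1, exp(−ΔE/T))`. Runs thermalize
   from a hot start, then record consecutive configurations and the
   magnetization `M = mean(sᵢ)`.
3. **Correlation networks.** Pearson's `r` between every pair of node
   time-series (lattice sites, or individual energy series); edges where
   `r > p`, with `p` chosen so the mean degree `⟨k⟩` hits a target (default
   110) so that networks from different systems are comparable.
4. **Degree-distribution MLE.** Discrete maximum likelihood for the power
   law `k^(−α)`, the truncated power law `k^(−α) e^(−λk)`, and the
   discretized log-normal, on a common tail `k ≥ xmin` selected by
   Kolmogorov–Smirnov distance; families compared by Vuong-style normalized
   log-likelihood ratios.
5. **Small-world metrics.** Average clustering `C`, average shortest-path
   length `L`, and exact diameter `D` of the giant component, against an
   ensemble of Erdős–Rényi `G(n, p)` graphs matched on `n` and `⟨k⟩`.
6. **Hurst exponent.** From the cumulative-deviation profile
   `K_sum(t) = Σᵢ≤t (Kᵢ − μ)`, the lag variance
   `Var(τ) = ⟨(K_sum(t+τ) − K_sum(t))²⟩` scales as `τ^(2H)`; `H` is half the
   OLS slope of `log Var` on `log τ` (with a finite-sample bridge
   correction; see `docs/methods.md`). `H ≈ 0.5` is memoryless; `H > 0.5`
   signals persistent long-range temporal correlation. A seeded shuffle
   control destroys temporal order and must return `H ≈ 0.5`.

Because the original colony recordings are third-party and not deposited,
`hivecrit.synth` generates hive-like detection tables with planted,
controllable structure (correlated activity groups with burst/quiescence
switching, inactive individuals, detection dropouts) plus exact fractional
Gaussian noise with known `H` — so every stage of the pipeline is testable
against ground truth.

## Worked example

```python
import numpy as np
from hivecrit import ising, corrnet, netstats, hurst

cfg = ising.SimulationConfig(L=100, T=2.3, n_therm=10_000, n_record=2_000, seed=42)
run = ising.run_simulation(cfg)                       # ~3 s (numba kernel)
corr = corrnet.pearson_matrix(ising.site_series(run)) # 10,000 x 10,000 Pearson matrix
p, k = corrnet.choose_threshold(corr, target_k=110.0)
net = corrnet.build_network(corr, p)
giant = netstats.giant_component(net)
print(f"p={p:.3f}  <k>={k:.1f}  C={netstats.clustering(giant):.3f}")
pm = netstats.path_metrics(giant, n_sources=1000, seed=7)
print(f"L={pm.L:.2f}  D={pm.D}")
est = hurst.estimate_hurst(run.magnetization)
print(f"H={est.H:.2f} (r^2={est.r_squared:.3f})")
```

prints (seed 42):

```
p=0.271  <k>=110.7  C=0.549
L=5.53  D=21
H=1.11 (r^2=1.000)
```

Read: at the critical temperature the site-correlation network at mean
degree 110 is strongly clustered (`C ≈ 0.55`, some fifty times the matched
Erdős–Rényi value `⟨k⟩/(n−1) ≈ 0.011`) while its path length stays a few
hops — the small-world signature — and the magnetization series is strongly
persistent (`H` far above the 0.5 of a memoryless process). Re-running at
`T = 2.0` or `T = 3.0` collapses `C` to ≈ 0.07–0.12 and `H` toward 0.5:
the signatures appear only near criticality.

A command-line interface mirrors the library:

```bash
hivecrit simulate-ising --L 100 --T 2.3 --therm 10000 --record 2000 --seed 1 --out run/
hivecrit synth hive --seed 1 --out detections.csv
hivecrit run --mode ising --seed 1 --out results/
hivecrit hurst --input series.csv --shuffle-control --seed 1 --out hurst.json
```

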