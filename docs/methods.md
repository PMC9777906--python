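# Methods

This note documents the models, estimators, parameter choices, and known
limitations of the package. Everything stated here is computed by the test
suite or by `scripts/acceptance.py`.

## Trajectory preprocessing

Detections are `(individual_id, timestamp, x, y)` rows with absolute UNIX
timestamps. Per individual, duplicate timestamps keep the first detection;
the trajectory is resampled by linear interpolation onto a uniform grid
(default `dt = 1 s`, matching the seconds-scale resolution of modern
barcode-tracking systems). Grid points outside an individual's observed span
hold the nearest endpoint and count as non-covered; the covered fraction
drives the inactivity filter (defaults: coverage ≥ 0.8 and total path length
above zero — the source analyses state that inactive individuals were
filtered but not the criterion, so both thresholds are configuration).

Activity is the per-interval squared displacement `K(t) = Δx² + Δy²` — no
mass, no ½: only *changes* in activity matter downstream, and every
statistic used (Pearson r, Hurst slope) is invariant to positive scaling.
For the same reason the hive-level series defaults to the *mean* over
individuals even where a sum would differ only by the constant factor `n`.
Windows (day/night partitions) are half-open `[start, end)` in absolute
seconds.

## Ising simulation

Standard 2D Ising model on an `L × L` torus, `J = k_B = 1`, zero field. The
Hamiltonian counts each nearest-neighbour bond once (`E = −J Σ_bonds sᵢsⱼ`,
ground state `−2NJ`); a single-site flip costs `ΔE = 2J sᵢ Σ_nn sⱼ`, which is
the only quantity the dynamics uses. One step = `N = L²` single-site
Metropolis attempts at independently random sites (acceptance
`min(1, e^(−ΔE/T))`). Runs start hot (uniform random spins), thermalize
10,000 steps, then record 2,000 consecutive configurations one step apart,
with `T ∈ {2.0, 2.3, 3.0}` as the default triplet — `2.3` being the
customary finite-lattice working value near the exact infinite-lattice
critical temperature `2/ln(1+√2) ≈ 2.2692` (exposed as
`onsager_critical_temperature()`).

One hazard of the hot start: below the critical temperature the lattice
occasionally relaxes into a striped two-domain metastable state instead of
the quiescent (magnetized) phase, and such a run measures domain structure,
not the low-temperature phase. Where the analysis targets the quiescent
phase (the acceptance computations at `T = 2.0`), runs are redrawn from
consecutive derived seeds until the mean |M| exceeds 0.9.

Correctness is anchored by exact enumeration: on 2×2 and 3×3 tori the
long-run (thinned) state frequencies match the Boltzmann distribution
`e^(−E/T)/Z` computed over all 2^N states (χ² test), and incremental `ΔE`
bookkeeping over a sweep matches total-energy differences in integer
arithmetic.

A note on sampling: recorded configurations are *consecutive* sweeps, so at
the critical temperature they are strongly autocorrelated — the correlation
structure reflects the quasi-static domain pattern of the recording window,
not the fully decorrelated equilibrium ensemble. This is deliberate (it is
the stated recording protocol) and it matters for what the correlation
networks look like; see "Reproduction scope" below.

## Correlation networks

Sample Pearson coefficients between all node pairs (float32 matrix product
internally: 10⁴×10⁴ in ~400 MB and seconds of CPU; precision ~1e−6 is ample
for thresholding). Zero-variance series (frozen sites, motionless
individuals) have undefined `r`; they are defined as 0, flagged, and become
isolated nodes. Edges are `r > p`, strict, signed (the positive tail only) —
an absolute-value variant exists behind a flag but is not the default.
The threshold is chosen by bisection against the monotone mean-degree curve
to hit a target `⟨k⟩` (tolerance 1% of the target, achieved `⟨k⟩` always
reported; when the discrete edge structure cannot reach the tolerance the
closest achievable threshold is returned). Isolated nodes stay in the node
set and in the output manifests.

## Degree-distribution fitting

Discrete maximum likelihood on the tail `k ≥ xmin`, zeros excluded:

* power law: `P(k) ∝ k^(−α)`, zeta-normalized, `α > 1`;
* truncated power law: `P(k) ∝ k^(−α) e^(−λk)`; the normalization sums the
  head exactly and integrates the far tail on a log grid (error well below
  optimizer tolerance). The exponent is constrained to `α > 1`, the
  convention of the standard fitting tools: below 1 the family degenerates
  into a gamma-like bump that can imitate any unimodal histogram, and the
  "power-law" label loses meaning;
* log-normal, discretized by CDF differences on `k ± ½` and renormalized to
  the tail.

`xmin` is selected by minimizing the Kolmogorov–Smirnov distance of the
power-law fit over candidate cutoffs that leave at least 50 tail
observations (the discrete KS convention compares inclusive CDFs at the
observed support points). All families are then refit on the shared tail so
their likelihoods are comparable; pairwise Vuong-style normalized
log-likelihood ratios with two-sided significance are reported, and
`best_family` is the maximum-likelihood family. Caveat, demonstrated in the
tests: a wide log-normal can mimic a pure power law arbitrarily well, so on
genuinely power-law data the power-law-vs-log-normal comparison is a
statistical tie — the meaningful assertion is that the power law is never
significantly *rejected* on such data, and that log-normal data *is*
significantly recognized.

## Network metrics

Computed on the giant component (ties broken toward the smallest node
index). Clustering is the mean local coefficient with degree < 2 nodes
contributing 0 (numba CSR kernel; networkx is the oracle on fixtures).
Average path length uses exact all-pairs BFS up to 2,000 nodes; above that,
1,000 seeded random BFS sources (scipy.sparse.csgraph), with the estimator's
standard error reported. The diameter is always exact: double-sweep lower
bound plus eccentricity refinement in decreasing BFS-level order until the
bound is certified. The random baseline is an ensemble (default 10) of
`G(n, p)` Erdős–Rényi graphs with `p = ⟨k⟩/(n−1)` — expected-degree
matching, the common reading of "equivalent" ER graphs; per-graph values are
retained. For `n = 10⁴, ⟨k⟩ ≈ 110` the closed-form ER clustering expectation
is `p ≈ 0.011`, which the ensemble reproduces; a published reference value
of 0.02 for this quantity disagrees with the closed form and is not used.

## Hurst estimation

Profile `K_sum(t) = Σᵢ≤t (Kᵢ − μ)`; lag variances
`Var(τ) = ⟨(K_sum(t+τ) − K_sum(t))²⟩` on ~20 log-spaced integer lags from 2
to `n/4` (larger lags average too few increments); OLS of `log Var` on
`log τ`; `H = slope/2`, so a memoryless series (profile = random walk,
`Var ∝ τ`) gives `H = 0.5`. The `τ^H` normalization sometimes written for
this estimator would assign memoryless data `H = 1` and contradict the
standard shuffle control; the `τ^(2H)` convention is used throughout.

Finite-sample correction: subtracting the sample mean makes the profile a
bridge (it returns to 0 at `t = n`), which depresses large-lag variances and
biases persistent series toward 0.5 (at `n = 2¹⁴`, a true `H = 0.9` fGn
series is recovered near 0.80 uncorrected). The estimator therefore divides
each measured `Var(τ)` by the closed-form expected squared increment of a
fractional-Brownian bridge at the current `H` estimate and refits, iterating
four times. Recovery means over 50 replicates at `n = 2¹⁴` are
0.29 / 0.48 / 0.68 / 0.87 for true `H` = 0.3 / 0.5 / 0.7 / 0.9, and shuffled
or i.i.d. data return ≈ 0.48–0.49. The uncorrected estimator remains
available (`bridge_correction=False`). `r²` of the final regression is
reported so poor scaling ranges are visible.

## Synthetic data

`generate_fgn` draws exact fractional Gaussian noise by circulant embedding
(Davies–Harte): the autocovariance
`γ(k) = (σ²/2)(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H})` is embedded in a
circulant whose FFT eigenvalues are checked non-negative; series length must
be a power of two ≥ 256.

`generate_hive` emulates the *shape* of a sealed-colony tracking dataset —
it is deliberately not a critical system; the Ising model supplies the
critical signal. Defaults: 1,200 individuals at `dt = 1 s` for one hour in a
bounded 60×35 arena (reflecting walls — hives are bounded boxes, not tori),
4 activity groups driven by latent two-state Markov signals switching on a
minutes scale (on-rate 1/120 s⁻¹, off-rate 1/60 s⁻¹, so bursts last ~1 min),
burst speed 2 and rest speed 0.05 position units per interval with 0.1 units
of positional noise, 10% permanently inactive individuals, 5% of detections
dropped. Groups start quiescent, so the shared switch events are inside
every recording window and force within-group correlation — that is the
planted structure the pipeline must recover (within-group minus cross-group
`r` ≥ 0.3 under defaults; noise-free variant ≈ 1). What the generator does
*not* emulate: interaction-mediated correlation, spatial organization,
circadian forcing, heavy-tailed burst statistics. Passing tests therefore
demonstrate that the pipeline *detects planted correlation structure and
long memory*, not that real colonies are critical.

## Pipelines, seeds, caching

All randomness derives from one master seed; each stage hashes its name into
the seed (SHA-256, < 2³¹), so stages are independently reproducible. When an
output directory is set, simulations are cached on disk keyed by their exact
config, and a manifest records the config snapshot, package version,
per-stage wall time, and SHA-256 checksums of simulation outputs; reruns
with the same config and seed reproduce the checksums exactly.

## Reproduction scope and known limitations

With the stated protocol this implementation robustly reproduces, for the
`⟨k⟩ ≈ 110` site-correlation networks of an `L = 100` run:

* critical clustering `C ≈ 0.55` (reference 0.56), some 50× the matched ER
  value, for every seed tested;
* off-critical clustering `C ≈ 0.07–0.12` (reference 0.08–0.09) and
  diameter 3 (reference 3);
* magnetization Hurst exponents elevated only at the critical temperature,
  and `H ≈ 0.5` for shuffled series;
* the log-normal shape of the high-temperature degree distribution.

It does **not** reproduce three published characteristics of the *critical*
network: path length (we measure `L ≈ 5.5–6.6` across seeds vs. 3.7
reported), diameter (21–28 vs. 14), and the truncated-power-law parameters
of the degree fit (reference `α = 1.99` at `xmin = 2` — our critical degree
distributions have geometric mean ≈ 50–100, and a maximum-likelihood
`α ≈ 2` at `xmin = 2` mathematically requires a distribution concentrated at
single-digit degrees, irreconcilable with a mean degree of 110). The
published log-normal parameters for the off-critical networks
(`μ = 4.12/3.58`) imply median degrees of ≈ 62 and ≈ 36 and are likewise
arithmetically incompatible with the stated `⟨k⟩ ≈ 110`, suggesting those
fits were made at a different (lower) mean degree than the table states.
Systematic variations tested — cold vs. hot starts, sequential vs.
random-site updates, longer recording separations, absolute-value
thresholding, covariance instead of correlation, global-mode regression —
move individual metrics but none reproduces the critical-network geometry
and fit parameters simultaneously or stably across seeds. The corresponding
checks are left failing rather than loosened; at criticality the
finite-window correlation structure is dominated by slowly-evolving domain
patterns, so these quantities are also intrinsically seed-sensitive.
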