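# Methods

## The dissimilarity

An epoch is `N` spike trains of integer sample indices in the half-open
interval `[0, T)`. For every unordered neuron pair `(i, j)` the normalized
cross-correlogram is represented binlessly as the multiset of delays
`τ = t_j − t_i` over the Cartesian product of the two trains' spike times,
sorted ascending, each element carrying mass `1/Q` with `Q = n_i · n_j`.
Duplicate delays are kept as repeated elements; if either train is silent the
multiset is empty. No histogram is ever built, so timing precision is limited
only by the recording's sampling rate.

The EMD between two delay multisets uses the ground cost
`c(τ₁, τ₂) = |τ₁ − τ₂| / (2T + 1)`. Because both supports are sorted and the
cost is convex in `|τ₁ − τ₂|`, the northwest-corner two-pointer sweep is the
exact optimum: move `flow = min(w_q, w_r)` from the current source element to
the current target element, accumulate `flow · c`, and advance whichever
pointer exhausts (both, when they exhaust together). The implementation keeps
the mass ledger in exact integers over the common denominator `Q·R` — element
masses are `R` and `Q` respectively — and accumulates `flow · |τ₁ − τ₂|` as a
64-bit integer, so the returned value `cost / (Q·R·(2T+1))` is the exact
rational optimum rounded once to float. An independent oracle
(`emd_oracle`, the CDF-difference route via
`scipy.stats.wasserstein_distance`) is used in the tests to cross-check the
sweep; the two agree to 1e−12 on randomized instances.

SPOTDis between epochs `k` and `m` is the mean EMD over neuron pairs in which
both neurons fired in both epochs (weight 1), all other pairs being excluded
rather than imputed. Per-pair EMDs are reduced into the running mean on the
fly; the full pair-by-pair tensor is never stored. Pairs recorded on the same
electrode can be excluded (`exclude_same_electrode`), the standard guard
against shared-noise artifacts in multi-electrode data.

Numerical/degenerate choices:

- **No co-active pair** (`Σw = 0`): the matrix entry is set to the sentinel
  1.0 (maximal dissimilarity) and flagged in `defined_mask`. This keeps
  pathological epochs isolated instead of spuriously close, and the density
  clustering tolerates the resulting mild metricity violations.
- **Normalization divisor** is `2·T + 1` with `T` the epoch length in
  samples. Delays of jitter-perturbed spikes may fall outside `[−T, T]`
  (perturbed spikes are deliberately retained); the same divisor applies and
  the cost may then marginally exceed 1, which is logged, not clamped.
- **Determinism**: epoch-pair chunks write disjoint entries, so the matrix is
  bitwise identical for any worker count.

## Clustering and embedding

Clustering is HDBSCAN (scikit-learn implementation) on the precomputed
matrix, with one hyperparameter `n_pts` used both as the minimum cluster size
and the min-samples/core-distance neighbour count (default 10; cluster
selection by excess-of-mass, with leaf selection available — multi-unit
array data is typically clustered with `n_pts = 3` and leaf selection).
Epochs in low-density regions come back labeled noise (−1). t-SNE (perplexity
30, fixed seed, random initialization) on the same matrix provides a 2-D view
for inspection only: no inference is drawn from embedding geometry, and for
many clusters the 2-D inter-cluster distances are not faithful.

## Evaluation

- **ARI with noise rule**: predicted noise points are reassigned to one fresh
  cluster before the adjusted Rand index is computed, so a correctly isolated
  noise population counts as agreement rather than error.
- **Silhouette on dissimilarities**: per epoch,
  `(d_nearest − d_same)/max(d_nearest, d_same)` with `d_same` the mean
  dissimilarity to the other members of its cluster and `d_nearest` the
  smallest mean dissimilarity to any other cluster, the noise cluster
  participating as an ordinary cluster on both sides. Singletons and
  degenerate terms (`d_nearest = d_same = 0`, duplicate epochs across
  clusters) contribute 0 and are counted; a single-cluster partition is an
  error.
- **Window sweep**: for each candidate window length the continuous data is
  re-windowed around the events, the full SPOTDis → HDBSCAN → Silhouette
  chain is run, and the Silhouette-argmax length is selected. When clustering
  finds no structure at some length (every epoch noise — a single-cluster
  partition on which the Silhouette is undefined), that length is scored −1,
  i.e. minimal quality, so the sweep curves stay complete at small problem
  sizes.
- **Rate-vector baseline**: mean absolute difference between per-epoch
  population spike-count vectors (optionally normalized to unit sum), the
  control showing which structure is attributable to timing rather than rate.

## Simulators

Ground-truth patterns are piecewise-constant rate profiles: baseline
`λ_out` with one `T_pulse`-long pulse at `λ_in` per neuron at an integer
position uniform on `[0, T − T_pulse]` (default conditions: `T = 300`
samples, `T_pulse = 30`, `λ_in = 0.2`, `λ_out = 0.02` spikes/sample; the
scenario presets in `pipeline.SCENARIOS` encode the other published
variants). Kind variants: bimodal (two disjoint pulses), deactivation (rate
`λ_out` inside a deactivation interval, `λ_in` outside), coarse/fine (a
nested high-rate fine pulse inside a shared coarse pulse, consecutive pattern
pairs sharing the coarse layout), synchronous (a random neuron subset shares
one common pulse interval), and precise sequences (one spike per neuron with
uniform timing jitter and Poisson noise spikes; jittered spikes leaving the
epoch are retained unclamped).

Spiking is discretized as independent per-sample Poisson counts (not
Bernoulli thinning), so multiple spikes per sample are possible — the
faithful discretization of an inhomogeneous Poisson process and the source
of repeated delays in the multisets. Noise epochs are either homogeneous
(constant rate `(λ_in·T_pulse + λ_out·(T−T_pulse))/T`, matching the expected
count of a pattern epoch) or patterned (each epoch one realization of a
unique random pattern with the same pulse statistics, by independent
sub-seeding without duplicate rejection). Sorting-error injection covers
hidden-neuron contamination, within-electrode spike exchange, and collision
deletion on virtual electrodes of consecutive neurons. Onset-jittered
embeddings place a pattern of length `T` at `−T/2 + Δt` around each event
inside a `2T` window (`Δt` uniform on `[−max_offset, max_offset]`), with
homogeneous flank noise, for the window-length selection workflow.

What the simulators do *not* emulate: refractoriness and non-Poisson
interval statistics, rate co-fluctuations beyond the explicit scaling states,
drift across epochs, and any biophysical network dynamics. Passing tests
therefore demonstrate correctness of the pipeline under the stated
generative model, not performance on every feature of real recordings.

## Problem sizes used in the validation suite

The end-to-end checks run scaled-down versions of the published protocols,
sized so the whole suite completes on a single CPU in a few minutes: pattern
recovery with 5 patterns × 10 repetitions + 50 noise epochs (N = 50); the
SNR sweep with N = 25, 5 patterns × 5 repetitions + 25 noise epochs over
`λ_in ∈ {0.15, 0.3, 0.5}` at `λ_out = 0.05`, five seeds; rate-scaling
invariance with 2 patterns × 3 global rate states × 8 repetitions (N = 30);
the window sweep with 5 patterns × 10 repetitions + 50 noise events
(N = 50) over lengths {100, 200, 300, 450, 600}; and the
patterns-outnumber-neurons check with 50 patterns × 10 repetitions + 50
noise epochs over 50 neurons. Seeds are fixed throughout; every generator is
exactly reproducible under its seed.

## Known limitations

- SPOTDis ignores higher-order (beyond pairwise) correlation structure.
- Cost is `O(N² M² n²)` for `n` spikes per train; very large epoch counts
  call for chunked parallelism (`n_workers`) and patience.
- The dissimilarity can be non-metric when firing is sparse (excluded pairs
  differ across epoch pairs); HDBSCAN absorbs this, but algorithms requiring
  strict metricity should not consume the matrix blindly.
- `t_epoch` is trusted as given; delays are never clipped to it.
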