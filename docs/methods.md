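# Methods

## The generative model

Let `z = (z_1 … z_N)` be the observed, strictly increasing firing times of
all threshold-crossing events on an extracellular channel, `X = (x_1 … x_N)`
the corresponding D-dimensional waveform parameterizations (raw samples or
PCA features), and `c` the hidden cluster labels in `[0, K)`. The joint
likelihood factorizes as `P(X | c) · P(z | c) · P(c)` under two assumptions:
waveforms and times are conditionally independent given the labels, and
waveforms are i.i.d. given their cluster.

- **Waveforms**: one multivariate Gaussian per cluster, `θ_j = {μ_j, Σ_j}`.
- **Firing times**: `z` is treated as the aggregation (superposition) of K
  independent renewal point processes. The ISI density of cluster `j` is
  lognormal, `f_j(τ) = LogNorm(τ; μ_isi, σ²_isi)` — supported on `(0, ∞)`
  and a good empirical fit to ISI data with a hard refractory floor. The
  first firing of a cluster after an empty history window follows a Poisson
  count model with rate `β_j`, evaluated at one event in a window of length
  `t`: `w_j(t) = β_j t · e^{−β_j t}`.
- **Labels**: `P(c) = Π_i P(c_i)`, with no transition structure — all
  temporal dependence lives in the point processes, not in a Markov chain
  over labels.

A full-train likelihood for a single cluster's times `t_k` is
`w_k(t_{k,1}) Π_i f_k(t_{k,i} − t_{k,i−1}) · S_k(T − t_{k,N_k})`, where the
survival factor `S_k` accounts for the censored final interval. The package
exposes this as `ensemble_loglik` for diagnostics only; the decoding
objective below drops the survival term and evaluates `w_j` at the window
length rather than the elapsed time. The two conventions are deliberately
kept side by side (`sequence_loglik` vs `ensemble_loglik`) and their exact
difference is pinned by a test.

## Decoding

The maximizer of the joint likelihood over labels is found by L-best beam
search over the event lattice. Processing events in time order, a path
(partial labeling) carries only the (time, label) pairs inside the history
window `(z_n − τ_win, z_n]` — half-open, so a spike exactly `τ_win` old has
just left. The per-event score of extending a path with label `j` is

```
max(log N(x_n; θ_j), −745) + max(log p(z_n | c_n=j, ζ_j), −745)
                           + max(log P(c_n=j), −745)
```

with the piecewise temporal term: lognormal ISI density at `z_n − ζ_j` if
cluster `j` fired inside the window (`ζ_j` = its most recent in-window
time), else `w_j(τ_win)`. Flooring each term at −745 (the smallest double
whose exponential is nonzero) prevents a single impossible event from
annihilating every path in the beam; the number of floored terms is
reported on the result.

Two exactness mechanisms:

- **Merging.** A path's future scores depend only on its window content, so
  paths with identical window label-content are merged keeping the higher
  cumulative likelihood. This is Viterbi-style dynamic programming on a
  growing state space and is lossless with respect to the windowed
  objective; it is what lets `decode` with `L ≥ K^N` provably reproduce the
  exhaustive argmax (tested on 200 random instances against
  `brute_force_decode`).
- **Deterministic tie-breaking.** Candidates are ordered by likelihood
  descending, then label sequence lexicographically ascending. Exact
  likelihood ties are rare (measure zero for generic inputs), so full
  sequences are reconstructed only inside exactly-equal groups; degenerate
  groups larger than 64 (possible only when everything hit the floor) fall
  back to stable candidate order, still deterministic.

Beam width `L` defaults to 10000 and trades accuracy for time and memory;
the best final log-likelihood is non-decreasing in `L`.

## Parameter estimation and the window rule

Given labels, per-cluster maximum-likelihood estimates are: waveform sample
mean and covariance with a ridge `ε = 10⁻⁶·trace(Σ)/D` on the diagonal;
lognormal parameters as the mean and (unbiased) variance of the log of
within-cluster ISIs, with a variance floor of 10⁻⁴ to avoid delta-like
densities; first-firing rate `β_j = N_j / T` (the Poisson MLE over the
recording of length `T`). Clusters with fewer than 2 members or 2 ISIs keep
the previous iteration's parameters (pooled all-data estimates at
initialization), so K never changes during iteration.

The history window is set from the fitted ISI densities:
`τ = max_j exp(μ_isi,j + σ_isi,j · Φ⁻¹(coverage))` with coverage 0.99 — the
99% lognormal quantile of the widest cluster — so the first-firing branch
fires rarely. τ is estimated once from the initial waveform-only clustering
and held fixed (re-estimation each iteration is available behind a flag).

**Units.** All times are seconds internally. Lognormal location parameters
are unit-dependent (`μ_ms = μ_s + ln 1000`; the variance is unit-free), and
the reference ISI parameter table is quoted in log-milliseconds; the
conversion helpers `logms_to_logs` / `logs_to_logms` handle the boundary.

## The iterative procedure

1. Fit a full-covariance EM-GMM to the waveform features (5 k-means++
   restarts, tol 10⁻⁶, ≤500 iterations) and take MAP labels.
2. Estimate all parameters from that clustering; derive τ.
3. Alternate: beam-decode → re-estimate, until the labels reach a fixed
   point or `max_iter` (default 20).

Convergence is declared on unchanged labels, not on likelihood: the
procedure is deliberately greedy and is *not* guaranteed monotone in the
joint likelihood, so no monotonicity stop is imposed. Everything downstream
of the seed is deterministic, so identical seeds give bit-identical
results.

**Cluster priors.** The label prior `P(c_i = j)` is fixed at `1/K` by
default. Estimating empirical proportions each iteration (available via
`uniform_prior=False`) couples cluster size into every event's score and
creates a rich-get-richer feedback: once a cluster shrinks, its lower prior
(and sparser, longer ISIs) make it still less attractive, and the iteration
can drain it entirely. With uniform priors the iteration is stable and the
improvement over the waveform-only baseline is consistent; this is the
package's design choice where the model itself does not dictate the prior's
form.

## The synthetic-data generator

`simulate` emulates the standard semiartificial benchmark construction:

- **Firing times**: K independent lognormal-ISI renewal trains. Defaults
  are the three reference parameter pairs (log-ms)
  `(1.5814, 2.4203), (2.1610, 1.9380), (1.9651, 2.7068)`, a 3 ms refractory
  floor, and a 24 s horizon, which yields ≈2.4–2.5k aggregate events. The
  refractory is enforced by redraw (i.e. sampling the truncated lognormal):
  the truncated-lognormal analytic means (≈25.4, 29.0, 38.8 ms by
  quadrature) bracket the published single-realization sample means within
  Monte-Carlo error, whereas shifting (3 + τ) does not. Each train starts
  with an ISI draw from t = 0 — no separate first-firing distribution is
  simulated. Times are continuous doubles; no sampling-grid quantization
  unless a trace is rendered.
- **Waveforms**: difference-of-Gaussians biphasic templates with unit peak.
  The "easy" family is three fixed well-separated shapes (pairwise cosine
  < 0.7); the "difficult" family is a fixed trio of near-identical shapes
  (pairwise cosine 0.98–0.99), emulating a benchmark's characteristic
  templates — across seeds only firing times and noise vary, not shapes.
  For K > 3 extra shapes are drawn randomly under the same constraints.
- **Noise**: i.i.d. Gaussian on the waveform matrix at a target SNR,
  defined as `10·log10(mean(X²)/σ²_noise)` over the clean matrix entries,
  applied in waveform space before PCA. (Power, not peak-amplitude, SNR —
  the simpler convention; note this makes nominal dB levels not directly
  comparable to benchmarks using other definitions.)
- Optionally, `render_trace` places templates on a flat 20 kHz baseline
  with Gaussian background noise for end-to-end detection tests.

What the generator does *not* emulate: realistic correlated background
noise (real recordings superimpose distant units), overlapping-spike
waveform summation in the event stream, electrode drift, bursting or
rate nonstationarity. Passing tests on this generator therefore
demonstrates correctness of the inference machinery and behavior under the
modeled difficulty axes (shape similarity, noise level), not performance on
real tissue.

## Detection

Spikes are detected on the (optionally high-passed: zero-phase Butterworth,
order 4, 300 Hz cutoff — both configurable, results should not be sensitive
to this choice) trace as contiguous excursions of `|signal|` above
`5σ`, where `σ = median(|x|)/0.6745` is the robust noise scale (immune to
the spikes themselves). The event time is the excursion's peak sample;
excursions closer than 1 ms are merged keeping the larger peak; waveforms
are `round(window_ms·rate/1000)` samples (forced odd: 4 ms at 20 kHz → 81)
centered on the peak, and events whose window would overrun the trace are
dropped rather than zero-padded. Intracellular spikes are peaks of the
first backward difference above the same robust-threshold rule (the
threshold choice for the differenced signal is an extrapolation; it is
configurable), merged within 1 ms; extracellular events within 1 ms
(inclusive) of an intracellular spike inherit the partial ground-truth
label.

## Evaluation

- `best_match_error`: 1 − accuracy under the optimal one-to-one assignment
  between true and putative clusters (exhaustive permutations for K ≤ 6,
  Hungarian algorithm otherwise; identical where both apply).
- `partial_error`: when only one neuron's firings are known, the putative
  cluster representing it is the one minimizing FP + FN (the assignment
  most favorable to any method equally; max-overlap is available behind a
  flag); the rate divides FP + FN by the total event count. Ties go to the
  lowest cluster index.

## Problem sizes used in the test suite

Simulator fidelity is checked over 200 seeded 24 s realizations plus a 10⁶
draw comparison against truncated-lognormal quadrature; decoder exactness
over 200 random instances with N ≤ 6, K ≤ 3 against exhaustive search; the
method-vs-baseline comparison runs 20 seeds of the difficult family at
8 dB SNR, ~1000 events each, with L = 1000 and 5 iterations — sizes chosen
to make the statistical comparisons sharp while keeping a full run of the
suite inside a few minutes on one core.

## Known limitations

- K is fixed by the user; no automatic model selection (AIC/BIC over the
  GMM initialization would be a simple extension) and no dynamic cluster
  pruning.
- Overlapping spikes are neither simulated in waveform space nor resolved;
  coincident firings closer than the detector's merge window collapse.
- The method inherits its initialization's failure mode: when the
  waveform-only GMM is degenerate (extreme noise and near-identical
  shapes), iterating from it does not recover and can worsen the labeling.
- The beam decoder is approximate for L < K^N; only the L = K^N limit is
  exact.
- Stationary model: firing statistics and waveform shapes are assumed
  constant over the recording.
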