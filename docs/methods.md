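# Methods

This note records the models implemented in `modular_esn`, the parameter
choices that matter, and the places where the design was genuinely open and a
decision had to be made.

## Graph model

Reservoir topologies come from a planted-partition, degree-regular variant of
the configuration model. A `GraphSpec` fixes `N` nodes in `n_c` equal
communities (contiguous index blocks), an in-degree `k`, and a mixing
parameter μ ∈ [0, 0.5]. Each node draws `n_int` presynaptic sources from its
own community (excluding itself) and `k − n_int` from the rest of the network,
without replacement, where `n_int` is the unbiased stochastic rounding of
`(1 − μ)k`. Consequences:

- in-degree is exactly `k` for every node and every μ; the edge count `N·k`
  is conserved, so μ sweeps are controlled for density;
- no self-loops or duplicate edges can occur, and no rewiring/retry loop is
  needed;
- the realized bridge fraction is an unbiased estimate of μ with standard
  deviation ≈ 0.004 at N = 500, k = 6 (tests assert ±0.02);
- at μ = 0 the graph decomposes into ≥ `n_c` weakly connected components —
  disconnection at vanishing μ is a property the experiments rely on, not a
  defect.

Edges are *directed* and out-degree is left binomial. The generator does not
implement power-law degree or community-size distributions: the experiments
all use constant degree and equal community sizes, so the full LFR machinery
would add unused complexity. Edge direction convention: `W[i, j]` is the
weight from presynaptic `j` to postsynaptic `i`, so `W @ x` accumulates each
neuron's inputs.

Weights are i.i.d. uniform on `[w_low, w_high]` times a global scale `W_s`,
drawn from a seed stream separate from the topology stream so either can be
held fixed.

## Neuron model and readout

The activation is the general sigmoid `f(z) = a/(b + e^{−g(z−c)}) − d` with
the threshold preset `(1, 1, 1, 10, 0)`: a step-like response centered at
z = 1. Because a neuron needs several simultaneously active presynaptic
partners to cross the threshold, activity spreads as a complex contagion and
network topology matters far more than in the linear/tanh regimes (both
available as presets; the linear control normalizes the recurrent matrix to
spectral radius 0.95).

Readouts are linear maps on the concatenated `[x(t) : u(t)]` vector trained by
the exact pseudoinverse (numpy `lstsq`, `rcond=None`) with no regularization;
for rank-deficient designs this returns the minimum-norm solution, which is
exactly what lets collapsed attractor states show up as recall failures
rather than crashes. Task outputs pass through the step rule
`g(z) = 1 if z > 0.5 else 0`; the boundary maps to 0 per the piecewise
definition. The concatenation order (state, then input) is fixed for
reproducibility; any fixed order is equivalent.

## Spreading experiments

A constant unit drive on one channel is injected into a fraction `r_sig` of
neurons and the network is iterated to equilibrium (max one-step change
< 1e−9, cap 1,000 steps; non-convergence is flagged, not raised — the cap
exists for constructed oscillators and for slowly ratcheting cascades).
Outcomes are the per-community mean activations and the total fractional
activation `(1/N) Σ x_i(t_e)`, averaged over independent reservoir
realizations with the standard error of the mean.

Parameter choices here were genuinely open, and two matter:

- **Input weights** follow the task projection — uniform[−0.2, 1] with gain
  1.0 — rather than a constant. With constant unit input weights every driven
  neuron is parked at or above the sigmoid midpoint, the driven baseline alone
  is `r_sig/2`, and the interesting subthreshold regime is compressed into
  `r_sig` of a few percent. With the task draw only ~1/6 of driven neurons
  land near threshold, so the contagion must be consolidated by the topology
  and the transition sits at `r_sig ≈ 0.2–0.3`, where the phase diagrams
  resolve it.
- **Recurrent weights** default to excitatory uniform[0.2, 0.65] (mean
  in-strength 6 × 0.425 ≈ 2.6, comparable to the task reservoirs' ≈ 2.7). A
  narrow positive distribution keeps the neuron-level contagion threshold
  sharp; with the heavy-tailed mixed-sign task distribution, sporadic strong
  excitatory chains let even unstructured (μ = 0.5) graphs ignite under
  sustained drive, which blurs the contrast between the optimal band and the
  random end. The optimum itself appears under both distributions.

With these defaults the two-community layout reproduces the canonical
picture: at μ = 0 a strongly driven seed community saturates while its
neighbor stays at the rest state f(0) ≈ 4.5e−5; for μ ∈ [0.2, 0.3] both
communities ignite; past μ ≈ 0.35 activity collapses. The 50-community layout
with scattered input shows the same interior optimum in total activation.

## Memory-capacity task

One Bernoulli(0.5) channel drives the reservoir (N = 500, 50 × 10, in-degree
6, weights uniform[−0.2, 1] × 1.13, inputs uniform[−0.2, 1] × 1.0 into
`r_sig·N` neurons). After a 500-step washout, lag readouts for k = 1..40 are
trained on 1,500 steps in a single multi-target least-squares solve
(mathematically identical to independent fits, one SVD instead of forty), and
scored on an independently drawn stream with its own washout. The lag score is
the squared Pearson correlation between `u(t − k)` and the *graded* readout
output; the step nonlinearity is not applied when scoring, since the
covariance form presumes a graded output. Zero-variance series score 0 by
convention. The sum truncates at lag 40: the r² profile is numerically dead
well before that for these reservoir sizes, and the truncation is a config
knob.

Mean MC over reservoirs rises steeply from the disconnected regime to a
plateau at μ ≈ 0.2–0.3 and declines toward μ = 0.5. Two features of the
distribution are worth knowing when interpreting sweeps: it is left-skewed —
a minority of reservoirs lock into attractors during the washout and score
near zero, more often at low μ — and some reservoirs are multistable enough
that their score depends on the particular stream draw. Cell means therefore
carry standard errors of ~0.3 even at 64 samples, and the argmax over a
0.05-step μ grid can move within the 0.2–0.3 plateau from seed to seed.

## Recall task and attractor census

Each episode presents a one-hot 4×5 sequence for 5 steps (channels 1–4),
holds the reservoir through ΔT all-zero distractor steps, raises a cue
channel for one step, and evaluates all 20 step-readout bits once at the
following step; a recall is perfect only if all 20 bits match. The reservoir
is reset to the zero state per episode, so a whole sequence set is stepped as
one batched state matrix. Training uses one design column per episode (the
decision-step state; the decision-step input is all-zero) against the
flattened sequences. The distractor is silent by choice: zero drive isolates
intrinsic attractor storage from input-driven rehearsal.

Reservoir defaults: N = 1,000, communities of 10, weights uniform[−0.1, 1.0],
five input channels each wired to 30% of the neurons with constant weight 1.0
and gain 2.0, ΔT = 80, 200 sequences. The in-degree default is 4 — the task's
nominal connectivity of 7 read as total (in + out) degree, i.e. mean
in-degree 3.5, rounded up. This is the one parameter where the implementation
had to depart from the nominal value: sequence storage requires
community-level bistability without global saturation. The ON state of a
community self-sustains when `(1 − μ)·k·w̄ > 1` (≈ 1.6 at k = 4, w̄ = 0.45);
at k = 7 the mean in-strength is ≈ 3.15 and every episode ignites the entire
reservoir into a single global attractor (census of 1, zero recall at every
μ), while at k = 3 the ON state is marginal and attractors dissolve during
the distractor. With k = 4 the task exhibits its full phenomenology: recall
spikes near μ ≈ 0.05–0.1, collapses for random wiring, and degrades beyond
roughly 200–400 stored sequences.

The census runs every episode to the moment the cue arrives (the state after
the last distractor step) and groups the collected states by single linkage:
two states share an attractor if connected by a chain of pairwise Euclidean
distances below ε = 0.1. Single linkage is the transitive completion of the
pairwise rule — without it the pairwise relation is not an equivalence. The
count is insensitive to ε over 0.01–0.5 (a few percent) because converged
states are either nearly coincident or far apart; limit cycles (common for
0 < μ < 0.2) are compared at the common cue-time phase, so a cycle visited at
different phases by different sequences counts as distinct usable states,
which is what the readout sees. The attractor count upper-bounds recall:
`fraction_perfect ≤ n_attractors / n_sequences` whenever the census is
smaller than the sequence set.

## Seeding and orchestration

All randomness flows through `derive_seed(master, *labels)`, a SHA-256-based
map onto 31-bit seeds. Sweep cells label their seeds with (experiment, cell
indices, sample index), so results are independent of evaluation order and
worker count, and any single cell can be reproduced in isolation. The
experiment runner validates config dicts before computing, writes long-format
CSV plus a JSON metadata sidecar (config hash, package version, timestamps),
and backs the `modular-esn` CLI.

## Problem sizes

The shipped defaults are the full experiment sizes (N = 500 / 1,000
reservoirs, 500 + 1,500 + 1,500 step streams, ΔT = 80). Sweep sample counts
are the package's choices for each context: the acceptance script uses 64
reservoirs per cell for the 1-D memory-capacity sweep, 24 per cell for the
2-D sweep and 12 per cell for recall; the test suite uses 8–16 samples per
cell with fixed seeds. Unit tests that exercise contracts rather than
phenomena run smaller reservoirs (N = 60–300).

## Known limitations

- The generator covers only the degree-regular, equal-community-size regime;
  no overlapping communities, weighted LFR, or community detection.
- Synthetic inputs are exactly the task distributions (Bernoulli streams,
  one-hot sequences, constant drives); nothing here emulates temporal
  correlations, noise, or continuous-valued signals of real sensory data, so
  passing tests speak to the structure–memory mechanism, not to performance
  on natural time series.
- The spreading experiments' weight distribution is a package choice (the
  relevant constants are not pinned down by the tasks); the location of the
  subthreshold band in `r_sig` moves with the weight scale, though the
  interior optimum itself is robust.
- Mean memory capacity has a genuine plateau over μ ≈ 0.2–0.3 at these sizes;
  argmax locations read from single sweeps inherit that ambiguity.
- The linear-control contrast is qualitative (random ≥ modular at spectral
  radius 0.95); no spectral-radius-matched replication of the threshold
  sweeps is attempted.
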