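# Methods

## The cells

A gated recurrent unit (GRU) mixes its previous state into every neuron
through full recurrent kernels.  The bistable recurrent cell (BRC)
implemented here replaces that network-level memory with *cellular* memory:
each neuron's state depends, among hidden states, only on its own past
value, and a feedback gate with range (0, 2) lets the neuron become bistable.
The updates are

    BRC:   a_t = 1 + tanh(U_a x_t + w_a ⊙ h_{t-1})
           c_t = σ(U_c x_t + w_c ⊙ h_{t-1})
           h_t = c_t ⊙ h_{t-1} + (1 - c_t) ⊙ tanh(U x_t + a_t ⊙ h_{t-1})

    nBRC:  same state update; gates use full kernels W_a h_{t-1}, W_c h_{t-1}

    GRU:   z_t = σ(U_z x_t + W_z h_{t-1}),  r_t = σ(U_r x_t + W_r h_{t-1})
           h_t = z_t ⊙ h_{t-1} + (1 - z_t) ⊙ tanh(U_h x_t + r_t ⊙ W_h h_{t-1})

`a` plays the role of the feedback gain α in the neuronal IV-curve picture
I = V − α·tanh(V): for a ≤ 1 the neuron is monostable, for a > 1 it holds one
of two signed stable states — input history decides which, giving
never-fading memory.  `c` acts like a membrane capacitance: it sets how fast
the state moves, and a transient dip in c makes the neuron maximally
sensitive to the current input.  The nBRC's gates are *recurrently
neuromodulated*: computed from the whole layer's previous state, adding
network memory on top of the cellular memory while the state path itself
stays elementwise.

Design choices where the update rules leave room:

* **Biases.** The printed update rules carry no bias terms.  We include
  additive biases initialised to zero — at initialisation the computation is
  exactly the bias-free rule — because they are standard practice and cost
  nothing.  `init_weights(..., bias=False)` freezes them at zero for literal
  fidelity; nothing in our results depends on this switch.
* **Initialisation** (not fixed by the cell definitions): variance-scaled
  normal (std 1/√input_dim) for input kernels, orthogonal matrices for all
  full recurrent kernels (nBRC gates, GRU), uniform(−0.1, 0.1) for the BRC's
  per-neuron recurrent gains.  Conventional, seedable, and documented here so
  runs are reproducible.
* **Initial state** is the zero vector and is not trained.
* **No pre-activation clipping**: tanh and σ saturate on their own, which is
  exactly the numerical-stability argument behind bounding a inside (0, 2).

## Autodiff

No deep-learning framework is used: forward unrolling caches each step's
gates, candidate and state, and `bptt.backward_layer` replays them in
reverse, accumulating exact analytic gradients (backpropagation through
time), layer by layer down the stack.  Correctness is property-tested
against central finite differences (relative error < 1e-4 on 2-neuron,
5-step, 2-layer stacks for all three cells).  The optimiser is plain Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e-8).  Training runs in float32 for speed;
the dynamical-systems analyses run in float64.

## Scalar-map analysis

With frozen gates a single neuron is the one-dimensional map
F(h) = c·h + (1−c)·tanh(u + a·h).  `find_fixed_points` scans
G(h) = h − F(h) for sign changes on [−1−|u|, 1+|u|] (every fixed point lies
inside: F is a convex combination of h and a tanh value) and refines each
bracket with Brent's method to |G| < 1e-12.  Stability follows the
linearised gain: F′(h*) ∈ [0, 1) stable, > 1 unstable, within 1e-9 of 1
labelled "singular" (the measure-zero pitchfork case; ties break toward
reporting it).  The default scan grid (2001 points) resolves the symmetric
branch pair down to a gain excess of order 1e-6 above critical.

`bifurcation_diagram` sweeps a at fixed c, counts stable fixed points, and
refines the first count transition by bisection in a — an independent,
purely numerical detection of the critical gain, which lands at a = 1 for
every c ∈ [0, 1), matching the linearised origin gain c + (1−c)a crossing 1.
`pitchfork_conditions` evaluates the six supercritical-pitchfork conditions
for G at (h, a) = (0, 1) in closed form (the four zero-conditions; the cubic
term 2(1−c) > 0; the mixed term c − 1 < 0); the tests cross-check them
against high-order finite differences of G, keeping the analytic path
authoritative.

## Benchmarks

The generators are pure functions of (parameters, seed); all randomness
comes from `numpy.random.default_rng(seed)`.

* **copy-first-input**: steps are indexed 0..T (length T+1), i.i.d. N(0, 1);
  the target is x₀, read after x_T.  The length convention is the only one
  in which "output after receiving x_T" is well defined alongside x₀..x_T
  indexing.  The zero predictor's expected MSE is exactly 1 (the variance),
  which is the chance level all results are compared against.
* **denoising**: 2 channels, same length convention.  Five relevant steps
  t₁ < … < t₅ are drawn *without replacement* from {0, .., T−N−1} — the
  strict bound keeps every relevant input out of the forgetting window — and
  sorted, so targets pair with the five output steps in temporal order.
  Channel 0 is +1 at relevant steps, 0 at step T−4 (the "output starts now"
  cue; the marker-0 assignment takes precedence, and a +1/0 collision cannot
  occur since t_i < T−N ≤ T−5), −1 otherwise.  Channel 1 is N(0, 1) data,
  zeroed on steps T−4..T.  The loss is the mean over the five squared
  prediction errors.
* **sequential-MNIST transforms**: a fixed, seed-determined permutation of
  the 784 pixels shared by the whole dataset; line-by-line feeding (28-dim
  inputs); N all-zero "black" lines appended as a forgetting period
  (28 + N lines; 100 and 500 for N = 72 and 472); for the variable-length
  variant N ~ U{0..X} per sample plus a final marker line of value 2.0 —
  any value strictly above 1.0 (a white pixel) works, 2.0 is our documented
  choice.  The image benchmarks need an external MNIST download (IDX files,
  reader included) and are covered by transform property tests only.

What the synthetic benchmarks do *not* emulate: real-data correlations
(MNIST stroke structure), input noise that is informative, or class
imbalance.  Passing them shows a cell can store and retrieve information
across a forgetting period under i.i.d. Gaussian distractors — the
long-memory property — not that it is a better general-purpose sequence
model.

## Training protocol

Reference protocol: two layers of 128 neurons, Adam at learning rate 1e-3,
mini-batch 100, 50 epochs, 40 000 training / 50 000 test samples, metrics
averaged over three seeds.  The readout is one affine layer on the top
recurrent state at the prediction step(s) only — the minimal head consistent
with "predict after the last element(s)" — with softmax cross-entropy for
classification.  No gradient clipping, learning-rate schedule or weight
decay (a clipping flag exists, default off).  Mini-batch order reshuffles
every epoch from a generator derived from the run seed, so (config, seed)
fully determines a run; divergence (non-finite loss) raises immediately.

### Desk-scale protocols

The package's own benchmark runs (tests and the acceptance script) use
scaled-down versions of the reference protocol chosen once for a
single-CPU NumPy backend, preserving the quantities that matter — the
horizon T, the T−N ratio, batch size 100, learning rate 1e-3:

* copy T = 50: 2×128 networks, 10 000 training samples, the reference
  50 000-sample test set (large enough that the test set's own chance level
  sits at 1.00 ± 0.01), 10 epochs, 2 seeds (acceptance script); the test
  suite uses the same shape at 8 epochs, 3 000 test samples and one seed
  per cell.
* denoising: T = 60, N = 30 (same T−N ratio as the reference T = 400,
  N = 200), 2×64 network, 8 000 train / 1 000 test, 40 epochs.
* the gate-dynamics analysis records that trained scaled-down denoising
  nBRC rather than a 4×100 network.

On the copy task the qualitative picture survives scaling: the nBRC falls
well below chance (MSE ≈ 0.02–0.04) while the GRU stays pinned at chance
(≈ 0.96).  On the denoising task only part of it does: the scaled nBRC
learns (MSE ≈ 0.23 at desk scale, still falling), but at these short
horizons a GRU can learn the task too — the cell *separation* on denoising
is a genuinely long-horizon effect that requires the full T = 400, N = 200
protocol, consistent with the reference results where the GRU is excellent
at N = 5 and at chance only for N = 200.  The desk-scale denoising check
therefore asserts the generator's structural invariants and that the nBRC
learns, not a GRU gap.  Absolute errors at desk scale are higher than the
reference protocol's (fewer optimisation steps), which is why scaled-down
runs are compared as bounds/gaps rather than point values.

## Introspection

`record_gates` re-runs one sequence with gate recording on;
`summarize_gates` reduces the trace to the per-layer bistable fraction
(strictly a > 1: at a = 1 the map sits at its pitchfork and is still
monostable) and mean update gate.  `detect_relevant_steps` scores each step
by how far the layer-mean c falls below the average of its two neighbours (a
local V-shape), sums the score over layers, and returns the top-k steps —
a rank-based recovery of the relevant inputs from the summary alone, with no
smoothing window.

## Known limitations

* CPU NumPy only; large-scale runs (full 50-epoch protocols, the MNIST
  variants) are possible but slow.
* Gate recording stores (layers × steps × neurons) arrays per sample; it is
  off during training and meant for single-sequence analysis.
* The fixed-point scanner targets the scalar map; coupled multi-neuron
  fixed-point structure is out of scope.
* `iv_curve` and the bistability analysis treat the continuous-time neuron
  picture only as motivation; no ODE model is implemented.
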