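# Methods

This note describes the model and procedures implemented in `skelhmm`, the
rationale for every tunable parameter, and the known limitations.

## 1. Depth segmentation

A depth image is a 2-D array of ranges in millimetres; a sentinel value
(default `0.0`) marks pixels with no measurement. The human subject is
assumed to be the object closest to the camera, in front of a more distant
background. Segmentation thresholds at a fixed fraction of the maximum
*measured* depth:

```
lambda = K * d_max,      foreground = { pixels with d < lambda }
```

The comparison is strict and sentinel pixels are always background. An
image with no measurable depth at all is an error rather than an empty
mask.

**K = 0.75 (default).** The subject typically occupies the nearer quarter
to half of the depth range when the background is a wall or room boundary;
0.75 puts the cut comfortably between subject and background for indoor
ranges (subject ~2–3 m, background ~3.5 m and beyond) while still tolerating
a moderately close background.

## 2. Amplitude-limiting filter

Joint streams from consumer skeleton trackers carry two artefact types with
distinct signatures: micro-jitter (a millimetre-scale tremor around the true
position) and tracking spikes (a joint thrown hundreds of millimetres off
for a frame or two). The filter is causal and per joint. With
`delta = ||x_t − x̂_{t−1}||`, the Euclidean displacement of the new sample
from the previous *filtered* position:

* `delta < jitter_radius` — hold `x̂_{t−1}` (tremor suppressed);
* `delta > deviation_radius` — clamp to
  `x̂_{t−1} + deviation_radius · (x_t − x̂_{t−1}) / delta` (spike rejected,
  direction preserved);
* otherwise — pass `x_t` through unchanged.

The first frame passes as-is. Untracked samples hold the last tracked
filtered position; per-joint state is initialized from the first tracked
sample so dropouts at the start of a sequence still yield a credible
anchor. A joint with no tracked sample anywhere in the sequence is an
error. Filter state never crosses sequence boundaries.

**jitter_radius = 5 mm.** Static-pose jitter of consumer depth trackers is
a few millimetres RMS; 5 mm suppresses it without eating genuine slow
motion (a 5 mm/frame dead-band at 30 Hz still admits any movement faster
than 0.15 m/s).

**deviation_radius = 50 mm.** 50 mm per frame at 30 Hz corresponds to
1.5 m/s — faster than almost all deliberate joint motion in daily actions —
so any larger jump is overwhelmingly a tracking failure. Clamping (rather
than discarding) keeps the filter robust when a large displacement is real:
the filtered trajectory follows at 1.5 m/s and re-converges within a few
frames.

## 3. Keyframe extraction

Compression treats the number of retained frames and the reconstruction
error as the two optimization goals. Given a per-joint, per-frame error
budget `max_error`, the extractor finds the **smallest** keyframe set
(first and last frame always kept) such that linearly interpolating every
dropped frame between its surviving neighbours deviates at most
`max_error`. This is solved exactly as a shortest path over feasible spans:
frame `b` is reachable from keyframe `a` in one step when the span `a..b`
reconstructs within budget; dynamic programming minimizes the number of
steps. Ties between equally small sets resolve to the earliest predecessor,
making the output deterministic.

A greedy alternative — repeatedly deleting the frame whose removal keeps
the local interpolation error within budget — was evaluated and rejected:
it retains noticeably more frames on the same budget because early
deletions can block later, better ones. Since minimizing keyframes is the
stated objective, the exact optimum is both cleaner and strictly better,
at the same asymptotic cost on smooth motion.

**Span-scan grace window = 5.** Interpolation error grows with span length
on smooth motion, so once a span is infeasible, longer spans almost never
become feasible again; noise can, however, produce an isolated dip. The
scan therefore abandons a span only after 5 *consecutive* infeasible
extensions. This keeps the search near-linear in the typical span length
instead of scanning all O(T²) spans, and on all sequences exercised in the
test suite it returns the same result as the exhaustive scan.

`reconstruct` rebuilds the full-length sequence from the keyframes by
per-coordinate linear interpolation, and `reconstruction_error` verifies
the bound; the compression study in `skelhmm.benchmark` re-checks the bound
on every sequence and fails loudly if it is violated.

**Compression ratio** = total frames / retained frames.

## 4. Pose features and vector quantization

A discrete HMM consumes a finite alphabet, so each frame is summarized and
quantized:

1. translate the skeleton so `spine_base` is the origin (camera-position
   invariance);
2. scale by the torso length `||spine_shoulder − spine_base||`
   (subject-size invariance); a zero-length torso is an error;
3. concatenate the coordinates of 12 "vital" joints — head, hands, elbows,
   shoulders, knees, feet, and spine_base — giving a 36-dim vector.
   Optionally, first differences of the features can be appended
   (velocity), doubling the dimension; the default pipeline does not use
   them.

The codebook is k-means over the pooled training frames (scikit-learn,
`n_init=10`, fixed `random_state`). Centroids are sorted lexicographically
after fitting so the codebook is independent of k-means' internal label
order. Encoding assigns each frame the nearest centroid in Euclidean
distance; exact near-ties are re-checked in unexpanded form and resolve to
the lowest symbol index. Symbols are 1-based (V₁…V_M).

**M = 16 (default).** The five default actions visit on the order of 3–6
distinguishable poses each; 16 symbols give each class a few "own" symbols
plus shared ones, which is enough for near-perfect separation while keeping
the emission matrices well-estimated from tens of sequences. Larger M
raises estimation variance with no observed accuracy gain on the
benchmark.

## 5. Discrete hidden Markov models

Each action class gets an HMM λ = (π, A, B): initial distribution π (N),
transition matrix A (N×N), emission matrix B (N×M). All implementations
live in `skelhmm.hmm`:

* **Forward/backward** use per-step scaling, accumulating the log
  normalizers, so log-likelihoods of long sequences are exact; an
  impossible sequence yields −inf rather than an exception.
* **Posteriors** γ (state) and ξ (transition) are computed from the scaled
  trellises; the scale factors cancel in the per-timestep normalization.
* **Baum–Welch** re-estimates over multiple sequences: π as the mean of the
  per-sequence γ₁, A and B from pooled expected counts. Stochastic rows are
  floored and renormalized (see below). Iteration stops when the total
  log-likelihood improves by less than `tol` or after `max_iter`
  iterations. The per-iteration log-likelihood history is returned;
  monotone non-decrease is asserted in the tests.
* **Viterbi** runs in log space; ties take the lowest state index, the
  returned path is 1-based.
* **Sampling** is ancestral from a seeded generator, used for the
  model-recovery experiments.

**Initialization by uniform segmentation.** Each training sequence of
length T is split into N equal contiguous segments (remainder frames go to
the later segments); segment membership defines a state path. π⁰ is the
empirical distribution of first-frame states (an indicator on state 1),
A⁰ the row-normalized adjacent-pair transition counts, and B⁰ the per-state
symbol frequencies with add-one smoothing. A sequence shorter than N states
is an error. This initialization encodes the left-to-right temporal
structure of an action without hard-coding a left-to-right topology.

**Smoothing floor = 1e-6.** Unsmoothed Baum–Welch can drive emission
probabilities of unseen symbols to exact zero, making any future occurrence
of that symbol score −inf. A floor of 1e-6 per cell (rows renormalized) is
far below any probability the data can support, so it never distorts
estimates, while keeping log-likelihoods finite. With the floor disabled,
a zero-probability training set raises an error instead.

**Convergence: tol = 1e-4, max_iter = 100.** On the benchmark the total
log-likelihood moves by less than 1e-4 nats well within 100 iterations;
the cap only guards against pathological slow crawl.

**N = 5 states (default).** The default actions are cyclic motions with a
handful of distinguishable phases; five states capture a
rise–peak–fall–trough structure with a spare state. Accuracy on the
benchmark is flat for N in 4–8.

## 6. Classification and evaluation

`train_action_models` groups labeled observation sequences by class (sorted
label order) and trains one HMM per class with the shared (N, M). To
classify, `recognize` computes the forward log-likelihood under every class
model and returns the argmax; ties resolve to the lexicographically first
label. The result carries all per-class log-likelihoods and the margin over
the runner-up. `evaluate` produces the recognition rate, per-class rates
and a confusion matrix over a labeled test set; an unknown true label is an
error.

## 7. Synthetic data

`skelhmm.synthetic` generates labeled motions from parametric templates: a
standing 25-joint skeleton of realistic proportions (torso 500 mm,
spine_base at (0, 1000, 2500) mm in camera space) plus additive per-joint
motion primitives — sinusoids along an axis, circles in a plane, and
constant offsets (held posture changes). The default library holds five
whole-body actions chosen to span distinct coordination patterns: a lateral
overhead arm wave, a frontal-plane hand circle, a squat, a sit-up cycle and
a pull-up cycle.

The noise model adds (a) i.i.d. Gaussian jitter (default sd 3 mm) to every
coordinate and (b) isotropic spikes of fixed magnitude (default 150 mm)
with small per-joint-frame probability (default 0.005) — precisely the two
artefact classes the amplitude-limiting filter targets. Datasets are
reproducible: per-sequence generators are spawned from a single master
`SeedSequence`, so the same master seed regenerates an identical dataset
and no two sequences share a random stream.

**What the generator does and does not emulate.** It reproduces the
statistical signatures relevant to the pipeline (smooth quasi-periodic
joint trajectories, jitter, spikes, dropouts via the `tracked` flags) but
not biomechanics: limbs are displaced additively, so bone lengths are not
preserved during motion, there is no inter-subject style variation beyond
noise, and no self-occlusion model. Results on this data characterize the
pipeline, not performance on real captures.

## 8. Benchmark studies

The studies in `skelhmm.benchmark` (driven by `scripts/acceptance.py`) use
problem sizes chosen to be large enough for stable statistics and small
enough to run in minutes:

* **Recognition:** 5 classes × 40 sequences (first 20 per class train, last
  20 test), T = 120 frames, default noise, N = 5, M = 16.
* **Sample efficiency:** same pool; the held-out half is fixed and the
  models are retrained on 20 versus 13 sequences per class (codebook
  refitted per subset, so the comparison covers the whole pipeline); the
  gap in recognition rate is averaged over 5 consecutive master seeds.
* **Compression:** keyframe extraction at a 10 mm budget on low-jitter
  sequences (sd 1 mm — e.g. pre-smoothed or high-grade capture), T = 120,
  with the reconstruction-error bound re-verified per sequence. At the
  default 3 mm jitter, a 10 mm budget leaves little room to drop frames and
  ratios stay near 1; compression is a property of the noise floor relative
  to the budget, and the study documents the low-noise regime where frame
  reduction is actually useful.

All randomness in a study derives from its single seed argument; reports
are written with sorted keys so repeated runs are byte-identical.

## 9. Determinism and tie-breaking summary

* k-means: fixed `random_state`, centroids lexicographically sorted.
* encoding: nearest centroid, exact tie re-check, lowest symbol index.
* keyframes: earliest-predecessor tie rule in the DP.
* Viterbi: lowest state index on ties.
* recognition: lexicographically first label on exact likelihood ties.
* datasets: `SeedSequence` spawning, one child stream per sequence.

## 10. Limitations

* The HMMs are ergodic with segmentation-based initialization rather than a
  constrained left-to-right topology; on strongly ordered non-cyclic
  actions a Bakis topology could converge faster.
* The amplitude-limiting filter is causal and memory-1; a spike lasting
  many frames is tracked (at the clamped rate) rather than rejected.
* Depth segmentation assumes a single near subject in front of a distant
  background; it has no connected-component reasoning.
* Synthetic data does not preserve bone lengths under motion and carries no
  subject-to-subject variation, so absolute accuracies are optimistic
  relative to real captures.
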