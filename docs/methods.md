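# Methods

## Model

The circuit is a fully connected feed-forward classifier
2 → 512 → 512 → 256 → 4 with per-layer binary sparsity masks. Effective
weights are `W ⊙ M` everywhere; biases are never masked. Hidden units are
rectifiers by default; a bounded (tanh) unit is available as the
saturating-firing analogue. The output layer is linear + softmax.

Each hidden layer applies, in order: linear map → nonlinearity → additive
internal noise ε ~ N(0, σ²) per unit per sample → multiplicative gain γ.
The ordering is a modelling commitment, not a convenience: the gain stands
in for tonic GABAergic inhibition, which damps *overall* post-synaptic
activity — the stress noise included. Damping the noise is precisely how
the neurosteroid analogue buffers the combined-stress condition while
active, and it reproduces the characteristic pattern that the on-state
outperforms the off-state under moderate noise yet underperforms it under
extreme noise (with γ = 0.7 and tanh the signal is bounded by γ, so very
large σ overwhelms it even after attenuation). With the opposite order
(noise added after the gain) the on-state loses both properties. The
output layer receives neither noise nor gain.

Internal noise is a stressor, not part of the drug: the modulation's
`enabled` switch toggles the gain and the activation override only, and
withdrawal ("off") restores both the unit gain and the rectifier. The
alternative reading — withdrawal removes only the gain, leaving tanh — was
considered and rejected; neither reading reproduces every published
off-state read-out, but reverting both matches the extreme-noise behaviour
and keeps the "drug imposes gain + saturation" bundle symmetric.

## Task

Four isotropic Gaussian clusters at (−3,−3), (3,3), (−3,3), (3,−3),
σ = 0.8, one per class; 12,000 training, 4,000 standard-test and 2,000
clean-test points, classes balanced by round-robin assignment and shuffled
within each split. "Clean" means held-out draws from the intrinsic cluster
distribution; the "standard" split is clean-process draws plus additive
input jitter of σ = 0.8 — so "clean" reads as "no added perturbation" and
the printed ordering clean ≥ standard ≥ combined stress emerges naturally.
Cluster centres sit ≈ 3.75σ from the Bayes decision boundaries, so the
dense task is near-separable and every deficit is attributable to pruning
or noise.

## Training

Mini-batch Adam (β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸) on categorical
cross-entropy, batch 128, data reshuffled each epoch. Gradients at masked
positions are zeroed before every step, so masks are conserved exactly
through any amount of training. Training-time internal noise follows a
schedule; the linear taper uses denominator E−1 so σ reaches its end value
exactly at the final epoch. Cross-entropy clips probabilities at 10⁻¹² 
before the log. Weight init is Kaiming-uniform, W, b ~ U(±1/√fan_in).
All arithmetic is float32 (float64 softmax for stability); oracle tests may
build float64 networks, which the forward/backward pass preserves.

## Pathology and protocols

Pruning removes the ⌊f·n⌋ smallest-|w| unmasked entries per layer (ties by
row-major index; floor rounding), sets them to exactly zero, and never
resurrects previously masked entries. The insult uses f = 0.95 on all four
weight matrices; the relapse challenge reuses the identical rule with
f = 0.40 on the survivors, per layer.

Ketamine-like regrowth scores every masked entry by Σ|∂L/∂w| accumulated
over 30 noise-free batches (sum of absolute per-batch gradients rather than
|Σ| or RMS — robust to sign cancellation across batches), regrows the top
⌊0.5·pruned⌋ per layer from N(0, 0.03²), then consolidates 15 epochs at
lr 5·10⁻⁴, σ = 0, mask locked. Per-layer quotas keep all layers connected;
overall sparsity lands at 47.5% either way. The SSRI protocol delegates to
the trainer (100 epochs, lr 10⁻⁵, σ: 0.5 → 0). The neurosteroid protocol
tunes 10 epochs at lr 5·10⁻⁴ with the modulation active and σ = 0, then
attaches the modulation to the returned state. Consolidation and tuning run
noise-free for consistency with the noise-free gradient accumulation.

## Evaluation

Top-1 accuracy (%) per condition. Combined stress = standard split + extra
input noise σ = 1.0 + internal σ = 0.5; the internal-noise sweep runs on
the standard split with no extra input noise over
σ ∈ {0, 0.3, 0.5, 1.0, 1.5, 2.0, 2.5} (the untreated no-noise sweep column
therefore equals the standard-split accuracy, matching the published
tables' internal consistency). Noisy conditions are averaged over 8
independent draws from a fixed evaluation stream — the published numbers
come from single passes, so averaging tightens the stochastic read-outs
without changing their expectation. Evaluation noise is resampled per
activation element per forward call. The relapse drop is (combined before −
combined after) in percentage points, measured on a pruned copy.

## Iso-dose analysis

Dose = Σ|W_after ⊙ M_after − W_before ⊙ M_before| / (number of weight
entries); biases excluded; structural change registers as |w| per affected
entry. Normalising by total weights (not changed weights) keeps the proxy
comparable across protocols that alter very different entry counts. Default
sweep grids: ketamine regrow ∈ {0.1, 0.2, 0.3, 0.5}; SSRI
lr ∈ {10⁻⁶, 5·10⁻⁶, 10⁻⁵, 5·10⁻⁵} × epochs {25, 100}; neurosteroid
γ ∈ {0.5, 0.7, 0.9} × tuning epochs {0, 5, 10}. Records match when doses
differ by ≤ 25% relative to the larger; grouping is greedy along the dose
axis with at most one record per protocol per group.

## Randomness and determinism

One master seed (default 42) spawns named child streams (data, init, train,
ghost, regrow, per-treatment, evaluation, sweep) via `SeedSequence` spawn
keys, so adding an evaluation never perturbs training reproducibility.
Reruns with the same seed are bit-identical within one environment; BLAS
differences across platforms are absorbed by evaluation tolerances, not
promised away.

## Problem sizes in the test suite

Unit and property tests run on a reduced geometry — a 2→16→16→8→4 network
and 2,000/400/400 points — which preserves every mechanism (masking,
regrowth, schedules, dose accounting) at negligible cost; the end-to-end
acceptance checks run the full canonical configuration once and reuse the
fitted states, and the iso-dose acceptance check uses reduced grids
(ketamine regrow {0.05, 0.1, 0.3}; SSRI lr {10⁻⁵, 5·10⁻⁵} × 25 epochs;
neurosteroid γ {0.5, 0.7} × tuning {5, 10}) chosen so the mechanisms' dose
ranges can overlap: simple dose arithmetic (regrown count × E|N(0, 0.03²)|
per parameter) puts the canonical 50% regrowth an order of magnitude above
any drift-based protocol's reach, so the comparison lives at small regrowth
fractions.

## Known limitations

* The untreated pruned network's *noise-free* accuracies are chaotic
  functions of the seed and training trajectory (observed clean-split range
  ≈ 25–70% across seeds); its noisy read-outs (combined stress, noise
  sweep) and all between-condition orderings are stable. Comparisons
  against any single published run should weight the latter.
* A feed-forward rate model with i.i.d. Gaussian "stress" cannot capture
  recurrence, neuromodulator time courses, cell-type heterogeneity, or
  glial pruning mechanisms; pruning by weight magnitude and regrowth by
  gradient ranking are deliberate abstractions.
* The generator emulates the canonical 2-D task only; the machinery is
  dimension-agnostic but untested claims beyond 2-D are not made.
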