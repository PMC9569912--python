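# Methods

This note documents the model, its parameters and defaults, the synthetic
data the package tests itself on, and the numerical and design choices
that were genuinely open.

## Model

A drug–target pair is a multiple-instance bag. The forward path is:

1. **Tokenization.** A unigram language-model tokenizer is trained per
   stream (SMILES; protein). Training seeds the candidate vocabulary with
   all corpus substrings up to 8 characters (capped at 8× the requested
   vocabulary, scored by frequency×length), runs EM over the segmentation
   lattice (forward–backward expected counts, 4 sweeps per round), then
   prunes the lowest-expected-count multi-character pieces (25% per round)
   until the requested size is reached. Single characters are never
   pruned, so every string over the training alphabet is segmentable;
   unseen characters map to the `unk` id (pad = 0, unk = 1). Encoding is
   the Viterbi (maximum-likelihood) segmentation, truncated from the tail
   and padded. An optional character-level mode (identity vocabulary)
   supports atom-level inputs; it is off by default because the default
   pipeline consumes the substructure view only.
2. **Encoders.** Token ids are embedded (dimension d_model), summed with
   sinusoidal positional encodings, and passed through a stack of
   post-norm transformer layers — multi-head self-attention (scaled by
   1/√head_dim), then a ReLU position-wise FFN, each wrapped as
   LayerNorm(x + f(x)). Drug and protein stacks share no parameters.
   Padded key positions are excluded from every softmax, so pad content
   cannot influence unmasked rows (property-tested).
3. **Instances.** Each stream runs through a residual dilated GatedCNN: a
   causal dilated 1-D convolution doubles the channels, the output splits
   into content and gate halves, content ⊗ σ(gate) is layer-normalized and
   the block input is added back. Masked global max pooling (pads set to
   −1e30 before the max) yields the pooled private features; the drug one
   is the `private_d` instance and the pair's concatenation is
   `public_concat`. Two multi-head cross-attention blocks (queries from
   one stream, keys/values from the other, residual add of the query
   stream) followed by pooling give `public_dp` and `public_pd`.
4. **MIL head.** Each instance has its own MLP scorer (independent
   parameters — the concatenation instance is twice as wide as the rest,
   and per-instance score semantics are preserved). The affinity is the
   learned linear fusion ŷ = Σ wᵢsᵢ, no intercept by default (a config
   toggle exists). Training minimizes the mean squared error.

## Parameters and defaults

Full-scale defaults (desk-scale work overrides them downward):

| parameter | default | meaning |
|---|---|---|
| d_model | 128 | embedding/feature width everywhere |
| n_layers / n_heads | 2 / 4 | per encoder stack |
| ffn_dim | 4·d_model | FFN hidden width (transformer convention) |
| drug/protein vocab | 900 / 10,000 | unigram pieces per stream |
| drug/protein max_len | 128 / 512 | token-sequence lengths |
| gate blocks | 3, kernel 3, filters 128 each | GatedCNN stack |
| dilation rates | (1, 2, 4) | exponential receptive-field growth |
| scorer MLP | 1024, 1024, 512, 1 | per-instance scorer widths |
| optimizer | AdamW, lr 1e-3, betas (0.9, 0.999), eps 1e-8 | weight_decay 0 so the objective is exactly the MSE |
| batch size | 64 | tuning knob |
| early stopping | patience 20 on validation MSE, min_delta 1e-6 | improvements smaller than min_delta do not reset patience |

Open choices resolved here (the sources of these conventions are
documented in code where they matter):

- **Dilation rates** are unstated for the three gate blocks; (1, 2, 4) is
  the standard exponential schedule, giving a receptive field of
  2·(1+2+4) = 14 positions (probe-tested).
- **Channel split order** in the gate block: first half content, second
  half gate (arbitrary but fixed).
- **Causal (left-zero-padded) convolution**, matching the backward-looking
  index arithmetic of the dilated-convolution definition; it also
  guarantees tail padding can never leak into valid positions.
- **Fusion weights** initialize at 0.25 each (symmetric start).
- **MSE as a mean** rather than a bare sum: keeps the loss scale
  independent of batch size and matches the metric's name.
- **Concordance index** normalizes by the number of comparable pairs
  (true affinities differing), not the sample count; ties in the truth are
  excluded, tied predictions count 0.5. This is the standard CI and is
  cross-checked against lifelines.
- **rm²** uses the standard form r²·(1 − √(r² − r0²)) with r0² the squared
  correlation of the least-squares fit of observed on predicted through
  the origin (slope k = Σyp/Σp²). A noise floor treats |r² − r0²| < 1e-12
  as zero so perfect predictions give exactly rm² = 1; genuinely negative
  radicands are clamped with a warning.
- **Blind-split "mixed" pairs** (training drug × test target or vice
  versa) are discarded from all partitions and counted: placing them
  anywhere would leak an entity across the cold boundary.
- **Tokenizers are fitted on training+validation entity strings only**, so
  the vocabulary carries no test-set information.
- **Scorer MLPs are scorers only** (no auxiliary feature-extraction path),
  and the four scorers are independent.
- The per-stream token vocabulary is trained from whatever corpus the user
  supplies; large public corpora (e.g. UniProtKB, ChEMBL-derived compound
  sets) can be passed through the same `tokenize train` hook.

## Autodiff core

The network runs on a ~300-line reverse-mode automatic-differentiation
module over numpy arrays (broadcasting arithmetic, batched matmul,
reductions including argmax-routed max, slicing, concatenation, a
time-shift primitive for causal convolution, embedding lookup). Every
operation's gradient is verified against central finite differences in the
test suite, and the fused model loss gradient is finite-difference checked
end to end. Float64 throughout; determinism on one CPU thread follows from
seeding every `numpy.random.Generator` (initialization, shuffling,
splits, synthetic data).

## Synthetic data: what it emulates, what it does not

The generator emulates the *shape* of public DTA benchmarks: a drug ×
target grid observed at controllable density (1.0 down to ~0.0007, the
range spanned by the common benchmarks), SMILES-like strings over a small
chemical alphabet and protein-like strings over the 20 amino-acid
alphabet, affinities on a pKd-like scale (baseline 5, effects of order 1,
optional Gaussian noise, default σ = 0.1). The planted signal is
deliberately *interactive*: affinity rises by aₖ only when drug motif k
and its partner protein motif are both present, so drug-only or
target-only models cannot fit it exactly (regression-tested); this is
precisely the signal the public (interaction) instances exist to capture.
Motif membership is evaluated on the final emitted strings, so labels are
always an exact function of the sequences plus noise. Pair sampling is
uniform by default; a power-law drug-degree option emulates
screening-panel bias.

What it does not emulate: real chemistry (no valence or grammar in the
SMILES-like strings), homology structure between proteins, assay noise
heteroscedasticity, or the label distributions of real benchmarks.
Passing tests therefore demonstrate that the implementation is correct and
that the architecture can represent and learn drug×target interaction
signal — not that the model reaches any particular accuracy on real data.

## Problem sizes used in the self-checks

The package's heavier self-checks run at desk scale, chosen so the whole
suite completes in a few minutes of one CPU: the end-to-end learnability
check trains a reduced model (width 32, 1 encoder layer, 4 heads, 1 gate
block, scorers 64–32–1, drug/protein token lengths 24/48) on 500 noiseless
pairs from a 50×30 grid (drug strings 12–32 characters, proteins 40–90)
and requires training CI ≥ 0.95 within 200 epochs; a full 200-epoch run of
that configuration reaches training CI ≈ 0.999. The ablation harness runs
its seven instance-subset configurations at a smaller scale still (width
8, 58 pairs, 3 epochs) — it checks the orchestration, not accuracy.

## Known limitations

- The numpy network is single-threaded and desk-scale; full benchmark
  reproduction (hundreds of thousands of pairs, ~10⁷ parameters) is out of
  scope and would need a GPU framework behind the same module surfaces.
- Affinity values are consumed as given (no pKd conversion or
  per-dataset label transforms).
- Unigram tokenizer training enumerates substrings of deduplicated
  sentences; it is quadratic in sentence length and intended for corpora
  of up to roughly 10⁵ short sequences, not millions.
- The blind split can legitimately fail on very sparse grids when the
  sampled test entities have no observed pairs; it raises and suggests a
  new seed rather than silently shrinking the test set.
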