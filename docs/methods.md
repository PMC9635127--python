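# Methods

## The classification problem

Adaptor proteins are identified here from PSI-BLAST position-specific
scoring matrices (PSSMs): for a protein of length `N`, an `N x 20` matrix of
log-odds scores, one column per amino acid in the fixed PSI-BLAST order
`A R N D C Q E G H I L K M F P S T W Y V`. Two properties of such cohorts
shape everything downstream: lengths vary over three orders of magnitude
(minimum 18), which rules out padding or windowing and forces batch size 1,
and positives are outnumbered about 1:9, which rules out unweighted losses
and accuracy-centric evaluation.

## Model

The network is deliberately tiny (12,137 trainable scalars at defaults):

1. **Three convolutional blocks.** Each block is a 1-D convolution along
   the sequence (20 output channels, kernel 3, stride 1, zero same-padding,
   bias), layer normalisation per position over channels with the biased
   variance and learned per-element `γ, β` (`eps = 1e-5`), ReLU, then
   non-overlapping average pooling of kernel 2 with floor length division.
   An `N`-position profile leaves the stack with `floor(N/8)` positions and
   20 channels, so `N >= 8` is required (the generator's minimum of 18
   leaves 2).
2. **One post-norm transformer encoder layer.** Multi-head self-attention
   with `d = 20`, `h = 5` heads of width `d_k = 4`: per head,
   `Q_i = Z W_i^Q`, `K_i = Z W_i^K`, `V_i = Z W_i^V` (no biases),
   `head_i = softmax(Q_i K_i^T / sqrt(d_k)) V_i`, heads concatenated and
   reprojected by `W^O` (no bias); then `Mid = LayerNorm(Z + MultiHead)`,
   a position-wise FFN `ReLU(Mid W_1 + b_1) W_2 + b_2` with `d_ff = 128`,
   and `Output = LayerNorm(Mid + FFN)`. There is no positional encoding,
   making the encoder permutation-equivariant (a tested property); order
   information enters only through the convolutional front end.
3. **Head.** Global average pooling over positions (maps any length to one
   20-vector), FC 20→64, ReLU, inverted dropout 0.5 (training only),
   FC 64→1, sigmoid.

Setting `use_transformer=False` removes the encoder (and exactly its 6,948
parameters) — the ablation configuration.

### Parameter accounting conventions

The published size series pins down every convention that the architecture
description leaves open. With Q/K/V/O projections bias-free, biases on
conv/FFN/FC layers, per-element `γ, β` on every layer norm, one encoder
layer, no positional encoding, and an FC hidden width of 64, the model
counts 12,137 parameters and the seven FFN widths
{20, 32, 64, 80, 128, 200, 256} count {7,709 … 17,385} — matching the
reported series "7.7k … 17.3k" under truncation (not rounding) to one
decimal in units of 1000. This is the unique simple convention we found
that reproduces all eight printed sizes simultaneously; it is enforced by
exact integer tests.

### Numerical notes

- Everything is float64 numpy; with a fixed seed, training is reproducible
  bit-for-bit on a given platform.
- Softmax rows are max-shifted before exponentiation.
- The loss and its gradient are evaluated from the pre-sigmoid logit
  (`log p = -softplus(-z)`), so saturated predictions cannot overflow.
- Backpropagation is hand-derived per layer and verified against central
  finite differences on every tensor, and against an analytic
  summed-gradient oracle for the accumulation step.
- Weight initialisation is Kaiming-uniform fan-in with matching bias bounds
  (the PyTorch default scheme), layer norms at `γ=1, β=0`; the scheme is a
  design choice — nothing downstream depends on its details beyond giving
  stable early training.
- Floor pooling drops a trailing odd position; its gradient is exactly zero
  (tested).

## Training protocol

Weighted binary cross-entropy
`L = -[w_pos · y · log p + w_neg · (1-y) · log(1-p)]` with
`w_c = (n_pos + n_neg) / n_c` (inverse class frequency; the study's
training counts 1069/9695 give the pair 10.07/1.11, reported to two
decimals, used unrounded). Both weights are applied, each to its own term;
the loss is the negated, minimised form.

Each profile is one batch. Gradients are **summed** (not averaged) over
groups of 24 profiles before a single Adam update
(`lr = 5e-4`, `β₁ = 0.9`, `β₂ = 0.999`, `eps = 1e-8`); the final partial
group of an epoch still triggers an update. Summation rather than averaging
follows the accumulate-then-step reading of the protocol; with Adam's
per-parameter scale adaptivity the difference amounts to a modest effective
learning-rate shift.

Per epoch the training order is reshuffled (seeded) and the validation AUC
is computed. Two independent stale counters key on strict AUC improvement
(ties are stale): after 6 stale epochs the learning rate is halved and that
counter resets; after 20 stale epochs training stops. The 50-epoch cap
applies regardless. The returned checkpoint is from the best-validation-AUC
epoch. Cross-validation uses seeded stratified 5-fold partitions (per-class
round-robin dealing after a shuffle; fold sizes differ by ≤ 1 per class),
each fold training with its own derived seed.

A single seed drives three spawned, independent RNG streams per training
run (initialisation, epoch shuffling, dropout masks) via numpy
`SeedSequence` spawning.

## Evaluation

Predictions are positive when `score >= threshold` (default 0.5).
Sensitivity `TP/(TP+FN)`, specificity `TN/(TN+FP)`, accuracy, and MCC with
the four-factor denominator and the 0-on-degenerate convention. The ROC
curve enumerates every distinct score threshold plus both endpoints, with
tied scores moving together; AUC is the trapezoidal area and is internally
asserted (to 1e-9) to equal the Mann–Whitney statistic with ties counted
one half. AUPRC uses the step-wise average-precision rule, since
trapezoidal interpolation of precision–recall curves is optimistic.
scikit-learn implementations serve as independent cross-checks in the test
suite only.

## Synthetic cohort

The generator emulates the statistical shape of the real data rather than
its biology. Defaults are the study conditions at desk scale: 200 positives
vs 1800 negatives (the 1:9 imbalance), lengths log-uniform on [18, 500]
(the real minimum is 18 and the distribution is heavily right-skewed;
log-uniform reproduces "wide range of lengths" while keeping runtimes
sensible — the forward pass itself is tested up to length 50,000), integer
scores from Gaussian noise (sd 2.0) rounded and clipped to [-16, 13], the
usual PSI-BLAST log-odds range. Positives receive +6.0 on a fixed subset of
5 residue columns over 9 consecutive positions at a random offset before
rounding/clipping — a conserved-column motif. Because the classifier ends
in global average pooling, a purely positional signal would be invisible;
a column-level shift is both what PSSM conservation looks like and a signal
that survives pooling. With the motif gain set to 0 the classes are
exchangeable by construction (verified by a permutation test).

What passing on this cohort shows: the architecture, loss, optimisation and
selection machinery can extract a column-statistics signal under the real
data's length variability and imbalance, and the transformer contributes
measurably. What it does not show: performance on real adaptor proteins,
whose discriminative structure is richer than one additive motif; real-data
results additionally require PSI-BLAST profile generation and the deposited
cohort.

## Problem sizes and runtime choices

Unit and property tests run on profiles of lengths 8–300 and cohorts of
48–400 profiles. The end-to-end check trains the full protocol twice
(with and without the encoder) on the default 2000-profile cohort; with
early stopping this takes a few minutes per configuration on one CPU.
PSSM values are fed to the model unscaled — no clipping or squashing is
applied beyond what the generator itself does — keeping the input contract
identical for parsed real profiles and synthetic ones.

## Known limitations

- One encoder layer, no positional encoding, and the stated bias
  conventions are inferred from the published parameter counts, not from an
  architecture dump; other conventions summing to the same counts are
  conceivable.
- The train/test split fraction is exposed as a parameter (default 0.2)
  rather than reproducing any particular published split file.
- FLOPs accounting is not implemented; no reference sequence length exists
  for a variable-length model, so any single number would be arbitrary.
- The CLI covers the workflow but not PSI-BLAST invocation; profiles must
  already exist (or be simulated).
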