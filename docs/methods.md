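# Methods

## Problem and model

`seqsite` labels every residue of a protein sequence as ligand-binding or
not, from sequence-derived features alone.  The classifier is a fully
convolutional encoder–decoder over the residue axis.  Per-residue features
(d = 30) enter a k×d convolution producing 2c channels; two encoder stages
of N blocks follow; a decoder maps each residue's 2c-channel representation
to a 2-way softmax.  All convolutions have stride 1 and are padded to
preserve the sequence length m, so inputs of any length are processed
without windowing or segmentation.

### BasicBlock

Each block computes LN → GLU → Conv with a residual connection:
layer normalization is applied per residue over the channel axis
(ε = 1e−5, learned gain and offset); the gated linear unit splits the 2c
channels into halves A (first c) and B (last c) and outputs A·σ(B); the
width-k convolution maps c back to 2c channels, zero-padded (k−1)/2 per
side; the block input is added back.  The first block of each stage is
"Plain" — identical but without the residual — because the input transform
or the context transform that precedes it produces a representation on a
different scale than the block output; the remaining N−1 blocks are
residual.  One extra layer normalization sits at the top of each stage to
stabilize scale between stages.  The padding expression k/2 is implemented
as (k−1)/2 and even k is rejected at config validation, since only odd
widths keep the output centred on its input position.

### Receptive field

n stacked width-k stride-1 convolutions give each output an input field of
1 + n(k−1) residues.  In a full encoder n = 2N + 1 (input transform plus
2N block convolutions) — always odd, which is why the probe tests exercise
free-standing block stacks for even n and whole encoders for odd n.  The
empirical probe perturbs a single input channel (a uniform shift of a whole
residue row is invisible to layer normalization) and records which input
positions reach a fixed output row.

### Decoders

The standard decoder applies two 1×1 projections (2c → c → 2); the first
is wrapped in dropout (rate 0.5 by default) during training; no
nonlinearity sits between them — none is specified for this head, and the
GLU gating in the encoder already supplies the nonlinear capacity.  Rows
belonging to padding are removed before the softmax.

The context-aware (en) decoder receives, in addition to the encoder
output, an m×2 context tensor: one-hot labels during training (teacher
forcing), the first pass's softmax probabilities at inference, or zeros for
the first pass.  A k×2 convolution lifts the context to 2c channels; two
parallel causal stages of M blocks process it.  The left branch shifts the
context right by one position (the vacated first row acts as a zero start
mark) and uses convolutions padded k−1 on the left only, so its output at
position i depends only on context strictly left of i; the right branch
mirrors this.  Both branch outputs are added to the encoder output and the
standard decoding path follows.  Branch causality is verified by
perturbation tests.

The stage-top layer norms of the context branches are initialized with
zero gain and offset, so a freshly extended en model is
prediction-identical to the std model it came from; fine-tuning moves away
from that point only by reducing the teacher-forced loss.  This removes
the risk that attaching an untrained context path degrades a trained
predictor, and it makes the paired std/en comparison meaningful from the
first iteration.

### Masking and padding

Sequences in a batch are padded to the batch maximum with dummy residues
(residue-type index 20).  The batch container keeps the dummy embedding
rows, but the network multiplies masked rows to zero before every
convolution and after every block.  Consequently the activations a valid
residue sees are identical whether its protein is processed alone (where
convolutions zero-pad beyond the ends) or inside any padded batch — the
test suite asserts bit-level equality — and padded residues contribute
exactly nothing to the loss or its gradient.

## Objective and optimization

The loss is softmax cross-entropy over valid residues plus γ‖θ‖², where θ
ranges over convolution and projection kernels only; layer-norm gains and
offsets and biases are excluded, since penalizing normalization parameters
fights the normalization itself.  The cross-entropy is reduced as a mean
over valid residues (default) so that γ has a batch-size-independent
scale; the summed form is available via `reduction="sum"`.  Default
γ = 0.2, dropout 0.5.

Optimization is whole-sequence mini-batch gradient descent: sequences are
never split, batches are padded to their own maximum, shuffling is seeded,
and no class resampling or reweighting is applied — each batch carries
approximately the natural ~3% positive fraction.  The learning-rate
schedule has three stages (preheat; a raised second stage to escape the
all-negative local minimum that the skew induces; a conservative finish),
each decaying exponentially: rate = initial · decay^⌊elapsed/interval⌋.
Plain SGD is the default optimizer; momentum and Adam are available, and
the training-heavy studies below use Adam because it converges at these
small problem sizes in a fraction of the iterations.  An optional global
gradient-norm clip exists for the steep-preheat case and is off by
default.

En-mode training loads all std weights, freezes the encoder (asserted
bit-identical afterwards), fine-tunes the standard-decoder projections and
trains the fresh context branches under teacher forcing, which keeps the
forward pass parallel over the whole sequence.

All parameters and activations are float64.  Gradients come from a small
tape-based reverse-mode autodiff (`seqsite.autodiff`) providing exactly
the fused operations the model needs (conv1d via im2col, layer norm, GLU,
dropout, masking, shifted sequences, masked cross-entropy, L2); every
operation is checked against central finite differences, and the composed
network gradient is checked end-to-end.

## Feature space

Column layout (fixed, 30 columns): 20 squashed PSSM scores, RSA, 3
secondary-structure propensities, φ/ψ /360, RE and JSD conservation
scores, residue type, position.

Decisions where the conventions were open:

* **Residue indexing** — the 20 standard amino acids in alphabetical
  one-letter order take indices 0–19; the dummy residue is 20; the encoded
  value is index/21.
* **Position embedding** — 1-based, PE_i = i/L ∈ (0, 1], so no real
  residue sits at exactly 0 and the last residue is exactly 1.
* **Dihedrals** — x/360 applied to the angle as given; negative angles
  yield negative features.  Callers preferring [0, 360) can wrap first;
  the network is indifferent to a fixed affine shift of one input column.
* **RSA/SS/CS** — consumed as given; the 25% buried/exposed
  discretization is deliberately not applied (the continuous value is more
  informative).
* **Conservation scores** — when computed here rather than supplied,
  logarithms are base 2, making JSD ≤ 1.
* **P_BR audit convention** — `dataset_summary` reports
  100·N_BR/N_NBR (binding-to-non-binding ratio) rounded half-up to two
  decimals; this is the convention that reproduces the published audit
  tables of the curated benchmark datasets, although the quantity is
  labelled a "proportion" there (BR/(BR+NBR) does not reproduce them).

## Synthetic corpora

The generator emulates the statistics the design targets, with defaults
chosen once as the study conditions: 3% target positive fraction,
sequence lengths 60–200, positive runs with geometric lengths of mean 3
(binding residues aggregate into short runs), a 3-letter motif written at
each run start, PSSM/conservation mean-shifts on positive residues
(snr_pssm = 2 raw log-odds units on six signature columns, snr_cs = 1),
and a label-independent +5 log-odds shift of each residue's own PSSM
column, the profile's identity signal.  RSA is uniform, secondary
structure Dirichlet, dihedrals uniform — deliberately label-independent
noise.

The long-range pair rule labels residue i positive iff tryptophan occurs
at position i−D or i+D.  Its realized skew (~1 − (19/20)² ≈ 9.7% for one
trigger letter) is set by the trigger frequency, not by the target
fraction.  `receptive_field_challenge` builds pair-rule-only corpora at
several D with the feature signal-to-noise dials forced to zero, so the
label is reachable only through the sequence at distance D; corpora at
different D share sequences, lengths and feature noise (per-protein RNG
streams independent of the rule), differing only in labels.

What the generator does **not** emulate: real ligand chemistry, true PSSM
column correlations, homology structure between proteins, or realistic
secondary-structure/dihedral coupling.  Passing the studies below
demonstrates the mechanisms (capacity, dependency-length control, context
decoding) under the stated statistical conditions, not benchmark-level
accuracy on biological data.

## Study problem sizes

Chosen once as the package's own experimental design:

* **Capacity** — 20 proteins (length 40–60), reduced net (k=3, N=2, c=8),
  Adam at 3e−3, 300 iterations: training MCC reaches ≥ 0.95 (typically 1.0).
* **Dependency length** — 1200 training / 100 held-out proteins (length
  40–60), same reduced net with dropout 0.5, 2500 Adam iterations.  The
  net's input field is 11 residues, so the D = 3 rule (span 7) is
  learnable (held-out MCC ≈ 0.82–0.86 across seeds) while the D = 15 rule
  (span 31) yields chance-level held-out MCC (≈ 0.0).  The corpus is
  deliberately large: with fewer proteins the model memorizes feature
  noise instead of the rule, which depresses held-out MCC without
  affecting the beyond-field conclusion.
* **Paired decoder comparison** — 160/40 proteins (length 60–100,
  clustered labels), k=5, N=2, c=16; std trained 800 Adam iterations,
  en fine-tuned 400 at a quarter of the rate.  Held-out MCC ≈ 0.95 for
  both, en ≥ std, encoder bit-identical.

Training for these studies pins γ = 0 (the capacity and rule-recovery
questions concern fit, not regularized generalization; dropout provides
the regularization where it matters).

## Numerical choices and degenerate inputs

* MCC returns 0 when any denominator factor is zero; precision/recall
  return 0 on zero denominators and are flagged degenerate.
* Thresholds must lie strictly inside (0, 1); a residue is positive when
  its probability is ≥ the threshold, making recall and the
  predicted-positive count non-increasing in the threshold.
* An all-masked batch, an empty dataset, an empty threshold grid, a
  non-finite loss (divergence), and config/weight shape mismatches are
  rejected with diagnostics rather than propagated.
* Checkpoints store float64 tensors in NPZ with a JSON metadata block
  (format version, config, provenance, training summary); load → predict
  is bit-identical to in-memory predict, and version or shape mismatches
  are rejected cleanly.
* Feature tables are written with %.17g and read with round-trip float
  parsing, so the TSV round trip is lossless at float64 precision.

## Known limitations

* Plain SGD at the shipped default schedule needs many more iterations
  than Adam at the study sizes; the defaults document the intended
  full-scale regime rather than a fast desk-scale recipe.
* The implementation is CPU/NumPy; it is intended for method study and
  moderate corpora, not for training at the scale of hundreds of
  thousands of sequences.
* The en decoder's benefit is small on corpora whose labels are already
  locally decodable from features; it is designed to help when context
  aggregation carries information, and the paired study asserts
  non-degradation (en ≥ std − 0.02) rather than a fixed improvement.
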