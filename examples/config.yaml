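# Shipped default configuration for `seqsite train`.
# Every value mirrors a library default; acceptance-style studies and the
# examples pin their own (usually smaller) values.

network:
  k: 5                  # odd convolution width in every block
  blocks_per_stage: 10  # N: blocks per encoder stage (two stages)
  context_blocks: 2     # M: blocks per causal context stage (en mode)
  c: 256                # channel half-width; blocks carry 2c = 512 channels
  d: 30                 # per-residue feature dimension (fixed layout)
  dropout: 0.5          # around the first 1x1 decoder projection

training:
  gamma: 0.2            # L2 coefficient over conv/projection kernels
  batch_size: 8         # whole sequences per mini-batch
  reduction: mean       # cross-entropy per valid residue ("sum" also accepted)
  optimizer: sgd        # plain mini-batch gradient descent; momentum/adam available
  grad_clip: null       # max gradient norm; off by default
  # three-stage schedule: preheat, raised escape stage, conservative finish;
  # within a stage: rate = initial_rate * decay ** floor(elapsed / interval)
  stages:
    - {initial_rate: 0.05, decay: 0.9, interval: 100, iterations: 200}
    - {initial_rate: 0.15, decay: 0.8, interval: 100, iterations: 400}
    - {initial_rate: 0.02, decay: 0.8, interval: 100, iterations: 200}

simulation:
  n_proteins: 200
  length_range: [60, 200]
  positive_fraction: 0.03   # the ~3% binding-residue skew regime
  motif_weight: 1.0
  pair_weight: 0.0
  pair_distance: 5
  snr_pssm: 2.0
  snr_cs: 1.0
  clustering: 3.0           # mean positive-run length
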