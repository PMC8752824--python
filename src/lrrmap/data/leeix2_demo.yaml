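# LeEIX2 demo: 31-LRR tomato receptor ectodomain with terminal caps and a
# loopout insertion. The loopout position (between repeats 27 and 28) is an
# assumption reconstructed from refinement-round construct naming; it is a
# config field, not a model constant. The planted paratopes are the two
# repeat windows with the strongest competable binding signal in the
# motivating experiments.
protein:
  name: LeEIX2
  n_repeats: 31
  loopout:
    after_repeat: 27
design:
  k_initial: 3
  segment_length: 13
  tolerance: 0.9
  edge_margin: 2
  selection_rule: largest
sim:
  truth:
    paratopes:
      - [6, 10]
      - [22, 26]
    min_contig: 3
    signal_scale: 1.0
    leak: 0.05
    background: 0.05
  noise_sd: 0.25
  cq_baseline: 20.0
  batch_offsets: [0.0]
  replicates: 3
  seed: 17
stats:
  alpha: 0.1
  outlier_k: 1.5
  min_delta_floor: 1.0
  min_support: 1
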