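cluster:
  k: 6
colocalize:
  flank: 0
enrich:
  study: il_specific_induced
physiology:
  simulate: true
preprocess:
  detection_threshold: 100.0
  pseudocount: 1.0
regulon:
  r_cutoff: 0.9
  specific_driver: DREB1C
sam:
  fc_threshold: 5.0
  n_permutations: 1000
  p_threshold: 0.05
  pooling: across_genes
  s0_mode: percentile
  s0_value: 50.0
seed: 42
simulate:
  effect_log2: 3.0
  n_genes: 400
  noise_sd_log2: 0.25
  planted_counts:
    common_induced: 24
    common_repressed: 8
    constitutive_down_il: 4
    constitutive_up_il: 6
    down_then_up: 4
    il_specific_induced: 9
    il_specific_repressed: 3
    recurrent_specific_induced: 10
    recurrent_specific_repressed: 8
    up_then_down_il: 4
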