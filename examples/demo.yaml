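# Two-taxon demonstration: one full pooled screen (16 source plates -> one
# 96-well assay plate), deconvolution, confirmation, TNF/ESOM binning of the
# confirmed clones, and predicted-vs-confirmed concordance.
seed: 5

library:
  n_clones: 1520
  n_taxa: 2
  genome_length: 500000
  insert_size_range: [36000, 48000]
  active_gene_rate: 0.05

noise:
  background_mean: 5.0
  background_sd: 1.0
  host_background: 0.0      # knockout expression host
  active_signal_mean: 10.0
  active_signal_sd: 1.0

pooling:
  plates_per_pool: 16
  clones_per_plate: 95
  rounds_per_day: 8
  n_substrates: 14

hit_calling:
  sd_multiplier: 2.0
  combine_timepoints: any

binning:
  fragment_length: 2000
  min_sequence_length: 2000

esom:
  neurons_per_point: 5.5
  start_radius: 24
  epochs: 20

annotation:
  fn_rate: 0.0
  fp_rate: 0.0
  evalue_threshold: 0.1
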