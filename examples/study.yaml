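# Demo study configuration for `gentox run-all --config examples/study.yaml`.
#
# Any SimulationConfig field may appear under `simulation`; compounds are
# CompoundSpec fields.  The `bmc` block sets resampling problem sizes
# (permutations for the Williams trend prefilter, bootstrap refits per gene,
# bootstrap resamples for the gene-set median CI, bootstrap refits for flow
# endpoints).
seed: 1
simulation:
  n_biomarker_genes: 64
  n_training_chemicals: 28
  n_ddi_training: 14
  effect_size: 1.0
  noise_sd: 0.25
  compounds:
    - {name: CLAST-1, is_ddi: true, moa: clastogen, potency_b: 20.0}
    - {name: ANEU-1, moa: aneugen, potency_b: 20.0}
    - {name: PAN-1, is_ddi: true, moa: pan, potency_b: 20.0}
    - {name: NEG-1, moa: none}
bmc:
  n_perm: 100
  n_boot_gene: 40
  n_boot_median: 500
  n_boot_flow: 100
toxpi:
  k_clusters: 2
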