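# Demo pipeline configuration: simulate a small cohort with planted sponge
# structure and decoy predictions, then run the full inference cascade.
# Run with:  circernet run examples/demo_config.yaml --outdir demo_out
seed: 11
outdir: demo_out
sim:
  n_circ: 8
  n_mirna: 10
  n_mrna: 20
  n_background_mrna: 60
  n_background_circ: 40
  planted_triples: 12
  decoy_concordant_edges: 6
  decoy_low_resource_edges: 4
  nb_dispersion: 0.05
  batch_sd: 0.0
thresholds:
  bsj_min_reads: 5
  bsj_min_sample_frac: 0.5
  mrna_padj_max: 0.01
  circ_p_max: 0.05
  circ_abs_lfc_min: 1.0
  mirna_padj_max: 0.05
  mm_min_resources: 5
  mm_min_confidence: high
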