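# Full pipeline run configuration (every value shown is the default).
seed: 7
outdir: demo
simulate:
  n_genes: 300
  n_circ_hosting: 20
  replicates_per_stage: 3
  depth: 9000000
  circ_ratio: 0.10
  contaminant_fraction: 0.05
circ_call:
  min_reads: 2
  tol: 0
quantify:
  min_attomole: 0.001
  anchor: 25
deg:
  four_cell_stage: "4cell"
  fc_up: 2.0
  fc_down: 0.5
  alpha_fdr: 0.05
  min_rpkm_gate: 1.0
novel_filter:
  min_rpkm: 0.5
  min_rep_rpkm: 0.25
  min_dist: 10000
  min_exons: 2
  min_len: 500
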