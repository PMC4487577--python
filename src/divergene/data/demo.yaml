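# Demo pipeline configuration: small synthetic study, full stage list.
outdir: divergene_demo
seed: 7
synth:
  n_families: 40
  n_de_genes: 10
  de_fold: 8.0
  library_size: 300000
  n_accessions: 24
  n_markers: 20
evalue_cutoff: 1.0e-10
de_fdr: 0.01
de_fc: 2.0
snp_min_depth: 10
snp_min_score: 30.0
snp_min_spacing: 5
bootstrap_B: 100
aligner: blastn
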