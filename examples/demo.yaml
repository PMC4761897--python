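# Demo end-to-end run: a small synthetic hybrid study with one
# disrupted-site activator motif (TF01, broken in strain S2, coupled to a
# cis effect) and one trans-active TF (TF02, 2x activity in strain S3).
seed: 42
simulate:
  n_genes: 250
  n_strains: 4
  promoter_len: 200
  orf_len: 500
  snp_rate: 0.005
  n_replicates: 3
  baseline_mean: 200
  dispersion: 0.05
  frac_cis: 0.08
  cis_log2_effect: 1.0
motifs:
  n_total: 8
  length: 8
plants:
  - motif: TF01
    n_targets: 30
    disrupt_in_strain: S2
    couple_cis_log2: 1.0
  - motif: TF02
    n_targets: 30
tf_activities:
  TF02:
    S3: 2.0
thresholds:
  min_reads: 10
  ase_fdr: 0.05
  cse_alpha: 0.1
  enrich_fdr: 0.1
n_perm: 200
qvalue_method: storey
gomer_mode: prob
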