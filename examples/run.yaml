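# Full pipeline run on a simulated cohort.
# Swap `simulate:` for `vcf:` + `samples:` paths to analyze real data
# (the samples TSV needs sample_id, family_id, line, cage_id, role and
# the six trait columns).
simulate:
  n_families: 25
  n_selection_families: 19
  offspring_per_family: 8
  n_markers: 5000
  n_chromosomes: 10
  chromosome_length: 2000000
  divergent_fraction: 0.01
  divergence_fst: 0.4
  # plant a major QTL (trait, marker index, allele-substitution effect)
  qtl_list:
    - [Bwd8m, 2500, 1.5]

traits: [iBwt, iBlen, Bwt8m, Blen8m, Bdp8m, Bwd8m]

# marker QC
min_call_rate: 0.8
min_maf: 0.01

# Fst / diversity scan
window_bp: 1000000          # signature-calling windows
pi_window_bp: 2000000       # diversity-reporting windows
manhattan_window_bp: 100000 # Manhattan export
elevated_mean: 0.05         # window flag: mean per-SNP Fst
elevated_q95: 0.25          # window flag: 95% quantile of per-SNP Fst
top_quantile: 0.01          # genome-wide outlier SNP fraction

# QTL scan
scan_alpha: 0.05            # Bonferroni family-wise level
min_distance_bp: 1000000    # exclusion radius around accepted QTL
max_qtl: 20

# overlap
overlap_criterion: elevated_q95   # or elevated_mean / top_quantile
flank_bp: 5000

seed: 1
out_dir: divergescan_run
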