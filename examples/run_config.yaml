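# Template run configuration for `toxannot run-all --config <file> --out <dir>`.
# Every key is optional; values shown are the resolved defaults.

seed: 0

# Either a simulation block (synthetic benchmark) or an inputs block (real
# data), never both. With neither, the default simulation is used.
simulation:
  n_families: 4              # toxin gene families in the transcriptome
  leaves_per_family: [12, 20]
  birth_rate: 1.0            # Yule branching rate (tree shape only)
  root_length_aa: 90         # ancestral (mature) protein length
  subst_rate: 0.5            # expected subs/site, root -> non-toxin leaf
  toxin_clade_fraction: 0.8  # P(family has a recruited toxin clade)
  toxin_rate_multiplier: 3.0 # rate acceleration of recruited clades
  p_secreted_nontoxin: 0.5   # secreted (signal-peptide) non-toxin paralogues
  vg_logFPKM_toxin: [2.5, 0.7]     # log10 FPKM mean/sd, venom gland
  vg_logFPKM_nontoxin: [0.8, 0.7]
  muscle_logFPKM: [0.8, 0.7]
  detection_slope: 1.5       # logistic detection vs log10(FPKM_vg + 1)
  detection_intercept: -3.0
  frag_prob: 0.25            # fraction of contigs emitted truncated
                             # (a free assembly-quality parameter, not an
                             # empirical estimate)
  db_divergence: 0.8         # extra subs/site of distant-tier entries
  distant_coverage: 0.75     # family coverage of the distant tier
  n_decoy_families: 3
  population_divergence: 0.25
  library_size_vg: 1000000
  library_size_muscle: 1000000

# inputs:                    # real-data mode (ground-truth sections empty)
#   contigs: contigs.fasta
#   counts: counts.tsv       # id, length_bp, count_vg, count_muscle
#   proteome: proteome_ids.txt
#   databases:
#     species: db_species.fasta   # headers: family|subject_id
#     lineage: db_lineage.fasta
#     distant: db_distant.fasta

filter:
  min_fpkm_vg: 100.0         # venom-gland FPKM floor
  min_fold: 10.0             # minimum VG/muscle fold-overexpression
  pseudocount: 0.01          # FPKM added to the muscle denominator

e_threshold: 0.001           # homology search E-value cut-off
d_max: median                # clade-evidence patristic radius (or a number)
cluster_thresholds: [0.95, 0.90]
sp_mode: truth               # 'truth' (generator labels) or 'heuristic'
out_dir: toxannot_out
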