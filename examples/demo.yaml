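# Desk-scale demo of the full pipeline (see README).
# The SNP panel is a scaled-down stand-in for a genome-wide panel, so the
# enrichment cutoff is more liberal than the production default of 1e-4.
seed: 11
simulation:
  n_discovery: 2000
  n_target_pairs: 581
  n_snps: 3000
  n_causal: 500
scoring:
  thresholds: [0.05, 0.10, 0.20, 0.30, 0.40, 0.50]
  mode: avg
moderation:
  score_threshold: 0.05
  environments: [parental_knowledge, peer_deviance]
enrichment:
  cutoff: 0.01
  r2_max: 0.50
  alpha: 0.05
  n_perm: 9999
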