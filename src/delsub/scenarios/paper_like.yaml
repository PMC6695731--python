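# Desk-scale analogue of the kinase substrate-mediated library selection:
# truncated log-normal gene abundances, a small fraction of phenol-capped
# members active as substrates, antibody capture with nonspecific
# background back-solved from the dope-in calibration, and a LYNtide-like
# dope-in at 300,000 copies.  Library scaled to 10x10x10x4 members.
name: paper_like
seed: 1
mode: counts
design:
  n: [10, 10, 10, 4]
  codon_seed: 11
  d_min: 8
library_copies_per_member: 10000
abundance:
  sigma10: 0.2551
  trunc10: 1.0
activity:
  pi_active: 0.02
  x_mu10: -2.0
  x_sigma10: 0.5
  nonphenol_active_rate: 0.0
selection:
  p_ab: 0.09
  beta: 3.4615384615384617e-05
  depth: 200000
dope_ins:
  - id: LYNtide
    copies: 300000
    x: 1.0
analysis:
  alpha: 1.0
  merge_rule: mean_log
  top_k: 200
  min_enrichment: 10.0
  family_min_size: 3
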