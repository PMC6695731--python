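# Validation affinity selection: one cycle-3 building block is a planted
# pharmacophore (aryl-sulfonamide-like binder of carbonic anhydrase II);
# capture separation is strong, so every top-enriched molecule should
# carry the pharmacophore.  Library scaled to 12x12x12x4 members.
name: caii_validation
seed: 1
mode: counts
design:
  n: [12, 12, 12, 4]
  codon_seed: 23
  d_min: 8
library_copies_per_member: 10000
pharmacophore:
  cycle: 3
  block_id: 0
  p_cap: 0.05
  background: 1.0e-05
selection:
  depth: 1000000
analysis:
  alpha: 1.0
  merge_rule: mean_log
  top_k: 400
  min_enrichment: 10.0
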