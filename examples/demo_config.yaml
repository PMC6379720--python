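# Demo run: simulated 3-species ortholog set with five planted codon
# pairs, sized so the planted pairs are recoverable as >3-sigma outliers.
#   paircons run-all --config examples/demo_config.yaml --out demo_out
seed: 11
code_table: 1
k_sigma: 3.0
pseudocount: auto
frames: [0, 1, 2]
min_species_conserved: 2
n_random_sets: 20
random_set_size: 5
simulate:
  n_species: 3
  n_genes: 250
  gene_length_range: [100, 300]
  substitution_prob: 0.25
  indel_prob: 0.0
  seed: 2024
  # codon-disjoint pairs so no planted pair inflates another's codon rates
  planted_pairs:
    - {pair: CGA-CGA, lock_fraction: 1.0, occurrences: 80}
    - {pair: CTC-CCG, lock_fraction: 1.0, occurrences: 80}
    - {pair: GTA-ATA, lock_fraction: 1.0, occurrences: 80}
    - {pair: GCG-CTG, lock_fraction: 1.0, occurrences: 80}
property_shifts:
  focal:
    protein_abundance: 0.1
    mrna_half_life: 0.7
    polysome_probs: [0.25, 0.40, 0.25, 0.08, 0.02]
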