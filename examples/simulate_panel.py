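"""Simulate a germplasm genotype panel with known ground truth.

Generates a 356-accession x 32-marker diploid SNP panel with two admixed
subpopulations and one group of seven duplicate accessions (identical
genotypes apart from missing calls), then prints the panel shape and the
planted structure. The truth record is what downstream recovery tests are
scored against.
"""

from radfp import SimulationConfig, simulate_genotypes

config = SimulationConfig(seed=1)
matrix, truth = simulate_genotypes(config)

print(f"panel: {matrix.n_accessions} accessions x {matrix.n_markers} markers")
print(f"missing calls: {matrix.missing_mask().mean():.3%} of cells")
print(f"duplicate group: {truth.duplicate_groups[0]}")
print("subpopulation sizes:",
      [truth.subpop_assignment.count(k) for k in range(config.k_subpops)])
# The duplicate group emulates sets of re-submitted varieties that genotyping
# cannot tell apart; the two subpopulations emulate the panel's structure.
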