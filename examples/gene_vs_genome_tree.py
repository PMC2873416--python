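"""Gene-tree / genome-tree discordance: the introgression signature.

Simulates a germplasm panel where the focal locus's cultivated haplotype
was swept and shared across both cultivated subpopulations
(introgression), while the rest of the genome keeps their separate
domestication histories.  The focal-locus NJ tree then clusters all
cultivars; the genome-wide SNP tree does not.
"""

from domestiscan import (SimScenario, distance_matrix, monophyly_check,
                         neighbor_joining, robinson_foulds,
                         simulate_germplasm_panel)

scn = SimScenario(seed=3, sweep=True, introgression=True)
alns, truths, genotypes = simulate_germplasm_panel(scn, n_loci=5)

focal = alns[0].subset(["japonica", "indica", "wild"])
cultivars = {s for s, p in focal.populations.items()
             if p in ("japonica", "indica")}

gene_tree = neighbor_joining(distance_matrix(focal, "jc"))
genome_tree = neighbor_joining(distance_matrix(genotypes,
                                               "allele_sharing"))

print(f"panel: {len(alns)} loci, genome matrix "
      f"{genotypes.genotypes.shape[0]} samples x "
      f"{genotypes.genotypes.shape[1]} SNPs")
print("cultivar monophyly, focal-locus gene tree:",
      monophyly_check(gene_tree, cultivars))
print("cultivar monophyly, genome-wide SNP tree:",
      monophyly_check(genome_tree, cultivars))
print("Robinson-Foulds distance between the trees:",
      robinson_foulds(gene_tree, genome_tree))
# True/False with a large RF distance is the discordance pattern:
# one locus telling a different history than the genome implies either
# introgression of that locus between subspecies or parallel selection.
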