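"""Per-gene divergence, Ka/Ks, region-class ANOVA and NJ topology check.

Simulates a five-taxon clade with class-specific rates (structural RNAs
slow, cytochrome oxidases slow among proteins, ND6/ATP8 fast, control
region fastest), then summarizes divergence per gene, tests whether
region classes differ in variability, and checks that neighbour joining
on the concatenated heavy-strand proteins recovers the true topology.
"""

import numpy as np

from mitocomp import (
    concat_and_nj,
    divergence_table,
    region_class_identities,
    region_variability_anova,
)
from mitocomp.simulate import SimulationConfig, simulate_clade

tree = "(((t1:0.2,t2:0.2):0.2,(t3:0.2,t4:0.2):0.2):0.1,t5:0.5);"
clade = simulate_clade(SimulationConfig(seed=4, n_taxa=5, tree_newick=tree))

table = divergence_table(clade.genomes,
                         genes=["COI", "COII", "ND2", "ND5", "ATP8", "ND6",
                                "12S rRNA", "tRNA-Phe", "CR"])
print(table[["nt_identity_mean", "aa_identity_mean", "kaks_mean",
             "variable_sites_pct"]].round(2).to_string())

groups = region_class_identities(clade.genomes)
f_stat, p = region_variability_anova(groups)
print("\nregion-class mean identities:",
      {k: round(float(np.mean(v)), 1) for k, v in groups.items()})
print(f"one-way ANOVA across region classes: F={f_stat:.1f}, p={p:.2e}")

check = concat_and_nj(clade.genomes,
                      reference_newick="(((t1,t2),(t3,t4)),t5);")
print(f"\nNJ on {len(check.genes_used)} concatenated H-strand proteins "
      f"(ND6 excluded): RF distance to truth = {check.rf_distance}")
print("Ka/Ks well below 1 across genes indicates purifying selection; "
      "CR < CDS < tRNA/rRNA identity mirrors the expected conservation order.")
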