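"""Rarefaction, alpha diversity, Bray-Curtis and gene-to-KO rollup.

Rarefies the stool genus table to an even depth, computes richness,
Shannon diversity (bits) and Pielou evenness per sample, a Bray-Curtis
distance matrix, and demonstrates the equal-splitting gene-to-KO count
aggregation.
"""

import pandas as pd

from vaxbiome import (
    CohortConfig,
    alpha_diversity,
    bray_curtis,
    generate_cohort,
    genes_to_kos,
    rarefy,
)

cohort = generate_cohort(CohortConfig(seed=3))
genus = cohort.features["stool_genus"]

rarefied, dropped = rarefy(genus, depth=5000, seed=0)
print(f"rarefied {len(rarefied)} samples to 5000 reads "
      f"({len(dropped)} below depth dropped)")

alpha = alpha_diversity(rarefied)
print("\nalpha diversity (first 4 samples):")
print(alpha.head(4).round(3).to_string())
print(f"\ncohort mean Shannon: {alpha.shannon.mean():.2f} bits; "
      f"mean evenness: {alpha.evenness.mean():.2f}")

dm = bray_curtis(rarefied.iloc[:5])
print("\nBray-Curtis distances among the first 5 samples:")
print(dm.round(2).to_string())

# gene -> KO aggregation: a gene in m KO groups contributes count/m to each
genes = pd.DataFrame({"geneA": [10], "geneB": [6]}, index=["sample1"])
mapping = pd.DataFrame({"gene_id": ["geneA", "geneA", "geneB"],
                        "ko_id": ["K00001", "K00002", "K00002"]})
kos, info = genes_to_kos(genes, mapping)
print("\ngene counts {geneA: 10, geneB: 6} with geneA in two KO groups ->")
print(kos.to_string())
print("mapped mass is conserved:", kos.sum(axis=1).item() == 16)
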