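"""Recover population structure from genotypes by stratification PCA.

Simulates four geographic groups - three source continents under
Balding-Nichols drift plus one admixed group, the layout that lets all
four separate on the first two principal components - normalizes each
site by its allele frequency, and scores how well k-means on PC1/PC2
recovers the true groups (adjusted Rand index: 1 = perfect).
"""

from mirvarmap.pca import eigenstrat_pca
from mirvarmap.simulate import four_group_cohort, pca_group_recovery

genotypes, labels = four_group_cohort(n_per_group=30, n_sites=300, seed=1)
print(f"genotype matrix: {genotypes.shape[0]} sites x {genotypes.shape[1]} samples, "
      f"4 groups of 30")

result = eigenstrat_pca(genotypes, k=4)
print(f"leading eigenvalues: {[round(float(e), 2) for e in result.eigenvalues]}")

ari = pca_group_recovery(result.coords[:, :2], labels, seed=0)
print(f"adjusted Rand index, k-means on PC1-PC2 vs truth: {ari:.3f}")
print("\n(>= 0.9 means the four geographic clusters are essentially")
print(" perfectly recovered from miRNA-variant genotypes alone)")
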