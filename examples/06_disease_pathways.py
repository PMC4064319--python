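"""Cross-tabulate the variant map against disease and pathway annotations.

Builds the population-by-population shared-variant matrix (all sites and
seed-region-only), the population-by-disease-category count matrix
(pleiotropy preserved: a variant counts toward every category its miRNA
is linked to), the percentage-of-pathways-affected profile, and the
agglomerative-clustering row order used for heat-map export.
"""

import tempfile

from mirvarmap import VariantMap, simulate_cohort, small_config
from mirvarmap.annotation import (
    DiseaseTable, PathwayTable, cluster_order, pathway_category_profile,
    population_disease_matrix, shared_variant_matrix,
)

with tempfile.TemporaryDirectory() as tmp:
    sim = simulate_cohort(small_config(seed=5), tmp)
    vmap = VariantMap.build(sim.vcf_path, sim.gff_path, sim.panel_path)
    disease = DiseaseTable.from_tsv(sim.disease_path)
    pathways = PathwayTable.from_tsv(sim.targets_path, sim.pathways_path)

pop_sites = vmap.population_site_sets()
seed_sites = {p.variant.site for p in vmap.profiles if p.region.is_seed}
m_all = shared_variant_matrix(pop_sites, scope="all")
m_seed = shared_variant_matrix(pop_sites, scope="seed-only", seed_sites=seed_sites)
print("shared variant sites between population pairs (diagonal = own count):")
print(m_all.matrix.to_string())
print(f"\nsame, restricted to seed-region sites (total {len(seed_sites)}):")
print(m_seed.matrix.to_string())

dm = population_disease_matrix(vmap.population_site_mirnas(), disease)
print("\nvariants per population linked to each disease category (first 5):")
print(dm.iloc[:, :5].to_string())
order = cluster_order(dm)
print(f"clustered row order for the heat map: {order.row_order}")

prof = pathway_category_profile(vmap.seed_mirnas_by_population(), pathways)
print("\npercent of pathways affected per category via seed-variant miRNAs (first 5):")
print(prof.iloc[:, :5].round(1).to_string())
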