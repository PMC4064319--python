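"""End-to-end orchestration: build the map, run every analysis, write tables.

The report bundle mirrors the published table layouts: a per-population
summary (subjects, SNVs, known SNVs, precursor/mature split, zygosity,
disease-linked miRNAs), the seed-variant table, the HWE-deviation table,
the shared-variant and disease/pathway matrices with clustering orders,
PCA coordinates, the allele-frequency spectrum, per-individual burden,
and a filter ledger recording counts at every drop step.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import annotation, pca, popgen
from .variants import HET, HOM_ALT, VariantMap, profiles_frame

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    vcf: Path
    gff: Path
    panel: Path
    out_dir: Path
    id_table: Optional[Path] = None
    disease: Optional[Path] = None
    targets: Optional[Path] = None
    pathways: Optional[Path] = None
    cohort_denominator: Optional[int] = None  # default: panel size
    alpha: float = 0.05
    yates: bool = True
    pca_components: int = 10
    pca_min_coverage: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0,1), got {self.alpha}")
        for name in ("vcf", "gff", "panel", "id_table", "disease", "targets", "pathways"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} input not found: {p}")


@dataclass
class ReportBundle:
    vmap: VariantMap
    population_summary: pd.DataFrame
    seed_table: pd.DataFrame
    hwe_table: pd.DataFrame
    region_counts: dict
    spectrum: pd.DataFrame
    burden: popgen.BurdenSummary
    shared_all: Optional[annotation.PopulationSimilarityMatrix] = None
    shared_seed: Optional[annotation.PopulationSimilarityMatrix] = None
    disease_matrix: Optional[pd.DataFrame] = None
    pathway_profile: Optional[pd.DataFrame] = None
    pca_coords: Optional[pd.DataFrame] = None
    pca_eigenvalues: Optional[np.ndarray] = None
    filter_ledger: dict = field(default_factory=dict)


def population_summary(vmap: VariantMap, disease_table=None) -> pd.DataFrame:
    """Per-population variant summary in the published layout.

    A site counts as "heterozygous" ("homozygous") in a population when
    at least one individual there carries it het (hom-alt); the two
    columns are not a partition.  "Precursor" sites lie in flank/loop
    regions, "mature" sites in seed/rom regions.
    """
    cols = vmap.panel.column_indices(vmap.matrix.samples)
    idx = {v.key: i for i, v in enumerate(vmap.matrix.variants)}
    rows = []
    for pop in vmap.panel.populations:
        ci = cols[pop]
        sites, known, mature_sites, precursor_sites = set(), set(), set(), set()
        het_sites, hom_sites, diseased_mirnas, diseases = set(), set(), set(), set()
        for p in vmap.profiles:
            sub = vmap.matrix.gt[idx[p.variant.key]][ci]
            has_het = bool((sub == HET).any())
            has_hom = bool((sub == HOM_ALT).any())
            if not (has_het or has_hom):
                continue
            site = p.variant.site
            sites.add(site)
            if not p.is_novel:
                known.add(site)
            if p.region.is_mature:
                mature_sites.add(site)
            else:
                precursor_sites.add(site)
            if has_het:
                het_sites.add(site)
            if has_hom:
                hom_sites.add(site)
            if disease_table is not None and p.premirna_id in disease_table.mirnas():
                diseased_mirnas.add(p.premirna_id)
                diseases |= disease_table.diseases_of(p.premirna_id)
        rows.append(
            {
                "group": vmap.panel.group_of_population(pop),
                "population": pop,
                "subjects": vmap.panel.population_sizes()[pop],
                "snvs": len(sites),
                "snvs_known": len(known),
                "snvs_precursor": len(precursor_sites),
                "snvs_mature": len(mature_sites),
                "n_heterozygous": len(het_sites),
                "n_homozygous": len(hom_sites),
                "mirnas_with_disease": len(diseased_mirnas),
                "diseases": len(diseases),
            }
        )
    return pd.DataFrame(rows)


def seed_variant_table(vmap: VariantMap) -> pd.DataFrame:
    """Seed-region variants in the published critical-regions layout."""
    rows = []
    for p in sorted(vmap.profiles, key=lambda q: (str(q.region), q.variant.chrom, q.variant.pos)):
        if not p.region.is_seed:
            continue
        rows.append(
            {
                "location": f"{p.variant.chrom}:{p.variant.pos}",
                "snv": f"{p.variant.ref}/{p.variant.alt}",
                "premirna": p.premirna_id,
                "mature": p.mature_id,
                "known_id": p.variant.known_id or "-",
                "region": str(p.region),
                "n_samples": p.n_carriers,
                "frequency_pct": round(p.pooled_frequency_pct, 4),
                "n_heterozygous": p.n_het,
                "n_homozygous": p.n_hom_alt,
            }
        )
    cols = ["location", "snv", "premirna", "mature", "known_id", "region",
            "n_samples", "frequency_pct", "n_heterozygous", "n_homozygous"]
    return pd.DataFrame(rows, columns=cols)


def hwe_deviation_table(vmap: VariantMap, alpha: float = 0.05, yates: bool = True) -> pd.DataFrame:
    """Significant HWE deviations per (population, variant) in table layout."""
    results = popgen.hwe_scan(
        vmap.matrix, vmap.panel, alpha=alpha, continuity_correction=yates, significant_only=True
    )
    premirna_of = {}
    region_of = {}
    for p in vmap.profiles:
        premirna_of.setdefault(p.variant.key, []).append(p.premirna_id)
        region_of.setdefault(p.variant.key, str(p.region))
    rows = []
    for r in results:
        key = r.variant_key
        rows.append(
            {
                "population": r.population,
                "location": f"{key[0]}:{key[1]}",
                "snv": f"{key[2]}/{key[3]}",
                "premirna": ";".join(sorted(set(premirna_of.get(key, [])))),
                "region": region_of.get(key, ""),
                "n_subjects": r.n_het + r.n_hom_alt,
                "n_heterozygous": r.n_het,
                "n_homozygous": r.n_hom_alt,
                "hwe_p_value": r.p_value,
            }
        )
    cols = ["population", "location", "snv", "premirna", "region",
            "n_subjects", "n_heterozygous", "n_homozygous", "hwe_p_value"]
    return pd.DataFrame(rows, columns=cols)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run every stage and write the report bundle under ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    vmap = VariantMap.build(
        config.vcf, config.gff, config.panel,
        id_table_path=config.id_table,
        total_n=config.cohort_denominator,
    )
    ledger = vmap.ledger.as_dict()
    ledger["profiled_variant_precursor_pairs"] = len(vmap.profiles)
    ledger["distinct_profiled_sites"] = len({p.variant.site for p in vmap.profiles})
    # retained records with no carrier anywhere are excluded from the map
    ledger["zero_carrier_sites"] = ledger["retained"] - ledger["distinct_profiled_sites"]
    logger.info("filter ledger: %s", ledger)

    disease_table = annotation.DiseaseTable.from_tsv(config.disease) if config.disease else None
    pathway_table = (
        annotation.PathwayTable.from_tsv(config.targets, config.pathways)
        if config.targets and config.pathways
        else None
    )

    profiles_frame(vmap.profiles).to_csv(out / "variant_profiles.tsv", sep="\t", index=False)

    summary = population_summary(vmap, disease_table)
    summary.to_csv(out / "population_summary.tsv", sep="\t", index=False)

    seed_tab = seed_variant_table(vmap)
    seed_tab.to_csv(out / "seed_variants.tsv", sep="\t", index=False)

    hwe_tab = hwe_deviation_table(vmap, alpha=config.alpha, yates=config.yates)
    hwe_tab.to_csv(out / "hwe_deviations.tsv", sep="\t", index=False)

    from .variants import region_occurrence_profile

    region_counts = region_occurrence_profile(vmap.profiles)
    pd.Series(region_counts, name="n_variants").rename_axis("region").to_csv(
        out / "region_occurrence.tsv", sep="\t"
    )

    freqs = popgen.profile_allele_frequencies(vmap.profiles, vmap.matrix)
    dedup: dict = {}
    idx = {v.key: i for i, v in enumerate(vmap.matrix.variants)}
    for p, f in zip(vmap.profiles, freqs):
        dedup[p.variant.key] = f
    site_freqs = [f for f in dedup.values() if f > 0]
    spectrum = pd.DataFrame(
        [
            {"bin_low": b.low, "bin_high": b.high, "n_variants": b.count}
            for b in popgen.af_spectrum(site_freqs)
        ]
    )
    spectrum.to_csv(out / "af_spectrum.tsv", sep="\t", index=False)

    burden = popgen.burden_per_individual(vmap.matrix, vmap.panel)
    burden.per_sample.rename_axis("sample").to_csv(out / "burden_per_sample.tsv", sep="\t")
    burden.group_stats.to_csv(out / "burden_by_group.tsv", sep="\t")

    bundle = ReportBundle(
        vmap=vmap,
        population_summary=summary,
        seed_table=seed_tab,
        hwe_table=hwe_tab,
        region_counts=region_counts,
        spectrum=spectrum,
        burden=burden,
        filter_ledger=ledger,
    )

    if vmap.profiles:
        pop_sites = vmap.population_site_sets()
        seed_sites = {
            p.variant.site for p in vmap.profiles if p.region.is_seed
        }
        bundle.shared_all = annotation.shared_variant_matrix(pop_sites, scope="all")
        bundle.shared_seed = annotation.shared_variant_matrix(
            pop_sites, scope="seed-only", seed_sites=seed_sites
        )
        bundle.shared_all.matrix.to_csv(out / "shared_variants_all.tsv", sep="\t")
        bundle.shared_seed.matrix.to_csv(out / "shared_variants_seed.tsv", sep="\t")
        if bundle.shared_all.matrix.shape[0] >= 2:
            order = annotation.cluster_order(bundle.shared_all.matrix)
            (out / "shared_variants_all.order.json").write_text(
                json.dumps({"rows": list(map(str, order.row_order)),
                            "cols": list(map(str, order.col_order))}, indent=1)
            )

        if disease_table is not None:
            pairs = vmap.population_site_mirnas()
            bundle.disease_matrix = annotation.population_disease_matrix(pairs, disease_table)
            bundle.disease_matrix.to_csv(out / "population_disease_matrix.tsv", sep="\t")
            mp, mc = annotation.hive_edges(pairs, disease_table=disease_table)
            mp.to_csv(out / "hive_mirna_population.tsv", sep="\t", index=False)
            mc.to_csv(out / "hive_mirna_disease_category.tsv", sep="\t", index=False)
        if pathway_table is not None:
            seed_mirnas = vmap.seed_mirnas_by_population()
            bundle.pathway_profile = annotation.pathway_category_profile(seed_mirnas, pathway_table)
            bundle.pathway_profile.to_csv(out / "pathway_category_profile.tsv", sep="\t")

    # stratification PCA over sites with >=1 carrier (and coverage when present)
    site_keys = list(dict.fromkeys(p.variant.key for p in vmap.profiles))
    if len(site_keys) >= 2 and vmap.matrix.n_samples >= 3:
        rows = [idx[k] for k in site_keys]
        carriers = [
            int(((vmap.matrix.gt[r] == HET) | (vmap.matrix.gt[r] == HOM_ALT)).sum()) for r in rows
        ]
        coverage = None
        if vmap.matrix.depth is not None:
            coverage = [float(np.nanmean(vmap.matrix.depth[r])) for r in rows]
        keep = pca.filter_sites_for_pca(
            carriers, coverage, min_coverage=config.pca_min_coverage
        )
        if keep.size >= 2:
            dosage = vmap.matrix.dosage()[[rows[i] for i in keep]]
            result = pca.eigenstrat_pca(dosage, k=config.pca_components, samples=vmap.matrix.samples)
            bundle.pca_coords = pca.coordinates_frame(result, vmap.panel)
            bundle.pca_eigenvalues = result.eigenvalues
            bundle.pca_coords.to_csv(out / "pca_coordinates.tsv", sep="\t", index=False)
            pd.Series(result.eigenvalues, name="eigenvalue").rename_axis("component").to_csv(
                out / "pca_eigenvalues.tsv", sep="\t"
            )

    (out / "filter_ledger.json").write_text(json.dumps(ledger, indent=1) + "\n")
    return bundle
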