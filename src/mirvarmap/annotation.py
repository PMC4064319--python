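"""Disease and pathway cross-tabulation of the variant map.

Joins the per-population variant presence against miRNA-disease and
miRNA-target/pathway annotation tables to build:

* population x population shared-variant matrices (all sites or
  seed-region sites only);
* population x disease-category variant-count matrices, preserving
  pleiotropy (a variant in a miRNA linked to several disease categories
  counts toward each of them);
* population x pathway-category "percentage of pathways affected"
  profiles (a pathway counts as affected in a population when at least
  one of its genes is targeted by a miRNA carrying a seed variant there);
* weighted bipartite edge lists (miRNA-population, miRNA-category) for
  hive-plot rendering by external tools;
* agglomerative-clustering row/column orders for heat-map export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)


class AnnotationError(ValueError):
    pass


@dataclass
class DiseaseTable:
    """miRNA -> diseases, each disease in exactly one category."""

    links: pd.DataFrame  # columns: mirna, disease, category

    def __post_init__(self) -> None:
        required = {"mirna", "disease", "category"}
        if not required.issubset(self.links.columns):
            raise AnnotationError(f"disease table needs columns {sorted(required)}")
        if (self.links["disease"].astype(str).str.len() == 0).any() or self.links["disease"].isna().any():
            raise AnnotationError("empty disease names are not allowed")
        if self.links["category"].isna().any():
            raise AnnotationError("every disease must carry a category")
        conflicts = self.links.groupby("disease")["category"].nunique()
        bad = conflicts[conflicts > 1]
        if len(bad):
            raise AnnotationError(f"diseases mapped to several categories: {list(bad.index)}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DiseaseTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    @property
    def categories(self) -> list[str]:
        return sorted(self.links["category"].unique())

    def categories_of(self, mirna: str) -> set[str]:
        return set(self.links.loc[self.links["mirna"] == mirna, "category"])

    def diseases_of(self, mirna: str) -> set[str]:
        return set(self.links.loc[self.links["mirna"] == mirna, "disease"])

    def mirnas(self) -> set[str]:
        return set(self.links["mirna"])


@dataclass
class PathwayTable:
    """miRNA -> target genes; gene -> pathways; pathway -> one category."""

    targets: pd.DataFrame  # columns: mirna, gene
    pathways: pd.DataFrame  # columns: gene, pathway, category

    def __post_init__(self) -> None:
        if not {"mirna", "gene"}.issubset(self.targets.columns):
            raise AnnotationError("target table needs columns mirna, gene")
        if not {"gene", "pathway", "category"}.issubset(self.pathways.columns):
            raise AnnotationError("pathway table needs columns gene, pathway, category")
        per_pathway = self.pathways.groupby("pathway")["category"].nunique()
        bad = per_pathway[per_pathway > 1]
        if len(bad):
            raise AnnotationError(f"pathways with several categories: {list(bad.index)}")

    @classmethod
    def from_tsv(cls, targets_path: str | Path, pathways_path: str | Path) -> "PathwayTable":
        return cls(
            targets=pd.read_csv(targets_path, sep="\t", dtype=str),
            pathways=pd.read_csv(pathways_path, sep="\t", dtype=str),
        )

    def genes_of(self, mirna: str) -> set[str]:
        return set(self.targets.loc[self.targets["mirna"] == mirna, "gene"])

    def pathway_category(self) -> dict[str, str]:
        return dict(self.pathways.drop_duplicates("pathway")[["pathway", "category"]].values)

    def pathways_of_gene(self, gene: str) -> set[str]:
        return set(self.pathways.loc[self.pathways["gene"] == gene, "pathway"])

    def pathways_per_category(self) -> pd.Series:
        return (
            self.pathways.drop_duplicates("pathway").groupby("category")["pathway"].size()
        )


@dataclass
class PopulationSimilarityMatrix:
    """Symmetric population x population shared-variant-count matrix."""

    matrix: pd.DataFrame
    scope: str  # "all" or "seed-only"

    def validate(self) -> None:
        m = self.matrix.values
        if not np.array_equal(m, m.T):
            raise AnnotationError("similarity matrix must be symmetric")
        diag = np.diag(m)
        for i in range(m.shape[0]):
            for j in range(m.shape[1]):
                if i != j and m[i, j] > min(diag[i], diag[j]):
                    raise AnnotationError("off-diagonal exceeds its diagonal bound")


def shared_variant_matrix(
    pop_sites: Mapping[str, set],
    scope: str = "all",
    seed_sites: Optional[set] = None,
    populations: Optional[Sequence[str]] = None,
) -> PopulationSimilarityMatrix:
    """Pairwise counts of shared variant sites between populations.

    ``pop_sites`` maps population -> set of (chrom, pos, alt) site keys
    present (>=1 carrier) in that population.  With ``scope='seed-only'``
    the sets are first intersected with ``seed_sites``.
    """
    if scope not in ("all", "seed-only"):
        raise AnnotationError(f"scope must be 'all' or 'seed-only', got {scope!r}")
    pops = list(populations) if populations is not None else list(pop_sites)
    missing = [p for p in pops if p not in pop_sites]
    if missing:
        raise AnnotationError(f"unknown population(s): {missing}")
    sets = {p: set(pop_sites[p]) for p in pops}
    if scope == "seed-only":
        if seed_sites is None:
            raise AnnotationError("seed-only scope requires seed_sites")
        sets = {p: s & seed_sites for p, s in sets.items()}
    m = pd.DataFrame(0, index=pops, columns=pops, dtype=int)
    for i, a in enumerate(pops):
        for b in pops[i:]:
            shared = len(sets[a] & sets[b])
            m.loc[a, b] = shared
            m.loc[b, a] = shared
    out = PopulationSimilarityMatrix(matrix=m, scope=scope)
    out.validate()
    return out


def population_disease_matrix(
    pop_site_mirnas: Mapping[str, Iterable[tuple]],
    disease_table: DiseaseTable,
) -> pd.DataFrame:
    """Population x disease-category counts of variant positions.

    An entry (P, D) counts the distinct variant positions present in
    population P whose miRNA is linked to at least one disease of
    category D.  A variant whose miRNA is linked to several categories
    increments each of them (pleiotropy preserved).  miRNAs absent from
    the disease table contribute nothing (logged).
    """
    categories = disease_table.categories
    pops = list(pop_site_mirnas)
    cat_cache: dict[str, set[str]] = {}
    unknown: set[str] = set()
    m = pd.DataFrame(0, index=pops, columns=categories, dtype=int)
    known_mirnas = disease_table.mirnas()
    for pop, pairs in pop_site_mirnas.items():
        per_cat: dict[str, set] = {c: set() for c in categories}
        for site, mirna in pairs:
            if mirna not in known_mirnas:
                unknown.add(mirna)
                continue
            if mirna not in cat_cache:
                cat_cache[mirna] = disease_table.categories_of(mirna)
            for c in cat_cache[mirna]:
                per_cat[c].add(site)
        for c in categories:
            m.loc[pop, c] = len(per_cat[c])
    if unknown:
        logger.info("%d miRNA(s) absent from disease table: %s", len(unknown), sorted(unknown)[:10])
    return m


def pathway_category_profile(
    pop_seed_mirnas: Mapping[str, set],
    pathway_table: PathwayTable,
) -> pd.DataFrame:
    """Population x pathway-category percentage of pathways affected.

    A pathway is affected in population P when >=1 of its genes is a
    target of a miRNA carrying a seed-region variant present in P; the
    entry is 100 * affected pathways / pathways in the category.
    """
    pathway_cat = pathway_table.pathway_category()
    per_cat_total = pathway_table.pathways_per_category()
    categories = list(per_cat_total.index)
    pops = list(pop_seed_mirnas)
    out = pd.DataFrame(0.0, index=pops, columns=categories)
    for pop, mirnas in pop_seed_mirnas.items():
        genes: set[str] = set()
        for m in mirnas:
            genes |= pathway_table.genes_of(m)
        affected: set[str] = set()
        for g in genes:
            affected |= pathway_table.pathways_of_gene(g)
        hit_per_cat: dict[str, int] = {c: 0 for c in categories}
        for pw in affected:
            hit_per_cat[pathway_cat[pw]] += 1
        for c in categories:
            total = per_cat_total[c]
            out.loc[pop, c] = 100.0 * hit_per_cat[c] / total if total else np.nan
    return out


def hive_edges(
    pop_site_mirnas: Mapping[str, Iterable[tuple]],
    disease_table: Optional[DiseaseTable] = None,
    pathway_table: Optional[PathwayTable] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Weighted bipartite edge lists for hive-plot rendering.

    Returns (miRNA-population edges, miRNA-category edges).  The
    miRNA-population weight is the number of distinct variant sites of
    that miRNA present in the population; the miRNA-category weight is
    the number of distinct sites (cohort-wide) in that miRNA, emitted
    once per linked category, so summing miRNA-population weights over
    the miRNAs linked to a category reproduces the corresponding
    population x category matrix entries.
    """
    mp_rows = []
    sites_per_mirna: dict[str, set] = {}
    for pop, pairs in pop_site_mirnas.items():
        per_mirna: dict[str, set] = {}
        for site, mirna in pairs:
            per_mirna.setdefault(mirna, set()).add(site)
            sites_per_mirna.setdefault(mirna, set()).add(site)
        for mirna, sites in sorted(per_mirna.items()):
            mp_rows.append({"mirna": mirna, "population": pop, "weight": len(sites)})
    mp = pd.DataFrame(mp_rows, columns=["mirna", "population", "weight"])

    mc_rows = []
    for mirna, sites in sorted(sites_per_mirna.items()):
        if disease_table is not None:
            cats = disease_table.categories_of(mirna)
        elif pathway_table is not None:
            pcat = pathway_table.pathway_category()
            cats = set()
            for g in pathway_table.genes_of(mirna):
                cats |= {pcat[pw] for pw in pathway_table.pathways_of_gene(g)}
        else:
            cats = set()
        for c in sorted(cats):
            mc_rows.append({"mirna": mirna, "category": c, "weight": len(sites)})
    mc = pd.DataFrame(mc_rows, columns=["mirna", "category", "weight"])
    return mp, mc


@dataclass
class ClusterOrder:
    row_order: list
    col_order: list
    row_linkage: Optional[np.ndarray]
    col_linkage: Optional[np.ndarray]


def cluster_order(matrix: pd.DataFrame, method: str = "complete") -> ClusterOrder:
    """Agglomerative clustering (Euclidean distances) row/column ordering.

    Returns leaf orders for heat-map export plus the merge trees.  A
    constant matrix yields an arbitrary but deterministic order.
    """
    if matrix.shape[0] < 2:
        raise AnnotationError("need at least 2 rows to cluster")
    values = matrix.to_numpy(dtype=float)
    row_link = linkage(pdist(values, metric="euclidean"), method=method)
    row_order = [matrix.index[i] for i in leaves_list(row_link)]
    if matrix.shape[1] >= 2:
        col_link = linkage(pdist(values.T, metric="euclidean"), method=method)
        col_order = [matrix.columns[i] for i in leaves_list(col_link)]
    else:
        col_link = None
        col_order = list(matrix.columns)
    return ClusterOrder(row_order, col_order, row_link, col_link)
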