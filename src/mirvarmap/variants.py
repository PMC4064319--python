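"""Cohort variant ingestion and per-variant profiles.

Reads a multi-sample VCF, keeps biallelic SNVs falling inside annotated
pre-miRNA precursors, and summarizes each variant across the pooled
cohort: carrier count, zygosity breakdown, pooled carrier frequency (in
percent of the full cohort), mean read depth, mean alternative-allele
read fraction over heterozygous calls, novelty versus a known-variant
table, and the substructure region hit.

Conventions (chosen to reproduce the published table arithmetic):

* the pooled-frequency denominator is the full multi-population cohort
  (1 carrier of 1,152 -> 0.0868%), not the within-population size;
* missing genotypes count as non-carriers for frequencies but are
  excluded from genotype-count statistics;
* half-calls (``./1``) are treated as missing;
* a variant overlapped by several precursors yields one profile per
  precursor.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from intervaltree import IntervalTree

from .structure import (
    PositionOutsidePrecursor,
    PreMiRNA,
    RegionLabel,
    SubstructureMap,
    build_substructure_maps,
)

logger = logging.getLogger(__name__)

# genotype codes
HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

_BASES = frozenset("ACGT")


class PanelError(ValueError):
    """Sample panel does not cover the VCF samples."""


class IdTableError(ValueError):
    """Known-variant table is internally inconsistent."""


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic single-nucleotide variant."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    known_id: Optional[str] = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def site(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.alt)


@dataclass
class GenotypeMatrix:
    """Variant-by-sample genotype calls with optional per-call depth/AD."""

    variants: list[VariantRecord]
    samples: list[str]
    gt: np.ndarray  # (n_variants, n_samples) int8; codes above
    depth: Optional[np.ndarray] = None  # float, NaN when absent
    alt_fraction: Optional[np.ndarray] = None  # alt reads / total AD reads, NaN when absent

    def __post_init__(self) -> None:
        expected = (len(self.variants), len(self.samples))
        if self.gt.shape != expected:
            raise ValueError(f"genotype matrix shape {self.gt.shape} != {expected}")
        bad = ~np.isin(self.gt, (HOM_REF, HET, HOM_ALT, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be in {0,1,2,-1}")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def dosage(self) -> np.ndarray:
        """0/1/2 alt-allele dosage with missing as NaN (for PCA)."""
        d = self.gt.astype(float)
        d[self.gt == MISSING] = np.nan
        return d


@dataclass
class PopulationPanel:
    """sample -> population -> geographic group assignment."""

    samples: list[str]
    population: dict[str, str]
    group: dict[str, str]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PopulationPanel":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"sample", "population", "group"}
        if not required.issubset(df.columns):
            raise PanelError(f"panel must have columns {sorted(required)}; got {list(df.columns)}")
        if df["sample"].duplicated().any():
            dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
            raise PanelError(f"duplicate panel samples: {dups}")
        return cls(
            samples=df["sample"].tolist(),
            population=dict(zip(df["sample"], df["population"])),
            group=dict(zip(df["sample"], df["group"])),
        )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.population[s], None)
        return list(seen)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.group[s], None)
        return list(seen)

    def population_sizes(self) -> dict[str, int]:
        return dict(Counter(self.population[s] for s in self.samples))

    def group_of_population(self, pop: str) -> str:
        for s in self.samples:
            if self.population[s] == pop:
                return self.group[s]
        raise KeyError(pop)

    def samples_of(self, pop: str) -> list[str]:
        return [s for s in self.samples if self.population[s] == pop]

    def column_indices(self, vcf_samples: Sequence[str]) -> dict[str, np.ndarray]:
        """Per-population column index arrays into the VCF sample order."""
        col = {s: i for i, s in enumerate(vcf_samples)}
        return {
            pop: np.array([col[s] for s in self.samples_of(pop)], dtype=int)
            for pop in self.populations
        }

    def validate_vcf_samples(self, vcf_samples: Sequence[str]) -> None:
        orphans = [s for s in vcf_samples if s not in self.population]
        if orphans:
            raise PanelError(f"VCF samples missing from panel: {orphans}")


@dataclass(frozen=True)
class VariantProfile:
    """Pooled-cohort summary of one variant within one precursor."""

    variant: VariantRecord
    region: RegionLabel
    premirna_id: str
    mature_id: Optional[str]
    n_carriers: int
    n_het: int
    n_hom_alt: int
    n_hom_ref: int
    n_missing: int
    pooled_frequency_pct: float
    mean_coverage: Optional[float]
    mean_alt_fraction: Optional[float]
    is_novel: bool

    def __post_init__(self) -> None:
        if self.n_carriers != self.n_het + self.n_hom_alt:
            raise ValueError("n_carriers must equal n_het + n_hom_alt")
        if not (0.0 <= self.pooled_frequency_pct <= 100.0):
            raise ValueError("pooled frequency must be a percentage")
        if self.mean_alt_fraction is not None and not (0.0 <= self.mean_alt_fraction <= 1.0):
            raise ValueError("mean_alt_fraction must lie in [0,1]")


@dataclass
class FilterLedger:
    """Counts at every filtering step, for the pipeline's drop-reasons log."""

    records_read: int = 0
    alleles_seen: int = 0
    dropped_non_snv: int = 0
    dropped_outside_precursor: int = 0
    retained: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def _precursor_trees(premirnas: Sequence[PreMiRNA]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for pre in premirnas:
        iv = pre.interval
        trees.setdefault(iv.chrom, IntervalTree())[iv.start : iv.end + 1] = pre
    return trees


def overlapping_precursors(
    premirnas: Sequence[PreMiRNA], chrom: str, pos: int,
) -> list[PreMiRNA]:
    """Precursors whose interval contains (chrom, pos)."""
    trees = _precursor_trees(premirnas)
    if chrom not in trees:
        return []
    return sorted((hit.data for hit in trees[chrom][pos]), key=lambda p: p.id)


def read_cohort_vcf(
    path: str | Path,
    premirnas: Sequence[PreMiRNA],
) -> tuple[GenotypeMatrix, FilterLedger]:
    """Read a multi-sample VCF, keeping biallelic SNVs inside precursors.

    Multiallelic records are split into one biallelic record per SNV
    alternative allele; non-SNV alleles are dropped and counted in the
    returned :class:`FilterLedger`.
    """
    trees = _precursor_trees(premirnas)
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    ledger = FilterLedger()

    variants: list[VariantRecord] = []
    gt_rows: list[np.ndarray] = []
    dp_rows: list[np.ndarray] = []
    af_rows: list[np.ndarray] = []
    any_dp = False
    any_ad = False

    for rec in vcf:
        ledger.records_read += 1
        if "GT" not in (rec.FORMAT or []):
            raise ValueError(f"record {rec.CHROM}:{rec.POS} has no GT field")
        geno = np.array([g[:2] for g in rec.genotypes], dtype=int)
        dp = rec.format("DP")
        ad = rec.format("AD")
        for alt_index, alt in enumerate(rec.ALT, start=1):
            ledger.alleles_seen += 1
            if len(rec.REF) != 1 or len(alt) != 1 or rec.REF not in _BASES or alt not in _BASES:
                ledger.dropped_non_snv += 1
                continue
            chrom = rec.CHROM
            if chrom not in trees or not trees[chrom][rec.POS]:
                ledger.dropped_outside_precursor += 1
                continue
            alt_count = (geno == alt_index).sum(axis=1)
            codes = np.where(alt_count >= 2, HOM_ALT, np.where(alt_count == 1, HET, HOM_REF))
            codes = np.where((geno < 0).any(axis=1), MISSING, codes).astype(np.int8)
            variants.append(VariantRecord(chrom=chrom, pos=rec.POS, ref=rec.REF, alt=alt))
            gt_rows.append(codes)

            if dp is not None:
                any_dp = True
                row = dp.astype(float).reshape(len(samples), -1)[:, 0]
                row[row < 0] = np.nan
                dp_rows.append(row)
            else:
                dp_rows.append(np.full(len(samples), np.nan))
            if ad is not None and ad.shape[1] > alt_index:
                any_ad = True
                adf = ad.astype(float)
                adf[adf < 0] = np.nan
                total = np.nansum(adf, axis=1)
                with np.errstate(invalid="ignore", divide="ignore"):
                    frac = adf[:, alt_index] / total
                af_rows.append(frac)
            else:
                af_rows.append(np.full(len(samples), np.nan))
            ledger.retained += 1

    gt = (
        np.vstack(gt_rows) if gt_rows else np.empty((0, len(samples)), dtype=np.int8)
    )
    matrix = GenotypeMatrix(
        variants=variants,
        samples=samples,
        gt=gt,
        depth=np.vstack(dp_rows) if (dp_rows and any_dp) else None,
        alt_fraction=np.vstack(af_rows) if (af_rows and any_ad) else None,
    )
    if ledger.dropped_non_snv:
        logger.info("dropped %d non-SNV alleles", ledger.dropped_non_snv)
    return matrix, ledger


def write_cohort_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write the retained records back out as an uncompressed VCF 4.2 file."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    for chrom in dict.fromkeys(v.chrom for v in matrix.variants):
        header.contigs.add(chrom)
    for s in matrix.samples:
        header.add_sample(s)
    gt_tuples = {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        order = sorted(range(matrix.n_variants), key=lambda i: (matrix.variants[i].chrom, matrix.variants[i].pos, matrix.variants[i].alt))
        for i in order:
            v = matrix.variants[i]
            rec = out.new_record(contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt))
            if v.known_id:
                rec.id = v.known_id
            for j, s in enumerate(matrix.samples):
                rec.samples[s]["GT"] = gt_tuples[int(matrix.gt[i, j])]
                if matrix.depth is not None and np.isfinite(matrix.depth[i, j]):
                    rec.samples[s]["DP"] = int(matrix.depth[i, j])
            out.write(rec)


def load_id_table(path: str | Path) -> dict[tuple[str, int, str, str], str]:
    """Load a dbSNP-style (chrom, pos, ref, alt) -> rsID table from TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "pos": int, "ref": str, "alt": str, "rsid": str})
    required = {"chrom", "pos", "ref", "alt", "rsid"}
    if not required.issubset(df.columns):
        raise IdTableError(f"id table must have columns {sorted(required)}")
    table: dict[tuple[str, int, str, str], str] = {}
    for row in df.itertuples(index=False):
        key = (row.chrom, int(row.pos), row.ref, row.alt)
        if key in table and table[key] != row.rsid:
            raise IdTableError(f"conflicting IDs for {key}: {table[key]} vs {row.rsid}")
        table[key] = row.rsid
    return table


def annotate_known(
    variants: Iterable[VariantRecord],
    id_table: Mapping[tuple[str, int, str, str], str],
) -> list[VariantRecord]:
    """Attach rsIDs; matching requires allele agreement, not just position."""
    out = []
    for v in variants:
        out.append(
            VariantRecord(v.chrom, v.pos, v.ref, v.alt, known_id=id_table.get(v.key))
        )
    return out


def profile_variant(
    variant: VariantRecord,
    gt_row: np.ndarray,
    total_n: int,
    *,
    region: RegionLabel,
    premirna_id: str,
    mature_id: Optional[str] = None,
    depth_row: Optional[np.ndarray] = None,
    alt_fraction_row: Optional[np.ndarray] = None,
) -> VariantProfile:
    """Summarize one variant over the pooled cohort.

    Carriers are samples with at least one alternative allele; the pooled
    frequency is ``100 * n_carriers / total_n`` with the *full* cohort as
    denominator.  Mean alt-read fraction is averaged over heterozygous
    calls that carry allelic-depth information (None when absent).
    """
    if total_n <= 0:
        raise ValueError("total_n must be positive")
    gt_row = np.asarray(gt_row)
    n_het = int((gt_row == HET).sum())
    n_hom_alt = int((gt_row == HOM_ALT).sum())
    n_hom_ref = int((gt_row == HOM_REF).sum())
    n_missing = int((gt_row == MISSING).sum())

    mean_cov = None
    if depth_row is not None and np.isfinite(depth_row).any():
        mean_cov = float(np.nanmean(depth_row))
    mean_af = None
    if alt_fraction_row is not None:
        het_af = alt_fraction_row[gt_row == HET]
        het_af = het_af[np.isfinite(het_af)]
        if het_af.size:
            mean_af = float(het_af.mean())

    return VariantProfile(
        variant=variant,
        region=region,
        premirna_id=premirna_id,
        mature_id=mature_id,
        n_carriers=n_het + n_hom_alt,
        n_het=n_het,
        n_hom_alt=n_hom_alt,
        n_hom_ref=n_hom_ref,
        n_missing=n_missing,
        pooled_frequency_pct=100.0 * (n_het + n_hom_alt) / total_n,
        mean_coverage=mean_cov,
        mean_alt_fraction=mean_af,
        is_novel=variant.known_id is None,
    )


def build_profiles(
    matrix: GenotypeMatrix,
    premirnas: Sequence[PreMiRNA],
    total_n: Optional[int] = None,
    maps: Optional[Mapping[str, SubstructureMap]] = None,
    drop_uncarried: bool = True,
) -> list[VariantProfile]:
    """One profile per (variant, overlapping precursor).

    Variants with zero carriers in the cohort are excluded from the map
    (they carry no information about observed variability).
    """
    if maps is None:
        maps = build_substructure_maps(premirnas)
    trees = _precursor_trees(premirnas)
    n = total_n if total_n is not None else matrix.n_samples
    profiles: list[VariantProfile] = []
    for i, v in enumerate(matrix.variants):
        hits = sorted((h.data for h in trees.get(v.chrom, IntervalTree())[v.pos]), key=lambda p: p.id)
        for pre in hits:
            smap = maps[pre.id]
            try:
                seg = smap.locate_segment(v.pos)
            except PositionOutsidePrecursor:  # pragma: no cover - tree guarantees containment
                continue
            prof = profile_variant(
                v,
                matrix.gt[i],
                n,
                region=seg.label,
                premirna_id=pre.id,
                mature_id=seg.mature_id,
                depth_row=matrix.depth[i] if matrix.depth is not None else None,
                alt_fraction_row=matrix.alt_fraction[i] if matrix.alt_fraction is not None else None,
            )
            if drop_uncarried and prof.n_carriers == 0:
                continue
            profiles.append(prof)
    return profiles


def region_occurrence_profile(profiles: Iterable[VariantProfile]) -> dict[str, int]:
    """Variant counts per substructure label ("(mix)" variants tallied separately)."""
    return dict(Counter(str(p.region) for p in profiles))


def profiles_frame(profiles: Sequence[VariantProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        rows.append(
            {
                "chrom": p.variant.chrom,
                "pos": p.variant.pos,
                "ref": p.variant.ref,
                "alt": p.variant.alt,
                "known_id": p.variant.known_id,
                "premirna": p.premirna_id,
                "mature": p.mature_id,
                "region": str(p.region),
                "n_carriers": p.n_carriers,
                "n_het": p.n_het,
                "n_hom_alt": p.n_hom_alt,
                "frequency_pct": round(p.pooled_frequency_pct, 4),
                "mean_coverage": p.mean_coverage,
                "mean_alt_fraction": p.mean_alt_fraction,
                "is_novel": p.is_novel,
            }
        )
    cols = [
        "chrom", "pos", "ref", "alt", "known_id", "premirna", "mature", "region",
        "n_carriers", "n_het", "n_hom_alt", "frequency_pct", "mean_coverage",
        "mean_alt_fraction", "is_novel",
    ]
    return pd.DataFrame(rows, columns=cols)


@dataclass
class VariantMap:
    """The assembled cohort variant map: inputs joined and profiled."""

    premirnas: list[PreMiRNA]
    maps: dict[str, SubstructureMap]
    matrix: GenotypeMatrix
    panel: PopulationPanel
    profiles: list[VariantProfile]
    ledger: FilterLedger

    @classmethod
    def build(
        cls,
        vcf_path: str | Path,
        gff_path: str | Path,
        panel_path: str | Path,
        id_table_path: Optional[str | Path] = None,
        total_n: Optional[int] = None,
    ) -> "VariantMap":
        from .structure import parse_mirna_gff

        premirnas = parse_mirna_gff(gff_path)
        maps = build_substructure_maps(premirnas)
        matrix, ledger = read_cohort_vcf(vcf_path, premirnas)
        panel = PopulationPanel.from_tsv(panel_path)
        panel.validate_vcf_samples(matrix.samples)
        if id_table_path is not None:
            table = load_id_table(id_table_path)
            matrix.variants = annotate_known(matrix.variants, table)
        profiles = build_profiles(matrix, premirnas, total_n=total_n or panel.n_samples, maps=maps)
        return cls(premirnas, maps, matrix, panel, profiles, ledger)

    # ---- population-level views used by the disease/pathway joins ----

    def _pop_columns(self) -> dict[str, np.ndarray]:
        return self.panel.column_indices(self.matrix.samples)

    def _variant_index(self) -> dict[tuple[str, int, str, str], int]:
        return {v.key: i for i, v in enumerate(self.matrix.variants)}

    def population_site_sets(self, seed_only: bool = False) -> dict[str, set]:
        """Per population: set of (chrom, pos, alt) sites with >=1 carrier."""
        idx = self._variant_index()
        cols = self._pop_columns()
        out: dict[str, set] = {pop: set() for pop in self.panel.populations}
        for p in self.profiles:
            if seed_only and not p.region.is_seed:
                continue
            row = self.matrix.gt[idx[p.variant.key]]
            for pop, ci in cols.items():
                sub = row[ci]
                if ((sub == HET) | (sub == HOM_ALT)).any():
                    out[pop].add(p.variant.site)
        return out

    def population_site_mirnas(self, seed_only: bool = False) -> dict[str, set]:
        """Per population: set of ((chrom,pos,alt), premirna_id) pairs present."""
        idx = self._variant_index()
        cols = self._pop_columns()
        out: dict[str, set] = {pop: set() for pop in self.panel.populations}
        for p in self.profiles:
            if seed_only and not p.region.is_seed:
                continue
            row = self.matrix.gt[idx[p.variant.key]]
            for pop, ci in cols.items():
                sub = row[ci]
                if ((sub == HET) | (sub == HOM_ALT)).any():
                    out[pop].add((p.variant.site, p.premirna_id))
        return out

    def seed_mirnas_by_population(self) -> dict[str, set]:
        """Per population: miRNA precursors with a seed-region variant present."""
        return {
            pop: {mirna for (_site, mirna) in pairs}
            for pop, pairs in self.population_site_mirnas(seed_only=True).items()
        }
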