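"""Synthetic multi-population cohorts with known ground truth.

Emulates the structure of a worldwide resequencing cohort so every
pipeline stage is testable without controlled-access downloads:

* precursor hairpins with 0-2 mature arms on random strands, written as
  miRBase-dialect GFF3;
* variant sites placed with region-dependent density (seed lowest, arm
  flanks highest, mirroring the observed occurrence gradient across the
  hairpin substructures);
* per-population allele frequencies drawn from the Balding-Nichols
  model: p_k ~ Beta(p0(1-F)/F, (1-p0)(1-F)/F) around an ancestral
  frequency p0, with divergence F per population;
* genotypes drawn under Hardy-Weinberg proportions, optionally distorted
  at planted sites by an inbreeding coefficient f (excess homozygosity;
  negative f gives heterozygote excess);
* extra sites private to high-diversity groups (``density_scale``),
  reproducing the higher per-individual burden of African cohorts;
* randomized disease and target/pathway annotation taxonomies.

The default configuration mirrors a worldwide survey design: 15
populations totalling 1,152 individuals over 4 geographic groups, 720
precursor hairpins, ~40x mean depth, 35% of sites absent from the
known-variant table.  A fixed seed makes the emitted files byte-identical
across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import structure
from .structure import GenomicInterval, MatureMiRNA, PreMiRNA, decompose
from .popgen import hwe_test

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    size: int
    fst: float  # Balding-Nichols divergence from the ancestral pool
    group: str  # geographic group (EUR/ASI/AMR/AFR in the default cohort)
    density_scale: float = 1.0  # >1 adds sites private to this group


@dataclass
class SimulationConfig:
    populations: list[PopulationSpec]
    n_precursors: int = 720
    # hairpin geometry (uniform integer ranges, inclusive)
    flank_length: tuple[int, int] = (6, 14)
    arm_length: tuple[int, int] = (20, 23)
    loop_length: tuple[int, int] = (8, 16)
    # probability that a precursor is annotated with one / zero mature arms
    p_single_arm: float = 0.2
    p_no_arm: float = 0.05
    # per-base site probability = per_base_rate * region_density[class];
    # defaults sized so the worldwide cohort yields ~530 *observed* sites
    # (generated sites with no carrier anywhere never enter the map)
    per_base_rate: float = 0.0166
    region_density: dict = field(
        default_factory=lambda: {"seed": 0.3, "rom": 0.5, "loop": 0.6, "mir": 1.0}
    )
    # two-component ancestral frequency spectrum.  Rare sites model recent
    # mutations: very low frequency, *no* population drift applied (a new
    # mutation has not equilibrated), observed mostly as heterozygous
    # singletons.  Common sites model standing variation and get the full
    # Balding-Nichols per-population draw.  The default mixture reproduces
    # a worldwide cohort in which ~28 variant sites are carried per
    # individual and ~3/4 of observed sites are never homozygous-alt.
    rare_site_fraction: float = 0.86
    rare_beta: tuple[float, float] = (0.2, 80.0)
    rare_bounds: tuple[float, float] = (2e-4, 0.5)
    common_beta: tuple[float, float] = (1.2, 8.0)
    common_bounds: tuple[float, float] = (0.02, 0.95)
    # planted Hardy-Weinberg distortion (applied at common sites, where a
    # zygosity distortion is observable)
    planted_f: float = 0.5
    n_planted: int = 0
    planted_min_freq: float = 0.1
    fraction_novel: float = 0.35
    mean_depth: float = 40.0
    # annotation-table sizes
    n_disease_categories: int = 12
    n_diseases: int = 60
    p_mirna_diseased: float = 0.6
    n_genes: int = 400
    n_pathways: int = 60
    n_pathway_categories: int = 20
    targets_per_mirna: tuple[int, int] = (5, 30)
    chrom: str = "1"
    seed: int = 0

    def validate(self) -> None:
        if not self.populations:
            raise ConfigError("at least one population is required")
        for p in self.populations:
            if p.size < 1:
                raise ConfigError(f"population {p.name} has size {p.size} < 1")
            if not (0.0 <= p.fst < 1.0):
                raise ConfigError(f"population {p.name} has F={p.fst} outside [0,1)")
            if p.density_scale < 1.0:
                raise ConfigError(f"population {p.name} density_scale must be >=1")
        if not (-1.0 < self.planted_f < 1.0):
            raise ConfigError(f"planted f={self.planted_f} outside (-1,1)")
        if self.n_planted < 0:
            raise ConfigError("n_planted must be >=0")
        if any(d < 0 for d in self.region_density.values()):
            raise ConfigError("region densities must be >=0")
        if not (0.0 <= self.fraction_novel <= 1.0):
            raise ConfigError("fraction_novel must lie in [0,1]")
        if not (0.0 <= self.rare_site_fraction <= 1.0):
            raise ConfigError("rare_site_fraction must lie in [0,1]")
        if self.n_precursors < 1:
            raise ConfigError("n_precursors must be >=1")

    @property
    def total_samples(self) -> int:
        return sum(p.size for p in self.populations)


def default_populations() -> list[PopulationSpec]:
    """The 15-population, 1,152-individual worldwide cohort layout."""
    eur = [("TSI", 98), ("FIN", 93), ("GBR", 89), ("CEU", 85), ("IBS", 14), ("AND", 60)]
    asi = [("CHB", 97), ("CHS", 100), ("JPT", 89)]
    amr = [("MXL", 66), ("PUR", 55), ("CLM", 60)]
    afr = [("YRI", 88), ("LWK", 97), ("ASW", 61)]
    specs = []
    for name, size in eur:
        specs.append(PopulationSpec(name, size, fst=0.08, group="EUR"))
    for name, size in asi:
        specs.append(PopulationSpec(name, size, fst=0.12, group="ASI"))
    for name, size in amr:
        specs.append(PopulationSpec(name, size, fst=0.10, group="AMR"))
    for name, size in afr:
        # African cohorts carry ~1.4x the per-individual variant burden,
        # modelled as extra group-private segregating sites
        specs.append(PopulationSpec(name, size, fst=0.05, group="AFR", density_scale=1.4))
    return specs


def default_config(seed: int = 0) -> SimulationConfig:
    return SimulationConfig(populations=default_populations(), seed=seed)


def small_config(seed: int = 0, n_precursors: int = 50) -> SimulationConfig:
    """Scaled-down cohort (4 populations x 30 samples) for fast test runs."""
    pops = [
        PopulationSpec("EU1", 30, fst=0.08, group="EUR"),
        PopulationSpec("AS1", 30, fst=0.12, group="ASI"),
        PopulationSpec("AM1", 30, fst=0.10, group="AMR"),
        PopulationSpec("AF1", 30, fst=0.05, group="AFR", density_scale=1.4),
    ]
    return SimulationConfig(populations=pops, n_precursors=n_precursors, seed=seed)


@dataclass
class CohortTruth:
    """Ground truth for everything the generator planted."""

    sites: pd.DataFrame  # chrom,pos,ref,alt,premirna,region,ancestral_p,planted_f,restricted_group,rsid
    pop_freq: pd.DataFrame  # site rows x population columns, true allele frequencies
    disease_links: pd.DataFrame  # mirna,disease,category
    target_links: pd.DataFrame  # mirna,gene
    pathway_links: pd.DataFrame  # gene,pathway,category


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    truth: CohortTruth
    premirnas: list[PreMiRNA]
    vcf_path: Path
    gff_path: Path
    panel_path: Path
    id_table_path: Path
    disease_path: Path
    targets_path: Path
    pathways_path: Path


def _region_class(label: structure.RegionLabel) -> str:
    if label.is_seed:
        return "seed"
    if label.is_mature:
        return "rom"
    if label.value == structure.LOOP:
        return "loop"
    return "mir"


def _make_precursors(config: SimulationConfig, rng: np.random.Generator) -> list[PreMiRNA]:
    pres: list[PreMiRNA] = []
    cursor = 1000
    for i in range(config.n_precursors):
        f5 = int(rng.integers(config.flank_length[0], config.flank_length[1] + 1))
        a5 = int(rng.integers(config.arm_length[0], config.arm_length[1] + 1))
        lp = int(rng.integers(config.loop_length[0], config.loop_length[1] + 1))
        a3 = int(rng.integers(config.arm_length[0], config.arm_length[1] + 1))
        f3 = int(rng.integers(config.flank_length[0], config.flank_length[1] + 1))
        L = f5 + a5 + lp + a3 + f3
        strand = "+" if rng.random() < 0.5 else "-"
        start = cursor
        end = start + L - 1
        cursor = end + 500

        pre_iv = GenomicInterval(config.chrom, start, end, strand)
        name = f"syn-mir-{i + 1}"
        # transcribed-coordinate arm spans
        spans = {"5p": (f5 + 1, f5 + a5), "3p": (f5 + a5 + lp + 1, f5 + a5 + lp + a3)}
        u = rng.random()
        if u < config.p_no_arm:
            keep: list[str] = []
        elif u < config.p_no_arm + config.p_single_arm:
            keep = ["5p" if rng.random() < 0.5 else "3p"]
        else:
            keep = ["5p", "3p"]

        matures = []
        helper = PreMiRNA(id=name, interval=pre_iv)  # for coordinate conversion only
        for arm in keep:
            t1, t2 = spans[arm]
            iv = helper.to_genomic(t1, t2)
            matures.append(MatureMiRNA(id=f"syn-miR-{i + 1}-{arm}", interval=iv, arm=arm))
        pres.append(
            PreMiRNA(id=name, interval=pre_iv, mature_arms=tuple(sorted(matures, key=lambda m: m.interval.start)))
        )
    return pres


def _write_gff(premirnas: Sequence[PreMiRNA], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for k, pre in enumerate(premirnas, start=1):
            iv = pre.interval
            pid = f"MI{k:07d}"
            fh.write(
                f"{iv.chrom}\t.\tmiRNA_primary_transcript\t{iv.start}\t{iv.end}\t.\t{iv.strand}\t.\t"
                f"ID={pid};Name={pre.id}\n"
            )
            for j, m in enumerate(pre.mature_arms, start=1):
                mi = m.interval
                fh.write(
                    f"{mi.chrom}\t.\tmiRNA\t{mi.start}\t{mi.end}\t.\t{mi.strand}\t.\t"
                    f"ID={pid}_{j};Name={m.id};Derives_from={pid}\n"
                )


def _genotype_probs(p: float, f: float) -> np.ndarray:
    pq = p * (1.0 - p)
    probs = np.array(
        [(1.0 - p) ** 2 + f * pq, 2.0 * pq * (1.0 - f), p * p + f * pq]
    )
    probs = np.clip(probs, 0.0, None)
    return probs / probs.sum()


def _write_vcf(path: Path, samples: Sequence[str], rows: list[dict]) -> None:
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    for chrom in dict.fromkeys(r["chrom"] for r in rows):
        header.contigs.add(chrom)
    for s in samples:
        header.add_sample(s)
    gt_tuple = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in rows:
            rec = out.new_record(contig=r["chrom"], start=r["pos"] - 1, alleles=(r["ref"], r["alt"]))
            for j, s in enumerate(samples):
                g = int(r["gt"][j])
                rec.samples[s]["GT"] = gt_tuple[g]
                dp = int(r["dp"][j])
                rec.samples[s]["DP"] = dp
                alt_reads = int(r["ad_alt"][j])
                rec.samples[s]["AD"] = (dp - alt_reads, alt_reads)
            out.write(rec)


def simulate_cohort(config: SimulationConfig, outdir: str | Path) -> SimulatedCohort:
    """Generate the full input bundle (VCF/GFF3/panel/ID/annotation TSVs) plus truth.

    All files are written under ``outdir``; a fixed config seed yields
    byte-identical output.  The config is validated before anything is
    written.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    premirnas = _make_precursors(config, rng)
    gff_path = outdir / "mirna.gff3"
    _write_gff(premirnas, gff_path)

    # panel
    samples: list[str] = []
    panel_rows = []
    for spec in config.populations:
        for i in range(spec.size):
            s = f"{spec.name}{i:04d}"
            samples.append(s)
            panel_rows.append({"sample": s, "population": spec.name, "group": spec.group})
    panel_path = outdir / "panel.tsv"
    pd.DataFrame(panel_rows).to_csv(panel_path, sep="\t", index=False)

    # candidate variant sites, region-weighted, plus group-private extras
    scaled_groups = sorted(
        {p.group: p.density_scale for p in config.populations if p.density_scale > 1.0}.items()
    )
    site_rows = []
    for pre in premirnas:
        smap = decompose(pre)
        bases = sorted(smap.iter_base_labels(), key=lambda t: t[0])
        taken: set[int] = set()
        for pos, label in bases:
            dens = config.region_density[_region_class(label)]
            if rng.random() < config.per_base_rate * dens:
                taken.add(pos)
                site_rows.append(
                    {"pos": pos, "premirna": pre.id, "region": str(label), "restricted_group": None}
                )
        for group, scale in scaled_groups:
            extra_rate = config.per_base_rate * (scale - 1.0)
            for pos, label in bases:
                if pos in taken:
                    continue
                dens = config.region_density[_region_class(label)]
                if rng.random() < extra_rate * dens:
                    taken.add(pos)
                    site_rows.append(
                        {"pos": pos, "premirna": pre.id, "region": str(label), "restricted_group": group}
                    )
    if not site_rows:  # degenerate tiny configs: force one site
        pre = premirnas[0]
        smap = decompose(pre)
        pos, label = next(iter(sorted(smap.iter_base_labels())))
        site_rows.append({"pos": pos, "premirna": pre.id, "region": str(label), "restricted_group": None})
    site_rows.sort(key=lambda r: r["pos"])
    n_sites = len(site_rows)

    # alleles and ancestral / per-population frequencies: rare recent
    # mutations carry no drift, common standing variation drifts per
    # population under the Balding-Nichols model
    is_rare = rng.random(n_sites) < config.rare_site_fraction
    p0 = np.where(
        is_rare,
        np.clip(rng.beta(*config.rare_beta, size=n_sites), *config.rare_bounds),
        np.clip(rng.beta(*config.common_beta, size=n_sites), *config.common_bounds),
    )
    pop_names = [p.name for p in config.populations]
    pop_freq = np.zeros((n_sites, len(config.populations)))
    for k, spec in enumerate(config.populations):
        if spec.fst == 0.0:
            pk = p0.copy()
        else:
            ratio = (1.0 - spec.fst) / spec.fst
            pk = np.where(is_rare, p0, rng.beta(p0 * ratio, (1.0 - p0) * ratio))
        pop_freq[:, k] = pk
    for j, row in enumerate(site_rows):
        g = row["restricted_group"]
        if g is not None:
            for k, spec in enumerate(config.populations):
                if spec.group != g:
                    pop_freq[j, k] = 0.0

    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_shift = rng.integers(1, 4, size=n_sites)
    refs = _BASES[ref_idx]
    alts = _BASES[(ref_idx + alt_shift) % 4]

    planted_f = np.zeros(n_sites)
    if config.n_planted:
        eligible = np.flatnonzero(p0 >= config.planted_min_freq)
        if eligible.size == 0:  # degenerate config: fall back to commonest sites
            eligible = np.argsort(p0)[-config.n_planted:]
        n_plant = min(config.n_planted, eligible.size)
        planted_idx = rng.choice(eligible, size=n_plant, replace=False)
        planted_f[planted_idx] = config.planted_f

    # genotypes, depth and allelic depth
    n_samples = len(samples)
    gt = np.zeros((n_sites, n_samples), dtype=np.int8)
    col = 0
    pop_cols = []
    for spec in config.populations:
        pop_cols.append((spec, np.arange(col, col + spec.size)))
        col += spec.size
    for j in range(n_sites):
        for spec, ci in pop_cols:
            k = pop_names.index(spec.name)
            probs = _genotype_probs(pop_freq[j, k], planted_f[j])
            u = rng.random(ci.size)
            g = np.searchsorted(np.cumsum(probs)[:2], u, side="right")
            gt[j, ci] = g
    dp = rng.poisson(config.mean_depth, size=(n_sites, n_samples)).astype(int)
    dp = np.maximum(dp, 1)
    ad_alt = np.zeros_like(dp)
    het_mask = gt == 1
    ad_alt[het_mask] = rng.binomial(dp[het_mask], 0.5)
    ad_alt[gt == 2] = dp[gt == 2]

    # known-variant table: all but fraction_novel of the sites get an rsID
    novel = rng.random(n_sites) < config.fraction_novel
    rsids = np.array([f"rs{1000000 + j}" for j in range(n_sites)], dtype=object)
    rsids[novel] = None
    id_rows = [
        {"chrom": config.chrom, "pos": site_rows[j]["pos"], "ref": refs[j], "alt": alts[j], "rsid": rsids[j]}
        for j in range(n_sites)
        if rsids[j] is not None
    ]
    id_table_path = outdir / "known_ids.tsv"
    pd.DataFrame(id_rows, columns=["chrom", "pos", "ref", "alt", "rsid"]).to_csv(
        id_table_path, sep="\t", index=False
    )

    # VCF
    vcf_rows = [
        {
            "chrom": config.chrom,
            "pos": site_rows[j]["pos"],
            "ref": str(refs[j]),
            "alt": str(alts[j]),
            "gt": gt[j],
            "dp": dp[j],
            "ad_alt": ad_alt[j],
        }
        for j in range(n_sites)
    ]
    vcf_path = outdir / "cohort.vcf"
    _write_vcf(vcf_path, samples, vcf_rows)

    # disease taxonomy
    categories = [f"category_{c:02d}" for c in range(1, config.n_disease_categories + 1)]
    disease_cat = {
        f"disease_{d:03d}": categories[int(rng.integers(0, len(categories)))]
        for d in range(1, config.n_diseases + 1)
    }
    disease_names = list(disease_cat)
    disease_rows = []
    for pre in premirnas:
        if rng.random() < config.p_mirna_diseased:
            n_links = 1 + int(rng.poisson(1.5))
            chosen = rng.choice(len(disease_names), size=min(n_links, len(disease_names)), replace=False)
            for d in chosen:
                name = disease_names[int(d)]
                disease_rows.append({"mirna": pre.id, "disease": name, "category": disease_cat[name]})
    disease_path = outdir / "disease.tsv"
    disease_links = pd.DataFrame(disease_rows, columns=["mirna", "disease", "category"])
    disease_links.to_csv(disease_path, sep="\t", index=False)

    # target genes and pathway taxonomy
    genes = [f"gene_{g:04d}" for g in range(1, config.n_genes + 1)]
    pathways = [f"pathway_{p:03d}" for p in range(1, config.n_pathways + 1)]
    pw_categories = [f"pwcat_{c:02d}" for c in range(1, config.n_pathway_categories + 1)]
    pathway_cat = {pw: pw_categories[int(rng.integers(0, len(pw_categories)))] for pw in pathways}
    pathway_rows = []
    for g in genes:
        n_pw = 1 + int(rng.integers(0, 3))
        for p_i in rng.choice(len(pathways), size=n_pw, replace=False):
            pw = pathways[int(p_i)]
            pathway_rows.append({"gene": g, "pathway": pw, "category": pathway_cat[pw]})
    target_rows = []
    for pre in premirnas:
        n_t = int(rng.integers(config.targets_per_mirna[0], config.targets_per_mirna[1] + 1))
        for g_i in rng.choice(len(genes), size=min(n_t, len(genes)), replace=False):
            target_rows.append({"mirna": pre.id, "gene": genes[int(g_i)]})
    targets_path = outdir / "targets.tsv"
    pathways_path = outdir / "pathways.tsv"
    target_links = pd.DataFrame(target_rows, columns=["mirna", "gene"])
    pathway_links = pd.DataFrame(pathway_rows, columns=["gene", "pathway", "category"])
    target_links.to_csv(targets_path, sep="\t", index=False)
    pathway_links.to_csv(pathways_path, sep="\t", index=False)

    sites = pd.DataFrame(
        {
            "chrom": config.chrom,
            "pos": [r["pos"] for r in site_rows],
            "ref": refs,
            "alt": alts,
            "premirna": [r["premirna"] for r in site_rows],
            "region": [r["region"] for r in site_rows],
            "ancestral_p": p0,
            "is_rare": is_rare,
            "planted_f": planted_f,
            "restricted_group": [r["restricted_group"] for r in site_rows],
            "rsid": rsids,
        }
    )
    truth = CohortTruth(
        sites=sites,
        pop_freq=pd.DataFrame(pop_freq, columns=pop_names),
        disease_links=disease_links,
        target_links=target_links,
        pathway_links=pathway_links,
    )
    sites.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
    logger.info("simulated %d sites over %d precursors, %d samples",
                n_sites, config.n_precursors, n_samples)
    return SimulatedCohort(
        config=config,
        truth=truth,
        premirnas=premirnas,
        vcf_path=vcf_path,
        gff_path=gff_path,
        panel_path=panel_path,
        id_table_path=id_table_path,
        disease_path=disease_path,
        targets_path=targets_path,
        pathways_path=pathways_path,
    )


# ---------------------------------------------------------------------------
# Monte-Carlo harnesses for the Hardy-Weinberg test


def hwe_null_calibration(
    n: int = 100,
    maf: float = 0.2,
    n_tests: int = 10_000,
    alpha: float = 0.05,
    continuity_correction: bool = False,
    seed: int = 0,
) -> float:
    """Fraction of null (Hardy-Weinberg) cohorts flagged at level alpha."""
    rng = np.random.default_rng(seed)
    p, q = 1.0 - maf, maf
    counts = rng.multinomial(n, [p * p, 2 * p * q, q * q], size=n_tests)
    flagged = 0
    for rr, het, aa in counts:
        r = hwe_test(int(rr), int(het), int(aa),
                     continuity_correction=continuity_correction, alpha=alpha)
        flagged += r.significant
    return flagged / n_tests


def hwe_power_planted(
    n: int = 200,
    maf: float = 0.2,
    f: float = 0.5,
    n_reps: int = 1_000,
    alpha: float = 0.05,
    continuity_correction: bool = True,
    seed: int = 0,
) -> float:
    """Power to flag a planted inbreeding distortion f at sample size n."""
    rng = np.random.default_rng(seed)
    probs = _genotype_probs(maf, f)
    counts = rng.multinomial(n, probs, size=n_reps)
    flagged = 0
    for rr, het, aa in counts:
        r = hwe_test(int(rr), int(het), int(aa),
                     continuity_correction=continuity_correction, alpha=alpha)
        flagged += r.significant
    return flagged / n_reps


def simulate_structured_genotypes(
    group_sizes: Sequence[int],
    fst_values: Sequence[float],
    n_sites: int,
    seed: int = 0,
    ancestral_beta: tuple[float, float] = (0.8, 0.8),
    ancestral_bounds: tuple[float, float] = (0.05, 0.95),
    admixture: Optional[dict] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Balding-Nichols genotypes for a PCA recovery experiment.

    ``admixture`` maps a group index to mixing weights over the *other*
    (pure) groups; that group's base frequencies are the weighted average
    of the source groups' drawn frequencies, with its own residual drift
    ``fst`` applied on top.  Admixed groups are how the American cohorts
    of worldwide panels separate from the three source continents on the
    first two principal components: an admixed centroid is coplanar with
    its sources, so the between-group structure stays two-dimensional.

    Returns (sites x samples dosage matrix, per-sample group labels).
    """
    if len(group_sizes) != len(fst_values):
        raise ConfigError("group_sizes and fst_values must align")
    admixture = admixture or {}
    rng = np.random.default_rng(seed)
    p0 = np.clip(rng.beta(*ancestral_beta, size=n_sites), *ancestral_bounds)
    n_groups = len(group_sizes)
    freqs: dict[int, np.ndarray] = {}

    def drift(base: np.ndarray, fst: float) -> np.ndarray:
        if fst == 0.0:
            return base
        ratio = (1.0 - fst) / fst
        return rng.beta(base * ratio, (1.0 - base) * ratio)

    for g in range(n_groups):  # pure groups first (deterministic rng order)
        if g not in admixture:
            freqs[g] = drift(p0, fst_values[g])
    for g in range(n_groups):
        if g in admixture:
            w = np.asarray(admixture[g], dtype=float)
            sources = [s for s in range(n_groups) if s not in admixture]
            if len(w) != len(sources):
                raise ConfigError("admixture weights must cover the pure groups")
            base = np.clip(sum(wi * freqs[s] for wi, s in zip(w / w.sum(), sources)), 1e-6, 1 - 1e-6)
            freqs[g] = drift(base, fst_values[g])

    cols = []
    labels = []
    for g, size in enumerate(group_sizes):
        dose = rng.binomial(2, freqs[g][:, None], size=(n_sites, size))
        cols.append(dose)
        labels.extend([g] * size)
    return np.hstack(cols), np.array(labels)


def four_group_cohort(
    n_per_group: int = 30,
    n_sites: int = 300,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """The worldwide four-group layout used for stratification recovery.

    Three source continents at distinct divergences (0.05, 0.10, 0.15)
    and one admixed group (equal parts of the three, with 0.02 residual
    drift), mirroring how African, European, Asian and admixed American
    cohorts segregate on the first two principal components.
    """
    return simulate_structured_genotypes(
        [n_per_group] * 4,
        [0.05, 0.10, 0.15, 0.02],
        n_sites,
        seed=seed,
        admixture={3: [1 / 3, 1 / 3, 1 / 3]},
    )


def pca_group_recovery(coords: np.ndarray, labels: np.ndarray, seed: int = 0) -> float:
    """Adjusted Rand index between k-means clusters on PCs and true groups."""
    from sklearn.cluster import KMeans
    from sklearn.metrics import adjusted_rand_score

    k = len(np.unique(labels))
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(coords)
    return float(adjusted_rand_score(labels, km.labels_))


# ---------------------------------------------------------------------------
# Truth recovery report


class TruthMismatchError(ValueError):
    pass


@dataclass
class RecoveryReport:
    allele_freq_rmse: float
    per_population_rmse: dict
    region_confusion: pd.DataFrame  # truth label x pipeline label
    region_exact: bool
    hwe_power: Optional[float]
    hwe_type1: Optional[float]
    pca_ari: Optional[float]

    def as_dict(self) -> dict:
        return {
            "allele_freq_rmse": self.allele_freq_rmse,
            "per_population_rmse": self.per_population_rmse,
            "region_exact": self.region_exact,
            "hwe_power": self.hwe_power,
            "hwe_type1": self.hwe_type1,
            "pca_ari": self.pca_ari,
        }


def truth_compare(
    vmap,
    truth: CohortTruth,
    hwe_results=None,
    pca_ari: Optional[float] = None,
    alpha: float = 0.05,
) -> RecoveryReport:
    """Compare pipeline outputs against the generator's ground truth.

    Checks empirical per-population allele frequencies against the drawn
    frequencies (RMSE), the region labels assigned by the pipeline
    against the generator's per-site labels (confusion matrix must be
    diagonal), and, when a HWE scan is supplied, the flag rates at
    planted versus unplanted sites.
    """
    from .popgen import allele_frequency
    from .variants import HET, HOM_ALT, HOM_REF

    truth_keys = set(zip(truth.sites["chrom"], truth.sites["pos"], truth.sites["ref"], truth.sites["alt"]))
    map_keys = {v.key for v in vmap.matrix.variants}
    if truth_keys != map_keys:
        raise TruthMismatchError(
            f"site sets differ: {len(truth_keys - map_keys)} truth-only, "
            f"{len(map_keys - truth_keys)} map-only"
        )

    key_to_row = {v.key: i for i, v in enumerate(vmap.matrix.variants)}
    cols = vmap.panel.column_indices(vmap.matrix.samples)
    sq_err: dict[str, list[float]] = {pop: [] for pop in vmap.panel.populations}
    for j, rec in truth.sites.iterrows():
        key = (rec["chrom"], rec["pos"], rec["ref"], rec["alt"])
        row = vmap.matrix.gt[key_to_row[key]]
        for pop in vmap.panel.populations:
            sub = row[cols[pop]]
            n_rr = int((sub == HOM_REF).sum())
            n_het = int((sub == HET).sum())
            n_aa = int((sub == HOM_ALT).sum())
            emp = allele_frequency(n_rr, n_het, n_aa)
            sq_err[pop].append((emp - truth.pop_freq.iloc[j][pop]) ** 2)
    per_pop = {pop: float(np.sqrt(np.mean(v))) for pop, v in sq_err.items() if v}
    overall = float(np.sqrt(np.mean([e for v in sq_err.values() for e in v])))

    # region-label agreement, keyed by (site, precursor)
    truth_region = {
        ((r["chrom"], r["pos"], r["alt"]), r["premirna"]): r["region"]
        for _, r in truth.sites.iterrows()
    }
    pairs = []
    for p in vmap.profiles:
        k = (p.variant.site, p.premirna_id)
        if k in truth_region:
            pairs.append((truth_region[k], str(p.region)))
    labels = sorted({a for a, _ in pairs} | {b for _, b in pairs})
    conf = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for t, o in pairs:
        conf.loc[t, o] += 1
    exact = bool((conf.values.sum() - np.trace(conf.values)) == 0)

    power = type1 = None
    if hwe_results is not None:
        planted = {
            (r["chrom"], r["pos"], r["ref"], r["alt"])
            for _, r in truth.sites.iterrows()
            if r["planted_f"] != 0.0
        }
        planted_hit = {k: False for k in planted}
        null_tests = 0
        null_flagged = 0
        for r in hwe_results:
            if r.variant_key in planted:
                planted_hit[r.variant_key] |= r.significant
            else:
                null_tests += 1
                null_flagged += r.significant
        power = (sum(planted_hit.values()) / len(planted_hit)) if planted_hit else None
        type1 = (null_flagged / null_tests) if null_tests else None

    return RecoveryReport(
        allele_freq_rmse=overall,
        per_population_rmse=per_pop,
        region_confusion=conf,
        region_exact=exact,
        hwe_power=power,
        hwe_type1=type1,
        pca_ari=pca_ari,
    )
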