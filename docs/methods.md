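# Methods

## Substructure model

A pre-miRNA is an interval on a stranded chromosome carrying zero, one
or two annotated mature products. All coordinates — GFF3 annotation and
VCF variant positions alike — are 1-based inclusive, so no off-by-one
conversion happens anywhere inside the package (BED export is the one
documented exception: 0-based half-open, as BED requires).

Decomposition works in transcribed coordinates (position 1 = the 5' end
of the hairpin transcript), so a minus-strand precursor produces the
same label sequence as its plus-strand mirror. Each mature arm splits
into:

* **seed** — mature positions 2–8 (7 nt). The seed definition that
  includes position 1 exists in the literature; this package uses 2–8
  and assigns position 1 to rest-of-mature. Arms shorter than 8 nt get a
  truncated seed (positions 2..L) with a warning.
* **rom** ("rest of mature") — position 1 and positions 9..end.

The segment strictly between the two arms is the **loop** (omitted when
the arms abut); precursor sequence outside the arms is the **5' mir** /
**3' mir** flank. When a side has no annotated mature product its flank
carries a **"(mix)"** qualifier: such a region mixes the (unannotated)
star strand with true flank, and the tables keep those tallies separate.
This qualifier is this package's own documented convention — upstream
catalogues print "(mix)" without defining it. A precursor with no arms
at all splits at the transcribed midpoint into "5' mir (mix)" and
"3' mir (mix)" (the 5' half takes the extra base for odd lengths).

Arm side (5p/3p) is taken from the mature name suffix when present,
otherwise inferred by the transcribed-midpoint rule. The decomposition
is validated as an exact partition: segment lengths always sum to the
precursor length with no overlaps, and this is enforced at construction
time, not just in tests.

## Variant map conventions

* Only biallelic SNVs enter the map; multiallelic records are split
  into one record per SNV alternative allele and non-SNV alleles are
  dropped with a ledger count.
* The pooled carrier-frequency denominator is the **full**
  multi-population cohort, not the within-population size (one carrier
  in 1,152 → 0.0868%).
* Missing genotypes count as non-carriers for frequencies but are
  excluded from Hardy-Weinberg genotype counts; half-calls (`./1`) are
  missing.
* A variant under several (overlapping) precursors yields one profile
  per precursor; population summaries count distinct *sites*, so the
  per-region columns may sum to more than the site total.
* Variants with zero carriers anywhere are excluded from the map and
  accounted for in the filter ledger.
* Novelty requires allele-level agreement with the known-variant table:
  the same position with a different alternative allele is still novel.
* Mean alternative-allele read fraction is averaged over heterozygous
  calls carrying allelic-depth (AD) information and reported as a QC
  quantity only; no read-fraction filter is enforced.

Per-population summary tables define "heterozygous"/"homozygous" site
counts as sites with ≥1 het (resp. ≥1 hom-alt) carrier in that
population — the two columns may overlap — and "precursor" vs "mature"
sites as flank/loop vs seed/rom hits. These conventions are stated here
because published table layouts of this kind leave them ambiguous.

## Hardy-Weinberg test

Genotype counts (n₀, n₁, n₂) are tested with a 1-df chi-square against
expectations (np², 2npq, nq²) at the observed allele frequency, with the
Yates continuity correction **on by default**:

χ² = Σ (max(|obs − exp| − c, 0))² / exp,  c = 0.5.

The deviation is floored at zero so the corrected statistic can never
exceed the uncorrected one. The corrected test is conservative (null
flag rate ≈ 2% at α = 0.05 for n = 100, maf 0.2); the uncorrected test
is close to nominal (≈ 4.7%). Monomorphic counts return χ² = 0, p = 1
by convention so scan totals are stable; p-values are floored at the
smallest positive double so `0 < p ≤ 1` always holds.

The scan runs one test per (variant, population) with at least one
carrier in that population, using the full population as denominator
(cohort members without the variant are homozygous reference). Raw
p-values are reported with **no multiple-testing correction** by
default, matching the convention of the surveys this mirrors;
Benjamini–Hochberg is available behind a flag. α defaults to 0.05.

## Stratification PCA

Sites-by-samples dosages (0/1/2) are mean-imputed per site, centered by
the site mean and scaled by √(p̂(1−p̂)) with the shrunk allele-frequency
estimator p̂ = (1+Σg)/(2+2n) (a flag switches to the plain MLE; the
shrunk form stabilizes rare-variant scaling on small cohorts). The
components are eigenvectors of the sample covariance; signs are
canonicalized so the largest-magnitude loading of each component is
positive, making results deterministic. Sites monomorphic after
imputation are dropped with a warning. The site filter retains sites
with coverage **strictly** greater than the threshold (default 10×) in
the anchoring cohort and at least one carrier; which cohort anchors the
coverage filter is a runtime choice, and when no coverage is available
the filter is skipped with a warning. Tracy–Widom eigenvalue
significance, outlier-removal iterations and LD pruning are out of
scope (miRNA sites are sparse).

## Disease and pathway joins

Disease categories and miRNA→target tables are explicit inputs — no
ontology or target-prediction algorithm is bundled, because neither has
a canonical choice. A variant position present in a population counts
toward **every** disease category its miRNA is linked to (pleiotropy
preserved); cells count distinct variant positions, not variant–disease
pairs. A pathway is "affected" in a population when ≥1 of its genes is
targeted by a miRNA with a seed-region variant present there; profile
entries are percentages of pathways affected per category. Hive-plot
edge lists are emitted so that miRNA–population edge weights
marginalize exactly to the population × category matrix entries.
Heat-map ordering uses agglomerative clustering on Euclidean distances
with complete linkage (configurable); rendering itself is out of scope.

## Synthetic cohort generator

The generator emulates the design of a worldwide miRNA resequencing
survey. Defaults: 15 populations (TSI 98, FIN 93, GBR 89, CEU 85,
IBS 14, AND 60; CHB 97, CHS 100, JPT 89; MXL 66, PUR 55, CLM 60;
YRI 88, LWK 97, ASW 61 — total 1,152) in 4 geographic groups, 720
precursor hairpins, mean depth 40×, 35% of sites left out of the
known-variant table.

**Variant placement.** Sites are placed per base with probability
`per_base_rate × region_density`, the relative densities
(seed 0.3 < rom 0.5 < loop 0.6 < flank 1.0) mirroring the observed
occurrence gradient across the hairpin: strongest depletion in the
seed, mildest in the flanks.

**Frequency spectrum.** Two components, because a single beta law
cannot reproduce a realistic cohort jointly in site count, per-individual
burden and zygosity:

* *rare* sites (86%): ancestral frequency ~ Beta(0.2, 80) clipped to
  [2·10⁻⁴, 0.5], **no** population drift — a recent mutation has not
  equilibrated, and applying equilibrium drift to such sites makes them
  implausibly bursty and homozygote-rich. Observed rare sites are
  mostly heterozygous singletons.
* *common* sites (14%): ancestral frequency ~ Beta(1.2, 8) clipped to
  [0.02, 0.95], per-population frequencies from the Balding–Nichols
  model with divergence F per population (defaults: EUR 0.08, ASI 0.12,
  AMR 0.10, AFR 0.05).

At the default full scale this yields ≈ 520 observed variant sites,
≈ 24 carried sites per individual, and ≈ 75% of sites never seen
homozygous-alternative.

**Group diversity.** Higher per-individual burden in African cohorts is
modelled as extra group-private segregating sites (`density_scale`,
default 1.4 for AFR). It is *not* modelled by raising F: expected
carrier burden Σ(2p − p²) is concave in p, so extra Balding–Nichols
variance around the same ancestral mean slightly *lowers* expected
burden — higher diversity is a segregating-sites effect, not a drift
effect.

**Planted distortions.** Selected sites get genotypes drawn with an
inbreeding coefficient f (P(het) = 2pq(1−f); negative f gives
heterozygote excess). Planted sites are drawn among sites with ancestral
frequency ≥ 0.1 (`planted_min_freq`): a zygosity distortion at an
effectively monomorphic site is unobservable. The Monte-Carlo power
harness plants f at maf 0.2, the same frequency the type-I calibration
uses; at n = 200 and f = 0.5 the χ² noncentrality ≈ n·f² = 50, so
detection is essentially certain.

**Stratification-recovery experiment.** `four_group_cohort` draws three
source groups at divergences 0.05/0.10/0.15 and one *admixed* group
(equal parts of the three, 0.02 residual drift). Four mutually
independent groups span three dimensions, so projecting onto the first
two components structurally merges the closest pair; an admixed
centroid is coplanar with its sources, which is exactly why worldwide
panels separate four continents on PC1–PC2. The experiment mirrors that
geometry.

**Determinism.** All randomness flows from one `numpy` generator seeded
by the config; a fixed seed yields byte-identical output files.

**What the generator does not emulate.** Linkage disequilibrium between
sites (sites are independent), shared drift phylogeny between
populations within a group (populations are exchangeable draws),
sequencing error and genotyping uncertainty (genotypes are exact draws
from the model), indels and structural variants, and realistic
mutation-rate heterogeneity beyond the region densities. Passing tests
on synthetic data therefore validate the *bookkeeping and statistics* of
the pipeline — interval assignment, counting, test calibration,
recovery of planted structure — not robustness to real-data artifacts
such as mapping bias or batch effects.

## Problem sizes used in tests and the acceptance script

The test suite runs a 4-population × 30-sample × 40-precursor cohort
(shared session fixture), 10,000-replicate null calibration and
1,000-replicate power Monte-Carlo for the HWE test, 1,000 fuzzed
precursors for the partition property, and a 120-sample × 300-site
stratification experiment. The acceptance script additionally runs the
full default-scale cohort (1,152 samples × 720 precursors) through the
entire pipeline. These sizes keep a complete run in the tens of seconds
while leaving all Monte-Carlo margins wide relative to their thresholds.

## Known limitations

* The exact (enumeration-based) Hardy-Weinberg test is not implemented;
  the chi-square approximation with continuity correction is the
  default deliberately, as it is what the summary tables this package
  reproduces used. For very small expected counts the approximation is
  rough (the conventions here floor the deviation and report the raw
  p-value).
* Duplex 3' overhangs are not distinguished: everything strictly
  between the arms is "loop".
* Whether a "(mix)" region is star strand or flank is unknowable
  without secondary-structure prediction, which is out of scope.
* The functional-ratio comparison takes explicit numerators and
  denominators; it does not guess which element counts a published
  ratio used.
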