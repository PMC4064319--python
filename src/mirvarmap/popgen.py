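"""Population-genetic summaries of the variant map.

Hardy-Weinberg deviation scan (chi-square, 1 df, Yates continuity
correction on by default), allele frequencies, per-individual variant
burden, the allele-frequency spectrum, and the functional-variants-per-
element ratio used to compare miRNA variability against the
loss-of-function load of protein-coding genes.

The continuity correction and the full-population denominator (treating
cohort members without the variant as homozygous reference) are the
defaults because together they reproduce the published per-population
HWE p-values from raw genotype counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .variants import HET, HOM_ALT, HOM_REF, GenotypeMatrix, PopulationPanel, VariantProfile


class MonomorphicError(ValueError):
    pass


@dataclass(frozen=True)
class HWEResult:
    """Chi-square Hardy-Weinberg test for one variant in one population."""

    variant_key: tuple
    population: Optional[str]
    n_total: int
    n_hom_ref: int
    n_het: int
    n_hom_alt: int
    alt_allele_freq: float
    chi2: float
    p_value: float
    significant: bool

    def __post_init__(self) -> None:
        if self.n_hom_ref + self.n_het + self.n_hom_alt != self.n_total:
            raise ValueError("genotype counts must sum to n_total")
        if not (0 < self.p_value <= 1):
            raise ValueError("p-value must lie in (0, 1]")
        if self.chi2 < 0:
            raise ValueError("chi2 must be non-negative")


def allele_frequency(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Alternative-allele fraction from genotype counts."""
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise MonomorphicError("no genotyped samples")
    return (n_het + 2 * n_hom_alt) / (2 * n)


# smallest positive double: p-values are clamped here so "0 < p" always holds
_P_FLOOR = np.nextafter(0.0, 1.0)


def hwe_test(
    n_hom_ref: int,
    n_het: int,
    n_hom_alt: int,
    continuity_correction: bool = True,
    alpha: float = 0.05,
    variant_key: tuple = (),
    population: Optional[str] = None,
) -> HWEResult:
    """Chi-square test of Hardy-Weinberg proportions (1 df).

    Expected counts are n*p^2, 2npq, n*q^2 at the observed allele
    frequency.  With the continuity correction each deviation is reduced
    by 0.5 (floored at zero) before squaring.  Monomorphic counts return
    chi2 = 0, p = 1 by convention so scans stay total-preserving.
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise MonomorphicError("need at least one genotyped sample")
    q = allele_frequency(n_hom_ref, n_het, n_hom_alt)
    if q <= 0.0 or q >= 1.0:
        return HWEResult(variant_key, population, n, n_hom_ref, n_het, n_hom_alt,
                         q, 0.0, 1.0, False)
    p = 1.0 - q
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    c = 0.5 if continuity_correction else 0.0
    dev = np.maximum(np.abs(observed - expected) - c, 0.0)
    chi2 = float(np.sum(dev * dev / expected))
    p_value = float(stats.chi2.sf(chi2, df=1))
    p_value = max(p_value, _P_FLOOR)
    return HWEResult(
        variant_key, population, n, n_hom_ref, n_het, n_hom_alt,
        q, chi2, p_value, p_value < alpha,
    )


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(pvals, method="fdr_bh")[1]


def hwe_scan(
    matrix: GenotypeMatrix,
    panel: PopulationPanel,
    alpha: float = 0.05,
    continuity_correction: bool = True,
    bh_correction: bool = False,
    significant_only: bool = False,
) -> list[HWEResult]:
    """One HWE test per (variant, population) with >=1 carrier in that population.

    Missing genotypes are excluded from the counts.  No multiple-testing
    correction is applied by default (raw p-values are reported);
    ``bh_correction`` switches the significance call to Benjamini-Hochberg
    adjusted p-values.  Results are sorted by population then position.
    """
    cols = panel.column_indices(matrix.samples)
    results: list[HWEResult] = []
    for pop in panel.populations:
        ci = cols[pop]
        for i, v in enumerate(matrix.variants):
            row = matrix.gt[i, ci]
            n_rr = int((row == HOM_REF).sum())
            n_het = int((row == HET).sum())
            n_aa = int((row == HOM_ALT).sum())
            if n_het + n_aa == 0:
                continue
            results.append(
                hwe_test(
                    n_rr, n_het, n_aa,
                    continuity_correction=continuity_correction,
                    alpha=alpha,
                    variant_key=v.key,
                    population=pop,
                )
            )
    results.sort(key=lambda r: (r.population, r.variant_key))
    if bh_correction and results:
        adj = _bh_adjust(np.array([r.p_value for r in results]))
        results = [
            HWEResult(
                r.variant_key, r.population, r.n_total, r.n_hom_ref, r.n_het,
                r.n_hom_alt, r.alt_allele_freq, r.chi2, r.p_value,
                bool(a < alpha),
            )
            for r, a in zip(results, adj)
        ]
    if significant_only:
        results = [r for r in results if r.significant]
    return results


def hwe_frame(results: Sequence[HWEResult]) -> pd.DataFrame:
    rows = [
        {
            "population": r.population,
            "chrom": r.variant_key[0] if r.variant_key else None,
            "pos": r.variant_key[1] if r.variant_key else None,
            "ref": r.variant_key[2] if len(r.variant_key) > 2 else None,
            "alt": r.variant_key[3] if len(r.variant_key) > 3 else None,
            "n_total": r.n_total,
            "n_hom_ref": r.n_hom_ref,
            "n_het": r.n_het,
            "n_hom_alt": r.n_hom_alt,
            "alt_allele_freq": r.alt_allele_freq,
            "chi2": r.chi2,
            "p_value": r.p_value,
            "significant": r.significant,
        }
        for r in results
    ]
    cols = ["population", "chrom", "pos", "ref", "alt", "n_total", "n_hom_ref",
            "n_het", "n_hom_alt", "alt_allele_freq", "chi2", "p_value", "significant"]
    return pd.DataFrame(rows, columns=cols)


@dataclass
class BurdenSummary:
    """Per-individual count of variant sites carried, grouped geographically."""

    per_sample: pd.Series  # sample -> count
    group_stats: pd.DataFrame  # group x {n, mean, median, q25, q75}


def burden_per_individual(matrix: GenotypeMatrix, panel: PopulationPanel) -> BurdenSummary:
    carried = (matrix.gt == HET) | (matrix.gt == HOM_ALT)
    counts = pd.Series(carried.sum(axis=0), index=matrix.samples, name="burden")
    if matrix.n_samples == 0:
        return BurdenSummary(
            per_sample=counts,
            group_stats=pd.DataFrame(columns=["n", "mean", "median", "q25", "q75"]),
        )
    groups = pd.Series({s: panel.group[s] for s in matrix.samples}, name="group")
    df = pd.DataFrame({"burden": counts, "group": groups})
    stats_df = df.groupby("group")["burden"].agg(
        n="size", mean="mean", median="median",
        q25=lambda x: x.quantile(0.25), q75=lambda x: x.quantile(0.75),
    )
    return BurdenSummary(per_sample=counts, group_stats=stats_df)


@dataclass(frozen=True)
class SpectrumBin:
    low: float  # exclusive
    high: float  # inclusive
    count: int


def af_spectrum(
    frequencies: Iterable[float],
    bin_edges: Optional[Sequence[float]] = None,
) -> list[SpectrumBin]:
    """Histogram of allele frequencies over (0, 1].

    Default bins are the deciles of (0, 1].  Bins are right-inclusive so
    a frequency of exactly 1 lands in the top bin and counts conserve the
    number of variants.
    """
    freqs = np.asarray(list(frequencies), dtype=float)
    edges = np.asarray(bin_edges if bin_edges is not None else np.linspace(0.0, 1.0, 11))
    if edges.ndim != 1 or len(edges) < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("bin edges must be strictly increasing with >=2 values")
    if freqs.size and (freqs.min() <= edges[0] or freqs.max() > edges[-1]):
        raise ValueError(f"frequencies must lie in ({edges[0]}, {edges[-1]}]")
    # right-inclusive binning: f in (e_i, e_{i+1}]
    idx = np.searchsorted(edges, freqs, side="left") - 1
    counts = np.bincount(idx, minlength=len(edges) - 1) if freqs.size else np.zeros(len(edges) - 1, int)
    return [
        SpectrumBin(float(lo), float(hi), int(c))
        for lo, hi, c in zip(edges[:-1], edges[1:], counts)
    ]


def functional_ratio(
    n_functional: int, n_elements: int, reference_ratio: Optional[float] = None
) -> tuple[float, Optional[float]]:
    """Functional variants per element, optionally as a fold over a reference.

    The reference used in the field is the loss-of-function load of
    protein-coding genes (~0.014 LOF variants per gene).
    """
    if n_elements <= 0:
        raise ValueError("n_elements must be positive")
    ratio = n_functional / n_elements
    if reference_ratio is None:
        return ratio, None
    if reference_ratio <= 0:
        raise ValueError("reference_ratio must be positive")
    return ratio, ratio / reference_ratio


def profile_allele_frequencies(
    profiles: Sequence[VariantProfile], matrix: GenotypeMatrix
) -> np.ndarray:
    """Pooled alternative-allele frequency for each profiled variant."""
    idx = {v.key: i for i, v in enumerate(matrix.variants)}
    out = []
    for p in profiles:
        row = matrix.gt[idx[p.variant.key]]
        out.append(
            allele_frequency(
                int((row == HOM_REF).sum()), int((row == HET).sum()), int((row == HOM_ALT).sum())
            )
        )
    return np.asarray(out)
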