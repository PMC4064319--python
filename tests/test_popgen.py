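"""Hardy-Weinberg scan, frequencies, burden, spectrum and functional ratios."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.integrate import quad

from mirvarmap.popgen import (
    BurdenSummary, MonomorphicError, af_spectrum, allele_frequency,
    burden_per_individual, functional_ratio, hwe_frame, hwe_scan, hwe_test,
)
from mirvarmap.variants import GenotypeMatrix, PopulationPanel, VariantRecord


def oracle_hwe_p(n_rr, n_het, n_aa, yates):
    """Independent recomputation: expected counts by hand, survival
    function by numerical integration of the 1-df chi-square density."""
    n = n_rr + n_het + n_aa
    q = (n_het + 2 * n_aa) / (2 * n)
    p = 1 - q
    exp = [n * p * p, 2 * n * p * q, n * q * q]
    c = 0.5 if yates else 0.0
    chi2 = sum(max(abs(o - e) - c, 0.0) ** 2 / e for o, e in zip([n_rr, n_het, n_aa], exp))
    density = lambda x: math.exp(-x / 2.0) / math.sqrt(2.0 * math.pi * x)
    tail, _ = quad(density, chi2, np.inf)
    return chi2, tail


class TestAlleleFrequency:
    def test_direct_count(self):
        assert allele_frequency(25, 13, 22) == pytest.approx(57 / 120)

    @pytest.mark.parametrize("counts,expected", [((7, 0, 0), 0.0), ((0, 0, 9), 1.0)])
    def test_fixed_alleles(self, counts, expected):
        assert allele_frequency(*counts) == expected

    def test_all_missing_raises(self):
        with pytest.raises(MonomorphicError):
            allele_frequency(0, 0, 0)


class TestHWETest:
    @pytest.mark.parametrize(
        "counts,printed_p",
        [
            ((25, 13, 22), 2.82e-05),  # n=60, strong het deficit
            ((29, 15, 17), 3.03e-04),  # n=61
            ((76, 8, 5), 2.23e-05),  # n=89, rare hom excess
        ],
    )
    def test_reproduces_published_per_population_p_values(self, counts, printed_p):
        """Corrected chi-square on raw genotype counts matches the printed
        per-population p-values to their two significant figures."""
        r = hwe_test(*counts, continuity_correction=True)
        assert r.p_value == pytest.approx(printed_p, rel=0.02)
        assert r.significant

    def test_exact_hardy_weinberg_counts_give_p_one_without_correction(self):
        r = hwe_test(16, 32, 16, continuity_correction=False)
        assert r.chi2 == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_monomorphic_returns_p_one(self):
        r = hwe_test(50, 0, 0)
        assert r.p_value == 1.0 and r.chi2 == 0.0 and not r.significant

    def test_matches_independent_integration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            counts = rng.integers(0, 60, size=3)
            if counts.sum() == 0 or counts[1] + counts[2] == 0 or counts[0] + counts[1] == 0:
                continue
            for yates in (True, False):
                chi2, tail = oracle_hwe_p(*map(int, counts), yates)
                r = hwe_test(*map(int, counts), continuity_correction=yates)
                assert r.chi2 == pytest.approx(chi2, rel=1e-9)
                # quad's far-tail relative error is ~1e-5; compare within that
                assert r.p_value == pytest.approx(max(tail, 5e-324), rel=1e-4)

    def test_correction_never_increases_chi2(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            counts = [int(x) for x in rng.integers(0, 80, size=3)]
            if sum(counts) == 0:
                continue
            with_c = hwe_test(*counts, continuity_correction=True).chi2
            without = hwe_test(*counts, continuity_correction=False).chi2
            assert with_c <= without + 1e-12

    def test_invariant_under_allele_relabeling(self):
        a = hwe_test(25, 13, 22)
        b = hwe_test(22, 13, 25)
        assert a.chi2 == pytest.approx(b.chi2) and a.p_value == pytest.approx(b.p_value)

    def test_null_p_values_super_uniform_corrected_roughly_uniform_uncorrected(self):
        rng = np.random.default_rng(5)
        n, maf = 120, 0.3
        counts = rng.multinomial(n, [(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2], size=2000)
        for yates, bound in ((True, 0.05), (False, 0.075)):
            rate = np.mean([
                hwe_test(int(a), int(b), int(c), continuity_correction=yates).significant
                for a, b, c in counts
            ])
            assert rate <= bound


class TestHWEScan:
    def test_one_result_per_carried_variant_population_pair(self, small_map):
        results = hwe_scan(small_map.matrix, small_map.panel)
        keys = [(r.population, r.variant_key) for r in results]
        assert len(keys) == len(set(keys))
        assert keys == sorted(keys)
        # every result's population really carries the variant
        for r in results:
            assert r.n_het + r.n_hom_alt >= 1

    def test_published_row_is_flagged_in_scan(self, tmp_path):
        """A het-deficient variant like the published flagged rows is caught."""
        gt = np.array([[2] * 5 + [1] * 8 + [0] * 76], dtype=np.int8)
        samples = [f"S{i}" for i in range(89)]
        matrix = GenotypeMatrix([VariantRecord("19", 54240174, "G", "A")], samples, gt)
        panel_path = tmp_path / "panel.tsv"
        panel_path.write_text(
            "sample\tpopulation\tgroup\n"
            + "\n".join(f"{s}\tJPT\tASI" for s in samples) + "\n"
        )
        panel = PopulationPanel.from_tsv(panel_path)
        (r,) = hwe_scan(matrix, panel, significant_only=True)
        assert r.p_value == pytest.approx(2.23e-05, rel=0.02)

    def test_bh_correction_only_changes_significance_calls(self, small_map):
        raw = hwe_scan(small_map.matrix, small_map.panel)
        adj = hwe_scan(small_map.matrix, small_map.panel, bh_correction=True)
        assert [r.p_value for r in raw] == [r.p_value for r in adj]
        n_raw = sum(r.significant for r in raw)
        n_adj = sum(r.significant for r in adj)
        assert n_adj <= n_raw

    def test_frame_columns(self, small_map):
        df = hwe_frame(hwe_scan(small_map.matrix, small_map.panel))
        assert {"population", "pos", "chi2", "p_value", "significant"}.issubset(df.columns)


class TestBurden:
    def test_simple_count(self):
        gt = np.array([[1, 0], [2, 0], [1, 0]], dtype=np.int8)
        matrix = GenotypeMatrix(
            [VariantRecord("1", p, "A", "G") for p in (10, 20, 30)], ["S1", "S2"], gt
        )
        panel = PopulationPanel(["S1", "S2"], {"S1": "P", "S2": "P"}, {"S1": "EUR", "S2": "EUR"})
        summary = burden_per_individual(matrix, panel)
        assert summary.per_sample["S1"] == 3 and summary.per_sample["S2"] == 0

    def test_high_density_group_has_highest_mean_burden(self, small_cohort, small_map):
        """The generator plants extra AFR-private sites; the AFR group mean
        per-individual burden must come out on top."""
        summary = burden_per_individual(small_map.matrix, small_map.panel)
        means = summary.group_stats["mean"]
        assert means.idxmax() == "AFR"

    def test_empty_cohort_slice_no_crash(self):
        matrix = GenotypeMatrix([], [], np.empty((0, 0), dtype=np.int8))
        panel = PopulationPanel([], {}, {})
        summary = burden_per_individual(matrix, panel)
        assert len(summary.per_sample) == 0


class TestSpectrum:
    def test_singletons_all_in_lowest_bin(self):
        n = 1152
        freqs = [1 / (2 * n)] * 7
        bins = af_spectrum(freqs)
        assert bins[0].count == 7 and sum(b.count for b in bins) == 7

    def test_fuzzed_counts_equal_brute_force(self):
        rng = np.random.default_rng(6)
        freqs = rng.uniform(1e-4, 1.0, size=300)
        edges = np.linspace(0, 1, 11)
        bins = af_spectrum(freqs, edges)
        for b in bins:
            brute = int(np.sum((freqs > b.low) & (freqs <= b.high)))
            assert b.count == brute
        assert sum(b.count for b in bins) == 300

    def test_boundary_frequency_one_lands_in_top_bin(self):
        bins = af_spectrum([1.0])
        assert bins[-1].count == 1

    def test_non_monotone_edges_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            af_spectrum([0.5], [0.0, 0.6, 0.4, 1.0])

    def test_out_of_range_frequency_rejected(self):
        with pytest.raises(ValueError, match="lie in"):
            af_spectrum([1.2])


class TestFunctionalRatio:
    def test_loss_of_function_reference_ratio(self):
        ratio, _ = functional_ratio(300, 21160)
        assert ratio == pytest.approx(0.014, abs=5e-4)

    def test_fold_against_reference(self):
        ratio, fold = functional_ratio(45, 720, reference_ratio=0.014)
        assert ratio == pytest.approx(0.0625)
        assert fold == pytest.approx(0.0625 / 0.014)

    def test_zero_numerator(self):
        assert functional_ratio(0, 10)[0] == 0.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            functional_ratio(1, 0)
        with pytest.raises(ValueError):
            functional_ratio(1, 10, reference_ratio=0.0)
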