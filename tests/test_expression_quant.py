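"""Promoter assignment, TMM normalization, TPM conversion and filters."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from ernalink.expression_quant import (
    ExpressionMatrix,
    assign_promoters,
    ceil_fraction,
    filter_expressed,
    gene_expression,
    sum_tss_to_peaks,
    tmm_factors,
    to_tpm,
    PromoterAssignment,
)
from ernalink.genome_model import (
    CagePeak,
    GeneModel,
    GenomicInterval,
    SampleMetadata,
    Transcript,
)


def _samples(n, prefix="s"):
    return [SampleMetadata(f"{prefix}{i}", "macrophage", "untreated") for i in range(n)]


def _matrix(arr, state="raw_counts", prefix="s"):
    arr = np.asarray(arr)
    samples = _samples(arr.shape[1], prefix)
    values = pd.DataFrame(
        arr, index=[f"f{i}" for i in range(arr.shape[0])],
        columns=[s.sample_id for s in samples],
    )
    return ExpressionMatrix(values, samples, state)


def _peak(pid, start, end, strand, summit=None, chrom="chr1", n_samples=2):
    summit = start if summit is None else summit
    return CagePeak(
        pid, GenomicInterval(chrom, start, end, strand), summit, np.zeros(n_samples)
    )


class TestSumTssToPeaks:
    def test_sums_member_positions_per_sample(self):
        samples = _samples(2)
        tss = pd.DataFrame(
            {
                "chrom": ["chr1"] * 3,
                "pos": [100, 105, 500],
                "strand": ["+"] * 3,
                "s0": [3, 4, 9],
                "s1": [0, 5, 9],
            }
        )
        peaks = [_peak("pk1", 95, 110, "+"), _peak("pk2", 600, 650, "+")]
        em = sum_tss_to_peaks(tss, peaks, samples)
        assert em.values.loc["pk1"].tolist() == [7, 5]
        assert em.values.loc["pk2"].tolist() == [0, 0]  # peak with no TSS

    def test_opposite_strand_position_is_not_counted(self):
        samples = _samples(1)
        tss = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [100], "strand": ["-"], "s0": [7]}
        )
        em = sum_tss_to_peaks(tss, [_peak("pk", 95, 110, "+", n_samples=1)], samples)
        assert em.values.loc["pk", "s0"] == 0


class TestAssignPromoters:
    def _gene(self, tss, strand, gene_id="g", chrom="chr1"):
        return GeneModel(
            gene_id, chrom, "protein_coding",
            [Transcript(f"{gene_id}.t0", tss, strand)],
            [GenomicInterval(chrom, max(0, tss - 100), tss + 100, strand)],
        )

    @pytest.mark.parametrize(
        "peak_start,tss,strand,assigned",
        [
            (1300, 1000, "+", True),  # 300 <= 500
            (1501, 1000, "+", False),  # 501 > 500, boundary
            (1500, 1000, "+", True),  # exactly at the window
        ],
    )
    def test_window_rule(self, peak_start, tss, strand, assigned):
        pk = _peak("pk", peak_start, peak_start + 10, strand)
        got = assign_promoters([pk], [self._gene(tss, strand)], window=500)
        assert bool(got) is assigned

    def test_strand_rule(self):
        pk = _peak("pk", 1000, 1010, "-", summit=1000)
        assert not assign_promoters([pk], [self._gene(1005, "+")], window=500)

    def test_gene_ids_union_over_transcripts(self):
        gene = GeneModel(
            "g", "chr1", "protein_coding",
            [Transcript("t0", 1000, "+"), Transcript("t1", 1200, "+")],
            [GenomicInterval("chr1", 1000, 1500, "+")],
        )
        (a,) = assign_promoters([_peak("pk", 1100, 1110, "+")], [gene], window=500)
        assert set(a.transcript_ids) == {"t0", "t1"}
        assert a.gene_ids == ("g",)


class TestTmm:
    def test_proportional_counts_give_unit_factors(self):
        em = _matrix([[10, 20], [20, 40], [30, 60]])
        np.testing.assert_allclose(tmm_factors(em), [1.0, 1.0], atol=1e-12)

    def test_stable_under_library_scaling(self):
        # M-values are exactly invariant to a global rescale of one
        # sample's counts; the precision weights depend weakly on absolute
        # depth, so the weighted factors move only slightly.
        rng = np.random.default_rng(5)
        base = rng.integers(1, 200, size=(50, 4))
        f1 = tmm_factors(_matrix(base))
        scaled = base.copy()
        scaled[:, 2] *= 7  # global rescale of one sample's counts
        f2 = tmm_factors(_matrix(scaled))
        np.testing.assert_allclose(f1, f2, rtol=0.05)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(7)
        em = _matrix(rng.integers(0, 300, size=(80, 5)) + 1)
        f = tmm_factors(em)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_six_feature_toy_matches_direct_formula_oracle(self):
        # five proportional features plus one 8-fold feature in sample B;
        # the 30% M-trim drops exactly the 8-fold feature, so the factor is
        # the untrimmed inverse-variance weighted mean over the other five.
        counts = np.array(
            [[100, 100], [100, 100], [100, 100], [100, 100], [100, 100], [100, 800]]
        )
        em = _matrix(counts)
        got = tmm_factors(em)

        y_a, y_b = counts[:, 0].astype(float), counts[:, 1].astype(float)
        n_a, n_b = y_a.sum(), y_b.sum()
        M = np.log2((y_b / n_b) / (y_a / n_a))
        w = (n_b - y_b) / (n_b * y_b) + (n_a - y_a) / (n_a * y_a)
        retained = np.arange(5)  # the proportional features
        f_b = np.sum(M[retained] / w[retained]) / np.sum(1.0 / w[retained])
        expected = np.array([1.0, 2.0**f_b])
        expected /= np.exp(np.mean(np.log(expected)))
        # reference sample is A (its upper quartile is closer to the mean)
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_all_zero_sample_is_error_naming_sample(self):
        em = _matrix([[1, 0], [2, 0]])
        with pytest.raises(ValueError, match="s1"):
            tmm_factors(em)


class TestToTpm:
    def test_simple_scaling(self):
        em = _matrix([[5], [999_995]])
        tpm = to_tpm(em, np.array([1.0]))
        assert tpm.values.iloc[0, 0] == pytest.approx(5.0)
        assert tpm.state == "tpm"

    def test_zero_count_stays_zero(self):
        em = _matrix([[0, 3], [10, 7]])
        tpm = to_tpm(em, np.array([1.0, 1.0]))
        assert tpm.values.iloc[0, 0] == 0.0

    def test_column_sums_equal_millions_over_factor(self):
        rng = np.random.default_rng(3)
        em = _matrix(rng.integers(1, 100, size=(30, 3)))
        factors = tmm_factors(em)
        tpm = to_tpm(em, factors)
        np.testing.assert_allclose(
            tpm.values.sum(axis=0).to_numpy(), 1e6 / factors, rtol=1e-6
        )


class TestFilterExpressed:
    def test_ceiling_convention_at_184_samples(self):
        n = 184  # >=1 TPM required in ceil(18.4) = 19 samples
        vals = np.zeros((2, n))
        vals[0, :19] = 1.0
        vals[1, :18] = 1.0
        em = _matrix(vals, state="tpm")
        kept = filter_expressed(em, em.sample_ids, min_tpm=1.0, frac=0.10)
        assert kept == ["f0"]

    def test_monotone_in_min_tpm(self):
        rng = np.random.default_rng(9)
        em = _matrix(rng.random((40, 20)) * 3, state="tpm")
        prev = None
        for thr in (0.5, 1.0, 2.0):
            kept = set(filter_expressed(em, em.sample_ids, thr, 0.10))
            if prev is not None:
                assert kept <= prev
            prev = kept

    def test_zero_threshold_keeps_any_nonzero(self):
        em = _matrix([[0.1] + [0] * 9, [0] * 10], state="tpm")
        kept = filter_expressed(em, em.sample_ids, min_tpm=0.0, frac=0.10)
        assert kept == ["f0", "f1"]  # 0 >= 0 holds everywhere

    def test_ceil_fraction_is_float_noise_safe(self):
        assert ceil_fraction(0.10, 184) == 19
        assert ceil_fraction(0.10, 40) == 4  # not ceil(4.0000000000000005) = 5
        assert ceil_fraction(0.25, 16) == 4


class TestGeneExpression:
    def test_sums_and_sharing(self):
        em = _matrix([[2.0], [3.5], [7.0]], state="tpm")
        assignments = [
            PromoterAssignment("f0", ("tA",), ("gA",)),
            PromoterAssignment("f1", ("tA2",), ("gA",)),
            PromoterAssignment("f2", ("tB", "tC"), ("gB", "gC")),  # shared peak
        ]
        genes = gene_expression(em, assignments)
        assert genes.values.loc["gA", "s0"] == pytest.approx(5.5)
        assert genes.values.loc["gB", "s0"] == pytest.approx(7.0)
        assert genes.values.loc["gC", "s0"] == pytest.approx(7.0)

    def test_single_promoter_gene_equals_its_promoter(self):
        em = _matrix([[4.25]], state="tpm")
        genes = gene_expression(em, [PromoterAssignment("f0", ("t",), ("g",))])
        assert genes.values.loc["g", "s0"] == pytest.approx(4.25)
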