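"""Hypergeometric gene-set tests, TFBS overlap statistics, background
sampling and Monte-Carlo over-representation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from _oracles import hypergeom_enumeration
from ernalink.enrichment import (
    GeneSetCollection,
    gene_set_enrichment,
    hypergeom_test,
    monte_carlo_p,
    read_gmt,
    region_hits,
    sample_background_regions,
    significant_tfbs,
    tfbs_overlap_stat,
    write_gmt,
)
from ernalink.genome_model import GenomicInterval, TAD


def _regions(spans, chrom="chr1"):
    return [GenomicInterval(chrom, a, b) for a, b in spans]


def _summits(positions, chrom="chr1"):
    return pd.DataFrame({"chrom": chrom, "pos": positions})


class TestHypergeom:
    def test_complete_overlap_closed_form(self):
        # N=10, K=5, n=5, k=5 -> 1 / C(10,5) * C(5,5)C(5,0) = 1/252
        universe = [f"g{i}" for i in range(10)]
        res = hypergeom_test(universe[:5], universe[:5], universe)
        assert res.p == pytest.approx(1 / 252)

    def test_zero_overlap_gives_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        res = hypergeom_test(universe[5:7], universe[:3], universe)
        assert res.p == pytest.approx(1.0) or res.p <= 1.0
        # upper tail from k=0 is always 1
        res0 = hypergeom_test([], universe[:3], universe)
        assert res0.p == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_for_small_universes(self):
        for N in range(2, 13):
            universe = [f"g{i}" for i in range(N)]
            for K in range(N + 1):
                for n in range(N + 1):
                    term = universe[:K]
                    query = universe[:n]  # overlap k = min(n, K)
                    res = hypergeom_test(query, term, universe)
                    expected = hypergeom_enumeration(N, K, n, min(n, K))
                    assert res.p == pytest.approx(expected, abs=1e-12), (N, K, n)

    def test_collection_bh_and_gmt_roundtrip(self, tmp_path):
        universe = [f"g{i}" for i in range(20)]
        coll = GeneSetCollection(
            {"A": universe[:5], "B": universe[5:15], "C": universe}, universe
        )
        path = tmp_path / "sets.gmt"
        write_gmt(coll, path)
        coll2 = read_gmt(path, universe)
        assert coll2.sets == coll.sets
        df = gene_set_enrichment(universe[:5], coll2)
        assert set(df.columns) >= {"term", "k", "p", "q"}
        assert ((df["q"] >= df["p"] - 1e-15) | (df["q"] <= 1.0)).all()


class TestOverlapStat:
    def test_fraction_of_regions_with_summit(self):
        regions = _regions([(0, 10), (20, 30), (40, 50), (60, 70)])
        stat = tfbs_overlap_stat(regions, _summits([5, 25]))
        assert stat == pytest.approx(0.5)

    def test_half_open_conventions(self):
        region = _regions([(100, 200)])
        assert tfbs_overlap_stat(region, _summits([100])) == 1.0  # closed start
        assert tfbs_overlap_stat(region, _summits([200])) == 0.0  # open end

    def test_empty_query_is_error(self):
        with pytest.raises(ValueError):
            tfbs_overlap_stat([], _summits([1]))


class TestBackgroundSampler:
    def test_containment_with_empty_exclusions(self):
        tads = [TAD("t", GenomicInterval("chr1", 0, 1000))]
        rng = np.random.default_rng(0)
        regions = sample_background_regions(50, [40] * 50, tads, [], rng)
        assert all(0 <= r.start and r.end <= 1000 for r in regions)

    def test_seed_determinism(self):
        tads = [TAD("t", GenomicInterval("chr1", 0, 10_000))]
        a = sample_background_regions(20, [100] * 20, tads, [],
                                      np.random.default_rng(7))
        b = sample_background_regions(20, [100] * 20, tads, [],
                                      np.random.default_rng(7))
        assert a == b

    def test_single_legal_slot_is_found(self):
        # exclusions cover everything except [100, 140): only width-40 start 100
        tads = [TAD("t", GenomicInterval("chr1", 0, 1000))]
        excl = _regions([(0, 100), (140, 1000)])
        rng = np.random.default_rng(1)
        (region,) = sample_background_regions(1, [40], tads, excl, rng)
        assert (region.start, region.end) == (100, 140)

    def test_impossible_width_is_error(self):
        tads = [TAD("t", GenomicInterval("chr1", 0, 100))]
        with pytest.raises(ValueError, match="width 500"):
            sample_background_regions(1, [500], tads, [], np.random.default_rng(0))

    def test_large_draw_never_touches_exclusions(self):
        tads = [
            TAD("t1", GenomicInterval("chr1", 0, 300_000)),
            TAD("t2", GenomicInterval("chr2", 0, 300_000)),
        ]
        rng = np.random.default_rng(123)
        excl = []
        for _ in range(60):
            chrom = "chr1" if rng.random() < 0.5 else "chr2"
            s = int(rng.integers(0, 299_000))
            excl.append(GenomicInterval(chrom, s, s + int(rng.integers(50, 900))))
        widths = [401] * 10_000
        regions = sample_background_regions(10_000, widths, tads, excl, rng)
        tad_by_chrom = {t.interval.chrom: t.interval for t in tads}
        for r in regions:
            tad = tad_by_chrom[r.chrom]
            assert tad.start <= r.start and r.end <= tad.end
        # exhaustive intersection check against every exclusion
        for r in regions:
            for e in excl:
                if e.chrom == r.chrom:
                    assert min(r.end, e.end) <= max(r.start, e.start)


class TestMonteCarlo:
    def test_plus_one_estimator_bounds(self):
        regions = _regions([(0, 10), (20, 30)])
        pool = _regions([(100, 110), (120, 130), (140, 150), (0, 10), (20, 30)])
        summits = _summits([5, 25])  # both query regions hit, pool mostly not
        rng = np.random.default_rng(0)
        obs, p = monte_carlo_p(regions, summits, pool, trials=1000, rng=rng)
        assert obs == 1.0
        assert 1 / 1001 <= p <= 1.0

    def test_observed_below_background_gives_p_one(self):
        regions = _regions([(100, 110)])  # no summit
        pool = _regions([(0, 10)] * 5)  # summit in every pool region
        summits = _summits([5])
        _, p = monte_carlo_p(regions, summits, pool, trials=50,
                             rng=np.random.default_rng(0))
        assert p == pytest.approx(1.0)

    def test_toy_matches_exhaustive_enumeration_within_mc_error(self):
        # pool of 5 regions, 2 of which contain a summit; query of 3 regions
        # with 1 hit -> observed frac 1/3.  Exact P(trial >= 1/3) over all
        # C(5,3) = 10 subsets counts subsets with >= 1 hit region.
        pool = _regions([(0, 10), (20, 30), (40, 50), (60, 70), (80, 90)])
        summits = _summits([5, 25])
        query = _regions([(0, 10), (200, 210), (220, 230)])
        observed = tfbs_overlap_stat(query, summits)
        hits = region_hits(pool, summits)
        exact = np.mean([
            np.mean(hits[list(c)]) >= observed
            for c in itertools.combinations(range(5), 3)
        ])
        trials = 2000
        _, p = monte_carlo_p(query, summits, pool, trials=trials,
                             rng=np.random.default_rng(42))
        mc_sd = np.sqrt(exact * (1 - exact) / trials)
        assert abs(p - exact) <= 3 * mc_sd + 2 / (trials + 1)

    def test_pool_smaller_than_query_is_error(self):
        with pytest.raises(ValueError, match="pool"):
            monte_carlo_p(_regions([(0, 10), (20, 30)]), _summits([5]),
                          _regions([(0, 10)]), trials=10,
                          rng=np.random.default_rng(0))


class TestSignificantTfbs:
    def test_all_three_backgrounds_and_expression_required(self):
        results = {
            "keep": {"all_enhancers": 0.001, "non_macrophage_enhancers": 0.002,
                     "random_regions": 0.009},
            "one_bg_fails": {"all_enhancers": 0.001,
                             "non_macrophage_enhancers": 0.02,
                             "random_regions": 0.001},
            "unexpressed": {"all_enhancers": 0.001,
                            "non_macrophage_enhancers": 0.001,
                            "random_regions": 0.001},
        }
        expr = {"keep": 5.0, "one_bg_fails": 5.0, "unexpressed": 0.0}
        assert significant_tfbs(results, expr, alpha=0.01) == ["keep"]

    def test_missing_background_is_error(self):
        with pytest.raises(ValueError, match="missing background"):
            significant_tfbs({"tf": {"all_enhancers": 0.001}}, {"tf": 1.0})
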