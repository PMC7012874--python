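"""Rate arithmetic, enrichment testing, cohort normalization, quartiles and
breakpoint distances."""

import numpy as np
import pandas as pd
import pytest

from conftest import brute_closest, brute_counts, random_genome, random_regions, random_snvs
from tfmutscan.catalog import MutationCatalog
from tfmutscan.intervals import RegionSet
from tfmutscan.randomization import ShuffleConfig
from tfmutscan.rates import (
    breakpoint_distance_distribution,
    enrichment_test,
    mutation_rate,
    normalized_rate_by_cohort,
    quartile_rates,
)


def _catalog(snvs: pd.DataFrame, cancer_type: str = "") -> MutationCatalog:
    return MutationCatalog(snvs=snvs, cancer_type=cancer_type)


def _snv(chrom, pos, sample="s"):
    return (chrom, pos, "C", "T", sample, np.nan, np.nan)


SNV_COLS = ["chrom", "pos", "ref", "alt", "sample_id", "vaf", "caller_count"]


class TestMutationRate:
    def test_five_snvs_in_50kb_is_100_per_mb(self):
        rs = RegionSet.from_arrays(["chr1"], [0], [50_000])
        snvs = pd.DataFrame([_snv("chr1", p) for p in
                             (10, 200, 3000, 40_000, 49_999)],
                            columns=SNV_COLS)
        assert mutation_rate(rs, _catalog(snvs)) == pytest.approx(100.0)

    def test_zero_mutations_zero_rate(self):
        rs = RegionSet.from_arrays(["chr1"], [0], [1000])
        assert mutation_rate(rs, _catalog(pd.DataFrame(columns=SNV_COLS))) == 0

    def test_zero_bp_errors(self):
        with pytest.raises(ValueError):
            mutation_rate(RegionSet(), _catalog(pd.DataFrame(columns=SNV_COLS)))

    def test_matches_brute_force(self, toy_genome):
        rs = random_regions(61, toy_genome, 25)
        snvs = random_snvs(62, toy_genome, 400)
        want = brute_counts(rs, snvs).sum() / rs.total_bp * 1e6
        assert mutation_rate(rs, _catalog(snvs)) == pytest.approx(want)


class TestEnrichmentTest:
    def test_planted_enrichment_gives_p_raw_zero(self, toy_genome):
        # 5 SNVs in each of 10 regions, none elsewhere; a single shuffled
        # interval can recapture at most one cluster, so no null rate can
        # reach the observed rate
        rs = RegionSet.from_arrays(["chr1"] * 10,
                                   range(1000, 41_000, 4000),
                                   range(1500, 41_500, 4000))
        snvs = pd.DataFrame([_snv("chr1", 1100 + 4000 * r + i)
                             for r in range(10) for i in range(5)],
                            columns=SNV_COLS)
        res = enrichment_test(rs, _catalog(snvs), toy_genome,
                              ShuffleConfig(n_iterations=500, seed=1))
        assert res.p_raw == 0.0
        assert res.p_add_one == pytest.approx(1 / 501)
        assert res.fold > 10

    def test_zero_catalog_degenerate(self, toy_genome):
        rs = RegionSet.from_arrays(["chr1"], [0], [500])
        res = enrichment_test(rs, _catalog(pd.DataFrame(columns=SNV_COLS)),
                              toy_genome, ShuffleConfig(100, seed=2))
        assert res.observed_rate == 0.0
        assert res.fold == 0.0
        assert res.p_raw == 1.0  # ties (all-zero null) count as >=

    def test_null_vector_retained_with_length_n(self, toy_genome):
        rs = random_regions(71, toy_genome, 5)
        snvs = random_snvs(72, toy_genome, 100)
        res = enrichment_test(rs, _catalog(snvs), toy_genome,
                              ShuffleConfig(250, seed=3))
        assert len(res.null_rates) == 250
        assert 0 < res.p_add_one <= 1

    def test_p_add_one_never_zero_and_monotone(self, toy_genome):
        rs = random_regions(73, toy_genome, 5)
        snvs = random_snvs(74, toy_genome, 200)
        res = enrichment_test(rs, _catalog(snvs), toy_genome,
                              ShuffleConfig(200, seed=4))
        null = res.null_rates
        n = len(null)
        ps = []
        for obs in np.linspace(0, null.max() * 1.1, 25):
            ps.append((1 + (null >= obs).sum()) / (n + 1))
        assert all(p > 0 for p in ps)
        assert all(a >= b for a, b in zip(ps, ps[1:]))  # non-increasing


class TestNormalizedRateByCohort:
    def test_region_rate_equal_genome_rate_gives_ratio_one(self, toy_genome):
        # one SNV inside the region, region is 1/80 of genome -> put 1 in
        # region and spread the rest to equalize the rates exactly:
        # simplest exact case: regions = whole genome
        rs = RegionSet.from_arrays(
            ["chr1", "chr2"], [0, 0],
            [toy_genome.lengths["chr1"], toy_genome.lengths["chr2"]])
        snvs = random_snvs(81, toy_genome, 50)
        out = normalized_rate_by_cohort(rs, {"X": _catalog(snvs, "X")},
                                        toy_genome)
        assert out["normalized_rate"].iloc[0] == pytest.approx(1.0)

    def test_identical_catalogs_identical_distributions(self, toy_genome):
        rs = random_regions(82, toy_genome, 10)
        snvs = random_snvs(83, toy_genome, 300)
        out = normalized_rate_by_cohort(
            rs, {"A": _catalog(snvs, "A"), "B": _catalog(snvs, "B")},
            toy_genome)
        a = out[out["cancer_type"] == "A"]["normalized_rate"].to_numpy()
        b = out[out["cancer_type"] == "B"]["normalized_rate"].to_numpy()
        np.testing.assert_allclose(a, b)

    def test_zero_mutation_sample_excluded_with_warning(self, toy_genome):
        rs = random_regions(84, toy_genome, 10)
        snvs = random_snvs(85, toy_genome, 40, sample_id="sA")
        cat = MutationCatalog(snvs=snvs, samples={"sA", "sEmpty"})
        with pytest.warns(UserWarning, match="sEmpty"):
            out = normalized_rate_by_cohort(rs, {"X": cat}, toy_genome)
        assert set(out["sample_id"]) == {"sA"}

    def test_planted_regional_enrichment_recovered(self, toy_genome):
        # cohort P: 5x as many SNVs inside regions as expected; cohort F flat
        rs = RegionSet.from_arrays(["chr1"], [10_000], [20_000])
        rng = np.random.default_rng(86)
        rows_f, rows_p = [], []
        for sample in ("f1", "f2", "f3"):
            for p in rng.integers(1, 50_000, size=200):
                rows_f.append(_snv("chr1", int(p), sample))
        for sample in ("p1", "p2", "p3"):
            for p in rng.integers(1, 50_000, size=200):
                rows_p.append(_snv("chr1", int(p), sample))
            for p in rng.integers(10_001, 20_000, size=160):
                rows_p.append(_snv("chr1", int(p), sample))
        out = normalized_rate_by_cohort(
            rs,
            {"flat": _catalog(pd.DataFrame(rows_f, columns=SNV_COLS), "flat"),
             "planted": _catalog(pd.DataFrame(rows_p, columns=SNV_COLS),
                                 "planted")},
            toy_genome)
        med = out.groupby("cancer_type")["normalized_rate"].median()
        assert med["planted"] > 2 * med["flat"]


class TestQuartileRates:
    def test_eight_intervals_grouped_by_score(self):
        rs = RegionSet.from_arrays(
            ["chr1"] * 8, range(0, 8000, 1000),
            range(500, 8500, 1000), score=[1, 2, 3, 4, 5, 6, 7, 8])
        qr = quartile_rates(rs, _catalog(pd.DataFrame(columns=SNV_COLS)))
        got = [sorted(q.df["score"]) for q in qr.quartiles]
        assert got == [[1, 2], [3, 4], [5, 6], [7, 8]]

    def test_sizes_differ_by_at_most_one(self, toy_genome):
        rs = random_regions(91, toy_genome, 11)
        qr = quartile_rates(rs, _catalog(pd.DataFrame(columns=SNV_COLS)))
        sizes = [len(q) for q in qr.quartiles]
        assert max(sizes) - min(sizes) <= 1
        assert sum(sizes) == 11

    def test_constant_scores_tie_broken_by_genomic_order(self):
        rs = RegionSet.from_arrays(
            ["chr1"] * 8, range(0, 8000, 1000),
            range(500, 8500, 1000), score=[5.0] * 8)
        qr = quartile_rates(rs, _catalog(pd.DataFrame(columns=SNV_COLS)))
        starts = [sorted(q.df["start"]) for q in qr.quartiles]
        assert starts == [[0, 1000], [2000, 3000], [4000, 5000],
                          [6000, 7000]]

    def test_fewer_than_four_errors(self):
        rs = RegionSet.from_arrays(["chr1"] * 3, [0, 10, 20], [5, 15, 25],
                                   score=[1, 2, 3])
        with pytest.raises(ValueError):
            quartile_rates(rs, _catalog(pd.DataFrame(columns=SNV_COLS)))

    def test_missing_scores_rejected(self):
        rs = RegionSet.from_arrays(["chr1"] * 4, [0, 10, 20, 30],
                                   [5, 15, 25, 35])
        with pytest.raises(ValueError, match="score"):
            quartile_rates(rs, _catalog(pd.DataFrame(columns=SNV_COLS)))


class TestBreakpointDistances:
    def test_matches_brute_force_and_inside_zero(self, toy_genome):
        snvs = random_snvs(95, toy_genome, 100, sample_id="sA")
        bps = random_regions(96, toy_genome, 20)
        cat = MutationCatalog(snvs=snvs, samples={"sA"})
        table, summary = breakpoint_distance_distribution(cat, {"sA": bps})
        pts = {str(c): g["pos"].to_numpy() - 1
               for c, g in snvs.groupby("chrom")}
        want = brute_closest(pts, bps)
        got = {str(c): g.sort_values("pos")["distance"].to_numpy()
               for c, g in table.groupby("chrom")}
        for c in pts:
            w = want[c][np.argsort(pts[c], kind="stable")]
            assert got[c].tolist() == w.tolist()
        assert "median" in summary.columns

    def test_sample_without_breakpoints_flagged(self, toy_genome):
        snvs = random_snvs(97, toy_genome, 10, sample_id="sB")
        cat = MutationCatalog(snvs=snvs, samples={"sB"})
        table, summary = breakpoint_distance_distribution(cat, {})
        assert table["no_breakpoints"].all()
        assert (table["distance"] == -1).all()
        assert len(summary) == 0
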