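import numpy as np
import pandas as pd
import pytest

from clonalscape import divstats
from conftest import make_matrix
from _oracles import (pairwise_pi_sum, tajimas_d, watterson_sum,
                      wc_fst_components)


class TestThetaPi:
    def test_single_het_pair(self):
        # 2 samples both 0/1: alleles {0,0,1,1}, 2*2=4 differing of C(4,2)=6
        g = make_matrix([[1, 1]], pos=[50_000])
        track = divstats.window_theta_pi(g, span=100_000,
                                         chrom_lengths=[("chr1", 100_000)])
        assert track["theta_pi"].iloc[0] == pytest.approx(4 / 6 / 100_000)

    def test_monomorphic_window_zero(self):
        g = make_matrix([[0, 0, 0]], pos=[10])
        track = divstats.window_theta_pi(g, span=100_000,
                                         chrom_lengths=[("chr1", 100_000)])
        assert track["theta_pi"].iloc[0] == 0.0

    def test_matches_allpairs_oracle(self, random_matrix):
        track = divstats.window_theta_pi(
            random_matrix, span=500_000, chrom_lengths=[("chr1", 500_000)])
        expect = pairwise_pi_sum(random_matrix.calls) / 500_000
        assert track["theta_pi"].iloc[0] == pytest.approx(expect, rel=1e-10)


class TestThetaW:
    def test_harmonic_formula(self):
        # 3 segregating sites, k=4 alleles: theta_w = 3 / a1 / span
        g = make_matrix([[1, 0], [0, 1], [1, 2]], pos=[10, 20, 30])
        track = divstats.window_theta_w(g, span=100_000,
                                        chrom_lengths=[("chr1", 100_000)])
        a1 = 1 + 1 / 2 + 1 / 3
        assert track["theta_w"].iloc[0] == pytest.approx(3 / a1 / 1e5,
                                                         rel=1e-10)
        assert track["theta_w"].iloc[0] == pytest.approx(1.636e-5, rel=1e-3)

    def test_no_segregating_sites(self):
        g = make_matrix([[0, 0], [2, 2]], pos=[10, 20])
        track = divstats.window_theta_w(g, span=100_000,
                                        chrom_lengths=[("chr1", 100_000)])
        # site fixed for alt has no within-sample variation: not segregating
        assert track["theta_w"].iloc[0] == 0.0

    def test_matches_oracle_with_missing_data(self, random_matrix):
        track = divstats.window_theta_w(
            random_matrix, span=500_000, chrom_lengths=[("chr1", 500_000)])
        expect = watterson_sum(random_matrix.calls) / 500_000
        assert track["theta_w"].iloc[0] == pytest.approx(expect, rel=1e-10)


class TestTajimasD:
    def test_published_constants(self):
        # k=4, S=3, summed pi = 2.0
        d = divstats.tajimas_d_from_counts(3, 2.0, 4)
        assert d == pytest.approx(tajimas_d(3, 2.0, 4), rel=1e-12)
        assert d == pytest.approx(2.01, abs=0.01)

    def test_zero_when_pi_equals_watterson(self):
        a1 = 1 + 1 / 2 + 1 / 3
        assert divstats.tajimas_d_from_counts(3, 3 / a1, 4) == pytest.approx(
            0.0, abs=1e-12)

    def test_undefined_cases(self):
        assert np.isnan(divstats.tajimas_d_from_counts(0, 0.0, 10))
        assert np.isnan(divstats.tajimas_d_from_counts(3, 1.0, 2))

    def test_neutral_coalescent_expectations(self):
        """On msprime neutral data: mean D near 0 and theta_pi ~ theta_w."""
        msprime = pytest.importorskip("msprime")
        ts = msprime.sim_ancestry(
            samples=10, sequence_length=20_000_000,
            recombination_rate=1e-8, population_size=10_000,
            random_seed=7)
        ts = msprime.sim_mutations(ts, rate=1e-8, random_seed=7,
                                   model=msprime.BinaryMutationModel())
        calls, pos = [], []
        for var in ts.variants():
            gt = np.asarray(var.genotypes).reshape(-1, 2).sum(axis=1)
            p = int(var.site.position) + 1
            if pos and p <= pos[-1]:
                continue
            calls.append(gt)
            pos.append(p)
        g = make_matrix(np.array(calls, dtype=np.int8), pos=pos,
                        sample_ids=[f"I{i}" for i in range(10)])
        span = 100_000
        lens = [("chr1", 20_000_000)]
        d = divstats.window_tajimas_d(g, span, lens)
        defined = d["tajima_d"].dropna()
        assert len(defined) >= 190
        assert abs(defined.mean()) <= 0.3
        pi = divstats.window_theta_pi(g, span, lens)["theta_pi"]
        tw = divstats.window_theta_w(g, span, lens)["theta_w"]
        assert pi.mean() == pytest.approx(tw.mean(), rel=0.15)
        # theta per bp should be near 4*Ne*mu = 4e-4
        assert pi.mean() == pytest.approx(4e-4, rel=0.25)


class TestFst:
    def test_fixed_difference_is_one(self):
        calls = [[0] * 10 + [2] * 10]
        g = make_matrix(calls)
        labels = ["p1"] * 10 + ["p2"] * 10
        track = divstats.window_fst(g, labels, span=100_000,
                                    chrom_lengths=[("chr1", 100_000)])
        assert track["fst"].iloc[0] == pytest.approx(1.0)

    def test_toy_counts_match_component_oracle(self):
        # pop1: six 0/0 + two 0/1; pop2: two 0/0 + six 0/1
        calls = [[0] * 6 + [1] * 2 + [0] * 2 + [1] * 6]
        g = make_matrix(calls)
        labels = ["p1"] * 8 + ["p2"] * 8
        comp = divstats.site_fst_components(g, labels)
        a, b, c = wc_fst_components(np.array(calls[0]), labels)
        assert comp["a"].iloc[0] == pytest.approx(a, rel=1e-10)
        assert comp["b"].iloc[0] == pytest.approx(b, rel=1e-10)
        assert comp["c"].iloc[0] == pytest.approx(c, rel=1e-10)

    def test_null_populations_near_zero(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0.2, 0.8, 2000)
        calls = rng.binomial(2, p[:, None], (2000, 40)).astype(np.int8)
        g = make_matrix(calls, pos=np.arange(1, 2001) * 10)
        labels = ["p1"] * 20 + ["p2"] * 20
        track = divstats.window_fst(g, labels, span=100_000,
                                    chrom_lengths=[("chr1", 100_000)])
        assert abs(track["fst"].iloc[0]) <= 0.02

    def test_single_site_window_equals_site_ratio(self):
        calls = [[0, 0, 1, 1, 1, 2, 2, 0]]
        g = make_matrix(calls)
        labels = ["p1"] * 4 + ["p2"] * 4
        comp = divstats.site_fst_components(g, labels)
        site_ratio = comp["a"].iloc[0] / (comp["a"] + comp["b"]
                                          + comp["c"]).iloc[0]
        track = divstats.window_fst(g, labels, span=100_000,
                                    chrom_lengths=[("chr1", 100_000)])
        assert track["fst"].iloc[0] == pytest.approx(site_ratio, rel=1e-12)


class TestDaf:
    def test_ref_homozygous_outgroup(self):
        # outgroup 0/0; ingroup {0/1, 1/1, 0/0} -> derived = alt, DAF = 3/6
        g = make_matrix([[1, 2, 0, 0]],
                        sample_ids=["A", "B", "C", "OG"])
        track, per_site = divstats.polarize_and_daf(
            g, "OG", span=100_000, chrom_lengths=[("chr1", 100_000)])
        assert per_site["daf"].iloc[0] == pytest.approx(0.5)

    def test_alt_homozygous_outgroup_fixed_ingroup(self):
        # outgroup 1/1, ingroup all 1/1: derived allele is ref, absent
        g = make_matrix([[2, 2, 2, 2]], sample_ids=["A", "B", "C", "OG"])
        _, per_site = divstats.polarize_and_daf(
            g, "OG", span=100_000, chrom_lengths=[("chr1", 100_000)])
        assert per_site["daf"].iloc[0] == pytest.approx(0.0)

    def test_het_outgroup_not_polarizable(self):
        g = make_matrix([[1, 2, 0, 1]], sample_ids=["A", "B", "C", "OG"])
        track, per_site = divstats.polarize_and_daf(
            g, "OG", span=100_000, chrom_lengths=[("chr1", 100_000)])
        assert not per_site["polarizable"].iloc[0]
        assert track["n_polarizable"].iloc[0] == 0

    def test_outgroup_coverage_on_synthetic_data(self, default_sim):
        cfg, g, meta, truth = default_sim
        og_col = g.sample_ids.index(cfg.outgroup_id)
        og = g.calls[:, og_col]
        called = og[og >= 0]
        assert np.mean((called == 0) | (called == 2)) >= 0.99


class TestTopQuantileRegions:
    def _track(self, values):
        starts = np.arange(len(values)) * 100_000 + 1
        return pd.DataFrame({"chrom": "chr1", "start": starts,
                             "end": starts + 99_999, "span": 100_000,
                             "score": values})

    def test_top_one_percent_of_hundred(self):
        regions = divstats.top_quantile_regions(
            self._track(np.arange(1, 101)), 0.01)
        assert regions.cutoff == 100
        assert len(regions.intervals) == 1
        assert regions.intervals["n_windows"].iloc[0] == 1

    def test_all_equal_ties_qualify(self):
        regions = divstats.top_quantile_regions(self._track([5.0] * 20), 0.1)
        assert regions.intervals["n_windows"].sum() == 20

    def test_qualifying_count_matches_sort_and_slice(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(0, 1, 500)
        uf = 0.02
        regions = divstats.top_quantile_regions(self._track(vals), uf)
        n_q = regions.intervals["n_windows"].sum()
        expect = int(np.ceil(uf * len(vals)))
        cutoff = np.sort(vals)[::-1][expect - 1]
        ties = int((vals == cutoff).sum())
        assert expect <= n_q <= expect + ties
        assert regions.cutoff == pytest.approx(
            np.sort(vals)[::-1][n_q - 1], rel=1e-12)

    def test_adjacent_windows_merge(self):
        vals = [0, 0, 10, 11, 12, 0, 0, 10, 0, 0]
        regions = divstats.top_quantile_regions(self._track(vals), 0.4)
        assert len(regions.intervals) == 2
        assert regions.intervals["n_windows"].tolist() == [3, 1]


class TestGeneOverlap:
    def test_shared_single_bp(self):
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [6000],
                                "end": [7000]})
        genes = pd.DataFrame({"chrom": ["chr1"], "start": [5000],
                              "end": [6000], "gene_id": ["g1"]})
        assert divstats.genes_overlapping_regions(regions, genes) == [["g1"]]

    def test_adjacent_but_disjoint(self):
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [6000],
                                "end": [7000]})
        genes = pd.DataFrame({"chrom": ["chr1"], "start": [5000],
                              "end": [5999], "gene_id": ["g1"]})
        assert divstats.genes_overlapping_regions(regions, genes) == [[]]
        assert divstats.genes_overlapping_regions(regions, genes,
                                                  flank=1) == [["g1"]]

    def test_matches_quadratic_scan(self):
        rng = np.random.default_rng(8)
        r_start = rng.integers(1, 100_000, 200)
        g_start = rng.integers(1, 100_000, 200)
        regions = pd.DataFrame({"chrom": "chr1", "start": r_start,
                                "end": r_start + rng.integers(1, 5000, 200)})
        genes = pd.DataFrame({"chrom": "chr1", "start": g_start,
                              "end": g_start + rng.integers(1, 3000, 200),
                              "gene_id": [f"g{i}" for i in range(200)]})
        got = divstats.genes_overlapping_regions(regions, genes)
        for row, hits in zip(regions.itertuples(), got):
            expect = [g.gene_id for g in genes.itertuples()
                      if g.start <= row.end and g.end >= row.start]
            assert sorted(hits) == sorted(expect)
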