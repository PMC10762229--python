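"""Insulation scores, boundary calling, stacking, and overlap statistics."""

import numpy as np
import pandas as pd
import pytest

from microdomain import (
    BinnedGenome,
    RegionSet,
    SignalTrack,
    annotate_regions,
    balance_ice,
    call_boundaries,
    insulation_score,
    overlap_stats,
    permutation_overlap,
    stack_track,
)
from microdomain.boundaries import _minima_with_prominence
from conftest import make_matrix, random_dense
from oracles import brute_prominences, dense_insulation, quadratic_overlap


def _track(values, bin_size=200, window=None, chrom="chrT"):
    g = BinnedGenome((chrom,), (len(values) * bin_size,), bin_size)
    meta = {"window": window} if window else {}
    return SignalTrack(g, {chrom: np.asarray(values, float)}, meta)


class TestInsulation:
    def test_uniform_matrix_scores_zero(self, uniform_matrix):
        t = insulation_score(uniform_matrix, window=1000)
        v = t["chrT"]
        assert np.allclose(v[np.isfinite(v)], 0.0, atol=1e-12)
        # defined exactly where the full diamond fits
        assert np.isnan(v[:5]).all() and np.isnan(v[-5:]).all()

    def test_scale_invariance_and_normalization(self):
        dense = random_dense(80, seed=3)
        t1 = insulation_score(_bal(dense), window=1000)
        t2 = insulation_score(_bal(dense * 7.5), window=1000)
        v1, v2 = t1["chrT"], t2["chrT"]
        assert np.allclose(v1[np.isfinite(v1)], v2[np.isfinite(v2)], atol=1e-9)
        assert np.nanmean(2 ** v1) == pytest.approx(1.0, abs=1e-6)

    def test_dense_oracle_block_matrix(self):
        n = 60
        dense = np.full((n, n), 0.05)
        dense[:30, :30] += 3.0
        dense[30:, 30:] += 3.0
        dense += np.eye(n)
        m = make_matrix(dense)
        m.weights = {"chrT": np.ones(n)}  # already uniform marginals not needed: raw check
        t = insulation_score(m, window=5 * 200)
        got = t["chrT"]
        want = dense_insulation(dense, 5)
        assert np.allclose(got[np.isfinite(want)], want[np.isfinite(want)], atol=1e-10)
        # unique minimum at the block junction
        assert np.nanargmin(got) in (29, 30)

    def test_non_multiple_window_errors(self, uniform_matrix):
        with pytest.raises(ValueError):
            insulation_score(uniform_matrix, window=700)

    def test_short_chromosome_all_nan(self):
        m = _bal(random_dense(8, seed=0))
        with pytest.warns(UserWarning, match="shorter"):
            t = insulation_score(m, window=1000)
        assert np.isnan(t["chrT"]).all()


def _bal(dense):
    return balance_ice(make_matrix(dense), tol=1e-12)


class TestCallBoundaries:
    def test_constant_track_no_minima(self):
        t = _track(np.zeros(50), window=200)
        bset = call_boundaries(t)
        assert len(bset) == 0 and bset.n_candidates == 0

    def test_quantile_count_and_ranking(self):
        # 8 well-separated minima of graded depth on a smooth baseline
        n = 200
        v = np.zeros(n)
        depths = [4.0, 3.5, 3.0, 2.5, 2.0, 1.5, 1.0, 0.5]
        pos = np.arange(20, 180, 20)
        for p, d in zip(pos, depths):
            v[p] = -d
        t = _track(v, window=200)
        bset = call_boundaries(t, keep_fraction=0.25, min_prominence=0.0)
        assert bset.n_candidates == 8
        assert len(bset) == 2  # ceil(0.25 * 8)
        got = set(bset.regions.df["start"] // 200)
        assert got == {20, 40}  # the two deepest
        # keep_fraction 1 returns every minimum
        assert len(call_boundaries(t, keep_fraction=1.0, min_prominence=0.0)) == 8

    def test_prominence_matches_brute_force(self):
        rng = np.random.default_rng(11)
        v = np.cumsum(rng.normal(0, 1, 300))
        v[:3] = np.nan
        v[-4:] = np.nan
        minima, proms = _minima_with_prominence(v)
        bm, bp = brute_prominences(v)
        assert np.array_equal(minima, bm)
        assert np.allclose(proms, bp)

    def test_strength_quantile_consistency(self):
        rng = np.random.default_rng(5)
        t = _track(np.cumsum(rng.normal(0, 1, 400)), window=200)
        bset = call_boundaries(t, keep_fraction=0.3, min_prominence=0.0)
        assert len(bset) == int(np.ceil(0.3 * bset.n_candidates))
        kept = bset.regions.df["strength"].min()
        rejected = bset.candidates[
            ~bset.candidates["bin"].isin(bset.regions.df["start"] // 200)
        ]["strength"]
        if len(rejected):
            assert kept >= rejected.max() - 1e-12

    def test_bad_keep_fraction(self):
        with pytest.raises(ValueError):
            call_boundaries(_track(np.zeros(10)), keep_fraction=0.0)

    def test_flanks_partition_between_boundaries(self):
        v = np.zeros(100)
        v[[20, 50, 80]] = -3.0
        bset = call_boundaries(_track(v, window=200), keep_fraction=1.0, min_prominence=0.0)
        f = bset.flanks.df
        assert list(f["start"] // 200) == [21, 51]
        assert list(f["end"] // 200) == [50, 80]


class TestStackTrack:
    def test_constant_track(self):
        t = _track(np.full(100, 3.25))
        anchors = RegionSet.from_arrays(["chrT"] * 3, [4000, 8000, 12000], [4001, 8001, 12001])
        stack, mean = stack_track(t, anchors, flank=1000)
        assert np.allclose(stack, 3.25)
        assert np.allclose(mean, 3.25)

    def test_single_anchor_is_slice(self):
        v = np.arange(100.0)
        t = _track(v)
        anchors = RegionSet.from_arrays(["chrT"], [50 * 200], [50 * 200 + 1])
        stack, mean = stack_track(t, anchors, flank=600)
        assert np.allclose(stack[0], v[47:54])

    def test_minus_strand_flipped(self):
        v = np.arange(100.0)
        t = _track(v)
        anchors = RegionSet.from_arrays(["chrT"], [50 * 200], [50 * 200 + 1], strand=["-"])
        stack, _ = stack_track(t, anchors, flank=600)
        assert np.allclose(stack[0], v[47:54][::-1])

    def test_chromosome_end_nan_padded(self):
        t = _track(np.ones(20))
        anchors = RegionSet.from_arrays(["chrT"], [100], [101])
        stack, _ = stack_track(t, anchors, flank=1000)
        assert np.isnan(stack[0][:5]).sum() > 0

    def test_empty_anchors_error(self):
        t = _track(np.ones(20))
        with pytest.raises(ValueError):
            stack_track(t, RegionSet(pd.DataFrame({"chrom": [], "start": [], "end": []})), flank=200)


class TestAnnotateRegions:
    @pytest.fixture
    def genes(self):
        return RegionSet.from_arrays(
            ["c", "c"], [5000, 20_000], [8000, 24_000], strand=["+", "-"], name=["g1", "g2"]
        )

    def test_promoter_precedence(self, genes):
        # query overlapping both the g1 promoter window and its gene body
        q = RegionSet.from_arrays(["c"], [4900], [5200])
        out = annotate_regions(q, genes)
        assert out.set_index("category").loc["promoter", "count"] == 1

    def test_plain_promoter_and_strand_awareness(self, genes):
        q = RegionSet.from_arrays(["c", "c"], [4000, 24_500], [4100, 24_600])
        out = annotate_regions(q, genes).set_index("category")
        assert out.loc["promoter", "count"] == 2  # g2 promoter is downstream-of-end on minus strand

    def test_unstranded_genes_error(self):
        genes = RegionSet.from_arrays(["c"], [100], [200])
        with pytest.raises(ValueError):
            annotate_regions(RegionSet.from_arrays(["c"], [0], [10]), genes)

    def test_counts_match_interval_oracle(self, genes):
        rng = np.random.default_rng(3)
        starts = rng.integers(0, 40_000, 100)
        q = RegionSet.from_arrays(["c"] * 100, starts, starts + 50)
        out = annotate_regions(q, genes).set_index("category")["count"]

        def oracle_cat(s, e):
            ivs = {
                "promoter": [(3500, 5000), (24_000, 25_500)],
                "gene_body": [(5000, 8000), (20_000, 24_000)],
                "downstream": [(8000, 9500), (18_500, 20_000)],
            }
            for kind in ("promoter", "gene_body", "downstream"):
                if any(s < ie and e > is_ for is_, ie in ivs[kind]):
                    return kind
            return "intergenic"

        want = pd.Series([oracle_cat(s, s + 50) for s in starts]).value_counts()
        for cat in ("promoter", "gene_body", "downstream", "intergenic"):
            assert out[cat] == want.get(cat, 0)


class TestOverlap:
    def test_full_cover_fraction_one(self, tiny_genome):
        a = RegionSet.from_arrays(["chrA"] * 4, [0, 100, 5000, 9000], [50, 200, 5100, 9100])
        b = RegionSet.from_arrays(["chrA"], [0], [10_000])
        n, frac = overlap_stats(a, b)
        assert (n, frac) == (4, 1.0)

    def test_disjoint_zero(self):
        a = RegionSet.from_arrays(["c"], [0], [10])
        b = RegionSet.from_arrays(["c"], [100], [110])
        assert overlap_stats(a, b) == (0, 0.0)

    def test_quadratic_oracle(self):
        rng = np.random.default_rng(9)
        a_st = rng.integers(0, 5000, 20)
        b_st = rng.integers(0, 5000, 20)
        a = RegionSet.from_arrays(["c"] * 20, a_st, a_st + rng.integers(10, 300, 20))
        b = RegionSet.from_arrays(["c"] * 20, b_st, b_st + rng.integers(10, 300, 20))
        n, _ = overlap_stats(a, b)
        assert n == quadratic_overlap(a.df, b.df)

    def test_empty_query_errors(self):
        b = RegionSet.from_arrays(["c"], [0], [10])
        with pytest.raises(ValueError):
            overlap_stats(RegionSet(pd.DataFrame({"chrom": [], "start": [], "end": []})), b)


class TestPermutationOverlap:
    def test_whole_genome_cover_p_one(self, tiny_genome):
        a = RegionSet.from_arrays(["chrA"] * 5, [0, 1000, 2000, 3000, 4000], np.array([0, 1000, 2000, 3000, 4000]) + 100)
        b = RegionSet.from_arrays(["chrA", "chrB"], [0, 0], [10_000, 6_000])
        res = permutation_overlap(a, b, tiny_genome, n_perm=99, seed=1)
        assert res["observed"] == 5
        assert res["p"] == 1.0

    def test_planted_enrichment_min_p(self):
        g = BinnedGenome(("c",), (10_000_000,), 200)
        rng = np.random.default_rng(2)
        st = rng.integers(0, 9_999_000, 30)
        a = RegionSet.from_arrays(["c"] * 30, st, st + 500)
        b = RegionSet.from_arrays(["c"] * 30, st - 100, st + 600)
        res = permutation_overlap(a, b, g, n_perm=999, seed=3)
        assert res["p"] == pytest.approx(1 / 1000)

    def test_region_longer_than_chromosome_errors(self, tiny_genome):
        a = RegionSet.from_arrays(["chrB"], [0], [60_000])
        b = RegionSet.from_arrays(["chrB"], [0], [100])
        with pytest.raises(ValueError):
            permutation_overlap(a, b, tiny_genome, n_perm=10, seed=0)

    def test_zero_permutations_error(self, tiny_genome):
        a = RegionSet.from_arrays(["chrA"], [0], [100])
        with pytest.raises(ValueError):
            permutation_overlap(a, a, tiny_genome, n_perm=0, seed=0)
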