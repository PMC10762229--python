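"""Aggregate pileups, gene-pair geometry, strata, SE pattern scores."""

import numpy as np
import pandas as pd
import pytest

from microdomain import (
    RegionSet,
    balance_ice,
    classify_gene_pairs,
    expression_strata,
    observed_over_expected,
    pileup_centered,
    pileup_difference,
    pileup_rescaled,
    se_pattern_score,
)
from conftest import make_matrix, random_dense
from oracles import dense_centered_pileup, dense_oe, dense_rescaled_block


def _bal(dense):
    return balance_ice(make_matrix(dense), tol=1e-12)


def _dense_oe_of(mb):
    w = mb.weights["chrT"]
    return dense_oe(mb.dense("chrT") * np.outer(w, w))


class TestGenePairs:
    @pytest.mark.parametrize(
        "s1,s2,label",
        [("-", "+", "divergent"), ("+", "-", "convergent"), ("+", "+", "tandem"), ("-", "-", "tandem")],
    )
    def test_definitions(self, s1, s2, label):
        genes = RegionSet.from_arrays(["c", "c"], [0, 2000], [1000, 3000], strand=[s1, s2])
        out = classify_gene_pairs(genes, max_gap=5000)
        assert out["label"].tolist() == [label]

    def test_gap_filter(self):
        genes = RegionSet.from_arrays(["c", "c"], [0, 50_000], [1000, 51_000], strand=["+", "+"])
        assert len(classify_gene_pairs(genes, max_gap=10_000)) == 0


class TestExpressionStrata:
    def test_quantile_oracle(self):
        expr = [0, 0, 1, 2, 3, 4, 5, 6, 7, 8, 9]
        genes = RegionSet.from_arrays(
            ["c"] * 11, np.arange(11) * 1000, np.arange(11) * 1000 + 500, expression=expr
        )
        labels = expression_strata(genes, n_classes=3).df["expression_class"].tolist()
        assert labels[:2] == [1, 1]  # silent class
        assert labels[2:] == [2, 2, 2, 2, 2, 3, 3, 3, 3]  # median split, sizes differ <= 1

    def test_all_equal_ties_stable(self):
        genes = RegionSet.from_arrays(
            ["c"] * 7, np.arange(7) * 1000, np.arange(7) * 1000 + 500, expression=[2.0] * 7
        )
        labels = np.array(expression_strata(genes, n_classes=4).df["expression_class"])
        sizes = np.bincount(labels)[2:]
        assert sizes.max() - sizes.min() <= 1
        assert (np.diff(labels) >= 0).all()  # stable input order

    def test_single_class(self):
        genes = RegionSet.from_arrays(["c"] * 3, [0, 1000, 2000], [500, 1500, 2500], expression=[1, 2, 3])
        assert set(expression_strata(genes, n_classes=1).df["expression_class"]) == {1}

    def test_all_silent_warns(self):
        genes = RegionSet.from_arrays(["c"] * 3, [0, 1000, 2000], [500, 1500, 2500], expression=[0, 0, 0])
        with pytest.warns(UserWarning, match="silenced"):
            labels = expression_strata(genes).df["expression_class"]
        assert set(labels) == {1}


class TestCenteredPileup:
    def test_uniform_enrichment_one(self, uniform_matrix):
        anchors = RegionSet.from_arrays(["chrT"] * 4, [4000, 6000, 8000, 10_000], [4001, 6001, 8001, 10_001])
        res = pileup_centered(uniform_matrix, anchors, flank=1000, seed=0)
        assert np.allclose(res.enrichment, 1.0)

    def test_single_anchor_equals_dense_slice(self):
        mb = _bal(random_dense(40, seed=6))
        oe = _dense_oe_of(mb)
        anchors = RegionSet.from_arrays(["chrT"], [20 * 200], [20 * 200 + 1])
        res = pileup_centered(mb, anchors, flank=1000, seed=0)
        assert np.allclose(res.grid, oe[15:26, 15:26], atol=1e-10)

    def test_multi_anchor_dense_oracle(self):
        mb = _bal(random_dense(50, seed=8))
        oe = _dense_oe_of(mb)
        centers = [10, 25, 40]
        anchors = RegionSet.from_arrays(
            ["chrT"] * 3, [c * 200 for c in centers], [c * 200 + 1 for c in centers]
        )
        res = pileup_centered(mb, anchors, flank=800, seed=0)
        assert np.allclose(res.grid, dense_centered_pileup(oe, centers, 4), atol=1e-10, equal_nan=True)

    def test_strand_mirror_transposes_grid(self):
        mb = _bal(random_dense(50, seed=8))
        pos = [10 * 200, 30 * 200]
        plus = RegionSet.from_arrays(["chrT"] * 2, pos, [p + 1 for p in pos], strand=["+", "+"])
        minus = RegionSet.from_arrays(["chrT"] * 2, pos, [p + 1 for p in pos], strand=["-", "-"])
        g1 = pileup_centered(mb, plus, flank=800, seed=0).grid
        g2 = pileup_centered(mb, minus, flank=800, seed=0).grid
        assert np.allclose(g2, g1[::-1, ::-1], atol=1e-12, equal_nan=True)

    def test_empty_anchors_error(self, uniform_matrix):
        with pytest.raises(ValueError):
            pileup_centered(
                uniform_matrix, RegionSet(pd.DataFrame({"chrom": [], "start": [], "end": []})), flank=1000
            )


class TestRescaledPileup:
    def test_uniform_enrichment_one(self, uniform_matrix):
        regions = RegionSet.from_arrays(["chrT"] * 2, [3000, 7000], [4200, 8200])
        res = pileup_rescaled(uniform_matrix, regions, out_size=11, seed=0)
        assert np.allclose(res.enrichment[np.isfinite(res.enrichment)], 1.0)

    def test_single_region_dense_resize_oracle(self):
        mb = _bal(random_dense(60, seed=4))
        oe = _dense_oe_of(mb)
        s, e = 20, 30  # bins; flank_frac 1 -> block rows 10..40
        regions = RegionSet.from_arrays(["chrT"], [s * 200], [e * 200])
        res = pileup_rescaled(mb, regions, out_size=10, flank_frac=1.0, seed=0)
        want = dense_rescaled_block(oe[10:40, 10:40], 10)
        assert np.allclose(res.grid, want, atol=1e-10, equal_nan=True)

    def test_planted_domain_center_enriched(self):
        n = 80
        dense = np.full((n, n), 1.0)
        dense[30:50, 30:50] *= 4.0
        mb = _bal(dense)
        regions = RegionSet.from_arrays(["chrT"], [30 * 200], [50 * 200])
        res = pileup_rescaled(mb, regions, out_size=12, flank_frac=0.5, seed=0)
        c = res.grid[4:8, 4:8].mean()
        edges = np.nanmean(res.grid[:2, :2])
        # balancing and O/E absorb part of the planted multiplier, but the
        # central block must clearly dominate the flanks
        assert c > 1.5 * edges and c > 1.3

    def test_short_regions_dropped_then_error(self, uniform_matrix):
        regions = RegionSet.from_arrays(["chrT"], [3000], [3400])  # 2 bins
        with pytest.warns(UserWarning, match="dropped"):
            with pytest.raises(ValueError):
                pileup_rescaled(uniform_matrix, regions, out_size=8, seed=0)


class TestPileupDifference:
    def test_zero_and_negation(self, uniform_matrix):
        anchors = RegionSet.from_arrays(["chrT"] * 2, [4000, 8000], [4001, 8001])
        a = pileup_centered(uniform_matrix, anchors, flank=1000, seed=0)
        assert np.allclose(pileup_difference(a, a), 0.0)
        mb = _bal(random_dense(60, seed=2))
        b = pileup_centered(mb, anchors, flank=1000, seed=0)
        assert np.allclose(pileup_difference(a, b), -pileup_difference(b, a), equal_nan=True)

    def test_size_mismatch(self, uniform_matrix):
        anchors = RegionSet.from_arrays(["chrT"], [4000], [4001])
        a = pileup_centered(uniform_matrix, anchors, flank=1000, seed=0)
        b = pileup_centered(uniform_matrix, anchors, flank=800, seed=0)
        with pytest.raises(ValueError):
            pileup_difference(a, b)


class TestSEPattern:
    def _setup(self, pattern, n=400):
        """Deterministic map with one planted SE pattern."""
        dense = np.full((n, n), 1.0)
        a, p = 200, 232  # SE anchor and promoter bins
        if pattern == "loop":
            for di in range(-3, 4):
                for dj in range(-3, 4):
                    dense[a + di, p + dj] += 5 * np.exp(-(di**2 + dj**2) / (2 * 1.5**2))
                    dense[p + dj, a + di] = dense[a + di, p + dj]
        elif pattern == "stripe":
            dense[a - 1 : a + 2, a + 2 : a + 100] *= 4.0
            dense[a + 2 : a + 100, a - 1 : a + 2] = dense[a - 1 : a + 2, a + 2 : a + 100].T
        elif pattern == "domain":
            dense[a : p + 1, a : p + 1] *= 3.0
        mb = _bal(dense)
        se = ("chrT", (a - 5) * 200, (a + 5) * 200)
        genes = RegionSet.from_arrays(["chrT"], [p * 200], [(p + 10) * 200], strand=["+"])
        return mb, se, genes

    @pytest.mark.parametrize("pattern", ["loop", "stripe", "domain"])
    def test_planted_patterns_recovered(self, pattern):
        mb, se, genes = self._setup(pattern)
        cat, scores = se_pattern_score(mb, se, genes)
        assert cat == pattern, scores

    def test_uniform_is_other(self):
        mb, se, genes = self._setup("none")
        cat, scores = se_pattern_score(mb, se, genes)
        assert cat == "other"
        for s in ("loop", "stripe", "domain"):
            assert scores[s] == pytest.approx(1.0, abs=0.05)

    def test_near_end_flagged_other(self):
        mb, _, genes = self._setup("none")
        cat, scores = se_pattern_score(mb, ("chrT", 1000, 2000), genes)
        assert cat == "other" and scores.get("flag") == "near_chromosome_end"


class TestBackgroundCalibration:
    def test_random_anchor_enrichment_near_one(self, bench):
        """Anchors drawn from the background distribution score 1 +- 0.1
        in grid-mean enrichment (>= 200 anchors on the benchmark map)."""
        rng = np.random.default_rng(31)
        chrom = bench["genome"].chrom_names[0]
        L = bench["genome"].length(chrom)
        pos = rng.integers(50_000, L - 50_000, 200)
        anchors = RegionSet.from_arrays([chrom] * 200, pos, pos + 1)
        res = pileup_centered(bench["matrix"], anchors, flank=4_000, seed=32)
        assert abs(np.nanmean(res.enrichment) - 1.0) <= 0.1
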