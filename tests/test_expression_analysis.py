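"""Gene loci, normalization, shift test, locus bins and seLoci."""

import numpy as np
import pandas as pd
import pytest

from enhancer_rewire.enhancer_classify import EnhancerRecord
from enhancer_rewire.expression_analysis import (
    GeneLocus,
    assign_enhancers_to_loci,
    bin_by_enhancer_count,
    build_loci,
    normalize_expression,
    rpe_expression_shift,
    seloci_test,
    wilcoxon_rank_sum_greater,
)
from enhancer_rewire.formats_io import GenomicInterval

from oracles import exact_rank_sum_p_greater, fisher_two_sided


def iv(start, end, seq="chr1"):
    return GenomicInterval(seq, start, end)


def gene(gid, start, end, seq="chr1"):
    return (gid, iv(start, end, seq))


class TestBuildLoci:
    def test_midpoint_boundary(self):
        loci = build_loci([gene("g1", 1000, 2000), gene("g2", 4000, 5000)],
                          {"chr1": 10_000})
        assert [(l.locus.start, l.locus.end) for l in loci] == [(0, 3000), (3000, 10_000)]

    def test_single_gene_takes_whole_sequence(self):
        [l] = build_loci([gene("g1", 400, 600)], {"chr1": 5000})
        assert (l.locus.start, l.locus.end) == (0, 5000)

    def test_three_genes_gap_midpoints(self):
        # gaps of 100 and 600 -> boundaries 50 and 300 into each gap
        loci = build_loci(
            [gene("g1", 0, 500), gene("g2", 600, 900), gene("g3", 1500, 1600)],
            {"chr1": 2000},
        )
        assert [(l.locus.start, l.locus.end) for l in loci] == [
            (0, 550), (550, 1200), (1200, 2000)
        ]

    def test_tiling_property(self):
        rng = np.random.default_rng(3)
        genes = []
        pos = 0
        for i in range(15):
            pos += int(rng.integers(1, 500))
            end = pos + int(rng.integers(50, 300))
            genes.append(gene(f"g{i}", pos, end))
            pos = end
        length = pos + 100
        loci = build_loci(genes, {"chr1": length})
        assert loci[0].locus.start == 0 and loci[-1].locus.end == length
        for a, b in zip(loci, loci[1:]):
            assert a.locus.end == b.locus.start  # no gap, no double assignment
        for l in loci:
            assert l.gene.start >= l.locus.start and l.gene.end <= l.locus.end

    def test_gene_beyond_sequence_is_error(self):
        with pytest.raises(ValueError, match="beyond"):
            build_loci([gene("g1", 0, 2000)], {"chr1": 1000})


class TestAssignment:
    def test_straddling_enhancer_goes_to_larger_overlap(self):
        loci = build_loci([gene("g1", 0, 900), gene("g2", 1100, 2000)],
                          {"chr1": 3000})
        # boundary at 1000; enhancer 920-1220 overlaps locus1 by 80, locus2 by 220
        e = EnhancerRecord(iv(920, 1220), enhancer_id="e1")
        assign_enhancers_to_loci(loci, [e])
        assert [x.enhancer_id for x in loci[1].enhancers] == ["e1"]

    def test_below_min_overlap_unassigned(self):
        loci = build_loci([gene("g1", 0, 900)], {"chr1": 3000})
        e = EnhancerRecord(iv(2980, 3000), enhancer_id="e1")
        assign_enhancers_to_loci(loci, [e], min_overlap=50)
        assert loci[0].enhancers == []


class TestNormalize:
    def test_median_division(self):
        df = pd.DataFrame({"liver": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        out = normalize_expression(df)
        assert list(out["liver"]) == [0.5, 1.0, 1.5]

    def test_idempotent_on_normalized(self):
        df = pd.DataFrame({"t": [0.5, 1.0, 1.5]}, index=list("abc"))
        out = normalize_expression(normalize_expression(df))
        assert np.allclose(out["t"], [0.5, 1.0, 1.5])

    def test_columns_independent(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [2.0, 4.0, 6.0]},
                          index=list("abc"))
        out = normalize_expression(df)
        assert np.allclose(out["x"], 1.0)
        assert np.allclose(out["y"], [0.5, 1.0, 1.5])

    def test_zero_median_names_tissue(self):
        df = pd.DataFrame({"bad": [0.0, 0.0, 1.0]}, index=list("abc"))
        with pytest.raises(ValueError, match="bad"):
            normalize_expression(df)


class TestWilcoxon:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exact_enumeration_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = int(rng.integers(2, 9)), int(rng.integers(2, 9))
        pooled = rng.permutation(np.arange(1, n1 + n2 + 1, dtype=float) * 1.37)
        x, y = pooled[:n1], pooled[n1:]
        assert wilcoxon_rank_sum_greater(x, y) == pytest.approx(
            exact_rank_sum_p_greater(x, y), rel=1e-9
        )

    def test_three_vs_three_enumeration(self):
        x, y = [7.0, 8.0, 9.0], [1.0, 2.0, 3.0]
        # all C(6,3) = 20 assignments; only the observed one is as extreme
        assert wilcoxon_rank_sum_greater(x, y) == pytest.approx(1 / 20)


class TestShift:
    def _world(self, n_genes, fold, noise_sd, rng=None):
        genes = [gene(f"g{i}", i * 2000 + 500, i * 2000 + 800) for i in range(n_genes)]
        loci = build_loci(genes, {"chr1": n_genes * 2000})
        rpes = [
            EnhancerRecord(iv(i * 2000 + 1000, i * 2000 + 1400),
                           enhancer_id=f"e{i}", category="RPE")
            for i in range(n_genes)
        ]
        base = np.full(n_genes, 100.0)
        b = base * fold
        if noise_sd:
            base = base * np.exp(rng.normal(0, noise_sd, n_genes))
            b = b * np.exp(rng.normal(0, noise_sd, n_genes))
        expr = pd.DataFrame({"ta": base, "tb": b}, index=[g[0] for g in genes])
        return loci, rpes, expr

    def test_planted_fold_recovered_exactly_no_noise(self):
        loci, rpes, expr = self._world(100, 1.4, 0.0)
        res = rpe_expression_shift(rpes, loci, expr, "ta", "tb")
        assert res.fold_change == pytest.approx(1.4)
        assert res.n_genes == 100
        assert res.p_value < 0.05

    def test_null_gives_fold_one(self):
        loci, rpes, expr = self._world(50, 1.0, 0.0)
        res = rpe_expression_shift(rpes, loci, expr, "ta", "tb")
        assert res.fold_change == pytest.approx(1.0)
        assert res.p_value > 0.05

    def test_single_gene_flagged_unreliable(self):
        loci, rpes, expr = self._world(1, 1.4, 0.0)
        res = rpe_expression_shift(rpes, loci, expr, "ta", "tb")
        assert not res.reliable

    def test_null_rejection_rate_controlled(self):
        """<= 7% rejections at alpha 0.05 over 200 null runs."""
        rng = np.random.default_rng(55)
        rejections = 0
        for _ in range(200):
            loci, rpes, expr = self._world(30, 1.0, 0.5, rng)
            res = rpe_expression_shift(rpes, loci, expr, "ta", "tb")
            rejections += res.p_value <= 0.05
        assert rejections / 200 <= 0.07


class TestBins:
    def _loci_with_counts(self, counts, categories):
        loci = []
        recs = iter(categories)
        for i, k in enumerate(counts):
            loc = GeneLocus(f"g{i}", iv(i * 1000, i * 1000 + 100),
                            iv(i * 1000, (i + 1) * 1000))
            loc.enhancers = [
                EnhancerRecord(iv(i * 1000 + 200 + j * 60, i * 1000 + 250 + j * 60),
                               enhancer_id=f"e{i}_{j}", category=next(recs))
                for j in range(k)
            ]
            loci.append(loc)
        return loci

    def test_zero_enhancer_locus_counts_genes_only(self):
        loci = self._loci_with_counts([0, 2], ["RPE", "FCE"])
        expr = pd.DataFrame({"t": [1.0, 3.0]}, index=["g0", "g1"])
        out = bin_by_enhancer_count(loci, expr, "t")
        assert out.loc[0, "n_genes"] == 1
        assert np.isnan(out.loc[0, "frac_RPE"])
        assert out.loc[2, "frac_RPE"] == 0.5

    def test_pooling_above_max_bin(self):
        loci = self._loci_with_counts([5, 7], ["RPE"] * 12)
        out = bin_by_enhancer_count(loci, max_bin=4)
        assert list(out.index) == [4]
        assert out.loc[4, "n_enhancers"] == 12

    def test_planted_trend_recovered(self):
        """RPE fraction rises with locus size when the generator biases
        reprogramming toward multi-enhancer loci."""
        from enhancer_rewire.enhancer_classify import classify_genome_wide
        from enhancer_rewire.synthetic_data import ScenarioConfig, simulate

        ds = simulate(
            ScenarioConfig(
                seed=31, n_enhancers=240, sequence_length=600_000,
                enhancers_per_locus_range=(1, 4), rpe_bias_by_locus_size=True,
                category_fractions=(0.2, 0.4, 0.4),
            )
        )
        classified = classify_genome_wide(ds.records("A"), ds.tissue_sets("B"),
                                          ds.chains)
        loci = build_loci(ds.genes_a, {s: len(v) for s, v in ds.sequences_a.items()})
        assign_enhancers_to_loci(loci, classified)
        out = bin_by_enhancer_count(loci)
        occupied = out[out.n_enhancers > 0]
        fr = occupied["frac_RPE"].to_numpy()
        assert len(fr) >= 3
        assert all(a <= b + 1e-9 for a, b in zip(fr, fr[1:]))


class TestSeLoci:
    def _loci(self, se_cats, multi_cats):
        loci = []
        i = 0
        for cat in se_cats:
            loc = GeneLocus(f"s{i}", iv(i * 1000, i * 1000 + 100),
                            iv(i * 1000, (i + 1) * 1000))
            loc.enhancers = [EnhancerRecord(iv(i * 1000 + 200, i * 1000 + 260),
                                            enhancer_id=f"se{i}", category=cat)]
            loci.append(loc)
            i += 1
        for j in range(0, len(multi_cats), 2):
            loc = GeneLocus(f"m{j}", iv(i * 1000, i * 1000 + 100),
                            iv(i * 1000, (i + 1) * 1000))
            loc.enhancers = [
                EnhancerRecord(iv(i * 1000 + 200 + k * 70, i * 1000 + 260 + k * 70),
                               enhancer_id=f"me{j}_{k}", category=c)
                for k, c in enumerate(multi_cats[j : j + 2])
            ]
            loci.append(loc)
            i += 1
        return loci

    def test_no_seloci_returns_none(self):
        loci = self._loci([], ["RPE", "FCE"])
        assert seloci_test(loci) is None

    def test_fisher_p_matches_enumeration(self):
        # 2x2 table for RPE: (3 of 10 in seLoci) vs (12 of 20 in multi)
        loci = self._loci(
            ["RPE"] * 3 + ["FCE"] * 7,
            ["RPE"] * 12 + ["FCE"] * 8,
        )
        out = seloci_test(loci)
        assert out.loc["RPE", "n_seloci_cat"] == 3
        assert out.loc["RPE", "p_value"] == pytest.approx(
            fisher_two_sided(3, 7, 12, 8), rel=1e-9
        )

    def test_planted_depletion_recovered(self):
        loci = self._loci(
            ["RPE"] * 2 + ["FCE"] * 18,
            ["RPE"] * 14 + ["FCE"] * 6,
        )
        out = seloci_test(loci)
        assert out.loc["RPE", "odds_ratio"] < 1
        assert out.loc["RPE", "frac_seloci"] < out.loc["RPE", "frac_all"]
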