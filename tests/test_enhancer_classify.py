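"""Filtering, projection and FCE/RPE/EG classification."""

import numpy as np
import pytest

from enhancer_rewire.enhancer_classify import (
    EnhancerRecord,
    center_to_fixed_width,
    classify_genome_wide,
    classify_tissue_pair,
    filter_enhancers,
    overlaps,
    project,
    reprogramming_rate,
)
from enhancer_rewire.formats_io import AlignmentChain, GenomicInterval

from oracles import brute_force_tissue_pair, project_per_base


def iv(start, end, seq="chr1"):
    return GenomicInterval(seq, start, end)


def rec(start, end, tissues=("liver",), seq="chr1", eid=None, species="A"):
    return EnhancerRecord(
        iv(start, end, seq), species=species, tissues=frozenset(tissues),
        enhancer_id=eid or f"e{start}",
    )


class TestCenterToFixedWidth:
    def test_one_kb_centering(self):
        out, clipped = center_to_fixed_width(iv(10400, 10600), 1000)
        assert (out.start, out.end) == (10000, 11000)
        assert not clipped

    def test_clipping_at_sequence_start(self):
        out, clipped = center_to_fixed_width(iv(0, 10), 1000, seq_length=505)
        assert (out.start, out.end) == (0, 505)
        assert clipped

    def test_width_one_identity(self):
        out, clipped = center_to_fixed_width(iv(5, 6), 1)
        assert (out.start, out.end) == (5, 6)
        assert not clipped


class TestFilter:
    @pytest.fixture()
    def genome(self):
        # 4000 bp, last 1000 bp fully lowercase
        return {"chr1": "A" * 3000 + "a" * 1000}

    def test_length_rule_strict_exceedance(self, genome):
        kept, rejected = filter_enhancers([rec(0, 3001)], genome)
        assert not kept and "length" in rejected[0][1]
        kept, _ = filter_enhancers([rec(0, 3000)], genome)
        assert len(kept) == 1  # exactly 3000 bp is kept

    def test_repeat_rule(self, genome):
        # 240 upper + 760 lower = 76% repeats -> removed
        kept, rejected = filter_enhancers([rec(2760, 3760)], genome)
        assert not kept and "repeat" in rejected[0][1]
        # exactly 75% repeats is kept
        kept, _ = filter_enhancers([rec(2750, 3750)], genome)
        assert len(kept) == 1

    def test_out_of_bounds_is_error(self, genome):
        with pytest.raises(ValueError, match="beyond"):
            filter_enhancers([rec(3500, 4500)], genome)


class TestOverlaps:
    def test_fifty_bp_rule(self):
        assert overlaps(iv(0, 100), iv(50, 200))
        assert not overlaps(iv(0, 100), iv(51, 200))
        assert overlaps(iv(0, 60), iv(0, 60))
        assert not overlaps(iv(0, 100), iv(50, 200, seq="chr2"))


class TestProject:
    def test_identity_chain(self):
        ch = AlignmentChain("1", 100, "chr1", 1000, "chrB", 1000, ((0, 0, 1000),))
        p = project(iv(100, 200), [ch])
        assert (p.interval.start, p.interval.end) == (100, 200)
        assert p.aligned_bases == 100

    def test_interval_in_gap_is_absent(self):
        ch = AlignmentChain("1", 100, "chr1", 1000, "chrB", 1000,
                            ((0, 0, 100), (500, 500, 100)))
        assert project(iv(200, 300), [ch]) is None

    def test_query_insertion_widens_span(self):
        # two blocks separated by a 10 bp query-side insertion
        ch = AlignmentChain("1", 100, "chr1", 1000, "chrB", 1000,
                            ((0, 0, 100), (100, 110, 100)))
        p = project(iv(50, 150), [ch])
        assert p.interval.length == 110
        assert p.aligned_bases == 100

    def test_best_scoring_chain_wins(self):
        lo = AlignmentChain("1", 10, "chr1", 1000, "chrB", 1000, ((0, 0, 500),))
        hi = AlignmentChain("2", 99, "chr1", 1000, "chrB", 1000, ((0, 700, 300),))
        p = project(iv(100, 200), [lo, hi])
        assert p.chain_id == "2"
        assert p.interval.start == 800

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_per_base_oracle(self, seed):
        r = np.random.default_rng(seed)
        chains = []
        for cid in range(3):
            blocks = []
            pos_r, pos_q = int(r.integers(0, 50)), int(r.integers(0, 50))
            for _ in range(int(r.integers(1, 5))):
                size = int(r.integers(1, 40))
                blocks.append((pos_r, pos_q, size))
                pos_r += size + int(r.integers(0, 30))
                pos_q += size + int(r.integers(0, 30))
            chains.append(
                AlignmentChain(str(cid), float(r.integers(1, 100)), "chr1", 2000,
                               "chrB", 2000, tuple(blocks))
            )
        for _ in range(20):
            s = int(r.integers(0, 300))
            q = iv(s, s + int(r.integers(1, 80)))
            got = project(q, chains)
            expected = project_per_base(q, chains)
            if expected is None:
                assert got is None
            else:
                assert (got.interval, got.aligned_bases) == expected


def _simple_world():
    """One identity chain; destination liver enhancer at 0-1000,
    heart enhancer at 2000-3000."""
    ch = AlignmentChain("1", 100, "chr1", 10_000, "chr1", 10_000, ((0, 0, 10_000),))
    dst = {
        "liver": [iv(0, 1000)],
        "heart": [iv(2000, 3000)],
    }
    return [ch], dst


class TestClassifyGenomeWide:
    def test_shared_tissue_is_fce(self):
        chains, dst = _simple_world()
        [out] = classify_genome_wide([rec(100, 600, ("liver",))], dst, chains)
        assert out.category == "FCE"
        assert out.reprogrammed_to == frozenset()

    def test_novel_tissue_is_rpe_with_precedence(self):
        chains, dst = _simple_world()
        # ortholog overlaps heart only
        [out] = classify_genome_wide([rec(2100, 2600, ("liver",))], dst, chains)
        assert out.category == "RPE"
        assert out.reprogrammed_to == frozenset({"heart"})
        # overlapping both shared and novel tissue: RPE still wins
        dst2 = {"liver": [iv(2000, 3000)], "heart": [iv(2000, 3000)]}
        [out] = classify_genome_wide([rec(2100, 2600, ("liver",))], dst2, chains)
        assert out.category == "RPE"

    def test_unalignable_is_eg(self):
        ch = AlignmentChain("1", 100, "chr1", 10_000, "chr1", 10_000, ((0, 0, 100),))
        _, dst = _simple_world()
        [out] = classify_genome_wide([rec(5000, 5500, ("liver",))], dst, [ch])
        assert out.category == "EG"
        assert out.ortholog is None

    def test_aligned_but_inactive_is_eg(self):
        chains, dst = _simple_world()
        [out] = classify_genome_wide([rec(6000, 6500, ("liver",))], dst, chains)
        assert out.category == "EG"
        assert out.ortholog is not None

    def test_unknown_tissue_is_config_error(self):
        chains, dst = _simple_world()
        with pytest.raises(ValueError, match="absent from destination"):
            classify_genome_wide([rec(100, 600, ("brain",))], dst, chains)

    def test_every_record_gets_exactly_one_category(self, default_dataset):
        ds = default_dataset
        out = classify_genome_wide(ds.records("A"), ds.tissue_sets("B"), ds.chains)
        assert len(out) == len(ds.records("A"))
        assert all(r.category in ("FCE", "RPE", "EG") for r in out)


def _random_pair_instance(seed, n_max=30):
    r = np.random.default_rng(seed)
    L = 5000
    # one chain with random gaps
    blocks = []
    pos_r = pos_q = 0
    while pos_r < L - 100:
        size = int(r.integers(50, 400))
        blocks.append((pos_r, pos_q, size))
        pos_r += size + int(r.integers(0, 300))
        pos_q += size + int(r.integers(0, 300))
    chains = [AlignmentChain("1", 1.0, "chr1", L + 1000, "chr1",
                             pos_q + 1000, tuple(blocks))]

    def random_set(n, tag):
        out = []
        for i in range(n):
            s = int(r.integers(0, L - 200))
            out.append(rec(s, s + int(r.integers(60, 200)), eid=f"{tag}{i}"))
        return out

    n = int(r.integers(0, n_max + 1))
    n_a = int(r.integers(0, n + 1))
    a_src = random_set(n_a, "a")
    b_src = random_set(n - n_a, "b")
    a_dst = [x.interval for x in random_set(int(r.integers(0, 15)), "m")]
    b_dst = [x.interval for x in random_set(int(r.integers(0, 15)), "n")]
    return a_src, b_src, a_dst, b_dst, chains


class TestClassifyTissuePair:
    def test_planted_single_reprogramming_event(self):
        chains, _ = _simple_world()
        # A-tissue human enhancer whose ortholog is a B-tissue mouse enhancer
        a_src = [rec(2100, 2700, ("A",), eid="rpe")]
        b_src = [rec(7000, 7400, ("B",), eid="fce_b")]
        a_dst = [iv(7000, 7400)]   # matches b? no - it is tissue-A mouse set
        b_dst = [iv(2100, 2700)]
        res = classify_tissue_pair(a_src, b_src, a_dst, b_dst, chains,
                                   tissue_a="A", tissue_b="B")
        assert [x.enhancer_id for x in res.reprogrammed_a_to_b] == ["rpe"]
        assert res.reprogrammed_a_to_b[0].reprogrammed_to == frozenset({"B"})
        # b_src projects onto the tissue-A mouse enhancer -> reprogrammed B->A
        assert [x.enhancer_id for x in res.reprogrammed_b_to_a] == ["fce_b"]

    def test_all_shared_enhancers_drop_out(self):
        chains, _ = _simple_world()
        shared = [rec(100, 600, ("A",), eid="s1")]
        res = classify_tissue_pair(shared, shared, [], [], chains)
        assert not any([res.a1_src, res.b1_src, res.fce_a, res.fce_b,
                        res.reprogrammed_a_to_b, res.eg_a])

    def test_empty_destination_all_alignable_become_eg(self):
        chains, _ = _simple_world()
        a_src = [rec(100, 600, ("A",))]
        res = classify_tissue_pair(a_src, [], [], [], chains)
        assert len(res.eg_a) == 1 and res.eg_a[0].category == "EG"

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_brute_force(self, seed):
        a_src, b_src, a_dst, b_dst, chains = _random_pair_instance(seed)
        res = classify_tissue_pair(a_src, b_src, a_dst, b_dst, chains,
                                   tissue_a="A", tissue_b="B")
        expected = brute_force_tissue_pair(a_src, b_src, a_dst, b_dst, chains)
        got = {}
        for x in res.fce_a + res.fce_b:
            got[x.enhancer_id] = "FCE"
        for x in res.reprogrammed_a_to_b + res.reprogrammed_b_to_a:
            got[x.enhancer_id] = "RPE"
        for x in res.eg_a + res.eg_b:
            got[x.enhancer_id] = "EG"
        assert got == expected

    def test_symmetry(self):
        for seed in range(10):
            a_src, b_src, a_dst, b_dst, chains = _random_pair_instance(seed + 1000)
            fwd = classify_tissue_pair(a_src, b_src, a_dst, b_dst, chains,
                                       tissue_a="A", tissue_b="B")
            rev = classify_tissue_pair(b_src, a_src, b_dst, a_dst, chains,
                                       tissue_a="B", tissue_b="A")
            assert {x.enhancer_id for x in fwd.reprogrammed_a_to_b} == {
                x.enhancer_id for x in rev.reprogrammed_b_to_a
            }
            assert {x.enhancer_id for x in fwd.reprogrammed_b_to_a} == {
                x.enhancer_id for x in rev.reprogrammed_a_to_b
            }

    def test_min_overlap_monotonicity_genome_wide(self):
        # raising the overlap threshold can only shrink the set of
        # qualifying destination overlaps, so the RPE count and the
        # combined FCE+RPE count never increase
        for seed in range(10):
            a_src, _, a_dst, b_dst, chains = _random_pair_instance(seed + 2000)
            dst = {"liver": a_dst, "heart": b_dst}
            counts = []
            for mo in (20, 50, 100):
                out = classify_genome_wide(a_src, dst, chains, min_overlap=mo)
                n_rpe = sum(r.category == "RPE" for r in out)
                n_fce = sum(r.category == "FCE" for r in out)
                counts.append((n_rpe, n_rpe + n_fce))
            assert counts[0][0] >= counts[1][0] >= counts[2][0]
            assert counts[0][1] >= counts[1][1] >= counts[2][1]


class TestReprogrammingRate:
    def test_rate_arithmetic(self):
        records = [rec(i * 1000, i * 1000 + 100, ("cortex",), eid=str(i))
                   for i in range(4)]
        for r, cat in zip(records, ["RPE", "FCE", "EG", "RPE"]):
            r.category = cat
        assert reprogramming_rate(records, "cortex") == pytest.approx(0.5)
        assert reprogramming_rate(records, "liver") is None

    def test_all_rpe_is_one(self):
        records = [rec(0, 100, ("t",), eid="x")]
        records[0].category = "RPE"
        assert reprogramming_rate(records, "t") == 1.0
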