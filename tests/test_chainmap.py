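"""Chain parsing and cross-assembly mapping criteria."""

import numpy as np
import pytest

from heartenh.chainmap import (ChainAlignment, ChainBlock, ChainParseError,
                               MappingStatus, identity_chains, map_interval,
                               map_reciprocal, read_chain, write_chain)
from heartenh.intervals import GenomicInterval


def iv(start, end, chrom="chrS", assembly="asmB"):
    return GenomicInterval(chrom, start, end, assembly)


TWO_BLOCK_CHAIN = (
    "chain 1000 chrS 10000 + 100 1200 chrT 20000 + 5000 6120 1\n"
    "500 100 120\n"
    "500\n"
)

NEG_STRAND_CHAIN = (
    "chain 900 chrS 10000 + 0 400 chrT 9000 - 100 500 2\n"
    "400\n"
)


class TestReadChain:
    def test_two_block_fixture_hand_arithmetic(self, tmp_path):
        p = tmp_path / "c.chain"
        p.write_text(TWO_BLOCK_CHAIN)
        (ch,) = read_chain(p)
        # block 1: source [100,600) -> target [5000,5500)
        # gap: dt=100 on source, dq=120 on target
        # block 2: source [700,1200) -> target [5620,6120)
        assert ch.blocks == [ChainBlock(100, 600, 5000, 5500),
                             ChainBlock(700, 1200, 5620, 6120)]

    def test_negative_strand_forward_coordinates(self, tmp_path):
        p = tmp_path / "n.chain"
        p.write_text(NEG_STRAND_CHAIN)
        (ch,) = read_chain(p)
        # reversed-strand span [100,500) of a 9000 bp chromosome is
        # [8500,8900) in forward coordinates
        assert ch.blocks == [ChainBlock(0, 400, 8500, 8900)]
        res = map_interval(iv(0, 100), [ch], target_assembly="asmA")
        assert res.ok and (res.target.start, res.target.end) == (8800, 8900)

    def test_arithmetic_mismatch_names_chain(self, tmp_path):
        p = tmp_path / "bad.chain"
        p.write_text("chain 10 chrS 10000 + 0 400 chrT 9000 + 0 401 7\n400\n")
        with pytest.raises(ChainParseError, match="chain 7"):
            read_chain(p)

    def test_truncated_file_errors(self, tmp_path):
        p = tmp_path / "t.chain"
        p.write_text("chain 10 chrS 10000 + 0 400 chrT 9000 + 0 400 3\n100 5 5\n")
        with pytest.raises(ChainParseError, match="truncated"):
            read_chain(p)

    def test_empty_file_empty_set(self, tmp_path):
        p = tmp_path / "e.chain"
        p.write_text("")
        assert read_chain(p) == []

    def test_write_read_round_trip(self, tmp_path):
        p1, p2 = tmp_path / "a.chain", tmp_path / "b.chain"
        p1.write_text(TWO_BLOCK_CHAIN + "\n" + NEG_STRAND_CHAIN)
        chains = read_chain(p1)
        write_chain(chains, p2)
        again = read_chain(p2)
        assert [c.blocks for c in again] == [c.blocks for c in chains]
        assert [c.tgt_strand for c in again] == [c.tgt_strand for c in chains]


class TestMapInterval:
    def test_identity_chain_is_identity(self):
        chains = identity_chains({"chrS": 10_000})
        rng = np.random.default_rng(9)
        for _ in range(1000):
            s = int(rng.integers(0, 9_000))
            e = int(rng.integers(s + 1, 10_000))
            res = map_interval(iv(s, e), chains)
            assert res.ok and res.mapped_fraction == 1.0
            assert (res.target.start, res.target.end) == (s, e)

    def test_fifty_percent_coverage_boundary(self):
        # a single 500 bp block inside a 1000 bp interval sits exactly at
        # the >=50% acceptance threshold
        ch = ChainAlignment("1", 1.0, "chrS", 10_000, "chrT", 10_000, "+",
                            [ChainBlock(1000, 1500, 2000, 2500)])
        ok = map_interval(iv(1000, 2000), [ch])
        assert ok.status is MappingStatus.MAPPED and ok.mapped_fraction == 0.5
        low = map_interval(iv(1001, 2001), [ch])
        assert low.status is MappingStatus.LOW_COVERAGE
        assert low.mapped_fraction == pytest.approx(0.499)

    def test_two_chains_ambiguous(self):
        chains = [
            ChainAlignment("1", 1.0, "chrS", 10_000, "chrT", 10_000, "+",
                           [ChainBlock(0, 1000, 0, 1000)]),
            ChainAlignment("2", 1.0, "chrS", 10_000, "chrU", 10_000, "+",
                           [ChainBlock(0, 1000, 5000, 6000)]),
        ]
        assert map_interval(iv(100, 600), chains).status is MappingStatus.AMBIGUOUS

    def test_absent_chromosome_unmapped(self):
        chains = identity_chains({"chrS": 10_000})
        res = map_interval(iv(0, 100, chrom="chrZ"), chains)
        assert res.status is MappingStatus.UNMAPPED

    def test_non_contributing_chain_does_not_break_uniqueness(self):
        chains = [
            ChainAlignment("1", 1.0, "chrS", 10_000, "chrT", 10_000, "+",
                           [ChainBlock(0, 1000, 0, 1000)]),
            ChainAlignment("2", 1.0, "chrS", 10_000, "chrU", 10_000, "+",
                           [ChainBlock(5000, 6000, 0, 1000)]),
        ]
        assert map_interval(iv(100, 600), chains).ok

    def test_permutation_invariant_in_chain_order(self):
        rng = np.random.default_rng(10)
        chains = []
        for i in range(10):
            s = 1000 * i
            chains.append(ChainAlignment(str(i), 1.0, "chrS", 20_000, "chrT",
                                         20_000, "+",
                                         [ChainBlock(s, s + 900, s + 37, s + 937)]))
        queries = [iv(int(a), int(a) + 200) for a in rng.integers(0, 19_000, 50)]
        base = [map_interval(q, chains) for q in queries]
        for _ in range(5):
            perm = list(rng.permutation(len(chains)))
            shuffled = [chains[i] for i in perm]
            assert [map_interval(q, shuffled) for q in queries] == base


class TestMapReciprocal:
    def test_identity_both_ways(self):
        f = identity_chains({"chrS": 10_000})
        res = map_reciprocal(iv(100, 600), f, f)
        assert res.ok and (res.target.start, res.target.end) == (100, 600)

    def test_constructed_non_reciprocal(self):
        fwd = [ChainAlignment("1", 1.0, "chrS", 10_000, "chrT", 10_000, "+",
                              [ChainBlock(0, 1000, 0, 1000)])]
        # the back chain sends chrT:[0,1000) to a disjoint source location
        bwd = [ChainAlignment("2", 1.0, "chrT", 10_000, "chrS", 10_000, "+",
                              [ChainBlock(0, 1000, 5000, 6000)])]
        res = map_reciprocal(iv(100, 600), fwd, bwd)
        assert res.status is MappingStatus.NON_RECIPROCAL

    def test_duplication_in_forward_is_ambiguous(self):
        fwd = [
            ChainAlignment("1", 1.0, "chrS", 10_000, "chrT", 10_000, "+",
                           [ChainBlock(0, 1000, 0, 1000)]),
            ChainAlignment("2", 1.0, "chrS", 10_000, "chrT", 10_000, "+",
                           [ChainBlock(0, 1000, 4000, 5000)]),
        ]
        bwd = [ChainAlignment("3", 1.0, "chrT", 10_000, "chrS", 10_000, "+",
                              [ChainBlock(0, 1000, 0, 1000)])]
        assert map_reciprocal(iv(10, 900), fwd, bwd).status is MappingStatus.AMBIGUOUS

    def test_reciprocal_filter_only_removes(self, small_world):
        """Everything reciprocally mapped is also forward-mapped, unchanged."""
        fwd = read_chain(small_world.paths["forward_chain"])
        bwd = read_chain(small_world.paths["backward_chain"])
        rng = np.random.default_rng(12)
        L = small_world.chrom_lengths["chr1"]
        n_recip = 0
        for _ in range(300):
            s = int(rng.integers(0, L - 3000))
            q = iv(s, s + int(rng.integers(300, 3000)), chrom="chr1")
            f = map_interval(q, fwd, target_assembly="asmA")
            r = map_reciprocal(q, fwd, bwd, target_assembly="asmA")
            if r.ok:
                n_recip += 1
                assert f.ok and f.target == r.target
        assert n_recip > 0

    def test_back_projection_overlaps_original(self, small_world):
        fwd = read_chain(small_world.paths["forward_chain"])
        bwd = read_chain(small_world.paths["backward_chain"])
        rng = np.random.default_rng(13)
        L = small_world.chrom_lengths["chr1"]
        checked = 0
        for _ in range(200):
            s = int(rng.integers(0, L - 2000))
            q = iv(s, s + 1000, chrom="chr1")
            r = map_reciprocal(q, fwd, bwd, target_assembly="asmA")
            if r.ok:
                back = map_interval(r.target, bwd, target_assembly="asmB")
                assert back.ok
                from heartenh.intervals import overlap_bases

                assert overlap_bases(back.target, q) >= 0.5 * q.length
                checked += 1
        assert checked > 0
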