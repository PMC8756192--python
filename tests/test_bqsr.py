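"""Recalibration counting, exact table merging, and quality application."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shardcall.bqsr import (
    MIN_OBS_FOR_APPLY,
    RecalTable,
    RecalTableError,
    apply_bqsr,
    bin_cycle,
    build_table,
    empirical_quality,
    merge_tables,
    tree_merge,
)
from shardcall.formats_io import (
    AlignedRead,
    Contig,
    KnownSites,
    ReferenceGenome,
    read_sam,
)
from shardcall.region_partitioner import partition_from_sam, shuffle_by_region
from shardcall.region_processing import mark_duplicates, sort_key


@pytest.fixture
def genome():
    rng = np.random.default_rng(42)
    seq = "".join("ACGT"[b] for b in rng.integers(0, 4, 2000))
    return ReferenceGenome([Contig("c1", 2000, seq)])


@pytest.fixture
def no_known():
    return KnownSites(snv={}, sites_id="none")


def make_read(genome, pos, length=100, qual=30, mutate_at=(), qname="r",
              reverse=False, rg="rg"):
    seq = list(genome.contig("c1").sequence[pos:pos + length])
    for off in mutate_at:
        seq[off] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[off]]
    return AlignedRead(
        qname=qname, flags=0x10 if reverse else 0, contig="c1", pos=pos,
        mapq=60, cigar=((0, length),), seq="".join(seq),
        qual=np.full(length, qual, dtype=np.uint8), read_group=rg,
        library="lib")


class TestBuildTable:
    def test_perfect_read_counts_bases_without_errors(self, genome, no_known):
        table = build_table([make_read(genome, 50)], genome, no_known)
        assert table.total_observations() == 100
        assert table.total_errors() == 0

    def test_mismatch_at_known_site_is_fully_excluded(self, genome):
        known = KnownSites(snv={"c1": [60]}, sites_id="k")
        read = make_read(genome, 50, mutate_at=(10,))  # ref pos 60
        table = build_table([read], genome, known)
        assert table.total_observations() == 99
        assert table.total_errors() == 0

    def test_mismatch_elsewhere_is_an_error(self, genome, no_known):
        table = build_table([make_read(genome, 50, mutate_at=(10,))],
                            genome, no_known)
        assert table.total_observations() == 100
        assert table.total_errors() == 1

    def test_soft_clips_and_insertions_contribute_nothing(self, genome,
                                                          no_known):
        read = make_read(genome, 50, length=100)
        read.cigar = ((4, 10), (0, 80), (1, 5), (0, 5))
        seq = genome.contig("c1").sequence
        read.seq = ("N" * 10 + seq[50:130] + "N" * 5 + seq[130:135])
        table = build_table([read], genome, no_known)
        assert table.total_observations() == 85

    def test_duplicates_mapq0_and_boundary_copies_are_skipped(self, genome,
                                                              no_known):
        dup = make_read(genome, 50, qname="d")
        dup.flags |= 0x400
        mq0 = make_read(genome, 50, qname="m")
        mq0.mapq = 0
        copy = make_read(genome, 50, qname="c")
        copy.primary = False
        table = build_table([dup, mq0, copy], genome, no_known)
        assert table.total_observations() == 0

    def test_planted_error_rate_is_recovered(self, genome, no_known):
        rng = np.random.default_rng(5)
        reads = []
        for i in range(500):
            pos = int(rng.integers(0, 1900))
            hits = np.nonzero(rng.random(100) < 0.01)[0]
            reads.append(make_read(genome, pos, mutate_at=tuple(hits),
                                   qname=f"r{i}"))
        table = build_table(reads, genome, no_known)
        obs, err = table.total_observations(), table.total_errors()
        p = err / obs
        sigma = math.sqrt(0.01 * 0.99 / obs)
        assert abs(p - 0.01) < 3 * sigma

    def test_reverse_strand_cycles_are_negative(self, genome, no_known):
        table = build_table([make_read(genome, 50, reverse=True)],
                            genome, no_known)
        assert all(cyc < 0 for (_, _, cyc, _) in table.counts)
        fwd = build_table([make_read(genome, 50)], genome, no_known)
        assert all(cyc > 0 for (_, _, cyc, _) in fwd.counts)


class TestMerge:
    def test_identity_and_keywise_sum(self):
        t = RecalTable(genome_id="g", known_sites_id="k",
                       counts={("rg", 30, 1, "AC"): (10, 1)})
        assert merge_tables(t, RecalTable()) == t
        b = RecalTable(genome_id="g", known_sites_id="k",
                       counts={("rg", 30, 1, "AC"): (5, 2)})
        merged = merge_tables(t, b)
        assert merged.counts[("rg", 30, 1, "AC")] == (15, 3)

    def test_metadata_mismatch_is_an_error(self):
        a = RecalTable(genome_id="g1", counts={("r", 30, 1, "AC"): (1, 0)})
        b = RecalTable(genome_id="g2", counts={("r", 30, 1, "AC"): (1, 0)})
        with pytest.raises(RecalTableError):
            merge_tables(a, b)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(
        st.dictionaries(
            st.tuples(st.just("rg"), st.integers(2, 40),
                      st.integers(-50, 50), st.just("AC")),
            st.tuples(st.integers(0, 100), st.integers(0, 100)).map(
                lambda oe: (max(oe), min(oe))),
            max_size=5),
        min_size=1, max_size=6))
    def test_merge_is_associative_and_commutative(self, dicts):
        tables = [RecalTable(genome_id="g", known_sites_id="k", counts=d)
                  for d in dicts]
        left = tables[0]
        for t in tables[1:]:
            left = merge_tables(left, t)
        right = tables[-1]
        for t in tables[-2::-1]:
            right = merge_tables(t, right)
        assert left == right == tree_merge(tables)

    def test_random_region_split_merges_to_single_pass_table(
            self, small_dataset, tmp_path):
        ds = small_dataset
        genome = ds.genome
        known = KnownSites.from_vcf(ds.known_vcf)
        spec = partition_from_sam(ds.tumor_sam, genome, n_regions=8, seed=13)
        tumor = list(read_sam(ds.tumor_sam, genome))
        normal = list(read_sam(ds.normal_sam, genome))
        res = shuffle_by_region(tumor, normal, spec, tmp_path / "sh")
        partials = []
        for path in res["paths"]:
            shard = sorted(read_sam(path, genome),
                           key=lambda r: sort_key(r, genome))
            partials.append(build_table(
                mark_duplicates(shard, genome, check_sorted=False),
                genome, known))
        rng = np.random.default_rng(0)
        rng.shuffle(partials)
        merged = tree_merge(partials)
        whole = sorted(tumor + normal, key=lambda r: sort_key(r, genome))
        single = build_table(mark_duplicates(whole, genome,
                                             check_sorted=False),
                             genome, known)
        assert merged == single


class TestEmpiricalQuality:
    @pytest.mark.parametrize("obs,err,expected", [
        (0, 0, -10 * math.log10(1 / 2)),       # prior only, ~3.01
        (998, 0, 30.0),
        (100, 100, -10 * math.log10(101 / 102)),
    ])
    def test_formula(self, obs, err, expected):
        assert empirical_quality(obs, err) == pytest.approx(expected,
                                                            abs=1e-9)

    def test_cap_and_validation(self):
        assert empirical_quality(10 ** 9, 0) == 60.0
        with pytest.raises(ValueError):
            empirical_quality(5, 6)
        with pytest.raises(ValueError):
            empirical_quality(-1, 0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 10 ** 6), st.integers(0, 10 ** 6))
    def test_monotone_nonincreasing_in_errors(self, obs, err):
        err = min(err, obs)
        if err + 1 <= obs:
            assert empirical_quality(obs, err + 1) <= empirical_quality(obs,
                                                                        err)


class TestApply:
    def test_absent_key_leaves_quality_unchanged(self, genome):
        read = make_read(genome, 50, qual=33)
        out = apply_bqsr(read, RecalTable())
        assert np.array_equal(out.qual, read.qual)
        assert out.seq == read.seq

    def test_rg_aggregate_with_998_clean_obs_gives_q30(self, genome):
        table = RecalTable(genome_id="g", known_sites_id="k",
                           counts={("rg", 33, 1, "NN"): (998, 0)})
        read = make_read(genome, 50, qual=33)
        out = apply_bqsr(read, table)
        assert (out.qual == 30).all()

    def test_full_key_beats_aggregate_when_observed_enough(self, genome):
        # the first machine cycle has its own well-observed (noisy) cell;
        # every other cycle is absent and falls back to the cleaner
        # (read group, reported quality) aggregate
        table = RecalTable(genome_id="g", known_sites_id="k",
                           counts={("rg", 33, 1, "NN"): (150, 15),
                                   ("rg", 33, 151, "AA"): (1000, 0)})
        read = make_read(genome, 50, qual=33)
        out = apply_bqsr(read, table)
        assert out.qual[0] == round(empirical_quality(150, 15))
        assert out.qual[1] == round(empirical_quality(1150, 15))

    def test_min_observation_gate(self):
        assert MIN_OBS_FOR_APPLY == 100

    def test_bin_cycle(self):
        assert bin_cycle(np.array([1, 30, 31, 40, 41, 101])).tolist() == \
            [1, 30, 31, 31, 41, 101]
        assert bin_cycle(np.array([-1, -35])).tolist() == [-1, -31]
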