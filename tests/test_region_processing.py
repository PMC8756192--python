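"""Sorting and duplicate marking against independent oracles."""

import numpy as np
import pytest

from shardcall.formats_io import AlignedRead, Contig, ReferenceGenome, read_sam
from shardcall.region_processing import (
    SortOrderError,
    mark_duplicates,
    sort_key,
    sort_region,
    unclipped_start,
)

CLIP_OPS = (4, 5)  # soft, hard
REF_OPS = (0, 2, 3, 7, 8)


@pytest.fixture
def genome():
    return ReferenceGenome([Contig("c1", 100_000, "A" * 100_000)])


def make_read(qname, pos, cigar, reverse=False, quals=None, length=None,
              paired=True, read2=False, library="lib"):
    qlen = length or sum(n for op, n in cigar if op in (0, 1, 4, 7, 8))
    flags = (0x1 if paired else 0) | (0x10 if reverse else 0)
    flags |= 0x80 if read2 else (0x40 if paired else 0)
    q = np.asarray(quals if quals is not None else [30] * qlen,
                   dtype=np.uint8)
    return AlignedRead(
        qname=qname, flags=flags, contig="c1", pos=pos, mapq=60,
        cigar=tuple(cigar), seq="A" * qlen, qual=q, read_group="rg",
        library=library, mate_contig="c1" if paired else None, mate_pos=0)


class TestUnclippedStart:
    @pytest.mark.parametrize("pos,cigar,reverse,expected", [
        (100, ((0, 100),), False, 100),
        (100, ((4, 5), (0, 95)), False, 95),       # 5S95M forward
        (100, ((0, 95), (4, 5)), True, 199),       # 95M5S reverse: 194 + 5
        (100, ((5, 3), (4, 2), (0, 95)), False, 95),
        (50, ((0, 90), (5, 10)), True, 149),
    ])
    def test_clip_arithmetic(self, pos, cigar, reverse, expected):
        read = make_read("r", pos, cigar, reverse=reverse)
        assert unclipped_start(read) == expected

    def test_missing_cigar_is_an_error(self):
        read = make_read("r", 10, ((0, 10),))
        read.cigar = ()
        with pytest.raises(ValueError):
            unclipped_start(read)


class TestSortRegion:
    def test_already_sorted_input_is_unchanged(self, genome):
        reads = [make_read(f"r{i}", i * 10, ((0, 50),)) for i in range(20)]
        out = list(sort_region(iter(reads), genome))
        assert [r.qname for r in out] == [r.qname for r in reads]

    def test_empty_region_yields_empty_output(self, genome):
        assert list(sort_region(iter([]), genome)) == []

    def test_spilled_sort_equals_in_memory_oracle(self, small_dataset,
                                                  tmp_path):
        genome = small_dataset.genome
        reads = list(read_sam(small_dataset.tumor_sam, genome))
        rng = np.random.default_rng(8)
        shuffled = [reads[i] for i in rng.permutation(len(reads))]
        oracle = sorted(shuffled, key=lambda r: sort_key(r, genome))
        spilled = list(sort_region(iter(shuffled), genome,
                                   spill_threshold=500,
                                   scratch=tmp_path / "scratch"))
        assert [r.qname for r in spilled] == [r.qname for r in oracle]
        assert [(r.pos, r.flags) for r in spilled] \
            == [(r.pos, r.flags) for r in oracle]

    def test_sort_is_stable_under_input_permutation(self, genome):
        reads = [make_read(f"r{i}", (i * 13) % 40, ((0, 50),),
                           reverse=bool(i % 2)) for i in range(60)]
        a = list(sort_region(iter(reads), genome))
        b = list(sort_region(iter(reads[::-1]), genome))
        assert [r.qname for r in a] == [r.qname for r in b]


# ---------------------------------------------------------------------------
# duplicate-marking oracle: all-pairs grouping, written independently
# ---------------------------------------------------------------------------

def _oracle_end(read):
    if read.is_reverse:
        end = read.pos
        for op, n in read.cigar:
            if op in REF_OPS:
                end += n
        trail = 0
        for op, n in read.cigar[::-1]:
            if op not in CLIP_OPS:
                break
            trail += n
        return (end - 1 + trail, True)
    lead = 0
    for op, n in read.cigar:
        if op not in CLIP_OPS:
            break
        lead += n
    return (read.pos - lead, False)


def oracle_duplicate_flags(reads):
    """Expected flags via O(n^2) group construction; returns {qname: bool}."""
    units = {}
    for r in reads:
        units.setdefault(r.qname, []).append(r)
    pair_units, frag_units = [], []
    for name, rs in units.items():
        if len(rs) == 2:
            ends = sorted([(r.library, *_oracle_end(r)) for r in rs])
            score = sum(int(q) for r in rs for q in r.qual if q >= 15)
            pair_units.append((tuple(ends), score, name))
        else:
            r = rs[0]
            score = sum(int(q) for q in r.qual if q >= 15)
            frag_units.append(((r.library, *_oracle_end(r)), score, name))
    flags = {}
    # all-pairs comparison of pair units
    for i, (key_i, score_i, name_i) in enumerate(pair_units):
        best = True
        for j, (key_j, score_j, name_j) in enumerate(pair_units):
            if i == j or key_i != key_j:
                continue
            if (score_j, [name_i]) > (score_i, [name_j]):
                pass
            if score_j > score_i or (score_j == score_i and name_j < name_i):
                best = False
        flags[name_i] = not best
    pair_ends = {e for key, _, _ in pair_units for e in key}
    for i, (key_i, score_i, name_i) in enumerate(frag_units):
        if key_i in pair_ends:
            flags[name_i] = True
            continue
        best = True
        for j, (key_j, score_j, name_j) in enumerate(frag_units):
            if i == j or key_i != key_j:
                continue
            if score_j > score_i or (score_j == score_i and name_j < name_i):
                best = False
        flags[name_i] = not best
    return flags


def random_markdup_instance(rng, n_target=500):
    """Coordinate-colliding pairs/fragments with varied clipping and quality."""
    reads = []
    serial = 0
    while len(reads) < n_target:
        u1 = int(rng.integers(1000, 90_000))
        e2 = u1 + int(rng.integers(150, 400))
        n_pairs = int(rng.integers(1, 4))
        for _ in range(n_pairs):
            name = f"q{serial:05d}"
            serial += 1
            s = int(rng.integers(0, 6))
            cigar1 = ((4, s), (0, 100 - s)) if s else ((0, 100),)
            t = int(rng.integers(0, 6))
            cigar2 = ((0, 100 - t), (4, t)) if t else ((0, 100),)
            q1 = rng.integers(2, 41, size=100)
            q2 = rng.integers(2, 41, size=100)
            reads.append(make_read(name, u1 + s, cigar1, quals=q1))
            reads.append(make_read(name, e2 - 100 + 1, cigar2, reverse=True,
                                   quals=q2, read2=True))
        if rng.random() < 0.5:  # a fragment, sometimes colliding with a pair
            name = f"q{serial:05d}"
            serial += 1
            pos = u1 if rng.random() < 0.5 else int(rng.integers(1000, 90_000))
            reads.append(make_read(name, pos, ((0, 100),), paired=False,
                                   quals=rng.integers(2, 41, size=100)))
    reads.sort(key=lambda r: r.pos)
    return reads


class TestMarkDuplicates:
    def test_single_pair_is_never_marked(self, genome):
        reads = [make_read("p", 100, ((0, 100),)),
                 make_read("p", 300, ((0, 100),), reverse=True, read2=True)]
        out = mark_duplicates(reads, genome)
        assert not any(r.is_duplicate for r in out)

    def test_lower_quality_pair_is_marked(self, genome):
        # identical unclipped ends; quality sums 360 vs 300 per read-pair
        hi = [make_read("a", 100, ((0, 100),), quals=[18] * 10 + [2] * 90),
              make_read("a", 300, ((0, 100),), reverse=True, read2=True,
                        quals=[18] * 10 + [2] * 90)]
        lo = [make_read("b", 100, ((0, 100),), quals=[15] * 10 + [2] * 90),
              make_read("b", 300, ((0, 100),), reverse=True, read2=True,
                        quals=[15] * 10 + [2] * 90)]
        out = mark_duplicates(sorted(hi + lo, key=lambda r: r.pos), genome)
        flags = {r.qname: r.is_duplicate for r in out}
        assert flags == {"a": False, "b": True}

    def test_clipped_pair_shares_group_with_unclipped(self, genome):
        # 5S95M at pos 105 has the same unclipped start as 100M at pos 100
        a = [make_read("a", 100, ((0, 100),), quals=[40] * 100),
             make_read("a", 300, ((0, 100),), reverse=True, read2=True,
                       quals=[40] * 100)]
        b = [make_read("b", 105, ((4, 5), (0, 95)), quals=[20] * 100),
             make_read("b", 300, ((0, 95), (4, 5)), reverse=True, read2=True,
                       quals=[20] * 100)]
        out = mark_duplicates(sorted(a + b, key=lambda r: r.pos), genome)
        flags = {r.qname: r.is_duplicate for r in out}
        assert flags == {"a": False, "b": True}

    def test_fragment_matching_pair_end_is_marked(self, genome):
        pair = [make_read("p", 100, ((0, 100),)),
                make_read("p", 300, ((0, 100),), reverse=True, read2=True)]
        frag = [make_read("f", 100, ((0, 100),), paired=False,
                          quals=[40] * 100)]
        out = mark_duplicates(sorted(pair + frag, key=lambda r: r.pos), genome)
        flags = {r.qname: r.is_duplicate for r in out}
        assert flags == {"p": False, "f": True}

    def test_unsorted_input_is_detected(self, genome):
        reads = [make_read("a", 500, ((0, 100),)),
                 make_read("b", 100, ((0, 100),))]
        with pytest.raises(SortOrderError):
            mark_duplicates(reads, genome)

    @pytest.mark.parametrize("seed", range(5))
    def test_flags_equal_brute_force_oracle(self, genome, seed):
        rng = np.random.default_rng(100 + seed)
        reads = random_markdup_instance(rng)
        expected = oracle_duplicate_flags(reads)
        out = mark_duplicates(reads, genome)
        got = {r.qname: r.is_duplicate for r in out}
        assert got == expected

    @pytest.mark.parametrize("seed", [0, 1])
    def test_flags_do_not_depend_on_input_order(self, genome, seed):
        rng = np.random.default_rng(200 + seed)
        reads = random_markdup_instance(rng, n_target=200)
        a = {r.qname: r.is_duplicate
             for r in mark_duplicates(list(reads), genome)}
        b = {r.qname: r.is_duplicate
             for r in mark_duplicates(list(reads), genome,
                                      check_sorted=False)}
        rng.shuffle(reads)
        c = {r.qname: r.is_duplicate
             for r in mark_duplicates(reads, genome, check_sorted=False)}
        assert a == b == c

    def test_simulator_duplicates_are_found(self, small_dataset, genome):
        ds = small_dataset
        genome = ds.genome
        reads = sorted(read_sam(ds.tumor_sam, genome),
                       key=lambda r: (genome.index[r.contig], r.pos))
        out = mark_duplicates(reads, genome)
        dup_names = {r.qname for r in out if r.is_duplicate}
        # every registered clone group loses exactly all but one member
        registry = [(orig, dup) for sample, orig, dup in
                    ds.truth.duplicate_pairs if sample == "tumor"]
        assert registry
        for orig, dup in registry:
            # at least one member of each planted clone group is flagged
            assert orig in dup_names or dup in dup_names
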