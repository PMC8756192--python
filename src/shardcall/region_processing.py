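"""Per-region coordinate sorting and deterministic duplicate marking.

Sorting is an external merge sort: reads are buffered up to a spill
threshold, sorted chunks are spilled to scratch SAM files, and the chunks
are heap-merged back into one stream.  Duplicate marking re-implements the
standard PCR-duplicate criteria (identical library and unclipped 5' end
coordinates, paired ends canonicalised), with the representative chosen by
base-quality sum and qname — never by arrival order — so the flags are a
pure function of the read set.  That order-freedom is what makes the
pipeline's output independent of how the genome is partitioned: copies of
a duplicate group that were shuffled into two adjacent regions receive the
same flags in both.
"""

from __future__ import annotations

import heapq
import os
from contextlib import ExitStack
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from .formats_io import (
    OP_H,
    OP_S,
    AlignedRead,
    ReferenceGenome,
    read_sam,
    write_sam,
)

#: bases below this phred score do not count toward the representative score
DUP_SCORE_MIN_BASEQ = 15


class SortOrderError(ValueError):
    """Input that must be coordinate-sorted is not."""


def sort_key(read: AlignedRead, genome: ReferenceGenome) -> tuple:
    """Total, run-stable ordering: (contig ordinal, pos, strand, qname, mate)."""
    return (genome.index[read.contig], read.pos, read.is_reverse,
            read.qname, read.is_read2)


def unclipped_start(read: AlignedRead) -> int:
    """5'-most position of the read before clipping, 0-based.

    Forward strand: alignment start minus leading soft/hard clips.  Reverse
    strand: last aligned base plus trailing soft/hard clips (the 5' end of
    a reverse read is its rightmost coordinate).
    """
    if not read.cigar:
        raise ValueError(f"read {read.qname} has no cigar")
    if read.is_reverse:
        clip = 0
        for op, n in reversed(read.cigar):
            if op in (OP_S, OP_H):
                clip += n
            else:
                break
        return read.reference_end - 1 + clip
    clip = 0
    for op, n in read.cigar:
        if op in (OP_S, OP_H):
            clip += n
        else:
            break
    return read.pos - clip


# ---------------------------------------------------------------------------
# external merge sort
# ---------------------------------------------------------------------------

def sort_region(reads: Iterable[AlignedRead],
                genome: ReferenceGenome,
                spill_threshold: Optional[int] = None,
                scratch: str | os.PathLike | None = None
                ) -> Iterator[AlignedRead]:
    """Yield reads in :func:`sort_key` order with bounded memory.

    Chunks of at most ``spill_threshold`` records are sorted in memory and
    spilled to ``scratch``; the sorted chunks are then merged.  With no
    threshold (or input below it) this is a plain in-memory sort, and the
    output is identical either way.
    """
    key = lambda r: sort_key(r, genome)
    if spill_threshold is None:
        yield from sorted(reads, key=key)
        return
    if spill_threshold < 1:
        raise ValueError("spill_threshold must be >= 1")
    spills: list[Path] = []
    buffer: list[AlignedRead] = []
    scratch_dir: Optional[Path] = None

    def _spill() -> None:
        nonlocal scratch_dir
        if scratch is None:
            raise ValueError("spill_threshold set but no scratch directory")
        scratch_dir = Path(scratch)
        scratch_dir.mkdir(parents=True, exist_ok=True)
        path = scratch_dir / f"spill_{len(spills):05d}.sam"
        buffer.sort(key=key)
        write_sam(buffer, genome, path)
        spills.append(path)
        buffer.clear()

    for read in reads:
        buffer.append(read)
        if len(buffer) >= spill_threshold:
            _spill()
    if not spills:
        yield from sorted(buffer, key=key)
        return
    if buffer:
        _spill()
    streams = [read_sam(p, genome) for p in spills]
    yield from heapq.merge(*streams, key=key)
    for p in spills:
        p.unlink(missing_ok=True)


# ---------------------------------------------------------------------------
# duplicate marking
# ---------------------------------------------------------------------------

def _end_signature(read: AlignedRead,
                   genome: ReferenceGenome) -> tuple[int, int, bool]:
    return (genome.index[read.contig], unclipped_start(read), read.is_reverse)


def _score(read: AlignedRead) -> int:
    return int((read.qual[read.qual >= DUP_SCORE_MIN_BASEQ]).sum())


def _library(read: AlignedRead) -> str:
    return read.library or read.read_group or ""


def mark_duplicates(reads: Iterable[AlignedRead],
                    genome: ReferenceGenome,
                    check_sorted: bool = True) -> list[AlignedRead]:
    """Set the duplicate flag on all but the best read/pair of each group.

    Groups share (library, canonical pair of unclipped-5'-end signatures);
    a read whose mate is absent or unmapped groups by its single end.  The
    representative is the pair (or read) with the highest sum of base
    qualities >= 15, ties broken by smallest qname.  Any unpaired read whose
    end matches a paired group's end is marked (pairs outrank fragments).
    Flags are recomputed from scratch; input order never affects them.
    """
    out: list[AlignedRead] = []
    last: Optional[tuple[int, int]] = None
    for r in reads:
        if check_sorted and not r.is_unmapped:
            k = (genome.index[r.contig], r.pos)
            if last is not None and k < last:
                raise SortOrderError(
                    f"input not coordinate-sorted at read {r.qname}")
            last = k
        out.append(r)

    # collect gradable reads and locate mates within this shard
    by_name: dict[str, list[AlignedRead]] = {}
    gradable: list[AlignedRead] = []
    for r in out:
        if r.is_unmapped or r.is_secondary or r.is_supplementary:
            continue
        r.set_duplicate(False)
        gradable.append(r)
        by_name.setdefault(r.qname, []).append(r)

    pair_groups: dict[tuple, list[tuple[AlignedRead, AlignedRead]]] = {}
    frag_groups: dict[tuple, list[AlignedRead]] = {}
    handled_pairs: set[str] = set()
    for r in gradable:
        mates = by_name[r.qname]
        if (r.is_paired and not r.mate_unmapped and len(mates) == 2
                and mates[0].is_read2 != mates[1].is_read2):
            if r.qname in handled_pairs:
                continue
            handled_pairs.add(r.qname)
            a, b = mates
            ea, eb = _end_signature(a, genome), _end_signature(b, genome)
            if eb < ea:
                a, b, ea, eb = b, a, eb, ea
            pair_groups.setdefault((_library(r), ea, eb), []).append((a, b))
        elif r.qname not in handled_pairs:
            frag_groups.setdefault(
                (_library(r), _end_signature(r, genome)), []).append(r)

    paired_ends: set[tuple] = set()
    for (lib, ea, eb), pairs in pair_groups.items():
        paired_ends.add((lib, ea))
        paired_ends.add((lib, eb))
        if len(pairs) == 1:
            continue
        ranked = sorted(pairs,
                        key=lambda p: (-(_score(p[0]) + _score(p[1])),
                                       p[0].qname))
        for a, b in ranked[1:]:
            a.set_duplicate(True)
            b.set_duplicate(True)

    for (lib, end), frags in frag_groups.items():
        if (lib, end) in paired_ends:
            for f in frags:
                f.set_duplicate(True)
            continue
        if len(frags) == 1:
            continue
        ranked = sorted(frags, key=lambda f: (-_score(f), f.qname))
        for f in ranked[1:]:
            f.set_duplicate(True)
    return out


def process_region_file(path: str | os.PathLike,
                        genome: ReferenceGenome,
                        out_path: str | os.PathLike,
                        spill_threshold: Optional[int] = None,
                        scratch: str | os.PathLike | None = None) -> int:
    """Sort + mark one region shard, writing a flagged coordinate-sorted SAM."""
    ordered = sort_region(read_sam(path, genome), genome,
                          spill_threshold=spill_threshold, scratch=scratch)
    flagged = mark_duplicates(ordered, genome, check_sorted=False)
    return write_sam(flagged, genome, out_path, sort_order="coordinate")
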