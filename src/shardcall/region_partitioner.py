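"""Load-balanced genome partitioning and read-to-region assignment.

The genome is cut into N regions such that each region holds roughly the
same number of aligned tumor reads.  Region boundaries are placed at
quantiles of a random sample of tumor alignment-start positions (default
sample size 60 reads per requested region), snapped so that no region
crosses a contig.  Reads of both samples are then shuffled into per-region
shard files; a read (or its mate) whose alignment overlaps several regions
is copied into every one of them, so each region is self-contained for
pileup, and exactly one copy — the one in the region containing the read's
own alignment start — carries the primary marker that governs all
single-counting rules downstream.
"""

from __future__ import annotations

import copy
import math
import os
import random
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from .formats_io import (
    AlignedRead,
    ReferenceGenome,
    read_bed,
    read_sam,
    write_bed,
    write_sam,
)

#: default reads sampled per requested region (sample size = 60·N)
DEFAULT_SAMPLE_PER_REGION = 60
#: default number of regions for production genomes
DEFAULT_N_REGIONS = 1800


class PartitionError(ValueError):
    pass


@dataclass(frozen=True)
class SamplePositions:
    """Sorted (contig ordinal, position) sample of alignment starts."""

    positions: tuple[tuple[int, int], ...]
    seed: int


class RegionSpec:
    """Ordered, disjoint, genome-covering list of contig intervals."""

    def __init__(self, regions: Sequence[tuple[str, int, int]],
                 genome: ReferenceGenome):
        self.regions: list[tuple[str, int, int]] = list(regions)
        self.genome = genome
        self._validate()
        # per-contig: sorted region starts + the ordinal of each
        self._starts: dict[str, list[int]] = {}
        self._ordinals: dict[str, list[int]] = {}
        for i, (contig, start, _end) in enumerate(self.regions):
            self._starts.setdefault(contig, []).append(start)
            self._ordinals.setdefault(contig, []).append(i)

    def _validate(self) -> None:
        seen_end: dict[str, int] = {}
        last_key: Optional[tuple[int, int]] = None
        for contig, start, end in self.regions:
            if contig not in self.genome.index:
                raise PartitionError(f"region on unknown contig {contig!r}")
            if not (0 <= start < end <= self.genome.contig(contig).length):
                raise PartitionError(
                    f"region {contig}:{start}-{end} outside contig bounds")
            key = (self.genome.index[contig], start)
            if last_key is not None and key <= last_key:
                raise PartitionError("regions not sorted by (contig, start)")
            last_key = key
            if contig in seen_end and start != seen_end[contig]:
                raise PartitionError(
                    f"gap or overlap before {contig}:{start}")
            if contig not in seen_end and start != 0:
                raise PartitionError(f"contig {contig} does not start at 0")
            seen_end[contig] = end
        for c in self.genome:
            if seen_end.get(c.name) != c.length:
                raise PartitionError(f"contig {c.name} not fully covered")

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        return iter(self.regions)

    def region_of(self, contig: str, pos: int) -> int:
        """Ordinal of the unique region containing (contig, pos)."""
        starts = self._starts.get(contig)
        if starts is None:
            raise PartitionError(f"unknown contig {contig!r}")
        i = bisect_right(starts, pos) - 1
        if i < 0 or pos >= self.regions[self._ordinals[contig][i]][2]:
            raise PartitionError(f"position {contig}:{pos} outside genome")
        return self._ordinals[contig][i]

    def overlapping(self, contig: str, start: int, end: int) -> range:
        """Ordinals of all regions overlapping [start, end) on one contig."""
        if end <= start:
            return range(0)
        first = self.region_of(contig, start)
        last = self.region_of(contig, min(end - 1,
                                          self.genome.contig(contig).length - 1))
        return range(first, last + 1)

    # -- BED round trip ----------------------------------------------------
    def to_bed(self, path: str | os.PathLike) -> None:
        write_bed(((c, s, e, i) for i, (c, s, e) in enumerate(self.regions)),
                  path)

    @classmethod
    def from_bed(cls, path: str | os.PathLike,
                 genome: ReferenceGenome) -> "RegionSpec":
        rows = sorted(read_bed(path), key=lambda r: r[3])
        return cls([(c, s, e) for c, s, e, _ in rows], genome)


# ---------------------------------------------------------------------------
# sampling and boundary computation
# ---------------------------------------------------------------------------

def sample_positions(reads: Iterable[AlignedRead], k: int, seed: int,
                     genome: ReferenceGenome) -> SamplePositions:
    """Reservoir-sample k alignment-start positions from mapped reads.

    Uses Algorithm R with a seeded RNG, so the result depends only on the
    read sequence order and the seed.  Returns all positions when fewer
    than ``k`` mapped reads exist; raises when there are none.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = random.Random(seed)
    reservoir: list[tuple[int, int]] = []
    n = 0
    for read in reads:
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        item = (genome.index[read.contig], read.pos)
        if n < k:
            reservoir.append(item)
        else:
            j = rng.randrange(n + 1)
            if j < k:
                reservoir[j] = item
        n += 1
    if n == 0:
        raise PartitionError("no mapped reads to sample from")
    reservoir.sort()
    return SamplePositions(positions=tuple(reservoir), seed=seed)


def compute_regions(samples: SamplePositions, genome: ReferenceGenome,
                    n_regions: int) -> RegionSpec:
    """Place region boundaries at quantiles of the sampled positions.

    Every ⌈k/n_regions⌉-th sorted sample position becomes an intra-contig
    boundary; contigs always start a fresh region, and contigs that drew no
    sample get one whole-contig region, so the requested N is approximate.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    if n_regions > genome.total_length:
        raise PartitionError(
            f"n_regions={n_regions} exceeds genome length {genome.total_length}")
    k = len(samples.positions)
    cuts: dict[int, set[int]] = {}
    if n_regions > 1:
        step = math.ceil(k / n_regions)
        for idx in range(step, k, step):
            ord_, pos = samples.positions[idx]
            if 0 < pos < genome.contigs[ord_].length:
                cuts.setdefault(ord_, set()).add(pos)
    regions: list[tuple[str, int, int]] = []
    for ord_, contig in enumerate(genome.contigs):
        bounds = [0, *sorted(cuts.get(ord_, ())), contig.length]
        for s, e in zip(bounds, bounds[1:]):
            regions.append((contig.name, s, e))
    return RegionSpec(regions, genome)


def partition_from_sam(tumor_sam: str | os.PathLike,
                       genome: ReferenceGenome,
                       n_regions: int,
                       sample_per_region: int = DEFAULT_SAMPLE_PER_REGION,
                       seed: int = 0) -> RegionSpec:
    """Convenience: sample a tumor SAM and compute the region spec."""
    samples = sample_positions(
        read_sam(tumor_sam, genome), k=sample_per_region * n_regions,
        seed=seed, genome=genome)
    return compute_regions(samples, genome, n_regions)


# ---------------------------------------------------------------------------
# read-to-region assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionAssignment:
    """Region ordinals a read is copied into, and its unique primary region."""

    regions: frozenset[int]
    primary: int


def assign_to_regions(read: AlignedRead,
                      mate_interval: Optional[tuple[str, int, int]],
                      spec: RegionSpec) -> RegionAssignment:
    """Assign a mapped read to every region overlapped by its own alignment
    interval or its mate's, keeping the pair intact in every region either
    mate touches.  The primary region contains the read's alignment start.
    """
    if read.is_unmapped:
        raise PartitionError(f"read {read.qname} is unmapped")
    contig, start, end = read.interval
    ordinals = set(spec.overlapping(contig, start, end))
    if mate_interval is not None:
        m_contig, m_start, m_end = mate_interval
        ordinals |= set(spec.overlapping(m_contig, m_start, m_end))
    return RegionAssignment(regions=frozenset(ordinals),
                            primary=spec.region_of(contig, start))


def _mate_intervals(reads: Sequence[AlignedRead]
                    ) -> dict[tuple[str, bool], tuple[str, int, int]]:
    """(qname, is_read2) -> alignment interval, for primary mapped reads."""
    table: dict[tuple[str, bool], tuple[str, int, int]] = {}
    for r in reads:
        if r.is_unmapped or r.is_secondary or r.is_supplementary:
            continue
        table[(r.qname, r.is_read2)] = r.interval
    return table


def shuffle_by_region(tumor: Iterable[AlignedRead],
                      normal: Iterable[AlignedRead],
                      spec: RegionSpec,
                      out_dir: str | os.PathLike) -> dict:
    """Write one combined, sample-tagged SAM shard per region.

    Boundary-overlapping reads/pairs are duplicated into every region they
    touch; the copy in the read's primary region carries ``XP:i:1``, all
    other copies ``XP:i:0``.  Unmapped and secondary/supplementary records
    are dropped with a count.  Returns per-region paths and statistics.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    shards: list[list[AlignedRead]] = [[] for _ in range(len(spec))]
    dropped = 0
    primary_total = 0
    for sample_name, reads in (("T", tumor), ("N", normal)):
        reads = list(reads)
        mates = _mate_intervals(reads)
        for r in reads:
            if r.is_unmapped or r.is_secondary or r.is_supplementary:
                dropped += 1
                continue
            mate_iv = None
            if r.is_paired and not r.mate_unmapped:
                mate_iv = mates.get((r.qname, not r.is_read2))
                if mate_iv is None and r.mate_contig is not None:
                    # mate record absent from input; fall back to its start
                    mate_iv = (r.mate_contig, r.mate_pos, r.mate_pos + 1)
            asn = assign_to_regions(r, mate_iv, spec)
            primary_total += 1
            for ordinal in asn.regions:
                c = copy.copy(r)
                c.qual = r.qual  # share the array; copies are read-only
                c.sample = sample_name
                c.primary = (ordinal == asn.primary)
                shards[ordinal].append(c)
    paths = []
    for ordinal, shard in enumerate(shards):
        path = out_dir / f"region_{ordinal:05d}.sam"
        write_sam(shard, spec.genome, path)
        paths.append(str(path))
    return {
        "paths": paths,
        "dropped_unassigned": dropped,
        "primary_reads": primary_total,
        "per_region_counts": [len(s) for s in shards],
    }
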