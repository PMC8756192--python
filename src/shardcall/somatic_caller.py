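"""Position-local tumor/normal pileup somatic SNV caller and shard merging.

The built-in caller scores each site independently from the two samples'
pileups: per-base error rates come from (recalibrated) phred qualities,
and the alternate-read model is P(alt read | AF=f) = f(1-e) + (1-f)e/3.
TLOD is the log10 likelihood ratio of the tumor data at the empirical
allele fraction versus AF=0; NLOD is the log10 ratio supporting a
homozygous-reference normal against a germline heterozygote (AF=0.5).
Because every score depends only on the pileup column — and boundary
duplication guarantees each region sees every read overlapping it — the
merged calls are exactly independent of how the genome was partitioned.

External callers can be plugged in through :class:`CallerAdapter`, a
command-template contract (region + two region SAM paths in, VCF shard
out); the adapter is never required by the built-in path.
"""

from __future__ import annotations

import math
import os
import subprocess
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .bqsr import RecalTable, apply_bqsr
from .formats_io import AlignedRead, ReferenceGenome, VariantRecord, encode_bases
from .region_partitioner import RegionSpec

_BASES = "ACGT"


class CallerError(ValueError):
    pass


@dataclass(frozen=True)
class CallParams:
    """Thresholds of the built-in caller (all configurable)."""

    tlod_min: float = 6.3
    nlod_min: float = 2.2
    min_depth: int = 8
    max_normal_af: float = 0.03
    min_mapq: int = 20
    min_baseq: int = 13


@dataclass(slots=True)
class PileupColumn:
    """Allele/quality tallies of one sample at one position.

    ``depth`` counts filter-passing bases (including ambiguous ones);
    ``counts[i]`` and ``mean_q[i]`` cover A/C/G/T in that order, so the sum
    of allele counts never exceeds the depth.
    """

    contig: str
    pos: int
    ref: str
    depth: int
    counts: np.ndarray  # shape (4,), int64
    mean_q: np.ndarray  # shape (4,), float64; 0 where counts == 0


class RegionPileup:
    """Dense pileup arrays of one sample over one region interval."""

    def __init__(self, contig: str, start: int, end: int, ref_codes: np.ndarray):
        self.contig = contig
        self.start = start
        self.end = end
        self.ref_codes = ref_codes  # region slice of the reference
        n = end - start
        self.depth = np.zeros(n, dtype=np.int64)
        self.counts = np.zeros((4, n), dtype=np.int64)
        self.qual_sum = np.zeros((4, n), dtype=np.int64)

    def column(self, pos: int) -> PileupColumn:
        i = pos - self.start
        counts = self.counts[:, i].copy()
        with np.errstate(invalid="ignore"):
            mean_q = np.where(counts > 0,
                              self.qual_sum[:, i] / np.maximum(counts, 1), 0.0)
        ref_code = int(self.ref_codes[i])
        return PileupColumn(
            contig=self.contig, pos=pos,
            ref=_BASES[ref_code] if ref_code < 4 else "N",
            depth=int(self.depth[i]), counts=counts, mean_q=mean_q)


def pileup_region(reads: Iterable[AlignedRead],
                  genome: ReferenceGenome,
                  region: tuple[str, int, int],
                  min_mapq: int = 20,
                  min_baseq: int = 13) -> RegionPileup:
    """Tally filter-passing bases of one sample over one region.

    Uses every copy present in the shard (boundary duplication makes the
    shard self-contained) but skips duplicate-flagged, secondary,
    supplementary and low-mapq reads.  Only positions inside the region
    interval are tallied.  Input must be coordinate-sorted.
    """
    contig, start, end = region
    pile = RegionPileup(contig, start, end,
                        genome.base_codes(contig)[start:end])
    last_pos = -1
    for read in reads:
        if read.is_unmapped:
            continue
        if read.contig != contig:
            raise CallerError(
                f"read {read.qname} on {read.contig}, expected {contig}")
        if read.pos < last_pos:
            raise CallerError("pileup input is not coordinate-sorted")
        last_pos = read.pos
        if (read.is_duplicate or read.is_secondary or read.is_supplementary
                or read.mapq < min_mapq):
            continue
        qpos, rpos = read.aligned_pairs()
        if qpos.size == 0:
            continue
        keep = (rpos >= start) & (rpos < end) & (read.qual[qpos] >= min_baseq)
        if not keep.any():
            continue
        qpos, rpos = qpos[keep], rpos[keep]
        codes = encode_bases(read.seq)[qpos]
        offs = rpos - start
        np.add.at(pile.depth, offs, 1)
        acgt = codes < 4
        np.add.at(pile.counts, (codes[acgt], offs[acgt]), 1)
        np.add.at(pile.qual_sum, (codes[acgt], offs[acgt]),
                  read.qual[qpos[acgt]].astype(np.int64))
    return pile


@dataclass(slots=True)
class SomaticCall:
    record: VariantRecord
    tumor_af: float
    tlod: float
    nlod: float


def _phred_to_err(q: float) -> float:
    return 10.0 ** (-q / 10.0)


def _log10_alt_model(f: float, e: float) -> float:
    return math.log10(f * (1.0 - e) + (1.0 - f) * e / 3.0)


def _log10_ref_model(f: float, e: float) -> float:
    return math.log10((1.0 - f) * (1.0 - e) + f * e / 3.0)


def call_site(t: PileupColumn, n: PileupColumn,
              params: CallParams = CallParams()) -> Optional[SomaticCall]:
    """Score one locus; return a call iff all thresholds are met.

    TLOD compares the tumor reads' likelihood at f = alt count / depth
    against f = 0; NLOD compares the normal at f = 0 against a germline
    heterozygote (f = 0.5).  Sites with no tumor alt reads, insufficient
    depth, or normal alt contamination above ``max_normal_af`` yield None.
    """
    if t.pos != n.pos or t.contig != n.contig:
        raise CallerError("tumor and normal columns are at different loci")
    if t.depth == 0 or t.ref not in _BASES:
        return None
    ref_i = _BASES.index(t.ref)
    alt_counts = t.counts.copy()
    alt_counts[ref_i] = 0
    alt_i = int(np.argmax(alt_counts))  # ties: first in A<C<G<T order
    c_alt = int(alt_counts[alt_i])
    if c_alt == 0:
        return None
    c_ref = int(t.counts[ref_i])
    f_hat = c_alt / t.depth
    e_alt = _phred_to_err(float(t.mean_q[alt_i]))
    e_ref = _phred_to_err(float(t.mean_q[ref_i])) if c_ref else 0.0
    tlod = c_alt * (_log10_alt_model(f_hat, e_alt) - math.log10(e_alt / 3.0))
    if c_ref:
        tlod += c_ref * (_log10_ref_model(f_hat, e_ref)
                         - _log10_ref_model(0.0, e_ref))

    n_ref = int(n.counts[ref_i]) if n.depth else 0
    n_alt = int(n.counts[alt_i]) if n.depth else 0
    normal_af = n_alt / n.depth if n.depth else 0.0
    nlod = 0.0
    if n_ref:
        e = _phred_to_err(float(n.mean_q[ref_i]))
        nlod += n_ref * (_log10_ref_model(0.0, e) - _log10_ref_model(0.5, e))
    if n_alt:
        e = _phred_to_err(float(n.mean_q[alt_i]))
        nlod += n_alt * (_log10_alt_model(0.0, e) - _log10_alt_model(0.5, e))

    if (tlod < params.tlod_min or nlod < params.nlod_min
            or t.depth < params.min_depth or normal_af > params.max_normal_af):
        return None
    record = VariantRecord(
        contig=t.contig, pos=t.pos, ref=t.ref, alt=(_BASES[alt_i],),
        qual_score=round(tlod, 2), filter="PASS",
        info={"TLOD": round(tlod, 2), "NLOD": round(nlod, 2),
              "TAF": round(f_hat, 4), "TDP": t.depth, "NDP": n.depth},
    )
    return SomaticCall(record=record, tumor_af=f_hat, tlod=tlod, nlod=nlod)


def call_region(tumor_reads: Iterable[AlignedRead],
                normal_reads: Iterable[AlignedRead],
                genome: ReferenceGenome,
                region: tuple[str, int, int],
                table: Optional[RecalTable] = None,
                params: CallParams = CallParams()) -> list[SomaticCall]:
    """Pile up both samples over one region and score every candidate site.

    When ``table`` is given, base qualities are recalibrated first; pass
    None for inputs already produced by :func:`~shardcall.bqsr.apply_bqsr`.
    Only loci inside the region interval are emitted, in position order.
    """
    contig, start, end = region
    if contig not in genome.index or end > genome.contig(contig).length:
        raise CallerError(f"region {region} does not fit genome")
    if table is not None:
        tumor_reads = (apply_bqsr(r, table) for r in tumor_reads)
        normal_reads = (apply_bqsr(r, table) for r in normal_reads)
    t_pile = pileup_region(tumor_reads, genome, region,
                           params.min_mapq, params.min_baseq)
    n_pile = pileup_region(normal_reads, genome, region,
                           params.min_mapq, params.min_baseq)
    ref = t_pile.ref_codes
    alt_any = t_pile.counts.sum(axis=0)
    valid = ref < 4
    ref_cnt = np.where(valid, t_pile.counts[np.minimum(ref, 3),
                                            np.arange(ref.size)], 0)
    candidates = np.nonzero(valid & (alt_any - ref_cnt > 0))[0]
    calls = []
    for off in candidates.tolist():
        pos = start + off
        call = call_site(t_pile.column(pos), n_pile.column(pos), params)
        if call is not None:
            calls.append(call)
    return calls


def merge_shard_vcfs(shards: Sequence[Sequence[VariantRecord]],
                     spec: RegionSpec) -> list[VariantRecord]:
    """Concatenate per-region records in region order (= genome order).

    Each shard's records must lie inside its region — guaranteed by
    :func:`call_region` — so no locus can appear twice; both contracts are
    re-checked here.
    """
    if len(shards) != len(spec):
        raise CallerError(
            f"{len(shards)} shards for {len(spec)} regions")
    merged: list[VariantRecord] = []
    seen: set[tuple] = set()
    for ordinal, shard in enumerate(shards):
        contig, start, end = spec.regions[ordinal]
        for rec in shard:
            if rec.contig != contig or not (start <= rec.pos < end):
                raise CallerError(
                    f"record {rec.contig}:{rec.pos} outside region {ordinal} "
                    f"({contig}:{start}-{end})")
            if rec.key in seen:
                raise CallerError(f"duplicate locus {rec.key} in shards")
            seen.add(rec.key)
            merged.append(rec)
    return merged


@dataclass(frozen=True)
class CallerAdapter:
    """Command-template contract for external per-region callers.

    The template receives ``{tumor}``, ``{normal}``, ``{genome}``,
    ``{contig}``, ``{start}``, ``{end}`` and ``{out_vcf}``.  Nothing in the
    package requires an external binary; this is the seam where one plugs
    in.
    """

    command_template: str

    def run(self, tumor_sam: str, normal_sam: str, genome_fa: str,
            region: tuple[str, int, int], out_vcf: str) -> None:
        contig, start, end = region
        cmd = self.command_template.format(
            tumor=tumor_sam, normal=normal_sam, genome=genome_fa,
            contig=contig, start=start, end=end, out_vcf=out_vcf)
        subprocess.run(cmd, shell=True, check=True)
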