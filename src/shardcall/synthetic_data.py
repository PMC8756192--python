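"""Desk-scale tumor/normal read simulator with known truth.

Generates a small multi-contig reference, germline heterozygous and
somatic SNVs at chosen allele fractions, and paired-end reads for both
samples with: a systematic quality-miscalibration model (constant reported
quality, true error rate that jumps in late machine cycles and for chosen
dinucleotide contexts), cloned PCR duplicate pairs, and extra pairs placed
across likely region boundaries.  Reads are emitted pre-aligned (exact
simulated coordinates, ungapped cigars), which mirrors a pipeline run from
pre-aligned input and keeps every stage testable without an aligner; the
same reads can be exported as FASTQ for the chunker.

Everything is driven by one integer seed through a counter-based RNG, so
a dataset is bit-reproducible across runs and platforms.
"""

from __future__ import annotations

import gzip
import os
from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .formats_io import (
    FLAG_MATE_REVERSE,
    FLAG_PAIRED,
    FLAG_PROPER,
    FLAG_READ1,
    FLAG_READ2,
    FLAG_REVERSE,
    OP_M,
    AlignedRead,
    Contig,
    ReferenceGenome,
    VariantRecord,
    write_fasta,
    write_sam,
    write_vcf,
)

_BASES = "ACGT"
_COMP = {0: 3, 1: 2, 2: 1, 3: 0}


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions of the default simulation.

    The defaults describe a ~60 kb three-contig genome sequenced at
    60x/30x (tumor/normal) with 100 bp paired reads, 1e-3 germline
    heterozygote density, 30 somatic SNVs at mixed allele fractions, 5%
    PCR duplicate pairs, and a miscalibrated machine that reports Q40
    everywhere while truly erring at 1% beyond cycle 70 (plus a small
    context bump for GG).
    """

    contig_lengths: tuple[int, ...] = (30_000, 20_000, 10_000)
    germline_het_rate: float = 1e-3
    somatic_count: int = 30
    somatic_afs: tuple[float, ...] = (0.1, 0.2, 0.35, 0.5, 0.8)
    tumor_depth: float = 60.0
    normal_depth: float = 30.0
    read_length: int = 100
    fragment_mean: float = 300.0
    fragment_sd: float = 30.0
    duplicate_fraction: float = 0.05
    reported_q: int = 40
    base_error_rate: float = 1e-4
    miscal_cycle_start: int = 70  # cycles beyond this err at miscal_error_rate
    miscal_error_rate: float = 0.01
    context_error_boost: tuple[tuple[str, float], ...] = (("GG", 0.003),)
    coverage_skew: float = 1.0  # extra sampling weight on first half of contig 1
    boundary_pair_count: int = 60
    gc_content: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tumor_depth <= 0 or self.normal_depth <= 0:
            raise ValueError("depths must be positive")
        if not all(0 < af <= 1 for af in self.somatic_afs):
            raise ValueError("allele fractions must lie in (0, 1]")
        if self.read_length > self.fragment_mean:
            raise ValueError("read length must not exceed mean fragment size")
        if min(self.contig_lengths) < self.read_length:
            raise ValueError("contigs must be at least one read long")


@dataclass
class TruthSet:
    """Planted truth: variant loci, per-read errors, duplicate registry."""

    germline: dict[tuple[str, int], tuple[str, str]]
    somatic: dict[tuple[str, int], tuple[str, str, float]]
    read_errors: dict[str, list[int]] = field(default_factory=dict)
    duplicate_pairs: list[tuple[str, str, str]] = field(default_factory=list)


@dataclass
class SimulatedDataset:
    """Paths of one simulated run plus its in-memory truth."""

    genome: ReferenceGenome
    truth: TruthSet
    reference_fa: str
    tumor_sam: str
    normal_sam: str
    known_vcf: str
    truth_somatic_vcf: str
    truth_germline_vcf: str
    duplicates_tsv: str
    tumor_pair_count: int
    normal_pair_count: int


def simulate_reference(params: SimulationParams) -> ReferenceGenome:
    """IID reference at the configured GC content; seed-deterministic."""
    rng = np.random.default_rng(params.seed)
    gc = params.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    contigs = []
    for i, length in enumerate(params.contig_lengths):
        codes = rng.choice(4, size=length, p=probs)
        seq = "".join(_BASES[c] for c in codes)
        contigs.append(Contig(f"chr{i + 1}", length, seq))
    return ReferenceGenome(contigs)


def simulate_truth(params: SimulationParams,
                   genome: ReferenceGenome) -> TruthSet:
    """Draw germline het loci (rate per bp) and somatic SNV loci (disjoint)."""
    rng = np.random.default_rng(params.seed + 1)
    germline: dict[tuple[str, int], tuple[str, str]] = {}
    for c in genome:
        hits = np.nonzero(rng.random(c.length) < params.germline_het_rate)[0]
        for pos in hits.tolist():
            ref = c.sequence[pos]
            alt = _BASES[(_BASES.index(ref) + rng.integers(1, 4)) % 4]
            germline[(c.name, pos)] = (ref, alt)
    somatic: dict[tuple[str, int], tuple[str, str, float]] = {}
    total = genome.total_length
    offsets = np.cumsum([0] + [c.length for c in genome])
    attempts = 0
    while len(somatic) < params.somatic_count and attempts < 10_000:
        attempts += 1
        g = int(rng.integers(total))
        ci = int(np.searchsorted(offsets, g, side="right") - 1)
        contig = genome.contigs[ci]
        pos = g - int(offsets[ci])
        key = (contig.name, pos)
        if key in germline or key in somatic:
            continue
        ref = contig.sequence[pos]
        alt = _BASES[(_BASES.index(ref) + rng.integers(1, 4)) % 4]
        af = float(params.somatic_afs[len(somatic) % len(params.somatic_afs)])
        somatic[key] = (ref, alt, af)
    return TruthSet(germline=germline, somatic=somatic)


# ---------------------------------------------------------------------------
# read generation
# ---------------------------------------------------------------------------

def _fragment_coords(params: SimulationParams, genome: ReferenceGenome,
                     n_pairs: int, rng: np.random.Generator
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(contig index, start, length) arrays for n_pairs fragments.

    Sampling weight is uniform per base except the first half of contig 1,
    which is boosted by ``coverage_skew``.
    """
    segments = []  # (contig idx, start, end, weight)
    for ci, c in enumerate(genome.contigs):
        if ci == 0 and params.coverage_skew != 1.0:
            half = c.length // 2
            segments.append((ci, 0, half, params.coverage_skew))
            segments.append((ci, half, c.length, 1.0))
        else:
            segments.append((ci, 0, c.length, 1.0))
    weights = np.array([(e - s) * w for _, s, e, w in segments])
    weights = weights / weights.sum()
    seg_idx = rng.choice(len(segments), size=n_pairs, p=weights)
    lengths = np.clip(
        np.rint(rng.normal(params.fragment_mean, params.fragment_sd,
                           size=n_pairs)).astype(np.int64),
        params.read_length, None)
    contig_idx = np.empty(n_pairs, dtype=np.int64)
    starts = np.empty(n_pairs, dtype=np.int64)
    for i, si in enumerate(seg_idx.tolist()):
        ci, s, e, _ = segments[si]
        clen = genome.contigs[ci].length
        flen = min(int(lengths[i]), clen)
        lengths[i] = flen
        start = int(rng.integers(s, e))
        start = min(start, clen - flen)
        contig_idx[i] = ci
        starts[i] = start
    return contig_idx, starts, lengths


def _boundary_coords(params: SimulationParams, genome: ReferenceGenome,
                     rng: np.random.Generator
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fragments centered on evenly spaced genome positions, so that
    quantile-placed region boundaries on near-uniform coverage cut through
    a known minimum number of pairs."""
    n = params.boundary_pair_count
    if n == 0:
        return (np.empty(0, np.int64),) * 3
    total = genome.total_length
    offsets = np.cumsum([0] + [c.length for c in genome])
    centers = np.linspace(total / (n + 1), total - total / (n + 1), n)
    contig_idx = np.empty(n, dtype=np.int64)
    starts = np.empty(n, dtype=np.int64)
    lengths = np.clip(
        np.rint(rng.normal(params.fragment_mean, params.fragment_sd,
                           size=n)).astype(np.int64),
        params.read_length, None)
    for i, g in enumerate(centers):
        ci = int(np.searchsorted(offsets, g, side="right") - 1)
        clen = genome.contigs[ci].length
        flen = min(int(lengths[i]), clen)
        lengths[i] = flen
        start = int(g - offsets[ci]) - flen // 2
        start = max(0, min(start, clen - flen))
        contig_idx[i] = ci
        starts[i] = start
    return contig_idx, starts, lengths


def _haplotypes(params: SimulationParams, genome: ReferenceGenome,
                truth: TruthSet, sample: str,
                contig_idx: np.ndarray, starts: np.ndarray,
                lengths: np.ndarray, rng: np.random.Generator
                ) -> dict[int, list[tuple[int, int]]]:
    """fragment index -> [(position, alt base code)] substitutions.

    Germline hets are carried with probability 0.5 in both samples;
    somatic alts with probability AF in the tumor only.  Every somatic
    locus with at least one overlapping tumor fragment is guaranteed one
    carrier (the truth files must never name an unobservable variant).
    """
    carried: dict[int, list[tuple[int, int]]] = {}
    loci: list[tuple[str, int, str, float, bool]] = []
    for (cname, pos), (ref, alt) in truth.germline.items():
        loci.append((cname, pos, alt, 0.5, False))
    if sample == "tumor":
        for (cname, pos), (ref, alt, af) in truth.somatic.items():
            loci.append((cname, pos, alt, af, True))
    name_to_idx = {c.name: i for i, c in enumerate(genome.contigs)}
    ends = starts + lengths
    for cname, pos, alt, prob, is_somatic in loci:
        ci = name_to_idx[cname]
        over = np.nonzero((contig_idx == ci) & (starts <= pos)
                          & (pos < ends))[0]
        if over.size == 0:
            continue
        take = rng.random(over.size) < prob
        if is_somatic and not take.any():
            take[0] = True  # guarantee the locus is observable
        alt_code = _BASES.index(alt)
        for fi in over[take].tolist():
            carried.setdefault(fi, []).append((pos, alt_code))
    return carried


def _error_rates(params: SimulationParams,
                 machine_codes: np.ndarray) -> np.ndarray:
    """Per-cycle true substitution-error probability of one machine read."""
    n = machine_codes.size
    rates = np.full(n, params.base_error_rate)
    rates[params.miscal_cycle_start:] = params.miscal_error_rate
    for dinuc, boost in params.context_error_boost:
        p_code, c_code = _BASES.index(dinuc[0]), _BASES.index(dinuc[1])
        hit = (machine_codes[1:] == c_code) & (machine_codes[:-1] == p_code)
        rates[1:][hit] += boost
    return rates


class _ReadFactory:
    """Materialises SAM records for one sample."""

    def __init__(self, params: SimulationParams, genome: ReferenceGenome,
                 sample: str, rng: np.random.Generator, truth: TruthSet):
        self.p = params
        self.genome = genome
        self.sample = sample
        self.rng = rng
        self.truth = truth
        self.read_group = sample
        self.library = f"lib_{sample}"
        self._codes = {c.name: np.array(
            [_BASES.index(b) if b in _BASES else 4 for b in c.sequence],
            dtype=np.int8) for c in genome}

    def _machine_read(self, stored: np.ndarray, reverse: bool, qname: str,
                      mate: int) -> np.ndarray:
        """Inject sequencing errors; returns the stored-orientation codes."""
        machine = stored[::-1].copy() if reverse else stored.copy()
        if reverse:
            machine = np.array([_COMP.get(int(c), 4) for c in machine],
                               dtype=np.int8)
        rates = _error_rates(self.p, machine)
        hits = np.nonzero(self.rng.random(machine.size) < rates)[0]
        for i in hits.tolist():
            machine[i] = (machine[i] + int(self.rng.integers(1, 4))) % 4
            self.truth.read_errors.setdefault(
                f"{qname}/{mate}", []).append(i + 1)  # 1-based machine cycle
        if reverse:
            out = np.array([_COMP.get(int(c), 4) for c in machine[::-1]],
                           dtype=np.int8)
            return out
        return machine

    def make_pair(self, qname: str, ci: int, start: int, flen: int,
                  substitutions: list[tuple[int, int]]) -> tuple[AlignedRead,
                                                                 AlignedRead]:
        rl = self.p.read_length
        contig = self.genome.contigs[ci]
        frag = self._codes[contig.name][start:start + flen].copy()
        for pos, alt_code in substitutions:
            frag[pos - start] = alt_code
        r1_stored = self._machine_read(frag[:rl], reverse=False,
                                       qname=qname, mate=1)
        r2_stored = self._machine_read(frag[flen - rl:], reverse=True,
                                       qname=qname, mate=2)
        qual = np.full(rl, self.p.reported_q, dtype=np.uint8)
        pos1, pos2 = start, start + flen - rl
        common = FLAG_PAIRED | FLAG_PROPER
        reads = []
        for stored, pos, mate_pos, flags, tlen in (
                (r1_stored, pos1, pos2,
                 common | FLAG_MATE_REVERSE | FLAG_READ1, flen),
                (r2_stored, pos2, pos1,
                 common | FLAG_REVERSE | FLAG_READ2, -flen)):
            seq = "".join(_BASES[c] if c < 4 else "N" for c in stored.tolist())
            reads.append(AlignedRead(
                qname=qname, flags=flags, contig=contig.name, pos=pos,
                mapq=60, cigar=((OP_M, rl),), seq=seq, qual=qual.copy(),
                read_group=self.read_group, library=self.library,
                mate_contig=contig.name, mate_pos=mate_pos, tlen=tlen))
        return reads[0], reads[1]


def simulate_reads(params: SimulationParams, genome: ReferenceGenome,
                   truth: TruthSet, out_dir: str | os.PathLike
                   ) -> SimulatedDataset:
    """Write the full dataset (FASTA, two SAMs, truth/known VCFs, registry)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ref_fa = out_dir / "ref.fa"
    write_fasta(genome, ref_fa)

    sam_paths = {}
    pair_counts = {}
    for sample, depth, seed_off in (("tumor", params.tumor_depth, 2),
                                    ("normal", params.normal_depth, 3)):
        rng = np.random.default_rng(params.seed + seed_off)
        n_pairs = int(round(depth * genome.total_length
                            / (2 * params.read_length)))
        ci, st, ln = _fragment_coords(params, genome, n_pairs, rng)
        if sample == "tumor":
            bci, bst, bln = _boundary_coords(params, genome, rng)
            ci = np.concatenate([ci, bci])
            st = np.concatenate([st, bst])
            ln = np.concatenate([ln, bln])
        carried = _haplotypes(params, genome, truth, sample, ci, st, ln, rng)
        factory = _ReadFactory(params, genome, sample, rng, truth)
        prefix = "t" if sample == "tumor" else "n"
        reads: list[AlignedRead] = []
        for i in range(ci.size):
            qname = f"sim{prefix}_{i:07d}"
            r1, r2 = factory.make_pair(qname, int(ci[i]), int(st[i]),
                                       int(ln[i]), carried.get(i, []))
            reads.extend((r1, r2))
        # PCR duplicates: clone existing fragments with fresh errors
        n_dup = int(round(params.duplicate_fraction * ci.size))
        if n_dup:
            sources = rng.choice(ci.size, size=n_dup, replace=False)
            for j, src in enumerate(sorted(sources.tolist())):
                qname = f"sim{prefix}_dup{j:05d}"
                r1, r2 = factory.make_pair(qname, int(ci[src]), int(st[src]),
                                           int(ln[src]), carried.get(src, []))
                reads.extend((r1, r2))
                truth.duplicate_pairs.append(
                    (sample, f"sim{prefix}_{src:07d}", qname))
        path = out_dir / f"{sample}.sam"
        write_sam(reads, genome, path,
                  read_groups=[{"ID": sample, "LB": f"lib_{sample}",
                                "SM": sample}])
        sam_paths[sample] = str(path)
        pair_counts[sample] = ci.size + n_dup

    known_vcf = out_dir / "known.vcf"
    germ_records = [
        VariantRecord(contig=c, pos=p, ref=ref, alt=(alt,),
                      qual_score=None, filter="PASS", info={"AF": 0.5})
        for (c, p), (ref, alt) in sorted(
            truth.germline.items(),
            key=lambda kv: (genome.index[kv[0][0]], kv[0][1]))
    ]
    write_vcf(germ_records, genome, known_vcf)
    germline_vcf = out_dir / "truth_germline.vcf"
    write_vcf(germ_records, genome, germline_vcf)
    somatic_vcf = out_dir / "truth_somatic.vcf"
    write_vcf([
        VariantRecord(contig=c, pos=p, ref=ref, alt=(alt,),
                      qual_score=None, filter="PASS", info={"AF": af})
        for (c, p), (ref, alt, af) in sorted(
            truth.somatic.items(),
            key=lambda kv: (genome.index[kv[0][0]], kv[0][1]))
    ], genome, somatic_vcf)
    dup_tsv = out_dir / "duplicates.tsv"
    pd.DataFrame(truth.duplicate_pairs,
                 columns=["sample", "original", "duplicate"]).to_csv(
        dup_tsv, sep="\t", index=False)

    return SimulatedDataset(
        genome=genome, truth=truth, reference_fa=str(ref_fa),
        tumor_sam=sam_paths["tumor"], normal_sam=sam_paths["normal"],
        known_vcf=str(known_vcf), truth_somatic_vcf=str(somatic_vcf),
        truth_germline_vcf=str(germline_vcf), duplicates_tsv=str(dup_tsv),
        tumor_pair_count=pair_counts["tumor"],
        normal_pair_count=pair_counts["normal"],
    )


def simulate_dataset(params: SimulationParams,
                     out_dir: str | os.PathLike) -> SimulatedDataset:
    """Reference + truth + reads in one call."""
    genome = simulate_reference(params)
    truth = simulate_truth(params, genome)
    return simulate_reads(params, genome, truth, out_dir)


def export_fastq(sam_path: str | os.PathLike, genome: ReferenceGenome,
                 r1_path: str | os.PathLike,
                 r2_path: str | os.PathLike) -> int:
    """Write machine-orientation paired FASTQ (gzip) from a simulated SAM.

    Pairs are emitted in file order; reverse-strand mates are
    reverse-complemented back to sequencing orientation.  Returns the pair
    count.
    """
    from .formats_io import read_sam

    comp = str.maketrans("ACGTN", "TGCAN")
    pending: dict[str, AlignedRead] = {}
    n = 0
    with gzip.open(r1_path, "wt") as f1, gzip.open(r2_path, "wt") as f2:
        for read in read_sam(sam_path, genome):
            other = pending.pop(read.qname, None)
            if other is None:
                pending[read.qname] = read
                continue
            first, second = (other, read) if read.is_read2 else (read, other)
            for fh, r, mate in ((f1, first, 1), (f2, second, 2)):
                seq = r.seq
                qual = "".join(chr(q + 33) for q in r.qual)
                if r.is_reverse:
                    seq = seq.translate(comp)[::-1]
                    qual = qual[::-1]
                fh.write(f"@{r.qname}/{mate}\n{seq}\n+\n{qual}\n")
            n += 1
    if pending:
        raise ValueError(f"{len(pending)} reads without mates in {sam_path}")
    return n
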