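"""Readers and writers for the pipeline's on-disk formats.

All genomic coordinates are 0-based, half-open inside the package; the
1-based conventions of SAM and VCF text are converted exactly once, here at
the I/O boundary.  SAM and VCF parsing/serialisation are delegated to
pysam (htslib), FASTA access to pyfaidx; this module only adapts those
records to the package's lightweight domain types.

Supported formats: FASTA (+ .fai sidecar), FASTQ (plain or gzip), SAM
(plain or gzip; BAM works through the same htslib reader but is not the
required path), VCF 4.x, 3/4-column BED, and the tab-separated
recalibration report.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyfaidx import Fasta


class FormatError(ValueError):
    """A file violated its format contract."""


class SamFormatError(FormatError):
    pass


class VcfFormatError(FormatError):
    pass


# SAM flag bits
FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80
FLAG_SECONDARY = 0x100
FLAG_QCFAIL = 0x200
FLAG_DUPLICATE = 0x400
FLAG_SUPPLEMENTARY = 0x800

# cigar op codes, pysam/htslib order
CIGAR_OPS = "MIDNSHP=X"
OP_M, OP_I, OP_D, OP_N, OP_S, OP_H, OP_P, OP_EQ, OP_X = range(9)
_QUERY_CONSUMES = {OP_M, OP_I, OP_S, OP_EQ, OP_X}
_REF_CONSUMES = {OP_M, OP_D, OP_N, OP_EQ, OP_X}


def open_text(path: str | os.PathLike, mode: str = "rt"):
    """Open ``path``, transparently un/compressing ``.gz``."""
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# reference genome
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Contig:
    """One reference sequence; ``sequence`` is upper-case A/C/G/T/N."""

    name: str
    length: int
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != self.length:
            raise FormatError(
                f"contig {self.name}: length {self.length} != sequence length "
                f"{len(self.sequence)}"
            )


# base -> small integer code used by the hot loops; N and everything else -> 4
_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def encode_bases(s: str) -> np.ndarray:
    """Map a base string to uint8 codes A=0 C=1 G=2 T=3, other=4."""
    return _BASE_CODE[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]


class ReferenceGenome:
    """Ordered collection of contigs; contig order defines ordinals 0..n-1."""

    def __init__(self, contigs: Sequence[Contig]):
        names = [c.name for c in contigs]
        if len(set(names)) != len(names):
            raise FormatError("duplicate contig names in genome")
        self.contigs: list[Contig] = list(contigs)
        self.index: dict[str, int] = {c.name: i for i, c in enumerate(contigs)}
        self._codes: dict[str, np.ndarray] = {}

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "ReferenceGenome":
        fa = Fasta(os.fspath(path), as_raw=True, sequence_always_upper=True)
        contigs = [Contig(name, len(fa[name]), str(fa[name][:])) for name in fa.keys()]
        return cls(contigs)

    def contig(self, name: str) -> Contig:
        return self.contigs[self.index[name]]

    def base_codes(self, name: str) -> np.ndarray:
        """Cached uint8 base codes of one contig (A=0..T=3, N=4)."""
        arr = self._codes.get(name)
        if arr is None:
            arr = encode_bases(self.contig(name).sequence)
            self._codes[name] = arr
        return arr

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.contigs)

    def __len__(self) -> int:
        return len(self.contigs)

    def __iter__(self) -> Iterator[Contig]:
        return iter(self.contigs)

    def genome_id(self) -> str:
        """Cheap content fingerprint used to match tables to genomes."""
        import hashlib

        h = hashlib.sha256()
        for c in self.contigs:
            h.update(c.name.encode())
            h.update(c.sequence.encode())
        return h.hexdigest()[:16]


def write_fasta(genome: ReferenceGenome, path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.name, description="") for c in genome
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# aligned reads (SAM)
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class AlignedRead:
    """One SAM-record-equivalent read.

    ``pos`` is the 0-based leftmost aligned base.  ``cigar`` uses htslib
    integer op codes (see :data:`CIGAR_OPS`).  ``sample`` and ``primary``
    carry the pipeline's shard bookkeeping and are serialised as the local
    SAM tags ``XO:Z`` (sample of origin) and ``XP:i`` (1 iff this copy lives
    in the read's primary region).
    """

    qname: str
    flags: int
    contig: Optional[str]
    pos: int
    mapq: int
    cigar: tuple[tuple[int, int], ...]
    seq: str
    qual: np.ndarray
    read_group: Optional[str] = None
    library: Optional[str] = None
    mate_contig: Optional[str] = None
    mate_pos: int = -1
    tlen: int = 0
    sample: Optional[str] = None
    primary: Optional[bool] = None

    # -- flag helpers ------------------------------------------------------
    @property
    def is_paired(self) -> bool:
        return bool(self.flags & FLAG_PAIRED)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flags & FLAG_UNMAPPED)

    @property
    def mate_unmapped(self) -> bool:
        return bool(self.flags & FLAG_MATE_UNMAPPED)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flags & FLAG_REVERSE)

    @property
    def is_read2(self) -> bool:
        return bool(self.flags & FLAG_READ2)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flags & FLAG_SECONDARY)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flags & FLAG_SUPPLEMENTARY)

    @property
    def is_duplicate(self) -> bool:
        return bool(self.flags & FLAG_DUPLICATE)

    def set_duplicate(self, value: bool) -> None:
        if value:
            self.flags |= FLAG_DUPLICATE
        else:
            self.flags &= ~FLAG_DUPLICATE

    # -- coordinate helpers ------------------------------------------------
    @property
    def reference_end(self) -> int:
        """0-based exclusive end of the alignment on the reference."""
        return self.pos + sum(n for op, n in self.cigar if op in _REF_CONSUMES)

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.contig, self.pos, self.reference_end)

    def aligned_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """(query positions, reference positions) of M/=/X-aligned bases."""
        qs, rs = [], []
        q = r = 0
        for op, n in self.cigar:
            if op in (OP_M, OP_EQ, OP_X):
                qs.append(np.arange(q, q + n))
                rs.append(np.arange(r, r + n))
                q += n
                r += n
            elif op in (OP_I, OP_S):
                q += n
            elif op in (OP_D, OP_N):
                r += n
        if not qs:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        return np.concatenate(qs), self.pos + np.concatenate(rs)

    def validate(self, genome: Optional[ReferenceGenome] = None) -> None:
        if len(self.seq) != len(self.qual):
            raise SamFormatError(
                f"read {self.qname}: SEQ length {len(self.seq)} != QUAL length "
                f"{len(self.qual)}"
            )
        if not self.is_unmapped:
            qlen = sum(n for op, n in self.cigar if op in _QUERY_CONSUMES)
            if qlen != len(self.seq):
                raise SamFormatError(
                    f"read {self.qname}: cigar query length {qlen} != SEQ "
                    f"length {len(self.seq)}"
                )
            if genome is not None:
                contig = genome.contig(self.contig)
                if not (0 <= self.pos < contig.length):
                    raise SamFormatError(
                        f"read {self.qname}: pos {self.pos} outside contig "
                        f"{self.contig} (length {contig.length})"
                    )


def _make_header(genome: ReferenceGenome,
                 read_groups: Sequence[Mapping[str, str]] | None = None,
                 sort_order: str = "unknown") -> pysam.AlignmentHeader:
    d: dict = {
        "HD": {"VN": "1.6", "SO": sort_order},
        "SQ": [{"SN": c.name, "LN": c.length} for c in genome],
    }
    if read_groups:
        d["RG"] = [dict(rg) for rg in read_groups]
    return pysam.AlignmentHeader.from_dict(d)


def _from_pysam(seg: pysam.AlignedSegment,
                rg_library: Mapping[str, str]) -> AlignedRead:
    qual = seg.query_qualities
    rg = seg.get_tag("RG") if seg.has_tag("RG") else None
    return AlignedRead(
        qname=seg.query_name,
        flags=seg.flag,
        contig=None if seg.is_unmapped else seg.reference_name,
        pos=-1 if seg.is_unmapped else seg.reference_start,
        mapq=seg.mapping_quality,
        cigar=tuple(seg.cigartuples or ()),
        seq=seg.query_sequence or "",
        qual=np.asarray(qual, dtype=np.uint8) if qual is not None
        else np.empty(0, dtype=np.uint8),
        read_group=rg,
        library=rg_library.get(rg) if rg is not None else None,
        mate_contig=seg.next_reference_name
        if seg.next_reference_id >= 0 else None,
        mate_pos=seg.next_reference_start,
        tlen=seg.template_length,
        sample=seg.get_tag("XO") if seg.has_tag("XO") else None,
        primary=bool(seg.get_tag("XP")) if seg.has_tag("XP") else None,
    )


def read_sam(path: str | os.PathLike,
             genome: ReferenceGenome,
             validate: bool = True) -> Iterator[AlignedRead]:
    """Yield :class:`AlignedRead` from a plain/gzip SAM (or BAM) file.

    Header contigs must be a subset of ``genome`` with consistent lengths.
    SAM's 1-based POS becomes the internal 0-based ``pos`` (htslib performs
    the conversion; we only check the contract).
    """
    with pysam.AlignmentFile(os.fspath(path), "r", check_sq=True) as af:
        rg_library = {
            rg["ID"]: rg.get("LB")
            for rg in af.header.to_dict().get("RG", [])
        }
        for name, length in zip(af.references, af.lengths):
            if name not in genome.index:
                raise SamFormatError(
                    f"SAM header contig {name!r} not present in genome")
            if genome.contig(name).length != length:
                raise SamFormatError(
                    f"SAM header contig {name!r} length {length} != genome "
                    f"length {genome.contig(name).length}")
        n = 0
        it = iter(af)
        while True:
            try:
                seg = next(it)
            except StopIteration:
                return
            except (OSError, ValueError) as exc:
                raise SamFormatError(
                    f"malformed SAM record at or after record {n + 1}: {exc}"
                ) from exc
            n += 1
            read = _from_pysam(seg, rg_library)
            if validate:
                read.validate(genome)
            yield read


def _to_pysam(read: AlignedRead, header: pysam.AlignmentHeader,
              genome: ReferenceGenome) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(header)
    seg.query_name = read.qname
    seg.flag = read.flags
    if read.contig is not None:
        seg.reference_id = genome.index[read.contig]
        seg.reference_start = read.pos
    seg.mapping_quality = read.mapq
    if read.cigar:
        seg.cigartuples = list(read.cigar)
    seg.query_sequence = read.seq
    seg.query_qualities = pysam.qualitystring_to_array(
        "".join(chr(q + 33) for q in read.qual))
    if read.mate_contig is not None:
        seg.next_reference_id = genome.index[read.mate_contig]
        seg.next_reference_start = read.mate_pos
    seg.template_length = read.tlen
    if read.read_group is not None:
        seg.set_tag("RG", read.read_group)
    if read.sample is not None:
        seg.set_tag("XO", read.sample)
    if read.primary is not None:
        seg.set_tag("XP", int(read.primary))
    return seg


def write_sam(reads: Iterable[AlignedRead],
              genome: ReferenceGenome,
              path: str | os.PathLike,
              read_groups: Sequence[Mapping[str, str]] | None = None,
              sort_order: str = "unknown") -> int:
    """Write reads as SAM text; returns the record count.

    Read groups are synthesised from the reads when not given, so the
    RG→library mapping survives the round trip.
    """
    reads = list(reads) if not isinstance(reads, list) else reads
    if read_groups is None:
        seen: dict[str, Optional[str]] = {}
        for r in reads:
            if r.read_group is not None and r.read_group not in seen:
                seen[r.read_group] = r.library
        read_groups = [
            {"ID": rg, **({"LB": lb} if lb else {})} for rg, lb in seen.items()
        ]
    header = _make_header(genome, read_groups, sort_order)
    n = 0
    with pysam.AlignmentFile(os.fspath(path), "w", header=header) as out:
        for read in reads:
            out.write(_to_pysam(read, header, genome))
            n += 1
    return n


# ---------------------------------------------------------------------------
# variants (VCF)
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class VariantRecord:
    """One variant site; ``pos`` is 0-based internally, 1-based in VCF text."""

    contig: str
    pos: int
    ref: str
    alt: tuple[str, ...]
    qual_score: Optional[float] = None
    filter: str = "PASS"
    info: dict = field(default_factory=dict)

    @property
    def key(self) -> tuple:
        return (self.contig, self.pos, self.ref, self.alt)


#: INFO fields this pipeline reads/writes.
VCF_INFO_FIELDS = [
    ("AF", "A", "Float", "True/estimated allele fraction"),
    ("TLOD", "1", "Float", "log10 odds of variant in tumor vs sequencing error"),
    ("NLOD", "1", "Float", "log10 odds that the normal is homozygous reference"),
    ("TAF", "1", "Float", "tumor alternate allele fraction"),
    ("TDP", "1", "Integer", "tumor filtered depth"),
    ("NDP", "1", "Integer", "normal filtered depth"),
]


def _vcf_header(genome: ReferenceGenome) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for c in genome:
        header.contigs.add(c.name, length=c.length)
    for name, number, typ, desc in VCF_INFO_FIELDS:
        header.info.add(name, number, typ, desc)
    return header


def read_vcf(path: str | os.PathLike) -> Iterator[VariantRecord]:
    """Yield :class:`VariantRecord` with 0-based positions from a VCF 4.x file."""
    try:
        vf = pysam.VariantFile(os.fspath(path))
    except (OSError, ValueError) as exc:
        raise VcfFormatError(f"cannot parse VCF {path}: {exc}") from exc
    with vf:
        for rec in vf:
            info = {}
            for k, v in rec.info.items():
                if isinstance(v, tuple) and len(v) == 1:
                    v = v[0]
                info[k] = v
            filt = ";".join(rec.filter.keys()) or "PASS"
            yield VariantRecord(
                contig=rec.contig,
                pos=rec.start,  # pysam's .start is already 0-based
                ref=rec.ref,
                alt=tuple(rec.alts or ()),
                qual_score=rec.qual,
                filter=filt,
                info=info,
            )


def write_vcf(records: Iterable[VariantRecord],
              genome: ReferenceGenome,
              path: str | os.PathLike) -> int:
    header = _vcf_header(genome)
    n = 0
    with pysam.VariantFile(os.fspath(path), "w", header=header) as out:
        for rec in records:
            vr = out.new_record(
                contig=rec.contig,
                start=rec.pos,
                stop=rec.pos + len(rec.ref),
                alleles=(rec.ref, *rec.alt),
            )
            if rec.qual_score is not None:
                vr.qual = rec.qual_score
            if rec.filter and rec.filter != "PASS":
                for f in rec.filter.split(";"):
                    vr.filter.add(f)
            else:
                vr.filter.add("PASS")
            for k, v in rec.info.items():
                vr.info[k] = v
            out.write(vr)
            n += 1
    return n


# ---------------------------------------------------------------------------
# known sites
# ---------------------------------------------------------------------------

#: bases masked on either side of a known indel
INDEL_MASK_PAD = 5


class KnownSites:
    """Positions excluded from recalibration error counting.

    SNV sites mask their own position; indels mask the affected reference
    interval padded by ``INDEL_MASK_PAD`` on both sides.
    """

    def __init__(self, snv: Mapping[str, Sequence[int]],
                 indel_intervals: Mapping[str, Sequence[tuple[int, int]]] | None = None,
                 sites_id: str = ""):
        self.snv = {c: np.unique(np.asarray(p, dtype=np.int64))
                    for c, p in snv.items()}
        self.indel_intervals = {
            c: sorted(iv) for c, iv in (indel_intervals or {}).items()
        }
        self.sites_id = sites_id
        self._masks: dict[tuple[str, int], np.ndarray] = {}

    @classmethod
    def from_vcf(cls, path: str | os.PathLike) -> "KnownSites":
        snv: dict[str, list[int]] = {}
        indels: dict[str, list[tuple[int, int]]] = {}
        for rec in read_vcf(path):
            if all(len(a) == 1 for a in rec.alt) and len(rec.ref) == 1:
                snv.setdefault(rec.contig, []).append(rec.pos)
            else:
                span = max(len(rec.ref), 1)
                indels.setdefault(rec.contig, []).append(
                    (rec.pos - INDEL_MASK_PAD, rec.pos + span + INDEL_MASK_PAD))
        import hashlib

        with open_text(path, "rt") as fh:
            sid = hashlib.sha256(fh.read().encode()).hexdigest()[:16]
        return cls(snv, indels, sites_id=sid)

    def mask(self, contig: str, length: int) -> np.ndarray:
        """Boolean array: True where recalibration must skip the position."""
        key = (contig, length)
        m = self._masks.get(key)
        if m is None:
            m = np.zeros(length, dtype=bool)
            for p in self.snv.get(contig, ()):
                if 0 <= p < length:
                    m[p] = True
            for s, e in self.indel_intervals.get(contig, ()):
                m[max(s, 0):min(e, length)] = True
            self._masks[key] = m
        return m


# ---------------------------------------------------------------------------
# BED (region specs)
# ---------------------------------------------------------------------------

def write_bed(intervals: Iterable[tuple[str, int, int, int]],
              path: str | os.PathLike) -> None:
    """Write (contig, start, end, ordinal) rows as 4-column BED (0-based)."""
    with open(path, "w") as fh:
        for contig, start, end, ordinal in intervals:
            fh.write(f"{contig}\t{start}\t{end}\t{ordinal}\n")


def read_bed(path: str | os.PathLike) -> list[tuple[str, int, int, int]]:
    rows = []
    with open_text(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"BED line {i + 1}: fewer than 3 columns")
            name = parts[3] if len(parts) > 3 else str(len(rows))
            rows.append((parts[0], int(parts[1]), int(parts[2]), int(name)))
    return rows


# ---------------------------------------------------------------------------
# recalibration report
# ---------------------------------------------------------------------------

_RECAL_COLUMNS = ["read_group", "reported_q", "cycle", "dinuc_context",
                  "observations", "errors"]


def write_recal_report(table, path: str | os.PathLike) -> None:
    """Serialise a :class:`~shardcall.bqsr.RecalTable` as sorted TSV.

    Metadata travels in ``#key=value`` comment lines; rows are written in
    canonical key order so equal tables serialise to identical bytes.
    """
    rows = sorted(
        (rg, q, cyc, ctx, obs, err)
        for (rg, q, cyc, ctx), (obs, err) in table.counts.items()
    )
    df = pd.DataFrame(rows, columns=_RECAL_COLUMNS)
    with open(path, "w") as fh:
        fh.write(f"#genome_id={table.genome_id}\n")
        fh.write(f"#known_sites_id={table.known_sites_id}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_recal_report(path: str | os.PathLike):
    from .bqsr import RecalTable

    meta = {"genome_id": "", "known_sites_id": ""}
    with open_text(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for line in lines:
        if line.startswith("#"):
            k, _, v = line[1:].rstrip("\n").partition("=")
            meta[k] = v
            body_start += 1
        else:
            break
    df = pd.read_csv(
        io.StringIO("".join(lines[body_start:])), sep="\t",
        dtype={"read_group": str, "reported_q": int, "cycle": int,
               "dinuc_context": str, "observations": np.int64,
               "errors": np.int64},
    )
    if list(df.columns) != _RECAL_COLUMNS:
        raise FormatError(
            f"recalibration report {path}: unexpected columns {list(df.columns)}")
    table = RecalTable(genome_id=meta["genome_id"],
                       known_sites_id=meta["known_sites_id"])
    for row in df.itertuples(index=False):
        obs, err = int(row.observations), int(row.errors)
        if obs < 0 or err < 0 or err > obs:
            raise FormatError(
                f"recalibration report {path}: invalid counts "
                f"obs={obs} err={err} for key {(row.read_group, row.reported_q, row.cycle, row.dinuc_context)}")
        table.counts[(row.read_group, int(row.reported_q), int(row.cycle),
                      row.dinuc_context)] = (obs, err)
    return table


# ---------------------------------------------------------------------------
# FASTQ records
# ---------------------------------------------------------------------------

def iter_fastq_records(stream) -> Iterator[tuple[str, str, str, str]]:
    """Yield raw 4-line FASTQ records (lines keep no trailing newline)."""
    while True:
        lines = [stream.readline() for _ in range(4)]
        if not lines[0]:
            return
        if not lines[3]:
            raise FormatError("FASTQ line count is not a multiple of 4")
        header, seq, plus, qual = (ln.rstrip("\n") for ln in lines)
        if not header.startswith("@") or not plus.startswith("+"):
            raise FormatError(f"malformed FASTQ block starting at {header!r}")
        if len(seq) != len(qual):
            raise FormatError(
                f"FASTQ record {header!r}: SEQ/QUAL length mismatch")
        yield header, seq, plus, qual
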