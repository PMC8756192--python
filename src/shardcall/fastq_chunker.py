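"""Pair-preserving splitting of paired FASTQ input into work chunks.

Large paired-end inputs are decompressed and cut into chunks of roughly
``chunk_bytes`` uncompressed text (default 60 MiB) so downstream alignment
tasks get evenly sized units of work.  A chunk boundary never separates the
two mates of a pair, and concatenating the chunks in order reproduces the
input exactly.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .formats_io import FormatError, iter_fastq_records, open_text

#: default chunk size, uncompressed bytes
DEFAULT_CHUNK_BYTES = 60 * 2 ** 20


class PairingError(FormatError):
    """The two FASTQ files do not contain matching read pairs."""


@dataclass(frozen=True)
class ChunkManifest:
    chunk_id: int
    file_1: str
    file_2: str
    pair_count: int
    byte_size: int  # uncompressed text bytes, both files combined


def _record_text(rec: tuple[str, str, str, str]) -> str:
    return "\n".join(rec) + "\n"


def split_fastq_pairs(fastq_1: str | os.PathLike,
                      fastq_2: str | os.PathLike,
                      out_dir: str | os.PathLike,
                      chunk_bytes: int = DEFAULT_CHUNK_BYTES,
                      compress: bool = True) -> list[ChunkManifest]:
    """Split two mate-paired FASTQ files into pair-aligned chunks.

    A chunk is closed as soon as its uncompressed size reaches
    ``chunk_bytes``; it may exceed the target only by the pair that pushed
    it over.  Returns manifests in ``chunk_id`` order; a manifest TSV is
    written next to the chunks.
    """
    if chunk_bytes < 1:
        raise ValueError("chunk_bytes must be positive")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    suffix = ".fastq.gz" if compress else ".fastq"

    def _open_out(path: Path):
        return gzip.open(path, "wt") if compress else open(path, "w")

    manifests: list[ChunkManifest] = []
    with open_text(fastq_1) as fh1, open_text(fastq_2) as fh2:
        it1, it2 = iter_fastq_records(fh1), iter_fastq_records(fh2)
        chunk_id = 0
        out1 = out2 = None
        pair_count = size = 0

        def _close_chunk():
            nonlocal out1, out2, chunk_id, pair_count, size
            if out1 is None:
                return
            out1.close()
            out2.close()
            manifests.append(ChunkManifest(
                chunk_id=chunk_id,
                file_1=str(out_dir / f"chunk_{chunk_id:05d}_1{suffix}"),
                file_2=str(out_dir / f"chunk_{chunk_id:05d}_2{suffix}"),
                pair_count=pair_count,
                byte_size=size,
            ))
            out1 = out2 = None
            chunk_id += 1
            pair_count = size = 0

        while True:
            rec1 = next(it1, None)
            rec2 = next(it2, None)
            if rec1 is None and rec2 is None:
                break
            if rec1 is None or rec2 is None:
                raise PairingError(
                    "FASTQ files contain unequal record counts")
            if out1 is None:
                out1 = _open_out(out_dir / f"chunk_{chunk_id:05d}_1{suffix}")
                out2 = _open_out(out_dir / f"chunk_{chunk_id:05d}_2{suffix}")
            t1, t2 = _record_text(rec1), _record_text(rec2)
            out1.write(t1)
            out2.write(t2)
            pair_count += 1
            size += len(t1) + len(t2)
            if size >= chunk_bytes:
                _close_chunk()
        _close_chunk()

    pd.DataFrame([m.__dict__ for m in manifests]).to_csv(
        out_dir / "chunks.tsv", sep="\t", index=False)
    return manifests


def decompress_and_count(path: str | os.PathLike) -> tuple[int, int]:
    """Return (FASTQ record count, uncompressed byte count) of a gzip file."""
    records = 0
    nbytes = 0
    lines = 0
    with gzip.open(path, "rt") as fh:
        for line in fh:
            lines += 1
            nbytes += len(line)
    if lines % 4 != 0:
        raise FormatError(f"{path}: line count {lines} is not a multiple of 4")
    records = lines // 4
    return records, nbytes


def concatenate_chunks(manifests: Iterable[ChunkManifest],
                       mate: int) -> str:
    """Reassemble one mate's text from chunks, in chunk_id order."""
    parts = []
    for m in sorted(manifests, key=lambda m: m.chunk_id):
        path = m.file_1 if mate == 1 else m.file_2
        with open_text(path) as fh:
            parts.append(fh.read())
    return "".join(parts)


def read_chunk_manifest(path: str | os.PathLike) -> list[ChunkManifest]:
    df = pd.read_csv(path, sep="\t")
    return [ChunkManifest(int(r.chunk_id), str(r.file_1), str(r.file_2),
                          int(r.pair_count), int(r.byte_size))
            for r in df.itertuples(index=False)]
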