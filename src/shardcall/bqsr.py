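"""Base quality score recalibration with exactly mergeable count tables.

Each region produces a partial table of integer (observations, errors)
counts per covariate key (read group, reported quality, machine cycle,
dinucleotide context), counting each read once — only in its primary
region — so boundary-duplicated copies are never double-counted.  Partial
tables merge by keywise integer addition, an associative and commutative
operation with the empty table as identity; a tree-merge over any region
split therefore equals the single-pass whole-genome table exactly, which
is the property the rest of the pipeline's partition-invariance rests on.

The empirical quality assigned at application time is a Laplace-smoothed
error frequency, Q = -10*log10((errors+1)/(observations+2)), capped at 60.
This closed-form estimator is deliberately simple: the merge and
equivalence guarantees are independent of the estimator, and a
deterministic formula keeps them exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .formats_io import (
    AlignedRead,
    KnownSites,
    ReferenceGenome,
    encode_bases,
)

#: reported qualities are clamped into this range before keying
REPORTED_Q_MIN, REPORTED_Q_MAX = 2, 60
#: machine cycles above this are binned in steps of 10
CYCLE_BIN_START = 30
CYCLE_BIN_WIDTH = 10
#: minimum observations for a covariate cell to drive recalibration
MIN_OBS_FOR_APPLY = 100
#: assigned qualities are clamped into this range
APPLY_Q_MIN, APPLY_Q_MAX = 2, 60

_DINUC_NN = 16
_DINUC_STRINGS = [a + b for a in "ACGT" for b in "ACGT"] + ["NN"]
_DINUC_INDEX = {s: i for i, s in enumerate(_DINUC_STRINGS)}

# integer packing of (reported_q, binned cycle, dinuc) used by the hot loops
_CYCLE_OFFSET = 512
_CYCLE_SPAN = 1024
_NDINUC = 17


class RecalTableError(ValueError):
    pass


def bin_cycle(cycle: int | np.ndarray) -> int | np.ndarray:
    """Bin |cycle| above CYCLE_BIN_START into CYCLE_BIN_WIDTH-wide bins,
    keeping the sign (negative = reverse-strand read)."""
    a = np.abs(cycle)
    binned = np.where(
        a <= CYCLE_BIN_START, a,
        CYCLE_BIN_START + 1
        + ((a - CYCLE_BIN_START - 1) // CYCLE_BIN_WIDTH) * CYCLE_BIN_WIDTH)
    return np.sign(cycle) * binned


@dataclass
class RecalTable:
    """Integer covariate-count table: key -> (observations, errors)."""

    genome_id: str = ""
    known_sites_id: str = ""
    counts: dict[tuple[str, int, int, str], tuple[int, int]] = field(
        default_factory=dict)

    def __post_init__(self) -> None:
        self._app_cache: Optional["_ApplicationModel"] = None

    def total_observations(self) -> int:
        return sum(o for o, _ in self.counts.values())

    def total_errors(self) -> int:
        return sum(e for _, e in self.counts.values())

    def add(self, key: tuple[str, int, int, str], obs: int, err: int) -> None:
        if obs < 0 or err < 0 or err > obs:
            raise RecalTableError(f"invalid counts ({obs}, {err}) for {key}")
        o, e = self.counts.get(key, (0, 0))
        self.counts[key] = (o + obs, e + err)
        self._app_cache = None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RecalTable):
            return NotImplemented
        return (self.genome_id == other.genome_id
                and self.known_sites_id == other.known_sites_id
                and self.counts == other.counts)


def merge_tables(a: RecalTable, b: RecalTable) -> RecalTable:
    """Keywise integer sum of two partial tables (associative, commutative).

    An empty table acts as the identity; metadata of non-empty tables must
    agree so tables built against different genomes or known-site sets can
    never be mixed.
    """
    for attr in ("genome_id", "known_sites_id"):
        va, vb = getattr(a, attr), getattr(b, attr)
        if a.counts and b.counts and va != vb:
            raise RecalTableError(f"cannot merge tables: {attr} differs "
                                  f"({va!r} vs {vb!r})")
    out = RecalTable(
        genome_id=a.genome_id if a.counts or not b.counts else b.genome_id,
        known_sites_id=a.known_sites_id if a.counts or not b.counts
        else b.known_sites_id,
        counts=dict(a.counts),
    )
    for key, (obs, err) in b.counts.items():
        o, e = out.counts.get(key, (0, 0))
        out.counts[key] = (o + obs, e + err)
    return out


def tree_merge(tables: list[RecalTable]) -> RecalTable:
    """Pairwise reduction tree over the tables; result is shape-independent."""
    if not tables:
        return RecalTable()
    layer = list(tables)
    while len(layer) > 1:
        nxt = [merge_tables(layer[i], layer[i + 1])
               for i in range(0, len(layer) - 1, 2)]
        if len(layer) % 2:
            nxt.append(layer[-1])
        layer = nxt
    return layer[0]


# ---------------------------------------------------------------------------
# covariate extraction
# ---------------------------------------------------------------------------

def _covariate_codes(read: AlignedRead, qpos: np.ndarray,
                     seq_codes: np.ndarray) -> np.ndarray:
    """Packed (reported_q, binned cycle, dinuc) integer code per aligned base.

    Cycle is the 1-based machine cycle, negated for reverse-strand reads
    (whose stored sequence is the reverse complement of what the machine
    read).  The dinucleotide context is (previous machine-order base,
    current base); the first cycle and any N yield the "NN" context.
    """
    length = len(read.seq)
    q = np.clip(read.qual[qpos].astype(np.int64),
                REPORTED_Q_MIN, REPORTED_Q_MAX)
    cur = seq_codes[qpos]
    if read.is_reverse:
        cycle = -(length - qpos.astype(np.int64))
        cur_m = np.where(cur < 4, 3 - cur, 4)
        prev_idx = qpos + 1
        has_prev = prev_idx < length
        prev_raw = seq_codes[np.where(has_prev, prev_idx, 0)]
        prev_m = np.where(has_prev & (prev_raw < 4), 3 - prev_raw, 4)
    else:
        cycle = qpos.astype(np.int64) + 1
        cur_m = cur
        prev_idx = qpos - 1
        has_prev = prev_idx >= 0
        prev_raw = seq_codes[np.where(has_prev, prev_idx, 0)]
        prev_m = np.where(has_prev & (prev_raw < 4), prev_raw, 4)
    dinuc = np.where((prev_m < 4) & (cur_m < 4),
                     prev_m * 4 + cur_m, _DINUC_NN)
    cyc = bin_cycle(cycle) + _CYCLE_OFFSET
    return (q * _CYCLE_SPAN + cyc) * _NDINUC + dinuc


def _decode_key(read_group: str, code: int) -> tuple[str, int, int, str]:
    dinuc = int(code % _NDINUC)
    rest = code // _NDINUC
    cyc = int(rest % _CYCLE_SPAN) - _CYCLE_OFFSET
    q = int(rest // _CYCLE_SPAN)
    return (read_group, q, cyc, _DINUC_STRINGS[dinuc])


def counts_for_bqsr(read: AlignedRead) -> bool:
    """True iff the read contributes to table building in its shard: the
    primary-region copy of a non-duplicate, primary-alignment, mapq>0 read."""
    return not (read.is_unmapped or read.is_duplicate or read.is_secondary
                or read.is_supplementary or read.mapq == 0
                or read.primary is False)


def build_table(reads: Iterable[AlignedRead],
                genome: ReferenceGenome,
                known: KnownSites,
                region: Optional[tuple[str, int, int]] = None) -> RecalTable:
    """Count (observations, errors) per covariate key over one read set.

    Per aligned (M/=/X) base that is not at a known variant site and is not
    an N on either read or reference: observations += 1, and errors += 1
    when the base mismatches the reference.  Insertions and clips
    contribute nothing.  Boundary-duplicated copies (primary flag False)
    and duplicate/secondary/supplementary/mapq-0 reads are skipped, so
    summing any set of region tables counts every read exactly once.

    ``region`` is advisory; single-counting is governed by the primary
    flag, not by the interval.
    """
    per_rg_codes: dict[str, list[np.ndarray]] = {}
    per_rg_errs: dict[str, list[np.ndarray]] = {}
    for read in reads:
        if not counts_for_bqsr(read):
            continue
        qpos, rpos = read.aligned_pairs()
        if qpos.size == 0:
            continue
        ref_codes_all = genome.base_codes(read.contig)
        if rpos[-1] >= ref_codes_all.size:
            raise RecalTableError(
                f"read {read.qname} aligns past the end of {read.contig}")
        seq_codes = encode_bases(read.seq)
        refc = ref_codes_all[rpos]
        curc = seq_codes[qpos]
        masked = known.mask(read.contig, ref_codes_all.size)[rpos]
        usable = (~masked) & (curc < 4) & (refc < 4)
        if not usable.any():
            continue
        codes = _covariate_codes(read, qpos[usable], seq_codes)
        errs = curc[usable] != refc[usable]
        rg = read.read_group or ""
        per_rg_codes.setdefault(rg, []).append(codes)
        per_rg_errs.setdefault(rg, []).append(errs)

    table = RecalTable(genome_id=genome.genome_id(),
                       known_sites_id=known.sites_id)
    for rg, code_chunks in per_rg_codes.items():
        codes = np.concatenate(code_chunks)
        errs = np.concatenate(per_rg_errs[rg])
        ukeys, obs = np.unique(codes, return_counts=True)
        err_map = dict(zip(*np.unique(codes[errs], return_counts=True)))
        for code, o in zip(ukeys.tolist(), obs.tolist()):
            table.counts[_decode_key(rg, code)] = (o, int(err_map.get(code, 0)))
    return table


# ---------------------------------------------------------------------------
# empirical quality and application
# ---------------------------------------------------------------------------

def empirical_quality(observations: int, errors: int) -> float:
    """Laplace-smoothed phred-scaled error estimate, capped at 60."""
    if observations < 0 or errors < 0:
        raise ValueError("counts must be non-negative")
    if errors > observations:
        raise ValueError("errors cannot exceed observations")
    q = -10.0 * math.log10((errors + 1) / (observations + 2))
    return min(q, 60.0)


class _ApplicationModel:
    """Precomputed lookup chain: full key -> (rg, q) aggregate -> rg aggregate."""

    def __init__(self, table: RecalTable):
        self.full: dict[tuple[str, int], tuple[int, int]] = {}
        self.by_rq: dict[tuple[str, int], list[int]] = {}
        self.by_rg: dict[str, list[int]] = {}
        self._code_cache: dict[tuple[str, int], int] = {}
        for (rg, q, cyc, dinuc), (obs, err) in table.counts.items():
            code = ((q * _CYCLE_SPAN + cyc + _CYCLE_OFFSET) * _NDINUC
                    + _DINUC_INDEX[dinuc])
            self.full[(rg, code)] = (obs, err)
            a = self.by_rq.setdefault((rg, q), [0, 0])
            a[0] += obs
            a[1] += err
            g = self.by_rg.setdefault(rg, [0, 0])
            g[0] += obs
            g[1] += err

    def assigned_q(self, rg: str, code: int) -> Optional[int]:
        cached = self._code_cache.get((rg, code))
        if cached is not None:
            return None if cached < 0 else cached
        q_reported = code // (_CYCLE_SPAN * _NDINUC)
        for obs_err in (self.full.get((rg, code)),
                        self.by_rq.get((rg, int(q_reported))),
                        self.by_rg.get(rg)):
            if obs_err is not None and obs_err[0] >= MIN_OBS_FOR_APPLY:
                q = round(empirical_quality(obs_err[0], obs_err[1]))
                q = min(max(q, APPLY_Q_MIN), APPLY_Q_MAX)
                self._code_cache[(rg, code)] = q
                return q
        self._code_cache[(rg, code)] = -1
        return None


def _application_model(table: RecalTable) -> _ApplicationModel:
    if table._app_cache is None:
        table._app_cache = _ApplicationModel(table)
    return table._app_cache


def apply_bqsr(read: AlignedRead, table: RecalTable) -> AlignedRead:
    """Return a copy of the read with recalibrated base qualities.

    Per base the empirical quality of its full covariate cell is assigned
    when that cell holds at least MIN_OBS_FOR_APPLY observations, falling
    back to the (read group, reported quality) aggregate, then the read
    group aggregate, and finally leaving the reported quality unchanged.
    The sequence is untouched; unmapped reads pass through as-is.
    """
    import copy

    if read.is_unmapped or len(read.seq) == 0:
        return copy.copy(read)
    model = _application_model(table)
    seq_codes = encode_bases(read.seq)
    qpos = np.arange(len(read.seq), dtype=np.int64)
    codes = _covariate_codes(read, qpos, seq_codes)
    rg = read.read_group or ""
    new_qual = read.qual.copy()
    for i, code in enumerate(codes.tolist()):
        q = model.assigned_q(rg, code)
        if q is not None:
            new_qual[i] = q
    out = copy.copy(read)
    out.qual = new_qual
    return out
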