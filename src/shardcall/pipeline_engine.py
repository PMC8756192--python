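"""Three-stage scatter-gather orchestration over a process pool.

Job 1 samples the tumor alignments and fixes the region spec.  Job 2
shuffles both samples into per-region shards, sorts and duplicate-marks
each shard, builds partial recalibration tables and tree-merges them into
one genome-wide table.  Job 3 applies the merged table to every shard,
calls somatic variants per region, and merges the shard VCFs into the
final output.  Stage outputs are persisted with checksummed manifests, so
a completed stage is never recomputed; every per-region task is a pure
function of its shard plus the merged table, which makes the final output
independent of worker count and execution order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .bqsr import RecalTable, apply_bqsr, build_table, tree_merge
from .formats_io import (
    KnownSites,
    ReferenceGenome,
    VariantRecord,
    read_recal_report,
    read_sam,
    read_vcf,
    write_recal_report,
    write_sam,
    write_vcf,
)
from .region_partitioner import (
    RegionSpec,
    compute_regions,
    sample_positions,
    shuffle_by_region,
)
from .region_processing import mark_duplicates, sort_region
from .somatic_caller import CallParams, call_region, merge_shard_vcfs


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Flat run configuration (YAML-serialisable)."""

    tumor: str = ""
    normal: str = ""
    genome: str = ""
    known_sites: str = ""
    out_dir: str = "shardcall_out"
    input_mode: str = "aligned"  # "aligned" | "fastq"
    n_regions: int = 1800
    chunk_mb: int = 60
    sample_per_region: int = 60
    seed: int = 0
    workers: int = 1
    caller: str = "builtin"  # "builtin" | "adapter:<template>" | "both:<template>"
    spill_threshold: Optional[int] = None
    aligner_adapter: Optional[str] = None  # "{r1} {r2} {genome} > {sam}"
    tumor_r2: Optional[str] = None  # FASTQ mode second mate files
    normal_r2: Optional[str] = None
    tlod_min: float = 6.3
    nlod_min: float = 2.2
    min_depth: int = 8
    max_normal_af: float = 0.03
    min_mapq: int = 20
    min_baseq: int = 13

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        if self.workers < 1:
            raise ValueError("workers must be >= 1")

    def call_params(self) -> CallParams:
        return CallParams(tlod_min=self.tlod_min, nlod_min=self.nlod_min,
                          min_depth=self.min_depth,
                          max_normal_af=self.max_normal_af,
                          min_mapq=self.min_mapq, min_baseq=self.min_baseq)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def _sha256(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


@dataclass
class StageManifest:
    stage: str
    artifacts: dict[str, str] = field(default_factory=dict)  # path -> sha256
    complete: bool = False

    def path_for(self, out_dir: str | os.PathLike) -> Path:
        return Path(out_dir) / f"manifest_{self.stage}.json"

    def record(self, *paths: str | os.PathLike) -> None:
        for p in paths:
            self.artifacts[str(p)] = _sha256(p)

    def save(self, out_dir: str | os.PathLike) -> None:
        self.complete = True
        with open(self.path_for(out_dir), "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def load_if_complete(cls, stage: str, out_dir: str | os.PathLike
                         ) -> Optional["StageManifest"]:
        """Return the manifest iff it exists and all artifacts still match."""
        path = Path(out_dir) / f"manifest_{stage}.json"
        if not path.exists():
            return None
        try:
            with open(path) as fh:
                data = json.load(fh)
        except (OSError, json.JSONDecodeError):
            return None
        m = cls(stage=data["stage"], artifacts=data.get("artifacts", {}),
                complete=data.get("complete", False))
        if not m.complete:
            return None
        for p, digest in m.artifacts.items():
            if not os.path.exists(p) or _sha256(p) != digest:
                return None
        return m


# ---------------------------------------------------------------------------
# per-region worker tasks (top level: picklable for the process pool)
# ---------------------------------------------------------------------------

_GENOME_CACHE: dict[str, ReferenceGenome] = {}
_KNOWN_CACHE: dict[str, KnownSites] = {}


def _genome(path: str) -> ReferenceGenome:
    g = _GENOME_CACHE.get(path)
    if g is None:
        g = ReferenceGenome.from_fasta(path)
        _GENOME_CACHE[path] = g
    return g


def _known(path: str) -> KnownSites:
    k = _KNOWN_CACHE.get(path)
    if k is None:
        k = KnownSites.from_vcf(path)
        _KNOWN_CACHE[path] = k
    return k


def _job2_task(args: tuple) -> tuple[int, str, str]:
    (ordinal, shard_path, genome_fa, known_vcf, flagged_path, report_path,
     spill_threshold, scratch) = args
    genome = _genome(genome_fa)
    known = _known(known_vcf)
    ordered = sort_region(read_sam(shard_path, genome), genome,
                          spill_threshold=spill_threshold, scratch=scratch)
    flagged = mark_duplicates(ordered, genome, check_sorted=False)
    write_sam(flagged, genome, flagged_path, sort_order="coordinate")
    table = build_table(flagged, genome, known)
    write_recal_report(table, report_path)
    return ordinal, flagged_path, report_path


def _job3_task(args: tuple) -> tuple[int, str]:
    (ordinal, flagged_path, genome_fa, merged_report, region, shard_vcf,
     params_dict) = args
    genome = _genome(genome_fa)
    table = read_recal_report(merged_report)
    params = CallParams(**params_dict)
    tumor, normal = [], []
    for read in read_sam(flagged_path, genome):
        recal = apply_bqsr(read, table)
        (tumor if read.sample == "T" else normal).append(recal)
    calls = call_region(tumor, normal, genome, tuple(region),
                        table=None, params=params)
    write_vcf([c.record for c in calls], genome, shard_vcf)
    return ordinal, shard_vcf


def _run_tasks(task_fn, arg_list: Sequence[tuple], workers: int) -> list:
    if workers <= 1 or len(arg_list) <= 1:
        return [task_fn(a) for a in arg_list]
    with ProcessPoolExecutor(max_workers=workers) as pool:
        return list(pool.map(task_fn, arg_list))


# ---------------------------------------------------------------------------
# jobs
# ---------------------------------------------------------------------------

def _aligned_input(config: PipelineConfig, sample: str) -> str:
    """Path of the aligned SAM for one sample, aligning FASTQ if configured."""
    path = config.tumor if sample == "tumor" else config.normal
    if config.input_mode == "aligned":
        return path
    if config.aligner_adapter is None:
        raise PipelineError("FASTQ input mode requires an aligner adapter")
    from .fastq_chunker import split_fastq_pairs

    r2 = config.tumor_r2 if sample == "tumor" else config.normal_r2
    chunk_dir = Path(config.out_dir) / f"chunks_{sample}"
    manifests = split_fastq_pairs(path, r2, chunk_dir,
                                  chunk_bytes=config.chunk_mb * 2 ** 20)
    sam_paths = []
    import subprocess

    for m in manifests:
        sam = str(chunk_dir / f"chunk_{m.chunk_id:05d}.sam")
        cmd = config.aligner_adapter.format(
            r1=m.file_1, r2=m.file_2, genome=config.genome, sam=sam)
        subprocess.run(cmd, shell=True, check=True)
        sam_paths.append(sam)
    # concatenate chunk alignments into one SAM per sample
    genome = _genome(config.genome)
    merged = Path(config.out_dir) / f"{sample}_aligned.sam"
    reads = [r for p in sam_paths for r in read_sam(p, genome)]
    write_sam(reads, genome, merged)
    return str(merged)


def run_job1(config: PipelineConfig) -> RegionSpec:
    """Sample tumor alignment starts and fix the region spec (persisted BED)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome = _genome(config.genome)
    bed = out_dir / "regions.bed"
    if StageManifest.load_if_complete("job1_partition", out_dir):
        return RegionSpec.from_bed(bed, genome)
    tumor_sam = _aligned_input(config, "tumor")
    samples = sample_positions(
        read_sam(tumor_sam, genome),
        k=config.sample_per_region * config.n_regions,
        seed=config.seed, genome=genome)
    spec = compute_regions(samples, genome, config.n_regions)
    spec.to_bed(bed)
    manifest = StageManifest(stage="job1_partition")
    manifest.record(bed)
    manifest.save(out_dir)
    return spec


def run_job2(config: PipelineConfig, spec: RegionSpec) -> RecalTable:
    """Shuffle, sort, mark duplicates, build + tree-merge the BQSR table."""
    out_dir = Path(config.out_dir)
    merged_report = out_dir / "recal_merged.tsv"
    if StageManifest.load_if_complete("job2_prepare", out_dir):
        return read_recal_report(merged_report)
    genome = _genome(config.genome)
    tumor_sam = _aligned_input(config, "tumor")
    normal_sam = _aligned_input(config, "normal")
    for name, path in (("tumor", tumor_sam), ("normal", normal_sam)):
        if not any(not r.is_unmapped for r in read_sam(path, genome)):
            raise PipelineError(f"{name} input contains no mapped reads")
    shard_dir = out_dir / "shards"
    shuffle = shuffle_by_region(read_sam(tumor_sam, genome),
                                read_sam(normal_sam, genome), spec, shard_dir)
    flagged_dir = out_dir / "flagged"
    recal_dir = out_dir / "recal"
    flagged_dir.mkdir(exist_ok=True)
    recal_dir.mkdir(exist_ok=True)
    tasks = []
    for ordinal, shard_path in enumerate(shuffle["paths"]):
        tasks.append((
            ordinal, shard_path, config.genome, config.known_sites,
            str(flagged_dir / f"region_{ordinal:05d}.sam"),
            str(recal_dir / f"region_{ordinal:05d}.tsv"),
            config.spill_threshold,
            str(out_dir / "scratch" / f"region_{ordinal:05d}"),
        ))
    results = _run_tasks(_job2_task, tasks, config.workers)
    done = {ordinal for ordinal, *_ in results}
    missing = sorted(set(range(len(spec))) - done)
    if missing:
        raise PipelineError(f"job2 incomplete; failed regions: {missing}")
    tables = [read_recal_report(recal_dir / f"region_{o:05d}.tsv")
              for o in range(len(spec))]
    merged = tree_merge(tables)
    write_recal_report(merged, merged_report)
    manifest = StageManifest(stage="job2_prepare")
    manifest.record(merged_report,
                    *(flagged_dir / f"region_{o:05d}.sam"
                      for o in range(len(spec))))
    manifest.save(out_dir)
    return merged


def run_job3(config: PipelineConfig, spec: RegionSpec,
             table: Optional[RecalTable] = None) -> str:
    """Apply BQSR per shard, call somatic variants, merge shard VCFs."""
    out_dir = Path(config.out_dir)
    final_vcf = out_dir / "somatic.vcf"
    if StageManifest.load_if_complete("job3_call", out_dir):
        return str(final_vcf)
    merged_report = out_dir / "recal_merged.tsv"
    if not merged_report.exists():
        raise PipelineError("job3 requires the merged recalibration table")
    genome = _genome(config.genome)
    vcf_dir = out_dir / "shard_vcfs"
    vcf_dir.mkdir(exist_ok=True)
    params = dataclasses.asdict(config.call_params())
    tasks = []
    for ordinal, region in enumerate(spec.regions):
        tasks.append((
            ordinal, str(out_dir / "flagged" / f"region_{ordinal:05d}.sam"),
            config.genome, str(merged_report), list(region),
            str(vcf_dir / f"region_{ordinal:05d}.vcf"), params))
    _run_tasks(_job3_task, tasks, config.workers)
    shards = [list(read_vcf(vcf_dir / f"region_{o:05d}.vcf"))
              for o in range(len(spec))]
    merged_records = merge_shard_vcfs(shards, spec)
    write_vcf(merged_records, genome, final_vcf)
    manifest = StageManifest(stage="job3_call")
    manifest.record(final_vcf)
    manifest.save(out_dir)
    return str(final_vcf)


def run_pipeline(config: PipelineConfig) -> dict:
    """End-to-end run; returns the principal artifact paths."""
    spec = run_job1(config)
    table = run_job2(config, spec)
    vcf = run_job3(config, spec, table)
    out = {
        "regions_bed": str(Path(config.out_dir) / "regions.bed"),
        "recal_report": str(Path(config.out_dir) / "recal_merged.tsv"),
        "vcf": vcf,
        "n_regions": len(spec),
    }
    if config.caller.startswith(("adapter:", "both:")):
        out["adapter_vcf"] = _run_adapter_caller(config, spec)
    return out


def _run_adapter_caller(config: PipelineConfig, spec: RegionSpec) -> str:
    """Second caller over the persisted recalibrated shards (job 4)."""
    from .somatic_caller import CallerAdapter

    template = config.caller.split(":", 1)[1]
    adapter = CallerAdapter(template)
    out_dir = Path(config.out_dir)
    vcf_dir = out_dir / "adapter_vcfs"
    vcf_dir.mkdir(exist_ok=True)
    genome = _genome(config.genome)
    table = read_recal_report(out_dir / "recal_merged.tsv")
    shards = []
    for ordinal, region in enumerate(spec.regions):
        flagged = out_dir / "flagged" / f"region_{ordinal:05d}.sam"
        recal_t = out_dir / "adapter_vcfs" / f"region_{ordinal:05d}_t.sam"
        recal_n = out_dir / "adapter_vcfs" / f"region_{ordinal:05d}_n.sam"
        tumor, normal = [], []
        for read in read_sam(flagged, genome):
            (tumor if read.sample == "T" else normal).append(
                apply_bqsr(read, table))
        write_sam(tumor, genome, recal_t)
        write_sam(normal, genome, recal_n)
        shard_vcf = str(vcf_dir / f"region_{ordinal:05d}.vcf")
        adapter.run(str(recal_t), str(recal_n), config.genome,
                    region, shard_vcf)
        shards.append(list(read_vcf(shard_vcf)))
    merged = merge_shard_vcfs(shards, spec)
    out = out_dir / "somatic_adapter.vcf"
    write_vcf(merged, genome, out)
    return str(out)


# ---------------------------------------------------------------------------
# concordance assessment
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceResult:
    corresponding: int
    only_a: int
    only_b: int
    by_vaf: pd.DataFrame  # cumulative counts per allele-fraction bin


def vcf_concordance(a: Iterable[VariantRecord],
                    b: Iterable[VariantRecord],
                    vaf_bin: float = 0.05) -> ConcordanceResult:
    """Match two call sets on (contig, pos, ref, alt) and stratify by VAF.

    The allele fraction is taken from the a-side record (TAF, falling back
    to AF) when present, else from the b-side, else 0.  ``by_vaf`` holds
    cumulative counts of corresponding / a-only / b-only calls for VAF <=
    each bin's upper edge, bins of width ``vaf_bin`` over [0, 1].
    """
    def _vaf(rec: VariantRecord) -> float:
        for k in ("TAF", "AF"):
            if k in rec.info and rec.info[k] is not None:
                return float(rec.info[k])
        return 0.0

    a_map = {rec.key: rec for rec in a}
    b_map = {rec.key: rec for rec in b}
    both = a_map.keys() & b_map.keys()
    only_a = a_map.keys() - b_map.keys()
    only_b = b_map.keys() - a_map.keys()

    edges = np.round(np.arange(vaf_bin, 1.0 + vaf_bin / 2, vaf_bin), 10)
    rows = []
    vaf_both = np.array([_vaf(a_map[k]) for k in both]) if both else np.empty(0)
    vaf_a = np.array([_vaf(a_map[k]) for k in only_a]) if only_a else np.empty(0)
    vaf_b = np.array([_vaf(b_map[k]) for k in only_b]) if only_b else np.empty(0)
    for edge in edges:
        rows.append({
            "vaf_max": float(edge),
            "corresponding": int((vaf_both <= edge).sum()),
            "only_a": int((vaf_a <= edge).sum()),
            "only_b": int((vaf_b <= edge).sum()),
        })
    return ConcordanceResult(
        corresponding=len(both), only_a=len(only_a), only_b=len(only_b),
        by_vaf=pd.DataFrame(rows))
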