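# shardcall

Scatter-gather somatic SNV calling for tumor/normal pairs on a single
machine, engineered so that the partitioned, parallel run is **provably
identical** to the unpartitioned run.

## Who this is for

Pipeline developers and method researchers who need a somatic
variant-calling workflow whose parallelisation can be *verified* rather
than trusted: every stage that is usually a source of parallel/sequential
discrepancy (duplicate marking near shard boundaries, per-shard base
quality recalibration, shard-VCF merging) is implemented here so that the
output is a pure function of the input — independent of the number of
genomic regions, the number of worker processes, and the execution order.

## The method

The genome is split into N regions containing roughly equal numbers of
aligned tumor reads, estimated from a reservoir sample of alignment starts
(60 reads per region by default) by placing boundaries at sample
quantiles. Tumor and normal reads are shuffled into per-region shards;
a read pair overlapping several regions is copied into all of them, with
the copy in the region holding the read's alignment start marked as
*primary*. Per region, reads are coordinate-sorted (external merge sort)
and PCR duplicates are flagged with an order-free tie-break, so boundary
copies receive identical flags everywhere.

Base quality score recalibration counts, per covariate key
(read group, reported quality, machine cycle, dinucleotide context),
integer pairs (observations o, mismatches e) over primary copies only —
never counting a boundary-duplicated read twice — masking known variant
sites. Partial tables merge by keywise integer addition (associative and
commutative), so a tree-merge over any split equals the single-pass
genome-wide table exactly. Assigned qualities use the Laplace-smoothed
empirical estimate

    Q = −10·log10((e + 1)/(o + 2)),  capped at 60.

The built-in caller scores each site from the two pileups with the
alternate-read model P(alt | AF = f) = f(1−ε) + (1−f)ε/3, emitting a call
when TLOD (tumor data at f̂ = alt/depth vs AF = 0) ≥ 6.3, NLOD (normal
homozygous-reference vs heterozygote) ≥ 2.2, tumor depth ≥ 8 and normal
alt fraction ≤ 0.03. External callers can be plugged in per region via a
command-template adapter. Shard VCFs are concatenated in region order into
the final VCF.

A synthetic-data module generates the full study conditions (multi-contig
reference, germline + somatic truth, miscalibrated qualities, PCR
duplicates, boundary-spanning pairs) so everything is testable offline;
see `docs/methods.md` for the model details and limitations.

## Worked example

Simulate a ~60 kb tumor/normal dataset, run the pipeline with 16 regions
and 4 workers, and compare the calls with the planted truth:

```
$ shardcall simulate --seed 2 --out sim
tumor pairs     18963
normal pairs    9450
somatic truth   sim/truth_somatic.vcf

$ cat run.yaml
tumor: sim/tumor.sam
normal: sim/normal.sam
genome: sim/ref.fa
known_sites: sim/known.vcf
out_dir: run
n_regions: 16
workers: 4
seed: 7

$ shardcall run --config run.yaml
regions_bed     run/regions.bed
recal_report    run/recal_merged.tsv
vcf     run/somatic.vcf
n_regions       18

$ shardcall concordance run/somatic.vcf sim/truth_somatic.vcf
corresponding   28
only_a  0
only_b  2
```

`n_regions 18` is the requested 16 plus contig snapping (no region may
cross a contig). Of the 30 planted somatic SNVs, 28 are called with no
false positives; the 2 misses are low-allele-fraction loci
(`only_b`, visible in the allele-fraction-binned table the command also
prints). A typical record:

```
chr1  523  .  T  A  141.21  PASS  TLOD=141.21;NLOD=12.03;TAF=0.8246;TDP=57;NDP=40
```

i.e. a T→A variant supported at tumor allele fraction 0.82 (57× filtered
tumor depth), with log10-odds 141.2 for the variant in the tumor and 12.0
for the normal being homozygous reference at 40× depth.

Rerunning with `n_regions: 1` and `workers: 1` produces a byte-identical
`somatic.vcf` body — that equivalence is the point of the package, and the
test suite asserts it across N ∈ {1, 4, 16} × workers ∈ {1, 4}.

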