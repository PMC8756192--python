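# Methods

## The problem and the approach

Somatic variant calling compares tumor reads with a matched normal sample
to find mutations private to the tumor. The preprocessing and calling
stages (sorting, duplicate marking, base quality score recalibration,
per-site calling) are embarrassingly parallel *by genomic region* — except
for two couplings that a naive scatter-gather breaks:

1. **Reads near region boundaries** are needed by both flanking regions
   (for pileups and for duplicate groups that straddle the cut), and
2. **base quality recalibration (BQSR)** is only accurate when its
   mismatch statistics are pooled over the whole genome, not per region.

`shardcall` implements the scatter-gather architecture around these two
couplings so that the partitioned run is *exactly* equivalent to the
unpartitioned run: for any region count N and any worker count, the final
VCF is byte-identical. The test suite and `scripts/acceptance.py` verify
this directly.

The pipeline is organised as three jobs with persisted, checksummed
intermediates:

* **Job 1** — sample tumor alignment starts, fix the region spec
  (persisted as BED).
* **Job 2** — shuffle both samples into per-region SAM shards with
  boundary duplication; per region: external-merge sort, duplicate
  marking, partial BQSR table; tree-merge the partial tables into one
  genome-wide table.
* **Job 3** — apply the merged table per region, call somatic SNVs per
  region, merge shard VCFs in region order.

## Region partitioning

Boundaries are placed at quantiles of a reservoir sample of tumor
alignment-start positions (default 60 reads per requested region, i.e.
k = 60·N samples): every ⌈k/N⌉-th sorted sample becomes a cut. Cuts never
cross a contig; every contig starts a fresh region and contigs with no
sampled read get one whole-contig region, so the realised region count is
approximately N. Consequences:

* No region can hold many more sampled reads than the quantile step, so
  the maximum region load stays below twice the mean even under 2–3×
  coverage skew (asserted for N ∈ {4, 16, 64}).
* The *remainder* region at the end of each contig can hold far fewer
  reads than the step. This is deliberate: load balance is threatened by
  overloaded regions, not underloaded ones.

Reservoir sampling uses a single seeded RNG; the spec is a pure function
of (input read order, seed, N).

## Boundary duplication and the primary region

A mapped read is copied into **every region overlapped by its own
alignment interval or its mate's interval**. This is a superset of the
minimal "duplicate pairs that span a boundary" rule, chosen because it
gives two exact guarantees:

* every region's pileup sees every read overlapping every position of the
  region (position-local calling is then exactly partition-invariant), and
* both mates of a pair travel together into every region either mate
  touches, so duplicate groups (keyed on pair ends) are never split.

Exactly one copy — the one in the region containing the read's alignment
start (its *primary region*) — carries the `XP:i:1` tag. Every
single-counting rule downstream (BQSR observation counting) consumes only
primary copies, which makes partial counts add up to the whole-genome
counts as plain integer sums. Unmapped and secondary/supplementary records
are dropped at the shuffle with a logged count.

## Sorting and duplicate marking

Sorting is an external merge sort over the key (contig ordinal, position,
strand, read name, mate flag) — a total order, so the result is unique
regardless of input order or spill threshold. Chunks beyond the spill
threshold go to scratch SAM files and are heap-merged back.

Duplicate marking re-implements the standard PCR-duplicate criteria:
reads/pairs sharing (library, unclipped 5′-end coordinates and strands,
pair ends canonicalised) form a group; the representative is the pair (or
single read) with the highest sum of base qualities ≥ 15, ties broken by
lexicographically smallest read name; everything else is flagged. Paired
groups outrank fragments: an unpaired read whose end matches a paired
group's end is always flagged. Two deliberate choices:

* **No arrival-order tie-break.** The winner is a function of the read set
  only, so boundary copies of one group receive identical flags in every
  region that holds them — removing exactly the source of variability that
  makes naive parallel duplicate marking diverge from a sequential run.
* **No optical-duplicate detection** (tile/x/y parsing is
  sequencer-specific); all duplicates are treated as PCR-type.
  Flags are set, reads are never removed.

Both the unit suite and the acceptance checks compare the flags against an
independent brute-force O(n²) grouping oracle on randomised instances with
soft/hard-clipped reads.

## BQSR: mergeable tables and a closed-form estimator

Covariates are the standard four: read group, reported quality (clamped to
[2, 60]), signed machine cycle (1-based, negative on reverse-strand reads;
binned in steps of 10 beyond cycle 30 to bound the table), and machine-
order dinucleotide context (first cycle and Ns map to "NN"). Counting
walks aligned (M/=/X) bases of primary-copy, non-duplicate,
non-secondary, mapq>0 reads; a base contributes one observation — and one
error if it mismatches the reference — unless it sits at a known variant
site (SNV positions; known indels padded by ±5 bp) or either base is N.
Insertions and clips contribute nothing.

Partial tables merge by keywise integer addition: associative,
commutative, empty-table identity. A tree-reduction of any region split in
any order therefore equals the single-pass whole-genome table with exact
integer equality — this is the property the architecture exists for, and
it is asserted, not approximated.

The empirical quality assigned at application time is a Laplace-smoothed
frequency,

    Q(o, e) = −10·log10((e + 1)/(o + 2)),  capped at 60,

*not* a hierarchical shrinkage estimator: the merge and equivalence
guarantees are estimator-independent, and a closed form keeps them exact
and auditable. Application uses the full covariate cell when it holds at
least 100 observations, else the (read group, reported quality) aggregate,
else the read-group aggregate, else it leaves the reported quality
unchanged — an embodiment of the fact that recalibration accuracy grows
with the volume of observed data, which is why the genome-wide merge
matters.

## The built-in somatic caller

Calling is position-local by design: a per-site tumor/normal pileup caller
makes the partition-equivalence claim exactly testable, whereas
assembly-window callers are reachable through the `CallerAdapter` command
template but are outside this package's scope (as are indels, panels of
normals, and contamination modelling).

Pileups count non-duplicate, mapq ≥ 20, baseq ≥ 13 bases. With per-base
error ε (from the mean recalibrated phred of each allele's reads) and the
alternate-read model P(alt read | AF = f) = f(1−ε) + (1−f)·ε/3:

* **TLOD** = log10 likelihood ratio of the tumor data at f̂ = alt/depth
  versus f = 0;
* **NLOD** = log10 ratio supporting a homozygous-reference normal against
  a germline heterozygote (f = 0.5).

A call is emitted iff TLOD ≥ 6.3, NLOD ≥ 2.2, tumor depth ≥ 8, and normal
alt fraction ≤ 0.03 (defaults; all configurable). The hard normal-AF gate
is intentionally simple and is the caller's known brittleness: at 30×
normal depth a *single* sequencing-error read matching the alt pushes the
normal fraction to ~0.033 and vetoes the site, which is what occasionally
costs a true AF ≥ 0.2 variant (observed recall on the default simulation
is ~0.95–1.0 across seeds; specificity at germline heterozygous loci has
been 100% in all runs).

Ties between candidate alt alleles break in A<C<G<T order. Shard VCFs may
only contain loci inside their own region (re-checked at merge), so
concatenation in region order is the genome-ordered, duplicate-free final
VCF.

## Synthetic data: what it emulates and what it does not

The default generator — the dataset all headline checks run on — produces:

* three contigs of 30/20/10 kb, IID bases at GC 0.5;
* germline heterozygotes at 1e-3 per bp (present in both samples, carrier
  probability 0.5 per fragment) and 30 somatic SNVs at allele fractions
  cycling through {0.1, 0.2, 0.35, 0.5, 0.8} (tumor only, carrier
  probability = AF per fragment);
* 100 bp paired reads from Normal(300, 30) fragments at 60× tumor / 30×
  normal, emitted pre-aligned with exact coordinates and 100M cigars;
* a miscalibrated quality model: reported Q40 everywhere, true
  substitution error 1e-4 up to machine cycle 70, 1% beyond it, plus a
  +0.3% bump after GG contexts;
* 5% cloned PCR duplicate pairs (same fragment, fresh errors, registered
  in a truth file) and 60 extra pairs centred on evenly spaced positions
  so that quantile cuts are guaranteed to hit pairs;
* known-sites VCF = the germline truth; somatic truth VCF with true AFs.

Every somatic locus with at least one overlapping tumor fragment is
guaranteed one carrier (the first overlapping fragment is promoted if the
binomial draw produced none): truth files must never name an unobservable
variant. This inflates very low AFs by at most one read.

Not emulated, hence not demonstrated by passing tests: indels and
structural variants, alignment ambiguity and soft-clipping in the main
datasets (clipped reads are covered by hand-built fixtures only), optical
duplicate coordinates, realistic error spectra beyond the stated model,
mapping-quality variation, and reference bias. The exactness results
(merge, N-invariance, conservation) do not depend on any of these; the
statistical results (recall, calibration recovery) do.

Reads are emitted pre-aligned because the pipeline's aligned-input mode is
the tested path; FASTQ input plus an external aligner is supported through
a command-template adapter but never exercised by the tests.

## Numerical and engineering choices

* Internal coordinates are 0-based half-open everywhere; SAM/VCF text
  stays 1-based, converted exactly once at the I/O boundary.
* All counting is integer; the only floats are log-likelihoods and
  empirical qualities, computed from identical integers in every run
  configuration, so byte-identity of outputs is achievable and asserted.
* Scores in VCF output are rounded (TLOD/NLOD to 2 decimals, allele
  fraction to 4) before serialisation.
* The RNG is numpy's PCG64 seeded from the run seed; reservoir sampling
  uses Python's `random.Random`. No randomness survives into per-region
  processing, which is fully deterministic.
* Degenerate inputs: empty regions sort/mark/call to empty outputs; a
  normal sample without mapped reads aborts Job 2 before any work; zero
  tumor depth at a site means no call; an empty recalibration table
  applies as the identity.
* Stage manifests record SHA-256 of every artifact; a completed stage is
  skipped on rerun and recomputed if any artifact went stale.

## Problem sizes

The default simulation (~60 kb, 60×/30×, ~28k read pairs) is used for the
equivalence, conservation, calibration and recall checks; a 12 kb variant
at 30×/15× backs the 20-way random-split merge oracle and unit-level
pipeline tests. These sizes were chosen so the complete verification —
six full pipeline runs plus all oracles — executes in a few minutes on one
CPU while every stage (spilling sorts, boundary duplication, multi-contig
snapping, process pools) is still exercised.

## Known limitations

* SNVs only; no indel or haplotype-based calling.
* The recalibration estimator is intentionally simpler than shrinkage
  estimators used by production tools; absolute assigned qualities differ
  from theirs even though the merge semantics do not.
* The hard normal-AF veto described above.
* Single-machine process-pool execution only; there is no distributed
  shuffle, and fault tolerance is restart-from-manifest rather than
  lineage recomputation.
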