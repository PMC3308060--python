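# Methods

This document describes the models and numerical choices implemented in
`exocap`. It makes no empirical claims beyond what the test suite and
`scripts/acceptance.py` compute.

## Coordinate and data conventions

All genomic coordinates are 0-based, half-open (`[start, end)`), including
interval sets, simulator truth, and internal call records; BED and bedGraph
files use the same convention natively, while VCF and refFlat I/O convert
at the boundary (VCF positions 1-based, refFlat 0-based half-open).
Sequences are stored as `uint8` ASCII arrays for vectorized comparison.
Base qualities are Phred-scaled error probabilities
(`q = -10·log10(p)`); consensus qualities use the same scale, so consensus
quality 50 corresponds to a genotype error probability of exactly 1e-5.

## Lane-level filtering (steps 1–7)

A lane enters as paired FASTQ plus alignments and passes through seven
steps; every step's inputs and outputs are counted so accounting
identities (pairs in = pairs out + pairs dropped, per reason) hold exactly.

1. **Adapter clipping.** Read-through adapters are detected by aligning the
   two mates of a pair against each other: for each candidate overlap `o`
   the score is `o − 4·mm` (mm = mismatches); a clip is accepted only if
   the bases beyond the inferred insert end match the expected adapter
   flank. Minimum overlap 10, maximum mismatch rate 10%.
2. **Pair mapping quality** is the minimum of the two mates' qualities.
3. **Proper pairs**: forward–reverse orientation on one reference with an
   outer span ≤ 1000 (inclusive). Improper pairs are dropped with a reason.
4. **Duplicate removal** groups pairs by (reference, outer start, outer
   end, orientation) and keeps the pair with the highest summed base
   quality, ties broken by input order. Coordinate identity is the
   standard proxy for PCR duplication; its known failure mode at extreme
   depth is discussed under Limitations.
5. **Probe filtering** keeps pairs with pair mapping quality exactly 60
   (the unique-alignment stratum) and ≥ 20 aligned bases on a probe for
   *each* mate.
6. **Overlap collapsing.** When mates overlap, the overlapping bases of the
   lower-quality mate are trimmed so each fragment contributes at most one
   observation per position. Where the mates agree, the surviving base's
   quality becomes `min(q1 + q2, 60)`; where they disagree, the
   higher-quality base survives at quality `|q1 − q2|`. Reads whose
   alignments contain indels are dropped before collapsing.
7. **On-target accounting**: aligned bases falling in target regions are
   counted, giving the enrichment score (on-probe pairs after dedup over
   proper pairs after dedup) and feeding depth tracks.

## Consensus genotype calling

A naive-Bayes diploid model over the 10 unordered genotypes from {A,C,G,T}.
Each aligned base with error probability `e` contributes, per genotype
hypothesis `{a1, a2}`:

* both alleles match the base: likelihood `1 − e`;
* one allele matches: `(1 − e)/2 + (e/3)/2` (a heterozygote samples either
  allele with probability ½; an error hits a specific wrong base with
  probability `e/3`);
* neither matches: `e/3`.

Computation is in log space with per-column normalization. Priors:
heterozygous reference/non-reference `1e-3`, homozygous non-reference
`5e-4`, each of the three non-reference heterozygotes `het·hom_alt/3`;
the homozygous-reference prior absorbs the remainder. The consensus
quality is `−10·log10(1 − posterior)` capped at 255. Ties are broken
deterministically in preference order: homozygous reference, reference
heterozygotes, homozygous alternates, non-reference heterozygotes (each
lexicographic). Calls at quality ≥ 50 are emitted; gold standards built
from calls require quality ≥ 100.

Why these defaults: the q50 emission threshold targets a 1e-5 per-call
error budget, so on a ~60 kb target a handful of errors per million calls
is expected; priors reflect a ~1e-3 heterozygosity typical of the
simulated variant density (SNV rate 1e-3, 60% heterozygous).

## Capture metrics

Depth counts post-collapse base observations, so a read pair contributes at
most one observation per position. Breadth at threshold `t` is the
fraction of target bases with depth ≥ t (defaults: 1×, 20×). The
uniformity histogram bins every target base by depth (1-depth bins,
open-ended final bin at ≥ 300); bins partition the target, so counts sum
to the target size and `mean depth × target size` equals aligned on-target
bases. Depth tracks are additive across lanes. Insert sizes are outer
spans of proper pairs, summarized by mode and median. The raw-data model
converts a desired mean depth to whole-genome shotgun yield as
`depth × genome size` (3 Gb default), the no-waste lower bound.

## Concordance scoring

Two gold flavors: *variant-focused* (planted in-target variants only;
positions without a confident call count as misses) and *comprehensive*
(every target base). Reported counts include genotyped fraction,
disagreement among called positions, variant sensitivity (a variant call
at a true variant position, any non-reference genotype), variant FDR
(confident variant calls at positions whose true genotype is
homozygous-reference, over all variant calls at gold positions — scored
against the comprehensive standard because a variant-only standard has no
negative positions), heterozygote sensitivity/FDR/disagreement, and Ts/Tv
(transitions A↔G, C↔T over transversions, each alternate allele counted
once).

## Simulator

Scope: single-sample diploid genomes (i.i.d. bases at configurable GC),
phased SNVs only (no indels or structural variants), exon-like targets
tiled by probes with an optional untargeted fraction, paired-end reads of
fixed length with:

* insert models — gel-excised: truncated normal (mean 200, SD 25, range
  [150, 250]); bead-selected: lognormal (median 190, log-SD 0.4, floor
  100);
* a two-state base-quality model (15% low-quality bases at error
  `min(0.1, 4e)`, high state derived so the mixture matches the configured
  mean error rate);
* PCR duplicates as coordinate re-emissions with independently resampled
  errors; duplicate truth flags any repeated coordinate key;
* off-probe fragments placed to overlap no probe; on-probe fragments must
  overlap a probe by ≥ 20 bases with *both* mates, which requires the
  insert to satisfy `L ≤ probe_len + 2(R − 20)` — inserts violating it are
  resampled from the insert model (not clamped, which would pile fragments
  onto one coordinate);
* adapter read-through when the insert is shorter than the read.

Truth alignments are emitted directly (the simulator knows the
coordinates), with mapping quality 60 except for an optional ambiguous
fraction at 0. Every read is exactly reconstructible from (haplotype,
coordinates, recorded errors, adapter), which the tests verify.

Default study conditions: 2 Mb genome, 400 targets of mean length 150 bp
(SD 35), SNV rate 1e-3, 60% heterozygous, transition probability 2/3, gel
inserts, read length 76, error rate 0.5%, duplicate rate 10%, off-probe
fraction 12%, 80,000 pairs per lane. The pair count was fixed a priori
from a callability power analysis: a heterozygote needs roughly 8 covering
reads to clear the q50 threshold, and the low-depth tail of the coverage
distribution sits near 10% of the mean, so ~100× mean collapsed depth
keeps the expected number of uncallable variant positions well below one
per study.

## Numerical choices

* Genotype likelihoods accumulate in natural-log space; posteriors are
  normalized per column, and qualities capped at 255. Above ~q100 the
  implied error probability (< 1e-10) is at the resolution limit of double
  arithmetic, so alternative orderings of the same computation can differ
  in the last bits; the test oracles therefore compare qualities exactly
  only below q100 and require agreement-in-confidence above it.
* Deterministic seeding throughout: every stochastic component draws from
  `numpy.random.default_rng` on a seed derived from the run seed by a
  fixed affine-mod-2³¹ scheme, so runs are reproducible bit-for-bit and
  replicate seeds never collide in practice.
* Depth arrays are integer; breadth/uniformity are computed by exact
  counting, not floating accumulation.

## Limitations

* The simulator's genome is i.i.d. sequence: no repeats, no mappability
  structure, no GC-coverage bias; mapping quality is binary by
  construction. Capture efficiency is uniform across probes except for
  the geometric short-probe effect.
* Variants are SNVs only; the caller drops indel-containing reads rather
  than modeling indels.
* Coordinate-based duplicate removal cannot distinguish PCR copies from
  independent fragments that collide on coordinates. At very high local
  depth (~100× over short probes) natural collisions become material,
  so the enrichment score systematically underestimates the true on-probe
  fraction in that regime; the parameter-recovery tests therefore check
  estimator calibration at moderate depth, where the independence
  assumption behind the binomial tolerance holds.
* The raw-data model is the no-waste lower bound; real experiments need
  more raw data than it predicts.
* Gold standards derive from simulator truth; concordance numbers measure
  internal consistency of the pipeline under the simulator's assumptions,
  not performance on real libraries.
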