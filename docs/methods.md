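# Methods

## Analysis model

The pipeline treats a footprint sequencing library as a mixture of
RNase-protected fragments whose lengths reflect binding geometry. After
adapter trimming, inserts are placed exactly on the genome (all loci, both
strands) and stratified by length: **short** 8–12 nt, **long** ≥ 17 nt,
13–16 nt **intermediate** (kept in length histograms, excluded from
short/long counting). The boundaries are inclusive exactly as stated: 8 and
12 are short, 17 is long; inserts shorter than 8 nt are removed upstream.

Counting is strand-specific against a flat feature annotation. Antisense
transcripts are explicit records on the physical strand opposite their sense
partner, so an opposite-strand placement surfaces as an antisense-class hit
rather than silently missing.

### Prioritized assignment

Per-feature RPKM (count × 10⁹ / (feature length × total mapped reads)) is
computed from the long-read population, with the read total taken
stratum-specifically (long-read RPKM over the long-read total; this choice is
recorded in output headers). Features are sorted by descending RPKM, ties
broken lexicographically by feature id, and every antisense feature is
demoted below every non-antisense feature. An ambiguous read is assigned to
the best-ranked feature among those overlapping **any** of its placements
("pooled" scope). The alternative of ranking only the features at one
randomly resolved placement is available (`scope="placement"`); it cannot
move a read between loci and is strictly weaker at rescuing multi-mappers,
which is why pooled is the default — the point of prioritization is that a
read which *could* have come from a heavily bound transcript probably did.

Default-mode counting resolves each read to one uniformly random placement
(reproducibly: a per-read generator keyed on the global seed and a CRC32 of
the read id, so resolution is order-independent), then picks the
lexicographically first overlapping feature — default mode has no RPKM
ranking to appeal to, and the arbitrary-but-fixed rule keeps it
deterministic given the seed.

The long-read RPKM used for the priority list is itself computed from
randomly resolved long reads with the run's global seed; long reads are
nearly always unique-mapping, so this choice is immaterial in practice but
keeps the definition exact.

## Preprocessing rules

- **Adapter**: 3'-anchored matching of the adapter prefix, ≥ 4 nt overlap,
  ≤ 1 substitution, no indels; the leftmost qualifying match and everything
  3' of it is removed. Reads with no qualifying match are discarded —
  absence of the adapter indicates an artefact, not a long insert.
- **Length**: trimmed inserts < 8 nt are discarded.
- **Complexity**: a read is discarded when its longest contiguous
  homopolymer run exceeds 75% of its length (strict inequality: a 12-base
  run in a 16 nt read is exactly 75% and passes). "Stretch" is read as
  contiguous run; an alternative total-composition reading is available via
  `ComplexityPolicy(mode="composition")` but is not the default.
- **Quality**: simulated qualities are a constant placeholder, so quality
  filtering is a pass-through; the hook exists for real data.

## The simulator and what it does (not) emulate

`synthetic_data` generates, deterministically per seed:

- a genome of 2 × 50 kb by default (desk-scale stand-in for a megabase
  genome), uniform random bases;
- a feature catalogue: 1 pre-rRNA-like unit (6–7 kb), 30 mRNAs (0.8–2 kb),
  15 CUTs, 15 SUT/XUTs, 10 sn/snoRNAs, 10 tRNAs, placed without overlap,
  random strands; 30% of sense features get a coordinate-identical
  antisense twin on the opposite strand;
- exact repeat blocks (25–60 nt, verbatim copies between features or into
  intergenic space, never overwriting a previously planted copy) until 10%
  of the genome is covered by duplicated sequence — this is what makes
  short-read multi-mapping real rather than accidental;
- footprint lengths from a discretized truncated-normal mixture, modes
  10 (w=0.35, sd 1), 20 (w=0.45, sd 4.5), 39 and 44 nt (w=0.10 each,
  sd 1.5), truncated to [8, 60] — the elevated short peak, broad ~20 nt
  maximum, and minor long peaks of the phenomenon under study;
- class abundances: pre-rRNA 0.55, mRNA 0.18, CUT 0.06, SUT/XUT 0.06,
  sn/snoRNA 0.05, tRNA 0.04, antisense 0.02, intergenic 0.04. The true in
  vivo profile is not knowable from published figures alone; these defaults
  reproduce the dominant-rRNA regime and are ordinary user parameters;
- a 3' adapter (miRCat-style, `TGGAATTCTCGGGTGCCAAGG`) appended with
  probability 0.9, optionally with per-base substitution errors; FASTQ
  qualities constant `'I'`.

Not emulated: sequencing errors inside the insert, PCR duplicates, 5'
barcodes/UMIs, splicing, hierarchical gene models, and divergent (inexact)
repeats. Consequently, passing tests demonstrate the counting logic and the
rescue effect under honest multi-mapping; they do not demonstrate robustness
to base-call noise or to annotation ambiguity beyond flat features.

## Aligner

Exact matching only, seed (k = 8) and verify, reporting **all** placements;
forward hits on '+', reverse-complement hits on '-'. Exactness keeps the
aligner oracle-equivalent (the test suite checks it against a naive
full-genome scan), which matters because the whole analysis turns on knowing
the complete placement set. Real-data users with mismatch-tolerant
alignments can enter the pipeline through the BED6-like interchange table
instead. Reads with > 1,000 placements are flagged hyper-repetitive and
dropped from counting with a logged warning.

## Numerical and convention choices

- Coordinates 0-based half-open everywhere internally; GFF3 output is
  1-based inclusive.
- Overlap threshold: any intersection ≥ 1 nt counts.
- Class summaries use the sample (n−1) standard deviation across
  replicates; a single replicate reports sd 0 and `n_replicates = 1`.
- Pileup coverage is hits per million mapped reads of the profiled stratum
  (per-stratum denominator, recorded in output headers), using the
  placement the counting step assigned — profiles are consistent with
  count tables by construction. When a prioritized read has several
  placements inside its winning feature, the lexicographically smallest
  start is used.
- Histograms and class fractions are normalized to sum to one.

## Problem sizes

The shipped study condition is a 100 kb genome with 50,000 reads — large
enough that short-read multi-mapping is pervasive (an 8-mer is expected
~3 times in 200 kb of strand-specific sequence) and binomial/chi-square
checks have power, while the whole pipeline runs in seconds. Oracle
equivalence is verified over 20 independently seeded genomes of 10–20 kb.

## Known limitations

- Priority quality is bounded by long-read coverage: features absent from
  the long-read population rank at the bottom regardless of their true
  short-read occupancy, so a transcript targeted *only* via short footprints
  would be systematically under-assigned — a limitation inherent to the
  method, visible here because truth is known.
- Prioritized counting is winner-takes-all; reads genuinely produced by a
  low-priority feature whose sequence also occurs in a high-priority one are
  always assigned to the latter (no fractional/EM allocation).
- The strict-priority rule makes the short-read class distribution partially
  a function of the long-read distribution; interpretation of class shifts
  between strata should account for this coupling.
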