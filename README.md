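# cracpipe

Length-stratified analysis of RNase-protected protein–RNA crosslinking
footprints, with RPKM-prioritized rescue of ambiguously mapping short reads.

## The problem

In CRAC/CLIP-style experiments, an RNA-binding complex is crosslinked to its
substrates in vivo, purified, and partially digested with RNase so that only
the RNA segment protected by the complex survives into the sequencing
library. The length of each cDNA read is therefore a structural readout: for
the RNA exosome, ~30 nt footprints indicate threading through the central
channel while ~10 nt footprints indicate direct access to the Rrp44
exonuclease site. Mapped reads are split into two populations — **short**
(8–12 nt) and **long** (≥ 17 nt), with 13–16 nt reads held out as
intermediate — and analyzed separately.

The catch is that a short read cannot be mapped confidently: there are only
4¹² ≈ 17 × 10⁶ distinct 12-mers, about the size of a yeast-scale
transcriptome, so any 8–12 nt sequence is expected to occur at more than one
genomic site. Assigning multi-mapping reads to a random placement floods
unannotated and antisense regions with spurious signal.

## The method

The rescue implemented here uses the long reads, which map reliably, to
decide where the ambiguous short reads most plausibly came from:

1. Count long reads per annotated feature and compute
   **RPKM = count × 10⁹ / (length_nt × total mapped reads)**.
2. Sort features by RPKM into a priority list, demoting every **antisense**
   feature below all others (their apparent signal is presumed mis-mapping).
3. For each read, pool the features overlapping *any* of its exact
   placements (strand-specific, ≥ 1 nt overlap) and count it toward the
   pooled feature with the best priority rank. Reads overlapping nothing go
   to an `other` sink.

The baseline (`count_default`) instead resolves each read to one uniformly
random placement, mirroring the `-r Random` behavior of conventional
aligners.

Because real data at this scale are not shippable, the package includes a
first-class simulator: a seed-deterministic toy genome with an RNA-class
catalogue (pre-rRNA-like, mRNA, CUT, SUT/XUT, sn/snoRNA, tRNA, antisense
twins), exact duplicated sequence blocks so short reads genuinely multi-map,
a footprint-length mixture with modes at 10/20/39/44 nt, 3' adapters — and a
per-read truth table, so mis-assignment is measured, not assumed.

## Worked example

```python
from cracpipe import align as al
from cracpipe.pipeline import (run_default_simulation,
                               misassignment_rate, other_antisense_fraction)

res = run_default_simulation(seed=42)          # 100 kb genome, 50,000 reads
classes = res.feature_index.classes()
print("retained:", res.tally["retained"], "of", res.tally["input"])
print("short:", len(res.strata["short"]), "long:", len(res.strata["long"]))
for mode in ("default", "prioritized"):
    ct = res.counts[(mode, al.SHORT)]
    print(f"{mode:12s} misassigned {100*misassignment_rate(ct, res.truth):.1f}%  "
          f"other+antisense {100*other_antisense_fraction(ct, classes):.1f}%")
```

prints

```
retained: 45190 of 50000
short: 16418 long: 25066
default      misassigned 18.1%  other+antisense 16.9%
prioritized  misassigned 3.7%  other+antisense 5.1%
```

Reading: ~90% of reads carry the 3' adapter and survive filtering; of the
16,418 short (8–12 nt) mapped reads, random placement assigns 18.1% to the
wrong feature and puts 16.9% into unannotated/antisense space, while
prioritized counting cuts mis-assignment to 3.7% and deflates the spurious
"other"+antisense signal to 5.1% — close to the 6% of reads the simulator
truly drew from antisense/intergenic sources.

The same pipeline is available from the shell:

```bash
cracpipe simulate --seed 42 --outdir sim
cracpipe preprocess sim/reads.fastq inserts.fa --adapter TGGAATTCTCGGGTGCCAAGG
cracpipe align inserts.fa sim/genome.fa aln.bed
cracpipe count aln.bed sim/annotation.gff3 --mode prioritized --stratum short \
    --out counts.tsv --priority-out priority.tsv
cracpipe summarize --replicates counts.tsv --gff sim/annotation.gff3 --out summary.tsv
```

`cracpipe count` also accepts externally produced alignments in the BED6-like
interchange format (chrom, start, end, read_id, n_placements, strand).

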