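"""Synthetic genomes and RNase-protection footprint reads with ground truth.

This module fabricates the statistical structure the analysis pipeline
assumes: a small genome annotated with RNA classes of very unequal abundance,
deliberate exact sequence duplications so that short footprints genuinely map
to several loci, a footprint-length mixture with modes near 10 nt, ~20 nt and
39/44 nt, and a 3' sequencing adapter that downstream trimming must find.

Every simulated read carries a truth record (source feature, locus, protected
length), which is what makes mis-assignment of ambiguous short reads a
measurable quantity rather than a plausibility argument.

All randomness flows through `numpy.random.default_rng(seed)`; identical
specs and seeds give byte-identical FASTA/GFF/FASTQ output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .features import ANTISENSE_CLASS, Feature

logger = logging.getLogger(__name__)

DNA = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: miRCat-style small-RNA 3' linker used as the default simulated adapter.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

INTERGENIC_LABEL = "intergenic"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GenomePackingError(ValueError):
    """Requested features/repeats do not fit on the chromosomes."""


@dataclass(frozen=True)
class GenomeSpec:
    """Shape of the toy genome (a desk-scale stand-in for a ~12 Mb genome)."""

    n_chromosomes: int = 2
    chromosome_length: int = 50_000
    repeat_fraction: float = 0.10
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")
        if self.chromosome_length < 1000:
            raise ValueError("chromosome_length must be >= 1000")
        if not 0.0 <= self.repeat_fraction <= 0.5:
            raise ValueError("repeat_fraction must lie in [0, 0.5]")


@dataclass(frozen=True)
class ClassSpec:
    n_features: int
    min_length: int
    max_length: int


#: Feature classes loosely mirroring a budding-yeast annotation: one long
#: rRNA-precursor-like unit, many mRNAs, and the short non-coding classes.
DEFAULT_CLASSES: dict[str, ClassSpec] = {
    "pre_rRNA": ClassSpec(1, 6000, 7000),
    "mRNA": ClassSpec(30, 800, 2000),
    "CUT": ClassSpec(15, 200, 600),
    "SUT_XUT": ClassSpec(15, 200, 800),
    "sn_snoRNA": ClassSpec(10, 80, 300),
    "tRNA": ClassSpec(10, 70, 120),
}

#: Relative read-sampling weight per class.  Skewed so that the rRNA
#: precursor dominates, with small antisense and intergenic contributions —
#: the abundance regime in which RPKM prioritization has something to rescue.
DEFAULT_ABUNDANCE: dict[str, float] = {
    "pre_rRNA": 0.55,
    "mRNA": 0.18,
    "CUT": 0.06,
    "SUT_XUT": 0.06,
    "sn_snoRNA": 0.05,
    "tRNA": 0.04,
    ANTISENSE_CLASS: 0.02,
    INTERGENIC_LABEL: 0.04,
}


@dataclass(frozen=True)
class FeatureCatalogSpec:
    classes: dict[str, ClassSpec] = field(default_factory=lambda: dict(DEFAULT_CLASSES))
    antisense_fraction: float = 0.3
    abundance_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ABUNDANCE)
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.antisense_fraction <= 1.0:
            raise ValueError("antisense_fraction must lie in [0, 1]")
        w = list(self.abundance_weights.values())
        if any(x < 0 for x in w) or sum(w) <= 0:
            raise ValueError("abundance_weights must be >= 0 and not all zero")


@dataclass(frozen=True)
class LengthMixture:
    """Discretized truncated-normal mixture of protected footprint lengths.

    Components are (mode_nt, spread_nt, weight).  The default places a sharp
    peak at 10 nt (direct-access-length footprints), a broad bump around
    20 nt, and two minor peaks at 39 and 44 nt (channel-plus-helicase
    protection), truncated to [8, 60] nt.
    """

    components: tuple[tuple[float, float, float], ...] = (
        (10.0, 1.0, 0.35),
        (20.0, 4.5, 0.45),
        (39.0, 1.5, 0.10),
        (44.0, 1.5, 0.10),
    )
    min_nt: int = 8
    max_nt: int = 60

    def __post_init__(self) -> None:
        if self.min_nt < 1:
            raise ValueError("min_nt must be >= 1")
        if self.max_nt < self.min_nt:
            raise ValueError("max_nt must be >= min_nt")
        weights = [w for _, _, w in self.components]
        if not self.components or any(w < 0 for w in weights):
            raise ValueError("component weights must be >= 0")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")

    def sample(self, rng: np.random.Generator, n: int, max_length: int | None = None) -> np.ndarray:
        """Draw `n` integer lengths; rejection-sample into the truncation window."""
        hi = self.max_nt if max_length is None else min(self.max_nt, max_length)
        if hi < self.min_nt:
            raise ValueError("truncation window is empty")
        modes = np.array([c[0] for c in self.components])
        spreads = np.array([c[1] for c in self.components])
        weights = np.array([c[2] for c in self.components])
        out = np.empty(n, dtype=np.int64)
        need = np.arange(n)
        while need.size:
            comp = rng.choice(len(self.components), size=need.size, p=weights)
            draw = np.rint(rng.normal(modes[comp], spreads[comp])).astype(np.int64)
            ok = (draw >= self.min_nt) & (draw <= hi)
            out[need[ok]] = draw[ok]
            need = need[~ok]
        return out


@dataclass(frozen=True)
class RepeatBlock:
    """An exact duplicated substring and the loci carrying it."""

    block_id: str
    sequence: str
    loci: tuple[tuple[str, int], ...]  # (chrom, 0-based start) per copy

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Genome:
    sequences: dict[str, str]
    features: list[Feature]
    repeats: list[RepeatBlock]

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def sense_features(self) -> list[Feature]:
        return [f for f in self.features if not f.is_antisense]

    def intergenic_intervals(self, chrom: str) -> list[tuple[int, int]]:
        """Maximal intervals of `chrom` not covered by any sense feature."""
        return _gaps(self.features, chrom, len(self.sequences[chrom]))


def _gaps(features: Iterable[Feature], chrom: str, length: int) -> list[tuple[int, int]]:
    bounds = sorted(
        (f.start, f.end)
        for f in features
        if f.chrom == chrom and f.feature_class != ANTISENSE_CLASS
    )
    gaps, cursor = [], 0
    for s, e in bounds:
        if s > cursor:
            gaps.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < length:
        gaps.append((cursor, length))
    return gaps


def _chrom_name(i: int) -> str:
    return f"chr{i + 1}"


def _place_features(
    rng: np.random.Generator, spec: GenomeSpec, catalog: FeatureCatalogSpec
) -> list[Feature]:
    # draw lengths, scatter over chromosomes, then lay out with random gaps
    jobs: list[tuple[str, int]] = []
    for cls, cspec in catalog.classes.items():
        for _ in range(cspec.n_features):
            jobs.append((cls, int(rng.integers(cspec.min_length, cspec.max_length + 1))))
    chrom_of = rng.integers(0, spec.n_chromosomes, size=len(jobs))

    counters: dict[str, int] = {}
    features: list[Feature] = []
    for ci in range(spec.n_chromosomes):
        mine = [jobs[j] for j in range(len(jobs)) if chrom_of[j] == ci]
        rng.shuffle(mine)
        occupied = sum(length for _, length in mine)
        free = spec.chromosome_length - occupied
        if free < len(mine) + 1:
            raise GenomePackingError(
                f"{_chrom_name(ci)}: {len(mine)} features need {occupied} nt "
                f"but chromosome_length is {spec.chromosome_length}"
            )
        gaps = rng.multinomial(free, np.full(len(mine) + 1, 1.0 / (len(mine) + 1)))
        cursor = 0
        for k, (cls, length) in enumerate(mine):
            cursor += int(gaps[k])
            n = counters.get(cls, 0)
            counters[cls] = n + 1
            strand = "+" if rng.random() < 0.5 else "-"
            features.append(
                Feature(
                    feature_id=f"{cls}_{n:04d}",
                    chrom=_chrom_name(ci),
                    start=cursor,
                    end=cursor + length,
                    strand=strand,
                    feature_class=cls,
                )
            )
            cursor += length
    return features


def _add_antisense_twins(
    rng: np.random.Generator, features: list[Feature], antisense_fraction: float
) -> list[Feature]:
    twins = []
    for f in features:
        if rng.random() < antisense_fraction:
            twins.append(
                Feature(
                    feature_id=f"AS_{f.feature_id}",
                    chrom=f.chrom,
                    start=f.start,
                    end=f.end,
                    strand="-" if f.strand == "+" else "+",
                    feature_class=ANTISENSE_CLASS,
                )
            )
    return twins


def _plant_repeats(
    rng: np.random.Generator,
    seqs: dict[str, np.ndarray],
    features: list[Feature],
    gaps: dict[str, list[tuple[int, int]]],
    target_bases: int,
    block_range: tuple[int, int] = (25, 60),
) -> list[RepeatBlock]:
    """Copy exact blocks between features (or feature -> intergenic space).

    Each block is a verbatim plus-strand copy, so a footprint sampled inside
    the source window matches the genome at (at least) two loci.
    """
    sense = [f for f in features if not f.is_antisense]
    blocks: list[RepeatBlock] = []
    claimed: list[tuple[str, int, int]] = []  # loci that later writes must not touch
    covered = 0
    attempts = 0

    def clashes(chrom: str, start: int, end: int) -> bool:
        return any(c == chrom and start < e and s < end for c, s, e in claimed)

    while covered < target_bases:
        attempts += 1
        if attempts > 10_000:
            raise GenomePackingError(
                f"could not place repeat blocks covering {target_bases} nt: "
                "features + repeats exceed chromosome capacity"
            )
        blen = int(rng.integers(block_range[0], block_range[1] + 1))
        candidates = [f for f in sense if f.length_nt >= blen]
        if len(candidates) < 2:
            raise GenomePackingError("fewer than two features can hold a repeat block")
        src = candidates[rng.integers(len(candidates))]
        s0 = src.start + int(rng.integers(0, src.length_nt - blen + 1))
        block_seq = seqs[src.chrom][s0 : s0 + blen].tobytes().decode()

        if rng.random() < 0.7:
            dests = [f for f in candidates if f.feature_id != src.feature_id]
            dst = dests[rng.integers(len(dests))]
            d0 = dst.start + int(rng.integers(0, dst.length_nt - blen + 1))
            dchrom = dst.chrom
        else:
            wide = [(c, g) for c, gl in gaps.items() for g in gl if g[1] - g[0] >= blen]
            if not wide:
                continue
            dchrom, (g0, g1) = wide[rng.integers(len(wide))]
            d0 = g0 + int(rng.integers(0, (g1 - g0) - blen + 1))
        if dchrom == src.chrom and not (d0 + blen <= s0 or s0 + blen <= d0):
            continue  # would overlap its own source
        # a write over any earlier block locus would destroy that exact copy
        if clashes(dchrom, d0, d0 + blen):
            continue
        seqs[dchrom][d0 : d0 + blen] = np.frombuffer(block_seq.encode(), dtype="S1")
        claimed.append((src.chrom, s0, s0 + blen))
        claimed.append((dchrom, d0, d0 + blen))
        blocks.append(
            RepeatBlock(
                block_id=f"rep_{len(blocks):04d}",
                sequence=block_seq,
                loci=((src.chrom, s0), (dchrom, d0)),
            )
        )
        covered += 2 * blen
    return blocks


def generate_genome(
    spec: GenomeSpec, catalog: FeatureCatalogSpec | None = None
) -> Genome:
    """Random genome + annotation + exact repeat blocks, fully seed-determined."""
    catalog = catalog or FeatureCatalogSpec()
    rng = np.random.default_rng(spec.seed)
    seqs: dict[str, np.ndarray] = {}
    for i in range(spec.n_chromosomes):
        bases = rng.integers(0, 4, size=spec.chromosome_length)
        seqs[_chrom_name(i)] = np.frombuffer(
            "".join(DNA[b] for b in bases).encode(), dtype="S1"
        ).copy()

    sense = _place_features(rng, spec, catalog)
    twins = _add_antisense_twins(rng, sense, catalog.antisense_fraction)
    features = sorted(sense + twins, key=lambda f: (f.chrom, f.start, f.strand, f.feature_id))

    gaps = {c: _gaps(features, c, len(a)) for c, a in seqs.items()}

    repeats: list[RepeatBlock] = []
    if spec.repeat_fraction > 0:
        target = int(spec.repeat_fraction * spec.n_chromosomes * spec.chromosome_length)
        repeats = _plant_repeats(rng, seqs, features, gaps, target)

    return Genome(
        sequences={c: a.tobytes().decode() for c, a in seqs.items()},
        features=features,
        repeats=repeats,
    )


TRUTH_COLUMNS = ["read_id", "feature_id", "chrom", "start", "strand", "length"]


def simulate_reads(
    genome: Genome,
    mixture: LengthMixture | None = None,
    abundance_weights: dict[str, float] | None = None,
    n_reads: int = 50_000,
    seed: int = 42,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Sample protected footprints; return (read_id, insert) pairs + truth table.

    Source features are drawn with probability proportional to the abundance
    weight of their class (split uniformly within the class); the insert is
    the genomic substring, reverse-complemented for minus-strand sources.
    Lengths exceeding the chosen feature are resampled and logged.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    mixture = mixture or LengthMixture()
    weights = dict(abundance_weights or DEFAULT_ABUNDANCE)
    rng = np.random.default_rng(seed)

    by_class: dict[str, list[Feature]] = {}
    for f in genome.features:
        by_class.setdefault(f.feature_class, []).append(f)
    gaps = {
        c: [g for g in genome.intergenic_intervals(c) if g[1] - g[0] >= mixture.min_nt]
        for c in genome.sequences
    }
    gap_list = [(c, g) for c, gl in gaps.items() for g in gl]

    labels, probs = [], []
    for cls, w in sorted(weights.items()):
        if w <= 0:
            continue
        if cls == INTERGENIC_LABEL:
            if gap_list:
                labels.append(cls)
                probs.append(w)
            continue
        if by_class.get(cls):
            labels.append(cls)
            probs.append(w)
        else:
            logger.warning("abundance class %s has no features; dropped", cls)
    if not labels:
        raise ValueError("no sampleable source class has positive weight")
    probs = np.asarray(probs, dtype=float)
    probs /= probs.sum()

    gap_lens = np.array([g[1] - g[0] for _, g in gap_list], dtype=float)
    gap_p = gap_lens / gap_lens.sum() if gap_list else None

    class_idx = rng.choice(len(labels), size=n_reads, p=probs)
    lengths = mixture.sample(rng, n_reads)

    reads: list[tuple[str, str]] = []
    truth_rows = []
    n_resampled = 0
    for i in range(n_reads):
        cls = labels[class_idx[i]]
        length = int(lengths[i])
        if cls == INTERGENIC_LABEL:
            gi = int(rng.choice(len(gap_list), p=gap_p))
            chrom, (g0, g1) = gap_list[gi]
            if g1 - g0 < length:
                length = int(mixture.sample(rng, 1, max_length=g1 - g0)[0])
                n_resampled += 1
            start = g0 + int(rng.integers(0, (g1 - g0) - length + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            fid = INTERGENIC_LABEL
        else:
            pool = by_class[cls]
            f = pool[int(rng.integers(len(pool)))]
            if f.length_nt < length:
                length = int(mixture.sample(rng, 1, max_length=f.length_nt)[0])
                n_resampled += 1
            start = f.start + int(rng.integers(0, f.length_nt - length + 1))
            chrom, strand, fid = f.chrom, f.strand, f.feature_id
        insert = genome.sequences[chrom][start : start + length]
        if strand == "-":
            insert = revcomp(insert)
        rid = f"read_{i:06d}"
        reads.append((rid, insert))
        truth_rows.append((rid, fid, chrom, start, strand, length))
    if n_resampled:
        logger.info("resampled footprint length for %d reads (feature too short)", n_resampled)

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return reads, truth


def attach_adapters(
    reads: Sequence[tuple[str, str]],
    adapter_seq: str = DEFAULT_ADAPTER,
    adapter_present_prob: float = 0.9,
    per_base_error_rate: float = 0.0,
    seed: int = 42,
) -> list[SeqRecord]:
    """Append the 3' adapter (with substitution errors) to a fraction of reads.

    Reads lacking the adapter exercise the retention rule that discards them.
    FASTQ qualities are a constant placeholder ('I', Phred 40).
    """
    if len(adapter_seq) < 4:
        raise ValueError("adapter_seq must be >= 4 nt")
    if not 0.0 <= adapter_present_prob <= 1.0:
        raise ValueError("adapter_present_prob must lie in [0, 1]")
    if not 0.0 <= per_base_error_rate <= 1.0:
        raise ValueError("per_base_error_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    records = []
    for rid, insert in reads:
        seq = insert
        if rng.random() < adapter_present_prob:
            adapter = list(adapter_seq)
            for j in range(len(adapter)):
                if per_base_error_rate and rng.random() < per_base_error_rate:
                    alt = [b for b in DNA if b != adapter[j]]
                    adapter[j] = alt[int(rng.integers(3))]
            seq = insert + "".join(adapter)
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        records.append(rec)
    return records


def write_fasta(genome: Genome, path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=chrom, description="")
        for chrom, seq in genome.sequences.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


def write_fastq(records: Iterable[SeqRecord], path) -> None:
    SeqIO.write(records, str(path), "fastq")


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def load_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"read_id": str, "feature_id": str})
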