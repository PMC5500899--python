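"""Exhaustive exact placement of inserts on the genome, and length strata.

The aligner is deliberately a verifiable component: seed with an 8-mer
index, verify full-length, and report *every* exact match on both strands.
Multi-mapping is therefore fully observable, which is the property the
downstream prioritized counting exists to handle.  Mapped reads are
stratified into the two analyzed populations — short (8-12 nt) and long
(>= 17 nt) — with 13-16 nt reads kept as an "intermediate" class that is
excluded from short/long counting.
"""

from __future__ import annotations

import logging
import zlib
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synthetic_data import revcomp

logger = logging.getLogger(__name__)

SHORT, INTERMEDIATE, LONG = "short", "intermediate", "long"

SHORT_MIN, SHORT_MAX = 8, 12
LONG_MIN = 17

Placement = tuple[str, int, str]  # (chrom, 0-based start, strand)

BED_COLUMNS = ["chrom", "start", "end", "read_id", "n_placements", "strand"]


def distinct_kmer_count(k: int, alphabet_size: int = 4) -> int:
    """Number of distinct k-mers over the nucleotide alphabet.

    For k = 12 this is ~17 million — about the size of a yeast-scale
    transcriptome — which is why reads must exceed 12 nt to be expected to
    identify a unique site, and why the 8-12 nt stratum needs a rescue rule.
    """
    if k < 1 or alphabet_size < 1:
        raise ValueError("k and alphabet_size must be >= 1")
    return alphabet_size**k


def stratum_of(insert_length: int) -> str:
    """Short: 8-12 nt; long: >= 17 nt; 13-16 nt: intermediate."""
    if insert_length < SHORT_MIN:
        raise ValueError(f"insert length {insert_length} below the retention minimum")
    if insert_length <= SHORT_MAX:
        return SHORT
    if insert_length >= LONG_MIN:
        return LONG
    return INTERMEDIATE


@dataclass(frozen=True)
class AlignmentRecord:
    read_id: str
    insert_length: int
    placements: tuple[Placement, ...]  # sorted, non-empty

    @property
    def stratum(self) -> str:
        return stratum_of(self.insert_length)


class KmerIndex:
    """Exact k-mer -> [(chrom, offset, strand)] lookup over both strands.

    A '-' entry at offset p means the minus-strand read whose 5' k-mer is the
    key starts its genomic interval at p + k - L for insert length L.
    """

    def __init__(self, sequences: dict[str, str], k: int = 8):
        if k < 4:
            raise ValueError("k must be >= 4")
        self.k = k
        self.sequences = sequences
        index: dict[str, list[Placement]] = defaultdict(list)
        valid = set("ACGT")
        for chrom, seq in sequences.items():
            if len(seq) < k:
                logger.warning("chromosome %s shorter than k=%d; skipped", chrom, k)
                continue
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                if set(kmer) - valid:
                    continue
                index[kmer].append((chrom, pos, "+"))
                index[revcomp(kmer)].append((chrom, pos, "-"))
        self._index = dict(index)

    def lookup(self, kmer: str) -> list[Placement]:
        return self._index.get(kmer, [])


def build_index(sequences: dict[str, str], k: int = 8) -> KmerIndex:
    return KmerIndex(sequences, k=k)


def align_read(insert: str, index: KmerIndex) -> list[Placement]:
    """All exact placements of `insert`: forward on '+', reverse-complement on '-'."""
    L = len(insert)
    if L < index.k:
        raise ValueError(f"insert shorter than seed length k={index.k}")
    rc = revcomp(insert)
    hits: set[Placement] = set()
    for chrom, pos, strand in index.lookup(insert[:index.k]):
        if strand == "+":
            start = pos
            if index.sequences[chrom][start : start + L] == insert:
                hits.add((chrom, start, "+"))
        else:
            start = pos + index.k - L
            if start >= 0 and index.sequences[chrom][start : start + L] == rc:
                hits.add((chrom, start, "-"))
    return sorted(hits)


def align_reads(
    inserts: Iterable[tuple[str, str]],
    index: KmerIndex,
    max_placements: int = 1000,
) -> tuple[list[AlignmentRecord], dict[str, int]]:
    """Place every insert; unmapped and hyper-repetitive reads are dropped.

    Reads with more than `max_placements` exact loci are flagged
    hyper-repetitive (degenerate, homopolymer-adjacent inserts) and excluded
    from counting.
    """
    records: list[AlignmentRecord] = []
    stats = {"mapped": 0, "unmapped": 0, "hyper_repetitive": 0}
    for rid, insert in inserts:
        placements = align_read(insert, index)
        if not placements:
            stats["unmapped"] += 1
            continue
        if len(placements) > max_placements:
            stats["hyper_repetitive"] += 1
            logger.warning("read %s has %d placements; dropped", rid, len(placements))
            continue
        stats["mapped"] += 1
        records.append(AlignmentRecord(rid, len(insert), tuple(placements)))
    return records, stats


def stratify(records: Iterable[AlignmentRecord]) -> dict[str, list[AlignmentRecord]]:
    """Total, disjoint partition of mapped reads by insert length."""
    out: dict[str, list[AlignmentRecord]] = {SHORT: [], INTERMEDIATE: [], LONG: []}
    for rec in records:
        out[rec.stratum].append(rec)
    return out


def resolve_random(record: AlignmentRecord, seed: int) -> Placement:
    """Uniform random single placement, reproducible per (read_id, seed).

    The per-read generator is keyed on a hash of the read id so resolution
    does not depend on the order reads are processed in.
    """
    if not record.placements:
        raise ValueError(f"read {record.read_id} has no placements")
    if len(record.placements) == 1:
        return record.placements[0]
    rng = np.random.default_rng(
        (seed & 0x7FFFFFFF, zlib.crc32(record.read_id.encode()) & 0x7FFFFFFF)
    )
    return record.placements[int(rng.integers(len(record.placements)))]


def write_alignments(records: Sequence[AlignmentRecord], path) -> None:
    """BED6-like interchange table: one row per placement."""
    rows = []
    for rec in records:
        for chrom, start, strand in rec.placements:
            rows.append(
                (chrom, start, start + rec.insert_length, rec.read_id,
                 len(rec.placements), strand)
            )
    pd.DataFrame(rows, columns=BED_COLUMNS).to_csv(path, sep="\t", index=False, header=False)


def read_alignments(path) -> list[AlignmentRecord]:
    """Load the BED6-like table (also the entry point for external aligners)."""
    df = pd.read_csv(path, sep="\t", header=None, names=BED_COLUMNS,
                     dtype={"chrom": str, "read_id": str})
    records = []
    for rid, grp in df.groupby("read_id", sort=False):
        lengths = (grp["end"] - grp["start"]).unique()
        if len(lengths) != 1:
            raise ValueError(f"read {rid}: inconsistent placement lengths {lengths}")
        placements = tuple(sorted(
            (r.chrom, int(r.start), r.strand) for r in grp.itertuples(index=False)
        ))
        records.append(AlignmentRecord(str(rid), int(lengths[0]), placements))
    return records
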