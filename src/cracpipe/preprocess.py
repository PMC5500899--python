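"""Read retention rules: 3'-adapter trimming, length and complexity filters.

A footprint read is kept only if the 3' sequencing adapter is actually found
(an adapterless read is evidence of an artefact, not of a long insert), the
trimmed insert is at least 8 nt, and the insert is not dominated by a single
homopolymer stretch (which would be unalignable anyway).
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass
from itertools import groupby
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

RETAINED = "retained"
NO_ADAPTER = "no_adapter"
TOO_SHORT = "too_short"
LOW_COMPLEXITY = "low_complexity"


@dataclass(frozen=True)
class TrimPolicy:
    """3'-anchored adapter matching: substitutions only, no indels."""

    adapter_seq: str
    max_mismatches: int = 1
    min_overlap: int = 4
    min_length: int = 8

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if len(self.adapter_seq) < self.min_overlap:
            raise ValueError("adapter shorter than min_overlap")


@dataclass(frozen=True)
class ComplexityPolicy:
    """Reject reads whose content is mostly one nucleotide stretch.

    `mode="run"` measures the longest contiguous homopolymer run (the
    default: a "stretch" is contiguous); `mode="composition"` measures the
    most frequent base overall.  Both readings coincide on pure homopolymers.
    """

    max_homopolymer_fraction: float = 0.75
    mode: str = "run"

    def __post_init__(self) -> None:
        if not 0.0 < self.max_homopolymer_fraction <= 1.0:
            raise ValueError("max_homopolymer_fraction must lie in (0, 1]")
        if self.mode not in ("run", "composition"):
            raise ValueError("mode must be 'run' or 'composition'")


@dataclass(frozen=True)
class TrimResult:
    status: str  # RETAINED / NO_ADAPTER / TOO_SHORT
    insert: str | None


def trim_adapter(sequence: str, policy: TrimPolicy, require_adapter: bool = True) -> TrimResult:
    """Remove the leftmost 3'-anchored adapter match and everything 3' of it.

    A match is >= min_overlap bases of the adapter *prefix*, with at most
    max_mismatches substitutions, positioned so the adapter runs to the read's
    3' end or beyond.  No qualifying match => rejected (unless
    `require_adapter=False`, a re-trim mode that passes the read through).
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    adapter = policy.adapter_seq.upper()
    L, A = len(seq), len(adapter)
    cut = None
    for i in range(max(0, L - A), L - policy.min_overlap + 1):
        window = seq[i:]
        mism = sum(a != b for a, b in zip(window, adapter))
        if mism <= policy.max_mismatches:
            cut = i
            break
    if cut is None:
        if not require_adapter:
            return TrimResult(RETAINED, seq)
        return TrimResult(NO_ADAPTER, None)
    insert = seq[:cut]
    if len(insert) < policy.min_length:
        return TrimResult(TOO_SHORT, None)
    return TrimResult(RETAINED, insert)


def longest_homopolymer_run(sequence: str) -> int:
    return max(len(list(g)) for _, g in groupby(sequence))


def is_low_complexity(sequence: str, policy: ComplexityPolicy | None = None) -> bool:
    """True iff a single-nucleotide stretch exceeds the allowed fraction (strict >)."""
    if not sequence:
        raise ValueError("empty sequence")
    policy = policy or ComplexityPolicy()
    if policy.mode == "run":
        stretch = longest_homopolymer_run(sequence)
    else:
        stretch = max(Counter(sequence).values())
    return stretch / len(sequence) > policy.max_homopolymer_fraction


def _open_maybe_gz(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _iter_fastq(source) -> Iterator[SeqRecord]:
    if hasattr(source, "read"):  # open handle
        yield from SeqIO.parse(source, "fastq")
    elif isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        with _open_maybe_gz(source) as fh:
            yield from SeqIO.parse(fh, "fastq")
    else:  # already an iterable of SeqRecords
        yield from source


def preprocess_fastq(
    source,
    trim_policy: TrimPolicy,
    complexity_policy: ComplexityPolicy | None = None,
) -> tuple[list[tuple[str, str]], Counter]:
    """Apply adapter/length/complexity rules to a FASTQ file or record iterable.

    Returns retained (read_id, insert) pairs and a tally whose rejection
    categories partition the input: retained + rejects == input count.
    """
    complexity_policy = complexity_policy or ComplexityPolicy()
    tally: Counter = Counter({"input": 0, RETAINED: 0, NO_ADAPTER: 0, TOO_SHORT: 0, LOW_COMPLEXITY: 0})
    retained: list[tuple[str, str]] = []
    records = _iter_fastq(source)
    idx = -1
    while True:
        idx += 1
        try:
            rec = next(records, None)
        except ValueError as exc:  # malformed FASTQ
            raise ValueError(f"malformed FASTQ at record index {idx}: {exc}") from exc
        if rec is None:
            break
        tally["input"] += 1
        res = trim_adapter(str(rec.seq), trim_policy)
        if res.status != RETAINED:
            tally[res.status] += 1
            continue
        if is_low_complexity(res.insert, complexity_policy):
            tally[LOW_COMPLEXITY] += 1
            continue
        tally[RETAINED] += 1
        retained.append((rec.id, res.insert))
    return retained, tally


def tally_report(tally: Counter) -> str:
    """TSV rendering of a preprocessing tally (category, count)."""
    rows = ["category\tcount"]
    for key in ("input", RETAINED, NO_ADAPTER, TOO_SHORT, LOW_COMPLEXITY):
        rows.append(f"{key}\t{tally[key]}")
    return "\n".join(rows) + "\n"
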