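"""Strand-specific genomic features and annotation I/O.

A :class:`Feature` is a flat, strand-specific interval carrying an RNA-class
label (mRNA, CUT, tRNA, "antisense", ...).  Antisense transcripts are explicit
records on the strand opposite their sense partner, so downstream priority
rules can demote them like any other feature.

Coordinates are 0-based half-open internally; GFF3 output converts to the
1-based inclusive convention of that format.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from intervaltree import IntervalTree

ANTISENSE_CLASS = "antisense"
OTHER_LABEL = "other"

GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "frame", "attributes",
]


@dataclass(frozen=True, order=True)
class Feature:
    """A strand-specific annotated interval with an RNA-class label."""

    feature_id: str
    chrom: str
    start: int  # 0-based
    end: int    # half-open
    strand: str
    feature_class: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"feature {self.feature_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.feature_id}: invalid strand {self.strand!r}")
        if not self.feature_class:
            raise ValueError(f"feature {self.feature_id}: empty class")

    @property
    def length_nt(self) -> int:
        return self.end - self.start

    @property
    def is_antisense(self) -> bool:
        return self.feature_class == ANTISENSE_CLASS


def class_map(features: Iterable[Feature]) -> dict[str, str]:
    """feature_id -> RNA class, for grouping count tables."""
    return {f.feature_id: f.feature_class for f in features}


def write_gff3(features: Iterable[Feature], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                "\t".join(
                    [
                        f.chrom,
                        "cracpipe",
                        f.feature_class,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        f"ID={f.feature_id};class={f.feature_class}",
                    ]
                )
                + "\n"
            )


_ID_RE = re.compile(r"ID=([^;]+)")
_CLASS_RE = re.compile(r"class=([^;]+)")


def load_gff3(path) -> list[Feature]:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=GFF_COLUMNS, dtype={"seqid": str}
    )
    feats = []
    for row in df.itertuples(index=False):
        m = _ID_RE.search(row.attributes)
        if m is None:
            raise ValueError(f"GFF record without ID attribute: {row!r}")
        cm = _CLASS_RE.search(row.attributes)
        fclass = cm.group(1) if cm else row.type
        feats.append(
            Feature(
                feature_id=m.group(1),
                chrom=row.seqid,
                start=int(row.start) - 1,
                end=int(row.end),
                strand=row.strand,
                feature_class=fclass,
            )
        )
    return feats


class FeatureIndex:
    """Interval-tree lookup of features overlapping a stranded interval."""

    def __init__(self, features: Iterable[Feature]):
        self.features = list(features)
        ids = [f.feature_id for f in self.features]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate feature_id in annotation")
        self.by_id: dict[str, Feature] = {f.feature_id: f for f in self.features}
        self._trees: dict[str, IntervalTree] = {}
        for f in self.features:
            self._trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, f)

    def overlapping(
        self, chrom: str, start: int, end: int, strand: str, min_overlap: int = 1
    ) -> list[Feature]:
        """Features on `strand` intersecting [start, end) by >= min_overlap nt.

        An antisense record lives on the physical strand opposite its sense
        partner, so an opposite-strand placement surfaces the antisense twin.
        """
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = []
        for iv in tree.overlap(start, end):
            f: Feature = iv.data
            if f.strand != strand:
                continue
            if min(end, f.end) - max(start, f.start) >= min_overlap:
                hits.append(f)
        hits.sort(key=lambda f: f.feature_id)
        return hits

    def classes(self) -> Mapping[str, str]:
        return class_map(self.features)
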