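"""Feature counting with RPKM-derived priority rescue of ambiguous reads.

The core idea: an 8-12 nt footprint cannot be placed uniquely in a genome,
but the long (>= 17 nt) footprints from the same library identify which
transcripts the complex actually binds.  Per-feature RPKM computed from long
reads therefore induces a priority order over features — with antisense
records demoted below everything else, since their apparent signal is mostly
mis-mapping — and an ambiguous read is counted toward the highest-priority
feature it could have come from.

Two counting modes are provided for comparison:

* ``count_default`` — one uniformly random placement per read, then a fixed
  arbitrary (lexicographic) choice among overlapping features;
* ``count_prioritized`` — pool overlapping features across *all* placements
  of the read and assign to the best-ranked one (deterministic, no RNG).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .align import AlignmentRecord, Placement, resolve_random
from .features import ANTISENSE_CLASS, OTHER_LABEL, Feature, FeatureIndex

ASSIGNMENT_COLUMNS = ["read_id", "feature_id", "chrom", "start", "end", "strand"]


@dataclass
class RpkmTable:
    """Per-feature read count and RPKM (reads per kb of feature per million mapped)."""

    table: pd.DataFrame  # columns: feature_id, feature_class, length_nt, count, rpkm
    total_mapped_reads: int

    def rpkm(self, feature_id: str) -> float:
        row = self.table.loc[self.table["feature_id"] == feature_id, "rpkm"]
        if row.empty:
            raise KeyError(feature_id)
        return float(row.iloc[0])

    def as_mapping(self) -> dict[str, float]:
        return dict(zip(self.table["feature_id"], self.table["rpkm"]))


def compute_rpkm(
    counts: Mapping[str, int],
    features: Sequence[Feature],
    total_mapped_reads: int,
) -> RpkmTable:
    """RPKM = count x 10^9 / (length_nt x total_mapped_reads), per feature.

    Features absent from `counts` get count 0.  The read total is whatever
    population the counts were taken over (stratum-specific by convention
    here), and is recorded on the result.
    """
    if total_mapped_reads < 1:
        raise ValueError("total_mapped_reads must be >= 1")
    rows = []
    for f in features:
        if f.length_nt <= 0:
            raise ValueError(f"zero-length feature {f.feature_id}")
        c = int(counts.get(f.feature_id, 0))
        rpkm = c * 1e9 / (f.length_nt * total_mapped_reads)
        rows.append((f.feature_id, f.feature_class, f.length_nt, c, rpkm))
    return RpkmTable(
        pd.DataFrame(rows, columns=["feature_id", "feature_class", "length_nt", "count", "rpkm"]),
        total_mapped_reads,
    )


@dataclass(frozen=True)
class PriorityList:
    """Total order over features: rank 0 = first searched for ambiguous reads.

    Non-antisense features always outrank antisense ones; within each block
    the order is descending RPKM, ties broken lexicographically by id.
    """

    order: tuple[str, ...]
    _rank: dict[str, int] = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_rank", {fid: i for i, fid in enumerate(self.order)})
        if len(self._rank) != len(self.order):
            raise ValueError("priority list contains duplicates")

    def rank(self, feature_id: str) -> int:
        try:
            return self._rank[feature_id]
        except KeyError:
            raise KeyError(
                f"feature {feature_id!r} missing from priority list (must be total)"
            ) from None

    def __len__(self) -> int:
        return len(self.order)


def build_priority(rpkm: RpkmTable, features: Sequence[Feature]) -> PriorityList:
    """Sort features by long-read RPKM, demoting every antisense feature."""
    values = rpkm.as_mapping()
    ordered = sorted(
        features,
        key=lambda f: (f.is_antisense, -values.get(f.feature_id, 0.0), f.feature_id),
    )
    return PriorityList(tuple(f.feature_id for f in ordered))


def overlapping_features(
    placement: Placement,
    insert_length: int,
    index: FeatureIndex,
    min_overlap: int = 1,
) -> list[Feature]:
    """Same-strand features intersecting the placed interval by >= min_overlap nt."""
    chrom, start, strand = placement
    return index.overlapping(chrom, start, start + insert_length, strand, min_overlap)


@dataclass
class CountTable:
    """Per-feature read counts for one (mode, stratum), plus the 'other' sink.

    `assignments` records the per-read decision (feature and the placement
    used), so pileup profiles stay consistent with the counts.
    """

    counts: dict[str, int]
    mode: str  # "default" | "prioritized"
    stratum: str
    assignments: pd.DataFrame  # ASSIGNMENT_COLUMNS

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def fraction(self, feature_id: str) -> float:
        return self.counts.get(feature_id, 0) / self.total if self.total else 0.0

    def to_frame(self, rpkm: RpkmTable | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            sorted(self.counts.items()), columns=["feature_id", "count"]
        )
        df["mode"] = self.mode
        df["stratum"] = self.stratum
        if rpkm is not None:
            df = df.merge(
                rpkm.table[["feature_id", "feature_class", "rpkm"]],
                on="feature_id", how="left",
            )
        return df


def _finish(counts, rows, mode, stratum) -> CountTable:
    return CountTable(
        counts=dict(counts),
        mode=mode,
        stratum=stratum,
        assignments=pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS),
    )


def count_default(
    records: Iterable[AlignmentRecord],
    index: FeatureIndex,
    seed: int,
    stratum: str = "",
    min_overlap: int = 1,
) -> CountTable:
    """Random-placement counting: the baseline the priority rescue improves on.

    Each read gets one uniformly random placement; among the features
    overlapping that placement the lexicographically first id is counted
    (default mode has no RPKM ranking to break ties with).  No overlap
    => the 'other' sink.
    """
    counts: dict[str, int] = {}
    rows = []
    for rec in records:
        chrom, start, strand = resolve_random(rec, seed)
        feats = overlapping_features((chrom, start, strand), rec.insert_length, index, min_overlap)
        fid = feats[0].feature_id if feats else OTHER_LABEL  # feats pre-sorted by id
        counts[fid] = counts.get(fid, 0) + 1
        rows.append((rec.read_id, fid, chrom, start, start + rec.insert_length, strand))
    return _finish(counts, rows, "default", stratum)


def count_prioritized(
    records: Iterable[AlignmentRecord],
    index: FeatureIndex,
    priority: PriorityList,
    stratum: str = "",
    min_overlap: int = 1,
    scope: str = "pooled",
    seed: int | None = None,
) -> CountTable:
    """Assign each read to the best-ranked feature it overlaps.

    scope="pooled" (default): candidate features are pooled over *all*
    placements of the read, so a read can be moved to a different locus than
    random resolution would have chosen.  scope="placement": rank only the
    features at one randomly resolved placement (requires `seed`); this
    cannot relocate a read, only re-label one locus.
    """
    if scope not in ("pooled", "placement"):
        raise ValueError("scope must be 'pooled' or 'placement'")
    if scope == "placement" and seed is None:
        raise ValueError("placement scope needs a seed for random resolution")
    counts: dict[str, int] = {}
    rows = []
    for rec in records:
        if scope == "placement":
            placements = [resolve_random(rec, seed)]
        else:
            placements = list(rec.placements)
        best: tuple[int, str] | None = None
        best_placement: Placement | None = None
        for pl in placements:
            for f in overlapping_features(pl, rec.insert_length, index, min_overlap):
                r = priority.rank(f.feature_id)
                cand = (r, f.feature_id)
                # tie on feature: keep lexicographically smallest placement
                if best is None or cand < best or (cand == best and pl < best_placement):
                    best, best_placement = cand, pl
        if best is None:
            fid = OTHER_LABEL
            chrom, start, strand = placements[0]
        else:
            fid = best[1]
            chrom, start, strand = best_placement
        counts[fid] = counts.get(fid, 0) + 1
        rows.append((rec.read_id, fid, chrom, start, start + rec.insert_length, strand))
    return _finish(counts, rows, "prioritized", stratum)


def priority_frame(priority: PriorityList, rpkm: RpkmTable, index: FeatureIndex) -> pd.DataFrame:
    """Priority list as a table (rank, feature_id, class, RPKM) for export."""
    values = rpkm.as_mapping()
    classes = index.classes()
    return pd.DataFrame(
        {
            "rank": range(len(priority)),
            "feature_id": priority.order,
            "feature_class": [classes.get(fid, "?") for fid in priority.order],
            "rpkm": [values.get(fid, 0.0) for fid in priority.order],
        }
    )
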