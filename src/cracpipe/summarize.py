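"""Presentation layer: length histograms, class summaries, pileup profiles.

All normalizations follow the conventions of the counting step: histograms
and class fractions sum to one; pileup coverage is in hits per million
mapped reads of the stratum being profiled.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .assign import CountTable, RpkmTable
from .features import OTHER_LABEL, Feature

logger = logging.getLogger(__name__)


def length_histogram(lengths: Iterable[int]) -> pd.Series:
    """Normalized frequency of integer read lengths (index: length, value: fraction)."""
    lengths = list(lengths)
    if not lengths:
        raise ValueError("no reads: cannot build a length histogram")
    counts = pd.Series(lengths).value_counts().sort_index()
    return counts / counts.sum()


def histogram_local_maxima(hist: pd.Series, min_fraction: float = 0.0) -> list[int]:
    """Lengths whose frequency is a local maximum on a contiguous support grid."""
    full = hist.reindex(range(int(hist.index.min()), int(hist.index.max()) + 1), fill_value=0.0)
    v = full.to_numpy()
    peaks = []
    for i, length in enumerate(full.index):
        left = v[i - 1] if i > 0 else -np.inf
        right = v[i + 1] if i < len(v) - 1 else -np.inf
        if v[i] > left and v[i] >= right and v[i] >= min_fraction:
            peaks.append(int(length))
    return peaks


def pileup(
    assignments: pd.DataFrame,
    feature_id: str,
    features: Mapping[str, Feature] | Sequence[Feature],
    total_mapped_reads: int,
) -> np.ndarray:
    """Per-nucleotide coverage over a feature, in hits per million mapped reads.

    Only reads *assigned* to the feature contribute, using the placement the
    counting step recorded, so profiles agree with count tables by
    construction.
    """
    if total_mapped_reads < 1:
        raise ValueError("total_mapped_reads must be >= 1")
    if not isinstance(features, Mapping):
        features = {f.feature_id: f for f in features}
    try:
        feat = features[feature_id]
    except KeyError:
        raise KeyError(f"unknown feature {feature_id!r}") from None
    cov = np.zeros(feat.length_nt)
    sub = assignments[assignments["feature_id"] == feature_id]
    for row in sub.itertuples(index=False):
        lo = max(int(row.start), feat.start) - feat.start
        hi = min(int(row.end), feat.end) - feat.start
        if hi > lo:
            cov[lo:hi] += 1.0
    return cov * 1e6 / total_mapped_reads


def profile_frame(coverage: np.ndarray, feature_id: str) -> pd.DataFrame:
    return pd.DataFrame(
        {"feature_id": feature_id, "position": np.arange(len(coverage)), "coverage": coverage}
    )


@dataclass
class ClassSummary:
    """Per-class read fractions and summed RPKM, with replicate mean +/- sd."""

    table: pd.DataFrame  # class, read_fraction, rpkm_sum_mean, rpkm_sum_sd, n_replicates


def class_summary(
    count_tables: Sequence[CountTable],
    rpkm_tables: Sequence[RpkmTable],
    classes: Mapping[str, str],
) -> ClassSummary:
    """Aggregate replicate count/RPKM tables by RNA class.

    Read fractions are averaged across replicates (each replicate's fractions
    sum to one, hence so does the average).  RPKM is summed within class per
    replicate, then reported as mean and sample (n-1) standard deviation; a
    single replicate gets sd 0 and is flagged by n_replicates=1.
    """
    if not count_tables:
        raise ValueError("need at least one replicate")
    if len(count_tables) != len(rpkm_tables):
        raise ValueError("count and RPKM replicates must pair up")

    def cls_of(fid: str) -> str:
        if fid == OTHER_LABEL:
            return OTHER_LABEL
        c = classes.get(fid)
        if c is None:
            warnings.warn(f"feature {fid} absent from class map; grouped under '{OTHER_LABEL}'")
            return OTHER_LABEL
        return c

    frac_reps: list[pd.Series] = []
    for ct in count_tables:
        s = pd.Series(ct.counts, dtype=float)
        s.index = [cls_of(fid) for fid in s.index]
        frac_reps.append(s.groupby(level=0).sum() / s.sum())
    fractions = pd.concat(frac_reps, axis=1).fillna(0.0).mean(axis=1)

    rpkm_reps: list[pd.Series] = []
    for rt in rpkm_tables:
        s = pd.Series(rt.as_mapping(), dtype=float)
        s.index = [cls_of(fid) for fid in s.index]
        rpkm_reps.append(s.groupby(level=0).sum())
    rp = pd.concat(rpkm_reps, axis=1).fillna(0.0)
    n = rp.shape[1]
    mean = rp.mean(axis=1)
    sd = rp.std(axis=1, ddof=1).fillna(0.0) if n > 1 else pd.Series(0.0, index=rp.index)

    all_classes = sorted(set(fractions.index) | set(mean.index))
    table = pd.DataFrame(
        {
            "class": all_classes,
            "read_fraction": [float(fractions.get(c, 0.0)) for c in all_classes],
            "rpkm_sum_mean": [float(mean.get(c, 0.0)) for c in all_classes],
            "rpkm_sum_sd": [float(sd.get(c, 0.0)) for c in all_classes],
            "n_replicates": n,
        }
    )
    return ClassSummary(table)


def plot_length_histogram(hist: pd.Series, path, title: str = "Read length distribution"):
    """Optional convenience plot; TSV output is the contract."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(hist.index, hist.values, lw=1.5)
    ax.set_xlabel("read length (nt)")
    ax.set_ylabel("fraction of reads")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_profile(coverage: np.ndarray, path, feature_id: str = ""):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3))
    ax.fill_between(np.arange(len(coverage)), coverage, step="mid", alpha=0.8)
    ax.set_xlabel(f"position along {feature_id} (nt)")
    ax.set_ylabel("hits per million mapped reads")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
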