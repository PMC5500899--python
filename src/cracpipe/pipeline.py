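"""End-to-end orchestration: simulate -> preprocess -> align -> count -> summarize.

`run_pipeline` chains the modules on in-memory objects; `run_default_simulation`
is the shipped study condition (100 kb genome, 10% duplicated sequence,
50,000 footprint reads, seed 42) used throughout the examples and checks.

Because simulated reads carry ground truth, the pipeline can score its own
assignment quality: `misassignment_rate` compares assigned features against
read provenance, and `other_antisense_fraction` measures the apparent signal
in unannotated/antisense space that prioritization is meant to deflate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import align as al
from . import assign as asg
from . import preprocess as pp
from . import summarize as sm
from . import synthetic_data as sd
from .features import ANTISENSE_CLASS, OTHER_LABEL, FeatureIndex


@dataclass
class PipelineResult:
    genome: sd.Genome
    truth: pd.DataFrame
    tally: dict
    strata: dict[str, list[al.AlignmentRecord]]
    align_stats: dict[str, int]
    rpkm_long: asg.RpkmTable
    priority: asg.PriorityList
    counts: dict[tuple[str, str], asg.CountTable] = field(default_factory=dict)
    histogram: pd.Series | None = None

    @property
    def feature_index(self) -> FeatureIndex:
        return FeatureIndex(self.genome.features)


def run_pipeline(
    genome: sd.Genome,
    fastq_records,
    adapter_seq: str = sd.DEFAULT_ADAPTER,
    truth: pd.DataFrame | None = None,
    seed: int = 42,
    k: int = 8,
    min_overlap: int = 1,
    priority_scope: str = "pooled",
) -> PipelineResult:
    trim = pp.TrimPolicy(adapter_seq=adapter_seq)
    retained, tally = pp.preprocess_fastq(fastq_records, trim)

    index = al.build_index(genome.sequences, k=k)
    records, align_stats = al.align_reads(retained, index)
    strata = al.stratify(records)

    findex = FeatureIndex(genome.features)

    # Priority comes from the long-read population: count long reads with
    # random placement resolution, then rank features by RPKM.
    long_records = strata[al.LONG]
    long_ct = asg.count_default(long_records, findex, seed=seed, stratum=al.LONG,
                                min_overlap=min_overlap)
    feature_counts = {fid: c for fid, c in long_ct.counts.items() if fid != OTHER_LABEL}
    total_long = max(len(long_records), 1)
    rpkm_long = asg.compute_rpkm(feature_counts, genome.features, total_long)
    priority = asg.build_priority(rpkm_long, genome.features)

    result = PipelineResult(
        genome=genome,
        truth=truth if truth is not None else pd.DataFrame(columns=sd.TRUTH_COLUMNS),
        tally=dict(tally),
        strata=strata,
        align_stats=align_stats,
        rpkm_long=rpkm_long,
        priority=priority,
    )
    result.counts[("default", al.LONG)] = long_ct
    result.counts[("default", al.SHORT)] = asg.count_default(
        strata[al.SHORT], findex, seed=seed, stratum=al.SHORT, min_overlap=min_overlap
    )
    for stratum in (al.SHORT, al.LONG):
        result.counts[("prioritized", stratum)] = asg.count_prioritized(
            strata[stratum], findex, priority, stratum=stratum,
            min_overlap=min_overlap, scope=priority_scope, seed=seed,
        )
    result.histogram = sm.length_histogram(
        [rec.insert_length for recs in strata.values() for rec in recs]
    )
    return result


def run_default_simulation(
    seed: int = 42,
    n_reads: int = 50_000,
    genome_spec: sd.GenomeSpec | None = None,
    catalog: sd.FeatureCatalogSpec | None = None,
    mixture: sd.LengthMixture | None = None,
    adapter_present_prob: float = 0.9,
    adapter_error_rate: float = 0.0,
) -> PipelineResult:
    """The shipped study condition, exercised end to end with ground truth."""
    genome_spec = genome_spec or sd.GenomeSpec(seed=seed)
    catalog = catalog or sd.FeatureCatalogSpec()
    genome = sd.generate_genome(genome_spec, catalog)
    reads, truth = sd.simulate_reads(
        genome, mixture=mixture, abundance_weights=catalog.abundance_weights,
        n_reads=n_reads, seed=seed,
    )
    fastq = sd.attach_adapters(
        reads, adapter_present_prob=adapter_present_prob,
        per_base_error_rate=adapter_error_rate, seed=seed + 1,
    )
    return run_pipeline(genome, fastq, truth=truth, seed=seed)


def truth_labels(truth: pd.DataFrame) -> pd.Series:
    """read_id -> expected assignment label (intergenic provenance => 'other')."""
    lab = truth.set_index("read_id")["feature_id"]
    return lab.replace({sd.INTERGENIC_LABEL: OTHER_LABEL})


def misassignment_rate(
    count_table: asg.CountTable,
    truth: pd.DataFrame,
    feature_sources_only: bool = False,
) -> float:
    """Fraction of counted reads assigned to a feature other than their source.

    With `feature_sources_only`, reads of intergenic provenance are excluded;
    otherwise their correct label is the 'other' sink.
    """
    labels = truth_labels(truth)
    a = count_table.assignments.set_index("read_id")["feature_id"]
    expected = labels.reindex(a.index)
    if expected.isna().any():
        missing = expected.index[expected.isna()][:3].tolist()
        raise ValueError(f"reads missing from truth table, e.g. {missing}")
    if feature_sources_only:
        keep = expected != OTHER_LABEL
        a, expected = a[keep], expected[keep]
    if len(a) == 0:
        raise ValueError("no reads to score")
    return float((a != expected).mean())


def other_antisense_fraction(count_table: asg.CountTable, classes) -> float:
    """Fraction of counted reads ending up in 'other' or antisense features."""
    total = count_table.total
    if total == 0:
        raise ValueError("empty count table")
    bad = 0
    for fid, c in count_table.counts.items():
        if fid == OTHER_LABEL or classes.get(fid) == ANTISENSE_CLASS:
            bad += c
    return bad / total
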