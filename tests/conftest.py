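import pytest

from cracpipe import synthetic_data as sd
from cracpipe.pipeline import run_default_simulation


def naive_scan(sequences: dict[str, str], insert: str) -> list[tuple[str, int, str]]:
    """Independent full-genome exact search (oracle for the seeded aligner)."""
    hits = set()
    rc = sd.revcomp(insert)
    for chrom, seq in sequences.items():
        for probe, strand in ((insert, "+"), (rc, "-")):
            start = seq.find(probe)
            while start != -1:
                hits.add((chrom, start, strand))
                start = seq.find(probe, start + 1)
    return sorted(hits)


@pytest.fixture(scope="session")
def small_genome():
    """15 kb single-chromosome genome with duplicated blocks and twins."""
    spec = sd.GenomeSpec(n_chromosomes=1, chromosome_length=15_000,
                         repeat_fraction=0.05, seed=7)
    catalog = sd.FeatureCatalogSpec(
        classes={
            "pre_rRNA": sd.ClassSpec(1, 2000, 2500),
            "mRNA": sd.ClassSpec(6, 500, 1000),
            "CUT": sd.ClassSpec(4, 200, 400),
            "tRNA": sd.ClassSpec(3, 70, 120),
        },
        antisense_fraction=0.5,
    )
    return sd.generate_genome(spec, catalog)


@pytest.fixture(scope="session")
def default_run():
    """The shipped study condition: 100 kb genome, 50k reads, seed 42."""
    return run_default_simulation(seed=42)
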