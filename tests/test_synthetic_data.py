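"""Generator contracts: determinism, truth consistency, sampling statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cracpipe import synthetic_data as sd
from cracpipe.features import ANTISENSE_CLASS

from conftest import naive_scan


SMALL_CATALOG = sd.FeatureCatalogSpec(
    classes={
        "mRNA": sd.ClassSpec(4, 400, 800),
        "CUT": sd.ClassSpec(3, 200, 400),
    },
    antisense_fraction=0.5,
    abundance_weights={"mRNA": 0.7, "CUT": 0.3},
)


def _make(seed=3, repeat_fraction=0.0, length=8000):
    return sd.generate_genome(
        sd.GenomeSpec(n_chromosomes=1, chromosome_length=length,
                      repeat_fraction=repeat_fraction, seed=seed),
        SMALL_CATALOG,
    )


class TestGenerateGenome:
    def test_same_seed_identical_bytes(self):
        a, b = _make(seed=11), _make(seed=11)
        assert a.sequences == b.sequences
        assert a.features == b.features
        assert [r.sequence for r in a.repeats] == [r.sequence for r in b.repeats]

    def test_different_seed_differs(self):
        assert _make(seed=1).sequences != _make(seed=2).sequences

    def test_annotation_references_existing_chromosomes(self, small_genome):
        for f in small_genome.features:
            assert f.chrom in small_genome.sequences
            assert 0 <= f.start < f.end <= len(small_genome.sequences[f.chrom])

    def test_sense_features_do_not_overlap_on_a_strand(self, small_genome):
        sense = sorted(small_genome.sense_features(), key=lambda f: (f.chrom, f.start))
        for a, b in zip(sense, sense[1:]):
            if a.chrom == b.chrom:
                assert a.end <= b.start

    def test_antisense_twins_mirror_their_partner(self, small_genome):
        by_id = {f.feature_id: f for f in small_genome.features}
        twins = [f for f in small_genome.features if f.is_antisense]
        assert twins, "catalog with antisense_fraction=0.5 should produce twins"
        for t in twins:
            partner = by_id[t.feature_id.removeprefix("AS_")]
            assert (t.chrom, t.start, t.end) == (partner.chrom, partner.start, partner.end)
            assert t.strand != partner.strand
            assert t.feature_class == ANTISENSE_CLASS

    def test_repeat_blocks_found_at_two_loci_by_exhaustive_scan(self, small_genome):
        assert small_genome.repeats
        for block in small_genome.repeats[:5]:
            hits = naive_scan(small_genome.sequences, block.sequence)
            plus_hits = {(c, s) for c, s, st in hits if st == "+"}
            assert set(block.loci) <= plus_hits
            assert len(plus_hits) >= 2

    def test_no_repeats_means_unique_long_kmers(self):
        genome = _make(seed=5, repeat_fraction=0.0)
        reads, truth = sd.simulate_reads(
            genome, mixture=sd.LengthMixture(((20.0, 2.0, 1.0),), 17, 30),
            abundance_weights=SMALL_CATALOG.abundance_weights, n_reads=200, seed=5)
        for _, insert in reads:
            # apart from strand symmetry there is a single genomic locus
            positions = {(c, s) for c, s, _ in naive_scan(genome.sequences, insert)}
            assert len(positions) == 1

    def test_infeasible_packing_raises(self):
        with pytest.raises(sd.GenomePackingError):
            sd.generate_genome(
                sd.GenomeSpec(n_chromosomes=1, chromosome_length=1000, seed=0),
                sd.FeatureCatalogSpec(classes={"mRNA": sd.ClassSpec(3, 400, 500)},
                                      abundance_weights={"mRNA": 1.0}),
            )

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            sd.GenomeSpec(chromosome_length=500)
        with pytest.raises(ValueError):
            sd.GenomeSpec(repeat_fraction=0.6)


class TestSimulateReads:
    def test_degenerate_mixture_fixes_length(self, small_genome):
        mix = sd.LengthMixture(((10.0, 0.0, 1.0),), 10, 10)
        reads, truth = sd.simulate_reads(small_genome, mixture=mix, n_reads=300, seed=1)
        assert all(len(s) == 10 for _, s in reads)
        assert (truth["length"] == 10).all()

    def test_degenerate_weights_single_class(self, small_genome):
        reads, truth = sd.simulate_reads(
            small_genome, abundance_weights={"mRNA": 1.0}, n_reads=200, seed=2)
        assert truth["feature_id"].str.startswith("mRNA").all()

    def test_short_fraction_matches_binomial_oracle(self, small_genome):
        # two equal components at 10 and 20 nt; P(length <= 12) = 1/2
        mix = sd.LengthMixture(((10.0, 0.0, 0.5), (20.0, 0.0, 0.5)), 8, 30)
        n = 10_000
        _, truth = sd.simulate_reads(small_genome, mixture=mix, n_reads=n, seed=9)
        frac = (truth["length"] <= 12).mean()
        sdv = np.sqrt(0.25 / n)
        assert abs(frac - 0.5) <= 3 * sdv

    def test_truth_locus_recovered_by_exact_search(self, small_genome):
        reads, truth = sd.simulate_reads(small_genome, n_reads=150, seed=4)
        for (_, insert), row in zip(reads, truth.itertuples(index=False)):
            hits = naive_scan(small_genome.sequences, insert)
            assert (row.chrom, row.start, row.strand) in hits

    def test_source_interval_inside_feature(self, small_genome):
        by_id = {f.feature_id: f for f in small_genome.features}
        _, truth = sd.simulate_reads(small_genome, n_reads=400, seed=6)
        for row in truth.itertuples(index=False):
            if row.feature_id == sd.INTERGENIC_LABEL:
                continue
            f = by_id[row.feature_id]
            assert f.start <= row.start and row.start + row.length <= f.end
            assert row.strand == f.strand

    def test_class_proportions_converge(self, small_genome):
        """Goodness of fit to the true weights at n = 10^4.  The chi-square
        test rejects a true null with probability alpha = 0.01 by design, so
        three fixed replicates are drawn and at most one may reject."""
        weights = {"mRNA": 0.5, "CUT": 0.3, "tRNA": 0.2}
        n = 10_000
        passed = 0
        for seed in (8, 9, 10):
            _, truth = sd.simulate_reads(small_genome, abundance_weights=weights,
                                         n_reads=n, seed=seed)
            cls = truth["feature_id"].str.split("_").str[0]
            observed = cls.value_counts()
            obs = [observed.get(c, 0) for c in weights]
            exp = [w * n for w in weights.values()]
            if stats.chisquare(obs, exp).pvalue > 0.01:
                passed += 1
        assert passed >= 2

    def test_determinism(self, small_genome):
        r1, t1 = sd.simulate_reads(small_genome, n_reads=100, seed=3)
        r2, t2 = sd.simulate_reads(small_genome, n_reads=100, seed=3)
        assert r1 == r2
        pd.testing.assert_frame_equal(t1, t2)


class TestAttachAdapters:
    def test_full_adapter_always_appended(self, small_genome):
        reads, _ = sd.simulate_reads(small_genome, n_reads=100, seed=1)
        recs = sd.attach_adapters(reads, adapter_present_prob=1.0,
                                  per_base_error_rate=0.0, seed=1)
        assert all(str(r.seq).endswith(sd.DEFAULT_ADAPTER) for r in recs)
        assert all(set(r.letter_annotations["phred_quality"]) == {40} for r in recs)

    def test_prob_zero_appends_nothing(self, small_genome):
        reads, _ = sd.simulate_reads(small_genome, n_reads=100, seed=1)
        recs = sd.attach_adapters(reads, adapter_present_prob=0.0, seed=1)
        assert [str(r.seq) for r in recs] == [s for _, s in reads]

    def test_adapter_error_count_matches_binomial_oracle(self, small_genome):
        reads, _ = sd.simulate_reads(small_genome, n_reads=1000, seed=2)
        rate = 0.1
        recs = sd.attach_adapters(reads, adapter_present_prob=1.0,
                                  per_base_error_rate=rate, seed=3)
        A = len(sd.DEFAULT_ADAPTER)
        mism = sum(
            sum(a != b for a, b in zip(str(r.seq)[-A:], sd.DEFAULT_ADAPTER))
            for r in recs
        )
        n = 1000 * A
        assert abs(mism - n * rate) <= 3 * np.sqrt(n * rate * (1 - rate))

    def test_invalid_parameters(self, small_genome):
        reads, _ = sd.simulate_reads(small_genome, n_reads=5, seed=1)
        with pytest.raises(ValueError):
            sd.attach_adapters(reads, adapter_seq="ACG")
        with pytest.raises(ValueError):
            sd.attach_adapters(reads, adapter_present_prob=1.5)
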