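import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cico import expression as ex
from cico.circ_annotate import CircRNA, Feature
from cico.io_formats import GenomicInterval


def make_features():
    c1 = "circA"
    return [
        Feature(GenomicInterval("chr1", 100, 200, "+"), "exon", c1, 1),
        Feature(GenomicInterval("chr1", 200, 300, "+"), "intron", c1, 1),
        Feature(GenomicInterval("chr1", 300, 400, "+"), "exon", c1, 2),
    ]


class TestCountFeatures:
    def test_read_inside_exon_counts_once(self):
        feats = make_features()
        reads = {"s1": [GenomicInterval("chr1", 120, 170, "+")]}
        counts, skipped = ex.count_features(reads, feats)
        assert counts["s1"].tolist() == [1, 0, 0]
        assert skipped == {"s1": 0}

    def test_boundary_spanning_read_counts_both(self):
        feats = make_features()
        reads = {"s1": [GenomicInterval("chr1", 180, 220, "+")]}
        counts, _ = ex.count_features(reads, feats)
        assert counts["s1"].tolist() == [1, 1, 0]

    def test_strand_mismatch_not_counted(self):
        feats = make_features()
        reads = {"s1": [GenomicInterval("chr1", 120, 170, "-")]}
        counts, _ = ex.count_features(reads, feats)
        assert counts["s1"].sum() == 0

    def test_unknown_chromosome_skipped_and_reported(self):
        feats = make_features()
        reads = {"s1": [GenomicInterval("chrX", 120, 170, "+")]}
        counts, skipped = ex.count_features(reads, feats)
        assert counts["s1"].sum() == 0 and skipped == {"s1": 1}

    def test_empty_reads_zero_matrix(self):
        counts, _ = ex.count_features({"s1": []}, make_features())
        assert (counts.to_numpy() == 0).all()


class TestRpkm:
    @pytest.mark.parametrize("count,lib,length,expected", [
        (10, 1_000_000, 1000, 10.0),
        (0, 5_000_000, 200, 0.0),
        (7, 2_000_000, 500, 7.0),
    ])
    def test_values(self, count, lib, length, expected):
        assert ex.rpkm(count, lib, length) == pytest.approx(expected)

    @pytest.mark.parametrize("lib,length", [(0, 100), (100, 0), (-5, 100)])
    def test_degenerate_inputs_rejected(self, lib, length):
        with pytest.raises(ValueError):
            ex.rpkm(1, lib, length)

    @given(st.integers(0, 10_000), st.integers(1, 10**7),
           st.integers(1, 10**5), st.integers(1, 50))
    def test_scale_invariance(self, count, lib, length, c):
        """Multiplying count and library size by c leaves RPKM unchanged."""
        assert ex.rpkm(count * c, lib * c, length) == pytest.approx(
            ex.rpkm(count, lib, length))


class TestThresholdAndCalling:
    def mean_rpkm(self):
        return pd.DataFrame(
            {"PP": [5.0, 0.2, 3.5], "DP": [1.0, 3.5, 1.1], "N": [0.0, 0.1, 0.4]},
            index=["circA|exon1", "circA|intron1", "circA|exon2"],
        )

    def test_derive_threshold_is_max_intron_rpkm(self):
        t = ex.derive_threshold(["circA"], self.mean_rpkm(), make_features())
        assert t == 3.5

    def test_no_introns_instructs_default(self):
        feats = [f for f in make_features() if f.kind == "exon"]
        with pytest.raises(ValueError, match="DEFAULT_RPKM_THRESHOLD"):
            ex.derive_threshold(["circA"], self.mean_rpkm(), feats)

    def test_strict_inequality_at_threshold(self):
        expressed = ex.call_expressed(self.mean_rpkm(), 3.5)
        # exon1 exceeds in PP; intron1 equals 3.5 exactly -> not expressed
        assert expressed == {"circA|exon1"}

    def test_expressed_intron_does_not_promote_circ(self):
        mean = pd.DataFrame({"PP": [1.0, 9.0]},
                            index=["circA|exon1", "circA|intron1"])
        expressed = ex.call_expressed(mean, 3.5)
        assert expressed == {"circA|intron1"}
        assert ex.define_circ_set(expressed, make_features()) == set()

    def test_one_expressed_exon_promotes_circ(self):
        expressed = {"circA|exon2"}
        assert ex.define_circ_set(expressed, make_features()) == {"circA"}


def test_meta_feature_counts_sum_exons_only():
    feats = make_features()
    circ = CircRNA("circA", GenomicInterval("chr1", 100, 400, "+"),
                   "genic_exonic", features=feats)
    counts = pd.DataFrame({"s1": [3, 100, 4]},
                          index=[f.feature_id for f in feats])
    meta = ex.meta_feature_counts(counts, [circ])
    assert meta.at["circA", "s1"] == 7  # intron reads excluded


def test_noiseless_counts_recover_planted_rpkm(small_bundle):
    """With noiseless counts the counting + RPKM path inverts the generator."""
    from cico import circ_annotate
    circs = circ_annotate.annotate_junctions(
        small_bundle.junctions, small_bundle.annotation,
        prefix=small_bundle.config.id_prefix)
    features = [f for c in circs for f in c.features]
    counts, _ = ex.count_features(small_bundle.reads, features)
    meta = ex.meta_feature_counts(counts, circs)
    rpkm = ex.circ_rpkm(meta, small_bundle.library_sizes, circs)
    means = ex.population_means(rpkm, small_bundle.design,
                                small_bundle.config.populations)
    truth = small_bundle.manifest["circs"]
    for circ_id, info in truth.items():
        for pop, value in info["rpkm"].items():
            assert means.at[circ_id, pop] == pytest.approx(value, rel=1e-12)
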