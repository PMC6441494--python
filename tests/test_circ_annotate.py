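import pytest

from cico import circ_annotate as ca
from cico.io_formats import Annotation, Gene, GenomicInterval, Transcript


def make_annotation():
    """One plus-strand gene with 5 exons, one minus-strand gene elsewhere."""
    g1 = Gene("gA", "chr1", "+")
    exons = [(100, 200), (300, 400), (500, 600), (700, 800), (900, 1000)]
    g1.transcripts["tA1"] = Transcript("tA1", exons=list(exons))
    g2 = Gene("gB", "chr1", "-")
    g2.transcripts["tB1"] = Transcript("tB1", exons=[(2000, 2200), (2500, 2700)])
    return Annotation({"gA": g1, "gB": g2})


class TestClassify:
    def test_exon_boundary_match_is_genic_exonic(self):
        ann = make_annotation()
        cls, host = ca.classify(GenomicInterval("chr1", 300, 1000, "+"), ann)
        assert cls == "genic_exonic" and host.gene_id == "gA"

    def test_mid_exon_boundary_is_genic_other(self):
        ann = make_annotation()
        cls, host = ca.classify(GenomicInterval("chr1", 310, 990, "+"), ann)
        assert cls == "genic_other" and host.gene_id == "gA"

    def test_opposite_strand_only_is_antisense(self):
        ann = make_annotation()
        cls, host = ca.classify(GenomicInterval("chr1", 2100, 2600, "+"), ann)
        assert cls == "antisense" and host is None

    def test_no_gene_overlap_is_intergenic(self):
        ann = make_annotation()
        cls, _ = ca.classify(GenomicInterval("chr1", 1200, 1800, "+"), ann)
        assert cls == "intergenic"

    def test_unknown_chromosome_is_intergenic(self):
        ann = make_annotation()
        cls, _ = ca.classify(GenomicInterval("chrUn", 10, 100, "+"), ann)
        assert cls == "intergenic"

    def test_host_tiebreak_prefers_more_matches_then_lexicographic(self):
        exons = [(100, 200), (300, 400)]
        g1 = Gene("gZ", "chr1", "+")
        g1.transcripts["t1"] = Transcript("t1", exons=list(exons))
        g2 = Gene("gM", "chr1", "+")
        g2.transcripts["t2"] = Transcript("t2", exons=[(100, 250)])
        ann = Annotation({"gZ": g1, "gM": g2})
        # both ends match gZ's boundaries; only the start matches gM
        cls, host = ca.classify(GenomicInterval("chr1", 100, 400, "+"), ann)
        assert cls == "genic_exonic" and host.gene_id == "gZ"
        # exact tie: both genes match both boundaries -> smaller id wins
        g3 = Gene("gA2", "chr1", "+")
        g3.transcripts["t3"] = Transcript("t3", exons=list(exons))
        ann2 = Annotation({"gZ": g1, "gA2": g3})
        _, host2 = ca.classify(GenomicInterval("chr1", 100, 400, "+"), ann2)
        assert host2.gene_id == "gA2"


class TestDecompose:
    def test_two_exons_with_gap(self):
        ann = make_annotation()
        span = GenomicInterval("chr1", 300, 600, "+")
        feats = ca.decompose("c1", span, "genic_exonic", ann.genes["gA"])
        assert [f.kind for f in feats] == ["exon", "intron", "exon"]
        assert sum(f.interval.length for f in feats) == span.length

    def test_single_exon_no_intron(self):
        ann = make_annotation()
        feats = ca.decompose("c1", GenomicInterval("chr1", 300, 400, "+"),
                             "genic_exonic", ann.genes["gA"])
        assert [f.kind for f in feats] == ["exon"]

    def test_non_genic_is_single_exon_span(self):
        span = GenomicInterval("chr1", 1200, 1600, "+")
        feats = ca.decompose("c1", span, "intergenic", None)
        assert len(feats) == 1 and feats[0].kind == "exon"
        assert feats[0].interval.length == 400


class TestReconstruct:
    def test_plus_strand_concatenation(self):
        genome = {"chr1": "NNAACCGGTT"}
        circ = ca.CircRNA("c1", GenomicInterval("chr1", 2, 10, "+"), "genic_exonic",
                          features=[
                              ca.Feature(GenomicInterval("chr1", 2, 4, "+"), "exon", "c1", 1),
                              ca.Feature(GenomicInterval("chr1", 4, 6, "+"), "intron", "c1", 1),
                              ca.Feature(GenomicInterval("chr1", 6, 8, "+"), "exon", "c1", 2),
                          ])
        # introns are excluded: AA + GG
        assert ca.reconstruct_sequence(circ, genome) == "AAGG"

    def test_minus_strand_revcomp(self):
        genome = {"chr1": "AACC"}
        circ = ca.CircRNA("c1", GenomicInterval("chr1", 0, 4, "-"), "intergenic",
                          features=[ca.Feature(GenomicInterval("chr1", 0, 4, "-"),
                                               "exon", "c1", 1)])
        assert ca.reconstruct_sequence(circ, genome) == "GGTT"

    def test_feature_beyond_chromosome_rejected(self):
        genome = {"chr1": "AAAA"}
        circ = ca.CircRNA("c1", GenomicInterval("chr1", 0, 8, "+"), "intergenic",
                          features=[ca.Feature(GenomicInterval("chr1", 0, 8, "+"),
                                               "exon", "c1", 1)])
        with pytest.raises(ValueError, match="beyond chromosome"):
            ca.reconstruct_sequence(circ, genome)


class TestCatalogOverlap:
    def circ(self, start, end):
        span = GenomicInterval("chr1", start, end, "+")
        return ca.CircRNA("c1", span, "intergenic",
                          features=[ca.Feature(span, "exon", "c1", 1)])

    def test_identical_intervals_known_at_full_overlap(self):
        hits = ca.catalog_overlap([self.circ(100, 200)],
                                  [GenomicInterval("chr1", 100, 200)])
        assert hits["c1"].known and hits["c1"].level == 1.0

    def test_single_nucleotide_mode(self):
        hits = ca.catalog_overlap([self.circ(100, 200)],
                                  [GenomicInterval("chr1", 199, 400)],
                                  single_nucleotide=True)
        assert hits["c1"].known

    def test_reciprocity_required(self):
        # overlap 50: 50/100 passes f=0.5 but 50/400 fails -> novel at 0.5
        hits = ca.catalog_overlap([self.circ(100, 200)],
                                  [GenomicInterval("chr1", 150, 550)],
                                  levels=(0.5,))
        assert not hits["c1"].known

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            ca.catalog_overlap([self.circ(0, 10)], [], levels=(1.5,))


def test_classification_partitions_bundle(small_bundle):
    """Every junction gets exactly one of the four classes."""
    circs = ca.annotate_junctions(small_bundle.junctions, small_bundle.annotation)
    assert len(circs) == len(small_bundle.junctions)
    assert {c.circ_class for c in circs} <= set(ca.CIRC_CLASSES)
    for c in circs:
        if c.circ_class == "genic_exonic":
            assert sum(f.interval.length for f in c.features) == c.span.length
            assert len(c.exon_features) >= 1


def test_ids_are_stable_and_ordered():
    spans = [GenomicInterval("chr2", 5, 10), GenomicInterval("chr1", 5, 10),
             GenomicInterval("chr1", 2, 10)]
    ids = ca.assign_ids(spans, prefix="X")
    assert ids == ["X_000003", "X_000002", "X_000001"]
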