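import numpy as np
import pytest

from natlnc.errors import ValidationError
from natlnc.formats_io import AnnotationSet, GenomicInterval, TranscriptRecord
from natlnc.nat_classify import (
    brute_force_classify,
    classify_all,
    classify_lncrna,
)
from natlnc.synthetic_data import SyntheticConfig, generate_annotation

from conftest import make_gene, make_transcript, random_lncrnas


@pytest.fixture
def two_gene_anno():
    return AnnotationSet(
        [
            make_gene("GA", [(10000, 10600), (10900, 12000)], "+"),
            make_gene("GB", [(20000, 21500)], "+"),
        ]
    )


class TestClassifyRules:
    def test_antisense_tail_overlap_geometry(self, two_gene_anno):
        # antisense transcript starting near the partner's TTS whose 3' end
        # extends into the partner's first intron
        lnc = make_transcript("L", [(10700, 12300)], "-")
        rec = classify_lncrna(lnc, two_gene_anno)
        assert rec.lnc_class == "NAT_OVERLAPPING"
        assert rec.partner_gene_id == "GA"
        assert rec.overlap_bp == 12000 - 10700
        assert rec.exonic_overlap

    def test_head_to_head_within_window_is_divergent(self, two_gene_anno):
        # lnc on '-' ending 300 bp before GA's TSS: 5' ends flank the gap
        lnc = make_transcript("L", [(9000, 9700)], "-")
        rec = classify_lncrna(lnc, two_gene_anno, window_bp=1000)
        assert rec.lnc_class == "NAT_DIVERGENT"
        assert rec.partner_gene_id == "GA" and rec.end_gap_bp == 300

    def test_tail_to_tail_within_window_is_convergent(self, two_gene_anno):
        lnc = make_transcript("L", [(12400, 13000)], "-")
        rec = classify_lncrna(lnc, two_gene_anno, window_bp=1000)
        assert rec.lnc_class == "NAT_CONVERGENT"
        assert rec.partner_gene_id == "GA" and rec.end_gap_bp == 400

    def test_distant_transcript_is_lincrna(self, two_gene_anno):
        lnc = make_transcript("L", [(26500, 27200)], "-")
        rec = classify_lncrna(lnc, two_gene_anno)
        assert rec.lnc_class == "LINCRNA"
        assert rec.partner_gene_id == "GB"  # nearest-gene annotation only

    def test_overlap_beats_divergent_priority(self):
        anno = AnnotationSet(
            [
                make_gene("GA", [(10000, 11000)], "+"),
                make_gene("GB", [(11500, 12500)], "-"),
            ]
        )
        # overlaps GA antisense by 10 bp AND head-to-head with GB at 200 bp
        lnc = make_transcript("L", [(10990, 11300)], "-")
        rec = classify_lncrna(lnc, anno)
        assert rec.lnc_class == "NAT_OVERLAPPING" and rec.partner_gene_id == "GA"

    def test_sense_intron_containment_is_incrna(self, two_gene_anno):
        lnc = make_transcript("L", [(10650, 10850)], "+")
        rec = classify_lncrna(lnc, two_gene_anno)
        assert rec.lnc_class == "INCRNA" and rec.partner_gene_id == "GA"

    def test_unknown_chromosome_rejected(self, two_gene_anno):
        lnc = make_transcript("L", [(0, 500)], "+", chrom="chrZ")
        with pytest.raises(ValidationError, match="chrZ"):
            classify_lncrna(lnc, two_gene_anno)


class TestClassifyAll:
    def test_planted_class_recovery(self, default_annotation):
        cfg, anno, truth = default_annotation
        lnc_ids = truth.lnc_ids()
        lncs = anno.subset(lnc_ids)
        coding = anno.subset(
            truth.transcripts.index[truth.transcripts.role == "coding"]
        )
        records, summary = classify_all(lncs, coding, cfg.pairing_window_bp)
        assert summary == {
            "NAT_OVERLAPPING": 10, "NAT_DIVERGENT": 10, "NAT_CONVERGENT": 10,
            "LINCRNA": 10, "INCRNA": 10,
        }
        truth_roles = truth.transcripts.loc[lnc_ids, "role"]
        for r in records:
            assert r.lnc_class == truth_roles[r.transcript_id]

    def test_empty_input(self, two_gene_anno):
        records, summary = classify_all(AnnotationSet(), two_gene_anno)
        assert records == [] and all(v == 0 for v in summary.values())

    def test_window_monotonicity(self, default_annotation):
        cfg, anno, truth = default_annotation
        coding = anno.subset(
            truth.transcripts.index[truth.transcripts.role == "coding"]
        )
        lncs = AnnotationSet(random_lncrnas(coding, 150,
                                            np.random.default_rng(5)))
        n_paired = {}
        for window in (500, 1000, 2000):
            _, summary = classify_all(lncs, coding, window)
            n_paired[window] = summary["NAT_DIVERGENT"] + summary["NAT_CONVERGENT"]
        assert n_paired[500] <= n_paired[1000] <= n_paired[2000]

    def test_fold_incrna_options(self, default_annotation):
        cfg, anno, truth = default_annotation
        lncs = anno.subset(truth.lnc_ids())
        coding = anno.subset(
            truth.transcripts.index[truth.transcripts.role == "coding"]
        )
        _, keep = classify_all(lncs, coding, fold_incrna="keep")
        _, fold = classify_all(lncs, coding, fold_incrna="lincRNA")
        recs, drop = classify_all(lncs, coding, fold_incrna="drop")
        assert fold["INCRNA"] == 0
        assert fold["LINCRNA"] == keep["LINCRNA"] + keep["INCRNA"]
        assert drop["INCRNA"] == 0 and len(recs) == len(lncs) - keep["INCRNA"]


class TestOracleEquivalence:
    def test_indexed_equals_brute_force_on_random_lncrnas(self, default_annotation):
        cfg, anno, truth = default_annotation
        coding = anno.subset(
            truth.transcripts.index[truth.transcripts.role == "coding"]
        )
        rng = np.random.default_rng(2024)
        for lnc in random_lncrnas(coding, 250, rng):
            assert classify_lncrna(lnc, coding) == brute_force_classify(lnc, coding)

    def test_single_gene_genome_far_lnc(self):
        coding = AnnotationSet([make_gene("G", [(0, 1500)], "+")])
        lnc = make_transcript("L", [(50000, 50600)], "-")
        a = classify_lncrna(lnc, coding)
        b = brute_force_classify(lnc, coding)
        assert a == b and a.lnc_class == "LINCRNA"

    def test_adversarial_nested_genes(self):
        # a gene nested inside another gene's intron, opposite strands around
        coding = AnnotationSet(
            [
                make_gene("OUTER", [(1000, 2000), (9000, 10000)], "+"),
                make_gene("NESTED", [(4000, 5000)], "-"),
                make_gene("RIGHT", [(10200, 11000)], "-"),
            ]
        )
        probes = [
            make_transcript("P1", [(3000, 3500)], "+"),   # in OUTER intron
            make_transcript("P2", [(4500, 5500)], "+"),   # overlaps NESTED anti
            make_transcript("P3", [(5200, 5900)], "-"),   # near NESTED, in intron
            make_transcript("P4", [(10050, 10150)], "+"),  # between OUTER/RIGHT
            make_transcript("P5", [(2100, 2300)], "-"),   # antisense in intron
        ]
        for p in probes:
            assert classify_lncrna(p, coding) == brute_force_classify(p, coding)

    def test_reverse_complement_invariance(self, default_annotation):
        # classification is invariant under reverse-complementing the whole
        # chromosome: mirror every coordinate and flip every strand
        L = 10_000_000

        def flipped(anno):
            out = AnnotationSet()
            for t in anno:
                s = "-" if t.strand == "+" else "+"
                out.add(
                    TranscriptRecord(
                        t.transcript_id, t.gene_id,
                        tuple(GenomicInterval(e.chrom, L - e.end, L - e.start, s)
                              for e in t.exons),
                        class_code=t.class_code, biotype=t.biotype,
                    )
                )
            return out

        cfg, anno, truth = default_annotation
        coding = anno.subset(
            truth.transcripts.index[truth.transcripts.role == "coding"]
        )
        lncs = random_lncrnas(coding, 80, np.random.default_rng(8))
        coding_f = flipped(coding)
        for lnc in lncs:
            lnc_f = flipped(AnnotationSet([lnc]))[lnc.transcript_id]
            assert classify_lncrna(lnc, coding).lnc_class == \
                classify_lncrna(lnc_f, coding_f).lnc_class
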