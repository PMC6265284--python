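import numpy as np
import pytest

from natlnc.errors import ValidationError
from natlnc.formats_io import AnnotationSet, HomologyHit, read_annotation
from natlnc.lncrna_identify import (
    IdentifyParams,
    builtin_cp_scorer,
    class_code_filter,
    homology_coding_filter,
    identify_lncrnas,
    length_abundance_filter,
    scan_orfs,
    sense_overlap_filter,
)
from natlnc.synthetic_data import (
    SyntheticConfig,
    generate_annotation,
    generate_sequences,
)

from conftest import make_gene, make_transcript, simple_expr


class TestClassCodeFilter:
    def test_only_uxi_retained(self):
        anno = AnnotationSet(
            make_transcript(f"t{i}", [(i * 1000, i * 1000 + 500)], class_code=c)
            for i, c in enumerate(["u", "x", "i", "=", "o"])
        )
        retained, removed = class_code_filter(anno)
        assert {t.class_code for t in retained} == {"u", "x", "i"}
        assert len(retained) == 3 and len(removed) == 2
        assert set(removed.values()) == {"known/other class code"}

    def test_empty_and_all_u(self):
        assert class_code_filter(AnnotationSet()) == ([], {})
        anno = AnnotationSet([make_transcript("t", [(0, 500)], class_code="u")])
        retained, removed = class_code_filter(anno)
        assert len(retained) == 1 and removed == {}


class TestLengthAbundanceFilter:
    @pytest.mark.parametrize(
        "length,fmax,kept,reason_part",
        [
            (149, 5.0, False, "length"),     # below the 150-nt floor
            (150, 1.0, True, None),          # both criteria at their boundary
            (2000, 0.99, False, "FPKM_max"),  # below the abundance floor
        ],
    )
    def test_printed_boundaries(self, length, fmax, kept, reason_part):
        t = make_transcript("t", [(0, length)])
        expr = simple_expr({"t": [fmax / 2, fmax]})
        retained, removed = length_abundance_filter([t], expr)
        assert (len(retained) == 1) is kept
        if reason_part:
            assert reason_part in removed["t"]

    def test_missing_transcript_removed_with_reason(self):
        t = make_transcript("t", [(0, 500)])
        expr = simple_expr({"other": [1.0, 2.0]})
        retained, removed = length_abundance_filter([t], expr)
        assert retained == [] and "absent" in removed["t"]


class TestScanOrfs:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ATGAAATAG", 2),      # Met-Lys
            ("CCCCCC", 0),         # no start codon
            ("ATGTTTTTTTGA", 3),
            ("", 0),
            ("AUGAAAUAG", 2),      # RNA alphabet accepted
            ("ANGAAATAG", 0),      # N never completes a start codon
        ],
    )
    def test_hand_cases(self, seq, expected):
        assert scan_orfs(seq)[0] == expected

    def test_invalid_character_rejected(self):
        with pytest.raises(ValidationError):
            scan_orfs("ATGXXX")

    def test_against_brute_force_three_frame_scan(self):
        def brute_longest(seq):
            seq = seq.upper().replace("U", "T")
            best = 0
            for i in range(len(seq) - 2):
                if seq[i:i + 3] != "ATG":
                    continue
                aa = 0
                for j in range(i, len(seq) - 2, 3):
                    if seq[j:j + 3] in ("TAA", "TAG", "TGA"):
                        break
                    aa += 1
                best = max(best, aa)
            return best

        rng = np.random.default_rng(42)
        alphabet = np.array(list("ACGTN"))
        for _ in range(80):
            n = int(rng.integers(0, 300))
            seq = "".join(alphabet[rng.integers(0, 5, size=n)])
            assert scan_orfs(seq)[0] == brute_longest(seq), seq


class TestHomologyCodingFilter:
    def hit(self, **kw):
        base = dict(query_id="t", subject_id="P", aln_len_aa=40,
                    pct_identity=35.0, query_cov_pct=35.0, subject_cov_pct=0.0,
                    evalue=1e-10)
        base.update(kw)
        return HomologyHit(**base)

    def test_all_thresholds_inclusive_at_boundary(self):
        coding, h = homology_coding_filter("t", [self.hit()])
        assert coding and h is not None

    def test_single_failed_criterion_fails(self):
        coding, _ = homology_coding_filter(
            "t", [self.hit(aln_len_aa=39, pct_identity=99.0,
                           query_cov_pct=99.0, subject_cov_pct=99.0,
                           evalue=1e-50)]
        )
        assert not coding

    def test_evalue_gate_is_strict(self):
        coding, _ = homology_coding_filter(
            "t", [self.hit(aln_len_aa=100, pct_identity=80.0,
                           query_cov_pct=80.0, subject_cov_pct=80.0,
                           evalue=1e-3)]
        )
        assert not coding

    def test_subject_coverage_alone_suffices(self):
        coding, _ = homology_coding_filter(
            "t", [self.hit(query_cov_pct=0.0, subject_cov_pct=35.0)]
        )
        assert coding


class TestCodingPotentialScorer:
    def test_full_length_orf_scores_positive(self):
        t = make_transcript("t", [(0, 903)])
        seq = "ATG" + "GCT" * 299 + "TAA"  # one ORF spanning the transcript
        assert builtin_cp_scorer(t, seq) > 0

    def test_no_orf_scores_negative(self):
        t = make_transcript("t", [(0, 300)])
        assert builtin_cp_scorer(t, "C" * 300) < 0

    def test_sign_agreement_with_planted_truth(self):
        cfg = SyntheticConfig(n_decoys=50, seed=7)
        anno, truth = generate_annotation(cfg)
        seqs = generate_sequences(anno, truth, cfg)
        roles = truth.transcripts["role"]
        checked = agree = 0
        for tid, role in roles.items():
            if role == "coding":
                continue
            score = builtin_cp_scorer(anno[tid], seqs[tid])
            checked += 1
            if (score > 0) == (role == "decoy"):
                agree += 1
        assert checked == 50 + 50  # 50 decoys + 50 planted lncRNAs
        assert agree / checked >= 0.95


class TestSenseOverlapFilter:
    def setup_method(self):
        self.coding = AnnotationSet(
            [make_gene("G1", [(1000, 1600), (1900, 2600)], "+")]
        )

    def test_one_bp_sense_overlap_removed(self):
        t = make_transcript("t", [(2599, 3100)], "+")
        retained, removed = sense_overlap_filter([t], self.coding)
        assert retained == [] and "G1" in removed["t"]

    def test_antisense_full_containment_retained(self):
        t = make_transcript("t", [(1200, 2000)], "-")
        retained, removed = sense_overlap_filter([t], self.coding)
        assert len(retained) == 1 and removed == {}

    def test_geneless_chromosome_retained(self):
        t = make_transcript("t", [(0, 500)], "+", chrom="chr9")
        retained, _ = sense_overlap_filter([t], self.coding)
        assert len(retained) == 1

    def test_intron_contained_sense_transcript_exempt(self):
        t = make_transcript("t", [(1650, 1850)], "+")
        retained, _ = sense_overlap_filter([t], self.coding)
        assert len(retained) == 1
        retained, removed = sense_overlap_filter(
            [t], self.coding, exempt_intron_contained=False
        )
        assert retained == []


class TestIdentifyCascade:
    def test_toy_fixture_accounting(self, toy_bundle):
        from natlnc.examples import (
            toy_annotations, toy_expression, toy_hits, toy_sequences,
        )

        assembled, reference = toy_annotations()
        lncs, assessments, report = identify_lncrnas(
            assembled, toy_expression(), toy_hits(), toy_sequences(), reference
        )
        assert [s.n_removed for s in report.stages] == [1, 1, 1, 1]
        assert [s.n_in for s in report.stages] == [6, 5, 4, 3]
        assert sorted(lncs.transcripts) == ["TOY_LINC", "TOY_NAT"]
        for s in report.stages:
            assert s.n_out == s.n_in - s.n_removed

    def test_idempotence_on_own_output(self):
        from natlnc.examples import (
            toy_annotations, toy_expression, toy_hits, toy_sequences,
        )

        assembled, reference = toy_annotations()
        expr, hits, seqs = toy_expression(), toy_hits(), toy_sequences()
        lncs, _, _ = identify_lncrnas(assembled, expr, hits, seqs, reference)
        again, _, report = identify_lncrnas(lncs, expr, hits, seqs, reference)
        assert sorted(again.transcripts) == sorted(lncs.transcripts)
        assert all(s.n_removed == 0 for s in report.stages)

    def test_all_coding_input_empty_output(self):
        from natlnc.examples import toy_expression, toy_hits, toy_sequences

        anno = AnnotationSet(
            [make_transcript("TOY_CODING", [(7000, 7600)], "-", class_code="u")]
        )
        lncs, _, report = identify_lncrnas(
            anno, toy_expression(), toy_hits(), toy_sequences(), AnnotationSet()
        )
        assert len(lncs) == 0
        assert sum(s.n_removed for s in report.stages) == 1

    def test_threshold_monotonicity(self):
        from natlnc.examples import (
            toy_annotations, toy_expression, toy_hits, toy_sequences,
        )

        assembled, reference = toy_annotations()
        expr, hits, seqs = toy_expression(), toy_hits(), toy_sequences()
        baseline, _, _ = identify_lncrnas(assembled, expr, hits, seqs, reference)
        relaxed, _, _ = identify_lncrnas(
            assembled, expr, hits, seqs, reference,
            IdentifyParams(min_len=50, min_fpkm_max=0.0),
        )
        assert set(baseline.transcripts) <= set(relaxed.transcripts)

    def test_planted_truth_recovery(self, default_bundle):
        import pandas as pd

        d, config, _ = default_bundle
        truth = pd.read_csv(d / "truth.tsv", sep="\t", index_col=0)
        lncs = read_annotation(d / "results" / "lncrna.gtf")
        planted = set(truth.index[truth.role.isin(
            ["NAT_OVERLAPPING", "NAT_DIVERGENT", "NAT_CONVERGENT",
             "LINCRNA", "INCRNA"]
        )])
        decoys = set(truth.index[truth.role == "decoy"])
        got = set(lncs.transcripts)
        assert planted <= got
        assert not (decoys & got)
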