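import numpy as np
import pandas as pd
import pytest

from natlnc.errors import ConfigurationError
from natlnc.formats_io import GenomicInterval
from natlnc.synthetic_data import (
    LNC_CLASSES,
    SyntheticConfig,
    generate_annotation,
    generate_expression,
    generate_homology_hits,
    generate_sequences,
    generate_srna_counts,
)


def passes_all_criteria(h):
    return (h.evalue < 1e-4 and h.aln_len_aa >= 40 and h.pct_identity >= 35
            and max(h.query_cov_pct, h.subject_cov_pct) >= 35)


class TestGenerateAnnotation:
    def test_counts_from_config(self):
        cfg = SyntheticConfig(n_coding_genes=50, n_per_lnc_class=10,
                              n_cc_pairs=0, n_decoys=0, seed=7)
        anno, truth = generate_annotation(cfg)
        roles = truth.transcripts["role"]
        assert (roles == "coding").sum() == 50
        assert roles.isin(LNC_CLASSES).sum() == 50
        assert len(truth.transcripts) == 100
        assert len(anno) == 100

    def test_determinism_under_seed(self):
        cfg = SyntheticConfig(seed=11)
        a1, t1 = generate_annotation(cfg)
        a2, t2 = generate_annotation(SyntheticConfig(seed=11))
        assert [
            (t.transcript_id, t.class_code, [(e.start, e.end) for e in t.exons])
            for t in a1
        ] == [
            (t.transcript_id, t.class_code, [(e.start, e.end) for e in t.exons])
            for t in a2
        ]
        pd.testing.assert_frame_equal(t1.transcripts, t2.transcripts)

    def test_planted_geometry_postconditions(self, default_annotation):
        cfg, anno, truth = default_annotation
        window, margin = cfg.pairing_window_bp, cfg.class_margin_bp
        gene_spans = {g: anno.gene_span(g) for g in anno.genes
                      if anno.gene_transcripts(g)[0].biotype == "coding"}
        for tid, row in truth.transcripts.iterrows():
            role = row["role"]
            if role not in LNC_CLASSES:
                continue
            lnc = anno[tid]
            partner = row["partner_gene_id"]
            if role == "NAT_OVERLAPPING":
                gspan = gene_spans[partner]
                assert lnc.strand != gspan.strand
                assert lnc.span.overlap_bp(gspan) >= 1
            elif role == "NAT_DIVERGENT":
                gspan = gene_spans[partner]
                assert lnc.strand != gspan.strand
                assert lnc.span.overlap_bp(gspan) == 0
                gene_5p = gspan.start if gspan.strand == "+" else gspan.end
                gap = abs(lnc.five_prime - gene_5p)
                assert gap < window - margin
            elif role == "NAT_CONVERGENT":
                gspan = gene_spans[partner]
                gene_3p = gspan.end if gspan.strand == "+" else gspan.start
                assert abs(lnc.three_prime - gene_3p) < window - margin
            elif role == "LINCRNA":
                for gspan in gene_spans.values():
                    gap = max(gspan.start - lnc.span.end,
                              lnc.span.start - gspan.end)
                    assert gap >= window + margin
            elif role == "INCRNA":
                host = anno.gene_transcripts(partner)[0]
                assert host.strand == lnc.strand
                assert any(i.contains(lnc.span) for i in host.introns())

    def test_infeasible_chrom_length_rejected(self):
        with pytest.raises(ConfigurationError, match="chrom_length"):
            generate_annotation(SyntheticConfig(chrom_length=10_000))


class TestGenerateExpression:
    def test_degenerate_noise_gives_exact_correlation(self):
        cfg = SyntheticConfig(rho_nco=1.0, noise_sd=0.0, n_enriched=0,
                              n_cc_pairs=0, n_coding_genes=60, seed=3)
        anno, truth = generate_annotation(cfg)
        expr = generate_expression(truth, cfg)
        nco = truth.pairs[truth.pairs.pair_type == "NCO"]
        for _, p in nco.iterrows():
            a = expr.values.loc[p.a_feature]
            b = expr.values.loc[p.b_feature]
            assert np.corrcoef(a, b)[0, 1] == pytest.approx(1.0)

    def test_null_enrichment_configuration(self):
        cfg = SyntheticConfig(enrichment_log2fc=0.0, noise_sd=0.0, seed=3)
        anno, truth = generate_annotation(cfg)
        expr = generate_expression(truth, cfg)
        plus = expr.samples_where(fraction="polyA_plus")
        minus = expr.samples_where(fraction="polyA_minus")
        diff = np.log2(expr.values[plus]).mean(axis=1) - \
            np.log2(expr.values[minus]).mean(axis=1)
        assert np.allclose(diff, 0.0)

    def test_planted_correlation_recovered_monte_carlo(self):
        # 200 NCO pairs, 9 conditions x 3 replicates: mean log-scale Pearson
        # correlation across the planted pairs recovers rho_nco within 0.1
        cfg = SyntheticConfig(n_per_lnc_class=200, n_coding_genes=800,
                              n_cc_pairs=0, n_decoys=0, n_enriched=0,
                              rho_nco=0.8, seed=1)
        anno, truth = generate_annotation(cfg)
        expr = generate_expression(truth, cfg)
        log_vals = np.log2(expr.values)
        nco = truth.pairs[truth.pairs.pair_type == "NCO"]
        pccs = [
            np.corrcoef(log_vals.loc[p.a_feature], log_vals.loc[p.b_feature])[0, 1]
            for _, p in nco.iterrows()
        ]
        assert len(pccs) == 200
        assert abs(np.mean(pccs) - 0.8) < 0.1

    def test_all_values_strictly_positive(self, default_annotation):
        cfg, anno, truth = default_annotation
        expr = generate_expression(truth, cfg)
        assert (expr.values > 0).all().all()


class TestGenerateHomologyHits:
    def test_planted_hit_quality(self, default_annotation):
        cfg, anno, truth = default_annotation
        hits = generate_homology_hits(truth, cfg)
        by_tx = {}
        for h in hits:
            by_tx.setdefault(h.query_id, []).append(h)
        roles = truth.transcripts["role"]
        for tid in roles.index[roles == "decoy"]:
            assert any(passes_all_criteria(h) for h in by_tx[tid])
        for tid in roles.index[roles.isin(LNC_CLASSES)]:
            assert all(not passes_all_criteria(h) for h in by_tx.get(tid, []))

    def test_zero_decoys_no_noncoding_hits(self):
        cfg = SyntheticConfig(n_decoys=0, seed=5)
        anno, truth = generate_annotation(cfg)
        hits = generate_homology_hits(truth, cfg)
        lnc_ids = set(truth.lnc_ids())
        passing = [h for h in hits if h.query_id in lnc_ids
                   and passes_all_criteria(h)]
        assert passing == []


class TestGenerateSrna:
    def test_negative_case_all_reads_inside_window(self, default_annotation):
        cfg, anno, truth = default_annotation
        counts, total, tid, site = generate_srna_counts(truth, anno, cfg)
        assert total >= 1
        inside = counts[(counts.start >= site.start) & (counts.end <= site.end)]
        assert inside["count"].sum() == counts["count"].sum() == cfg.srna_reads

    def test_positive_case_spreads_reads_outside(self, default_annotation):
        cfg0, anno, truth = default_annotation
        cfg = SyntheticConfig(seed=cfg0.seed, srna_spread_fraction=0.5)
        counts, total, tid, site = generate_srna_counts(truth, anno, cfg)
        outside = counts[(counts.end <= site.start) | (counts.start >= site.end)]
        assert outside["count"].sum() == pytest.approx(cfg.srna_reads / 2, abs=1)

    def test_zero_reads_empty_table(self, default_annotation):
        cfg0, anno, truth = default_annotation
        cfg = SyntheticConfig(seed=cfg0.seed, srna_reads=0)
        counts, total, tid, site = generate_srna_counts(truth, anno, cfg)
        assert counts.empty and total > 0


class TestSequences:
    def test_lncrnas_have_no_orf_and_decoys_long_orfs(self, default_annotation):
        from natlnc.lncrna_identify import scan_orfs

        cfg, anno, truth = default_annotation
        seqs = generate_sequences(anno, truth, cfg)
        roles = truth.transcripts["role"]
        for tid, role in roles.items():
            assert len(seqs[tid]) == anno[tid].length
            orf_max, _ = scan_orfs(seqs[tid])
            if role in LNC_CLASSES:
                assert orf_max == 0
            elif role == "decoy":
                assert orf_max >= 100
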