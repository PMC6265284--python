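"""A hand-checkable six-transcript example bundle.

The bundle is constructed so that each cascade stage removes exactly one
transcript and two survive:

* ``TOY_KNOWN``  — class code ``=``            -> removed at class_code
* ``TOY_SHORT``  — 140 nt                      -> removed at length_abundance
* ``TOY_CODING`` — qualifying BLASTX hit + ORF -> removed at coding_potential
* ``TOY_SENSE``  — sense exonic overlap with GENE_B -> removed at sense_overlap
* ``TOY_NAT``    — antisense overlap with GENE_A -> survives (NAT_OVERLAPPING)
* ``TOY_LINC``   — isolated                     -> survives (LINCRNA)
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .formats_io import (
    AnnotationSet,
    ExpressionTable,
    GenomicInterval,
    HomologyHit,
    TranscriptRecord,
    write_annotation,
    write_expression_table,
    write_fasta,
    write_homology_hits,
)
from .pipeline import PipelineConfig
from .synthetic_data import _orf_seq, _random_seq, _strip_atg

CHROM = "chr1"


def toy_annotations() -> tuple[AnnotationSet, AnnotationSet]:
    """(assembled, reference) annotations of the six-transcript example."""

    def tx(tid, gid, intervals, strand, code, biotype="unknown"):
        return TranscriptRecord(
            tid, gid,
            tuple(GenomicInterval(CHROM, s, e, strand) for s, e in intervals),
            class_code=code, biotype=biotype,
        )

    reference = AnnotationSet(
        [
            tx("GENE_A.1", "GENE_A", [(1000, 1600), (1900, 2600)], "+", "=",
               "coding"),
            tx("GENE_B.1", "GENE_B", [(10000, 10600), (10900, 11600)], "+", "=",
               "coding"),
        ]
    )
    assembled = AnnotationSet(
        [
            tx("TOY_KNOWN", "TOY_KNOWN", [(5000, 5500)], "+", "="),
            tx("TOY_SHORT", "TOY_SHORT", [(6000, 6140)], "+", "u"),
            tx("TOY_CODING", "TOY_CODING", [(7000, 7600)], "-", "u"),
            tx("TOY_SENSE", "TOY_SENSE", [(11000, 11800)], "+", "u"),
            tx("TOY_NAT", "TOY_NAT", [(2200, 3000)], "-", "x"),
            tx("TOY_LINC", "TOY_LINC", [(20000, 20600)], "+", "u"),
        ]
    )
    return assembled, reference


def toy_expression() -> ExpressionTable:
    ids = ["GENE_A.1", "GENE_B.1", "TOY_KNOWN", "TOY_SHORT", "TOY_CODING",
           "TOY_SENSE", "TOY_NAT", "TOY_LINC"]
    # condition samples track two profiles; fraction samples are flat
    base = {
        "GENE_A.1": [10, 11, 30, 32, 8, 8, 8, 8],
        "GENE_B.1": [5, 6, 14, 15, 4, 4, 4, 4],
        "TOY_KNOWN": [2, 2, 2, 2, 2, 2, 2, 2],
        "TOY_SHORT": [5, 5, 6, 6, 5, 5, 5, 5],
        "TOY_CODING": [9, 9, 10, 10, 9, 9, 9, 9],
        "TOY_SENSE": [3, 3, 4, 4, 3, 3, 3, 3],
        "TOY_NAT": [4, 4.5, 12, 13, 3, 3, 3, 3],
        "TOY_LINC": [7, 7, 2, 2, 6, 6, 6, 6],
    }
    samples = pd.DataFrame(
        dict(
            sample_id=["c1_r1", "c1_r2", "c2_r1", "c2_r2",
                       "polyA_plus_r1", "polyA_plus_r2",
                       "polyA_minus_r1", "polyA_minus_r2"],
            condition=["cond1"] * 2 + ["cond2"] * 2 + ["fraction_assay"] * 4,
            timepoint=[0, 0, 1, 1, 0, 0, 0, 0],
            fraction=["total"] * 4 + ["polyA_plus"] * 2 + ["polyA_minus"] * 2,
            replicate=[1, 2, 1, 2, 1, 2, 1, 2],
        )
    ).set_index("sample_id")
    values = pd.DataFrame(
        {sid: [base[i][k] for i in ids] for k, sid in enumerate(samples.index)},
        index=pd.Index(ids, name="feature_id"), dtype=float,
    )
    return ExpressionTable(values=values, samples=samples)


def toy_sequences() -> dict[str, str]:
    rng = np.random.default_rng(20240101)
    seqs = {}
    for tid, n, coding in [
        ("GENE_A.1", 1300, True), ("GENE_B.1", 1300, True),
        ("TOY_KNOWN", 500, False), ("TOY_SHORT", 140, False),
        ("TOY_CODING", 600, True), ("TOY_SENSE", 800, False),
        ("TOY_NAT", 800, False), ("TOY_LINC", 600, False),
    ]:
        seqs[tid] = _orf_seq(rng, n) if coding else _strip_atg(_random_seq(rng, n))
    return seqs


def toy_hits() -> list[HomologyHit]:
    return [
        HomologyHit("TOY_CODING", "SP_00001", 150, 62.0, 75.0, 20.0, 1e-30),
        # near-miss: one residue short of the alignment-length criterion
        HomologyHit("TOY_LINC", "SP_00002", 39, 88.0, 60.0, 40.0, 1e-20),
    ]


def write_toy_bundle(out_dir: str | Path) -> PipelineConfig:
    """Write the example bundle to disk; returns a ready pipeline config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    assembled, reference = toy_annotations()
    write_annotation(assembled, out / "assembled.gtf")
    write_annotation(reference, out / "reference.gtf")
    write_expression_table(toy_expression(), out / "expression.tsv",
                           out / "samples.tsv")
    write_homology_hits(toy_hits(), out / "hits.tsv")
    write_fasta(toy_sequences(), out / "transcripts.fasta")
    config = PipelineConfig(
        assembled_gtf=str(out / "assembled.gtf"),
        reference_gtf=str(out / "reference.gtf"),
        expression_tsv=str(out / "expression.tsv"),
        sample_sheet_tsv=str(out / "samples.tsv"),
        hits_tsv=str(out / "hits.tsv"),
        fasta=str(out / "transcripts.fasta"),
        out_dir=str(out / "results"),
        kmeans_k=2,
        kmeans_seed=1,
        diff_condition_a="cond2",
        diff_condition_b="cond1",
    )
    config.to_yaml(out / "config.yaml")
    return config
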