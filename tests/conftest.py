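import numpy as np
import pandas as pd
import pytest

from natlnc.examples import write_toy_bundle
from natlnc.formats_io import (
    AnnotationSet,
    ExpressionTable,
    GenomicInterval,
    TranscriptRecord,
)
from natlnc.pipeline import make_fixtures, run_pipeline
from natlnc.synthetic_data import SyntheticConfig, generate_annotation


def make_transcript(tid, intervals, strand="+", chrom="chr1", gene_id=None,
                    class_code="u", biotype="unknown"):
    return TranscriptRecord(
        tid, gene_id or tid,
        tuple(GenomicInterval(chrom, s, e, strand) for s, e in intervals),
        class_code=class_code, biotype=biotype,
    )


def make_gene(gid, intervals, strand="+", chrom="chr1"):
    return make_transcript(f"{gid}.1", intervals, strand, chrom, gene_id=gid,
                           class_code="=", biotype="coding")


def simple_expr(rows: dict, n_reps_meta=None) -> ExpressionTable:
    """ExpressionTable from {feature: [values]} with autogenerated metadata."""
    values = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    values.columns = [f"s{i + 1}" for i in range(values.shape[1])]
    values.index.name = "feature_id"
    samples = pd.DataFrame(
        dict(
            sample_id=list(values.columns),
            condition=[f"c{i + 1}" for i in range(values.shape[1])],
            timepoint=0,
            fraction="total",
            replicate=1,
        )
    ).set_index("sample_id")
    return ExpressionTable(values=values, samples=samples)


def random_lncrnas(coding_anno: AnnotationSet, n: int, rng: np.random.Generator,
                   chrom="chrS"):
    """Random single-exon transcripts avoiding sense (non-intronic) gene overlap,
    the cascade's guarantee for classifier inputs."""
    spans = [coding_anno.gene_span(g) for g in coding_anno.genes]
    extent = max(s.end for s in spans) + 5000
    out = []
    while len(out) < n:
        length = int(rng.integers(200, 1200))
        start = int(rng.integers(0, extent - length))
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        cand = GenomicInterval(chrom, start, start + length, strand)
        sense_clash = False
        for gid in coding_anno.genes:
            gspan = coding_anno.gene_span(gid)
            if gspan.strand == strand and cand.overlap_bp(gspan) > 0:
                if not any(
                    i.contains(cand)
                    for t in coding_anno.gene_transcripts(gid)
                    for i in t.introns()
                ):
                    sense_clash = True
                    break
        if sense_clash:
            continue
        out.append(
            make_transcript(f"RND{len(out):05d}", [(start, start + length)],
                            strand, chrom)
        )
    return out


@pytest.fixture(scope="session")
def toy_bundle(tmp_path_factory):
    d = tmp_path_factory.mktemp("toy")
    config = write_toy_bundle(d)
    return d, config


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """Default synthetic genome (seed 7, 10 transcripts per class) + pipeline run."""
    d = tmp_path_factory.mktemp("bundle")
    config = make_fixtures(d, seed=7, scale="default")
    manifest = run_pipeline(config)
    return d, config, manifest


@pytest.fixture(scope="session")
def default_annotation():
    cfg = SyntheticConfig(seed=7)
    anno, truth = generate_annotation(cfg)
    return cfg, anno, truth
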