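"""End-to-end orchestration: fixtures, stage running, manifest and report.

``run_pipeline`` chains identify -> classify -> enrichment/differential ->
pairs -> sRNA QC on files, writing one TSV per result table plus a
machine-readable manifest (inputs, parameters, output checksums, versions)
and a human-readable report.  All outputs are pure functions of (inputs,
config); re-running with the same config reproduces every file byte for byte.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, NatlncError
from .formats_io import (
    GenomicInterval,
    read_annotation,
    read_expression_table,
    read_fasta,
    read_homology_hits,
    read_srna_counts,
    write_annotation,
    write_expression_table,
    write_fasta,
    write_homology_hits,
    write_srna_counts,
)
from .lncrna_identify import IdentifyParams, assessments_to_dataframe, identify_lncrnas
from .nat_classify import classify_all, records_to_dataframe as class_records_df
from .expression_stats import (
    Contrast,
    differential_call,
    fraction_enrichment,
    kmeans_order,
)
from .coexpression_pairs import (
    assign_pairs,
    compare_pair_categories,
    concordant_set,
    pair_correlations,
    records_to_dataframe as pair_records_df,
)
from .srna_qc import rpm_quantify, secondary_sirna_check
from .synthetic_data import (
    SyntheticConfig,
    generate_annotation,
    generate_expression,
    generate_homology_hits,
    generate_sequences,
    generate_srna_counts,
)


class PipelineStageError(NatlncError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All inputs and tunables of one pipeline run."""

    assembled_gtf: str
    reference_gtf: str
    expression_tsv: str
    sample_sheet_tsv: str
    hits_tsv: str
    fasta: str
    out_dir: str
    srna_counts_tsv: str | None = None
    srna_target_transcript: str | None = None
    srna_target_site: dict | None = None  # chrom/start/end/strand

    min_len: int = 150
    min_fpkm_max: float = 1.0
    evalue_max: float = 1e-4
    min_aln_aa: int = 40
    min_identity: float = 35.0
    min_cov: float = 35.0
    window_bp: int = 1000
    fold_incrna: str = "keep"
    alpha: float = 0.05
    fc_min: float = 2.0
    eps: float = 1.0
    fdr: bool = False
    pcc_min: float = 0.6
    fraction_a: str = "polyA_plus"
    fraction_b: str = "polyA_minus"
    diff_condition_a: str | None = None
    diff_condition_b: str | None = None
    kmeans_k: int = 6
    kmeans_seed: int = 0
    srna_flank_bp: int = 50
    min_outside_rpm: float = 1.0

    def validate(self) -> None:
        required = ["assembled_gtf", "reference_gtf", "expression_tsv",
                    "sample_sheet_tsv", "hits_tsv", "fasta"]
        for name in required:
            p = getattr(self, name)
            if not p:
                raise ConfigurationError(f"config missing input path {name!r}")
            if not Path(p).exists():
                raise ConfigurationError(f"{name}: file not found: {p}")
        if self.srna_counts_tsv and not Path(self.srna_counts_tsv).exists():
            raise ConfigurationError(
                f"srna_counts_tsv: file not found: {self.srna_counts_tsv}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _log(msg: str) -> None:
    print(f"[natlnc] {msg}", file=sys.stderr)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the manifest dict (also written to disk).

    Any stage error aborts with the stage name; outputs written before the
    failure are preserved in the output directory.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    report_lines: list[str] = [f"natlnc {__version__} pipeline report", ""]

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc
            _log(f"stage {name}: {time.perf_counter() - t0:.2f}s")
            return result
        return deco

    def save_df(df: pd.DataFrame, name: str, **to_csv) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=to_csv.pop("index", False), **to_csv)
        outputs[name] = path

    # ---- load ----
    def _load():
        return (
            read_annotation(config.assembled_gtf),
            read_annotation(config.reference_gtf),
            read_expression_table(config.expression_tsv, config.sample_sheet_tsv),
            read_homology_hits(config.hits_tsv),
            read_fasta(config.fasta),
        )

    anno, reference, expr, hits, seqs = stage("load_inputs")(_load)

    # ---- identify ----
    def _identify():
        params = IdentifyParams(
            min_len=config.min_len, min_fpkm_max=config.min_fpkm_max,
            evalue_max=config.evalue_max, min_aln_aa=config.min_aln_aa,
            min_identity=config.min_identity, min_cov=config.min_cov,
        )
        return identify_lncrnas(anno, expr, hits, seqs, reference, params)

    lncs, assessments, filt = stage("identify")(_identify)
    save_df(filt.to_dataframe(), "filter_report.tsv")
    save_df(filt.removal_reasons(), "filter_removals.tsv")
    save_df(assessments_to_dataframe(assessments), "coding_assessment.tsv")
    report_lines.append("Filter cascade:")
    for s in filt.stages:
        report_lines.append(
            f"  {s.name}: in {s.n_in}, removed {s.n_removed}, out {s.n_out}"
        )

    # ---- classify ----
    def _classify():
        return classify_all(lncs, reference, config.window_bp, config.fold_incrna)

    records, summary = stage("classify")(_classify)
    save_df(class_records_df(records), "classification.tsv")
    save_df(
        pd.DataFrame(sorted(summary.items()), columns=["lnc_class", "n"]),
        "class_summary.tsv",
    )
    for r in records:
        lncs[r.transcript_id].lnc_class = r.lnc_class
    write_annotation(lncs, out / "lncrna.gtf")
    outputs["lncrna.gtf"] = out / "lncrna.gtf"
    report_lines.append("")
    report_lines.append("LncRNA classes: " + ", ".join(
        f"{c}={n}" for c, n in sorted(summary.items())
    ))

    # ---- fraction enrichment ----
    def _enrich():
        lnc_expr_ids = [t for t in lncs.transcripts if t in expr.values.index]
        sub = expr.values.loc[lnc_expr_ids]
        sub_expr = dataclasses.replace(expr, values=sub)
        return fraction_enrichment(
            sub_expr, config.fraction_a, config.fraction_b,
            config.alpha, config.fc_min, config.eps, config.fdr,
        )

    calls, counts = stage("fraction_enrichment")(_enrich)
    save_df(calls, "enrichment.tsv", index=True)
    report_lines.append("")
    report_lines.append(
        f"Fraction enrichment ({config.fraction_a} vs {config.fraction_b}): "
        f"{counts['enriched_a']} enriched in {config.fraction_a}, "
        f"{counts['enriched_b']} in {config.fraction_b}, {counts['ns']} ns"
    )

    # ---- optional condition contrast ----
    if config.diff_condition_a and config.diff_condition_b:
        def _diff():
            ga = expr.samples_where(condition=config.diff_condition_a)
            gb = expr.samples_where(condition=config.diff_condition_b)
            contrast = Contrast(
                tuple(ga), tuple(gb),
                label=f"{config.diff_condition_a}_vs_{config.diff_condition_b}",
            )
            lnc_ids = [t for t in lncs.transcripts if t in expr.values.index]
            sub_expr = dataclasses.replace(expr, values=expr.values.loc[lnc_ids])
            return differential_call(
                sub_expr, contrast, config.alpha, config.fc_min, config.eps,
                config.fdr,
            )

        diff = stage("differential")(_diff)
        save_df(diff, "diffexp.tsv", index=True)
        n_de = int((diff["status"] != "ns").sum())
        report_lines.append(
            f"Differential ({config.diff_condition_a} vs "
            f"{config.diff_condition_b}): {n_de} lncRNAs"
        )

    # ---- heatmap ordering ----
    def _cluster():
        total = expr.samples_where(fraction="total")
        lnc_ids = [t for t in lncs.transcripts if t in expr.values.index]
        prof = expr.values.loc[lnc_ids, total]
        by_cond = prof.T.groupby(expr.samples.loc[total, "condition"]).mean().T
        k = min(config.kmeans_k, len(by_cond))
        return kmeans_order(by_cond, k, config.kmeans_seed)

    clus = stage("cluster")(_cluster)
    save_df(
        pd.DataFrame(
            dict(feature_id=clus.order,
                 cluster=[clus.labels[f] for f in clus.order])
        ),
        "cluster_order.tsv",
    )

    # ---- neighbour pairs ----
    def _pairs():
        pairs = assign_pairs(records, reference, lncs, config.window_bp)
        pair_recs = pair_correlations(pairs, expr, reference, config.min_fpkm_max)
        return pairs, pair_recs

    pairs, pair_recs = stage("pairs")(_pairs)
    save_df(pair_records_df(pair_recs), "pairs.tsv")
    scored = [r for r in pair_recs if not r.excluded]
    cats = sorted({r.pair_type for r in scored})
    cat_rows = []
    for ca in cats:
        for cb in cats:
            if ca == cb:
                continue
            res = compare_pair_categories(pair_recs, ca, cb)
            cat_rows.append(
                dict(cat_a=ca, cat_b=cb, pvalue=res["pvalue"],
                     median_a=res["summary_a"]["median"],
                     median_b=res["summary_b"]["median"],
                     n_a=res["summary_a"]["n"], n_b=res["summary_b"]["n"])
            )
    save_df(pd.DataFrame(cat_rows), "category_comparison.tsv")
    summary_rows = []
    for c in cats:
        vals = [r.pcc for r in scored if r.pair_type == c]
        s = pd.Series(vals)
        summary_rows.append(
            dict(pair_type=c, n=len(vals), median_pcc=s.median(),
                 q1=s.quantile(0.25), q3=s.quantile(0.75))
        )
    save_df(pd.DataFrame(summary_rows), "category_summary.tsv")
    conc = concordant_set(pair_recs, config.pcc_min, "NCO")
    save_df(pair_records_df(conc), "concordant_pairs.tsv")
    report_lines.append("")
    report_lines.append(
        f"Neighbour pairs: {len(scored)} scored, "
        f"{len(pair_recs) - len(scored)} excluded; "
        f"{len(conc)} concordant NCO pairs (pcc > {config.pcc_min})"
    )

    # ---- sRNA QC ----
    if config.srna_counts_tsv and config.srna_target_transcript:
        def _srna():
            counts, total_mapped = read_srna_counts(config.srna_counts_tsv)
            target = anno[config.srna_target_transcript]
            d = config.srna_target_site
            site = GenomicInterval(d["chrom"], int(d["start"]), int(d["end"]),
                                   d["strand"])
            site_stat = rpm_quantify(counts, total_mapped, site)
            check = secondary_sirna_check(
                counts, total_mapped, target, site,
                config.srna_flank_bp, config.min_outside_rpm,
            )
            return dict(
                target_transcript=target.transcript_id,
                site_rpm=site_stat.rpm,
                secondary_sirna_detected=bool(check["detected"]),
                inside_rpm=check["inside_rpm"],
                outside_rpm=check["outside_rpm"],
            )

        srna_result = stage("srna_qc")(_srna)
        path = out / "srna_qc.json"
        path.write_text(json.dumps(srna_result, indent=2, sort_keys=True) + "\n")
        outputs["srna_qc.json"] = path
        report_lines.append("")
        report_lines.append(
            f"sRNA QC on {srna_result['target_transcript']}: secondary siRNAs "
            f"{'DETECTED' if srna_result['secondary_sirna_detected'] else 'not detected'} "
            f"(outside RPM {srna_result['outside_rpm']:.2f})"
        )

    (out / "report.txt").write_text("\n".join(report_lines) + "\n")
    outputs["report.txt"] = out / "report.txt"

    manifest = dict(
        natlnc_version=__version__,
        config=dataclasses.asdict(config),
        inputs={
            name: _sha256(Path(getattr(config, name)))
            for name in ("assembled_gtf", "reference_gtf", "expression_tsv",
                         "sample_sheet_tsv", "hits_tsv", "fasta")
        },
        outputs={name: _sha256(path) for name, path in sorted(outputs.items())},
    )
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

SCALES = {
    "tiny": dict(n_coding_genes=24, n_per_lnc_class=2, n_decoys=2, n_cc_pairs=2,
                 n_enriched=4, n_conditions=4),
    "default": {},
}


def make_fixtures(
    out_dir: str | Path,
    seed: int = 7,
    scale: str = "default",
    cfg: SyntheticConfig | None = None,
) -> PipelineConfig:
    """Write a ready-to-run synthetic input bundle and its pipeline config."""
    if cfg is None:
        if scale not in SCALES:
            raise ConfigurationError(f"unknown scale {scale!r}")
        cfg = SyntheticConfig(seed=seed, **SCALES[scale])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    anno, truth = generate_annotation(cfg)
    expr = generate_expression(truth, cfg)
    hits = generate_homology_hits(truth, cfg)
    seqs = generate_sequences(anno, truth, cfg)
    srna, total_mapped, target_tid, site = generate_srna_counts(truth, anno, cfg)

    write_annotation(anno, out / "assembled.gtf")
    coding = anno.subset(
        [t.transcript_id for t in anno if t.biotype == "coding"]
    )
    write_annotation(coding, out / "reference.gtf")
    write_expression_table(expr, out / "expression.tsv", out / "samples.tsv")
    write_homology_hits(hits, out / "hits.tsv")
    write_fasta(seqs, out / "transcripts.fasta")
    write_srna_counts(srna, total_mapped, out / "srna_counts.tsv")
    truth.to_files(out / "truth.tsv", out / "truth_pairs.tsv")

    conditions = sorted(set(expr.samples["condition"]) - {"fraction_assay"})
    config = PipelineConfig(
        assembled_gtf=str(out / "assembled.gtf"),
        reference_gtf=str(out / "reference.gtf"),
        expression_tsv=str(out / "expression.tsv"),
        sample_sheet_tsv=str(out / "samples.tsv"),
        hits_tsv=str(out / "hits.tsv"),
        fasta=str(out / "transcripts.fasta"),
        srna_counts_tsv=str(out / "srna_counts.tsv"),
        srna_target_transcript=target_tid,
        srna_target_site=dict(chrom=site.chrom, start=site.start, end=site.end,
                              strand=site.strand),
        out_dir=str(out / "results"),
        window_bp=cfg.pairing_window_bp,
        diff_condition_a=conditions[1] if len(conditions) > 1 else None,
        diff_condition_b=conditions[0] if len(conditions) > 1 else None,
        kmeans_k=4,
        kmeans_seed=seed,
    )
    config.to_yaml(out / "config.yaml")
    return config
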