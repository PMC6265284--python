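"""Synthetic annotation, expression, homology and sRNA inputs with planted truth.

The generator lays planted loci sequentially along one synthetic chromosome
with guard spacing so that every geometric decision downstream (overlap,
divergent/convergent pairing, lincRNA isolation) is unambiguous: no planted
feature sits within ``class_margin_bp`` of a pairing-window boundary, and
consecutive loci are separated by more than ``pairing_window_bp +
class_margin_bp`` so no accidental neighbour relationships arise.

Expression follows a log-normal model: per-feature baseline + per-condition
effects (bivariate-normal correlated within planted pairs) + replicate noise,
all on the log2 scale, with FPKM = 2**value.  Fraction enrichment is planted
as a mean log2 offset between the two fraction sample groups.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .formats_io import (
    AnnotationSet,
    ExpressionTable,
    GenomicInterval,
    HomologyHit,
    TranscriptRecord,
)

CHROM = "chrS"

LNC_CLASSES = ("NAT_OVERLAPPING", "NAT_DIVERGENT", "NAT_CONVERGENT", "LINCRNA", "INCRNA")
#: assembler class code each planted class would receive
CLASS_CODES = {
    "NAT_OVERLAPPING": "x",
    "NAT_DIVERGENT": "u",
    "NAT_CONVERGENT": "u",
    "LINCRNA": "u",
    "INCRNA": "i",
    "decoy": "u",
}

STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
)


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic data bundle.

    Defaults mirror the conditions the pipeline is validated under: 120 coding
    genes (40 of them lncRNA partners, 60 in planted coding-coding pairs),
    10 planted lncRNAs per class, nine conditions x three replicates,
    strong within-pair correlation for overlapping NAT pairs (rho_nco = 0.8)
    against uncorrelated background pairs, a 3 log2-unit poly(A) fraction
    effect, and replicate noise of 0.2 log2 units.
    """

    n_coding_genes: int = 120
    n_per_lnc_class: int = 10
    n_decoys: int = 10
    n_cc_pairs: int = 10
    n_enriched: int = 30
    chrom_length: int | None = None
    pairing_window_bp: int = 1000
    class_margin_bp: int = 200
    n_conditions: int = 9
    n_replicates: int = 3
    rho_nco: float = 0.8
    rho_other: float = 0.0
    enrichment_log2fc: float = 3.0
    noise_sd: float = 0.2
    cond_effect_sd: float = 1.5
    srna_reads: int = 10000
    srna_total_mapped: int = 1_000_000
    srna_spread_fraction: float = 0.0
    seed: int = 7

    def validate(self) -> None:
        counts = dict(
            n_coding_genes=self.n_coding_genes,
            n_per_lnc_class=self.n_per_lnc_class,
            n_conditions=self.n_conditions,
            n_replicates=self.n_replicates,
        )
        for name, v in counts.items():
            if v < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {v}")
        for name in ("n_decoys", "n_cc_pairs", "n_enriched"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("rho_nco", "rho_other"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.class_margin_bp < 1:
            raise ConfigurationError("class_margin_bp must be >= 1")
        if self.pairing_window_bp < 4 * self.class_margin_bp:
            raise ConfigurationError(
                "pairing_window_bp must be >= 4 * class_margin_bp for unambiguous "
                "divergent/convergent gaps"
            )
        if self.n_enriched > self.n_per_lnc_class * len(LNC_CLASSES):
            raise ConfigurationError("n_enriched exceeds number of planted lncRNAs")
        needed = 4 * self.n_per_lnc_class + 6 * self.n_cc_pairs
        if self.n_coding_genes < needed:
            raise ConfigurationError(
                f"n_coding_genes={self.n_coding_genes} too small: "
                f"{needed} genes are consumed as lncRNA partners and CC pairs"
            )
        if not (0 <= self.srna_spread_fraction <= 1):
            raise ConfigurationError("srna_spread_fraction must be in [0, 1]")


@dataclass
class TruthTable:
    """Planted ground truth: per-transcript roles and per-pair correlations."""

    transcripts: pd.DataFrame  # index transcript_id; role, gene_id, partner_gene_id, enriched_fraction
    pairs: pd.DataFrame  # a_id, b_id, a_feature, b_feature, pair_type, rho

    def lnc_ids(self) -> list[str]:
        mask = self.transcripts["role"].isin(LNC_CLASSES)
        return list(self.transcripts.index[mask])

    def to_files(self, transcripts_path, pairs_path) -> None:
        self.transcripts.to_csv(transcripts_path, sep="\t", index_label="transcript_id")
        self.pairs.to_csv(pairs_path, sep="\t", index=False)


def _rng(cfg: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

_GENE_E1, _GENE_INTRON, _GENE_E2 = 600, 300, 700
_HOST_INTRON = 1400  # intron length of incRNA host genes


def _gene_exons(start: int, strand: str, intron: int = _GENE_INTRON):
    return [
        (start, start + _GENE_E1, strand),
        (start + _GENE_E1 + intron, start + _GENE_E1 + intron + _GENE_E2, strand),
    ]


def _gene_len(intron: int = _GENE_INTRON) -> int:
    return _GENE_E1 + intron + _GENE_E2


def generate_annotation(cfg: SyntheticConfig) -> tuple[AnnotationSet, TruthTable]:
    """Generate the planted genome annotation and its truth table.

    The assembled annotation contains the coding genes (class code ``=``,
    biotype coding), one lncRNA per planted class per ``n_per_lnc_class``,
    coding-potential decoys (class ``u``), and planted coding-coding pairs in
    the three pair geometries.  Deterministic given ``cfg.seed``.
    """
    cfg.validate()
    rng = _rng(cfg, 0)
    window, margin = cfg.pairing_window_bp, cfg.class_margin_bp

    # each block: list of feature dicts with block-local coordinates
    blocks: list[list[dict]] = []
    truth_rows: list[dict] = []
    pair_rows: list[dict] = []
    gene_n = 0
    lnc_n = {c: 0 for c in LNC_CLASSES}

    def new_gene_id() -> str:
        nonlocal gene_n
        gene_n += 1
        return f"G{gene_n:04d}"

    def gene_feature(gid: str, start: int, strand: str, intron: int = _GENE_INTRON) -> dict:
        return dict(
            tid=f"{gid}.1", gid=gid, strand=strand, class_code="=", biotype="coding",
            exons=[(s, e) for s, e, _ in _gene_exons(start, strand, intron)],
            role="coding", partner="",
        )

    def lnc_feature(cls: str, exons: list[tuple[int, int]], strand: str,
                    partner: str) -> dict:
        lnc_n[cls] += 1
        tid = f"LNC_{cls}_{lnc_n[cls]:04d}"
        return dict(
            tid=tid, gid=tid, strand=strand, class_code=CLASS_CODES[cls],
            biotype="unknown", exons=exons, role=cls, partner=partner,
        )

    def rand_strand() -> str:
        return "+" if rng.integers(0, 2) == 0 else "-"

    def lnc_len() -> int:
        return int(rng.integers(300, 801))

    def gap_bp() -> int:
        # kept clear of both window boundaries by class_margin_bp
        return int(rng.integers(margin, window - margin))

    n_lone_genes = (cfg.n_coding_genes
                    - 4 * cfg.n_per_lnc_class  # genes used as lnc partners
                    - 2 * 3 * cfg.n_cc_pairs)  # genes used in CC pairs

    for _ in range(n_lone_genes):
        blocks.append([gene_feature(new_gene_id(), 0, rand_strand())])

    for _ in range(cfg.n_per_lnc_class):  # overlapping NATs
        gid, s = new_gene_id(), rand_strand()
        g = gene_feature(gid, 0, s)
        ov = int(rng.integers(margin, 600))
        L = ov + int(rng.integers(200, 600))
        if s == "+":  # lnc on '-', overlaps gene 3' end, extends right
            exons = [(_gene_len() - ov, _gene_len() - ov + L)]
            lnc = lnc_feature("NAT_OVERLAPPING", exons, "-", gid)
        else:  # gene 3' end at local 0, lnc on '+' extends left
            exons = [(ov - L, ov)]
            lnc = lnc_feature("NAT_OVERLAPPING", exons, "+", gid)
        blocks.append([g, lnc])

    for _ in range(cfg.n_per_lnc_class):  # divergent (head-to-head)
        gid, s = new_gene_id(), rand_strand()
        g = gene_feature(gid, 0, s)
        d, L = gap_bp(), lnc_len()
        if s == "+":  # gene 5' at 0; lnc on '-' to the left, 5' end at -d
            lnc = lnc_feature("NAT_DIVERGENT", [(-d - L, -d)], "-", gid)
        else:  # gene 5' at its end; lnc on '+' to the right
            g_end = _gene_len()
            lnc = lnc_feature("NAT_DIVERGENT", [(g_end + d, g_end + d + L)], "+", gid)
        blocks.append([g, lnc])

    for _ in range(cfg.n_per_lnc_class):  # convergent (tail-to-tail)
        gid, s = new_gene_id(), rand_strand()
        g = gene_feature(gid, 0, s)
        d, L = gap_bp(), lnc_len()
        if s == "+":  # gene 3' at its end; lnc on '-' to the right, 3' at end+d
            g_end = _gene_len()
            lnc = lnc_feature("NAT_CONVERGENT", [(g_end + d, g_end + d + L)], "-", gid)
        else:  # gene 3' at 0; lnc on '+' to the left
            lnc = lnc_feature("NAT_CONVERGENT", [(-d - L, -d)], "+", gid)
        blocks.append([g, lnc])

    for _ in range(cfg.n_per_lnc_class):  # intronic, same strand as host
        gid, s = new_gene_id(), rand_strand()
        g = gene_feature(gid, 0, s, intron=_HOST_INTRON)
        L = min(lnc_len(), _HOST_INTRON - 2 * margin)
        lo = _GENE_E1 + margin
        hi = _GENE_E1 + _HOST_INTRON - margin - L
        start = int(rng.integers(lo, hi + 1))
        lnc = lnc_feature("INCRNA", [(start, start + L)], s, gid)
        blocks.append([g, lnc])

    for _ in range(cfg.n_per_lnc_class):  # lincRNAs, isolated
        L = lnc_len()
        blocks.append([lnc_feature("LINCRNA", [(0, L)], rand_strand(), "")])

    decoy_ids = []
    for k in range(cfg.n_decoys):
        tid = f"DECOY_{k + 1:04d}"
        decoy_ids.append(tid)
        L = int(rng.integers(600, 901))
        blocks.append([dict(tid=tid, gid=tid, strand=rand_strand(), class_code="u",
                            biotype="unknown", exons=[(0, L)], role="decoy",
                            partner="")])

    cc_specs = []
    for geom in ("CCO", "CCD", "CCC"):
        for _ in range(cfg.n_cc_pairs):
            ga, gb = new_gene_id(), new_gene_id()
            if geom == "CCO":
                ov = int(rng.integers(margin, 600))
                a = gene_feature(ga, 0, "+")
                b = gene_feature(gb, _gene_len() - ov, "-")
            elif geom == "CCD":
                d = gap_bp()
                a = gene_feature(ga, 0, "-")
                b = gene_feature(gb, _gene_len() + d, "+")
            else:  # CCC
                d = gap_bp()
                a = gene_feature(ga, 0, "+")
                b = gene_feature(gb, _gene_len() + d, "-")
            blocks.append([a, b])
            cc_specs.append((ga, gb, geom))

    # ---- place blocks along the chromosome with guard spacing -------------
    features: list[dict] = []
    cursor = margin
    for block in blocks:
        lo = min(s for f in block for s, _ in f["exons"])
        shift = cursor - lo
        hi = 0
        for f in block:
            f["exons"] = [(s + shift, e + shift) for s, e in f["exons"]]
            hi = max(hi, max(e for _, e in f["exons"]))
            features.append(f)
        cursor = hi + window + margin + int(rng.integers(500, 1500))

    needed = cursor
    if cfg.chrom_length is not None and cfg.chrom_length < needed:
        raise ConfigurationError(
            f"chrom_length={cfg.chrom_length} too short; need >= {needed} bp "
            "to place all loci without accidental adjacency"
        )

    anno = AnnotationSet(source="natlnc_synthetic")
    for f in features:
        anno.add(
            TranscriptRecord(
                transcript_id=f["tid"],
                gene_id=f["gid"],
                exons=tuple(
                    GenomicInterval(CHROM, s, e, f["strand"]) for s, e in f["exons"]
                ),
                class_code=f["class_code"],
                biotype=f["biotype"],
            )
        )
        truth_rows.append(
            dict(transcript_id=f["tid"], role=f["role"], gene_id=f["gid"],
                 partner_gene_id=f["partner"], enriched_fraction="")
        )

    truth_tx = pd.DataFrame(truth_rows).set_index("transcript_id")

    # planted fraction enrichment: a deterministic subset of lncRNAs
    lnc_ids = sorted(truth_tx.index[truth_tx["role"].isin(LNC_CLASSES)])
    enriched = rng.choice(lnc_ids, size=cfg.n_enriched, replace=False)
    truth_tx.loc[sorted(enriched), "enriched_fraction"] = "polyA_plus"

    # planted pairs (within-block) with their correlations
    def tx_of_gene(gid: str) -> str:
        return f"{gid}.1"

    for tid, row in truth_tx[truth_tx["partner_gene_id"] != ""].iterrows():
        role = row["role"]
        pair_type = {"NAT_OVERLAPPING": "NCO", "NAT_DIVERGENT": "NCD",
                     "NAT_CONVERGENT": "NCC", "INCRNA": "INC"}.get(role)
        if pair_type is None:
            continue
        rho = cfg.rho_nco if pair_type == "NCO" else cfg.rho_other
        pair_rows.append(
            dict(a_id=tid, b_id=row["partner_gene_id"], a_feature=tid,
                 b_feature=tx_of_gene(row["partner_gene_id"]),
                 pair_type=pair_type, rho=rho)
        )
    for ga, gb, geom in cc_specs:
        pair_rows.append(
            dict(a_id=ga, b_id=gb, a_feature=tx_of_gene(ga), b_feature=tx_of_gene(gb),
                 pair_type=geom, rho=cfg.rho_other)
        )

    pairs = pd.DataFrame(
        pair_rows,
        columns=["a_id", "b_id", "a_feature", "b_feature", "pair_type", "rho"],
    )
    return anno, TruthTable(transcripts=truth_tx, pairs=pairs)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def generate_expression(truth: TruthTable, cfg: SyntheticConfig) -> ExpressionTable:
    """Generate the replicate FPKM matrix implied by the truth table.

    Correlated per-condition effects are drawn jointly for each planted pair;
    the two fraction sample groups share one extra condition effect and differ
    only by the planted enrichment offset.
    """
    cfg.validate()
    rng = _rng(cfg, 1)
    feats = list(truth.transcripts.index)
    pos = {f: i for i, f in enumerate(feats)}
    for col in ("a_feature", "b_feature"):
        unknown = set(truth.pairs[col]) - set(pos)
        if unknown:
            raise ValidationError(f"truth/config mismatch: unknown features {unknown}")
    paired_b = list(truth.pairs["b_feature"])
    if len(set(paired_b)) != len(paired_b):
        raise ValidationError("truth/config mismatch: feature in multiple pairs")

    F = len(feats)
    C = cfg.n_conditions + 1  # +1 shared effect for the fraction assay
    mu = rng.uniform(3.0, 7.0, size=F)
    Z = rng.standard_normal((F, C))
    for _, p in truth.pairs.iterrows():
        ia, ib, rho = pos[p["a_feature"]], pos[p["b_feature"]], float(p["rho"])
        Z[ib] = rho * Z[ia] + math.sqrt(1.0 - rho**2) * Z[ib]
    E = cfg.cond_effect_sd * Z

    enr = np.zeros(F)
    enriched = truth.transcripts["enriched_fraction"] == "polyA_plus"
    enr[[pos[f] for f in truth.transcripts.index[enriched]]] = cfg.enrichment_log2fc

    cols: dict[str, np.ndarray] = {}
    sheet_rows = []

    def add_sample(sid: str, logv: np.ndarray, condition: str, timepoint: int,
                   fraction: str, replicate: int) -> None:
        noise = cfg.noise_sd * rng.standard_normal(F) if cfg.noise_sd > 0 else 0.0
        cols[sid] = np.exp2(logv + noise)
        sheet_rows.append(dict(sample_id=sid, condition=condition,
                               timepoint=timepoint, fraction=fraction,
                               replicate=replicate))

    for c in range(cfg.n_conditions):
        for r in range(1, cfg.n_replicates + 1):
            add_sample(f"cond{c + 1:02d}_r{r}", mu + E[:, c], f"cond{c + 1:02d}",
                       c, "total", r)
    for sign, frac in ((+0.5, "polyA_plus"), (-0.5, "polyA_minus")):
        for r in range(1, cfg.n_replicates + 1):
            add_sample(f"{frac}_r{r}", mu + E[:, -1] + sign * enr,
                       "fraction_assay", 0, frac, r)

    values = pd.DataFrame(cols, index=pd.Index(feats, name="feature_id"))
    samples = pd.DataFrame(sheet_rows).set_index("sample_id")
    return ExpressionTable(values=values, samples=samples)


# ---------------------------------------------------------------------------
# homology hits
# ---------------------------------------------------------------------------

def generate_homology_hits(truth: TruthTable, cfg: SyntheticConfig) -> list[HomologyHit]:
    """Plant protein-homology evidence.

    Coding transcripts and coding-potential decoys each get one hit passing
    all criteria (e-value < 1e-4, >= 40 aa, >= 35% identity, >= 35% coverage);
    roughly half of the true lncRNAs get a near-miss hit failing exactly one
    criterion, the rest get no hit.
    """
    cfg.validate()
    rng = _rng(cfg, 2)
    hits: list[HomologyHit] = []
    for tid, row in truth.transcripts.iterrows():
        role = row["role"]
        if role in ("coding", "decoy"):
            hits.append(
                HomologyHit(
                    query_id=tid, subject_id=f"SP_{rng.integers(10000, 99999)}",
                    aln_len_aa=int(rng.integers(80, 201)),
                    pct_identity=float(rng.uniform(45, 75)),
                    query_cov_pct=float(rng.uniform(50, 90)),
                    subject_cov_pct=float(rng.uniform(10, 30)),
                    evalue=float(10.0 ** -rng.integers(10, 41)),
                )
            )
        elif role in LNC_CLASSES and rng.integers(0, 2) == 1:
            fail = rng.integers(0, 3)
            hits.append(
                HomologyHit(
                    query_id=tid, subject_id=f"SP_{rng.integers(10000, 99999)}",
                    aln_len_aa=39 if fail == 0 else int(rng.integers(40, 80)),
                    pct_identity=30.0 if fail == 1 else float(rng.uniform(40, 60)),
                    query_cov_pct=20.0 if fail == 2 else float(rng.uniform(40, 60)),
                    subject_cov_pct=10.0,
                    evalue=1e-8,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _strip_atg(seq: str) -> str:
    # replacing the T with C cannot create a new ATG (ATG has no C)
    i = seq.find("ATG")
    while i != -1:
        seq = seq[: i + 1] + "C" + seq[i + 2:]
        i = seq.find("ATG")
    return seq


def _orf_seq(rng: np.random.Generator, n: int) -> str:
    """Sequence of length n whose first ATG opens an ORF covering ~90% of it."""
    leader = _strip_atg(_random_seq(rng, int(rng.integers(3, 16))))
    trailer_len = max(0, (n - len(leader) - 6) % 3) + 6
    n_codons = (n - len(leader) - 6 - trailer_len) // 3
    codons = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons)]
    body = "ATG" + "".join(codons) + "TAA"
    trailer = _strip_atg(_random_seq(rng, n - len(leader) - len(body)))
    return leader + body + trailer


def generate_sequences(anno: AnnotationSet, truth: TruthTable,
                       cfg: SyntheticConfig) -> dict[str, str]:
    """Per-transcript sequences: ORF-rich for coding/decoy, ATG-free otherwise."""
    rng = _rng(cfg, 4)
    seqs: dict[str, str] = {}
    for tid, row in truth.transcripts.iterrows():
        n = anno[tid].length
        if row["role"] in ("coding", "decoy"):
            seqs[tid] = _orf_seq(rng, n)
        else:
            seqs[tid] = _strip_atg(_random_seq(rng, n))
    return seqs


# ---------------------------------------------------------------------------
# sRNA region counts
# ---------------------------------------------------------------------------

def generate_srna_counts(
    truth: TruthTable,
    anno: AnnotationSet,
    cfg: SyntheticConfig,
    flank_bp: int = 50,
) -> tuple[pd.DataFrame, int, str, GenomicInterval]:
    """sRNA region counts around an amiRNA target site on one planted NAT.

    With ``srna_spread_fraction = 0`` all reads fall inside the 21-nt target
    window (no secondary siRNAs); a positive fraction spreads that share of
    reads across the transcript body outside the window +/- flank.
    Returns (counts, total_mapped, target_transcript_id, target_site).
    """
    cfg.validate()
    rng = _rng(cfg, 3)
    nat_ids = sorted(
        truth.transcripts.index[truth.transcripts["role"] == "NAT_OVERLAPPING"]
    )
    if not nat_ids:
        raise ConfigurationError("no planted NAT_OVERLAPPING transcript to target")
    target = anno[nat_ids[0]]
    span = target.span
    mid = (span.start + span.end) // 2
    site = GenomicInterval(span.chrom, mid - 10, mid + 11, span.strand)

    rows: list[tuple] = []
    inside = int(round(cfg.srna_reads * (1 - cfg.srna_spread_fraction)))
    outside = cfg.srna_reads - inside
    if inside > 0:
        rows.append((span.chrom, site.start, site.end, span.strand, inside))
    if outside > 0:
        regions = []
        if site.start - flank_bp - 21 >= span.start:
            regions.append((span.start, site.start - flank_bp))
        if site.end + flank_bp + 21 <= span.end:
            regions.append((site.end + flank_bp, span.end))
        if not regions:
            raise ConfigurationError("target transcript too short to spread reads")
        windows = []
        for lo, hi in regions:
            p = lo
            while p + 21 <= hi:
                windows.append((p, p + 21))
                p += 21
        picks = rng.integers(0, len(windows), size=min(len(windows), 10))
        per = np.zeros(len(windows), dtype=int)
        for i, w in enumerate(np.unique(picks)):
            per[w] = outside // len(np.unique(picks))
        per[np.unique(picks)[0]] += outside - per.sum()
        for (lo, hi), c in zip(windows, per):
            if c > 0:
                rows.append((span.chrom, lo, hi, span.strand, int(c)))

    counts = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "count"])
    return counts, cfg.srna_total_mapped, target.transcript_id, site
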