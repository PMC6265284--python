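"""Neighbour-pair co-expression analysis.

Pairs come in seven categories: CCO/CCD/CCC (adjacent protein-coding gene
pairs that are overlapped / divergent / convergent), NCO/NCD/NCC (a NAT-lncRNA
and its cognate or closest gene in the same three geometries) and LC (a
lincRNA and its closest gene).  Pearson correlation is computed across all
samples between the lncRNA's FPKM vector and the gene-level FPKM vector of
its partner (gene level = sum of isoform FPKM); pairs where either member has
FPKM_max below the abundance floor, or a zero-variance vector, are excluded
with a reason.  Category distributions are compared with a one-tailed
Mann-Whitney U test: exact enumeration over all rank assignments when both
categories have <= 8 members, normal approximation with tie and continuity
correction otherwise.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ValidationError
from .formats_io import AnnotationSet, ExpressionTable
from .nat_classify import ClassificationRecord, _genes_of, _head_to_head_gap, _tail_to_tail_gap

PAIR_TYPES = ("CCO", "CCD", "CCC", "NCO", "NCD", "NCC", "LC")

_CLASS_TO_PAIR = {
    "NAT_OVERLAPPING": "NCO",
    "NAT_DIVERGENT": "NCD",
    "NAT_CONVERGENT": "NCC",
    "LINCRNA": "LC",
}


@dataclass(frozen=True)
class PairRecord:
    a_id: str  # lncRNA transcript or coding gene
    b_id: str  # coding gene
    pair_type: str
    pcc: float | None
    n_samples: int
    excluded: bool
    reason: str = ""

    def __post_init__(self) -> None:
        if self.pair_type not in PAIR_TYPES:
            raise ValidationError(f"unknown pair type {self.pair_type!r}")
        if self.excluded == (self.pcc is not None):
            raise ValidationError("pcc must be present iff the pair is scored")
        if self.pcc is not None and not (-1.0000001 <= self.pcc <= 1.0000001):
            raise ValidationError(f"|pcc| > 1: {self.pcc}")


# ---------------------------------------------------------------------------
# pair assignment
# ---------------------------------------------------------------------------

def _nearest_gene(span, genes) -> str | None:
    best = None
    for g in genes:
        if g.chrom != span.chrom:
            continue
        gap = max(g.start - span.end, span.start - g.end, 0)
        cand = (gap, g.gene_id)
        if best is None or cand < best:
            best = cand
    return best[1] if best else None


def assign_pairs(
    class_records: Iterable[ClassificationRecord],
    coding_anno: AnnotationSet,
    lncs: AnnotationSet,
    window_bp: int = 1000,
) -> list[tuple[str, str, str]]:
    """Build (a_id, b_id, pair_type) tuples.

    NCO/NCD/NCC come from classification partners; LC pairs a lincRNA with its
    closest gene (span gap on either strand, ties by smaller gene_id); CC*
    pairs are immediately adjacent coding genes typed by the NAT geometry
    rules.  Each unordered pair appears once.
    """
    pairs: dict[tuple[str, str], str] = {}

    def put(a: str, b: str, ptype: str) -> None:
        pairs.setdefault(tuple(sorted((a, b))), ptype)

    genes = _genes_of(coding_anno)
    for rec in class_records:
        ptype = _CLASS_TO_PAIR.get(rec.lnc_class)
        if ptype is None:  # INCRNA pairs are not part of the seven categories
            continue
        partner = rec.partner_gene_id
        if ptype == "LC":
            partner = partner or _nearest_gene(lncs[rec.transcript_id].span, genes)
            if partner is None:
                continue
        put(rec.transcript_id, partner, ptype)

    # adjacent coding-coding pairs, typed by the same geometry rules
    per_chrom: dict[str, list] = {}
    for g in genes:
        per_chrom.setdefault(g.chrom, []).append(g)
    for chrom_genes in per_chrom.values():
        chrom_genes.sort(key=lambda g: (g.start, g.gene_id))
        for a, b in zip(chrom_genes, chrom_genes[1:]):
            ov = min(a.end, b.end) - max(a.start, b.start)
            if ov > 0:
                put(a.gene_id, b.gene_id, "CCO")
                continue
            if a.strand == b.strand:
                continue
            gap = b.start - a.end
            if gap > window_bp:
                continue
            # left gene transcribed away from the gap => tails or heads flank it
            if a.strand == "-" and b.strand == "+":
                put(a.gene_id, b.gene_id, "CCD")  # 5' ends flank the gap
            elif a.strand == "+" and b.strand == "-":
                put(a.gene_id, b.gene_id, "CCC")  # 3' ends flank the gap
    return [(a, b, t) for (a, b), t in sorted(pairs.items())]


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def gene_level_expression(expr: ExpressionTable,
                          coding_anno: AnnotationSet) -> pd.DataFrame:
    """Gene-level FPKM: sum of member-isoform rows (genes x samples)."""
    rows = {}
    for gid, tids in coding_anno.genes.items():
        present = [t for t in tids if t in expr.values.index]
        if present:
            rows[gid] = expr.values.loc[present].sum(axis=0)
    return pd.DataFrame(rows).T if rows else pd.DataFrame(columns=expr.values.columns)


def pair_correlations(
    pairs: Iterable[tuple[str, str, str]],
    expr: ExpressionTable,
    coding_anno: AnnotationSet,
    min_fpkm_max: float = 1.0,
    samples: list[str] | None = None,
) -> list[PairRecord]:
    """Pearson correlation per pair over all samples (or a sample subset).

    Exclusion reasons: ``missing expression`` (a member absent from the
    matrix), ``low abundance`` (FPKM_max < min_fpkm_max for a member,
    computed over all samples), ``constant`` (zero variance in a member's
    vector over the used samples).
    """
    gene_expr = gene_level_expression(expr, coding_anno)
    cols = list(expr.values.columns) if samples is None else list(samples)

    def vector(feature: str):
        if feature in gene_expr.index:
            full = gene_expr.loc[feature]
        elif feature in expr.values.index:
            full = expr.values.loc[feature]
        else:
            return None, None
        return full[cols].to_numpy(dtype=float), float(full.max())

    records = []
    for a_id, b_id, ptype in pairs:
        va, amax = vector(a_id)
        vb, bmax = vector(b_id)
        if va is None or vb is None:
            missing = a_id if va is None else b_id
            records.append(PairRecord(a_id, b_id, ptype, None, 0, True,
                                      f"missing expression: {missing}"))
            continue
        if amax < min_fpkm_max or bmax < min_fpkm_max:
            low = a_id if amax < min_fpkm_max else b_id
            records.append(PairRecord(a_id, b_id, ptype, None, len(cols), True,
                                      f"low abundance: FPKM_max({low}) < "
                                      f"{min_fpkm_max}"))
            continue
        if np.ptp(va) == 0 or np.ptp(vb) == 0:
            records.append(PairRecord(a_id, b_id, ptype, None, len(cols), True,
                                      "constant"))
            continue
        pcc = float(stats.pearsonr(va, vb).statistic)
        records.append(PairRecord(a_id, b_id, ptype, pcc, len(cols), False))
    return records


# ---------------------------------------------------------------------------
# Mann-Whitney comparison
# ---------------------------------------------------------------------------

def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for H1 'x stochastically greater than y' (ties count 1/2)."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mannwhitney_one_tailed(x, y, exact_max_n: int = 8) -> float:
    """One-tailed Mann-Whitney p-value for H1: x stochastically greater than y.

    Exact enumeration over all C(n+m, n) rank assignments when both samples
    have at most ``exact_max_n`` observations; otherwise the normal
    approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ConfigurationError("Mann-Whitney requires non-empty samples")
    if len(x) <= exact_max_n and len(y) <= exact_max_n:
        pooled = np.concatenate([x, y])
        n = len(x)
        u_obs = _u_statistic(x, y)
        idx = range(len(pooled))
        hits = total = 0
        for comb in combinations(idx, n):
            mask = np.zeros(len(pooled), dtype=bool)
            mask[list(comb)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if u >= u_obs - 1e-12:
                hits += 1
        return hits / total
    res = stats.mannwhitneyu(
        x, y, alternative="greater", use_continuity=True, method="asymptotic"
    )
    return float(res.pvalue)


def _box_summary(values: np.ndarray) -> dict[str, float]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo = values[values >= q1 - 1.5 * iqr].min()
    hi = values[values <= q3 + 1.5 * iqr].max()
    return dict(median=float(med), q1=float(q1), q3=float(q3),
                whisker_low=float(lo), whisker_high=float(hi),
                n=int(len(values)))


def compare_pair_categories(
    records: Iterable[PairRecord],
    cat_a: str,
    cat_b: str,
) -> dict:
    """One-tailed Mann-Whitney comparison of two categories' pcc distributions.

    Tests H1: pcc of ``cat_a`` stochastically greater than ``cat_b``.  Returns
    the p-value plus boxplot summaries (median, quartiles, 1.5xIQR whiskers).
    """
    by_cat: dict[str, list[float]] = {cat_a: [], cat_b: []}
    for r in records:
        if not r.excluded and r.pair_type in by_cat:
            by_cat[r.pair_type].append(r.pcc)
    for cat in (cat_a, cat_b):
        if not by_cat[cat]:
            raise ConfigurationError(f"category {cat!r} has no scored pairs")
    a = np.array(by_cat[cat_a])
    b = np.array(by_cat[cat_b])
    return dict(
        cat_a=cat_a, cat_b=cat_b,
        pvalue=mannwhitney_one_tailed(a, b),
        summary_a=_box_summary(a), summary_b=_box_summary(b),
    )


def concordant_set(
    records: Iterable[PairRecord],
    pcc_min: float = 0.6,
    pair_type: str = "NCO",
) -> list[PairRecord]:
    """Pairs of the requested type with pcc strictly greater than pcc_min."""
    return [
        r for r in records
        if not r.excluded and r.pair_type == pair_type and r.pcc > pcc_min
    ]


def records_to_dataframe(records: Iterable[PairRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(a_id=r.a_id, b_id=r.b_id, pair_type=r.pair_type,
                 pcc="" if r.pcc is None else r.pcc, n_samples=r.n_samples,
                 excluded=r.excluded, reason=r.reason)
            for r in records
        ],
        columns=["a_id", "b_id", "pair_type", "pcc", "n_samples", "excluded",
                 "reason"],
    )
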