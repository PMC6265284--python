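"""Strand-aware classification of lncRNAs relative to protein-coding genes.

Each lncRNA receives exactly one class, decided in priority order:

1. ``NAT_OVERLAPPING`` — span overlap of >= 1 bp with an opposite-strand
   coding gene (exon-exon overlap recorded as a flag, not required);
2. ``INCRNA`` — contained entirely within an intron of a same-strand gene;
3. ``NAT_DIVERGENT`` — nearest opposite-strand non-overlapping gene in
   head-to-head geometry (the two 5' ends flank the gap) within the window;
4. ``NAT_CONVERGENT`` — likewise tail-to-tail (the two 3' ends flank the gap);
5. ``LINCRNA`` — otherwise (the nearest gene is recorded as annotation only).

Partner ties are broken by largest overlap (rule 1), then smallest gap, then
lexicographically smallest gene_id.  ``brute_force_classify`` re-implements
the same contract by exhaustive scan with no index structures and serves as
the testing oracle for the indexed classifier.
"""
from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .errors import ConfigurationError, ValidationError
from .formats_io import AnnotationSet, GenomicInterval, TranscriptRecord

LNC_CLASS_NAMES = (
    "NAT_OVERLAPPING", "NAT_DIVERGENT", "NAT_CONVERGENT", "LINCRNA", "INCRNA"
)


@dataclass(frozen=True)
class ClassificationRecord:
    transcript_id: str
    lnc_class: str
    partner_gene_id: str | None
    overlap_bp: int = 0
    end_gap_bp: int | None = None
    exonic_overlap: bool = False

    def __post_init__(self) -> None:
        if self.lnc_class not in LNC_CLASS_NAMES:
            raise ValidationError(f"unknown lncRNA class {self.lnc_class!r}")
        if self.lnc_class.startswith("NAT") or self.lnc_class == "INCRNA":
            if self.partner_gene_id is None:
                raise ValidationError(f"{self.lnc_class} requires a partner gene")
        if (self.overlap_bp > 0) != (
            self.lnc_class in ("NAT_OVERLAPPING", "INCRNA")
        ):
            raise ValidationError(
                f"overlap_bp={self.overlap_bp} inconsistent with {self.lnc_class}"
            )


@dataclass(frozen=True)
class _Gene:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int


def _genes_of(coding_anno: AnnotationSet) -> list[_Gene]:
    genes = []
    for gid in coding_anno.genes:
        span = coding_anno.gene_span(gid)
        genes.append(_Gene(gid, span.chrom, span.strand, span.start, span.end))
    return genes


def _head_to_head_gap(lnc: TranscriptRecord, g: _Gene) -> int | None:
    """Gap if gene and lnc are non-overlapping head-to-head (5' ends flank it)."""
    if g.strand == lnc.strand:
        return None
    if lnc.strand == "+":
        # lnc 5' at span.start; opposite-strand gene 5' at its end, to the left
        gap = lnc.span.start - g.end
    else:
        gap = g.start - lnc.span.end
    return gap if gap >= 0 else None


def _tail_to_tail_gap(lnc: TranscriptRecord, g: _Gene) -> int | None:
    """Gap if gene and lnc are non-overlapping tail-to-tail (3' ends flank it)."""
    if g.strand == lnc.strand:
        return None
    if lnc.strand == "+":
        gap = g.start - lnc.span.end
    else:
        gap = lnc.span.start - g.end
    return gap if gap >= 0 else None


def _intron_containing(lnc: TranscriptRecord, coding_anno: AnnotationSet,
                       gid: str) -> bool:
    return any(
        intron.contains(lnc.span)
        for t in coding_anno.gene_transcripts(gid)
        for intron in t.introns()
    )


def _exonic_overlap(lnc: TranscriptRecord, coding_anno: AnnotationSet,
                    gid: str) -> bool:
    return any(
        le.overlap_bp(ge) > 0
        for t in coding_anno.gene_transcripts(gid)
        for ge in t.exons
        for le in lnc.exons
    )


class ClassifierIndex:
    """Sorted-endpoint index over coding-gene spans for fast classification."""

    def __init__(self, coding_anno: AnnotationSet,
                 known_chroms: Iterable[str] | None = None):
        self.coding_anno = coding_anno
        self.genes = _genes_of(coding_anno)
        self.known_chroms = set(known_chroms) if known_chroms is not None else {
            g.chrom for g in self.genes
        }
        self._by_start: dict[str, list[_Gene]] = {}
        self._starts: dict[str, list[int]] = {}
        self._prefix_max_end: dict[str, list[int]] = {}
        self._by_end: dict[str, list[_Gene]] = {}
        self._ends: dict[str, list[int]] = {}
        per_chrom: dict[str, list[_Gene]] = {}
        for g in self.genes:
            per_chrom.setdefault(g.chrom, []).append(g)
        for chrom, gs in per_chrom.items():
            by_start = sorted(gs, key=lambda g: (g.start, g.gene_id))
            self._by_start[chrom] = by_start
            self._starts[chrom] = [g.start for g in by_start]
            pme, m = [], -1
            for g in by_start:
                m = max(m, g.end)
                pme.append(m)
            self._prefix_max_end[chrom] = pme
            by_end = sorted(gs, key=lambda g: (g.end, g.gene_id))
            self._by_end[chrom] = by_end
            self._ends[chrom] = [g.end for g in by_end]

    # --- queries -----------------------------------------------------------

    def overlapping(self, span: GenomicInterval) -> list[_Gene]:
        """Genes whose span overlaps the query span by >= 1 bp (any strand)."""
        by_start = self._by_start.get(span.chrom, [])
        if not by_start:
            return []
        hi = bisect.bisect_left(self._starts[span.chrom], span.end)
        out = []
        pme = self._prefix_max_end[span.chrom]
        for i in range(hi - 1, -1, -1):
            if pme[i] <= span.start:
                break  # nothing further left can reach the query
            if by_start[i].end > span.start:
                out.append(by_start[i])
        return out

    def left_of(self, pos: int, chrom: str, max_gap: int) -> list[_Gene]:
        """Genes with end in [pos - max_gap, pos] (gap to `pos` <= max_gap)."""
        ends = self._ends.get(chrom, [])
        lo = bisect.bisect_left(ends, pos - max_gap)
        hi = bisect.bisect_right(ends, pos)
        return self._by_end[chrom][lo:hi]

    def right_of(self, pos: int, chrom: str, max_gap: int) -> list[_Gene]:
        """Genes with start in [pos, pos + max_gap]."""
        starts = self._starts.get(chrom, [])
        lo = bisect.bisect_left(starts, pos)
        hi = bisect.bisect_right(starts, pos + max_gap)
        return self._by_start[chrom][lo:hi]

    def nearest(self, span: GenomicInterval) -> tuple[str, int] | None:
        """Nearest non-overlapping gene by span gap; ties to smaller gene_id."""
        best: tuple[int, str] | None = None
        ends = self._ends.get(span.chrom, [])
        starts = self._starts.get(span.chrom, [])
        i = bisect.bisect_right(ends, span.start)
        if i > 0:
            gap = span.start - ends[i - 1]
            cands = [g for g in self._by_end[span.chrom] if g.end == ends[i - 1]]
            best = (gap, min(c.gene_id for c in cands))
        j = bisect.bisect_left(starts, span.end)
        if j < len(starts):
            gap = starts[j] - span.end
            cands = [g for g in self._by_start[span.chrom] if g.start == starts[j]]
            cand = (gap, min(c.gene_id for c in cands))
            if best is None or cand < best:
                best = cand
        if best is None:
            return None
        return best[1], best[0]


def classify_lncrna(
    lnc: TranscriptRecord,
    coding_anno: AnnotationSet | ClassifierIndex,
    window_bp: int = 1000,
) -> ClassificationRecord:
    """Classify one lncRNA against the coding annotation (see module rules)."""
    index = (
        coding_anno
        if isinstance(coding_anno, ClassifierIndex)
        else ClassifierIndex(coding_anno)
    )
    span = lnc.span
    if span.chrom not in index.known_chroms:
        raise ValidationError(
            f"{lnc.transcript_id}: chromosome {span.chrom!r} unknown to annotation"
        )

    hits = index.overlapping(span)

    # rule 1: antisense span overlap
    anti = [g for g in hits if g.strand != lnc.strand]
    if anti:
        ovs = {g.gene_id: min(span.end, g.end) - max(span.start, g.start)
               for g in anti}
        best_ov = max(ovs.values())
        best = min(
            (g for g in anti if ovs[g.gene_id] == best_ov),
            key=lambda g: g.gene_id,
        )
        ov = best_ov
        return ClassificationRecord(
            lnc.transcript_id, "NAT_OVERLAPPING", best.gene_id, overlap_bp=ov,
            exonic_overlap=_exonic_overlap(lnc, index.coding_anno, best.gene_id),
        )

    # rule 2: sense intron containment
    sense = sorted(
        (g for g in hits if g.strand == lnc.strand
         and _intron_containing(lnc, index.coding_anno, g.gene_id)),
        key=lambda g: g.gene_id,
    )
    if sense:
        return ClassificationRecord(
            lnc.transcript_id, "INCRNA", sense[0].gene_id, overlap_bp=span.length
        )

    # rules 3-4: divergent then convergent within the window
    for rule, cls in ((_head_to_head_gap, "NAT_DIVERGENT"),
                      (_tail_to_tail_gap, "NAT_CONVERGENT")):
        if lnc.strand == "+":
            near = index.left_of(span.start, span.chrom, window_bp) \
                if rule is _head_to_head_gap \
                else index.right_of(span.end, span.chrom, window_bp)
        else:
            near = index.right_of(span.end, span.chrom, window_bp) \
                if rule is _head_to_head_gap \
                else index.left_of(span.start, span.chrom, window_bp)
        cands = []
        for g in near:
            gap = rule(lnc, g)
            if gap is not None and gap <= window_bp:
                cands.append((gap, g.gene_id))
        if cands:
            gap, gid = min(cands)
            return ClassificationRecord(
                lnc.transcript_id, cls, gid, end_gap_bp=gap
            )

    # rule 5: lincRNA; record the nearest gene as annotation only
    nearest = index.nearest(span)
    return ClassificationRecord(
        lnc.transcript_id, "LINCRNA",
        nearest[0] if nearest else None,
        end_gap_bp=nearest[1] if nearest else None,
    )


def brute_force_classify(
    lnc: TranscriptRecord,
    coding_anno: AnnotationSet,
    window_bp: int = 1000,
    known_chroms: Iterable[str] | None = None,
) -> ClassificationRecord:
    """Same contract as :func:`classify_lncrna` by exhaustive scan (oracle)."""
    genes = _genes_of(coding_anno)
    chroms = set(known_chroms) if known_chroms is not None else {
        g.chrom for g in genes
    }
    span = lnc.span
    if span.chrom not in chroms:
        raise ValidationError(
            f"{lnc.transcript_id}: chromosome {span.chrom!r} unknown to annotation"
        )

    overlapping = []
    for g in genes:
        if g.chrom != span.chrom:
            continue
        ov = min(span.end, g.end) - max(span.start, g.start)
        if ov > 0:
            overlapping.append((g, ov))

    anti = [(g, ov) for g, ov in overlapping if g.strand != lnc.strand]
    if anti:
        # largest overlap, then smallest gene_id
        anti.sort(key=lambda t: (-t[1], t[0].gene_id))
        g, ov = anti[0]
        return ClassificationRecord(
            lnc.transcript_id, "NAT_OVERLAPPING", g.gene_id, overlap_bp=ov,
            exonic_overlap=_exonic_overlap(lnc, coding_anno, g.gene_id),
        )

    intronic = sorted(
        g.gene_id
        for g, _ in overlapping
        if g.strand == lnc.strand and _intron_containing(lnc, coding_anno, g.gene_id)
    )
    if intronic:
        return ClassificationRecord(
            lnc.transcript_id, "INCRNA", intronic[0], overlap_bp=span.length
        )

    for rule, cls in ((_head_to_head_gap, "NAT_DIVERGENT"),
                      (_tail_to_tail_gap, "NAT_CONVERGENT")):
        cands = []
        for g in genes:
            if g.chrom != span.chrom:
                continue
            if min(span.end, g.end) - max(span.start, g.start) > 0:
                continue  # non-overlapping only
            gap = rule(lnc, g)
            if gap is not None and gap <= window_bp:
                cands.append((gap, g.gene_id))
        if cands:
            gap, gid = min(cands)
            return ClassificationRecord(lnc.transcript_id, cls, gid, end_gap_bp=gap)

    best = None
    for g in genes:
        if g.chrom != span.chrom:
            continue
        if min(span.end, g.end) - max(span.start, g.start) > 0:
            continue  # nearest-gene annotation considers non-overlapping genes
        gap = max(g.start - span.end, span.start - g.end)
        cand = (gap, g.gene_id)
        if best is None or cand < best:
            best = cand
    return ClassificationRecord(
        lnc.transcript_id, "LINCRNA",
        best[1] if best else None,
        end_gap_bp=best[0] if best else None,
    )


def classify_all(
    lncs: AnnotationSet,
    coding_anno: AnnotationSet,
    window_bp: int = 1000,
    fold_incrna: str = "keep",
) -> tuple[list[ClassificationRecord], dict[str, int]]:
    """Classify every lncRNA; returns records plus a per-class count summary.

    ``fold_incrna`` controls the final taxonomy for sense-intronic
    transcripts: ``keep`` reports INCRNA as its own class, ``lincRNA`` folds
    it into LINCRNA, ``drop`` removes those records.
    """
    if fold_incrna not in ("keep", "lincRNA", "drop"):
        raise ConfigurationError(f"fold_incrna={fold_incrna!r}")
    index = ClassifierIndex(
        coding_anno, known_chroms=coding_anno.chroms() | lncs.chroms()
    )
    records = []
    for t in sorted(lncs, key=lambda t: t.transcript_id):
        rec = classify_lncrna(t, index, window_bp)
        if rec.lnc_class == "INCRNA" and fold_incrna != "keep":
            if fold_incrna == "drop":
                continue
            rec = ClassificationRecord(
                rec.transcript_id, "LINCRNA", rec.partner_gene_id
            )
        records.append(rec)
    summary = {c: 0 for c in LNC_CLASS_NAMES}
    for r in records:
        summary[r.lnc_class] += 1
    return records, summary


def records_to_dataframe(records: Iterable[ClassificationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                transcript_id=r.transcript_id,
                lnc_class=r.lnc_class,
                partner_gene_id=r.partner_gene_id or "",
                overlap_bp=r.overlap_bp,
                end_gap_bp="" if r.end_gap_bp is None else r.end_gap_bp,
                exonic_overlap=r.exonic_overlap,
            )
            for r in records
        ],
        columns=["transcript_id", "lnc_class", "partner_gene_id", "overlap_bp",
                 "end_gap_bp", "exonic_overlap"],
    )
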