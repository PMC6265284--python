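"""The lncRNA identification cascade.

Four ordered stages turn an assembled transcriptome into a lncRNA candidate
set:

1. class-code retention — only assembler class codes ``u`` (intergenic),
   ``x`` (antisense exonic overlap) and ``i`` (intronic) are kept; transcripts
   tagged as known ncRNAs in the input are dropped here too;
2. length/abundance — transcripts shorter than 150 nt or with maximum FPKM
   across all samples below 1 are dropped (strict inequalities);
3. coding potential — a transcript is coding if it has a qualifying protein
   homology hit (e-value < 1e-4, alignment >= 40 aa, identity >= 35%,
   coverage of query or subject >= 35%) OR a positive signed
   coding-potential score;
4. sense-overlap — transcripts whose span overlaps a protein-coding gene on
   the same strand are dropped, except transcripts fully contained within a
   single intron of that gene (those are the sense-intronic candidates the
   downstream classifier labels incRNA).

Every stage conserves counts (n_in = n_removed + n_out) and records a removal
reason per transcript.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import pandas as pd

from .errors import ValidationError
from .formats_io import AnnotationSet, ExpressionTable, HomologyHit, TranscriptRecord

RETAINED_CLASS_CODES = ("u", "x", "i")

_VALID_SEQ = re.compile(r"^[ACGTUN]*$")
STOPS = frozenset(("TAA", "TAG", "TGA"))


# ---------------------------------------------------------------------------
# report plumbing
# ---------------------------------------------------------------------------

@dataclass
class StageReport:
    name: str
    n_in: int
    removals: dict[str, str]  # transcript_id -> reason

    @property
    def n_removed(self) -> int:
        return len(self.removals)

    @property
    def n_out(self) -> int:
        return self.n_in - self.n_removed


@dataclass
class FilterReport:
    """Ordered per-stage accounting of the cascade."""

    stages: list[StageReport] = field(default_factory=list)

    def add(self, stage: StageReport) -> None:
        if self.stages and stage.n_in != self.stages[-1].n_out:
            raise ValidationError(
                f"stage {stage.name!r}: n_in={stage.n_in} does not chain from "
                f"previous n_out={self.stages[-1].n_out}"
            )
        self.stages.append(stage)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(stage=s.name, n_in=s.n_in, n_removed=s.n_removed, n_out=s.n_out)
                for s in self.stages
            ]
        )

    def removal_reasons(self) -> pd.DataFrame:
        rows = [
            dict(transcript_id=t, stage=s.name, reason=r)
            for s in self.stages
            for t, r in sorted(s.removals.items())
        ]
        return pd.DataFrame(rows, columns=["transcript_id", "stage", "reason"])


@dataclass
class CodingAssessment:
    """Per-transcript coding evidence and the final verdict."""

    transcript_id: str
    homology_coding: bool
    qualifying_hit: HomologyHit | None
    orf_max_aa: int
    cp_score: float

    @property
    def coding(self) -> bool:
        return self.homology_coding or self.cp_score > 0


# ---------------------------------------------------------------------------
# stage 1: class codes
# ---------------------------------------------------------------------------

def class_code_filter(
    anno: AnnotationSet,
) -> tuple[list[TranscriptRecord], dict[str, str]]:
    """Keep class codes u/x/i; everything else is a known/other transcript.

    Transcripts tagged biotype=known_ncRNA in the input are removed here as
    well (known ncRNA catalogs are consumed as input tags).
    """
    retained, removed = [], {}
    for t in anno:
        if t.biotype == "known_ncRNA":
            removed[t.transcript_id] = "known ncRNA biotype"
        elif t.class_code in RETAINED_CLASS_CODES:
            retained.append(t)
        else:
            removed[t.transcript_id] = "known/other class code"
    return retained, removed


# ---------------------------------------------------------------------------
# stage 2: length / abundance
# ---------------------------------------------------------------------------

def length_abundance_filter(
    transcripts: Iterable[TranscriptRecord],
    expr: ExpressionTable,
    min_len: int = 150,
    min_fpkm_max: float = 1.0,
) -> tuple[list[TranscriptRecord], dict[str, str]]:
    """Remove transcripts with length < min_len or FPKM_max < min_fpkm_max.

    FPKM_max is the maximum FPKM over all samples.  Transcripts absent from
    the expression matrix have undefined FPKM_max and are removed with their
    own reason code.
    """
    retained, removed = [], {}
    vals = expr.values
    for t in transcripts:
        if t.length < min_len:
            removed[t.transcript_id] = f"length {t.length} < {min_len} nt"
        elif t.transcript_id not in vals.index:
            removed[t.transcript_id] = "absent from expression matrix"
        elif (fmax := float(vals.loc[t.transcript_id].max())) < min_fpkm_max:
            removed[t.transcript_id] = f"FPKM_max {fmax:.4g} < {min_fpkm_max}"
        else:
            retained.append(t)
    return retained, removed


# ---------------------------------------------------------------------------
# stage 3: coding potential
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Orf:
    frame: int  # 0..2
    start_nt: int  # 0-based offset of the ATG in the transcript sequence
    aa_len: int  # residues including Met, excluding the stop
    has_stop: bool


def scan_orfs(seq: str) -> tuple[int, list[Orf]]:
    """Scan the three forward frames of an already-stranded transcript.

    An ORF runs from an ATG to the first in-frame stop (excluded from the
    length); an ATG with no downstream in-frame stop yields an open-ended ORF
    flagged ``has_stop=False``.  ``N`` never matches a start or stop codon.
    Returns (longest ORF length in aa, all maximal ORFs per frame).
    """
    seq = seq.upper().replace("U", "T")
    if not _VALID_SEQ.match(seq):
        bad = sorted(set(seq) - set("ACGTUN"))
        raise ValidationError(f"invalid sequence characters: {bad}")
    orfs: list[Orf] = []
    for frame in range(3):
        i = frame
        while i + 3 <= len(seq):
            if seq[i: i + 3] == "ATG":
                aa = 0
                j = i
                has_stop = False
                while j + 3 <= len(seq):
                    codon = seq[j: j + 3]
                    if codon in STOPS:
                        has_stop = True
                        break
                    aa += 1
                    j += 3
                orfs.append(Orf(frame=frame, start_nt=i, aa_len=aa, has_stop=has_stop))
                i = j + 3 if has_stop else len(seq)  # next ORF after this stop
            else:
                i += 3
    orf_max = max((o.aa_len for o in orfs), default=0)
    return orf_max, orfs


def homology_coding_filter(
    transcript_id: str,
    hits: Iterable[HomologyHit],
    evalue_max: float = 1e-4,
    min_aln_aa: int = 40,
    min_identity: float = 35.0,
    min_cov: float = 35.0,
) -> tuple[bool, HomologyHit | None]:
    """True iff some hit passes all criteria (hit thresholds are inclusive).

    Coverage is satisfied if either query or subject coverage reaches the
    threshold; the e-value gate is strict (< evalue_max).
    """
    for h in hits:
        if h.query_id != transcript_id:
            raise ValidationError(
                f"hit for {h.query_id!r} passed to filter for {transcript_id!r}"
            )
        if (
            h.evalue < evalue_max
            and h.aln_len_aa >= min_aln_aa
            and h.pct_identity >= min_identity
            and max(h.query_cov_pct, h.subject_cov_pct) >= min_cov
        ):
            return True, h
    return False, None


def builtin_cp_scorer(transcript: TranscriptRecord, seq: str) -> float:
    """Signed coding-potential score from ORF features (positive => coding).

    The score is a monotone sum of three centred terms: longest-ORF length
    (centred at 100 aa), ORF coverage of the transcript (centred at 0.5) and
    ORF integrity (presence of a stop codon).  A transcript with
    orf_max_aa < 100 and coverage < 0.5 always scores negative.  This honours
    the sign contract of a coding-potential calculator without reproducing any
    particular tool's score values.
    """
    orf_max, orfs = scan_orfs(seq)
    n = max(len(seq), 1)
    coverage = (3 * orf_max + 3) / n if orf_max > 0 else 0.0
    best = max((o for o in orfs if o.aa_len == orf_max), default=None,
               key=lambda o: o.has_stop)
    integrity = 1.0 if (best is not None and best.has_stop) else 0.0
    return (orf_max / 100.0 - 1.0) + (min(coverage, 1.0) / 0.5 - 1.0) \
        + 0.5 * (integrity - 1.0)


Scorer = Callable[[TranscriptRecord, str], float]


def score_coding_potential(
    transcript: TranscriptRecord, seq: str, scorer: Scorer | None = None
) -> float:
    """Apply a pluggable signed coding-potential scorer (positive => coding)."""
    scorer = scorer or builtin_cp_scorer
    try:
        return float(scorer(transcript, seq))
    except Exception as exc:
        raise ValidationError(
            f"coding-potential scorer failed for {transcript.transcript_id}: {exc}"
        ) from exc


# ---------------------------------------------------------------------------
# stage 4: sense overlap
# ---------------------------------------------------------------------------

def _contained_in_intron(t: TranscriptRecord, gene_transcripts) -> bool:
    return any(
        intron.contains(t.span)
        for gt in gene_transcripts
        for intron in gt.introns()
    )


def sense_overlap_filter(
    transcripts: Iterable[TranscriptRecord],
    coding_anno: AnnotationSet,
    exempt_intron_contained: bool = True,
) -> tuple[list[TranscriptRecord], dict[str, str]]:
    """Remove transcripts span-overlapping a coding gene on the same strand.

    Antisense overlap is retained.  By default a transcript fully contained
    within a single intron of the overlapped gene is exempt: such sense-
    intronic transcripts are classified (not discarded) downstream.
    """
    for t in coding_anno:
        if t.biotype != "coding":
            raise ValidationError(
                f"coding annotation contains non-coding transcript {t.transcript_id}"
            )
    gene_spans = {g: coding_anno.gene_span(g) for g in coding_anno.genes}
    retained, removed = [], {}
    for t in transcripts:
        reason = None
        for gid, gspan in gene_spans.items():
            if gspan.strand != t.strand or t.span.overlap_bp(gspan) == 0:
                continue
            if exempt_intron_contained and _contained_in_intron(
                t, coding_anno.gene_transcripts(gid)
            ):
                continue
            reason = f"sense overlap with {gid}"
            break
        if reason is None:
            retained.append(t)
        else:
            removed[t.transcript_id] = reason
    return retained, removed


# ---------------------------------------------------------------------------
# the full cascade
# ---------------------------------------------------------------------------

@dataclass
class IdentifyParams:
    min_len: int = 150
    min_fpkm_max: float = 1.0
    evalue_max: float = 1e-4
    min_aln_aa: int = 40
    min_identity: float = 35.0
    min_cov: float = 35.0
    scorer: Scorer | None = None
    exempt_intron_contained: bool = True


def identify_lncrnas(
    anno: AnnotationSet,
    expr: ExpressionTable,
    hits: Iterable[HomologyHit],
    seqs: Mapping[str, str],
    coding_anno: AnnotationSet,
    params: IdentifyParams | None = None,
) -> tuple[AnnotationSet, list[CodingAssessment], FilterReport]:
    """Run the four-stage cascade and return survivors, evidence and report."""
    params = params or IdentifyParams()
    report = FilterReport()

    current, removed = class_code_filter(anno)
    report.add(StageReport("class_code", len(anno), removed))

    current, removed = length_abundance_filter(
        current, expr, params.min_len, params.min_fpkm_max
    )
    report.add(StageReport("length_abundance", report.stages[-1].n_out, removed))

    hits_by_tx: dict[str, list[HomologyHit]] = {}
    for h in hits:
        hits_by_tx.setdefault(h.query_id, []).append(h)

    assessments: list[CodingAssessment] = []
    survivors, removed = [], {}
    for t in current:
        tid = t.transcript_id
        if tid not in seqs:
            raise ValidationError(f"stage coding_potential: no sequence for {tid}")
        hom, qhit = homology_coding_filter(
            tid, hits_by_tx.get(tid, ()), params.evalue_max, params.min_aln_aa,
            params.min_identity, params.min_cov,
        )
        orf_max, _ = scan_orfs(seqs[tid])
        cp = score_coding_potential(t, seqs[tid], params.scorer)
        a = CodingAssessment(tid, hom, qhit, orf_max, cp)
        assessments.append(a)
        if a.coding:
            why = []
            if hom:
                why.append(f"homology hit to {qhit.subject_id}")
            if cp > 0:
                why.append(f"coding-potential score {cp:.3g} > 0")
            removed[tid] = "; ".join(why)
        else:
            survivors.append(t)
    report.add(StageReport("coding_potential", report.stages[-1].n_out, removed))

    survivors, removed = sense_overlap_filter(
        survivors, coding_anno, params.exempt_intron_contained
    )
    report.add(StageReport("sense_overlap", report.stages[-1].n_out, removed))

    lnc = AnnotationSet(source=anno.source)
    for t in survivors:
        lnc.add(
            TranscriptRecord(
                transcript_id=t.transcript_id, gene_id=t.gene_id, exons=t.exons,
                class_code=t.class_code, biotype="unknown", lnc_class=t.lnc_class,
            )
        )
    return lnc, assessments, report


def assessments_to_dataframe(assessments: Iterable[CodingAssessment]) -> pd.DataFrame:
    rows = []
    for a in assessments:
        rows.append(
            dict(
                transcript_id=a.transcript_id,
                homology_coding=a.homology_coding,
                qualifying_hit=a.qualifying_hit.subject_id if a.qualifying_hit else "",
                orf_max_aa=a.orf_max_aa,
                cp_score=a.cp_score,
                coding=a.coding,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["transcript_id", "homology_coding", "qualifying_hit", "orf_max_aa",
                 "cp_score", "coding"],
    )
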