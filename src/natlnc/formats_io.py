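"""Domain types and readers/writers for every external format the pipeline touches.

Internal coordinates are 0-based half-open on both strands; GTF input/output
(1-based, inclusive) is the single point of conversion.  All readers validate
and reject rather than silently coercing bad values.

Homology hits use the BLAST tabular dialect ``outfmt 6`` extended with two
coverage columns (see :func:`read_homology_hits`).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

from .errors import ParseError, ValidationError

BIOTYPES = ("coding", "known_ncRNA", "unknown")

SAMPLE_SHEET_COLUMNS = ("condition", "timepoint", "fraction", "replicate")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Strand-agnostic span overlap in bp (0 if different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class TranscriptRecord:
    """A stranded, exon-structured transcript carrying its assembler class code."""

    transcript_id: str
    gene_id: str
    exons: tuple
    class_code: str = "="
    biotype: str = "unknown"
    lnc_class: str | None = None

    def __post_init__(self) -> None:
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        if not exons:
            raise ValidationError(f"{self.transcript_id}: transcript needs >=1 exon")
        chroms = {e.chrom for e in exons}
        strands = {e.strand for e in exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValidationError(
                f"{self.transcript_id}: exons span multiple chromosomes/strands"
            )
        for a, b in zip(exons, exons[1:]):
            if a.end > b.start:
                raise ValidationError(f"{self.transcript_id}: overlapping exons")
        if self.biotype not in BIOTYPES:
            raise ValidationError(
                f"{self.transcript_id}: biotype {self.biotype!r} not in {BIOTYPES}"
            )
        self.exons = exons

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def length(self) -> int:
        """Transcript length: sum of exon lengths (nt)."""
        return sum(e.length for e in self.exons)

    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out

    @property
    def five_prime(self) -> int:
        """Coordinate of the 5' end (TSS)."""
        return self.span.start if self.strand == "+" else self.span.end

    @property
    def three_prime(self) -> int:
        """Coordinate of the 3' end (TTS)."""
        return self.span.end if self.strand == "+" else self.span.start


class AnnotationSet:
    """A collection of transcripts keyed by transcript_id, grouped by gene_id."""

    def __init__(self, transcripts: Iterable[TranscriptRecord] = (), source: str = "natlnc"):
        self._transcripts: dict[str, TranscriptRecord] = {}
        self.genes: dict[str, list[str]] = {}
        self.source = source
        for t in transcripts:
            self.add(t)

    def add(self, t: TranscriptRecord) -> None:
        if t.transcript_id in self._transcripts:
            raise ValidationError(f"duplicate transcript_id {t.transcript_id!r}")
        self._transcripts[t.transcript_id] = t
        self.genes.setdefault(t.gene_id, []).append(t.transcript_id)

    @property
    def transcripts(self) -> dict[str, TranscriptRecord]:
        return self._transcripts

    def __len__(self) -> int:
        return len(self._transcripts)

    def __iter__(self) -> Iterator[TranscriptRecord]:
        return iter(self._transcripts.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._transcripts

    def __getitem__(self, transcript_id: str) -> TranscriptRecord:
        return self._transcripts[transcript_id]

    def subset(self, transcript_ids: Iterable[str]) -> "AnnotationSet":
        return AnnotationSet(
            (self._transcripts[i] for i in transcript_ids), source=self.source
        )

    def gene_transcripts(self, gene_id: str) -> list[TranscriptRecord]:
        return [self._transcripts[i] for i in self.genes[gene_id]]

    def gene_span(self, gene_id: str) -> GenomicInterval:
        """Union span over all member transcripts of the gene."""
        ts = self.gene_transcripts(gene_id)
        chrom, strand = ts[0].chrom, ts[0].strand
        return GenomicInterval(
            chrom,
            min(t.span.start for t in ts),
            max(t.span.end for t in ts),
            strand,
        )

    def chroms(self) -> set[str]:
        return {t.chrom for t in self}


@dataclass
class ExpressionTable:
    """FPKM matrix (features x samples) plus per-sample metadata.

    ``values``: DataFrame indexed by feature_id with one column per sample_id.
    ``samples``: DataFrame indexed by sample_id with columns
    condition / timepoint / fraction / replicate.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        vals = self.values
        if vals.isna().any().any():
            raise ValidationError("expression matrix contains missing values")
        try:
            bad = (vals < 0).any()
        except TypeError as exc:  # non-numeric column
            raise ValidationError(f"non-numeric expression values: {exc}") from exc
        if bad.any():
            col = bad[bad].index[0]
            raise ValidationError(f"negative FPKM in sample {col!r}")
        missing_meta = [c for c in vals.columns if c not in self.samples.index]
        if missing_meta:
            raise ValidationError(
                f"sample(s) in matrix absent from sample sheet: {missing_meta}"
            )
        missing_col = [s for s in self.samples.index if s not in vals.columns]
        if missing_col:
            raise ValidationError(
                f"sample(s) in sheet not found in matrix: {missing_col}"
            )
        for c in SAMPLE_SHEET_COLUMNS:
            if c not in self.samples.columns:
                raise ValidationError(f"sample sheet missing column {c!r}")
        dup = self.samples.duplicated(subset=["condition", "fraction", "replicate"])
        if dup.any():
            raise ValidationError(
                "replicate indices within a condition/fraction are not distinct: "
                f"{list(self.samples.index[dup])}"
            )

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    def samples_where(self, **criteria) -> list[str]:
        """Sample ids whose metadata match all given column=value criteria."""
        mask = pd.Series(True, index=self.samples.index)
        for col, val in criteria.items():
            mask &= self.samples[col] == val
        return list(self.samples.index[mask])


@dataclass(frozen=True)
class HomologyHit:
    """One protein-homology hit for a transcript (BLASTX-style)."""

    query_id: str
    subject_id: str
    aln_len_aa: int
    pct_identity: float
    query_cov_pct: float
    subject_cov_pct: float
    evalue: float

    def __post_init__(self) -> None:
        if self.aln_len_aa < 1:
            raise ValidationError(f"{self.query_id}: aln_len_aa must be >= 1")
        for name in ("pct_identity", "query_cov_pct", "subject_cov_pct"):
            v = getattr(self, name)
            if not (0 <= v <= 100):
                raise ValidationError(f"{self.query_id}: {name}={v} outside [0, 100]")
        if self.evalue < 0:
            raise ValidationError(f"{self.query_id}: negative e-value")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path, source_tag: str = "natlnc") -> AnnotationSet:
    """Read a GTF annotation into an :class:`AnnotationSet`.

    GTF coordinates (1-based inclusive) are converted to 0-based half-open.
    ``transcript`` lines may carry ``class_code``, ``biotype`` and
    ``lnc_class`` attributes; transcripts represented only by exon lines get
    class code ``=`` and biotype ``unknown``.
    """
    path = Path(path)
    exon_map: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, dict] = {}
    order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") != 8:
                raise ParseError(
                    f"{path}: malformed GTF line {lineno}: expected 9 fields"
                )
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise ParseError(f"{path}: malformed GTF line {lineno}: {exc}") from exc
            if feat.featuretype not in ("transcript", "exon"):
                continue
            attrs = feat.attributes
            try:
                tid = attrs["transcript_id"][0]
                gid = attrs["gene_id"][0]
            except KeyError as exc:
                raise ParseError(
                    f"{path}: line {lineno} lacks gene_id/transcript_id"
                ) from exc
            if feat.strand not in ("+", "-"):
                raise ValidationError(f"{path}: line {lineno}: strand {feat.strand!r}")
            start0, end0 = feat.start - 1, feat.end
            if end0 <= start0:
                raise ValidationError(
                    f"{path}: line {lineno}: end < start after conversion"
                )
            if tid not in meta:
                meta[tid] = {"gene_id": gid, "class_code": "=", "biotype": "unknown",
                             "lnc_class": None}
                order.append(tid)
            if feat.featuretype == "transcript":
                m = meta[tid]
                if "class_code" in attrs:
                    m["class_code"] = attrs["class_code"][0]
                if "biotype" in attrs:
                    m["biotype"] = attrs["biotype"][0]
                if "lnc_class" in attrs:
                    m["lnc_class"] = attrs["lnc_class"][0]
            else:
                exon_map.setdefault(tid, []).append(
                    GenomicInterval(feat.seqid, start0, end0, feat.strand)
                )

    anno = AnnotationSet(source=source_tag)
    for tid in order:
        m = meta[tid]
        if tid not in exon_map:
            raise ValidationError(f"{path}: transcript {tid!r} has no exon lines")
        anno.add(
            TranscriptRecord(
                transcript_id=tid,
                gene_id=m["gene_id"],
                exons=tuple(exon_map[tid]),
                class_code=m["class_code"],
                biotype=m["biotype"],
                lnc_class=m["lnc_class"],
            )
        )
    return anno


def write_annotation(anno: AnnotationSet, path: str | Path) -> None:
    """Write an :class:`AnnotationSet` as 1-based inclusive GTF.

    Record order is deterministic (chrom, span start, transcript_id), so the
    same AnnotationSet always produces byte-identical output.
    """
    recs = sorted(anno, key=lambda t: (t.chrom, t.span.start, t.transcript_id))
    lines = ["## natlnc annotation"]
    for t in recs:
        attrs = (
            f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
            f'class_code "{t.class_code}"; biotype "{t.biotype}";'
        )
        if t.lnc_class is not None:
            attrs += f' lnc_class "{t.lnc_class}";'
        span = t.span
        lines.append(
            "\t".join(
                [t.chrom, anno.source, "transcript", str(span.start + 1),
                 str(span.end), ".", t.strand, ".", attrs]
            )
        )
        for e in t.exons:
            lines.append(
                "\t".join(
                    [t.chrom, anno.source, "exon", str(e.start + 1), str(e.end),
                     ".", t.strand, ".", attrs]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# expression matrix + sample sheet
# ---------------------------------------------------------------------------

def read_expression_table(path: str | Path, sample_sheet: str | Path) -> ExpressionTable:
    """Read a TSV FPKM matrix (first column feature ids) and its sample sheet.

    The sheet is a TSV with columns sample_id, condition, timepoint, fraction,
    replicate; every matrix column must appear in the sheet and vice versa.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index.name = "feature_id"
    sheet = pd.read_csv(sample_sheet, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in sheet.columns:
        raise ValidationError(f"{sample_sheet}: missing sample_id column")
    sheet = sheet.set_index("sample_id")
    return ExpressionTable(values=values, samples=sheet)


def write_expression_table(expr: ExpressionTable, path: str | Path,
                           sample_sheet: str | Path) -> None:
    expr.values.to_csv(path, sep="\t")
    expr.samples.to_csv(sample_sheet, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# homology hits (BLAST outfmt-6 + qcovs/scovs)
# ---------------------------------------------------------------------------

#: column order of the extended BLAST tabular dialect used by the pipeline
HIT_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend "
    "sstart send evalue bitscore qcovs scovs"
).split()


def read_homology_hits(path: str | Path) -> list[HomologyHit]:
    """Read protein-homology hits from an extended BLAST tabular TSV.

    The dialect is the standard 12-column ``outfmt 6`` plus two trailing
    coverage columns: qcovs (percent of query covered by the alignment) and
    scovs (percent of subject covered).  For BLASTX output the ``length``
    column is in amino acids.
    """
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for rowno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(HIT_COLUMNS):
                raise ParseError(
                    f"{path}: row {rowno}: expected {len(HIT_COLUMNS)} columns, "
                    f"got {len(fields)}"
                )
            row = dict(zip(HIT_COLUMNS, fields))
            try:
                hit = HomologyHit(
                    query_id=row["qseqid"],
                    subject_id=row["sseqid"],
                    aln_len_aa=int(row["length"]),
                    pct_identity=float(row["pident"]),
                    query_cov_pct=float(row["qcovs"]),
                    subject_cov_pct=float(row["scovs"]),
                    evalue=float(row["evalue"]),
                )
            except ValueError as exc:
                if isinstance(exc, ValidationError):
                    raise
                raise ParseError(f"{path}: row {rowno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_homology_hits(hits: Iterable[HomologyHit], path: str | Path) -> None:
    """Write hits in the extended tabular dialect (placeholder coordinates)."""
    lines = []
    for h in hits:
        qlen_nt = h.aln_len_aa * 3
        lines.append(
            "\t".join(
                [
                    h.query_id, h.subject_id, f"{h.pct_identity:.2f}",
                    str(h.aln_len_aa), "0", "0", "1", str(qlen_nt),
                    "1", str(h.aln_len_aa), f"{h.evalue:.3g}", "100.0",
                    f"{h.query_cov_pct:.1f}", f"{h.subject_cov_pct:.1f}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read transcript sequences into a dict id -> uppercase sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# sRNA region counts (BED-like)
# ---------------------------------------------------------------------------

def read_srna_counts(path: str | Path) -> tuple[pd.DataFrame, int]:
    """Read a BED-like sRNA region count table.

    Format: a header line ``#total_mapped=<int>`` followed by tab-separated
    rows chrom, start, end, strand, count with 0-based half-open coordinates.
    Returns (DataFrame, total_mapped).
    """
    total_mapped = None
    rows = []
    with open(path) as fh:
        for rowno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#total_mapped="):
                total_mapped = int(line.split("=", 1)[1])
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ParseError(f"{path}: row {rowno}: expected 5 columns")
            try:
                rows.append(
                    (fields[0], int(fields[1]), int(fields[2]), fields[3],
                     int(fields[4]))
                )
            except ValueError as exc:
                raise ParseError(f"{path}: row {rowno}: {exc}") from exc
    if total_mapped is None:
        raise ParseError(f"{path}: missing '#total_mapped=' header line")
    if total_mapped < 1:
        raise ValidationError(f"{path}: total_mapped must be >= 1")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "count"])
    if len(df) and (df["count"] < 0).any():
        raise ValidationError(f"{path}: negative read count")
    return df, total_mapped


def write_srna_counts(counts: pd.DataFrame, total_mapped: int,
                      path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#total_mapped={total_mapped}\n")
        counts.to_csv(fh, sep="\t", header=False, index=False)
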