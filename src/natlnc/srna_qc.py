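"""sRNA-based artifact checks for knockdown lines.

Three checks exclude RNAi artifacts when interpreting amiRNA knockdowns:
region abundance in reads per million (RPM), detection of secondary siRNAs
outside the amiRNA target window, and amiRNA passenger-strand (amiRNA*)
specificity: 5' terminal uridine and base pairing against the sense mRNA with
attention to mismatches at the cleavage-critical positions.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import ValidationError
from .formats_io import GenomicInterval, TranscriptRecord

_RNA_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G", "N": "N"}
_VALID_NA = re.compile(r"^[ACGUN]+$")


@dataclass(frozen=True)
class SrnaRegionStat:
    region: GenomicInterval
    read_count: int
    total_mapped: int
    rpm: float


@dataclass(frozen=True)
class AmirnaCheck:
    star_seq: str
    has_5p_U: bool
    n_complementary: int
    mismatch_positions: tuple[int, ...]  # 1-based from the star 5' end
    critical_mismatch: bool


def _region_count(counts: pd.DataFrame, region: GenomicInterval,
                  stranded: bool) -> int:
    if counts.empty:
        return 0
    mask = (
        (counts["chrom"] == region.chrom)
        & (counts["start"] < region.end)
        & (counts["end"] > region.start)
    )
    if stranded:
        mask &= counts["strand"] == region.strand
    return int(counts.loc[mask, "count"].sum())


def rpm_quantify(
    counts: pd.DataFrame,
    total_mapped: int,
    region: GenomicInterval,
    stranded: bool = False,
) -> SrnaRegionStat:
    """Sum read counts of regions overlapping `region` (>= 1 bp) and scale to RPM."""
    if total_mapped < 1:
        raise ValidationError("total_mapped must be >= 1")
    n = _region_count(counts, region, stranded)
    return SrnaRegionStat(region, n, total_mapped, n / total_mapped * 1e6)


def secondary_sirna_check(
    counts: pd.DataFrame,
    total_mapped: int,
    transcript: TranscriptRecord,
    target_site: GenomicInterval,
    flank_bp: int = 50,
    min_outside_rpm: float = 1.0,
    stranded: bool = False,
) -> dict:
    """Detect secondary siRNAs: reads on the transcript outside the target site.

    ``outside_rpm`` is the RPM of reads overlapping the transcript span but not
    the target site extended by ``flank_bp``; secondary siRNAs are called
    detected when it reaches ``min_outside_rpm``.
    """
    span = transcript.span
    if not span.contains(target_site):
        raise ValidationError(
            f"target site {target_site} outside transcript span {span}"
        )
    if total_mapped < 1:
        raise ValidationError("total_mapped must be >= 1")
    pad = GenomicInterval(
        target_site.chrom,
        max(span.start, target_site.start - flank_bp),
        min(span.end, target_site.end + flank_bp),
        target_site.strand,
    )
    on_span = _region_count(counts, span, stranded)
    in_site = 0
    if not counts.empty:
        mask = (
            (counts["chrom"] == span.chrom)
            & (counts["start"] < span.end)
            & (counts["end"] > span.start)
            & (counts["start"] < pad.end)
            & (counts["end"] > pad.start)
        )
        if stranded:
            mask &= counts["strand"] == span.strand
        in_site = int(counts.loc[mask, "count"].sum())
    outside = on_span - in_site
    inside_rpm = in_site / total_mapped * 1e6
    outside_rpm = outside / total_mapped * 1e6
    return dict(
        detected=outside_rpm >= min_outside_rpm,
        inside_rpm=inside_rpm,
        outside_rpm=outside_rpm,
    )


def _normalize_rna(seq: str, what: str) -> str:
    if not seq:
        raise ValidationError(f"empty {what} sequence")
    seq = seq.upper().replace("T", "U")
    if not _VALID_NA.match(seq):
        bad = sorted(set(seq) - set("ACGUN"))
        raise ValidationError(f"{what}: invalid characters {bad}")
    return seq


def _pairs(star_base: str, mrna_base: str, allow_gu: bool) -> bool:
    if _RNA_COMPLEMENT.get(star_base) == mrna_base and star_base != "N":
        return True
    if allow_gu and {star_base, mrna_base} == {"G", "U"}:
        return True
    return False


def amirna_star_check(
    star_seq: str,
    sense_mrna_seq: str,
    critical_positions: Sequence[int] = (9, 10, 11),
    allow_gu: bool = False,
) -> AmirnaCheck:
    """Check whether an amiRNA* could silence the sense mRNA.

    Finds the best ungapped antisense match of the star strand in the sense
    mRNA (maximal Watson-Crick pairs; G:U wobble counted only with
    ``allow_gu``), reports mismatch positions 1-based from the star 5' end,
    whether any falls in the cleavage-critical window, and whether the star
    starts with a 5' uridine (favouring loading into the silencing effector).
    Inputs may be DNA or RNA; T and U are equivalent.
    """
    star = _normalize_rna(star_seq, "star")
    mrna = _normalize_rna(sense_mrna_seq, "mRNA")
    k = len(star)
    if k > len(mrna):
        raise ValidationError("star sequence longer than the sense mRNA")

    # antisense duplex: star position i (1-based from its 5' end) pairs with
    # mRNA position w + k - i within a window starting at w
    best_matches, best_mismatches = -1, ()
    for w in range(len(mrna) - k + 1):
        window = mrna[w: w + k]
        mism = tuple(
            i for i in range(1, k + 1)
            if not _pairs(star[i - 1], window[k - i], allow_gu)
        )
        n_match = k - len(mism)
        if n_match > best_matches:
            best_matches, best_mismatches = n_match, mism
    return AmirnaCheck(
        star_seq=star,
        has_5p_U=star[0] == "U",
        n_complementary=best_matches,
        mismatch_positions=best_mismatches,
        critical_mismatch=any(p in critical_positions for p in best_mismatches),
    )
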