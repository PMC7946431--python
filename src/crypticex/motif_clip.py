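"""UG-motif scoring of intronic windows and CLIP-peak overlap.

Scores are descriptive: UG occurrences are counted at every position
(overlapping matches included), density is occurrences per dinucleotide
position, and the longest run is the maximal n with (UG)^n as a substring of
the transcribed-strand sequence.  Peaks are merged before overlap so nothing
is double counted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

from crypticex.formats_io import GenomicInterval, PeakRecord, SequenceStore


@dataclass(frozen=True)
class MotifScore:
    window: GenomicInterval
    ug_count: int
    ug_density: float
    longest_ug_run: int
    clip_overlap_bp: Optional[int] = None
    clip_hit: Optional[bool] = None


def ug_score(
    genome: SequenceStore, window: GenomicInterval, transcribed_strand: str
) -> MotifScore:
    """Count UG dinucleotides on the transcribed strand of ``window``.

    The window shorter than 2 nt is an error (no dinucleotide fits)."""
    if window.length < 2:
        raise ValueError(f"window {window} shorter than 2 nt")
    seq = genome.fetch(
        GenomicInterval(window.contig, window.start, window.end, transcribed_strand)
    )
    # DNA alphabet: UG on the transcript reads TG on the transcribed strand
    count = sum(1 for i in range(len(seq) - 1) if seq[i : i + 2] == "TG")
    longest = 0
    i = 0
    while i < len(seq) - 1:
        run = 0
        j = i
        while j < len(seq) - 1 and seq[j : j + 2] == "TG":
            run += 1
            j += 2
        longest = max(longest, run)
        i = i + 1 if run == 0 else j
    return MotifScore(
        window=window,
        ug_count=count,
        ug_density=count / (window.length - 1),
        longest_ug_run=longest,
    )


def merge_intervals(
    intervals: Sequence[GenomicInterval],
) -> list[tuple[str, int, int]]:
    """Union of intervals per contig, strand-agnostic, sorted."""
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_contig.setdefault(iv.contig, []).append((iv.start, iv.end))
    merged: list[tuple[str, int, int]] = []
    for contig in sorted(by_contig):
        spans = sorted(by_contig[contig])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((contig, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((contig, cur_s, cur_e))
    return merged


def clip_overlap(
    window: GenomicInterval, peaks: Sequence[PeakRecord], flank: int = 0
) -> tuple[int, bool]:
    """Total bp of intersection between ``window`` (± flank) and merged peaks."""
    lo = max(0, window.start - flank)
    hi = window.end + flank
    total = 0
    for contig, s, e in merge_intervals([p.interval for p in peaks]):
        if contig != window.contig:
            continue
        total += max(0, min(hi, e) - max(lo, s))
    return total, total > 0


def score_window(
    genome: SequenceStore,
    window: GenomicInterval,
    transcribed_strand: str,
    peaks: Optional[Sequence[PeakRecord]] = None,
    flank: int = 0,
) -> MotifScore:
    """UG score plus CLIP overlap in one record."""
    score = ug_score(genome, window, transcribed_strand)
    if peaks is not None:
        bp, hit = clip_overlap(window, peaks, flank)
        score = replace(score, clip_overlap_bp=bp, clip_hit=hit)
    return score


def window_after_donor(
    contig: str,
    donor_site: int,
    strand: str,
    offset: int = 10,
    length: int = 200,
    contig_length: Optional[int] = None,
) -> GenomicInterval:
    """Scoring window ``offset``..``offset+length`` nt downstream of a donor
    site in transcript orientation (default 10-210 nt)."""
    if strand == "+":
        start, end = donor_site + offset, donor_site + offset + length
    else:
        start, end = donor_site - offset - length, donor_site - offset
    if contig_length is not None:
        start, end = max(0, start), min(contig_length, end)
    return GenomicInterval(contig, start, end, strand)
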