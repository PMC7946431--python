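"""Transcript splicing, ORF scanning, premature-stop/NMD classification, protein mass.

A spliced transcript carries its exon chain, strand-correct sequence and the
transcript-coordinate offsets of its exon-exon junctions.  The ORF scanner
translates from the CDS start and records the first in-frame stop; the NMD
classifier applies the (parameterised) 50-nt last-junction rule; protein mass
is the sum of average residue masses plus one water.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

from Bio.Seq import Seq

from crypticex.formats_io import GeneModel, GenomicInterval, SequenceStore

logger = logging.getLogger(__name__)

WATER_DA = 18.0153

# average (not monoisotopic) residue masses, Da; unmodified standard residues
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}


@dataclass(frozen=True)
class MatureTranscript:
    """A spliced transcript: exon chain, sequence, junction offsets, CDS start."""

    chain: tuple[GenomicInterval, ...]
    strand: str
    seq: str
    junction_offsets: tuple[int, ...]  # nt offset of each exon-exon boundary
    cds_start: Optional[int] = None  # transcript nt offset of the first CDS base

    def __post_init__(self) -> None:
        if len(self.seq) != sum(e.length for e in self.chain):
            raise ValueError("sequence length != sum of exon lengths")
        if list(self.junction_offsets) != sorted(set(self.junction_offsets)):
            raise ValueError("junction offsets must be strictly increasing")
        if self.cds_start is not None and not 0 <= self.cds_start < len(self.seq):
            raise ValueError("CDS start outside transcript")

    def tx_to_genomic(self, offset: int) -> int:
        """Genomic coordinate of the base at transcript ``offset``."""
        if not 0 <= offset < len(self.seq):
            raise ValueError(f"offset {offset} outside transcript")
        for e in self.chain:
            if offset < e.length:
                return e.start + offset if self.strand == "+" else e.end - 1 - offset
            offset -= e.length
        raise AssertionError("unreachable")


@dataclass(frozen=True)
class OrfAnnotation:
    """ORF scan result, optionally extended with PTC/NMD classification."""

    stop_tx: Optional[int]  # transcript offset of the stop codon's first base
    peptide: str
    is_ptc: Optional[bool] = None
    distance_to_last_junction: Optional[int] = None
    nmd_predicted: Optional[bool] = None

    @property
    def peptide_length(self) -> int:
        return len(self.peptide)

    @property
    def has_stop(self) -> bool:
        return self.stop_tx is not None


def splice_transcript(
    gene_strand: str,
    chain: Sequence[GenomicInterval],
    genome: SequenceStore,
    cds_start: Optional[int] = None,
) -> MatureTranscript:
    """Concatenate an exon chain into a mature transcript.

    ``chain`` must be ordered 5'->3' in transcript orientation (ascending
    genomic coordinates on '+', descending on '-') and non-overlapping."""
    if gene_strand not in ("+", "-"):
        raise ValueError("gene_strand must be '+' or '-'")
    chain = list(chain)
    for iv in chain:
        if iv.strand not in (gene_strand, "."):
            raise ValueError(f"exon {iv} crosses gene strand {gene_strand}")
    ordered = sorted(chain, key=lambda e: e.start)
    for a, b in zip(ordered, ordered[1:]):
        if a.end > b.start:
            raise ValueError(f"overlapping exons in chain: {a} / {b}")
    expected = ordered if gene_strand == "+" else ordered[::-1]
    if chain != expected:
        raise ValueError("chain not ordered 5'->3' in transcript orientation")
    seq = "".join(
        genome.fetch(GenomicInterval(e.contig, e.start, e.end, gene_strand))
        for e in chain
    )
    offsets = []
    pos = 0
    for e in chain[:-1]:
        pos += e.length
        offsets.append(pos)
    return MatureTranscript(
        chain=tuple(chain),
        strand=gene_strand,
        seq=seq,
        junction_offsets=tuple(offsets),
        cds_start=cds_start,
    )


def cds_start_offset(gene: GeneModel, transcript_index: int = 0) -> int:
    """Transcript-coordinate offset of the annotated CDS start (strand aware)."""
    t = gene.transcripts[transcript_index]
    if t.cds is None:
        raise ValueError(f"transcript {t.transcript_id} has no CDS annotation")
    start_g = t.cds.start if gene.strand == "+" else t.cds.end - 1
    offset = 0
    for e in t.exons:
        if e.contains_point(start_g):
            return offset + (
                start_g - e.start if gene.strand == "+" else e.end - 1 - start_g
            )
        offset += e.length
    raise ValueError("CDS start not contained in any exon of the transcript")


def scan_orf(t: MatureTranscript, cds_start: Optional[int] = None) -> OrfAnnotation:
    """Translate from the CDS start; record peptide and first in-frame stop.

    Transcripts whose frame runs off the 3' end without a stop are flagged
    non-stop (``stop_tx is None``)."""
    start = cds_start if cds_start is not None else t.cds_start
    if start is None:
        raise ValueError("no CDS start available (annotation absent and none given)")
    if start >= len(t.seq):
        raise ValueError(f"CDS start {start} beyond transcript of length {len(t.seq)}")
    coding = t.seq[start:]
    coding = coding[: len(coding) - len(coding) % 3]
    translated = str(Seq(coding).translate())
    stop_idx = translated.find("*")
    if stop_idx == -1:
        return OrfAnnotation(stop_tx=None, peptide=translated)
    return OrfAnnotation(stop_tx=start + 3 * stop_idx, peptide=translated[:stop_idx])


def _tx_scalar(strand: str, genomic_pos: int) -> int:
    return genomic_pos if strand == "+" else -genomic_pos


def classify_nmd(
    orf: OrfAnnotation,
    t: MatureTranscript,
    rule_distance: int = 50,
    annotated_stop_genomic: Optional[int] = None,
) -> OrfAnnotation:
    """Add PTC and NMD flags to an ORF annotation.

    ``annotated_stop_genomic`` is the genomic coordinate of the first base of
    the reference chain's stop codon; the scanned stop is premature when it
    lies 5' of it in transcript orientation.  NMD is predicted when the stop
    sits strictly more than ``rule_distance`` nt (first stop base to
    junction) upstream of the final exon-exon junction; single-exon
    transcripts are never NMD."""
    if not orf.has_stop:
        return replace(orf, is_ptc=False, nmd_predicted=False)
    is_ptc: Optional[bool] = None
    if annotated_stop_genomic is not None:
        stop_g = t.tx_to_genomic(orf.stop_tx)
        is_ptc = _tx_scalar(t.strand, stop_g) < _tx_scalar(
            t.strand, annotated_stop_genomic
        )
    if not t.junction_offsets:
        logger.info("single-exon transcript: NMD false by definition")
        return replace(orf, is_ptc=is_ptc, distance_to_last_junction=None,
                       nmd_predicted=False)
    distance = t.junction_offsets[-1] - orf.stop_tx
    return replace(
        orf,
        is_ptc=is_ptc,
        distance_to_last_junction=distance,
        nmd_predicted=distance > rule_distance,
    )


def protein_mass(peptide: str, empty_as_zero: bool = False) -> float:
    """Average-isotope molecular weight in Da: sum of residue masses + one water.

    The empty peptide returns one water mass (or 0.0 with ``empty_as_zero``)."""
    if not peptide:
        return 0.0 if empty_as_zero else WATER_DA
    try:
        total = sum(AVERAGE_RESIDUE_MASS[aa] for aa in peptide.upper())
    except KeyError as e:
        raise ValueError(f"unknown residue {e.args[0]!r} in peptide") from None
    return total + WATER_DA


def protein_mass_kda(peptide: str) -> float:
    return protein_mass(peptide) / 1000.0
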