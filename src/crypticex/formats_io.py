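"""Strand-aware readers/writers for GTF, FASTA, junction BED, peak BED and TSV reports.

Every coordinate handed around inside the package is 0-based half-open
(BED-native).  GTF's 1-based inclusive coordinates are converted at the
boundary, in :func:`read_gtf` / :func:`write_gtf`, and nowhere else.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (case preserved, N passes through)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """A file violated the expected format; message names the offending line."""


class ValidationError(ValueError):
    """Parsed content violated a semantic invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``contig``.

    ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def __str__(self) -> str:  # contig:start-end:strand, used in reports
        return f"{self.contig}:{self.start}-{self.end}:{self.strand}"


@dataclass(frozen=True)
class Transcript:
    """One transcript: exons stored in transcript 5'->3' order."""

    transcript_id: str
    exons: tuple[GenomicInterval, ...]
    cds: Optional[GenomicInterval] = None

    @property
    def span(self) -> GenomicInterval:
        starts = [e.start for e in self.exons]
        ends = [e.end for e in self.exons]
        return GenomicInterval(
            self.exons[0].contig, min(starts), max(ends), self.exons[0].strand
        )

    def introns(self) -> tuple[GenomicInterval, ...]:
        """Introns in transcript 5'->3' order (genomic intervals)."""
        genomic = sorted(self.exons, key=lambda e: e.start)
        out = []
        for a, b in zip(genomic, genomic[1:]):
            out.append(GenomicInterval(a.contig, a.end, b.start, a.strand))
        if self.exons and self.exons[0].strand == "-":
            out = out[::-1]
        return tuple(out)


@dataclass
class GeneModel:
    """A gene's transcript structures with optional externally supplied exon numbering.

    ``exon_ordinals`` maps exon intervals to the ordinal used in reports (the
    published exon numbering of the locus under study when available).  When
    no numbering is supplied, ordinals are assigned 1..n in transcript order
    of the first transcript and ``ordinals_provisional`` is set.
    """

    gene_id: str
    gene_name: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)
    exon_ordinals: dict[GenomicInterval, int] = field(default_factory=dict)
    ordinals_provisional: bool = False

    @property
    def contig(self) -> str:
        return self.transcripts[0].exons[0].contig

    @property
    def span(self) -> GenomicInterval:
        starts = [e.start for t in self.transcripts for e in t.exons]
        ends = [e.end for t in self.transcripts for e in t.exons]
        return GenomicInterval(self.contig, min(starts), max(ends), self.strand)

    def exon_by_ordinal(self, ordinal: int) -> GenomicInterval:
        for iv, n in self.exon_ordinals.items():
            if n == ordinal:
                return iv
        raise KeyError(f"no exon with ordinal {ordinal} in {self.gene_id}")

    def validate(self) -> None:
        for t in self.transcripts:
            genomic = sorted(t.exons, key=lambda e: e.start)
            for a, b in zip(genomic, genomic[1:]):
                if a.end > b.start:
                    raise ValidationError(
                        f"overlapping exons in {t.transcript_id}: {a} / {b}"
                    )
            expected = genomic if self.strand == "+" else genomic[::-1]
            if list(t.exons) != expected:
                raise ValidationError(
                    f"exons of {t.transcript_id} not in transcript 5'->3' order"
                )
            if t.cds is not None:
                ok_start = any(e.contains_point(t.cds.start) for e in t.exons)
                ok_end = any(e.contains_point(t.cds.end - 1) for e in t.exons)
                if not (ok_start and ok_end):
                    raise ValidationError(
                        f"CDS {t.cds} of {t.transcript_id} outside exon union"
                    )


@dataclass(frozen=True)
class JunctionRecord:
    """One intron observed in one sample with a junction-spanning read count."""

    intron: GenomicInterval
    count: int
    sample_id: str
    condition: str

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValidationError(f"negative junction count for {self.intron}")
        if self.intron.length < 4:
            raise ValidationError(
                f"intron {self.intron} shorter than 4 nt (no room for splice sites)"
            )


@dataclass(frozen=True)
class PeakRecord:
    """A CLIP (or other) peak interval with an optional score."""

    interval: GenomicInterval
    score: float = 0.0
    source: str = ""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


class SequenceStore:
    """In-memory contig sequences with strand-aware slicing by GenomicInterval."""

    def __init__(self, contigs: Mapping[str, str]):
        self._contigs = {name: seq.upper() for name, seq in contigs.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "SequenceStore":
        records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        if not records:
            raise FormatError(f"{path}: no FASTA records found")
        return cls(records)

    def contig_length(self, contig: str) -> int:
        return len(self._seq(contig))

    def _seq(self, contig: str) -> str:
        try:
            return self._contigs[contig]
        except KeyError:
            raise KeyError(f"contig {contig!r} not in sequence store") from None

    def fetch(self, interval: GenomicInterval) -> str:
        """Sequence of ``interval``; minus-strand intervals come back reverse-complemented."""
        seq = self._seq(interval.contig)
        if interval.end > len(seq):
            raise ValidationError(
                f"interval {interval} beyond end of {interval.contig} "
                f"(length {len(seq)})"
            )
        sub = seq[interval.start : interval.end]
        return reverse_complement(sub) if interval.strand == "-" else sub

    def contigs(self) -> list[str]:
        return list(self._contigs)


def write_fasta(store: SequenceStore, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in store.contigs():
            seq = store.fetch(GenomicInterval(name, 0, store.contig_length(name)))
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Parse an Ensembl-dialect GTF into :class:`GeneModel` objects.

    1-based inclusive GTF coordinates are converted to internal 0-based
    half-open.  Only ``gene`` / ``transcript`` / ``exon`` / ``CDS`` features
    are used; others are ignored.  Exon ordinals come from the
    ``exon_number`` attribute when present; otherwise they are assigned by
    transcript order and the model is flagged provisional.
    """
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            contig, _source, feature, start_s, end_s, _score, strand, _frame, attrs_s = fields
            if feature not in ("gene", "transcript", "exon", "CDS"):
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            if start1 < 1 or end1 < start1:
                raise FormatError(f"{path}: line {lineno}: bad coordinate range")
            attrs = _parse_attributes(attrs_s)
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise FormatError(f"{path}: line {lineno}: missing gene_id attribute")
            g = genes.setdefault(
                gene_id,
                {
                    "gene_name": attrs.get("gene_name", gene_id),
                    "strand": strand,
                    "contig": contig,
                    "transcripts": {},
                    "span": None,
                    "ordinals": {},
                    "has_exon_number": False,
                },
            )
            iv = GenomicInterval(contig, start1 - 1, end1, strand)
            if feature == "gene":
                g["span"] = iv
                continue
            tx_id = attrs.get("transcript_id")
            if tx_id is None:
                raise FormatError(
                    f"{path}: line {lineno}: {feature} without transcript_id"
                )
            tx = g["transcripts"].setdefault(
                tx_id, {"exons": [], "cds": [], "span": None}
            )
            if feature == "transcript":
                tx["span"] = iv
            elif feature == "exon":
                tx["exons"].append(iv)
                if "exon_number" in attrs:
                    g["ordinals"][iv] = int(attrs["exon_number"])
                    g["has_exon_number"] = True
            else:  # CDS
                tx["cds"].append(iv)

    out: list[GeneModel] = []
    for gene_id, g in genes.items():
        strand = g["strand"]
        transcripts: list[Transcript] = []
        for tx_id, tx in g["transcripts"].items():
            exons = sorted(tx["exons"], key=lambda e: e.start)
            if tx["span"] is not None:
                for e in exons:
                    if not tx["span"].contains(e):
                        raise ValidationError(
                            f"exon {e} outside span of transcript {tx_id}"
                        )
            if strand == "-":
                exons = exons[::-1]
            cds = None
            if tx["cds"]:
                cds = GenomicInterval(
                    g["contig"],
                    min(c.start for c in tx["cds"]),
                    max(c.end for c in tx["cds"]),
                    strand,
                )
            transcripts.append(Transcript(tx_id, tuple(exons), cds))
        model = GeneModel(
            gene_id=gene_id,
            gene_name=g["gene_name"],
            strand=strand,
            transcripts=transcripts,
            exon_ordinals=dict(g["ordinals"]),
        )
        if not g["has_exon_number"] and transcripts:
            model.exon_ordinals = {
                iv: i + 1 for i, iv in enumerate(transcripts[0].exons)
            }
            model.ordinals_provisional = True
        model.validate()
        out.append(model)
    return out


def write_gtf(genes: Iterable[GeneModel], path: str | Path, source: str = "crypticex") -> None:
    """Write gene models back out as GTF (1-based inclusive), round-trip safe."""
    with open(path, "w") as fh:
        for g in genes:
            span = g.span
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}";'
            fh.write(
                f"{span.contig}\t{source}\tgene\t{span.start + 1}\t{span.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for t in g.transcripts:
                ts = t.span
                tattrs = attrs + f' transcript_id "{t.transcript_id}";'
                fh.write(
                    f"{ts.contig}\t{source}\ttranscript\t{ts.start + 1}\t{ts.end}\t.\t"
                    f"{g.strand}\t.\t{tattrs}\n"
                )
                for e in t.exons:
                    ordinal = g.exon_ordinals.get(e)
                    extra = f' exon_number "{ordinal}";' if ordinal is not None else ""
                    fh.write(
                        f"{e.contig}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f"{g.strand}\t.\t{tattrs}{extra}\n"
                    )
                if t.cds is not None:
                    # emit CDS clipped to exons so the union reproduces the stored span
                    for e in sorted(t.exons, key=lambda x: x.start):
                        lo = max(e.start, t.cds.start)
                        hi = min(e.end, t.cds.end)
                        if lo < hi:
                            fh.write(
                                f"{e.contig}\t{source}\tCDS\t{lo + 1}\t{hi}\t.\t"
                                f"{g.strand}\t.\t{tattrs}\n"
                            )


# ---------------------------------------------------------------------------
# junction BED12 (regtools "junctions extract" dialect)
# ---------------------------------------------------------------------------


def read_junctions_bed(
    path: str | Path, sample_id: str, condition: str
) -> list[JunctionRecord]:
    """Read a 2-block BED12 junction file where the blocks are alignment anchors.

    The intron is the gap between the two anchors:
    ``[chromStart + blockSize1, chromEnd - blockSize2)``; the BED score column
    carries the junction-spanning read count.  Duplicate lines for the same
    intron are summed with a warning.
    """
    by_intron: dict[GenomicInterval, int] = {}
    dup_warned = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"{path}: line {lineno}: expected 12 BED columns, got {len(fields)}"
                )
            contig = fields[0]
            try:
                chrom_start, chrom_end = int(fields[1]), int(fields[2])
                score = int(float(fields[4]))
                block_count = int(fields[9])
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: non-numeric field") from None
            strand = fields[5]
            if block_count != 2:
                raise FormatError(
                    f"{path}: line {lineno}: junction lines must have exactly 2 "
                    f"blocks, got {block_count}"
                )
            sizes = [int(s) for s in fields[10].rstrip(",").split(",")]
            if len(sizes) != 2:
                raise FormatError(
                    f"{path}: line {lineno}: blockSizes does not list 2 blocks"
                )
            istart = chrom_start + sizes[0]
            iend = chrom_end - sizes[1]
            if iend <= istart:
                raise ValidationError(
                    f"{path}: line {lineno}: non-positive intron length after "
                    f"anchor removal"
                )
            iv = GenomicInterval(contig, istart, iend, strand)
            if iv in by_intron:
                if not dup_warned:
                    logger.warning(
                        "%s: duplicate junction lines for the same intron; counts summed",
                        path,
                    )
                    dup_warned = True
                by_intron[iv] += score
            else:
                by_intron[iv] = score
    return [
        JunctionRecord(iv, count, sample_id, condition)
        for iv, count in sorted(by_intron.items())
    ]


def write_junctions_bed(
    records: Sequence[JunctionRecord], path: str | Path, anchor: int = 20
) -> None:
    """Emit junctions in the 2-block BED12 anchor dialect (fixed anchor size)."""
    with open(path, "w") as fh:
        for i, rec in enumerate(sorted(records, key=lambda r: r.intron)):
            iv = rec.intron
            cs, ce = iv.start - anchor, iv.end + anchor
            if cs < 0:
                raise ValidationError(f"anchor extends past contig start for {iv}")
            fh.write(
                f"{iv.contig}\t{cs}\t{ce}\tJUNC{i:05d}\t{rec.count}\t{iv.strand}\t"
                f"{cs}\t{ce}\t255,0,0\t2\t{anchor},{anchor}\t0,{iv.end - cs}\n"
            )


# ---------------------------------------------------------------------------
# peaks BED and TSV reports
# ---------------------------------------------------------------------------


def read_peaks_bed(path: str | Path, source: str = "") -> list[PeakRecord]:
    """Read a BED3+ peak file."""
    peaks: list[PeakRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >=3 BED columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinates") from None
            strand = fields[5] if len(fields) >= 6 and fields[5] in STRANDS else "."
            score = 0.0
            if len(fields) >= 5 and fields[4] not in (".", ""):
                score = float(fields[4])
            peaks.append(
                PeakRecord(GenomicInterval(fields[0], start, end, strand), score, source)
            )
    return peaks


def write_report_tsv(
    rows: pd.DataFrame | Sequence[Mapping],
    path: str | Path,
    sort_by: Optional[Sequence[str]] = None,
) -> None:
    """Write a deterministic TSV report: header row, '.' for missing, fixed floats."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    if sort_by:
        df = df.sort_values(list(sort_by), kind="mergesort")
    df.to_csv(path, sep="\t", index=False, na_rep=".", float_format="%.6g")


def read_report_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["."])
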