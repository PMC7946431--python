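"""Cassette-exon discovery from splice-junction evidence.

Junctions are indexed donor->acceptor in transcript orientation (for a
minus-strand gene the donor sits at the intron's high-coordinate end).  A
cassette call requires an annotated donor splicing to an unannotated acceptor
inside an annotated intron, plus an unannotated donor downstream of that
acceptor splicing back to an annotated acceptor.  The best-supported cassette
per host intron is labelled CE1; acceptor-sharing variants with weaker,
further-downstream donors are labelled CE2, CE3, ... in transcript order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

from crypticex.formats_io import (
    GeneModel,
    GenomicInterval,
    JunctionRecord,
    SequenceStore,
)

logger = logging.getLogger(__name__)

READTHROUGH = "readthrough"


@dataclass(frozen=True)
class SpliceSite:
    """A splice-site boundary coordinate in 0-based half-open convention."""

    contig: str
    pos: int
    strand: str

    def tx_coord(self) -> int:
        """Scalar increasing in transcript 5'->3' direction (for ordering)."""
        return self.pos if self.strand == "+" else -self.pos


@dataclass
class JunctionIndex:
    """Donor->acceptor (and reverse) maps for one gene, counts per sample."""

    gene: GeneModel
    donor_to_acceptors: dict[int, dict[int, dict[tuple[str, str], int]]] = field(
        default_factory=dict
    )
    acceptor_to_donors: dict[int, dict[int, dict[tuple[str, str], int]]] = field(
        default_factory=dict
    )
    excluded: list[tuple[JunctionRecord, str]] = field(default_factory=list)

    @property
    def strand(self) -> str:
        return self.gene.strand

    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for accs in self.donor_to_acceptors.values():
            for counts in accs.values():
                for (_s, cond) in counts:
                    seen.setdefault(cond, None)
        return list(seen)

    def pair_count(
        self, donor: int, acceptor: int, condition: Optional[str] = None
    ) -> int:
        counts = self.donor_to_acceptors.get(donor, {}).get(acceptor, {})
        return sum(
            c
            for (_s, cond), c in counts.items()
            if condition is None or cond == condition
        )

    def donor_total(self, donor: int, condition: Optional[str] = None) -> int:
        return sum(
            self.pair_count(donor, a, condition)
            for a in self.donor_to_acceptors.get(donor, {})
        )


def intron_donor_acceptor(intron: GenomicInterval, strand: str) -> tuple[int, int]:
    """Boundary coordinates of donor and acceptor sites in transcript orientation."""
    if strand == "+":
        return intron.start, intron.end
    return intron.end, intron.start


def annotated_sites(gene: GeneModel) -> tuple[set[int], set[int], set[GenomicInterval]]:
    """(donor sites, acceptor sites, annotated introns) across all transcripts."""
    donors: set[int] = set()
    acceptors: set[int] = set()
    introns: set[GenomicInterval] = set()
    for t in gene.transcripts:
        for e in t.exons:
            if gene.strand == "+":
                donors.add(e.end)
                acceptors.add(e.start)
            else:
                donors.add(e.start)
                acceptors.add(e.end)
        introns.update(t.introns())
    return donors, acceptors, introns


def build_junction_index(
    junctions: Iterable[JunctionRecord], gene: GeneModel
) -> JunctionIndex:
    """Index junctions within the gene span; strand-mismatched or out-of-span
    junctions are excluded with a log entry.  Counts aggregate per
    (donor, acceptor, sample)."""
    idx = JunctionIndex(gene=gene)
    span = gene.span
    for j in junctions:
        if j.intron.strand == "." or j.intron.strand != gene.strand:
            idx.excluded.append((j, "strand_mismatch"))
            logger.debug("excluding %s: strand mismatch vs %s", j.intron, gene.gene_id)
            continue
        if not span.contains(j.intron):
            idx.excluded.append((j, "outside_gene_span"))
            logger.debug("excluding %s: outside span of %s", j.intron, gene.gene_id)
            continue
        donor, acceptor = intron_donor_acceptor(j.intron, gene.strand)
        key = (j.sample_id, j.condition)
        cell = idx.donor_to_acceptors.setdefault(donor, {}).setdefault(acceptor, {})
        cell[key] = cell.get(key, 0) + j.count
        cell2 = idx.acceptor_to_donors.setdefault(acceptor, {}).setdefault(donor, {})
        cell2[key] = cell2.get(key, 0) + j.count
    return idx


@dataclass
class CrypticExonCall:
    """An unannotated exonic segment supported by entry and exit junctions."""

    gene_id: str
    segment: GenomicInterval
    host_intron: GenomicInterval
    entry_junction: tuple[int, int]  # (donor site, acceptor site)
    exit_junction: Union[tuple[int, int], str]  # or READTHROUGH
    ce_class: str  # CE1 | CE2 | CE3... | minor
    splice_sites: tuple[str, Optional[str]]  # (acceptor dinuc, donor dinuc)
    canonical: bool
    support: dict[str, tuple[int, int]]  # condition -> (entry count, exit count)
    exit_max_sample_count: int = 0  # largest single-sample exit-junction count

    @property
    def support_total(self) -> int:
        return sum(e + x for e, x in self.support.values())

    def validate(self) -> None:
        if self.exit_junction == READTHROUGH:
            if not (
                self.host_intron.contains(self.segment)
                and self.segment.start > self.host_intron.start - 1
            ):
                raise ValueError(f"readthrough segment {self.segment} escapes host intron")
        else:
            ok = (
                self.host_intron.contains(self.segment)
                and self.segment.start > self.host_intron.start
                and self.segment.end < self.host_intron.end
            )
            if not ok:
                raise ValueError(
                    f"segment {self.segment} not strictly inside {self.host_intron}"
                )
        if sum(e for e, _ in self.support.values()) < 1:
            raise ValueError("cassette call without entry support")


def _segment(strand: str, acceptor: int, donor2: int, contig: str) -> GenomicInterval:
    if strand == "+":
        return GenomicInterval(contig, acceptor, donor2, strand)
    return GenomicInterval(contig, donor2, acceptor, strand)


def _tx_intron(strand: str, donor: int, acceptor: int, contig: str) -> GenomicInterval:
    """Genomic interval of the intron defined by (donor, acceptor) sites."""
    if strand == "+":
        return GenomicInterval(contig, donor, acceptor, strand)
    return GenomicInterval(contig, acceptor, donor, strand)


def _dinucs(
    genome: Optional[SequenceStore],
    strand: str,
    contig: str,
    entry: tuple[int, int],
    exit_: Optional[tuple[int, int]],
) -> tuple[str, Optional[str]]:
    """Acceptor dinucleotide (last 2 nt of entry intron) and donor dinucleotide
    (first 2 nt of exit intron), both read in transcript orientation."""
    if genome is None:
        return ("NN", None if exit_ is None else "NN")
    entry_iv = _tx_intron(strand, *entry, contig)
    entry_seq = genome.fetch(entry_iv)
    acc = entry_seq[-2:]
    don = None
    if exit_ is not None:
        exit_iv = _tx_intron(strand, *exit_, contig)
        don = genome.fetch(exit_iv)[:2]
    return acc, don


def call_cassette_exons(
    index: JunctionIndex,
    gene: GeneModel,
    genome: Optional[SequenceStore] = None,
    min_major_support: float = 5,
    emit_readthrough: bool = True,
) -> list[CrypticExonCall]:
    """Call unannotated cassette exons inside annotated introns.

    Non-canonical splice sites are flagged (``canonical=False``), never
    filtered.  Raises ``ValueError`` when the gene model has no transcripts;
    zero junctions simply yield an empty list.
    """
    if not gene.transcripts:
        raise ValueError(f"no annotation available for {gene.gene_id}")
    donors_ann, acceptors_ann, introns_ann = annotated_sites(gene)
    strand, contig = gene.strand, gene.contig
    exons_all = [e for t in gene.transcripts for e in t.exons]

    conditions = index.conditions()
    calls: list[CrypticExonCall] = []
    per_host: dict[GenomicInterval, list[CrypticExonCall]] = {}

    for donor, acc_map in index.donor_to_acceptors.items():
        if donor not in donors_ann:
            continue
        for acceptor in acc_map:
            if acceptor in acceptors_ann:
                continue
            host = next(
                (
                    hi
                    for hi in introns_ann
                    if hi.start < acceptor < hi.end
                ),
                None,
            )
            if host is None:
                continue
            # candidate exits: unannotated donors downstream of the acceptor
            # (transcript orientation) splicing to an annotated acceptor,
            # with the enclosed segment inside the host intron
            exits: list[tuple[int, int]] = []
            for d2, a2_map in index.donor_to_acceptors.items():
                if d2 in donors_ann:
                    continue
                site_a = SpliceSite(contig, acceptor, strand)
                site_d2 = SpliceSite(contig, d2, strand)
                if site_d2.tx_coord() <= site_a.tx_coord():
                    continue
                seg = _segment(strand, acceptor, d2, contig)
                if not (host.start < seg.start and seg.end < host.end):
                    continue
                for a2 in a2_map:
                    if a2 in acceptors_ann:
                        exits.append((d2, a2))
            entry = (donor, acceptor)
            made_call = False
            for (d2, a2) in exits:
                seg = _segment(strand, acceptor, d2, contig)
                if any(seg.overlaps(e) for e in exons_all):
                    continue
                support = {}
                for cond in conditions:
                    support[cond] = (
                        index.pair_count(donor, acceptor, cond),
                        index.pair_count(d2, a2, cond),
                    )
                acc_d, don_d = _dinucs(genome, strand, contig, entry, (d2, a2))
                exit_counts = index.donor_to_acceptors.get(d2, {}).get(a2, {})
                call = CrypticExonCall(
                    gene_id=gene.gene_id,
                    segment=seg,
                    host_intron=host,
                    entry_junction=entry,
                    exit_junction=(d2, a2),
                    ce_class="minor",
                    splice_sites=(acc_d, don_d),
                    canonical=(acc_d == "AG" and don_d == "GT"),
                    support=support,
                    exit_max_sample_count=max(exit_counts.values(), default=0),
                )
                call.validate()
                per_host.setdefault(host, []).append(call)
                made_call = True
            if not made_call and emit_readthrough:
                # entry junction with no detected exit: readthrough candidate
                if strand == "+":
                    seg = GenomicInterval(contig, acceptor, host.end, strand)
                else:
                    seg = GenomicInterval(contig, host.start, acceptor, strand)
                support = {
                    cond: (index.pair_count(donor, acceptor, cond), 0)
                    for cond in conditions
                }
                acc_d, _ = _dinucs(genome, strand, contig, entry, None)
                call = CrypticExonCall(
                    gene_id=gene.gene_id,
                    segment=seg,
                    host_intron=host,
                    entry_junction=entry,
                    exit_junction=READTHROUGH,
                    ce_class="minor",
                    splice_sites=(acc_d, None),
                    canonical=False,
                    support=support,
                )
                call.validate()
                per_host.setdefault(host, []).append(call)

    # classify per host intron
    for host, group in per_host.items():
        cassette = [c for c in group if c.exit_junction != READTHROUGH]
        ce1: Optional[CrypticExonCall] = None
        if cassette:
            best = max(cassette, key=lambda c: c.support_total)
            if best.support_total >= min_major_support:
                best.ce_class = "CE1"
                ce1 = best
        if ce1 is not None:
            ce1_donor_tx = SpliceSite(
                contig,
                ce1.segment.end if strand == "+" else ce1.segment.start,
                strand,
            ).tx_coord()
            variants = [
                c
                for c in cassette
                if c is not ce1
                and c.entry_junction[1] == ce1.entry_junction[1]
                and c.exit_max_sample_count < min_major_support
                and SpliceSite(
                    contig,
                    c.segment.end if strand == "+" else c.segment.start,
                    strand,
                ).tx_coord()
                > ce1_donor_tx
            ]
            variants.sort(
                key=lambda c: SpliceSite(
                    contig,
                    c.segment.end if strand == "+" else c.segment.start,
                    strand,
                ).tx_coord()
            )
            for i, c in enumerate(variants, start=2):
                c.ce_class = f"CE{i}"
        calls.extend(group)

    calls.sort(key=lambda c: (c.segment.start, c.segment.end))
    return calls


# ---------------------------------------------------------------------------
# isoform classification from alternative-exon usage flags
# ---------------------------------------------------------------------------

NF155_EXONS = (23, 24)
NF186_EXONS = (28, 29, 30)


def classify_isoform(flags: Mapping[int, Optional[bool]]) -> str:
    """Classify a neurofascin-style isoform from alternative-exon usage flags.

    ``flags`` maps exon ordinal -> True (included) / False (skipped) /
    None (unknown).  Exons 23+24 mark the glial isoform (NF155), exons 28-30
    the neuronal one (NF186); neither gives NF140, suffixed by the exon-27
    flag when known.  Missing decisive flags give ``indeterminate``; both
    marker sets present gives ``conflict``.
    """
    g155 = [flags.get(e) for e in NF155_EXONS]
    g186 = [flags.get(e) for e in NF186_EXONS]
    if any(v is None for v in g155 + g186):
        return "indeterminate"
    has155 = all(g155)
    has186 = all(g186)
    if has155 and has186:
        return "conflict"
    if has155:
        return "NF155"
    if has186:
        return "NF186"
    ex27 = flags.get(27)
    if ex27 is None:
        return "NF140"
    return "NF140+ex27" if ex27 else "NF140-ex27"


def exon_flags_from_junctions(
    index: JunctionIndex, gene: GeneModel, min_reads: int = 1
) -> dict[int, Optional[bool]]:
    """Derive exon usage flags from junction evidence, the way junction-spanning
    primers would: a junction joining exon i to exon j marks i and j included
    and every exon strictly between them skipped.  Conflicting evidence keeps
    the better-supported verdict."""
    ord_of_donor: dict[int, int] = {}
    ord_of_acceptor: dict[int, int] = {}
    for iv, n in gene.exon_ordinals.items():
        d, a = (iv.end, iv.start) if gene.strand == "+" else (iv.start, iv.end)
        ord_of_donor[d] = n
        ord_of_acceptor[a] = n
    votes: dict[int, dict[bool, int]] = {}

    def vote(exon: int, included: bool, weight: int) -> None:
        votes.setdefault(exon, {True: 0, False: 0})[included] += weight

    for donor, acc_map in index.donor_to_acceptors.items():
        if donor not in ord_of_donor:
            continue
        i = ord_of_donor[donor]
        for acceptor in acc_map:
            if acceptor not in ord_of_acceptor:
                continue
            j = ord_of_acceptor[acceptor]
            if j <= i:
                continue
            w = index.pair_count(donor, acceptor)
            if w < min_reads:
                continue
            vote(i, True, w)
            vote(j, True, w)
            for mid in range(i + 1, j):
                vote(mid, False, w)
    flags: dict[int, Optional[bool]] = {}
    for exon, v in votes.items():
        if v[True] == v[False]:
            flags[exon] = None
        else:
            flags[exon] = v[True] > v[False]
    return flags


# ---------------------------------------------------------------------------
# local spliceform enumeration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpliceformPath:
    """One junction-supported exon chain through the affected region."""

    labels: tuple[str, ...]  # e.g. ("E17", "CE1", "E19", "E20")
    chain: tuple[GenomicInterval, ...]
    support: Mapping[str, int]  # condition -> count of the first junction


def enumerate_spliceforms(
    gene: GeneModel,
    index: JunctionIndex,
    calls: Sequence[CrypticExonCall],
    upstream_ordinal: int,
    downstream_ordinal: int,
) -> list[SpliceformPath]:
    """Enumerate junction-supported exon chains from the upstream constitutive
    exon to the downstream one.  Path support per condition is the count of
    the path's first junction (the one leaving the upstream exon), so the
    supports of all paths from one donor sum to that donor's total."""
    strand, contig = gene.strand, gene.contig

    # nodes: annotated exons in the ordinal window + called cassette segments
    nodes: dict[str, GenomicInterval] = {}
    for iv, n in gene.exon_ordinals.items():
        if upstream_ordinal <= n <= downstream_ordinal:
            nodes[f"E{n}"] = iv
    for c in calls:
        if c.exit_junction == READTHROUGH:
            continue
        nodes[c.ce_class if c.ce_class != "minor" else f"seg:{c.segment}"] = c.segment

    def node_donor(iv: GenomicInterval) -> int:
        return iv.end if strand == "+" else iv.start

    def node_acceptor(iv: GenomicInterval) -> int:
        return iv.start if strand == "+" else iv.end

    acceptor_to_node = {node_acceptor(iv): name for name, iv in nodes.items()}

    start = f"E{upstream_ordinal}"
    goal = f"E{downstream_ordinal}"
    if start not in nodes or goal not in nodes:
        raise KeyError("upstream/downstream ordinals not present in gene model")

    paths: list[SpliceformPath] = []

    def dfs(name: str, labels: list[str], first_edge: Optional[tuple[int, int]]) -> None:
        if name == goal:
            support = {
                cond: index.pair_count(*first_edge, cond)
                for cond in index.conditions()
            }
            paths.append(
                SpliceformPath(
                    tuple(labels),
                    tuple(nodes[l] for l in labels),
                    support,
                )
            )
            return
        d = node_donor(nodes[name])
        for acceptor in index.donor_to_acceptors.get(d, {}):
            nxt = acceptor_to_node.get(acceptor)
            if nxt is None or nxt in labels:
                continue
            dfs(nxt, labels + [nxt], first_edge or (d, acceptor))

    dfs(start, [start], None)
    paths.sort(key=lambda p: p.labels)
    return paths
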