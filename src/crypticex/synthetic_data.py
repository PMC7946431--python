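"""Seeded generator of a toy multi-exon locus with a planted intronic cassette exon.

The generator emulates the situation the pipeline is built for: a host intron
that hides an unannotated cassette exon with canonical splice sites, an
in-frame premature stop codon inside the cassette, and a UG-rich tract a few
nucleotides downstream of the cassette's donor.  Per-sample junction read
counts are drawn binomially from configured true PSI values, so estimator
recovery can be checked against known truth without any external data.

All construction happens on the transcribed strand; for a minus-strand locus
the finished genome is reverse-complemented and every coordinate is mirrored.
"""

from __future__ import annotations

import hashlib
import zlib
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from crypticex.formats_io import (
    GeneModel,
    GenomicInterval,
    JunctionRecord,
    PeakRecord,
    SequenceStore,
    Transcript,
    ValidationError,
    reverse_complement,
    write_fasta,
    write_gtf,
    write_junctions_bed,
    write_report_tsv,
)

STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
)


class ConfigError(ValueError):
    """Simulation geometry cannot be satisfied."""


@dataclass(frozen=True)
class Condition:
    """One experimental condition with its true inclusion level."""

    name: str
    true_psi: float
    n_replicates: int
    donor_depth: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_psi <= 1.0:
            raise ConfigError(f"true_psi {self.true_psi} outside [0, 1]")
        if self.donor_depth <= 0:
            raise ConfigError("donor_depth must be positive")
        if self.n_replicates <= 0:
            raise ConfigError("n_replicates must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Geometry and sampling parameters of the simulated locus.

    The default geometry plants a 104-nt cassette exon in the intron after
    the second exon; with ``first_exon_ordinal = 16`` that intron is reported
    as the one downstream of "exon 17", mirroring the locus the pipeline was
    designed around.
    """

    seed: int = 0
    strand: str = "+"
    contig: str = "chrS"
    gene_id: str = "SIMG1"
    gene_name: str = "SimGene"
    exon_lengths: tuple[int, ...] = (150, 120, 90, 150, 180)
    intron_lengths: tuple[int, ...] = (300, 400, 350, 320)
    host_intron_index: int = 1
    cryptic_exon_length: int = 104
    cryptic_offset: int = 120
    ptc_frame_offset: int = 0
    ug_run_units: int = 12
    ug_gap: int = 10  # nt between cryptic donor and start of the UG tract
    conditions: tuple[Condition, ...] = (
        Condition("WT", 0.253, 3, 200),
        Condition("cKO", 0.931, 3, 200),
    )
    first_exon_ordinal: int = 16
    utr5: int = 30
    utr3: int = 45
    pad: int = 60
    emit_cryptic_junctions: bool = True
    # exon-offset targets of the cassette's exit junction and of exclusion reads
    ce_exit_exon_offset: int = 1
    skip_junction_fraction: float = 0.0  # fraction of exclusion on direct skip to exon+2
    emit_minor_junctions: bool = False
    minor_donor_offsets: tuple[int, ...] = ()
    background_depth: int = 200

    def validate(self) -> None:
        if self.strand not in ("+", "-"):
            raise ConfigError("strand must be '+' or '-'")
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ConfigError("need one intron fewer than exons")
        if not 0 <= self.host_intron_index < len(self.intron_lengths):
            raise ConfigError("host_intron_index out of range")
        if self.ptc_frame_offset not in (0, 1, 2):
            raise ConfigError("ptc_frame_offset must be 0, 1 or 2")
        host_len = self.intron_lengths[self.host_intron_index]
        c, k = self.cryptic_offset, self.cryptic_exon_length
        if c < 4:
            raise ConfigError("cryptic_offset must leave >=4 nt of upstream intron")
        ug_end = k + self.ug_gap + 2 * self.ug_run_units
        tail_need = max(ug_end, *(k + off + 2 for off in (*self.minor_donor_offsets, 2)))
        if c + tail_need > host_len - 2:
            raise ConfigError(
                "cryptic segment, UG tract and minor donors do not fit in the host intron"
            )
        for off in self.minor_donor_offsets:
            if off < 2:
                raise ConfigError("minor donor offsets must be >= 2 nt past the CE donor")
            if self.ug_gap <= off < self.ug_gap + 2 * self.ug_run_units:
                raise ConfigError("minor donor offset collides with the UG tract")
        last = self.host_intron_index + max(
            self.ce_exit_exon_offset, 2 if self.skip_junction_fraction > 0 else 1
        )
        if last >= len(self.exon_lengths):
            raise ConfigError("exit/skip junction target exon beyond gene end")
        if not 0.0 <= self.skip_junction_fraction <= 1.0:
            raise ConfigError("skip_junction_fraction outside [0, 1]")


@dataclass(frozen=True)
class CrypticTruth:
    """Ground-truth geometry of the planted cassette (genomic coordinates)."""

    cryptic: GenomicInterval
    host_intron: GenomicInterval
    entry_intron: GenomicInterval  # annotated donor -> cryptic acceptor
    exit_intron: GenomicInterval  # cryptic donor -> annotated acceptor
    exclusion_introns: tuple[GenomicInterval, ...]
    minor_introns: tuple[GenomicInterval, ...]
    ug_tract: GenomicInterval
    ptc_transcript_offset: Optional[int]  # first base of stop, inclusion transcript
    inclusion_chain: tuple[GenomicInterval, ...]


@dataclass
class LocusSim:
    """A simulated locus: sequences, annotation and planted truth."""

    config: SimConfig
    store: SequenceStore
    gene: GeneModel
    truth: CrypticTruth


@dataclass(frozen=True)
class TruthRecord:
    sample_id: str
    condition: str
    true_psi: float
    inclusion_count: int
    exclusion_count: int
    cryptic: str
    ptc_transcript_offset: Optional[int]


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    # one stream per sample, mixed from (seed, crc32(sample_id)); adding
    # samples never perturbs existing streams
    return np.random.default_rng([seed, zlib.crc32(sample_id.encode())])


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n)) if n > 0 else ""


def _sense_codon_stream(rng: np.random.Generator, n_nt: int) -> str:
    n_codons = -(-n_nt // 3)
    s = "".join(rng.choice(SENSE_CODONS, size=n_codons))
    return s[:n_nt]


def simulate_locus(config: SimConfig) -> LocusSim:
    """Build the genome, annotation and planted cassette geometry for ``config``."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0xC0FFEE])

    exonic_total = sum(config.exon_lengths)
    cds_len = exonic_total - config.utr5 - config.utr3
    cds_len -= cds_len % 3
    if cds_len < 9:
        raise ConfigError("exons too short for a coding sequence")
    utr3 = exonic_total - config.utr5 - cds_len

    # spliced annotated transcript: UTR5 + ATG + sense codons + stop + UTR3
    cds = "ATG" + _sense_codon_stream(rng, cds_len - 6) + "TGA"
    spliced = _random_bases(rng, config.utr5) + cds + _random_bases(rng, utr3)
    assert len(spliced) == exonic_total

    # cut the spliced sequence back into exon bodies
    exon_seqs: list[str] = []
    pos = 0
    for L in config.exon_lengths:
        exon_seqs.append(spliced[pos : pos + L])
        pos += L

    # intron bodies with canonical GT...AG; the host intron additionally
    # carries the cassette (AG|CE|GT), the UG tract and any minor GT donors
    c, k = config.cryptic_offset, config.cryptic_exon_length
    host_idx = config.host_intron_index
    upstream_exonic = sum(config.exon_lengths[: host_idx + 1])
    coding_offset_at_ce = upstream_exonic - config.utr5  # nt of CDS upstream of CE

    intron_seqs: list[str] = []
    ptc_in_ce: Optional[int] = None
    for i, L in enumerate(config.intron_lengths):
        body = list(_random_bases(rng, L))
        body[0:2] = "GT"
        body[L - 2 : L] = "AG"
        if i == host_idx:
            body[c - 2 : c] = "AG"
            # cassette body: sense codons aligned to the inclusion reading frame
            phase = coding_offset_at_ce % 3
            ce = list(_sense_codon_stream(rng, k + phase)[phase:])
            if phase:
                # the codon straddling the exon->CE junction mixes upstream
                # exon bases with CE bases; keep it a sense codon
                head = exon_seqs[host_idx][-phase:]
                while head + "".join(ce[: 3 - phase]) in STOP_CODONS:
                    fix = rng.choice(SENSE_CODONS)
                    ce[: 3 - phase] = fix[phase:]
            # plant the stop at the first position congruent to ptc_frame_offset
            # (offset 0 => in frame with the upstream CDS)
            p = next(
                q
                for q in range(6, k - 3)
                if (coding_offset_at_ce + q) % 3 == config.ptc_frame_offset
            )
            ce[p : p + 3] = "TGA"
            if config.ptc_frame_offset == 0:
                ptc_in_ce = p
            body[c : c + k] = ce
            body[c + k : c + k + 2] = "GT"
            ug_start = c + k + config.ug_gap
            body[ug_start : ug_start + 2 * config.ug_run_units] = (
                "TG" * config.ug_run_units
            )
            for off in config.minor_donor_offsets:
                body[c + k + off : c + k + off + 2] = "GT"
        intron_seqs.append("".join(body))

    # assemble genome on the transcribed strand, then mirror if minus
    parts = [_random_bases(rng, config.pad)]
    exon_t: list[tuple[int, int]] = []  # transcript-oriented genome coords
    cursor = config.pad
    for i, es in enumerate(exon_seqs):
        exon_t.append((cursor, cursor + len(es)))
        parts.append(es)
        cursor += len(es)
        if i < len(intron_seqs):
            parts.append(intron_seqs[i])
            cursor += len(intron_seqs[i])
    parts.append(_random_bases(rng, config.pad))
    genome_t = "".join(parts)
    total = len(genome_t)

    host_start_t = exon_t[host_idx][1]
    ce_t = (host_start_t + c, host_start_t + c + k)
    ug_t = (ce_t[1] + config.ug_gap, ce_t[1] + config.ug_gap + 2 * config.ug_run_units)
    minor_t = [ce_t[1] + off for off in config.minor_donor_offsets]

    cds_start_t = exon_t[0][0] + config.utr5
    # CDS end: walk utr5+cds_len transcript nt into the exon chain
    remaining = config.utr5 + cds_len
    for (s, e) in exon_t:
        if remaining <= e - s:
            cds_end_t = s + remaining
            break
        remaining -= e - s

    if config.strand == "+":
        genome = genome_t
        to_g = lambda a, b: (a, b)  # noqa: E731
    else:
        genome = reverse_complement(genome_t)
        to_g = lambda a, b: (total - b, total - a)  # noqa: E731

    def iv(a_t: int, b_t: int) -> GenomicInterval:
        a, b = to_g(a_t, b_t)
        return GenomicInterval(config.contig, a, b, config.strand)

    exons_tx_order = [iv(s, e) for (s, e) in exon_t]  # already 5'->3'
    cds_iv = iv(cds_start_t, cds_end_t)
    transcript = Transcript(f"{config.gene_id}.T1", tuple(exons_tx_order), cds_iv)
    gene = GeneModel(
        gene_id=config.gene_id,
        gene_name=config.gene_name,
        strand=config.strand,
        transcripts=[transcript],
        exon_ordinals={
            e: config.first_exon_ordinal + i for i, e in enumerate(exons_tx_order)
        },
    )
    gene.validate()

    host_intron = iv(exon_t[host_idx][1], exon_t[host_idx + 1][0])
    entry_intron = iv(exon_t[host_idx][1], ce_t[0])
    exit_target = host_idx + config.ce_exit_exon_offset
    exit_intron = iv(ce_t[1], exon_t[exit_target][0])
    exclusion = [iv(exon_t[host_idx][1], exon_t[host_idx + 1][0])]
    if config.skip_junction_fraction > 0:
        exclusion.append(iv(exon_t[host_idx][1], exon_t[host_idx + 2][0]))
    minor_introns = tuple(iv(m, exon_t[exit_target][0]) for m in minor_t)

    ptc_tx = upstream_exonic + ptc_in_ce if ptc_in_ce is not None else None
    inclusion_chain = tuple(
        exons_tx_order[: host_idx + 1]
        + [iv(*ce_t)]
        + exons_tx_order[exit_target:]
    )

    truth = CrypticTruth(
        cryptic=iv(*ce_t),
        host_intron=host_intron,
        entry_intron=entry_intron,
        exit_intron=exit_intron,
        exclusion_introns=tuple(exclusion),
        minor_introns=minor_introns,
        ug_tract=iv(*ug_t),
        ptc_transcript_offset=ptc_tx,
        inclusion_chain=inclusion_chain,
    )
    store = SequenceStore({config.contig: genome})
    return LocusSim(config, store, gene, truth)


def simulate_junction_counts(
    locus: LocusSim,
) -> tuple[dict[str, list[JunctionRecord]], list[TruthRecord]]:
    """Draw per-sample junction counts: inclusion ~ Binomial(donor_depth, true_psi).

    The entry junction (annotated donor -> cryptic acceptor) and the exit
    junction (cryptic donor -> annotated acceptor) share the same inclusion
    draw; exclusion reads go to the annotated junction(s) from the same
    donor.  All other annotated introns receive ``background_depth`` reads.
    """
    cfg = locus.config
    truth = locus.truth
    annotated_introns = locus.gene.transcripts[0].introns()

    per_sample: dict[str, list[JunctionRecord]] = {}
    records: list[TruthRecord] = []
    for cond in cfg.conditions:
        for rep in range(1, cond.n_replicates + 1):
            sample_id = f"{cond.name}_r{rep}"
            rng = _sample_rng(cfg.seed, sample_id)
            inclusion = int(rng.binomial(cond.donor_depth, cond.true_psi))
            exclusion = cond.donor_depth - inclusion
            juncs: list[JunctionRecord] = []

            def add(iv: GenomicInterval, count: int) -> None:
                if count > 0:
                    juncs.append(JunctionRecord(iv, count, sample_id, cond.name))

            if cfg.emit_cryptic_junctions:
                add(truth.entry_intron, inclusion)
                add(truth.exit_intron, inclusion)
            else:
                exclusion = cond.donor_depth
            n_skip = int(round(exclusion * cfg.skip_junction_fraction))
            if cfg.skip_junction_fraction > 0:
                add(truth.exclusion_introns[0], exclusion - n_skip)
                add(truth.exclusion_introns[1], n_skip)
            else:
                add(truth.exclusion_introns[0], exclusion)
            if cfg.emit_minor_junctions:
                for m in truth.minor_introns:
                    add(m, int(rng.integers(1, 5)))  # uniform 1..4: sub-threshold
            for iv_ann in annotated_introns:
                if iv_ann == truth.exclusion_introns[0]:
                    continue  # carries the exclusion reads already
                add(iv_ann, cfg.background_depth)

            per_sample[sample_id] = juncs
            records.append(
                TruthRecord(
                    sample_id=sample_id,
                    condition=cond.name,
                    true_psi=cond.true_psi,
                    inclusion_count=inclusion if cfg.emit_cryptic_junctions else 0,
                    exclusion_count=exclusion,
                    cryptic=str(truth.cryptic),
                    ptc_transcript_offset=truth.ptc_transcript_offset,
                )
            )
    return per_sample, records


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture_bundle(
    config: SimConfig, outdir: str | Path, include_peaks: bool = True
) -> dict[str, str]:
    """Simulate and write the full fixture bundle; returns {relative path: sha256}.

    Emits genome FASTA, annotation GTF (without the cassette), one junction
    BED per sample, an optional CLIP-style peak BED over the UG tract, a
    truth TSV, a config echo and a manifest TSV with checksums.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    locus = simulate_locus(config)
    per_sample, truths = simulate_junction_counts(locus)

    write_fasta(locus.store, outdir / "genome.fa")
    write_gtf([locus.gene], outdir / "annotation.gtf")

    (outdir / "junctions").mkdir(exist_ok=True)
    sample_files = {}
    for sample_id, juncs in sorted(per_sample.items()):
        rel = f"junctions/{sample_id}.bed"
        write_junctions_bed(juncs, outdir / rel)
        sample_files[sample_id] = rel

    if include_peaks:
        ug = locus.truth.ug_tract
        with open(outdir / "peaks.bed", "w") as fh:
            fh.write(
                f"{ug.contig}\t{max(0, ug.start - 5)}\t{ug.end + 5}\tclip_peak\t"
                f"100\t{ug.strand}\n"
            )

    write_report_tsv(
        [asdict(t) for t in truths], outdir / "truth.tsv", sort_by=["sample_id"]
    )

    cfg_dict = asdict(config)
    cfg_dict["conditions"] = [asdict(c) for c in config.conditions]
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg_dict, fh, sort_keys=True)

    files = ["genome.fa", "annotation.gtf", "truth.tsv", "config.yaml"]
    files += sorted(sample_files.values())
    if include_peaks:
        files.append("peaks.bed")
    manifest = {rel: _sha256(outdir / rel) for rel in sorted(files)}
    write_report_tsv(
        [{"path": k, "sha256": v, "seed": config.seed} for k, v in manifest.items()],
        outdir / "manifest.tsv",
        sort_by=["path"],
    )
    return manifest
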