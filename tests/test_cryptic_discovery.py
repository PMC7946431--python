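"""cryptic_discovery: junction indexing, cassette calls, isoforms, spliceforms."""

import dataclasses
import math

import pytest

from crypticex.formats_io import GenomicInterval, JunctionRecord
from crypticex.cryptic_discovery import (
    READTHROUGH,
    build_junction_index,
    call_cassette_exons,
    classify_isoform,
    enumerate_spliceforms,
    exon_flags_from_junctions,
    intron_donor_acceptor,
)
from crypticex.synthetic_data import (
    Condition,
    SimConfig,
    simulate_junction_counts,
    simulate_locus,
)
from conftest import all_junctions


class TestJunctionIndex:
    def test_plus_strand_orientation(self):
        assert intron_donor_acceptor(GenomicInterval("c", 150, 260, "+"), "+") == (150, 260)

    def test_minus_strand_orientation(self):
        assert intron_donor_acceptor(GenomicInterval("c", 150, 260, "-"), "-") == (260, 150)

    def test_three_acceptors_from_one_donor(self, plus_locus):
        gene = plus_locus.gene
        donor = gene.transcripts[0].exons[0].end
        span = gene.span
        mk = lambda end, n, s: JunctionRecord(  # noqa: E731
            GenomicInterval(span.contig, donor, end, "+"), n, s, "WT"
        )
        juncs = [
            mk(donor + 50, 10, "s1"), mk(donor + 50, 5, "s2"),
            mk(donor + 80, 3, "s1"), mk(donor + 120, 7, "s1"),
        ]
        idx = build_junction_index(juncs, gene)
        assert len(idx.donor_to_acceptors[donor]) == 3
        assert idx.pair_count(donor, donor + 50) == 15
        assert idx.donor_total(donor) == 25

    def test_out_of_span_and_strand_mismatch_excluded(self, plus_locus):
        gene = plus_locus.gene
        span = gene.span
        far = JunctionRecord(
            GenomicInterval(span.contig, span.end + 100, span.end + 300, "+"),
            5, "s1", "WT",
        )
        wrong = JunctionRecord(
            GenomicInterval(span.contig, span.start + 10, span.start + 60, "-"),
            5, "s1", "WT",
        )
        idx = build_junction_index([far, wrong], gene)
        assert idx.donor_to_acceptors == {}
        reasons = sorted(reason for _, reason in idx.excluded)
        assert reasons == ["outside_gene_span", "strand_mismatch"]


class TestCassetteCalls:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_planted_cassette_recovered_exactly(self, strand):
        locus = simulate_locus(SimConfig(seed=23, strand=strand))
        per_sample, _ = simulate_junction_counts(locus)
        idx = build_junction_index(all_junctions(per_sample), locus.gene)
        calls = call_cassette_exons(idx, locus.gene, locus.store)
        ce1 = [c for c in calls if c.ce_class == "CE1"]
        assert len(ce1) == 1
        assert ce1[0].segment == locus.truth.cryptic
        assert ce1[0].splice_sites == ("AG", "GT")
        assert ce1[0].canonical

    def test_annotated_junctions_only_give_empty_set(self, plus_locus):
        gene = plus_locus.gene
        juncs = [
            JunctionRecord(iv, 50, "s1", "WT")
            for iv in gene.transcripts[0].introns()
        ]
        idx = build_junction_index(juncs, gene)
        assert call_cassette_exons(idx, gene, plus_locus.store) == []

    def test_zero_junctions_empty_not_error(self, plus_locus):
        idx = build_junction_index([], plus_locus.gene)
        assert call_cassette_exons(idx, plus_locus.gene, plus_locus.store) == []

    def test_no_annotation_is_error(self, plus_locus):
        import copy

        bare = copy.deepcopy(plus_locus.gene)
        bare.transcripts = []
        idx = build_junction_index([], plus_locus.gene)
        with pytest.raises(ValueError, match="no annotation"):
            call_cassette_exons(idx, bare, plus_locus.store)

    def test_minor_variants_classified_ce2_ce3(self):
        cfg = SimConfig(seed=23, emit_minor_junctions=True, minor_donor_offsets=(40, 70))
        locus = simulate_locus(cfg)
        per_sample, _ = simulate_junction_counts(locus)
        idx = build_junction_index(all_junctions(per_sample), locus.gene)
        calls = call_cassette_exons(idx, locus.gene, locus.store)
        by_class = {c.ce_class: c for c in calls}
        assert set(by_class) == {"CE1", "CE2", "CE3"}
        # CE2/CE3 share CE1's acceptor, use donors further downstream
        assert by_class["CE2"].entry_junction == by_class["CE1"].entry_junction
        assert by_class["CE2"].segment.length == 104 + 40
        assert by_class["CE3"].segment.length == 104 + 70
        assert by_class["CE2"].exit_max_sample_count < 5
        assert by_class["CE3"].exit_max_sample_count < 5

    def test_threshold_monotonicity(self, plus_locus, plus_index):
        inf_calls = call_cassette_exons(
            plus_index, plus_locus.gene, plus_locus.store, min_major_support=math.inf
        )
        assert all(c.ce_class != "CE1" for c in inf_calls)
        one_calls = call_cassette_exons(
            plus_index, plus_locus.gene, plus_locus.store, min_major_support=1
        )
        assert any(c.ce_class == "CE1" for c in one_calls)

    def test_strand_symmetry(self):
        calls = {}
        for strand in "+-":
            locus = simulate_locus(SimConfig(seed=42, strand=strand))
            per_sample, _ = simulate_junction_counts(locus)
            idx = build_junction_index(all_junctions(per_sample), locus.gene)
            got = call_cassette_exons(idx, locus.gene, locus.store)
            calls[strand] = (got, locus)
        plus_calls, plus_locus = calls["+"]
        minus_calls, minus_locus = calls["-"]
        total = minus_locus.store.contig_length(minus_locus.config.contig)
        mirrored = sorted(
            (total - c.segment.end, total - c.segment.start) for c in minus_calls
        )
        assert mirrored == sorted((c.segment.start, c.segment.end) for c in plus_calls)

    def test_readthrough_when_exit_missing(self, plus_locus):
        gene = plus_locus.gene
        truth = plus_locus.truth
        juncs = [JunctionRecord(truth.entry_intron, 20, "s1", "KO")]
        idx = build_junction_index(juncs, gene)
        calls = call_cassette_exons(idx, gene, plus_locus.store)
        assert len(calls) == 1
        assert calls[0].exit_junction == READTHROUGH
        assert calls[0].splice_sites[0] == "AG"
        assert calls[0].splice_sites[1] is None

    def test_call_invariants(self, plus_locus, plus_index):
        for c in call_cassette_exons(plus_index, plus_locus.gene, plus_locus.store):
            c.validate()
            assert c.host_intron.contains(c.segment)
            assert not any(
                c.segment.overlaps(e)
                for t in plus_locus.gene.transcripts
                for e in t.exons
            )


class TestClassifyIsoform:
    def test_nf155(self):
        flags = {23: True, 24: True, 27: False, 28: False, 29: False, 30: False}
        assert classify_isoform(flags) == "NF155"

    def test_nf186(self):
        flags = {23: False, 24: False, 28: True, 29: True, 30: True}
        assert classify_isoform(flags) == "NF186"

    def test_nf140_with_ex27(self):
        flags = {23: False, 24: False, 27: True, 28: False, 29: False, 30: False}
        assert classify_isoform(flags) == "NF140+ex27"

    def test_nf140_without_ex27(self):
        flags = {23: False, 24: False, 27: False, 28: False, 29: False, 30: False}
        assert classify_isoform(flags) == "NF140-ex27"

    def test_conflict(self):
        flags = {23: True, 24: True, 28: True, 29: True, 30: True}
        assert classify_isoform(flags) == "conflict"

    def test_indeterminate_on_missing_flags(self):
        assert classify_isoform({23: True}) == "indeterminate"
        assert classify_isoform({}) == "indeterminate"


def _exon(contig, start, end):
    return GenomicInterval(contig, start, end, "+")


def test_exon_flags_from_junction_evidence():
    # junction-spanning evidence mirrors junction-annealing primer logic:
    # ex22->ex23 marks 23 included; ex22->ex25 marks 23 and 24 skipped
    from crypticex.formats_io import GeneModel, Transcript

    exons = [_exon("c", 100 * i, 100 * i + 50) for i in range(1, 6)]  # ordinals 22..26
    gene = GeneModel(
        gene_id="G",
        gene_name="G",
        strand="+",
        transcripts=[Transcript("T", tuple(exons))],
        exon_ordinals={e: 22 + i for i, e in enumerate(exons)},
    )
    j_22_23 = JunctionRecord(
        GenomicInterval("c", exons[0].end, exons[1].start, "+"), 30, "s", "WT"
    )
    j_22_25 = JunctionRecord(
        GenomicInterval("c", exons[0].end, exons[3].start, "+"), 10, "s", "WT"
    )
    idx = build_junction_index([j_22_23, j_22_25], gene)
    flags = exon_flags_from_junctions(idx, gene)
    assert flags[23] is True  # 30 inclusion votes beat 10 skip votes
    assert flags[24] is False  # only skip evidence
    assert flags[22] is True and flags[25] is True


@pytest.fixture(scope="module")
def three_path_setup():
    # cassette exits past the next exon (to E19); exclusion reads split
    # between the with-E18 and the skip-E18 annotated paths
    cfg = SimConfig(
        seed=8,
        ce_exit_exon_offset=2,
        skip_junction_fraction=0.4,
        conditions=(Condition("WT", 0.2, 3, 200), Condition("cKO", 0.9, 3, 200)),
    )
    locus = simulate_locus(cfg)
    per_sample, _ = simulate_junction_counts(locus)
    idx = build_junction_index(all_junctions(per_sample), locus.gene)
    calls = call_cassette_exons(idx, locus.gene, locus.store)
    return locus, idx, calls


class TestSpliceforms:

    def test_three_paths_enumerated(self, three_path_setup):
        locus, idx, calls = three_path_setup
        paths = enumerate_spliceforms(locus.gene, idx, calls, 17, 19)
        labels = {p.labels for p in paths}
        assert labels == {
            ("E17", "CE1", "E19"),
            ("E17", "E18", "E19"),
            ("E17", "E19"),
        }

    def test_two_paths_without_cryptic_call(self, three_path_setup):
        locus, _, _ = three_path_setup
        # re-run without cryptic junctions: only the two annotated paths remain
        cfg = dataclasses.replace(
            locus.config, emit_cryptic_junctions=False
        )
        loc2 = simulate_locus(cfg)
        per_sample, _ = simulate_junction_counts(loc2)
        idx2 = build_junction_index(all_junctions(per_sample), loc2.gene)
        calls2 = call_cassette_exons(idx2, loc2.gene, loc2.store)
        paths = enumerate_spliceforms(loc2.gene, idx2, calls2, 17, 19)
        assert {p.labels for p in paths} == {("E17", "E18", "E19"), ("E17", "E19")}

    def test_path_support_conserves_donor_total(self, three_path_setup):
        locus, idx, calls = three_path_setup
        paths = enumerate_spliceforms(locus.gene, idx, calls, 17, 19)
        donor = calls[0].entry_junction[0]
        for cond in idx.conditions():
            assert sum(p.support[cond] for p in paths) == idx.donor_total(donor, cond)
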