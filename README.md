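# crypticex

Cryptic cassette-exon discovery and quantification from splice-junction
evidence. Given a gene annotation (GTF), a genome/locus sequence (FASTA) and
per-sample splice-junction files (regtools-style 2-block BED12), the pipeline:

1. **discovers** unannotated cassette exons inside annotated introns from
   junction evidence, classifies them as the major cassette (CE1) or weaker
   acceptor-sharing downstream-donor variants (CE2, CE3, ...), and flags
   canonical GT/AG splice sites;
2. **quantifies** donor-anchored percent-spliced-in (PSI =
   inclusion / (inclusion + exclusion) reads) per condition, with
   count pooling or per-sample averaging;
3. **annotates** the consequences: splices the cassette into the reference
   transcript, scans the ORF, flags premature termination codons, applies the
   50-nt NMD rule, and computes the truncated protein's average-mass
   molecular weight;
4. **scores** the intron downstream of the cassette donor for UG-dinucleotide
   richness and overlap with CLIP peak intervals (BED);
5. **reports** everything as deterministic TSVs, including a Sashimi-style
   junction arc table, plus optional ddCq relative-expression quantification
   from a Cq table.

A seeded synthetic-locus generator (`crypticex.synthetic_data`) emulates the
whole situation — multi-exon gene on either strand, planted 104-nt intronic
cassette with canonical splice sites and an in-frame stop codon, downstream
UG tract, binomial junction counts at configured true PSI — so every stage is
testable without downloading anything.

## Command line

```bash
# write a seeded synthetic fixture bundle (FASTA + GTF + junction BEDs +
# peaks + truth/manifest TSVs)
crypticex simulate --seed 1 --outdir fx/

# run the full pipeline from a YAML config
crypticex run-all --config config.yaml

# single-stage entry points (same config; print the stage's report path)
crypticex discover --config config.yaml
crypticex psi --config config.yaml --pooling mean_of_samples
crypticex orf --config config.yaml --nmd-rule-distance 55
crypticex motif --config config.yaml
crypticex report --config config.yaml     # Sashimi arc table
```

Config example:

```yaml
gtf: fx/annotation.gtf
fasta: fx/genome.fa
junctions:
  - {path: fx/junctions/WT_r1.bed, sample: WT_r1, condition: WT}
  - {path: fx/junctions/cKO_r1.bed, sample: cKO_r1, condition: cKO}
peaks: fx/peaks.bed          # optional CLIP peaks (BED3+)
cq_table: cq.tsv             # optional; enables ddCq expression report
calibrator: WT
genes: [SIMG1]
min_major_support: 5
nmd_rule_distance: 50
pooling: pool_counts
outdir: out
```

Outputs in `outdir`: `calls.tsv` / `calls.bed`, `psi.tsv`, `orf.tsv`,
`motif.tsv`, `spliceforms.tsv`, `sashimi.tsv`, optional `expression.tsv`,
and `run.log`. Exit codes: 0 ok, 1 input error, 2 stage failure.

## Conventions

* All internal coordinates are 0-based half-open; GTF (1-based inclusive) is
  converted at the I/O boundary.
* Junction BED12: the two blocks are alignment anchors, the gap is the
  intron, the score column is the junction-spanning read count.
* Donor/acceptor roles are assigned in transcript orientation (minus-strand
  gene: donor at the intron's high-coordinate end). Junctions with `.`
  strand are kept but excluded from strand-aware discovery.
* PSI with a zero denominator is *undefined* (reported as missing), never 0
  or 1.

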