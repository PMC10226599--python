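# cleavecall

Genotype-contrast calling of endoribonuclease cleavage sites from 5′-monophosphate
(5′P) degradome count tracks, with downstream site-feature analytics and a seeded
synthetic-data generator.

The core idea: an mRNA position cut by an endoribonuclease leaves a 5′P decay
intermediate that accumulates when the cytoplasmic 5′→3′ exonuclease is absent
(exonuclease-null genotype) but disappears again when the endoribonuclease is also
knocked out (double mutant). The pipeline scores per-position 5′-end counts from
three genotypes, applies a cascade of abundance, fold-change, decapping/TSS
proximity, sequence-uniqueness and expression filters, and classifies at most one
site per transcript as **MaxSeq** (the transcript's most abundant 5′P position) or
**MajorInternal** (second most abundant, behind a catalogued decapping site).

## Modules

| Module | Purpose |
| --- | --- |
| `cleavecall.annotation_io` | FASTA/GFF3(GTF) parsing, transcript models, spliced-coordinate arithmetic |
| `cleavecall.degradome_quant` | bedGraph I/O, CPM normalization, replicate pooling, log2 comparison tracks |
| `cleavecall.site_caller` | the filter cascade, MaxSeq/MajorInternal classification, target/nontarget/other sets |
| `cleavecall.feature_analysis` | region assignment, metagene & junction profiles, IUPAC motif scanning, k-mer enrichment, overlap/half-life/decap-shift statistics |
| `cleavecall.synthetic_data` | seeded simulator with planted ground truth and recovery scoring |
| `cleavecall.cli` | `cleavecall simulate / call / features / report` |

## CLI

```bash
# 1. simulate a dataset with planted truth
cat > sim.yaml <<EOF
seed: 1
n_transcripts: 200
EOF
cleavecall simulate --config sim.yaml --out data/

# 2. call cleavage sites (needs wild_type, xrn4, dne1_xrn4 and cap_pare bedGraphs)
cleavecall call --data data/ --out run/

# 3. feature reports for the site table
cleavecall features --sites run/sites.tsv --data data/ --out features/ --seed 1

# 4. human-readable summary
cleavecall report --run run/
```

A dataset directory contains `genome.fa`, `annotation.gff3`, per-library
per-strand bedGraphs named `<genotype>_rep<r>.{plus,minus}.bedgraph`, and
optional `rnaseq.tsv` (expression filter) and `halflife.tsv`. `call` emits
`sites.tsv`, the three control-set lists, and a `manifest.json` with config,
input checksums and per-filter survivor counts.

Pipeline thresholds (all exposed in `PipelineConfig` / `--config`): xrn4
CPM ≥ 5 with log2 FC ≥ 2 vs wild type and vs the double mutant, prefilter
CPM ≥ 1, decap catalog at Cap-PARE CPM ≥ 5, ±5 nt TSS/decap exclusion, 20-mer
genome+transcriptome uniqueness, one-sided expression check
(log2 FC ≤ −0.58, FDR ≤ 0.05), pseudocount 0.01 with zero-over-zero skipping.

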