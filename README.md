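# lncdiscover

Integrative discovery of transcription-factor-regulated, tissue-restricted
long non-coding RNAs (lncRNAs) from RNA-seq and ChIP-seq evidence.

## The problem

A classic route to finding functional lncRNAs — the one that surfaced
muscle regulators such as the MyoD-interacting lincRNAs — is a simple
conjunction of genomic evidence:

1. keep RefSeq transcripts with non-coding accessions (`NR_*`);
2. keep those expressed above a floor, **Σ<sub>samples</sub> RPKM > 1**,
   where RPKM = reads per kilobase of exonic transcript per million mapped
   reads: `rpkm = counts × 10⁹ / (exonic_length × library_size)`;
3. call differential expression across a differentiation time course with a
   fold-change rule, |log₂(FC)| ≥ log₂ 2;
4. call a transcript TF-regulated when at least one ChIP peak overlaps its
   promoter window — **5 kb upstream to 0.5 kb downstream of the TSS**,
   strand-aware (TSS = txStart on `+`, txEnd on `−`);
5. optionally require tissue-restricted expression across a tissue panel.

`lncdiscover` implements the full computational chain as a tested library
and CLI: annotation parsing (BED12 / refFlat), RPKM quantification, the
expression gate, fold-change DE calls (with an exact binomial test as a
clearly labelled significance stand-in), Pearson/average-linkage
hierarchical clustering of time-course profiles, the strand-oriented
binding-intensity profile (25-bp grid, 100-bp flank: at each grid position
count the reads within 100 bp whose orientation points toward it), a naive
Poisson fallback peak caller, promoter-window peak assignment, and the
final candidate report.

Because real discovery runs depend on large external sequencing archives,
the package ships a first-class synthetic-data module that plants known DE
transcripts, known strand-shifted ChIP pileups inside promoter windows, and
known tissue-restricted transcripts — so every stage, and the end-to-end
pipeline, is verifiable against machine-readable ground truth.

## Worked example

Simulate a dataset with planted truth, run discovery, score the result:

```sh
lncdiscover simulate --out-dir sim --seed 7
lncdiscover discover --out-dir run \
    --annotation sim/annotation.bed --chrom-sizes sim/chrom.sizes \
    --counts sim/counts.tsv --chip-reads sim/chip_reads.bed \
    --tissue-matrix sim/tissue.tsv
lncdiscover evaluate --report run/report.tsv --truth sim/truth.json \
    --out run/metrics.json
```

The discover step logs its stage counts to stderr:

```
INFO lncdiscover: 200 transcripts, 112 non-coding
INFO lncdiscover: 112 non-coding transcripts pass the expression gate
INFO lncdiscover: 36 differentially expressed at fold >= 2.0
WARNING lncdiscover: no peak intervals supplied: calling peaks with the NAIVE
    Poisson fallback caller (not a substitute for a dedicated caller)
INFO lncdiscover: naive caller produced 20 peaks
```

Of the 200 simulated transcripts, 112 are non-coding and expressed, 36 are
differentially expressed at two-fold, 20 promoter windows carry a peak, 14
transcripts are both DE and bound, and 5 additionally pass the
muscle-restriction filter — the 5 final candidates. `run/metrics.json`
scores them against the planted truth:

```json
{"f1": 1.0, "n_called": 5, "n_hit": 5, "n_truth": 5,
 "precision": 1.0, "recall": 1.0}
```

i.e. for this seed the pipeline recovers exactly the transcripts that were
planted as DE ∧ bound ∧ restricted. `run/report.tsv` ranks every
non-coding transcript by |log₂FC| with its full evidence trail
(`expressed`, `log2_fc`, `n_peaks_in_window`, `tf_bound`,
`tissue_restricted`, `candidate`), and `run/summary.json` echoes the counts
and configuration.

The same machinery is available as a library:

```python
from lncdiscover import simulate_genome, simulate_expression, simulate_chip
from lncdiscover.cli import discover_pipeline

tx, layout, truth = simulate_genome(seed=1)
matrix, de = simulate_expression(tx, seed=2)
reads, bound = simulate_chip(tx, layout, seed=3, enriched_ids=sorted(de))
calls, summary, peaks = discover_pipeline(tx, layout, matrix, reads=reads)
```

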