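# Methods

## Model and procedure

`lncdiscover` screens a transcript annotation for lncRNA candidates by a
conjunction of independent evidence axes, evaluated per transcript:

```
candidate  =  non-coding  ∧  expressed  ∧  DE  ∧  TF-bound  [∧ restricted]
```

* **Non-coding** is decided from the RefSeq accession prefix alone
  (`NR_` = non-coding); no ORF scanning or coding-potential model is used.
  The screen therefore inherits whatever the annotation says about coding
  status.
* **Expressed** means Σ over samples of RPKM strictly greater than 1
  (`rpkm = counts × 10⁹ / (exonic_length_bp × library_size)`). The
  inequality is strict: a row summing to exactly 1.0 is dropped.
* **DE** compares mean RPKM between two sample sets with the rule
  |log₂(mean_A/mean_B)| ≥ log₂(fold_threshold), default two-fold. No
  pseudocount is used; zero-versus-positive yields ±∞, which exceeds any
  threshold — this keeps the fold rule exact on clean inputs, at the cost
  of calling any transcript that is fully off in one condition. log₂FC is
  computed as log₂(mean_A) − log₂(mean_B) so swapping conditions negates
  it exactly. An exact two-sided binomial test (pooled count k_A out of
  k_A + k_B against the library-size proportion N_A/(N_A+N_B), "minlike"
  two-sidedness) is available as a significance stand-in; output metadata
  labels it as such, because it is not the original pipelines' DE
  statistic. Conditions may be single samples, as in a one-library-per-time-
  point differentiation course; by default the later half of the samples is
  condition A and the earlier half condition B.
* **TF-bound** means at least one ChIP peak overlaps the promoter window,
  defined strand-aware as [TSS − 5000, TSS + 500) on `+` transcripts and
  mirrored on `−` (TSS = txEnd there). Windows are clipped at chromosome
  edges, never silently dropped; clipping to zero length is an error.
  Whether the published "start site" was strand-aware was genuinely open;
  we chose strand-aware and expose `tss_mode="tx_start"` for the
  alternative. Overlap is half-open, ≥1 bp.
* **Restricted** (optional, used only when a tissue panel is supplied):
  RPKM in the target tissue ≥ 1 and ≥ 5× the maximum over all other
  tissues — a computable surrogate for a Northern-blot-style panel screen.

Coordinates are 0-based half-open throughout (BED convention).

## Binding-intensity profile and the fallback caller

The oriented profile at 25-bp grid positions counts reads whose 5′ end is
within 100 bp and whose orientation points toward the position (forward
reads at or left of it, reverse reads at or right of it). Between a site's
forward and reverse clusters both strands point inward, producing the
plateau the statistic is designed to expose. Boundary ties (read exactly at
the position, |pos5 − p| exactly = flank) count, on both strands; the grid
is anchored at coordinate 0. These tie rules were unstated in the source
pipelines and are fixed here and enforced by brute-force oracle tests.

Peak calling proper is treated as an upstream input (dedicated callers do
it better); the shipped fallback is deliberately naive and labelled so in
its output: background rate λ = mean grid count of the chromosome, a bin
with count c is significant when P(X ≥ c; Poisson λ) falls below the
per-bin threshold, and ≥ 2 consecutive significant bins form a peak scored
by the maximum bin. The default per-bin threshold is genome-wide corrected,
`p_cutoff / n_bins` (Bonferroni): with ~40 000 bins per Mb an uncorrected
per-bin 0.05 would declare bins of count 2 significant at typical
background rates and emit tens of chance peaks per megabase from read
pairs alone, which would be useless as a binding call. `correction="none"`
restores the uncorrected per-bin rule for exploration.

## Clustering

Time-course overview clustering follows the classic expression-matrix
recipe: log₂(RPKM + 1) (the pseudocount keeps zeros at zero and is a
flag), row mean-centring, row scaling to unit sum of squares; constant
rows are dropped with a warning. Distance is 1 − Pearson r with average
linkage — common defaults for this kind of software, since the original
choice was not recorded. Merges are deterministic: among minimum-distance
pairs the lowest (i, j) node pair wins; leaf order is the left-before-right
traversal of the merge tree. Distances within 1e-12 of zero are snapped to
zero so identical profiles merge at height exactly 0. The implementation
is verified against a full-recomputation average-linkage oracle on small
instances.

## Synthetic data: what it emulates, and what it does not

The simulator generates the study conditions the pipeline is validated
under; its defaults are the validation conditions, not tuning knobs.

* **Genome** (default 2 × 1 Mb, 200 transcripts, 50% non-coding,
  1–4 exons): non-overlapping transcripts, 500–2500 bp, ≥ 6 kb from
  chromosome ends and ≥ 6.2 kb apart, so promoter windows are never
  truncated and can never reach a neighbour's planted site. Real genomes
  violate both properties (overlapping isoforms, bidirectional promoters);
  passing recovery tests therefore says nothing about peak-to-gene
  ambiguity in dense loci.
* **Expression** (4 time points, depth 10⁶, NB dispersion 0.1, 15% DE at
  4-fold): baselines log-normal (σ = 1) normalized to depth; planted-DE
  hosts (non-coding, split evenly up/down) have the later half of time
  points multiplied by fold or 1/fold and their baselines floored at 100
  expected counts so planted signal clears the expression gate. Library
  sizes are realized column sums, so planting DE shifts them slightly —
  exactly as in real data. Not emulated: replicate/batch structure,
  isoform-level ambiguity, length biases.
* **ChIP** (10% bound, 60 reads/site, shift 75 bp, positional SD 15 bp,
  background 1 read/kb): per site, half the reads are forward at
  Normal(summit − 75, 15) and half reverse at Normal(summit + 75, 15) — the
  ~150-bp strand separation sits at the scale the 100-bp-flank statistic is
  most sensitive to. Summits are planted near the TSS (offsets −700..+300
  along transcription). Bound hosts are drawn half from the planted-DE set
  (`enriched_frac = 0.5`), emulating TF-driven regulation — the premise of
  this kind of screen; fully independent axes would make the planted
  DE ∧ bound truth set vanishingly small. Not emulated: fragment-length
  variation, mappability, input/control structure.
* **Tissue panel** (8 tissues, 5% restricted, on 10 / off 0.1, log-normal
  noise σ = 0.25): restricted hosts likewise drawn half from the
  DE ∧ bound set, mirroring a lineage-specific transcript population.
* **Recovery metric**: precision/recall/F1 of final candidates against the
  planted DE ∧ bound (∧ restricted when simulated) set; with no calls
  precision is vacuously 1 and with empty truth recall is 1.

Problem sizes everywhere (200 transcripts, 2 Mb, 20 seeds) were chosen as
the smallest at which the planted-signal geometry is representative; the
whole validation study runs in seconds.

## Numerical choices and degenerate inputs

* Exact binomial p-values sum the probability mass of outcomes no more
  likely than the observed one, with a 1e-10 relative tie tolerance;
  tested against exact rational arithmetic to 1e-12.
* The expression gate, fold threshold and peak-overlap rules are exact
  comparisons, not tolerance-based.
* Duplicate ChIP reads are kept by default (unique-alignment filtering is
  an upstream responsibility); `dedup` collapses identical
  (chrom, pos5, strand) triples.
* Unknown transcript ids in the DE × bound intersection warn and count as
  unbound, so partial inputs (e.g. peaks for one chromosome) still run.
* Report rows are sorted by |log₂FC| descending with ±∞ first, ties by id;
  rows without a DE call sort last. Floats are written with 6 significant
  digits. The summary JSON echoes analysis parameters (not filesystem
  paths), so identical configurations give byte-identical outputs.
* CLI exit codes: 0 success, 2 usage, 3 validation, 4 I/O.

## Known limitations

* Transcript-level calls; the gene-union mode merely pools promoter
  windows of transcripts sharing a symbol.
* The stage order is fixed as gate → DE → bound; orderings that gate after
  DE would score borderline transcripts differently.
* No GO/gene-set enrichment, no motif analysis, no distal (enhancer) peak
  assignment, no isoform quantification, and no coding-potential
  assessment beyond the accession prefix.
* The naive caller has a single global background rate per chromosome; it
  is a pipeline-completeness device, not a peak caller for real data.
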