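# Methods

This note documents the models, defaults and numerical choices behind
`beredit`, and what the synthetic benchmarks do and do not demonstrate.

## Edit-calling model

Input is a pair of per-position base-count tables (treated and control)
over the reference plus strand, with the contract that base- and
mapping-quality filtering has **already been applied upstream** (the
counts stand in for `bam-readcount -q 20 -b 30` output); the package does
not traverse BAMs. A site is called an RNA A-to-I edit iff all of:

1. it lies inside exactly one annotated transcript (positions covered by
   transcripts on both strands are strand-ambiguous and excluded);
2. the transcript-orientation reference base is A (plus-strand gene with
   reference A, or minus-strand gene with reference T);
3. treated depth ≥ `min_depth` (default 10), transcript-orientation A→G
   reads ≥ `min_alt_reads` (default 3) and alt fraction ≥
   `min_alt_fraction` (default 1%);
4. the control covers the site at ≥ `min_depth` with reference fraction ≥
   `control_ref_fraction` (default 99%). Sites without sufficient control
   coverage are excluded (conservative: the reference-fraction test must
   be evaluable).

Efficiency is `alt_reads / depth` on the treated sample. `germline_like`
mode adds `efficiency ≥ 0.10`, an explicit emulation knob for the
detection floor of germline-oriented callers — not a model of any
caller's internals; upstream caller-specific annotations (e.g. quality-
by-depth) cannot be derived from pileup counts and are represented only
through this mode. Because the germline filter is a superset of the
somatic one, germline calls nest inside somatic calls and
`sensitivity_fold ≥ 1` by construction.

The alt-read floor (3 reads / 1%) is a deliberate addition: candidate
detection is normally delegated to an upstream caller, and without a
floor sequencing error floods the candidate list. Endogenous subtraction
removes any call whose (chrom, pos) appears in an endogenous set; the
pipeline derives that set from the control pileup itself (sites with alt
evidence in the control), mirroring the use of an untreated
transcriptome as endogenous-editing control.

## Motif model

Contexts are 9-nt transcript-orientation windows with the edited A at
the center (minus-strand genes are read through the stored, already
reverse-complemented transcript sequence). Strata use strict
inequalities (>20%, >40%). The position frequency matrix is the
column-wise base frequency; information content is `2 − H` bits with
Shannon entropy in bits, no small-sample correction and no pseudocounts;
non-ACGT bases are dropped per column with renormalisation. The center
column is pure A, hence exactly 2 bits. Motif distance is per-column
total variation, `0.5 · Σ_b |p_b − q_b|`.

## Amplicon model

Reads are globally aligned (Needleman–Wunsch, linear gaps; defaults
match +2 / mismatch −3 / gap −5, SNV-tolerant amplicon settings) to the
amplicon reference. A read is mapped when its score reaches
`min_score_fraction` (default 0.6) of its self-alignment score. On equal
score the traceback prefers match/mismatch over deletion over insertion,
which places gaps toward the sequence starts; minus-strand protospacers
are quantified in protospacer orientation (reads and reference
reverse-complemented first), so tie-breaking and PAM-distal numbering
are orientation-invariant and the strand round-trip is exact by
construction.

A read is indel-containing iff its alignment places ≥ 1 inserted or
deleted base within the 20-nt protospacer interval (insertions anchored
between positions k and k+1 count when k is inside the interval).
`indel_frequency = indel-containing reads / all mapped reads`; the
denominator deliberately includes every read passing the mapping
threshold. Substitution rates are computed only from reads **without**
protospacer indels, because alignment columns across an indel are
ill-defined; their denominator is that indel-free read count.
Window summaries take the maximum A→G rate over reference adenines in
the window (presets 4–8 for reporting, 2–9 for heat maps; ties go to the
smaller, more PAM-distal position). Fold changes are
`log2((v + pc)/(r + pc))` with pseudocount 0.01 to keep unedited
positions finite.

## Synthetic data: what it emulates

The generator reproduces the statistical structure the analysis depends
on, not raw reads:

- **Transcriptome** — 2,000 single-exon transcripts of 200–600 nt laid
  head-to-tail on 5 chromosomes, ~half on the minus strand. No introns,
  splicing, overlapping genes or expression differences: none of these
  change the per-site arithmetic under test.
- **Planted edits** — 500 sites: 100 motif sites carrying the DNA
  context `TACGA` (edited A last) with efficiency ~ Beta(10, 2); 360
  background sites ~ Beta(0.2, 60); 40 endogenous sites ~ Beta(5, 8)
  edited identically in treated and control. The mixture mirrors the
  published signature — a large mass of sub-10% edits (here ≈ 72% of
  planted sites) with motif-context adenines concentrated at high
  efficiency — and gives ≈ 110 recovered sites, enough that the 3-SD
  calibration criterion tolerates the occasional binomial tail event.
  Endogenous efficiencies are moderate, as typical for curated
  endogenous A-to-I sites.
- **Counts** — depth ~ NegativeBinomial(mean 50, size 20) truncated at
  ≥ 1 (mild RNA-seq overdispersion); at an edit of efficiency *e*, alt
  reads ~ Binomial(depth, e); remaining reads substitute to each non-
  reference base at `per_base_error_rate / 3` with
  `per_base_error_rate = 1e-4`, the residual error plausible after
  Phred ≥ 30 base- and mapping-quality filtering. Minus-strand-gene
  edits are emitted as T→C on the reference plus strand.
- **Amplicon reads** — each read independently applies the planted
  per-position A→G profile, converts unedited protospacer adenines to
  C/T at `nonG_rate`, applies uniform sequencing error, and with
  probability `indel_rate` receives one 1–3 nt insertion or deletion at
  a uniform position inside the protospacer. Qualities are constant Q30
  (quality filtering is modelled as pre-applied throughout).

Everything is driven by one seed (streams split via
`numpy.random.SeedSequence`), making all outputs bit-identical across
runs.

**What passing tests do not show about real data:** no splice
junctions, duplicates, mapping bias, strand-ambiguous overlapping
genes, expression-dependent coverage, batch effects or
quality-score-dependent errors are simulated, and the caller-mode fold
emulates only the allele-fraction floor, not reassembly or
active-region behaviour of real germline callers. Recovery rates here
are therefore upper bounds on real-data behaviour, not predictions.

## Benchmark scenarios and problem sizes

- **Default recovery run** — the conditions above (2,000 transcripts /
  500 edits / depth 50). Expected behaviour, from the site-level power
  analysis used to fix the defaults: sensitivity ≈ 0.985 for true
  efficiency ≥ 5%, ≈ 0 false calls (error sites cannot reach 3 alt
  reads at 1e-4 error), efficiency estimates within 3 binomial SDs of
  truth at ≈ 99.6% of recovered eligible sites. That last figure is a
  per-site rate: across ~110 sites an individual run occasionally dips
  just below 99%.
- **Calibration scope** — the 3-SD check is evaluated on sites recovered
  from the eligible set (true efficiency ≥ 5%). Sites below the
  detection floor enter the call set only via upward sampling
  fluctuations, so their estimates are > 3 SD high by construction
  (winner's curse); the all-calls fraction is reported separately in
  `report.json` rather than mixed into the calibration metric.
- **Fold scenario** — 125 motif + 375 background ~ Beta(8, 150) sites
  (≈ 75% below 10% efficiency, none below the detection limit), depth
  300, error 1e-5: the somatic/germline fold then equals the
  truth-table ratio `N_total / N_(e ≥ 0.1)` ≈ 4 up to sampling noise
  (±20% tolerance in tests).
- **Aligner sweep** — exhaustive pairs over a 2-letter alphabet to
  length 6 in the test suite (~1.6 × 10⁴ pairs; the acceptance script
  uses length 5 exhaustively plus 4,000 sampled pairs to length 8)
  against a memoised exhaustive recursion written independently of the
  production DP; Biopython's `PairwiseAligner` provides a third,
  library-independent score check.
- **Amplicon demo** — 10,000 reads, planted profile
  {pos 4: 0.15, pos 5: 0.60, pos 9: 0.08}, `indel_rate` 0.05,
  `nonG_rate` 0.004, error 1e-3 on a 120-bp amplicon with a plus-strand
  protospacer at 41–60.

## Degenerate inputs and tie-breaks

Empty transcriptomes, empty call sets and empty motif strata return
empty-but-valid objects (a stratum with no contexts yields an all-zero
matrix with n = 0, not an exception). A window without adenines returns
a flagged empty result. A zero germline denominator flags the fold
result instead of raising. Config validation reports every problem at
once. Chromosome order for Manhattan offsets is natural sort,
configurable. VCF ingestion keeps only single-nucleotide A>G / T>C
records consistent with the annotated strand; efficiencies come from
FORMAT/AF, then INFO/AF, then FORMAT/AD, else default to 1 (presence
only); malformed records raise with their record index.

## Known limitations

- One transcript per locus; the transcribed-strand rule is undefined for
  genes overlapping on both strands, and such sites are dropped.
- The germline-mode emulation is a single efficiency threshold; real
  caller disagreement has additional causes (depth, local assembly,
  filters) that are out of scope.
- Amplicon substitution rates ignore reads with protospacer indels; if
  indels and substitutions co-occur on the same molecules, substitution
  rates are conditional on the indel-free subpopulation.
- Sequencing error is uniform and quality-independent; the pileup error
  model has no strand bias or position effects.
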