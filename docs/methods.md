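# Methods

`orfgenesis` reconstructs the evolutionary history of a single-exon
protein-coding sequence (CDS) from a multiple genome alignment and
characterizes its coding and regulatory signatures. This note documents the
models, conventions and numerical choices behind each stage, and what the
synthetic-data generator does and does not emulate.

## Reference-anchored alignment (alignio)

Genome-browser MULTIZ alignments arrive as MAF blocks in plus-strand
reference coordinates. `stitch_cds` cuts the blocks down to the CDS interval
and concatenates them into one gapped matrix with a total, strictly
increasing map from each 1-based reference CDS position to its alignment
column. Conventions:

- **Coordinates** are 1-based inclusive everywhere in the public API
  (position 1 = first coding base); column indices are 0-based and internal.
- **Overlapping blocks** covering the same reference position: the block
  with more non-gap rows wins; ties go to the first block encountered, and
  the conflict is logged.
- **Uncovered reference positions** are emitted as `N` in the reference row
  with gaps in every other row, keeping the column map total.
- **Minus-strand intervals** are reverse-complemented after stitching so
  that CDS position 1 is the first coding base.
- **Alignable fraction** counts reference positions at which a species has a
  non-gap, non-`N` base, divided by the CDS length. IUPAC ambiguity codes
  count as aligned (they are real, if uncertain, bases); `N` does not,
  because MULTIZ uses it for low-quality fill. Gap columns inside otherwise
  aligned spans therefore do *not* count as aligned — the alternative
  convention (counting spanned-but-gapped positions) would raise every
  fraction slightly and is intentionally not used.
- A species expected in the alignment but present in no block is kept with
  fraction 0 and an `absent` flag rather than dropped, so downstream
  summaries can distinguish "absent from the genome" from "not requested".

## ORF-disruption tracing (orftrace)

For each species the scanner walks the alignment columns spanning the
reference CDS left to right and records four kinds of disruption:

- **start_loss** — the species bases aligned to reference codon 1 are not
  `ATG` (a fully unaligned first codon is a start loss with an `unaligned`
  note), reported at position 0;
- **frameshift_deletion / frameshift_insertion** — each maximal indel run
  (species gaps at reference positions, or species bases at reference-gap
  columns) whose length is not a multiple of 3. Detection is per run, not
  net-offset: two adjacent compensating runs are both reported even though
  the frame recovers. Insertions are anchored at the next reference base;
- **premature_stop** — the first stop codon encountered when the species
  sequence is read in the frame set by the start codon and shifted by the
  cumulative indel offset, provided it begins upstream of the reference stop
  codon. Stops in other frames are ignored;
- **nonstop** — no in-frame stop anywhere in the aligned span, reported at
  CDS length + 1.

**Protein-homology fraction.** The share of the reference protein N-terminal
to the first disruption, computed on coding nucleotides: (first event
position − 1) / coding length, where the coding length excludes the stop
codon (405 nt for a 135-codon protein). A 1-bp deletion at nucleotide 12
gives 11/405 = 2.7%, i.e. 3% rounded. Start loss gives 0. A species whose
*first* (only) disruption is nonstop also gets 0: a transcript without an
in-frame stop codon is a substrate of non-stop decay and yields no stable
protein, so no part of the reference protein is recoverable from it. This is
a deliberate convention — the alternative (treating the intact upstream
sequence as homologous) would report a fraction of 1.0 for a transcript that
cannot be translated into a comparable protein.

## Event placement on the phylogeny (phyloevents)

Shared disruptions are matched across species by identity — kind, reference
position and indel length — and placed under a Dollo-style single-gain
model: identical frameshifting indels and stop mutations are vanishingly
unlikely to recur independently, so an event carried by every informative
tip of a clade (and nothing outside it) is assigned to that clade's stem
branch. Details:

- Tips with alignable fraction below a configurable floor (default 0.10) are
  uninformative: too little of the CDS aligns for their ORF calls to mean
  anything, so they neither support nor veto a placement.
- The reference species is an informative non-carrier (its report is the
  identity), which prevents placements from creeping rootward past the
  reference lineage.
- Carrier sets that are not monophyletic are flagged `ambiguous` and
  decomposed into their maximal carrier clades, one placement per clade —
  the analyst decides between convergence and independent loss.
- `fitch_ancestral` provides two-pass Fitch parsimony for arbitrary discrete
  characters (state sets at internal nodes, ties kept as multi-state sets,
  minimum change count). On binary trees the count is exact; multifurcations
  use the majority-overlap generalization.
- `clade_lower_bound` bounds an ancestor's alignable CDS content by the
  maximum over its descendants' fractions — sequence present in any
  descendant was present in the ancestor, barring independent gain.

## Codon-usage bias (codonbias)

The score of a codon sequence C₁…Cₙ is the per-codon mean log-likelihood
ratio against a uniform triplet null:

    score = (1/n) Σᵢ ln( F(Cᵢ) / (1/64) )

with F a codon-frequency table estimated from known coding sequence. The
per-codon mean (rather than the raw sum) makes scores comparable across
genes of different lengths; natural log is the default and the base is
configurable. The terminal stop codon is removed before scoring and table
frequencies are renormalized over the 61 sense codons (a caller supplying an
exact-scale table, such as the literal 1/64 null, can disable
renormalization). The shipped human nuclear codon-usage table (standard
GenBank-derived frequencies per thousand codons) yields a usage-weighted
genome-average score of ≈0.15 under these conventions, matching the
published average for human genes — the calibration that fixes the log base
and normalization choices.

Significance is a composition-preserving permutation test: the nucleotides
of the CDS are permuted uniformly at random, each permutation is scored in
frame, and p is the fraction of `n_reps` permutations (default 10,000)
scoring at least as high as the observation. Permutations containing
in-frame stop codons are not rejected; their stop codons are simply skipped
in the per-codon mean (a stop carries no usage signal and has no defined
sense-codon frequency). The smallest reportable p is 1/n_reps and is
included in the result; the replicate count and seed travel with every
result for reproducibility.

## Ka/Ks (kaks)

The estimator is classical synonymous/nonsynonymous counting:

- **Sites.** Each codon position contributes the fraction of its three
  possible base changes that are synonymous; changes that create a stop
  codon count as nonsynonymous opportunities, so synonymous + nonsynonymous
  sites always total exactly 3 per codon. Pair sites are the average of the
  two codons' counts.
- **Differences.** Codons differing at 2–3 positions are decomposed into all
  orderings of single-base steps; orderings that pass through an
  intermediate stop codon are excluded (all are used if every ordering is
  blocked) and the per-step synonymous/nonsynonymous labels are averaged
  with equal weights.
- **Correction.** Proportions are Jukes-Cantor corrected,
  d = −(3/4)·ln(1 − 4p/3); p ≥ 0.75 is saturation and an error.
- **Pooling.** For a multiple alignment, counts are summed over
  reference-vs-other pairs after listwise removal of codon columns
  containing a gap or `N` in any retained species; per-pair results are
  always reported alongside the pooled ratio.
- **Confidence interval.** A parametric Monte Carlo: synonymous and
  nonsynonymous difference counts are resampled binomially at the estimated
  per-site proportions (the sampling distribution the estimator would see
  over simulated sequence pairs at those rates), the ratio is re-estimated
  per replicate, and the 2.5/97.5 percentiles are reported. Replicates that
  saturate or produce zero synonymous differences are dropped from the
  percentile computation. Ks = 0 leaves the ratio undefined and the CI
  omitted, flagged rather than silently infinite.

This is a deliberate approximation to the more elaborate site-classification
estimators used by dedicated Ka/Ks software; agreement with published values
computed by such tools should be judged within their confidence intervals,
not to three decimals.

## Promoter features, PCR, tracks (seqfeatures)

- **TSS-relative coordinates** follow promoter convention: the TSS base is
  +1, the base immediately upstream is −1, and there is no position 0.
- **GC window**: fraction of G+C over the 201-base window centered on the
  TSS (±100 bp); promoters below the configurable threshold (default 0.45,
  between the GC-poor TATA regime and CpG-island territory) are classified
  GC-poor, at or above it GC-rich. The threshold is reported with every
  classification.
- **Motif scanning** is exact IUPAC-consensus matching on the given strand,
  restricted to each motif's TSS-relative window; no position-weight
  scoring.
- **In-silico PCR** is exact-match only: the forward primer as written, the
  reverse complement of the reverse primer strictly downstream, product
  length spanning the outer primer ends, all products up to `max_product`
  reported sorted. Mismatch tolerance and melting temperature are out of
  scope — expected sizes on a reference template need neither.
- **Track summaries** report the arithmetic mean and the *population*
  standard deviation (divisor n, not n−1); missing bases are skipped and
  counted. The sd convention is recorded here because published mean±sd
  values rarely state it.

## Synthetic data (synthdata)

`simulate_cds_evolution` evolves a root ORF down a rooted tree. Per branch:
HKY-flavoured substitutions (transitions twice as likely as each
transversion) at the branch's substitution rate; indels at the indel rate
with geometric lengths of mean 2 (so 1-bp frameshifts are the most common
event, as in real pseudogenization) and equal insertion/deletion odds;
scripted events applied deterministically after the stochastic process.
Column identity is tracked through the simulation, so the emitted alignment
is the *true* alignment — there is no realignment step, which isolates the
ORF tracer and event placer from aligner error by design. The generator
returns the true branch placement of every scripted event for closed-loop
testing.

What it does not emulate: selection (no dN/dS-aware codon model),
rate heterogeneity across sites, alignment error, and assembly artifacts.
Passing the closed-loop suites therefore demonstrates the correctness of the
tracing and placement logic on faithful alignments, not robustness to
misalignment — on real data, alignment quality is a separate concern.

`simulate_expression` draws a standard-normal focal profile and plants
partners at exact population correlation r (partner = r·focal +
√(1−r²)·noise), with optional additive group effects; remaining genes are
independent noise. Real microarray structure (batch effects, heteroscedastic
noise, gene-gene correlation beyond the planted partners) is not modelled.
`make_promoter` draws background bases to a target GC in expectation and
writes motif texts verbatim at TSS-relative positions, rejecting overlaps.

All generators are deterministic given their seed.

## Problem sizes and defaults used in the test and acceptance suites

The packaged suites run on a 135-codon CDS (405 coding nt — the focal
gene's dimensions), trees of 6–11 tips, 50 random evolution scenarios,
permutation tests at 200–4,000 replicates, Ka/Ks CIs at 1,000 Monte-Carlo
replicates with coverage judged over 100 seeded runs, and expression
matrices up to 1,000 genes × 60 samples (the scale of the public
breast-cancer set the analysis layer mirrors). These sizes give stable
statistics for every property tested while keeping the full suite fast.

## Known limitations

- Single-exon CDSs only; no splice-aware stitching or chain/net handling.
- Event matching is by exact identity; near-identical events (e.g. the same
  stop arising one codon apart in two species) are treated as distinct.
- The Ka/Ks CI resamples counts, not sequences, so it ignores the (small)
  variance contribution of site-composition differences between replicates.
- Percentile ranks in the expression screen are by signed correlation with
  no multiple-testing correction, matching the exploratory analyses they
  reproduce; they are screening statistics, not calibrated p-values.
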