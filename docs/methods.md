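# Methods

## The CUB statistic and its ranking

Codon usage is summarized over all 64 DNA triplets in the classical
codon-table order (TTT, TTC, TTA … GGG; base order T, C, A, G). Stop codons
are counted like any other bin: the reference "artificial gene" is the
concatenation of every protein-coding gene and therefore contains internal
stops, and excluding bins would change the geometry of the distance for no
principled gain. Frequencies, not raw counts, enter the Euclidean distance,
so gene length influences only the sampling noise of a gene's vector, not
its scale. The reference pool includes the focal gene itself — the pooled
profile is defined over *all* protein-coding genes, with no leave-one-out
step — except in the de novo deviation (below), where the focal acr is
excluded from the CDS pool by default to keep the two reference pools
symmetric with respect to the gene being measured (`exclude_acr_from_cds`
toggles this).

Ranks come from a stable descending sort: rank 1 is the largest distance
(strongest bias), ties break by input gene order so ranks are always a
bijection onto 1..n. Percentiles are rank / n in (0, 1].

Codons containing non-ACGT characters are dropped and tallied per gene
(`n_skipped`), as is a trailing 1–2 nt remainder; a sequence shorter than
one codon produces an empty vector and a warning rather than an error, so
one malformed annotation cannot abort a genome-wide scan.

## ORF discovery and the intergenic class

The six-frame scanner reports maximal ORFs: from the 5′-most ATG after the
previous in-frame stop to the first stop (TAA/TAG/TGA, translation table
11), stop codon included in the interval, minimum length 75 nt by default
(the conventional ORF-finder default; configurable). Alternative start
codons are deliberately out of scope — ATG-only keeps the oracle semantics
exact and changes little for the statistics built on pooled ORF codon
usage.

An ORF is *intergenic* when its overlap with the union of all annotated
CDS intervals is strictly below 3% of the ORF's own length. Three choices
are worth making explicit: the denominator is the ORF length (the ratio is
a property of the ORF); overlap is computed against the interval union
(not the worst single CDS), so tiled annotations are not double-counted;
and the inequality is strict, so a ratio of exactly 0.03 is classified as
CDS-overlapping.

Virus genomes enter the de novo analysis only when completely assembled,
hosted by bacteria or archaea, and carrying 20–50 CDS (bounds inclusive);
a metadata row missing a field fails with a distinct reason rather than
crashing the batch.

## The de novo deviation

For each acr, `deviation = CUB(acr vs CDS pool) − CUB(acr vs intergenic
ORF pool)`; positive values mean the acr's codon usage is closer to
intergenic DNA. Pools are per genome — each genome supplies its own CDS
and intergenic references — because the comparison is between a gene and
*its* genome's two sequence classes; cross-genome pooling would mix codon
backgrounds. The acr-pinpointing e-value cutoffs default to 1e−3 and 1e−6
(both configurable, both inclusive).

## The genomic-island Monte Carlo test

Genes are assigned to islands by midpoint containment in the BED
intervals (genes straddling a boundary follow their midpoint). Each
iteration draws, without replacement, as many non-GI genes as there are
GI genes and records their mean rank; the one-sided empirical p (GI genes
expected at numerically small ranks) uses the add-one estimator
(1 + B)/(1 + n_iter), which is never zero and is exact in expectation for
the permutation null up to the complement effect noted below. The default
is 10 000 iterations.

A structural property of this design, inherited from the procedure it
implements: the null is resampled from the *complement* of the GI set, so
when GI genes happen to sit low in the ranking the remaining non-GI genes
necessarily sit high, and the test is mildly anti-conservative when the
GI fraction is large. At the ~3% GI fractions typical of annotated
islands the measured type-I error is statistically indistinguishable from
the nominal 5%; calibration checks therefore use a 3% GI fraction
(6 of 200 genes).

## Neighbor triage

Neighborhoods are the three genes on each side of a seed acr, truncated at
contig ends (a `circular` flag enables wraparound for phage genomes). The
"no validated function" exclusion is operationalized as a configurable
allow-list of unknown-function annotation substrings (hypothetical
protein, uncharacterized protein, unknown, or an empty product), matched
case-insensitively. All similarity thresholds are inclusive: catalog
match at e-value ≤ 0.01 and identity ≥ 35%; PDB chain mapping at e-value
≤ 1e−10, ≤ 1 mismatch and coverage ≥ 95%, where coverage is aligned query
length over full query length. Venn consensus statistics are exact set
arithmetic over the three predictor call-sets; directional overlap shares
|A∩B|/|B| are reported as percentages rounded half-up to two decimals.

## The synthetic-data generators

The generators produce the inputs the analyses assume, not phage biology.
Codon models are Dirichlet draws concentrated (α = 5 vs. 0.2) on two
disjoint halves of the 61 sense codons; `separation` ∈ [0, 1] linearly
interpolates a pool's model from the background toward the alternative.
Genes are an ATG, internal codons drawn i.i.d. from the model (stop
codons carry zero internal mass), and a uniform stop. Defaults are
desk-scale: host genomes of ≤ 100 genes with lengths 150–600 codons,
phage genomes of 20–50 CDS (150–300 codons) with planted intergenic ORFs
(80–160 codons) and 62–202-codon acrs, inter-gene gaps of uniform random
sequence. Each planted ORF is preceded by three in-frame stops so the
six-frame scan recovers exactly the planted interval, and sits wholly
inside an annotation gap (overlap 0 < 3% by construction).

What the generators do *not* emulate: real operon structure, GC skew,
amelioration gradients in transferred genes, tRNA-driven codon selection,
or overlapping genes. Passing tests therefore demonstrate that the
statistics recover the signals they are defined to detect under their own
generative assumptions, not that real acrs are born de novo.

Two deliberate design points in the evaluation conditions:

- **Null calibration of the deviation.** The null condition requires all
  three pools (acrs, CDS, intergenic ORFs) to be draws from one shared
  codon distribution. Spurious ORFs found by a six-frame scan in
  off-frame or reverse-strand readings of generated sequence are *not*
  draws from that model, so null-condition runs feed the deviation the
  generator's truth ORFs, while the signal conditions run the full
  scan-and-classify pipeline. The null generator also balances the
  expected codon mass of the CDS and intergenic pools (29 ORFs of
  250–350 codons against 29 non-focal CDS of the same length range, one
  acr per genome): a finite-size asymmetry between the two reference
  pools inflates the distance to the smaller pool and biases the
  deviation sign even under a shared model.
- **Monte Carlo evaluation sizes.** Calibration uses 100 label shuffles
  at 999 iterations (p resolution 1/1000, ample for α = 0.05); power
  uses 100 seeded genomes of 60 genes with a 10-gene island at
  separation 0.8. Simulation sizes throughout (50–500 genomes per
  condition) were chosen so that binomial sampling error is small
  relative to the margins being tested.

## Numerical and degenerate-input conventions

Internal coordinates are 0-based half-open; GFF3 (1-based inclusive) and
BED convert at the boundary. Multi-segment CDS sharing a GFF3 ID are
concatenated in transcription order. Empty codon vectors are an error in
distances but a warning in counting. Histogram bins align to multiples of
the bin width so summaries are reproducible. All stochastic entry points
take an explicit seed and are byte-reproducible; the CLI writes the full
effective configuration into a comment header of every output.

## Known limitations

The CUB distance ignores amino-acid composition, so it conflates codon
*choice* bias with protein-composition bias — acceptable for ranking
within a genome, not for cross-genome comparison of absolute distances.
The intergenic-ORF pool of a dense phage genome is small, making
per-genome deviations noisy; the toolkit reports distributions and
fractions rather than per-gene verdicts. The Monte Carlo test's
complement-resampling anti-conservatism grows with the GI fraction and
should be kept in mind above ~10%.
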