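# acrkit

Anti-CRISPR proteins (Acrs) are small phage- and mobile-element-encoded
inhibitors of CRISPR-Cas immunity. Because *acr* genes arrive by horizontal
transfer or are born de novo from non-genic DNA, their codon usage tends to
clash with the host genome's — a signal this toolkit quantifies and exploits
for candidate mining. It is aimed at researchers triaging Acr candidates
from genome annotations, predictor call tables and precomputed similarity
searches, without any database downloads: every analysis also runs on the
package's own seeded synthetic genomes.

## What it computes

**CUB distance and CUBRank.** A gene *i* is summarized by its 64-bin codon
frequency vector *f_i* (triplets TTT, TTC, … GGG). The genome's reference
profile *f_w* is the codon vector of the *artificial gene* obtained by
concatenating every protein-coding gene. The codon-usage-bias (CUB) of gene
*i* is the Euclidean distance

&nbsp;&nbsp;&nbsp;&nbsp;*d_i* = sqrt( Σ_j ( f_ij − f_wj )² ),

and CUBRank_i is the 1-based position of *d_i* after sorting all genes from
largest to smallest: rank 1 = the gene most at odds with its host, the
signature of transferred or de-novo-born genes.

**Intergenic ORFs and the de novo deviation.** Six-frame ORFs (ATG to the
first in-frame stop, translation table 11) whose overlap with annotated CDS
is below 3% of their length form the *intergenic ORF* pool of a phage
genome. For each *acr* the deviation

&nbsp;&nbsp;&nbsp;&nbsp;deviation = CUB_acr_CDS − CUB_acr_interORFs

is positive when the acr's codon usage sits closer to intergenic DNA than
to coding sequence — the de novo birth signature.

**Genomic-island Monte Carlo test.** Genes are split into inside/outside
genomic islands (GIs); the observed mean CUBRank of GI genes is compared
with the mean ranks of 10 000 equally sized random draws from the non-GI
genes. The one-sided empirical p-value uses the add-one estimator
(1 + #{null ≤ observed}) / (1 + n_iter).

**Neighbor triage.** Up to three genes on each side of every seed acr form
the candidate pool; candidates are screened to 60–200 aa with
unknown-function annotations, matched against a sequence catalog
(e-value ≤ 0.01, identity ≥ 35%) or PDB chains (e-value ≤ 1e−10,
≤ 1 mismatch, coverage ≥ 95%), and the calls of three predictors
(PaCRISPR, AcRanker, AcrCatalog) are aggregated into exact Venn-region
consensus counts and directional overlap percentages.

## Worked example

Simulate a 40-gene genome carrying a 6-gene genomic island whose codon
usage is shifted toward a foreign preference, then test whether the island
genes top the CUB ranking:

```sh
acrkit --seed 1 simulate gi --out sim --n-genes 40 --n-shifted 6
acrkit --seed 1 gi-sim --fasta sim/gi.fasta --gff sim/gi.gff3 \
       --gi sim/gi.bed --n-iter 9999 --out mc.tsv
```

`mc.tsv` ends with (after a `#` header recording version and config):

```
n_gi  n_non_gi  n_iter  observed_mean_rank  null_mean_of_means  n_null_at_or_beyond  empirical_p  seed
6     34        9999    3.500000            23.475364           0                    0.0001       1
```

The six island genes average rank 3.5 of 40 while random non-island draws
average ≈ 23.5; no null draw is as extreme, so the empirical p is the
add-one minimum 1/10000. The per-gene ranking behind it:

```sh
acrkit cubrank --fasta sim/gi.fasta --gff sim/gi.gff3 --out cub.tsv
```

```
gene_id   distance  rank  percentile
gene0029  0.195351  1     0.025000
gene0028  0.188045  2     0.050000
gene0031  0.186445  3     0.075000
```

— the top ranks are exactly the island genes (`sim/gi.truth.tsv` holds the
generator's truth labels). Other subcommands: `orfscan` (six-frame ORFs and
intergenic classification), `filter-genomes` (complete assembly,
prokaryotic host, 20–50 CDS), `deviation` (per-acr de novo deviation from
a hit table), `neighbors` (±3-gene triage) and `simulate host|phage|gi|hits`.

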