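# pantx — pan-transcriptome diversity analysis for coding and noncoding RNAs

`pantx` is a library for comparing the population-level diversity of mRNAs and
long noncoding RNAs (lncRNAs) within a **pan-transcriptome**: the non-redundant
union of transcripts expressed across a panel of accessions (e.g. maize inbred
lines). It implements the full analysis chain on top of a ground-truthed
synthetic population generator, so every statistic can be validated end to end
without external data.

## What it computes

* **Centroid clustering** (`pantx.cluster`) — greedy length-ordered clustering
  of transcripts at an identity threshold (matches/alignment-columns under a
  global alignment, terminal gaps excluded), plus the empirical calibration
  that maps a protein-level threshold to a nucleotide-level one via binned
  amino-acid vs nucleotide dissimilarity quartiles.
* **ePAV pan-structure** (`pantx.epav`) — a presence–absence matrix from TPM
  (present iff TPM ≥ 1), partitioned by occupancy into **core** (100 % of
  lines), **shell** (10–90 %) and **cloud** (< 10 %); permutation rarefaction
  curves of pan (union) and core (intersection) sizes; a power-law fit of the
  novel-gene gain, *n(N) = κ·N^(−α) + tg θ*, with the openness rule *α ≤ 1* ⇒
  open, *α > 1* ⇒ closed.
* **SNP diversity** (`pantx.popstats`) — a fixed variant-filter cascade
  (MAPQ > 30, missingness ≤ 0.25, MAF ≥ 0.05, Hardy–Weinberg exact test
  p ≥ 0.01, LD pruning at r² ≤ 0.2) followed by per-transcript nucleotide
  diversity π (= Σ n₁n₂/C(n,2) per site, also rescaled per 10 kb), SNP density
  and Tajima's *D* = (π − S/a₁)/√(e₁S + e₂S(S−1)).
* **Substitution rates** (`pantx.evorates`) — Nei–Gojobori (1986) Ka/Ks for
  coding pairs (per-position site counting, pathway-averaged differences,
  Jukes–Cantor correction) and Kn (JC-corrected p-distance) for noncoding
  pairs; per-line conserved fractions (Ka/Ks < 1; Kn/mean-Ks < 1); maximum-
  likelihood gamma fits (shape α, rate β) to rate histograms.
* **Genomic context** (`pantx.locus`) — antisense / intronic / intergenic
  classification of noncoding loci against gene models with a fixed
  precedence, a configurable BLAST-hit rule filter, and compartment ×
  locus-class contingency tables.
* **Synthetic populations** (`pantx.synthio`) — deterministic generator of
  lines × families with planted occupancy classes, expression, diverged
  sequences, annotation and variants, plus a coalescent (msprime) neutral
  variant simulator for frequency-spectrum nulls.

## Worked example

```sh
python examples/04_substitution_rates.py
```

prints (seeded, reproducible):

```
TTT vs TTA: S-sites=0.5, N-sites=2.5, Ks=0.0000, Ka=0.5716  (one nonsynonymous Phe->Leu change)
pooled gamma shapes: alpha(Ka)=0.96, alpha(Ks)=1.09, alpha(Kn)=1.63
  ka: core=0.81 < shell=1.10 < cloud=1.22
  ks: core=0.91 < shell=1.30 < cloud=1.50
  kn: core=1.41 < shell=1.86 < cloud=2.66
conserved fraction per line: mRNA (Ka/Ks<1) = 98.2%, lncRNA (Kn/mean-Ks<1) = 27.4%
```

The single-codon case is the textbook NG86 computation: TTT→TTA is one
nonsynonymous change over 2.5 nonsynonymous sites, so Ka = JC(0.4) = 0.5716
while Ks = 0. On the simulated population the gamma shape α rises in the
order α(Ka) < α(Ks) < α(Kn) — noncoding transcripts accumulate substitutions
faster than even synonymous coding sites — and, for each rate, in the order
core < shell < cloud: families shared by all lines are under the strongest
constraint. The other `examples/*.py` scripts cover dataset generation, pan
structure (cloud-heavy lncRNA stratum, both strata closed), the diversity
cascade (lncRNA π above mRNA π) and locus classification (antisense loci
enriched in the core).

A thin CLI mirrors the library for shell pipelines:

```sh
pantx simulate --out data --seed 7
pantx pan --expr data/expression.tsv --perms 100 --seed 42 --out panout
pantx popstats --vcf data/variants.vcf --lengths data/lengths.tsv --out stats.tsv
pantx classify --gff data/annotation.gff3 --out classes.tsv
```

## Layout

```
src/pantx/      synthio, cluster, epav, popstats, evorates, locus, io,
                workflows, cli
examples/       one short narrative script per capability
tests/          pytest suite (unit, property and acceptance tests)
docs/methods.md model assumptions, parameter choices, limitations
```
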