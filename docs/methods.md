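# Methods

## Scope and model overview

`pantx` analyses the diversity of a pan-transcriptome — the non-redundant set
of transcripts expressed across a panel of inbred lines — separately for its
coding (mRNA) and noncoding (lncRNA) strata. The statistical machinery is
deliberately classical: occupancy-band partitioning of an expression
presence–absence matrix, permutation rarefaction with a power-law openness
fit, standard population-genetic summaries (π, SNP density, Tajima's D) after
a fixed variant-filter cascade, Nei–Gojobori counting with Jukes–Cantor
correction for substitution rates, and maximum-likelihood gamma fits to rate
histograms. What the package adds is a single, consistently tested
implementation of this chain plus a generator that plants known structure so
the chain can be verified end to end.

## ePAV partition and openness

A family is *present* in a line iff TPM ≥ 1 (the threshold is configurable;
exactly 1 counts as expressed because only TPM < 1 is excluded). Occupancy
bands: core = 100 %, cloud = (0 %, 10 %), shell = [10 %, 100 %). The band
(90 %, 100 %) is not covered by the verbal definitions "10 to 90 %" and
"100 %"; it is assigned to **shell**, the only choice under which the three
classes partition the expressed families — this is flagged here because it is
a genuine interpretive decision. Families expressed nowhere are reported
separately as "absent" and excluded from partition denominators.

Rarefaction draws P (default 100) seeded random line orderings; pan size is
the cumulative union and core size the cumulative intersection of presence
sets. The novel-gain curve (mean novel families per added line, N ≥ 2) is fit
by nonlinear least squares to κ·N^(−α) + tg θ, with a two-parameter variant
(tg θ = 0) fitted alongside; the lower-residual model is reported (ties favour
the three-parameter form). Whether coverage numbers ("lines needed for 95 %")
use the mean or median across permutations is an open choice; the mean is the
default and the median is available.

## Variant filtering and diversity statistics

The cascade order is fixed: MAPQ (strict >30) → missingness (≤ 0.25) → MAF
(≥ 0.05, inclusive) → Hardy–Weinberg exact test → LD pruning. "HWE ≤ 0.01" is
interpreted as *dropping* sites whose exact-test p-value is below 0.01
(vcftools `--hwe` semantics); the test is the Wigginton-style full enumeration
of heterozygote counts conditional on allele counts. Because the lines are
haploid inbreds, HWE is ill-posed on primary data and the stage is a logged
no-op for haploid genotypes; it activates when pseudo-diploid genotypes are
supplied. "LD ≤ 0.2" is implemented as deterministic greedy pruning (drop the
later site of any pair with r² > 0.2) in sliding windows of 50 sites, step 5 —
the window scheme is a convention, not a published value, and is configurable.

π at a site with allele counts (n₁, n₂) is n₁n₂/C(n, 2); per-transcript π
divides the summed site values by the full transcript length (monomorphic
sites included in the denominator) and is also reported ×10⁴ ("per 10 kb").
Transcripts longer than 10 kb are split into consecutive windows, the last
partial window length-normalised. Tajima's D uses the standard 1989 constants
with n taken as the rounded mean number of called alleles per site; D is
reported only for S ≥ 1 and n ≥ 4. Missing calls are excluded per site
(pairwise deletion). Indel records are parsed but excluded from SNP
statistics.

## Substitution rates

Ka/Ks uses Nei–Gojobori (1986) counting. Synonymous sites: per codon
position, the fraction of the three possible point mutations that are
synonymous, with mutations to stop codons excluded from both numerator and
denominator at that position; N + S = 3 × codons exactly. Differences for
codons differing at k positions are averaged over the k! substitution orders;
orders passing through a stop codon are excluded and the average
renormalised. If *every* order passes through a stop, the pair is averaged
over all orders (stop-passing steps counted as nonsynonymous) and flagged
rather than silently imputed. Proportions are Jukes–Cantor corrected,
d = −(3/4)·ln(1 − 4p/3); p ≥ 0.75 sets a saturation flag and the distance is
NaN. Kn for noncoding pairs is the JC-corrected p-distance over gap-free
columns. NG86 was chosen over likelihood codon models because it is fully
specifiable and admits exact enumeration oracles; absolute rate values are
estimator-dependent, so only orderings and distribution shapes are treated as
robust quantities. A single trailing stop codon is trimmed (common in CDS);
internal stops raise.

Conserved fractions per line: mRNA = share of transcripts with Ka/Ks < 1
(Ks = 0 pairs excluded from numerator and denominator — they are not counted
as conserved); lncRNA = share with Kn / (that line's mean Ks over coding
transcripts) < 1. The mean-Ks denominator is per line, matching the
per-library framing of the analysis.

Gamma fits are maximum likelihood: Newton iteration on
ln α − ψ(α) = ln(mean) − mean(ln x) from a method-of-moments start, β =
α/mean. Zeros are excluded (gamma support is positive) with the exclusion
count reported; fewer than 10 positive values or a degenerate (constant)
sample raises. The implementation is cross-checked in the tests against an
independent ML fit (scipy, location fixed at zero).

## Locus classification

Precedence: (1) same-strand exon overlap → rejected as a likely sense coding
fragment; (2) any opposite-strand gene-span overlap (≥ 1 bp, no minimum
fraction) → antisense; (3) full containment in a single intron on the host
gene's strand → intronic; (4) otherwise intergenic. Intronic is same-strand
by decision (the convention is not universal and is therefore explicit and
configurable via the precedence implementation). Coordinates are 0-based
half-open internally; GFF3 is 1-based inclusive and converted on read/write,
with a round-trip test. The BLAST-hit filter is a first-match-wins rule list;
the shipped defaults drop full-coverage same-strand protein-coding hits,
full-coverage ncRNA hits, and transposable-element hits with identity
strictly above 80 % (80.0 is kept). Custom rule sets express the mRNA-side
screens (vector contamination, weak protein similarity) in the same engine.

## Clustering and threshold calibration

Greedy centroid clustering processes records in length-descending order (ties
by id) and joins the first centroid at or above the identity threshold.
Identity = matches / alignment columns of a global alignment (match +1,
mismatch −1, gap open −2, gap extend −1), terminal gap columns excluded,
internal gaps counted as mismatch columns — the closest fully-specified
analogue of the USEARCH definition, stated here because "identity" is
otherwise ambiguous (the alternative, matches/shorter-sequence, was not
used). No k-mer prefilter is applied at the package's intended problem sizes.
The aa→nt calibration bins codon-aligned pairs at amino-acid dissimilarity
0/10/20/30/40 % with a ±2.5-point window ("close to" is not given a width in
the verbal description; ±2.5 makes the bins exhaustive and disjoint) and
recommends 1 − Q3(nt dissimilarity) of the bin matching the protein
threshold.

## The synthetic generator

The generator emulates a resequencing-panel study design: L haploid lines
(inbred lines are effectively homozygous, so genotypes are single alleles),
gene families with planted occupancy classes, log-normal TPM (meanlog 3,
sdlog 1.2 — median ≈ 20 TPM) clamped at the presence threshold unless
sub-threshold dropout noise is requested, and substitution-only sequence
evolution from a family ancestor (no indels, so alignments are positional and
the NG86/Kn oracles are exact). Cloud occupancy is an integer count in
[1, ⌈0.1 L⌉ − 1] (hence cloud families require L ≥ 11); shell occupancy is
uniform on [0.10, 0.90] with realised counts clipped into the band, so truth
classes coincide with the partition bands by construction. Coding ancestors
are built stop-free by rejection sampling of codons; proposals creating stop
codons are rejected during evolution, and nonsynonymous proposals are
accepted with probability ω.

Default rate structure (per-site substitution rates drawn per family from a
gamma): shapes {core 0.7, shell 1.1, cloud 1.6} with mean rates
{0.08, 0.12, 0.18}; noncoding families get 1.8× the shape and 2× the mean;
ω ~ Beta(mean 0.3, concentration 12), i.e. selection strength varies
moderately among genes; sequence lengths uniform on 600–1500 nt (coding
lengths forced to multiples of 3). Two considerations fixed these values.
First, expected substitution counts per pair must be well above 1: when mean
rates are small or planted shapes are heavy at zero, many pairs yield
zero-rate estimates, and because zeros are excluded from gamma fitting, the
resulting left-truncation inflates fitted shapes most in exactly the
low-rate strata and can invert the planted orderings — an estimation
artifact, not biology. Second, the planted orderings (α rising Ka < Ks < Kn
and core < shell < cloud, noncoding rates above synonymous coding rates)
encode the qualitative structure the analysis is meant to detect; with the
defaults they are identifiable from the observed histograms, not just the
truth tables. Two stratum compositions are provided: `paper_like` (coding
8 %/81 %/11 %, noncoding 5 %/42.5 %/52.5 % across core/shell/cloud) for
pan-structure comparisons, and `rate_study` (coding 100/300/100, noncoding
50/200/250 families) which keeps every compartment large enough (≥ 50
families) for stable gamma-shape fits while preserving the cloud-heavy
noncoding stratum.

Because every line descends independently from the family ancestor (a star
genealogy), derived alleles are mostly line-private and Tajima's D is
strongly negative under this generator — that is the wrong null for
frequency-spectrum statistics. A separate coalescent-based simulator
(msprime: neutral haploid samples, no within-transcript recombination,
independent genealogies across transcripts) supplies the proper neutral null;
under it the mean D across transcripts sits near zero (slightly negative, as
expected at finite sample sizes), and the tests assert it within an empirical
band of ±0.3.

What the generator does **not** emulate: read-level noise (no FASTQ),
assembly artifacts and chimeras, expression quantification error beyond the
log-normal, indels and structural variation, shared demography linking
occupancy to sequence divergence, linked selection, or any mechanistic model
of why expression presence–absence arises (the occupancy bands are a
stand-in, not a claim about epigenetic vs genetic origin). Passing tests
therefore demonstrate correctness of the estimators and the internal
consistency of the pipeline under these idealised conditions, not robustness
to the full error structure of real RNA-seq panels.

## Problem sizes and numerical conventions

The shipped analyses use 1000 families × 50 lines for structure and rate
comparisons and a lower-rate 200-family population for the diversity cascade
(so that, as in real panels, only a few well-supported SNPs per transcript
survive filtering). Multi-allelic alignment columns are dropped, not split,
when deriving variants (biallelic-only is the simplest faithful contract for
downstream SNP statistics). Power-law fitting bounds κ > 0 and starts from a
log-log linear fit; the degenerate all-core case (no novel gain anywhere)
returns α = +∞ with a flag and classifies as closed. All stochastic steps
take explicit seeds and are deterministic given them, including byte-identical
regeneration of every output file.
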