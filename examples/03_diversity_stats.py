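"""SNP diversity through the filter cascade: pi, SNP density, Tajima's D.

Variants derived from the per-family alignments are filtered by mapping
quality (> 30), missingness (<= 0.25), minor allele frequency (>= 0.05),
Hardy-Weinberg exact test (pseudo-diploid input only) and LD pruning
(r^2 <= 0.2); surviving SNPs give per-transcript nucleotide diversity.
"""

import numpy as np

from pantx import popstats, synthio

cfg = synthio.SimConfig(
    n_lines=50, n_core=60, n_shell=120, n_cloud=20, seed=3,
    rate_shape=0.8,
    rate_rate={"core": 0.8 / 0.004, "shell": 0.8 / 0.006, "cloud": 0.8 / 0.008},
    seq_len_range=(600, 1500))
pop = synthio.simulate_all(cfg)
filt = popstats.filter_variants(pop.variants)
print(f"raw SNPs: {pop.variants.n_sites}; per-stage drops: {filt.filter_log}; "
      f"surviving: {filt.n_sites}")

lengths = {fid: int(r["length"]) for fid, r in pop.truth.families.iterrows()}
stats = popstats.transcript_stats(filt, lengths).set_index("transcript")
coding = pop.truth.families["coding"]
for tag, mask in (("mRNA", coding), ("lncRNA", ~coding)):
    sub = stats.loc[[i for i in stats.index if mask.get(i, False)]]
    d = sub["tajimas_d"].dropna()
    print(f"{tag}: mean pi per 10 kb = {sub['pi_per_10kb'].mean():.3f}, "
          f"SNPs/kb = {sub['snps_per_kb'].mean():.3f}, "
          f"mean Tajima's D = {d.mean():.2f} (n={len(d)})")

print("Noncoding transcripts evolve roughly twice as fast in this simulation, "
      "so their pi and SNP density come out higher than the coding stratum's. "
      "D is negative because the star-shaped generator yields mostly "
      "line-private (rare) alleles.")
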