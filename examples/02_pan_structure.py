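"""Pan-transcriptome structure: ePAV partition, rarefaction, openness.

Builds the presence-absence matrix at TPM >= 1, partitions families into
core (100% of lines), shell (10-90%) and cloud (<10%), and fits the novel-
gain power law n(N) = kappa*N^(-alpha) + tg(theta); alpha <= 1 means an open
pan-transcriptome (novel genes keep accruing), alpha > 1 a closed one.
"""

from pantx import epav, synthio, workflows

cfg = synthio.SimConfig.paper_like(n_lines=50, n_coding=500, n_noncoding=500, seed=1)
pop = synthio.simulate_population(cfg)
st = workflows.pan_structure(pop, permutations=100, seed=2)

for stratum in ("coding", "noncoding"):
    part = st[stratum]["partition"]
    fit = st[stratum]["fit"]
    n95 = epav.lines_to_coverage(st[stratum]["curves"], 0.95)
    print(f"{stratum}: core/shell/cloud = "
          + "/".join(f"{100*part.fractions[c]:.1f}%" for c in ("core", "shell", "cloud"))
          + f"; alpha = {fit.alpha:.2f} ({fit.openness}); "
          f"{n95} lines reach 95% of the pan set")

print("The noncoding stratum is cloud-heavy and saturates later (more lines "
      "needed for 95%), i.e. lncRNA repertoires are far more line-specific "
      "than mRNA repertoires.")
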