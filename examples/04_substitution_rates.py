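"""Substitution rates: NG86 Ka/Ks for coding pairs, Kn for noncoding pairs,
and gamma-shape comparison across strata.

Each present line's transcript is compared with the family ancestor.  The
gamma shape fitted to a rate histogram measures among-transcript dispersion:
small shape = most transcripts conserved with a fast-evolving tail.
"""

from pantx import evorates, synthio, workflows

# the single-codon textbook case first
est = evorates.ka_ks("TTT", "TTA")
print(f"TTT vs TTA: S-sites={est.s_sites}, N-sites={est.n_sites}, "
      f"Ks={est.ks:.4f}, Ka={est.ka:.4f}  (one nonsynonymous Phe->Leu change)")

cfg = synthio.SimConfig.rate_study(n_lines=50, seed=42)
pop = synthio.simulate_sequences(synthio.simulate_population(cfg))
rates = workflows.rate_table(pop)
gs = workflows.gamma_summary(rates)

pooled = {k: v.shape for k, v in gs["pooled"].items()}
print("pooled gamma shapes: "
      + ", ".join(f"alpha({k.capitalize()})={v:.2f}" for k, v in pooled.items()))
for stat in ("ka", "ks", "kn"):
    shapes = [gs["by_compartment"][c][stat].shape for c in ("core", "shell", "cloud")]
    print(f"  {stat}: core={shapes[0]:.2f} < shell={shapes[1]:.2f} < cloud={shapes[2]:.2f}")

per_lib = evorates.ratios_and_conserved(rates)["per_library"]
print(f"conserved fraction per line: mRNA (Ka/Ks<1) = "
      f"{100*per_lib['conserved_mrna'].mean():.1f}%, "
      f"lncRNA (Kn/mean-Ks<1) = {100*per_lib['conserved_lnc'].mean():.1f}%")
print("alpha rises Ka < Ks < Kn (noncoding sequences accumulate substitutions "
      "faster than even synonymous coding sites) and core < shell < cloud "
      "(widely shared families are under the strongest constraint).")
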