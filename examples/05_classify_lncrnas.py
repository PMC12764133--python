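"""Genomic-context classification of noncoding loci and BLAST-hit screening.

Noncoding transcripts are classified against gene models with a fixed
precedence (same-strand exon overlap -> rejected; opposite-strand gene
overlap -> antisense; intron containment -> intronic; else intergenic), then
cross-tabulated against the pan compartments.
"""

import pandas as pd

from pantx import locus, synthio

cfg = synthio.SimConfig(n_lines=30, n_core=100, n_shell=200, n_cloud=100, seed=9)
pop = synthio.simulate_sequences(synthio.simulate_population(cfg))

labels = locus.classify_all(pop.noncoding_loci, pop.genes)
print("classification:", labels.value_counts().to_dict())
tab = locus.stratify(pop.truth.families["pan_class"], labels)
print(tab)
frac = tab.div(tab.sum(axis=1), axis=0)
print(f"antisense core fraction {frac.loc['antisense','core']:.2f} vs "
      f"intergenic core fraction {frac.loc['intergenic','core']:.2f} — antisense "
      "loci sit preferentially in the conserved core, intergenic ones in the cloud.")

hits = pd.DataFrame(
    [("cand1", "protein_coding", 100.0, 97.0, "plus"),
     ("cand2", "TE", 55.0, 83.0, "plus"),
     ("cand3", "ncRNA", 90.0, 99.0, "minus")],
    columns=["qseqid", "sclass", "qcovs", "pident", "sstrand"])
print(locus.blast_filters(hits).to_string(index=False))
print("cand1 and cand2 are screened out (full-coverage sense coding hit; "
      ">80% transposable-element identity); cand3 survives.")
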