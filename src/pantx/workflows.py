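"""End-to-end analysis workflows over a (synthetic or loaded) population.

Ties the module layers together: ePAV matrix -> core/shell/cloud partition ->
rarefaction and power-law openness per stratum; per-pair Ka/Ks/Kn against the
family ancestor -> per-stratum gamma fits and conserved fractions.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
import pandas as pd

from . import epav, evorates
from .synthio import SimulatedPopulation


@lru_cache(maxsize=100_000)
def _sites_cached(seq: str) -> tuple[float, float]:
    return evorates.ng86_sites(seq)


def rate_table(pop: SimulatedPopulation) -> pd.DataFrame:
    """Per-(family, line) substitution-rate estimates against the ancestor.

    Columns: family, line, kind, pan_class, locus_class, ka, ks, kn.
    Coding pairs use NG86 with the ancestral reference; noncoding pairs use
    the Jukes–Cantor-corrected p-distance.  Saturated estimates come out NaN.
    """
    rows = []
    fam = pop.truth.families
    for fid, per_line in pop.sequences.items():
        row = fam.loc[fid]
        anc = pop.ancestors[fid]
        coding = bool(row["coding"])
        for line, seq in per_line.items():
            rec = {"family": fid, "line": line,
                   "kind": "coding" if coding else "noncoding",
                   "pan_class": row["pan_class"], "locus_class": row["locus_class"],
                   "ka": math.nan, "ks": math.nan, "kn": math.nan}
            if coding:
                est = evorates.ka_ks(anc, seq)
                rec["ka"], rec["ks"] = est.ka, est.ks
            else:
                rec["kn"] = evorates.kn(anc, seq).kn
            rows.append(rec)
    return pd.DataFrame(rows)


def pan_structure(pop: SimulatedPopulation, permutations: int = 100, seed: int = 0,
                  threshold: float | None = None) -> dict:
    """Partition + rarefaction + power-law fit per stratum (coding/noncoding).

    Returns {'all': ..., 'coding': ..., 'noncoding': ...}, each with the
    presence matrix, partition, curves and fit.
    """
    thr = pop.config.tpm_threshold if threshold is None else threshold
    fam = pop.truth.families
    out = {}
    strata = {
        "all": fam.index,
        "coding": fam.index[fam["coding"]],
        "noncoding": fam.index[~fam["coding"]],
    }
    for name, ids in strata.items():
        if len(ids) == 0:
            continue
        pam = epav.build_epav(pop.expression.loc[ids], threshold=thr)
        part = epav.partition(pam)
        curves = epav.rarefy(pam, permutations=permutations, seed=seed)
        fit = epav.fit_power_law(curves)
        out[name] = {"pam": pam, "partition": part, "curves": curves, "fit": fit}
    return out


def gamma_summary(rates: pd.DataFrame) -> dict:
    """Gamma shape fits for pooled Ka, Ks, Kn and per pan-compartment."""
    out: dict = {"pooled": {}, "by_compartment": {}}
    pools = {
        "ka": rates.loc[rates["kind"] == "coding", "ka"],
        "ks": rates.loc[rates["kind"] == "coding", "ks"],
        "kn": rates.loc[rates["kind"] == "noncoding", "kn"],
    }
    for stat, vals in pools.items():
        v = vals[np.isfinite(vals) & (vals > 0)]
        if len(v) >= 10:
            out["pooled"][stat] = evorates.fit_gamma(v)
    for cls, g in rates.groupby("pan_class"):
        fits = {}
        for stat, kind in (("ka", "coding"), ("ks", "coding"), ("kn", "noncoding")):
            vals = g.loc[g["kind"] == kind, stat]
            v = vals[np.isfinite(vals) & (vals > 0)]
            if len(v) >= 10:
                fits[stat] = evorates.fit_gamma(v)
        out["by_compartment"][cls] = fits
    return out
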