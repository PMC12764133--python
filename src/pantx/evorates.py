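"""Substitution-rate estimation for coding and noncoding transcript pairs.

Coding pairs are scored with the Nei–Gojobori (1986) counting method:
synonymous/nonsynonymous site counts per codon, pathway-averaged difference
counts for multi-hit codons, and Jukes–Cantor correction of the resulting
proportions into Ka and Ks.  Noncoding pairs get Kn, the Jukes–Cantor-corrected
p-distance.  Per-stratum collections of rates are summarised by a
maximum-likelihood gamma fit whose shape parameter describes among-transcript
rate dispersion (shape < 1: most transcripts conserved, a heavy tail of
fast-evolving ones).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special

from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_STOPS = frozenset(_STANDARD.stop_codons)
_BASES = "ACGT"


def _aa(codon: str) -> str:
    """Amino acid for a sense codon, '*' for a stop."""
    return "*" if codon in _STOPS else _STANDARD.forward_table[codon]


def _codon_site_fractions(codon: str) -> float:
    """Synonymous site count s for one codon.

    Per position, s gains the fraction of the possible point mutations that
    are synonymous; mutations creating stop codons are excluded from both the
    numerator and the denominator at that position.
    """
    aa0 = _aa(codon)
    s = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut in _STOPS:
                continue
            valid += 1
            if _aa(mut) == aa0:
                syn += 1
        if valid:
            s += syn / valid
    return s


_SITE_CACHE: dict[str, float] = {c: _codon_site_fractions(c) for c in _STANDARD.forward_table}


@dataclass
class RateEstimate:
    """Per-pair substitution-rate estimate.

    Coding pairs populate ka/ks and the NG86 counts; noncoding pairs populate
    kn and p_distance.  ``saturated`` is set when a proportion reaches the
    Jukes–Cantor domain boundary (p >= 0.75) and the corresponding distance is
    NaN.  ``stop_pathway_flagged`` marks codon pairs whose every substitution
    pathway passes through a stop codon.
    """

    ka: float = math.nan
    ks: float = math.nan
    kn: float = math.nan
    n_sites: float = math.nan
    s_sites: float = math.nan
    nd: float = math.nan
    sd: float = math.nan
    p_distance: float = math.nan
    saturated: bool = False
    stop_pathway_flagged: bool = False

    @property
    def ka_ks(self) -> float:
        if not math.isfinite(self.ka) or not math.isfinite(self.ks) or self.ks == 0:
            return math.nan
        return self.ka / self.ks


@dataclass
class GammaFit:
    shape: float
    rate: float
    n: int
    loglik: float
    converged: bool
    n_zeros_excluded: int = 0

    @property
    def mean(self) -> float:
        return self.shape / self.rate


def _codons(seq: str) -> list[str]:
    if len(seq) % 3:
        raise ValueError(f"coding sequence length {len(seq)} not divisible by 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def ng86_sites(seq: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts (S, N) for one coding sequence.

    A single trailing stop codon is trimmed; an internal stop raises.
    Invariant: S + N == 3 * number of counted codons.
    """
    seq = seq.upper().replace("U", "T")
    cods = _codons(seq)
    if cods and cods[-1] in _STOPS:
        cods = cods[:-1]
    s_total = 0.0
    for i, c in enumerate(cods):
        if c in _STOPS:
            raise ValueError(f"internal stop codon {c} at codon {i}")
        s_total += _SITE_CACHE[c]
    return s_total, 3 * len(cods) - s_total


def _pathways(c1: str, c2: str) -> tuple[float, float, bool]:
    """Pathway-averaged (Sd, Nd) between two codons plus an all-stop flag."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0, False
    valid: list[tuple[int, int]] = []
    all_paths: list[tuple[int, int]] = []
    for order in itertools.permutations(diff):
        cur = c1
        syn = nonsyn = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS and nxt != c2:
                through_stop = True
            if _aa(nxt) == _aa(cur):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        all_paths.append((syn, nonsyn))
        if not through_stop:
            valid.append((syn, nonsyn))
    paths = valid if valid else all_paths
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd, not valid


def ng86_differences(a: str, b: str) -> tuple[float, float, bool]:
    """Pathway-averaged synonymous/nonsynonymous differences (Sd, Nd).

    Codon pairs differing at k positions average over the k! orderings of
    single changes; orderings passing through stop codons are excluded and the
    average renormalised.  If every ordering passes through a stop the pair is
    averaged over all orderings and flagged (third return value).
    """
    a = a.upper().replace("U", "T")
    b = b.upper().replace("U", "T")
    if len(a) != len(b):
        raise ValueError("aligned coding sequences must have equal length")
    sd = nd = 0.0
    flagged = False
    for c1, c2 in zip(_codons(a), _codons(b)):
        s, n, f = _pathways(c1, c2)
        sd += s
        nd += n
        flagged = flagged or f
    return sd, nd, flagged


def jc_correct(p: float) -> float:
    """Jukes–Cantor multiple-hit correction d = -(3/4) ln(1 - 4p/3).

    Returns NaN for p >= 0.75 (saturation); callers should flag.
    """
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _strip_gap_codons(a: str, b: str) -> tuple[str, str]:
    ka, kb = [], []
    for i in range(0, len(a) - len(a) % 3, 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if "-" in ca or "-" in cb:
            continue
        ka.append(ca)
        kb.append(cb)
    return "".join(ka), "".join(kb)


def ka_ks(a: str, b: str) -> RateEstimate:
    """NG86 Ka/Ks for an aligned coding pair (gap codons stripped)."""
    a, b = a.upper().replace("U", "T"), b.upper().replace("U", "T")
    if len(a) != len(b):
        raise ValueError("pair must be aligned (equal length)")
    a, b = _strip_gap_codons(a, b)
    if not a:
        raise ValueError("zero aligned codons")
    sa, na = ng86_sites(a)
    sb, nb = ng86_sites(b)
    # sites averaged over the two sequences; a trailing stop trimmed by
    # ng86_sites in one sequence only would desynchronise the codon walk, so
    # trim both to the shared counted span
    ncod = min(len(a), len(b)) // 3
    sd, nd, flagged = ng86_differences(a[: 3 * ncod], b[: 3 * ncod])
    s_sites = (sa + sb) / 2.0
    n_sites = (na + nb) / 2.0
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = jc_correct(ps)
    ka = jc_correct(pn)
    return RateEstimate(
        ka=ka,
        ks=ks,
        n_sites=n_sites,
        s_sites=s_sites,
        nd=nd,
        sd=sd,
        saturated=math.isnan(ka) or math.isnan(ks),
        stop_pathway_flagged=flagged,
    )


def kn(a: str, b: str) -> RateEstimate:
    """Jukes–Cantor-corrected p-distance for an aligned noncoding pair."""
    if len(a) != len(b):
        raise ValueError("pair must be aligned (equal length)")
    a, b = a.upper(), b.upper()
    mism = cols = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        cols += 1
        if x != y:
            mism += 1
    if cols == 0:
        raise ValueError("zero compared columns")
    p = mism / cols
    d = jc_correct(p)
    return RateEstimate(kn=d, p_distance=p, saturated=math.isnan(d))


def fit_gamma(values: Iterable[float], tol: float = 1e-10, max_iter: int = 200) -> GammaFit:
    """Maximum-likelihood gamma fit (shape, rate) by Newton iteration.

    Zeros are excluded (gamma support is positive) with the exclusion count
    reported.  Method-of-moments start; Newton steps on
    f(shape) = ln(shape) - digamma(shape) - (ln(mean) - mean(ln x)).
    """
    x = np.asarray(list(values), dtype=float)
    x = x[np.isfinite(x)]
    n_zero = int(np.sum(x == 0))
    x = x[x > 0]
    if np.any(x < 0):
        raise ValueError("negative values not allowed")
    if x.size < 10:
        raise ValueError("insufficient data: need >= 10 positive values")
    m = float(x.mean())
    v = float(x.var())
    if v == 0:
        raise ValueError("degenerate sample: all values equal")
    c = math.log(m) - float(np.mean(np.log(x)))
    shape = m * m / v  # method-of-moments start
    converged = False
    for _ in range(max_iter):
        f = math.log(shape) - special.digamma(shape) - c
        fp = 1.0 / shape - special.polygamma(1, shape)
        step = f / fp
        new = shape - step
        if new <= 0:
            new = shape / 2.0
        if abs(new - shape) < tol * max(1.0, shape):
            shape = new
            converged = True
            break
        shape = new
    rate = shape / m
    ll = float(
        np.sum(shape * math.log(rate) - special.gammaln(shape) + (shape - 1) * np.log(x) - rate * x)
    )
    return GammaFit(shape=float(shape), rate=float(rate), n=int(x.size), loglik=ll, converged=converged, n_zeros_excluded=n_zero)


def ratios_and_conserved(
    rates: pd.DataFrame,
    strata: Sequence[str] = (),
    library_col: str = "line",
) -> dict:
    """Per-library Ka/Ks summaries, conserved fractions, and stratum pools.

    ``rates`` holds one row per (transcript, library) pair with columns
    ``kind`` ('coding'/'noncoding'), ``ka``, ``ks``, ``kn`` and optional
    stratum columns (e.g. pan class, locus class).

    Per library: mean Ka/Ks over defined ratios; conserved mRNA fraction
    (Ka/Ks < 1, pairs with Ks == 0 excluded from numerator and denominator);
    conserved lncRNA fraction (Kn / library-mean-Ks < 1).  Stratum pools group
    finite Ka, Ks and Kn values for downstream gamma fits.
    """
    per_lib = []
    for lib, g in rates.groupby(library_col, sort=True):
        cod = g[g["kind"] == "coding"]
        non = g[g["kind"] == "noncoding"]
        defined = cod[(cod["ks"] > 0) & np.isfinite(cod["ka"]) & np.isfinite(cod["ks"])]
        ratio = defined["ka"] / defined["ks"]
        mean_ks = float(cod["ks"][np.isfinite(cod["ks"])].mean()) if len(cod) else math.nan
        row = {
            library_col: lib,
            "mean_ka_ks": float(ratio.mean()) if len(ratio) else math.nan,
            "conserved_mrna": float((ratio < 1).mean()) if len(ratio) else math.nan,
            "mean_ks": mean_ks,
        }
        kn_vals = non["kn"][np.isfinite(non["kn"])]
        if len(kn_vals) and mean_ks and math.isfinite(mean_ks) and mean_ks > 0:
            row["conserved_lnc"] = float((kn_vals / mean_ks < 1).mean())
        else:
            row["conserved_lnc"] = math.nan
        per_lib.append(row)
    pools: dict[str, dict] = {}
    for col in strata:
        pools[col] = {}
        for key, g in rates.groupby(col, sort=True):
            pools[col][key] = {
                stat: g[stat][np.isfinite(g[stat])].to_numpy()
                for stat in ("ka", "ks", "kn")
                if stat in g
            }
    return {"per_library": pd.DataFrame(per_lib), "strata": pools}
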