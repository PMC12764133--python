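"""SNP-level diversity statistics under a fixed variant-filter cascade.

The variant table holds biallelic sites with haploid (inbred-line) or
pseudo-diploid genotype calls.  Filtering applies, in order: mapping quality
(MAPQ > threshold, strict), missingness (fraction missing <= threshold), minor
allele frequency (MAF >= threshold, inclusive), a Hardy–Weinberg exact test
(diploid input only; haploid input passes through with a notice), and greedy
sliding-window LD pruning on r².  Surviving sites feed per-transcript
nucleotide diversity pi (also rescaled "per 10 kb"), SNP density (SNPs/kb) and
Tajima's D.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1


@dataclass
class VariantTable:
    """Biallelic variant records with per-line genotype calls.

    ``sites`` columns: transcript, pos (1-based), ref, alt, mapq.
    ``gt`` is an int8 matrix (n_sites x n_lines) of alt-allele dosages:
    haploid 0/1, diploid 0/1/2; MISSING (-1) marks no-calls.
    """

    sites: pd.DataFrame
    gt: np.ndarray
    line_ids: list[str]
    ploidy: int = 1
    filter_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sites) != self.gt.shape[0]:
            raise ValueError("sites/gt row mismatch")
        if self.ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def subset(self, mask: np.ndarray) -> "VariantTable":
        return VariantTable(
            sites=self.sites.loc[mask].reset_index(drop=True),
            gt=self.gt[mask],
            line_ids=self.line_ids,
            ploidy=self.ploidy,
            filter_log=dict(self.filter_log),
        )


def _allele_counts(gt_row: np.ndarray, ploidy: int) -> tuple[int, int]:
    """(ref allele count, alt allele count) over non-missing calls."""
    called = gt_row[gt_row != MISSING]
    alt = int(called.sum())
    total = ploidy * called.size
    return total - alt, alt


def hwe_exact_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact Hardy–Weinberg p-value (Wigginton-style enumeration).

    Enumerates all heterozygote counts compatible with the observed allele
    counts and sums probabilities <= that of the observed configuration.
    Monomorphic sites return 1.0.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be >= 0")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("no genotypes")
    rare = 2 * min(n_aa, n_bb) + n_ab
    if rare == 0:
        return 1.0
    # probabilities over het counts with the parity of `rare`, built by the
    # standard recurrence from the mid het count
    mid = rare * (2 * n - rare) // (2 * n)
    if mid % 2 != rare % 2:
        mid += 1
    probs = {mid: 1.0}
    hom_r = (rare - mid) // 2
    hom_c = n - mid - hom_r
    h, p = mid, 1.0
    r, c = hom_r, hom_c
    while h >= 2:
        p_next = p * h * (h - 1) / (4.0 * (r + 1) * (c + 1))
        probs[h - 2] = p_next
        p = p_next
        h -= 2
        r += 1
        c += 1
    h, p = mid, 1.0
    r, c = hom_r, hom_c
    while h + 2 <= rare:
        p_next = p * 4.0 * r * c / ((h + 2) * (h + 1))
        probs[h + 2] = p_next
        p = p_next
        h += 2
        r -= 1
        c -= 1
    total = sum(probs.values())
    obs = probs.get(n_ab)
    if obs is None:
        raise ValueError("observed het count inconsistent with allele counts")
    return min(1.0, sum(v for v in probs.values() if v <= obs * (1 + 1e-12)) / total)


def _site_r2(x: np.ndarray, y: np.ndarray) -> float:
    """r² between two dosage vectors over lines called at both sites."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xv, yv = x[ok].astype(float), y[ok].astype(float)
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = float(np.mean((xv - xv.mean()) * (yv - yv.mean())) / (sx * sy))
    return r * r


def ld_prune(vt: VariantTable, r2_max: float = 0.2, window: int = 50, step: int = 5) -> VariantTable:
    """Greedy sliding-window LD pruning: for r² > r2_max, drop the later site.

    Windows of ``window`` sites advance by ``step`` within each transcript;
    sites are taken in (transcript, position) order, so the procedure is
    deterministic.
    """
    keep = np.ones(vt.n_sites, dtype=bool)
    order = vt.sites.sort_values(["transcript", "pos"], kind="mergesort").index.to_numpy()
    for tx, g in vt.sites.loc[order].groupby("transcript", sort=False):
        idx = g.index.to_numpy()
        start = 0
        while True:
            win = idx[start : start + window]
            live = [i for i in win if keep[i]]
            for a_pos in range(len(live)):
                if not keep[live[a_pos]]:
                    continue
                for b_pos in range(a_pos + 1, len(live)):
                    j = live[b_pos]
                    if not keep[j]:
                        continue
                    if _site_r2(vt.gt[live[a_pos]], vt.gt[j]) > r2_max:
                        keep[j] = False
            if start + window >= len(idx):
                break
            start += step
    out = vt.subset(keep)
    out.filter_log["ld"] = int((~keep).sum())
    return out


def filter_variants(
    vt: VariantTable,
    mapq_min: float = 30.0,
    miss_max: float = 0.25,
    maf_min: float = 0.05,
    hwe_p: float = 0.01,
    ld_r2: float = 0.2,
    ld_window: int = 50,
    ld_step: int = 5,
) -> VariantTable:
    """Apply the fixed filter cascade; per-stage drop counts in filter_log.

    Order: MAPQ (strict >) -> missingness (<=) -> MAF (>=, inclusive) ->
    HWE exact test (drop p < hwe_p; no-op with a notice for haploid calls) ->
    LD pruning.  An empty survivor set is returned with a warning, not raised.
    """
    log: dict[str, int] = {}
    mapq = vt.sites["mapq"].to_numpy(dtype=float)
    keep = mapq > mapq_min
    log["mapq"] = int((~keep).sum())
    vt = vt.subset(keep)

    miss = np.mean(vt.gt == MISSING, axis=1) if vt.n_sites else np.zeros(0)
    keep = miss <= miss_max
    log["missing"] = int((~keep).sum())
    vt = vt.subset(keep)

    mafs = np.empty(vt.n_sites)
    for i in range(vt.n_sites):
        n_ref, n_alt = _allele_counts(vt.gt[i], vt.ploidy)
        tot = n_ref + n_alt
        mafs[i] = min(n_ref, n_alt) / tot if tot else 0.0
    keep = mafs >= maf_min
    log["maf"] = int((~keep).sum())
    vt = vt.subset(keep)

    if vt.ploidy == 2:
        ps = np.empty(vt.n_sites)
        for i in range(vt.n_sites):
            row = vt.gt[i]
            called = row[row != MISSING]
            ps[i] = hwe_exact_p(
                int((called == 0).sum()), int((called == 1).sum()), int((called == 2).sum())
            )
        keep = ps >= hwe_p
        log["hwe"] = int((~keep).sum())
        vt = vt.subset(keep)
    else:
        logger.info("haploid calls: HWE stage skipped (ill-posed for inbred lines)")
        log["hwe"] = 0

    vt = ld_prune(vt, r2_max=ld_r2, window=ld_window, step=ld_step)
    log["ld"] = vt.filter_log.get("ld", 0)
    vt.filter_log = log
    if vt.n_sites == 0:
        logger.warning("all variant records removed by the filter cascade")
    return vt


def site_pi(n1: int, n2: int) -> float:
    """Per-site nucleotide diversity: n1*n2 / C(n,2) for allele counts n1, n2."""
    n = n1 + n2
    if n < 2:
        raise ValueError("need >= 2 alleles")
    return n1 * n2 / (n * (n - 1) / 2.0)


def tajimas_d(n: int, s: int, pi_total: float) -> float:
    """Tajima's (1989) D from n sequences, S segregating sites, and the mean
    number of pairwise differences pi_total."""
    if n < 4:
        raise ValueError("need n >= 4 sequences")
    if s < 1:
        raise ValueError("need S >= 1 segregating sites")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    var = e1 * s + e2 * s * (s - 1)
    return (pi_total - s / a1) / math.sqrt(var)


def transcript_stats(
    vt: VariantTable,
    lengths: Mapping[str, int],
    window_bp: int = 10_000,
) -> pd.DataFrame:
    """Per-transcript (or per-10-kb-window) diversity summary.

    Columns: transcript, window_start (1-based), length_bp, S, pi (per bp),
    pi_per_10kb (x 1e4), snps_per_kb, pi_total (mean pairwise differences),
    n_mean (mean called alleles per site), tajimas_d (NaN when S = 0 or
    n < 4).  Transcripts longer than ``window_bp`` are split into consecutive
    windows; the last, partial window is length-normalised.
    """
    rows = []
    by_tx: dict[str, list[int]] = {tx: [] for tx in lengths}
    for i, tx in enumerate(vt.sites["transcript"]):
        if tx not in by_tx:
            raise ValueError(f"no length for transcript {tx!r}")
        by_tx[tx].append(i)
    for tx, length in lengths.items():
        if length <= 0:
            raise ValueError(f"zero-length transcript {tx!r}")
        idxs = by_tx.get(tx, [])
        for wstart in range(1, length + 1, window_bp):
            wend = min(wstart + window_bp - 1, length)
            wlen = wend - wstart + 1
            win_idx = [i for i in idxs if wstart <= vt.sites.at[i, "pos"] <= wend]
            s = len(win_idx)
            pi_total = 0.0
            n_calls = []
            for i in win_idx:
                n_ref, n_alt = _allele_counts(vt.gt[i], vt.ploidy)
                pi_total += site_pi(n_ref, n_alt)
                n_calls.append(n_ref + n_alt)
            pi_bp = pi_total / wlen
            n_mean = float(np.mean(n_calls)) if n_calls else math.nan
            d = math.nan
            if s >= 1 and n_calls:
                n_round = int(round(n_mean))
                if n_round >= 4:
                    d = tajimas_d(n_round, s, pi_total)
            rows.append(
                {
                    "transcript": tx,
                    "window_start": wstart,
                    "length_bp": wlen,
                    "S": s,
                    "pi": pi_bp,
                    "pi_per_10kb": pi_bp * 1e4,
                    "snps_per_kb": s / (wlen / 1000.0),
                    "pi_total": pi_total,
                    "n_mean": n_mean,
                    "tajimas_d": d,
                }
            )
    return pd.DataFrame(rows)
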