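"""Greedy centroid clustering of transcripts at an identity threshold.

Records are processed in length-descending order (ties broken by id); each
joins the first existing centroid it matches at or above the threshold,
otherwise it founds a new cluster — the USEARCH/VSEARCH-style centroid
heuristic.  Identity is matches / alignment columns under a global alignment
(match +1, mismatch -1, gap open -2, gap extend -1 by default), with terminal
gap columns excluded from the denominator and internal gap columns counted as
mismatches.

The module also provides the empirical calibration tying a protein-level
clustering threshold to a nucleotide-level one: codon-aligned coding pairs are
binned by amino-acid dissimilarity (0/10/20/30/40%, +-2.5 points) and the
third quartile of nucleotide dissimilarity in the target bin gives the
recommended nucleotide threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Seq import Seq

AA_BINS = (0.0, 0.10, 0.20, 0.30, 0.40)
BIN_WINDOW = 0.025


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    seq: str
    kind: str = "nt"  # "nt" or "aa"

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty sequence for {self.id!r}")
        if self.kind not in ("nt", "aa"):
            raise ValueError("kind must be 'nt' or 'aa'")


@dataclass
class Cluster:
    centroid_id: str
    member_ids: list[str]
    member_identities: dict[str, float]


@dataclass
class CalibrationResult:
    """Per-aa-dissimilarity-bin quartiles of nucleotide dissimilarity."""

    bins: pd.DataFrame  # index: bin center; columns: n, q1, median, q3
    aa_threshold: float
    recommended_nt_threshold: float  # 1 - Q3(bin matching aa_threshold)


def _aligner(match: float = 1.0, mismatch: float = -1.0, gap_open: float = -2.0,
             gap_extend: float = -1.0) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner(mode="global")
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap_open
    al.extend_gap_score = gap_extend
    return al


def pairwise_identity(a: SequenceRecord, b: SequenceRecord,
                      aligner: Align.PairwiseAligner | None = None) -> float:
    """Global-alignment identity: matches / columns, terminal gaps excluded."""
    if a.kind != b.kind:
        raise ValueError("cannot compare nt with aa records")
    if aligner is None:
        aligner = _aligner()
    aln = aligner.align(a.seq, b.seq)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    lo, hi = 0, len(s1)
    while lo < hi and (s1[lo] == "-" or s2[lo] == "-"):
        lo += 1
    while hi > lo and (s1[hi - 1] == "-" or s2[hi - 1] == "-"):
        hi -= 1
    cols = hi - lo
    if cols == 0:
        return 0.0
    matches = sum(1 for i in range(lo, hi) if s1[i] == s2[i] and s1[i] != "-")
    return matches / cols


def greedy_cluster(records: Iterable[SequenceRecord], threshold: float,
                   aligner: Align.PairwiseAligner | None = None) -> list[Cluster]:
    """Length-descending greedy centroid clustering at an identity threshold."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if aligner is None:
        aligner = _aligner()
    ordered = sorted(records, key=lambda r: (-len(r.seq), r.id))
    clusters: list[Cluster] = []
    centroids: list[SequenceRecord] = []
    for rec in ordered:
        placed = False
        for cl, cen in zip(clusters, centroids):
            ident = pairwise_identity(rec, cen, aligner)
            if ident >= threshold:
                cl.member_ids.append(rec.id)
                cl.member_identities[rec.id] = ident
                placed = True
                break
        if not placed:
            clusters.append(Cluster(centroid_id=rec.id, member_ids=[rec.id],
                                    member_identities={rec.id: 1.0}))
            centroids.append(rec)
    return clusters


def _dissimilarities(nt_a: str, nt_b: str) -> tuple[float, float]:
    """(aa dissimilarity, nt dissimilarity) for one codon-aligned pair."""
    pa, pb = [], []
    for i in range(0, len(nt_a) - len(nt_a) % 3, 3):
        ca, cb = nt_a[i : i + 3], nt_b[i : i + 3]
        if "-" in ca or "-" in cb:
            continue
        pa.append(ca)
        pb.append(cb)
    if not pa:
        raise ValueError("no gap-free codons in pair")
    sa, sb = "".join(pa), "".join(pb)
    aa_a, aa_b = str(Seq(sa).translate()), str(Seq(sb).translate())
    aa_diss = sum(x != y for x, y in zip(aa_a, aa_b)) / len(aa_a)
    nt_diss = sum(x != y for x, y in zip(sa, sb)) / len(sa)
    return aa_diss, nt_diss


def calibrate_nt_threshold(codon_pairs: Sequence[tuple[str, str]],
                           aa_threshold: float = 0.20) -> CalibrationResult:
    """Bin codon-aligned pairs by aa dissimilarity; recommend an nt threshold.

    Pairs land in the nearest of the 0/10/20/30/40% bins when within +-2.5
    percentage points, else they are dropped.  The recommended nucleotide
    identity threshold is 1 - Q3(nt dissimilarity) of the bin matching
    ``aa_threshold``.
    """
    target = min(AA_BINS, key=lambda b: abs(b - aa_threshold))
    binned: dict[float, list[float]] = {b: [] for b in AA_BINS}
    for nt_a, nt_b in codon_pairs:
        if len(nt_a) != len(nt_b):
            raise ValueError("pair not aligned")
        aa_d, nt_d = _dissimilarities(nt_a, nt_b)
        b = min(AA_BINS, key=lambda c: abs(c - aa_d))
        if abs(aa_d - b) <= BIN_WINDOW:
            binned[b].append(nt_d)
    rows = []
    for b in AA_BINS:
        vals = np.array(binned[b])
        if vals.size:
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            rows.append({"bin": b, "n": vals.size, "q1": q1, "median": med, "q3": q3})
        else:
            rows.append({"bin": b, "n": 0, "q1": np.nan, "median": np.nan, "q3": np.nan})
    table = pd.DataFrame(rows).set_index("bin")
    if table.loc[target, "n"] == 0:
        raise ValueError("insufficient calibration pairs in the target bin")
    rec = 1.0 - float(table.loc[target, "q3"])
    return CalibrationResult(bins=table, aa_threshold=target, recommended_nt_threshold=rec)


def clusters_to_frame(clusters: Sequence[Cluster]) -> pd.DataFrame:
    """Flat (centroid_id, member_id, identity) table for TSV export."""
    rows = [
        {"centroid_id": c.centroid_id, "member_id": m, "identity": c.member_identities[m]}
        for c in clusters
        for m in c.member_ids
    ]
    return pd.DataFrame(rows)
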