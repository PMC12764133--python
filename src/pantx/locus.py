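"""Genomic-context classification of noncoding transcripts and rule filters.

A noncoding transcript is classified against annotated gene models by a fixed
precedence: same-strand exon overlap rejects it outright (it is likely a
coding fragment); otherwise any opposite-strand gene overlap makes it
antisense; otherwise full containment in a single intron on the host gene's
strand makes it intronic; everything else is intergenic.

The BLAST-hit rule engine expresses the drop rules used when screening
putative lncRNAs against reference databases (full-coverage same-strand
protein-coding hits, full-coverage ncRNA hits, >80%-identity transposable
element hits) and is configurable so the mRNA-side screens fit the same
machinery.  Coordinates are 0-based half-open internally; GFF3 (1-based
inclusive) is converted on read/write.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

ANTISENSE, INTRONIC, INTERGENIC = "antisense", "intronic", "intergenic"
REJECTED = "rejected_sense_exonic"
KNOWN_SUBJECT_CLASSES = {"protein_coding", "ncRNA", "TE"}


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"start {self.start} must be < end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def contains(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start <= other.start and other.end <= self.end


@dataclass
class GeneModel:
    gene_id: str
    span: GenomicInterval
    exons: list[GenomicInterval]

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(f"overlapping exons in gene {self.gene_id}")

    @property
    def strand(self) -> str:
        return self.span.strand

    @property
    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end < b.start:
                out.append(GenomicInterval(self.span.chrom, a.end, b.start, self.span.strand))
        return out


def classify_transcript(t: GenomicInterval, genes: Sequence[GeneModel]) -> str:
    """Classify one transcript interval against gene models (fixed precedence).

    1. same-strand exon overlap  -> rejected_sense_exonic
    2. opposite-strand gene-span overlap -> antisense
    3. full containment in a single same-strand intron -> intronic
    4. otherwise -> intergenic
    A transcript on a chromosome absent from the annotation is intergenic
    (with a warning).
    """
    on_chrom = [g for g in genes if g.span.chrom == t.chrom]
    if not on_chrom and genes:
        warnings.warn(f"chromosome {t.chrom!r} absent from annotation", stacklevel=2)
        return INTERGENIC
    for g in on_chrom:
        if g.strand == t.strand and any(t.overlaps(e) for e in g.exons):
            return REJECTED
    for g in on_chrom:
        if g.strand != t.strand and t.overlaps(g.span):
            return ANTISENSE
    for g in on_chrom:
        if g.strand == t.strand and any(i.contains(t) for i in g.introns):
            return INTRONIC
    return INTERGENIC


def classify_all(transcripts: Mapping[str, GenomicInterval],
                 genes: Sequence[GeneModel]) -> pd.Series:
    return pd.Series({tid: classify_transcript(iv, genes) for tid, iv in transcripts.items()},
                     name="locus_class")


DEFAULT_LNCRNA_RULES: list[dict] = [
    {"subject_class": "protein_coding", "qcovs_eq": 100.0, "sstrand": "plus",
     "reason": "full-coverage same-strand protein-coding hit"},
    {"subject_class": "ncRNA", "qcovs_eq": 100.0,
     "reason": "full-coverage ncRNA hit"},
    {"subject_class": "TE", "identity_gt": 80.0,
     "reason": "transposable-element identity above 80%"},
]


def _hit_matches(hit: pd.Series, rule: Mapping) -> bool:
    if hit["sclass"] != rule["subject_class"]:
        return False
    if "qcovs_eq" in rule and hit["qcovs"] != rule["qcovs_eq"]:
        return False
    if "sstrand" in rule and hit["sstrand"] != rule["sstrand"]:
        return False
    if "identity_gt" in rule and not hit["pident"] > rule["identity_gt"]:
        return False
    if "identity_lt" in rule and not hit["pident"] < rule["identity_lt"]:
        return False
    return True


def blast_filters(hits: pd.DataFrame, rules: Sequence[Mapping] | None = None,
                  known_classes: set[str] | None = None) -> pd.DataFrame:
    """Keep/drop decision per query from BLAST-style hit summaries.

    ``hits`` columns: qseqid, sclass, qcovs, pident, sstrand.  Rules are tried
    in order; the first rule any of the query's hits satisfies drops that
    query with the rule's reason.  Queries with no hits are kept.  A subject
    class outside the known set raises.
    """
    if rules is None:
        rules = DEFAULT_LNCRNA_RULES
    known = set(known_classes) if known_classes is not None else set(KNOWN_SUBJECT_CLASSES)
    known |= {r["subject_class"] for r in rules}
    bad = set(hits["sclass"]) - known
    if bad:
        raise ValueError(f"unknown subject class(es): {sorted(bad)}")
    out = []
    for qid, g in hits.groupby("qseqid", sort=True):
        keep, reason = True, ""
        for rule in rules:
            if any(_hit_matches(h, rule) for _, h in g.iterrows()):
                keep, reason = False, rule.get("reason", "rule matched")
                break
        out.append({"qseqid": qid, "keep": keep, "reason": reason})
    return pd.DataFrame(out)


def stratify(labels: pd.Series, locus_classes: pd.Series) -> pd.DataFrame:
    """Contingency table: locus class (rows) x pan compartment (columns).

    Both inputs are keyed by transcript/family id; a key mismatch raises with
    the offending ids listed.
    """
    missing = sorted(set(locus_classes.index) - set(labels.index))
    if missing:
        raise ValueError(f"ids missing from partition labels: {missing[:10]}")
    joined = pd.DataFrame({"locus": locus_classes, "compartment": labels.loc[locus_classes.index]})
    return pd.crosstab(joined["locus"], joined["compartment"])
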