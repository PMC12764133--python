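"""Readers and writers for the package's on-disk formats.

Per-line FASTA (headers ``family_id|line_id``), TSV expression matrices
(rows = families, columns = lines), GFF3 gene models (1-based inclusive,
converted to the internal 0-based half-open convention on read), VCF 4.2
variant tables (haploid or diploid GT, MAPQ in INFO/MQ) and truth-table TSVs.
All writers round-trip losslessly through the matching readers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .locus import GeneModel, GenomicInterval
from .popstats import MISSING, VariantTable
from .synthio import SimulatedPopulation, TruthTable


# -- expression ---------------------------------------------------------------

def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="family", float_format="%.6g")


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="family")


# -- FASTA --------------------------------------------------------------------

def write_fasta_per_line(pop: SimulatedPopulation, out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for line in pop.line_ids:
        recs = [
            SeqRecord(Seq(seqs[line]), id=f"{fid}|{line}", description="")
            for fid, seqs in sorted(pop.sequences.items())
            if line in seqs
        ]
        p = out_dir / f"{line}.fasta"
        SeqIO.write(recs, p, "fasta")
        paths.append(p)
    return paths


def read_fasta_dir(fasta_dir: str | Path) -> dict[str, dict[str, str]]:
    """-> {family_id: {line_id: sequence}} from per-line FASTA files."""
    out: dict[str, dict[str, str]] = {}
    for p in sorted(Path(fasta_dir).glob("*.fasta")):
        for rec in SeqIO.parse(p, "fasta"):
            fid, line = rec.id.split("|", 1)
            out.setdefault(fid, {})[line] = str(rec.seq)
    return out


# -- GFF3 ---------------------------------------------------------------------

def write_gff3(genes: list[GeneModel], noncoding: Mapping[str, GenomicInterval],
               chrom_length: int, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        chroms = sorted({g.span.chrom for g in genes} | {iv.chrom for iv in noncoding.values()})
        for c in chroms:
            fh.write(f"##sequence-region {c} 1 {chrom_length}\n")
        for g in genes:
            s = g.span
            fh.write(f"{s.chrom}\tpantx\tgene\t{s.start + 1}\t{s.end}\t.\t{s.strand}\t.\t"
                     f"ID={g.gene_id}\n")
            for i, e in enumerate(g.exons):
                fh.write(f"{e.chrom}\tpantx\texon\t{e.start + 1}\t{e.end}\t.\t{e.strand}\t.\t"
                         f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n")
        for tid, iv in sorted(noncoding.items()):
            fh.write(f"{iv.chrom}\tpantx\tlnc_RNA\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t"
                     f"ID={tid}\n")


def read_gff3(path: str | Path) -> tuple[list[GeneModel], dict[str, GenomicInterval]]:
    genes: dict[str, dict] = {}
    noncoding: dict[str, GenomicInterval] = {}
    with open(path) as fh:
        for raw in fh:
            if raw.startswith("#") or not raw.strip():
                continue
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = \
                raw.rstrip("\n").split("\t")
            a = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            if ftype == "gene":
                genes.setdefault(a["ID"], {"span": iv, "exons": []})["span"] = iv
            elif ftype == "exon":
                genes.setdefault(a["Parent"], {"span": None, "exons": []})["exons"].append(iv)
            elif ftype == "lnc_RNA":
                noncoding[a["ID"]] = iv
    models = [GeneModel(gene_id=gid, span=d["span"], exons=d["exons"])
              for gid, d in genes.items()]
    return models, noncoding


# -- VCF ----------------------------------------------------------------------

def write_vcf(vt: VariantTable, path: str | Path,
              contig_lengths: Mapping[str, int] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        contigs = contig_lengths or {
            t: int(vt.sites.loc[vt.sites["transcript"] == t, "pos"].max()) + 1
            for t in pd.unique(vt.sites["transcript"])
        }
        for c, l in contigs.items():
            fh.write(f"##contig=<ID={c},length={l}>\n")
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(vt.line_ids) + "\n")
        for i in range(vt.n_sites):
            r = vt.sites.iloc[i]
            if vt.ploidy == 1:
                calls = ["." if g == MISSING else str(int(g)) for g in vt.gt[i]]
            else:
                code = {0: "0/0", 1: "0/1", 2: "1/1"}
                calls = ["./." if g == MISSING else code[int(g)] for g in vt.gt[i]]
            fh.write(f"{r['transcript']}\t{int(r['pos'])}\t.\t{r['ref']}\t{r['alt']}\t.\t.\t"
                     f"MQ={float(r['mapq']):g}\tGT\t" + "\t".join(calls) + "\n")


def read_vcf(path: str | Path) -> VariantTable:
    """Read a VCF into a VariantTable (SNP records only; indels are skipped).

    Haploid and diploid GT are supported; diploid calls are stored as alt
    dosages.  MAPQ is taken from INFO/MQ (0 when absent).
    """
    vf = pysam.VariantFile(str(path))
    line_ids = list(vf.header.samples)
    sites, gts = [], []
    ploidy = 1
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            continue
        if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
            continue  # indel
        row = np.full(len(line_ids), MISSING, dtype=np.int8)
        for j, s in enumerate(line_ids):
            gt = rec.samples[s]["GT"]
            if gt is None or all(a is None for a in gt):
                continue
            ploidy = max(ploidy, len(gt))
            row[j] = sum(a for a in gt if a is not None)
        sites.append({"transcript": rec.chrom, "pos": rec.pos, "ref": rec.ref,
                      "alt": rec.alts[0], "mapq": float(rec.info.get("MQ", 0.0))})
        gts.append(row)
    if sites:
        return VariantTable(sites=pd.DataFrame(sites), gt=np.array(gts, dtype=np.int8),
                            line_ids=line_ids, ploidy=ploidy)
    return VariantTable(
        sites=pd.DataFrame(columns=["transcript", "pos", "ref", "alt", "mapq"]),
        gt=np.zeros((0, len(line_ids)), dtype=np.int8), line_ids=line_ids, ploidy=ploidy)


# -- truth tables & dataset bundle --------------------------------------------

def write_truth(truth: TruthTable, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth.families.to_csv(out_dir / "truth_families.tsv", sep="\t")
    truth.presence.astype(int).to_csv(out_dir / "truth_presence.tsv", sep="\t",
                                      index_label="family")


def read_truth(out_dir: str | Path) -> TruthTable:
    out_dir = Path(out_dir)
    families = pd.read_csv(out_dir / "truth_families.tsv", sep="\t", index_col="family")
    families["locus_class"] = families["locus_class"].fillna("")
    presence = pd.read_csv(out_dir / "truth_presence.tsv", sep="\t",
                           index_col="family").astype(bool)
    return TruthTable(families=families, presence=presence)


def write_dataset(pop: SimulatedPopulation, out_dir: str | Path) -> dict[str, Path]:
    """Write the full synthetic dataset; every file round-trips through the
    module's readers."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    write_expression(pop.expression, out_dir / "expression.tsv")
    paths["expression"] = out_dir / "expression.tsv"
    if pop.sequences:
        write_fasta_per_line(pop, out_dir / "fasta")
        paths["fasta"] = out_dir / "fasta"
        write_gff3(pop.genes, pop.noncoding_loci, pop.chrom_length,
                   out_dir / "annotation.gff3")
        paths["annotation"] = out_dir / "annotation.gff3"
    if pop.variants is not None and pop.variants.n_sites >= 0:
        lengths = {fid: int(row["length"])
                   for fid, row in pop.truth.families.iterrows()}
        write_vcf(pop.variants, out_dir / "variants.vcf", contig_lengths=lengths)
        paths["variants"] = out_dir / "variants.vcf"
        pd.Series(lengths, name="length").to_csv(out_dir / "lengths.tsv", sep="\t",
                                                 index_label="transcript")
        paths["lengths"] = out_dir / "lengths.tsv"
    write_truth(pop.truth, out_dir)
    paths["truth"] = out_dir
    return paths
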