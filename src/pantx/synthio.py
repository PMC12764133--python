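"""Synthetic pan-transcriptome populations with known ground truth.

Emulates a panel of inbred (haploid) lines expressing gene families that fall
into occupancy classes — core (every line), shell (10–90% of lines) and cloud
(fewer than 10%) — with log-normal TPM for present genes, family sequences
diverged from an ancestor at gamma-distributed per-site rates, purifying
selection on coding families (nonsynonymous acceptance probability omega < 1),
and genomic placement of noncoding loci (antisense / intronic / intergenic)
relative to simulated gene models.  Every emitted artefact is derivable from
the truth table plus the seed, so downstream modules can be tested for exact
recovery.

Evolution is substitution-only (no indels): the per-family "alignment" is
positional, which keeps the NG86 and Kn oracles exact.  A separate
coalescent-based generator (msprime) provides neutral genotype matrices with
a realistic shared genealogy for frequency-spectrum statistics; the default
star-shaped generator produces mostly line-private alleles, which is the
wrong null for Tajima's D.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from Bio.Data import CodonTable

from .locus import GeneModel, GenomicInterval, ANTISENSE, INTRONIC, INTERGENIC
from .popstats import MISSING, VariantTable

CLASSES = ("core", "shell", "cloud")
LOCUS_CLASSES = (ANTISENSE, INTRONIC, INTERGENIC)
_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = set(CodonTable.unambiguous_dna_by_id[1].stop_codons)
_FWD = CodonTable.unambiguous_dna_by_id[1].forward_table
_SENSE_CODONS = sorted(_FWD)


def _per_class(value, cls: str) -> float:
    return float(value[cls]) if isinstance(value, Mapping) else float(value)


@dataclass
class SimConfig:
    """Generating parameters for a synthetic pan-transcriptome population.

    Rate parameters may be scalars or per-class mappings; defaults plant mean
    substitution rate and gamma shape increasing core < shell < cloud, with
    noncoding families at ``noncoding_shape_scale`` times the shape and
    ``noncoding_rate_scale`` times the mean rate of coding families.
    Per-family omega is drawn from a Beta with mean ``omega`` (selection
    strength varies among genes); ``omega_concentration`` controls its spread.
    """

    n_lines: int = 50
    n_core: int = 20
    n_shell: int = 60
    n_cloud: int = 20
    coding_fraction: float | Mapping[str, float] = 0.5
    tpm_meanlog: float = 3.0
    tpm_sdlog: float = 1.2
    tpm_threshold: float = 1.0
    rate_shape: float | Mapping[str, float] = field(
        default_factory=lambda: {"core": 0.7, "shell": 1.1, "cloud": 1.6})
    rate_rate: float | Mapping[str, float] = field(
        default_factory=lambda: {"core": 0.7 / 0.08, "shell": 1.1 / 0.12, "cloud": 1.6 / 0.18})
    noncoding_shape_scale: float = 1.8
    noncoding_rate_scale: float = 2.0
    omega: float = 0.3
    omega_concentration: float = 12.0
    seq_len_range: tuple[int, int] = (600, 1500)
    dropout_below_threshold: bool = False
    mapq: float = 60.0
    locus_probs: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "core": (0.55, 0.15, 0.30),
            "shell": (0.34, 0.33, 0.33),
            "cloud": (0.15, 0.20, 0.65),
        })
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 2:
            raise ValueError("need at least 2 lines")
        if min(self.n_core, self.n_shell, self.n_cloud) < 0:
            raise ValueError("family counts must be >= 0")
        for cls in CLASSES:
            if _per_class(self.rate_shape, cls) <= 0 or _per_class(self.rate_rate, cls) <= 0:
                raise ValueError("gamma rate parameters must be > 0")
        if not 0 <= self.omega <= 1:
            raise ValueError("omega must be in [0, 1]")
        if self.n_cloud > 0 and math.ceil(0.1 * self.n_lines) - 1 < 1:
            raise ValueError(
                "cloud occupancy band (<10%) unrepresentable with "
                f"{self.n_lines} lines")
        lo, hi = self.seq_len_range
        if lo < 3 or hi < lo:
            raise ValueError("invalid seq_len_range")

    @classmethod
    def paper_like(cls, n_lines: int = 50, n_coding: int = 500, n_noncoding: int = 500,
                   seed: int = 0, **kw) -> "SimConfig":
        """Study-condition composition: the coding stratum is shell-dominated
        (8% core / 81% shell / 11% cloud) while the noncoding stratum is
        cloud-heavy (5% / 42.5% / 52.5%)."""
        cod = {"core": round(0.08 * n_coding), "cloud": round(0.11 * n_coding)}
        cod["shell"] = n_coding - cod["core"] - cod["cloud"]
        non = {"core": round(0.05 * n_noncoding), "cloud": round(0.525 * n_noncoding)}
        non["shell"] = n_noncoding - non["core"] - non["cloud"]
        counts = {c: cod[c] + non[c] for c in CLASSES}
        frac = {c: (cod[c] / counts[c] if counts[c] else 0.0) for c in CLASSES}
        return cls(n_lines=n_lines, n_core=counts["core"], n_shell=counts["shell"],
                   n_cloud=counts["cloud"], coding_fraction=frac, seed=seed, **kw)

    @classmethod
    def rate_study(cls, n_lines: int = 50, seed: int = 0, **kw) -> "SimConfig":
        """Composition for substitution-rate comparisons: every pan
        compartment holds enough families (>= 50 per stratum) for a stable
        gamma-shape fit, while the noncoding stratum stays cloud-heavy
        (coding 100/300/100, noncoding 50/200/250 across core/shell/cloud)."""
        return cls(n_lines=n_lines, n_core=150, n_shell=500, n_cloud=350,
                   coding_fraction={"core": 100 / 150, "shell": 300 / 500,
                                    "cloud": 100 / 350},
                   seed=seed, **kw)


@dataclass
class TruthTable:
    """Ground truth: per-family class/occupancy/rate/omega/locus-class and the
    per-line presence indicators."""

    families: pd.DataFrame  # index family_id; pan_class, occupancy, coding,
    #                          true_rate, omega, locus_class, length
    presence: pd.DataFrame  # bool, families x lines


@dataclass
class SimulatedPopulation:
    config: SimConfig
    truth: TruthTable
    expression: pd.DataFrame  # TPM, families x lines
    line_ids: list[str]
    ancestors: dict[str, str] = field(default_factory=dict)
    sequences: dict[str, dict[str, str]] = field(default_factory=dict)
    genes: list[GeneModel] = field(default_factory=list)
    noncoding_loci: dict[str, GenomicInterval] = field(default_factory=dict)
    chrom_length: int = 0
    variants: VariantTable | None = None


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def simulate_population(config: SimConfig) -> SimulatedPopulation:
    """Draw presence indicators, expression, true rates and locus classes.

    Core rows are all-present; shell occupancy is uniform on [0.10, 0.90]
    (realised counts clipped into the band); cloud rows are present in an
    integer number of lines between 1 and ceil(0.1 L) - 1.
    """
    rng = _rng(config, 1)
    L = config.n_lines
    line_ids = [f"line{j:03d}" for j in range(L)]
    fam_rows = []
    presence_rows = []
    counts = {"core": config.n_core, "shell": config.n_shell, "cloud": config.n_cloud}
    idx = 0
    for cls in CLASSES:
        shape = _per_class(config.rate_shape, cls)
        rate = _per_class(config.rate_rate, cls)
        frac = _per_class(config.coding_fraction, cls)
        n_coding_cls = int(round(frac * counts[cls]))
        for k in range(counts[cls]):
            fid = f"fam{idx:05d}"
            idx += 1
            coding = k < n_coding_cls
            if cls == "core":
                present = np.ones(L, dtype=bool)
            elif cls == "shell":
                occ = rng.uniform(0.10, 0.90)
                cnt = int(np.clip(round(occ * L), math.ceil(0.10 * L), math.floor(0.90 * L)))
                present = np.zeros(L, dtype=bool)
                present[rng.choice(L, size=cnt, replace=False)] = True
            else:
                cnt = int(rng.integers(1, math.ceil(0.10 * L)))  # in [1, ceil(0.1 L) - 1]
                present = np.zeros(L, dtype=bool)
                present[rng.choice(L, size=cnt, replace=False)] = True
            sh = shape * (1.0 if coding else config.noncoding_shape_scale)
            mean = (shape / rate) * (1.0 if coding else config.noncoding_rate_scale)
            true_rate = float(rng.gamma(sh, mean / sh))
            if coding:
                if 0 < config.omega < 1:
                    c = config.omega_concentration
                    om = float(rng.beta(config.omega * c, (1 - config.omega) * c))
                else:
                    om = float(config.omega)
                locus = ""
            else:
                om = math.nan
                locus = str(rng.choice(LOCUS_CLASSES, p=config.locus_probs[cls]))
            lo, hi = config.seq_len_range
            length = int(rng.integers(lo, hi + 1))
            if coding:
                length -= length % 3
                length = max(length, 3)
            fam_rows.append({
                "family": fid, "pan_class": cls, "occupancy": present.sum() / L,
                "coding": coding, "true_rate": true_rate, "omega": om,
                "locus_class": locus, "length": length,
            })
            presence_rows.append(present)
    families = pd.DataFrame(fam_rows).set_index("family")
    presence = pd.DataFrame(
        np.array(presence_rows, dtype=bool).reshape(len(fam_rows), L),
        index=families.index, columns=line_ids)
    expr = _simulate_expression(config, families, presence)
    truth = TruthTable(families=families, presence=presence)
    return SimulatedPopulation(config=config, truth=truth, expression=expr, line_ids=line_ids)


def _simulate_expression(config: SimConfig, families: pd.DataFrame,
                         presence: pd.DataFrame) -> pd.DataFrame:
    rng = _rng(config, 2)
    shape = presence.shape
    tpm = rng.lognormal(config.tpm_meanlog, config.tpm_sdlog, size=shape)
    if not config.dropout_below_threshold:
        tpm = np.maximum(tpm, config.tpm_threshold)
        absent_tpm = np.zeros(shape)
    else:
        absent_tpm = rng.uniform(0, config.tpm_threshold, size=shape)
    values = np.where(presence.to_numpy(), tpm, absent_tpm)
    return pd.DataFrame(values, index=presence.index, columns=presence.columns)


def _random_coding(rng: np.random.Generator, length: int) -> str:
    # stop-free by rejection: redraw any codon that comes out as a stop
    out = []
    for _ in range(length // 3):
        codon = "".join(rng.choice(list("ACGT"), size=3))
        while codon in _STOPS:
            codon = "".join(rng.choice(list("ACGT"), size=3))
        out.append(codon)
    return "".join(out)


def _evolve(rng: np.random.Generator, ancestor: str, rate: float, coding: bool,
            omega: float) -> str:
    """Apply Poisson(rate * length) proposed substitutions at uniform sites.

    For coding sequences a proposal creating a stop codon is rejected and a
    proposal changing the encoded amino acid is accepted with probability
    omega; synonymous proposals are always accepted.
    """
    seq = list(ancestor)
    n = rng.poisson(rate * len(seq))
    for _ in range(n):
        pos = int(rng.integers(len(seq)))
        old = seq[pos]
        new = "ACGT".replace(old, "")[int(rng.integers(3))]
        if coding:
            c0 = pos - pos % 3
            codon_old = "".join(seq[c0:c0 + 3])
            codon_new = codon_old[: pos - c0] + new + codon_old[pos - c0 + 1:]
            if codon_new in _STOPS:
                continue
            syn = _FWD[codon_new] == _FWD[codon_old]
            if not syn and rng.random() >= omega:
                continue
        seq[pos] = new
    return "".join(seq)


def simulate_sequences(pop: SimulatedPopulation) -> SimulatedPopulation:
    """Generate ancestral sequences and per-line diverged copies (gap-free)."""
    config = pop.config
    rng = _rng(config, 3)
    for fid, row in pop.truth.families.iterrows():
        length = int(row["length"])
        if row["coding"]:
            anc = _random_coding(rng, length)
        else:
            anc = "".join(rng.choice(list("ACGT"), size=length))
        pop.ancestors[fid] = anc
        pop.sequences[fid] = {}
        present = pop.truth.presence.loc[fid]
        for line in pop.line_ids:
            if present[line]:
                pop.sequences[fid][line] = _evolve(
                    rng, anc, row["true_rate"], bool(row["coding"]),
                    float(row["omega"]) if row["coding"] else 1.0)
    _place_annotation(pop)
    return pop


def _place_annotation(pop: SimulatedPopulation) -> None:
    """Lay gene models along one synthetic chromosome and drop noncoding loci
    into antisense / intronic / intergenic positions per the truth table."""
    config = pop.config
    rng = _rng(config, 4)
    chrom = "chr1"
    cursor = 2000
    genes: list[GeneModel] = []
    fam = pop.truth.families
    for fid, row in fam[fam["coding"]].iterrows():
        tx_len = int(row["length"])
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(2, 4))
        cuts = sorted(rng.choice(np.arange(1, tx_len), size=n_ex - 1, replace=False))
        ex_lens = np.diff([0, *cuts, tx_len])
        exons = []
        pos = cursor
        for i, el in enumerate(ex_lens):
            exons.append(GenomicInterval(chrom, pos, pos + int(el), strand))
            pos += int(el)
            if i < n_ex - 1:
                pos += int(rng.integers(1000, 2001))  # intron
        span = GenomicInterval(chrom, cursor, pos, strand)
        genes.append(GeneModel(gene_id=fid, span=span, exons=exons))
        cursor = pos + int(rng.integers(3000, 5001))
    pop.genes = genes
    pop.chrom_length = cursor + 5000

    gaps = []
    prev = 0
    for g in genes:
        if g.span.start - prev > 1000:
            gaps.append((prev + 100, g.span.start - 100))
        prev = g.span.end
    gaps.append((prev + 100, pop.chrom_length - 100))

    updates = {}
    for fid, row in fam[~fam["coding"]].iterrows():
        length = int(row["length"])
        want = row["locus_class"]
        placed = None
        if want == ANTISENSE and genes:
            g = genes[int(rng.integers(len(genes)))]
            span_len = g.span.end - g.span.start
            l = min(length, span_len)
            off = int(rng.integers(0, span_len - l + 1))
            placed = GenomicInterval(chrom, g.span.start + off, g.span.start + off + l,
                                     "-" if g.strand == "+" else "+")
        elif want == INTRONIC and genes:
            hosts = [(g, i) for g in genes for i in g.introns if i.end - i.start >= length + 2]
            if hosts:
                g, intron = hosts[int(rng.integers(len(hosts)))]
                off = int(rng.integers(1, intron.end - intron.start - length))
                placed = GenomicInterval(chrom, intron.start + off,
                                         intron.start + off + length, g.strand)
        if placed is None:  # intergenic, or fallback when no host exists
            spans = [(a, b) for a, b in gaps if b - a >= length]
            a, b = spans[int(rng.integers(len(spans)))]
            off = int(rng.integers(0, b - a - length + 1))
            placed = GenomicInterval(chrom, a + off, a + off + length,
                                     "+" if rng.random() < 0.5 else "-")
            if want != INTERGENIC:
                updates[fid] = INTERGENIC
        pop.noncoding_loci[fid] = placed
    for fid, cls in updates.items():
        pop.truth.families.loc[fid, "locus_class"] = cls


def simulate_variants(pop: SimulatedPopulation) -> VariantTable:
    """Biallelic variant records from the positional per-family alignments.

    Alignment columns with exactly two alleles among present lines become
    records (reference = ancestral allele when segregating, else the major
    allele); columns with more than two alleles are dropped.  Genotypes are
    haploid; lines lacking the family are missing calls.
    """
    config = pop.config
    if not pop.sequences:
        raise ValueError("simulate_sequences must run first")
    line_index = {l: j for j, l in enumerate(pop.line_ids)}
    sites = []
    gts = []
    for fid in pop.truth.families.index:
        seqs = pop.sequences[fid]
        if len(seqs) < 2:
            continue
        lines = sorted(seqs)
        mat = np.frombuffer("".join(seqs[l] for l in lines).encode(), dtype="S1")
        mat = mat.reshape(len(lines), -1)
        anc = np.frombuffer(pop.ancestors[fid].encode(), dtype="S1")
        present_mask = np.zeros((4, mat.shape[1]), dtype=bool)
        for k, b in enumerate(_BASES):
            present_mask[k] = (mat == b).any(axis=0)
        n_alleles = present_mask.sum(axis=0)
        for col in np.nonzero(n_alleles == 2)[0]:
            alleles = _BASES[present_mask[:, col]]
            a0, a1 = alleles[0], alleles[1]
            counts = ((mat[:, col] == a0).sum(), (mat[:, col] == a1).sum())
            if anc[col] in (a0, a1):
                ref = anc[col]
            else:
                ref = a0 if counts[0] >= counts[1] else a1
            alt = a1 if ref == a0 else a0
            gt = np.full(len(pop.line_ids), MISSING, dtype=np.int8)
            for i, l in enumerate(lines):
                gt[line_index[l]] = 0 if mat[i, col] == ref else 1
            sites.append({"transcript": fid, "pos": int(col) + 1,
                          "ref": ref.decode(), "alt": alt.decode(), "mapq": config.mapq})
            gts.append(gt)
    if sites:
        vt = VariantTable(sites=pd.DataFrame(sites),
                          gt=np.array(gts, dtype=np.int8),
                          line_ids=list(pop.line_ids), ploidy=1)
    else:
        vt = VariantTable(
            sites=pd.DataFrame(columns=["transcript", "pos", "ref", "alt", "mapq"]),
            gt=np.zeros((0, len(pop.line_ids)), dtype=np.int8),
            line_ids=list(pop.line_ids), ploidy=1)
    pop.variants = vt
    return vt


def simulate_all(config: SimConfig) -> SimulatedPopulation:
    """Population, sequences, annotation and variants in one deterministic go."""
    pop = simulate_population(config)
    simulate_sequences(pop)
    simulate_variants(pop)
    return pop


def simulate_neutral_variants(n_lines: int, n_transcripts: int, length: int = 2000,
                              population_size: float = 1e4, mu: float = 2e-6,
                              seed: int = 0, mapq: float = 60.0,
                              ) -> tuple[VariantTable, dict[str, int]]:
    """Neutral haploid variant tables on a shared coalescent genealogy.

    Uses msprime (standard neutral coalescent, no recombination within a
    transcript, independent genealogies across transcripts).  Suitable as the
    null for frequency-spectrum statistics such as Tajima's D, which the
    star-shaped substitution simulator deliberately is not.
    """
    import msprime

    rng = np.random.default_rng(seed)
    sites = []
    gts = []
    lengths = {}
    line_ids = [f"line{j:03d}" for j in range(n_lines)]
    for t in range(n_transcripts):
        tid = f"tx{t:04d}"
        lengths[tid] = length
        s1, s2 = int(rng.integers(1, 2**31 - 1)), int(rng.integers(1, 2**31 - 1))
        ts = msprime.sim_ancestry(samples=n_lines, ploidy=1, sequence_length=length,
                                  population_size=population_size, random_seed=s1)
        ts = msprime.sim_mutations(ts, rate=mu, random_seed=s2)
        for var in ts.variants():
            if len(var.alleles) != 2:
                continue
            sites.append({"transcript": tid, "pos": int(var.site.position) + 1,
                          "ref": var.alleles[0], "alt": var.alleles[1], "mapq": mapq})
            gts.append(var.genotypes.astype(np.int8))
    if sites:
        vt = VariantTable(sites=pd.DataFrame(sites), gt=np.array(gts, dtype=np.int8),
                          line_ids=line_ids, ploidy=1)
    else:
        vt = VariantTable(
            sites=pd.DataFrame(columns=["transcript", "pos", "ref", "alt", "mapq"]),
            gt=np.zeros((0, n_lines), dtype=np.int8), line_ids=line_ids, ploidy=1)
    return vt, lengths
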