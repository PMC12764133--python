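"""Generator contracts: occupancy bands, determinism, constraint direction,
variant emission, and lossless round-trips of every emitted file."""

import itertools

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from pantx import epav, evorates, io, synthio
from pantx.synthio import SimConfig


def test_core_rows_all_present():
    cfg = SimConfig(n_lines=20, n_core=5, n_shell=0, n_cloud=0, seed=1)
    pop = synthio.simulate_population(cfg)
    assert pop.truth.presence.shape == (5, 20)
    assert pop.truth.presence.all(axis=None)


def test_cloud_rows_within_band():
    cfg = SimConfig(n_lines=20, n_core=0, n_shell=0, n_cloud=5, seed=1)
    pop = synthio.simulate_population(cfg)
    sums = pop.truth.presence.sum(axis=1)
    # ceil(0.1*20)-1 = 1 -> every cloud row present in exactly 1 line
    assert (sums == 1).all()


def test_shell_occupancy_within_band_many_families():
    cfg = SimConfig(n_lines=50, n_core=0, n_shell=1000, n_cloud=0, seed=7)
    pop = synthio.simulate_population(cfg)
    occ = pop.truth.presence.sum(axis=1) / 50
    assert ((occ >= 0.10) & (occ <= 0.90)).all()


def test_cloud_unrepresentable_below_eleven_lines():
    with pytest.raises(ValueError, match="cloud"):
        SimConfig(n_lines=9, n_cloud=1)


def test_determinism_byte_identical():
    cfg = SimConfig(n_lines=15, n_core=5, n_shell=10, n_cloud=3, seed=99)
    a = synthio.simulate_all(cfg)
    b = synthio.simulate_all(cfg)
    assert a.expression.equals(b.expression)
    assert a.sequences == b.sequences
    assert a.ancestors == b.ancestors
    assert (a.variants.gt == b.variants.gt).all()
    assert a.variants.sites.equals(b.variants.sites)


def test_partition_recovers_truth_without_dropout(small_pop):
    pam = epav.build_epav(small_pop.expression)
    part = epav.partition(pam)
    truth = small_pop.truth.families["pan_class"]
    assert (part.labels.loc[truth.index] == truth).all()


def test_zero_rate_descendants_equal_ancestor():
    cfg = SimConfig(n_lines=12, n_core=4, n_shell=0, n_cloud=0, seed=3,
                    rate_shape=1.0, rate_rate=1.0)
    pop = synthio.simulate_population(cfg)
    pop.truth.families["true_rate"] = 0.0
    synthio.simulate_sequences(pop)
    for fid, per_line in pop.sequences.items():
        for seq in per_line.values():
            assert seq == pop.ancestors[fid]


def test_omega_zero_yields_only_synonymous_changes():
    cfg = SimConfig(n_lines=12, n_core=6, n_shell=0, n_cloud=0, seed=4,
                    coding_fraction=1.0, omega=0.0,
                    rate_shape=1.0, rate_rate=1.0 / 0.1)
    pop = synthio.simulate_sequences(synthio.simulate_population(cfg))
    changed = 0
    for fid, per_line in pop.sequences.items():
        anc_prot = str(Seq(pop.ancestors[fid]).translate())
        for seq in per_line.values():
            assert str(Seq(seq).translate()) == anc_prot
            changed += sum(a != b for a, b in zip(seq, pop.ancestors[fid]))
    assert changed > 0  # synonymous changes did occur


def test_coding_sequences_stop_free_and_length_multiple_of_three(small_pop):
    fam = small_pop.truth.families
    for fid in fam.index[fam["coding"]]:
        anc = small_pop.ancestors[fid]
        assert len(anc) % 3 == 0
        assert "*" not in str(Seq(anc).translate())
        for seq in small_pop.sequences[fid].values():
            assert "*" not in str(Seq(seq).translate())


def test_constraint_direction_mean_ka_ks_below_one():
    """With omega < 1 the mean Ka/Ks over coding families is < 1."""
    cfg = SimConfig(n_lines=10, n_core=500, n_shell=0, n_cloud=0, seed=21,
                    coding_fraction=1.0, rate_shape=1.0, rate_rate=1.0 / 0.1)
    pop = synthio.simulate_sequences(synthio.simulate_population(cfg))
    ratios = []
    for fid, per_line in pop.sequences.items():
        line, seq = next(iter(per_line.items()))
        est = evorates.ka_ks(pop.ancestors[fid], seq)
        if np.isfinite(est.ka_ks):
            ratios.append(est.ka_ks)
    assert len(ratios) >= 400
    assert np.mean(ratios) < 1.0


def test_gamma_rate_recovery_from_truth_table():
    """fit_gamma on the generator's own true rates recovers the planted shape."""
    cfg = SimConfig(n_lines=10, n_core=2000, n_shell=0, n_cloud=0, seed=3,
                    coding_fraction=1.0, rate_shape=0.5, rate_rate=2.0)
    pop = synthio.simulate_population(cfg)
    fit = evorates.fit_gamma(pop.truth.families["true_rate"])
    assert fit.shape == pytest.approx(0.5, abs=0.05)


# -- variants -----------------------------------------------------------------

def test_identical_lines_emit_no_variants():
    cfg = SimConfig(n_lines=12, n_core=3, n_shell=0, n_cloud=0, seed=5,
                    rate_shape=1.0, rate_rate=1.0)
    pop = synthio.simulate_population(cfg)
    pop.truth.families["true_rate"] = 0.0
    synthio.simulate_sequences(pop)
    vt = synthio.simulate_variants(pop)
    assert vt.n_sites == 0


def test_variant_allele_counts_single_column():
    cfg = SimConfig(n_lines=4, n_core=1, n_shell=0, n_cloud=0, seed=6,
                    rate_shape=1.0, rate_rate=1.0)
    pop = synthio.simulate_population(cfg)
    pop.truth.families["true_rate"] = 0.0
    synthio.simulate_sequences(pop)
    fid = pop.truth.families.index[0]
    line3 = pop.line_ids[3]
    seq = list(pop.sequences[fid][line3])
    seq[10] = "T" if seq[10] != "T" else "A"
    pop.sequences[fid][line3] = "".join(seq)
    vt = synthio.simulate_variants(pop)
    assert vt.n_sites == 1
    assert vt.sites.iloc[0]["pos"] == 11
    gt = vt.gt[0]
    assert (gt == 1).sum() == 1 and (gt == 0).sum() == 3


def test_variant_count_matches_bruteforce_column_scan(small_pop):
    vt = small_pop.variants
    expected = 0
    for fid, per_line in small_pop.sequences.items():
        seqs = list(per_line.values())
        if len(seqs) < 2:
            continue
        for col in range(len(seqs[0])):
            alleles = {s[col] for s in seqs}
            if len(alleles) == 2:
                expected += 1
    assert vt.n_sites == expected


# -- file round-trips ---------------------------------------------------------

def test_dataset_round_trips(tmp_path, small_pop):
    paths = io.write_dataset(small_pop, tmp_path)
    expr = io.read_expression(paths["expression"])
    assert np.allclose(expr.to_numpy(), small_pop.expression.to_numpy(), rtol=1e-4)

    vt = io.read_vcf(paths["variants"])
    orig = small_pop.variants
    assert vt.n_sites == orig.n_sites
    assert (vt.gt == orig.gt).all()
    assert vt.sites["pos"].tolist() == orig.sites["pos"].tolist()
    assert vt.sites["ref"].tolist() == orig.sites["ref"].tolist()

    genes, noncoding = io.read_gff3(paths["annotation"])
    by_id = {g.gene_id: g for g in genes}
    for g in small_pop.genes:
        assert by_id[g.gene_id].span == g.span
        assert by_id[g.gene_id].exons == g.exons
    assert noncoding == small_pop.noncoding_loci

    seqs = io.read_fasta_dir(paths["fasta"])
    assert seqs == small_pop.sequences

    truth = io.read_truth(tmp_path)
    assert (truth.presence.to_numpy() == small_pop.truth.presence.to_numpy()).all()
    assert truth.families["pan_class"].equals(small_pop.truth.families["pan_class"])


def test_expression_threshold_clamping_and_dropout():
    cfg = SimConfig(n_lines=15, n_core=10, n_shell=20, n_cloud=2, seed=8)
    pop = synthio.simulate_population(cfg)
    present = pop.truth.presence.to_numpy()
    tpm = pop.expression.to_numpy()
    assert (tpm[present] >= cfg.tpm_threshold).all()
    assert (tpm[~present] == 0).all()

    cfg_d = SimConfig(n_lines=15, n_core=10, n_shell=20, n_cloud=2, seed=8,
                      dropout_below_threshold=True)
    pop_d = synthio.simulate_population(cfg_d)
    absent_tpm = pop_d.expression.to_numpy()[~pop_d.truth.presence.to_numpy()]
    assert (absent_tpm < cfg.tpm_threshold).all()
    assert (absent_tpm > 0).any()
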