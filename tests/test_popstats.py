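"""Diversity statistics against brute-force pairwise oracles, and the
boundary behaviour of the variant-filter cascade."""

import itertools
import math
from math import comb, factorial

import numpy as np
import pandas as pd
import pytest

from pantx import popstats as ps
from pantx import synthio
from pantx.popstats import MISSING, VariantTable


# -- independent oracles ------------------------------------------------------

def _oracle_tajimas_d(n, s, pi_total):
    """Tajima's D coded independently (explicit constants, no shared code)."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi_total - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1.0))


def _oracle_hwe(n_aa, n_ab, n_bb):
    """Exact HWE p by direct hypergeometric-style enumeration with factorials."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    rare = min(na, 2 * n - na)

    def prob(het):
        hom_r = (rare - het) // 2
        hom_c = n - het - hom_r
        return (factorial(n) // (factorial(hom_r) * factorial(het) * factorial(hom_c))) \
            * 2**het * factorial(rare) * factorial(2 * n - rare) / factorial(2 * n)

    obs_het = n_ab
    total = 0.0
    acc = 0.0
    p_obs = prob(obs_het)
    for het in range(rare % 2, rare + 1, 2):
        p = prob(het)
        total += p
        if p <= p_obs * (1 + 1e-12):
            acc += p
    return min(1.0, acc / total)


def _mat_to_vt(columns, mapq=60.0, transcript="tx0"):
    """Build a haploid VariantTable from explicit 0/1/MISSING site columns."""
    gt = np.array(columns, dtype=np.int8)
    sites = pd.DataFrame({
        "transcript": [transcript] * len(columns),
        "pos": np.arange(1, len(columns) + 1),
        "ref": "A", "alt": "T", "mapq": mapq,
    })
    lines = [f"l{i}" for i in range(gt.shape[1])]
    return VariantTable(sites=sites, gt=gt, line_ids=lines, ploidy=1)


# -- site pi and total pi -----------------------------------------------------

def test_site_pi_equals_bruteforce_pairwise_difference(rng):
    for _ in range(50):
        n = int(rng.integers(2, 9))
        alleles = rng.integers(0, 2, size=n)
        n1, n2 = int((alleles == 0).sum()), int((alleles == 1).sum())
        brute = np.mean([a != b for a, b in itertools.combinations(alleles, 2)])
        assert ps.site_pi(n1, n2) == pytest.approx(brute, abs=1e-12)


@pytest.mark.parametrize("n1, n2, expected", [(2, 2, 4 / 6), (4, 0, 0.0), (1, 3, 0.5)])
def test_site_pi_examples(n1, n2, expected):
    assert ps.site_pi(n1, n2) == pytest.approx(expected)


def test_alignment_pi_total_equals_mean_pairwise_hamming(rng):
    """Sum of site pi over an alignment = mean pairwise Hamming distance."""
    for _ in range(20):
        n, L = int(rng.integers(4, 9)), int(rng.integers(5, 15))
        mat = rng.integers(0, 2, size=(n, L))
        biallelic = [c for c in range(L) if 0 < mat[:, c].sum() < n]
        total = sum(ps.site_pi(int((mat[:, c] == 0).sum()), int((mat[:, c] == 1).sum()))
                    for c in biallelic)
        brute = np.mean([(a != b).sum() for a, b in itertools.combinations(mat, 2)])
        assert total == pytest.approx(brute, abs=1e-9)


# -- Tajima's D ---------------------------------------------------------------

def test_tajimas_d_agrees_with_oracle_over_grid():
    for n in range(4, 21):
        a1 = sum(1.0 / i for i in range(1, n))
        for s in range(1, 51):
            pi_total = s / a1 * 1.3  # arbitrary diversity excess
            assert ps.tajimas_d(n, s, pi_total) == pytest.approx(
                _oracle_tajimas_d(n, s, pi_total), abs=1e-9)


def test_tajimas_d_worked_example_four_sequences():
    """AAA/AAT/ATT/TTT: S = 3, mean pairwise differences 10/6."""
    seqs = ["AAA", "AAT", "ATT", "TTT"]
    pi_total = np.mean([sum(a != b for a, b in zip(x, y))
                        for x, y in itertools.combinations(seqs, 2)])
    assert pi_total == pytest.approx(10 / 6)
    assert ps.tajimas_d(4, 3, pi_total) == pytest.approx(0.1677, abs=5e-4)


def test_tajimas_d_zero_when_estimators_agree():
    a1 = sum(1.0 / i for i in range(1, 10))
    assert ps.tajimas_d(10, 7, 7 / a1) == pytest.approx(0.0, abs=1e-12)


def test_tajimas_d_domain_errors():
    with pytest.raises(ValueError):
        ps.tajimas_d(3, 5, 1.0)
    with pytest.raises(ValueError):
        ps.tajimas_d(10, 0, 0.0)


def test_mean_d_near_zero_under_neutral_coalescent():
    """Neutral coalescent simulation: mean D across transcripts sits inside
    the empirical band around zero expected for finite samples."""
    vt, lengths = synthio.simulate_neutral_variants(40, 120, seed=9)
    stats = ps.transcript_stats(vt, lengths)
    d = stats["tajimas_d"].dropna()
    assert len(d) > 100
    assert abs(d.mean()) < 0.3


# -- HWE ----------------------------------------------------------------------

@pytest.mark.parametrize("counts", [(25, 50, 25), (50, 0, 50), (10, 0, 0),
                                    (5, 20, 5), (3, 1, 7), (0, 14, 0)])
def test_hwe_exact_matches_enumeration_oracle(counts):
    assert ps.hwe_exact_p(*counts) == pytest.approx(_oracle_hwe(*counts), rel=1e-9)


def test_hwe_boundary_behaviour():
    assert ps.hwe_exact_p(25, 50, 25) == pytest.approx(1.0, abs=0.05)
    assert ps.hwe_exact_p(50, 0, 50) < 0.01  # total heterozygote deficit
    assert ps.hwe_exact_p(10, 0, 0) == 1.0  # monomorphic


# -- filter cascade -----------------------------------------------------------

def test_filter_boundaries_missingness_maf_mapq():
    L = 100
    base = [0] * 50 + [1] * 50
    cols = [
        base,                                    # clean site
        [MISSING] * 26 + base[26:],              # 26% missing -> dropped
        [MISSING] * 25 + base[25:],              # 25% missing -> kept
        [1] * 5 + [0] * 95,                      # MAF exactly 0.05 -> kept
        [1] * 4 + [0] * 96,                      # MAF 0.04 -> dropped
    ]
    vt = _mat_to_vt(cols)
    vt.sites.loc[0, "mapq"] = 30.0  # strict >30 -> dropped
    out = ps.filter_variants(vt, ld_r2=2.0)  # disable LD effect (r2 <= 1)
    assert out.filter_log["mapq"] == 1
    assert out.filter_log["missing"] == 1
    assert out.filter_log["maf"] == 1
    kept_pos = set(out.sites["pos"])
    assert kept_pos == {3, 4}


def test_filter_cascade_is_idempotent():
    rng = np.random.default_rng(5)
    cols = rng.integers(0, 2, size=(40, 60)).tolist()
    vt = _mat_to_vt(cols)
    once = ps.filter_variants(vt)
    twice = ps.filter_variants(once)
    assert once.n_sites == twice.n_sites
    assert (once.gt == twice.gt).all()
    assert sum(twice.filter_log.values()) == 0


def test_ld_prune_duplicates_and_independent_sites(rng):
    base = list(rng.integers(0, 2, size=50))
    vt = _mat_to_vt([base, base, base])  # three identical sites
    out = ps.ld_prune(vt)
    assert out.n_sites == 1
    assert out.sites["pos"].tolist() == [1]
    # independent random sites stay (retention >= 99%)
    cols = rng.integers(0, 2, size=(200, 400)).tolist()
    vt2 = _mat_to_vt(cols)
    out2 = ps.ld_prune(vt2)
    assert out2.n_sites >= 198


def test_hwe_stage_noop_for_haploid_but_active_for_diploid():
    # diploid pseudo-genotypes with a gross heterozygote deficit
    gt = np.array([[0] * 30 + [2] * 30, [0] * 15 + [1] * 30 + [2] * 15], dtype=np.int8)
    sites = pd.DataFrame({"transcript": ["t", "t"], "pos": [1, 2],
                          "ref": "A", "alt": "T", "mapq": 60.0})
    vt = VariantTable(sites=sites, gt=gt, line_ids=[f"l{i}" for i in range(60)], ploidy=2)
    out = ps.filter_variants(vt, ld_r2=2.0)
    assert out.filter_log["hwe"] == 1
    assert out.sites["pos"].tolist() == [2]


# -- per-transcript stats -----------------------------------------------------

def test_transcript_stats_examples():
    cols = [[0, 0, 1, 1]]
    vt = _mat_to_vt(cols)
    stats = ps.transcript_stats(vt, {"tx0": 1000})
    row = stats.iloc[0]
    assert row["pi"] == pytest.approx(ps.site_pi(2, 2) / 1000)
    assert row["pi_per_10kb"] == pytest.approx(6.667, abs=1e-3)
    assert math.isnan(row["tajimas_d"]) is False  # S=1, n=4 -> defined
    # SNP density
    vt5 = _mat_to_vt([[0, 1, 0, 1]] * 5)
    dens = ps.transcript_stats(vt5, {"tx0": 2000}).iloc[0]
    assert dens["snps_per_kb"] == pytest.approx(2.5)
    # empty transcript
    empty = ps.transcript_stats(_mat_to_vt([[0, 1, 0, 1]]), {"tx0": 500, "other": 800})
    other = empty[empty["transcript"] == "other"].iloc[0]
    assert other["S"] == 0 and other["pi"] == 0 and math.isnan(other["tajimas_d"])


def test_long_transcripts_split_into_windows():
    cols = [[0, 0, 1, 1], [0, 1, 1, 1]]
    vt = _mat_to_vt(cols)
    vt.sites.loc[1, "pos"] = 12_000
    stats = ps.transcript_stats(vt, {"tx0": 15_000})
    assert len(stats) == 2
    assert stats.iloc[0]["S"] == 1 and stats.iloc[1]["S"] == 1
    assert stats.iloc[1]["length_bp"] == 5000


def test_zero_length_transcript_errors():
    with pytest.raises(ValueError):
        ps.transcript_stats(_mat_to_vt([[0, 1, 0, 1]]), {"tx0": 0})
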