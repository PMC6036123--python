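"""Block definition, EM phasing, frequency tables, and effect tests."""

import numpy as np
import pandas as pd
import pytest

from grammarqtl.data import GenotypeMatrix
from grammarqtl.haplotype import (
    EMPhaser,
    HaplotypeBlock,
    define_block,
    diplotype_test,
    haplotype_counts,
    haplotype_frequency_table,
    phase_block,
    retained_haplotypes,
    substitution_test,
)


def _geno_from_r2_chain(r2_targets, n=300, seed=0):
    """Adjacent-pair LD ladder: each next SNP copies the previous with noise."""
    rng = np.random.default_rng(seed)
    m = len(r2_targets) + 1
    codes = np.empty((n, m), dtype=np.int8)
    codes[:, 0] = rng.binomial(2, 0.5, n)
    for j, r2 in enumerate(r2_targets, start=1):
        keep = rng.random(n) < np.sqrt(max(r2, 0.0))
        codes[:, j] = np.where(keep, codes[:, j - 1], rng.binomial(2, 0.5, n))
    snps = pd.DataFrame(
        {
            "snp": [f"s{j}" for j in range(m)], "chrom": "1",
            "pos": np.arange(1, m + 1) * 1000, "allele1": "A", "allele2": "G",
        }
    )
    samples = pd.DataFrame(
        {"iid": [f"i{k}" for k in range(n)], "breed": "b", "sex": 1}
    )
    return GenotypeMatrix(codes, snps, samples)


def test_isolated_core_gives_single_snp_block():
    geno = _geno_from_r2_chain([0.0, 0.0, 0.0], seed=1)
    with pytest.warns(UserWarning, match="isolated"):
        block = define_block(geno, "s1")
    assert block == ["s1"]


def test_block_stops_at_low_r2_adjacency():
    """Chain r2 ~ (0.6, 0.6, 0.02): the block from the left end takes the
    first three SNPs and stops before the decorrelated one."""
    geno = _geno_from_r2_chain([0.6, 0.6, 0.02], n=800, seed=2)
    block = define_block(geno, "s0")
    assert block == ["s0", "s1", "s2"]


def test_block_capped_at_six():
    geno = _geno_from_r2_chain([0.9] * 9, n=500, seed=3)
    block = define_block(geno, "s4")
    assert len(block) == 6
    assert "s4" in block


# ---------------------------------------------------------------------------
# EM phasing
# ---------------------------------------------------------------------------

def test_fully_homozygous_individual_unique_diplotype():
    codes = np.array([[0, 2, 0], [2, 2, 2]])
    ph = EMPhaser(seed=0).fit(codes)
    assert np.allclose(ph.posterior_, 1.0)
    # haplotype bits follow the genotype directly
    h1 = ph.diplotypes_[0]
    assert h1[0] == h1[1] == 0b010


def test_unambiguous_data_matches_direct_counting():
    rng = np.random.default_rng(1)
    hap = rng.integers(0, 2, size=(40, 4))
    codes = 2 * hap  # everyone homozygous
    ph = EMPhaser(seed=0).fit(codes)
    counts = np.zeros(16)
    for row in hap:
        code = int(sum(b << j for j, b in enumerate(row)))
        counts[code] += 2
    np.testing.assert_allclose(ph.frequencies_, counts / counts.sum(), atol=1e-9)


def test_double_heterozygote_symmetric_solutions_reported():
    """All individuals het at both SNPs: two phase resolutions tie; both
    frequency vectors (0.5/0.5 on coupled vs repulsion pairs) are kept."""
    codes = np.ones((30, 2), dtype=int)
    ph = EMPhaser(seed=0, n_restarts=20).fit(codes)
    sols = [ph.frequencies_] + list(ph.alternative_frequencies_)
    assert len(sols) >= 2
    coupled = any(
        np.isclose(f[0b00], 0.5, atol=0.02) and np.isclose(f[0b11], 0.5, atol=0.02)
        for f in sols
    )
    repulsion = any(
        np.isclose(f[0b01], 0.5, atol=0.02) and np.isclose(f[0b10], 0.5, atol=0.02)
        for f in sols
    )
    assert coupled and repulsion


def test_em_frequency_recovery():
    haps = np.array([[0, 0, 1], [1, 1, 0], [0, 1, 1], [1, 0, 0]])
    freq = np.array([0.4, 0.4, 0.1, 0.1])
    rng = np.random.default_rng(7)
    pick = rng.choice(4, size=(1000, 2), p=freq)
    codes = haps[pick[:, 0]] + haps[pick[:, 1]]
    ph = EMPhaser(seed=3).fit(codes)
    for i, h in enumerate(haps):
        code = int(sum(b << j for j, b in enumerate(h)))
        assert abs(ph.frequencies_[code] - freq[i]) < 0.03


def test_em_deterministic_under_seed():
    rng = np.random.default_rng(9)
    codes = rng.integers(0, 3, size=(60, 4))
    a = EMPhaser(seed=5).fit(codes)
    b = EMPhaser(seed=5).fit(codes)
    np.testing.assert_array_equal(a.frequencies_, b.frequencies_)
    np.testing.assert_array_equal(a.diplotypes_, b.diplotypes_)


def test_em_rejects_wide_blocks():
    with pytest.raises(ValueError, match="6"):
        EMPhaser().fit(np.zeros((4, 7), dtype=int))


def test_diplotype_counts_conserved():
    rng = np.random.default_rng(11)
    codes = rng.integers(0, 3, size=(80, 3))
    ph = EMPhaser(seed=1).fit(codes)
    total = sum(
        haplotype_counts(ph.diplotypes_, h) for h in range(8)
    )
    assert (total == 2).all()


# ---------------------------------------------------------------------------
# frequency tables and retention
# ---------------------------------------------------------------------------

def test_frequency_table_sums_to_one_and_retention_rule():
    dip = np.array([[0, 0], [0, 1], [1, 1], [2, 2], [0, 0], [0, 0]])
    pops = np.array(["p1", "p1", "p1", "p2", "p2", "p2"])
    freqs = haplotype_frequency_table(dip, pops, 4)
    np.testing.assert_allclose(freqs.sum(axis=1), 1.0)
    # hap 2 present only in p2 at 1/3: retained (breed-private)
    assert 2 in retained_haplotypes(freqs, 0.05)
    # a haplotype under 5% everywhere is dropped
    assert 3 not in retained_haplotypes(freqs, 0.40)


# ---------------------------------------------------------------------------
# effect tests (constructed residuals exercise the regression contracts)
# ---------------------------------------------------------------------------

def _block_with_counts(counts, n_hap=4):
    n = len(counts)
    dip = np.zeros((n, 2), dtype=int)
    for i, c in enumerate(counts):
        dip[i] = {0: (1, 2), 1: (0, 1), 2: (0, 0)}[int(c)]
    return HaplotypeBlock(
        locus="L", member_snps=["s0", "s1"], core_snp="s0",
        hap_strings=["AA", "AG", "GA", "GG"],
        frequencies=pd.DataFrame({0: [0.5], 1: [0.3], 2: [0.2], 3: [0.0]}),
        diplotypes=dip, posterior=np.ones(n), tested_haplotypes=[0, 1],
    )


def test_substitution_effect_recovery_on_constructed_residuals():
    rng = np.random.default_rng(13)
    counts = rng.integers(0, 3, 400)
    block = _block_with_counts(counts)
    r = 10.0 * counts + rng.normal(0, 1, 400)
    mask = np.ones(400, dtype=bool)
    eff = substitution_test(block, 0, r, "BW5", n_tests=6, mask=mask)
    assert eff.testable
    assert abs(eff.effect - 10.0) < 2 * eff.se
    assert eff.significant


def test_substitution_not_testable_when_absent():
    counts = np.zeros(50, dtype=int)
    block = _block_with_counts(counts)
    r = np.random.default_rng(0).normal(size=50)
    eff = substitution_test(block, 3, r, "BW5", n_tests=6, mask=np.ones(50, bool))
    assert not eff.testable


def test_diplotype_contrast_recovery_and_min_carriers():
    rng = np.random.default_rng(15)
    counts = rng.integers(0, 3, 400)
    block = _block_with_counts(counts)
    hom = (counts == 2).astype(float)
    r = 50.0 * hom + rng.normal(0, 5, 400)
    eff = diplotype_test(block, 0, r, "BW5", n_tests=6, mask=np.ones(400, bool))
    assert abs(eff.effect - 50.0) < 2 * eff.se

    few = counts.copy()
    few[few == 2] = 1  # no homozygotes left
    block2 = _block_with_counts(few)
    eff2 = diplotype_test(block2, 0, r, "BW5", n_tests=6, mask=np.ones(400, bool))
    assert not eff2.testable


def test_opposite_direction_haplotypes_keep_signs():
    """Two haplotypes at one locus with opposing effects estimate with
    opposite signs (the BW_Q9-style configuration)."""
    rng = np.random.default_rng(17)
    n = 600
    pick = rng.choice(3, size=(n, 2), p=[0.4, 0.35, 0.25])
    dip = pick.copy()
    c0 = (dip == 0).sum(axis=1)
    c1 = (dip == 1).sum(axis=1)
    r = -30.0 * c0 + 60.0 * c1 + rng.normal(0, 5, n)
    block = HaplotypeBlock(
        locus="L", member_snps=["a", "b"], core_snp="a",
        hap_strings=["h0", "h1", "h2", "h3"],
        frequencies=pd.DataFrame({0: [0.4], 1: [0.35], 2: [0.25], 3: [0.0]}),
        diplotypes=dip, posterior=np.ones(n), tested_haplotypes=[0, 1],
    )
    mask = np.ones(n, dtype=bool)
    e0 = substitution_test(block, 0, r, "BW14", n_tests=6, mask=mask)
    e1 = substitution_test(block, 1, r, "BW14", n_tests=6, mask=mask)
    assert e0.effect < 0 < e1.effect


def test_phase_block_end_to_end(small_dataset):
    geno, _, _ = small_dataset
    core = geno.snps["snp"].iloc[10]
    block = phase_block(geno, core, locus="demo", seed=1)
    assert block.core_snp == core
    assert 1 <= len(block.member_snps) <= 6
    np.testing.assert_allclose(block.frequencies.sum(axis=1), 1.0, atol=1e-6)
    assert (block.posterior >= 0).all() and (block.posterior <= 1.0 + 1e-9).all()
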