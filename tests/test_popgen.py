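"""Diversity statistics against independent oracles and known identities."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaln

from grammarqtl.data import MISSING, GenotypeMatrix
from grammarqtl.popgen import (
    allele_freq_and_maf,
    diversity_summary,
    expected_het,
    hwe_exact,
    ibs_kinship,
    ld_decay,
    ld_r2,
    pca_structure,
    prune_independent,
)
from grammarqtl.simulate import simulate_genotypes

from conftest import small_config


# ---------------------------------------------------------------------------
# allele frequencies / He
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "codes,freq,maf",
    [
        ([0, 1, 2], 0.5, 0.5),
        ([0, 0, 0, 0], 0.0, 0.0),
        ([2, 2, 1, MISSING], 5 / 6, 1 / 6),
    ],
)
def test_allele_freq_examples(codes, freq, maf):
    out = allele_freq_and_maf(np.array(codes, dtype=np.int8).reshape(-1, 1))
    assert out["freq_allele2"].iloc[0] == pytest.approx(freq)
    assert out["maf"].iloc[0] == pytest.approx(maf)


def test_all_missing_snp_flagged():
    out = allele_freq_and_maf(np.full((4, 1), MISSING, dtype=np.int8))
    assert out["all_missing"].iloc[0]
    assert np.isnan(out["freq_allele2"].iloc[0])


@pytest.mark.parametrize(
    "freqs,expected",
    [([0.5, 0.5], 0.5), ([0.0, 0.0], 0.0), ([0.1, 0.3], np.mean([0.18, 0.42]))],
)
def test_expected_het(freqs, expected):
    assert expected_het(np.array(freqs)) == pytest.approx(expected)


def test_expected_het_empty_errors():
    with pytest.raises(ValueError):
        expected_het(np.array([]))


# ---------------------------------------------------------------------------
# HWE exact test vs full enumeration
# ---------------------------------------------------------------------------

def _hwe_enumeration(n_hom1, n_het, n_hom2):
    """Independent oracle: enumerate every table with the same allele counts."""
    n = n_hom1 + n_het + n_hom2
    na = 2 * n_hom1 + n_het
    nb = 2 * n_hom2 + n_het
    if na == 0 or nb == 0:
        return 1.0
    probs = {}
    for het in range(min(na, nb) + 1):
        if (na - het) % 2:
            continue
        h1 = (na - het) // 2
        h2 = (nb - het) // 2
        if h1 < 0 or h2 < 0 or h1 + h2 + het != n:
            continue
        logp = (
            gammaln(n + 1) - gammaln(h1 + 1) - gammaln(het + 1) - gammaln(h2 + 1)
            + het * np.log(2.0)
            + gammaln(na + 1) + gammaln(nb + 1) - gammaln(2 * n + 1)
        )
        probs[het] = np.exp(logp)
    p_obs = probs[n_het]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12)))


@pytest.mark.parametrize(
    "table,expected",
    [((100, 0, 0), 1.0), ((25, 50, 25), 1.0)],
)
def test_hwe_known_values(table, expected):
    assert hwe_exact(*table) == pytest.approx(expected)


def test_hwe_extreme_het_deficit():
    assert hwe_exact(50, 0, 50) < 1e-10


@settings(max_examples=200, deadline=None)
@given(
    st.integers(min_value=0, max_value=50),
    st.integers(min_value=0, max_value=50),
    st.integers(min_value=0, max_value=50),
)
def test_hwe_matches_enumeration(h1, het, h2):
    if h1 + het + h2 == 0:
        return
    assert hwe_exact(h1, het, h2) == pytest.approx(
        _hwe_enumeration(h1, het, h2), rel=1e-10
    )


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def test_ld_r2_identity_and_flip():
    rng = np.random.default_rng(1)
    g = rng.integers(0, 3, 100).astype(float)
    assert ld_r2(g, g) == pytest.approx(1.0)
    assert ld_r2(g, 2 - g) == pytest.approx(1.0)


def test_ld_r2_independent_snps_near_zero():
    rng = np.random.default_rng(2)
    vals = [
        ld_r2(rng.binomial(2, 0.5, 1000), rng.binomial(2, 0.5, 1000))
        for _ in range(20)
    ]
    assert np.mean(vals) < 0.01


def test_ld_r2_monomorphic_is_nan():
    assert np.isnan(ld_r2(np.zeros(10), np.arange(10) % 3))


def _brute_force_greedy(r2, pos, r2_max=0.2, window=10**9):
    kept = []
    for j in range(len(pos)):
        if all(
            r2[j, k] < r2_max or np.isnan(r2[j, k]) or pos[j] - pos[k] > window
            for k in kept
        ):
            kept.append(j)
    return kept


def test_prune_matches_brute_force():
    rng = np.random.default_rng(5)
    n, m = 80, 10
    base = rng.binomial(2, 0.4, n)
    codes = np.empty((n, m), dtype=np.int8)
    for j in range(m):  # correlated ladder of markers
        flip = rng.random(n) < 0.15 * (j % 4 + 1)
        base = np.where(flip, rng.binomial(2, 0.4, n), base)
        codes[:, j] = base
    snps = pd.DataFrame(
        {
            "snp": [f"s{j}" for j in range(m)], "chrom": "1",
            "pos": np.arange(1, m + 1) * 1000, "allele1": "A", "allele2": "G",
        }
    )
    samples = pd.DataFrame(
        {"iid": [f"i{k}" for k in range(n)], "breed": "b", "sex": 1}
    )
    geno = GenotypeMatrix(codes, snps, samples)
    r2 = np.array(
        [[ld_r2(codes[:, a], codes[:, b]) for b in range(m)] for a in range(m)]
    )
    expect = [f"s{j}" for j in _brute_force_greedy(r2, snps["pos"].to_numpy())]
    assert prune_independent(geno) == expect
    # post-hoc: no retained pair in LD
    kept_idx = [int(s[1:]) for s in expect]
    for a, b in itertools.combinations(kept_idx, 2):
        assert not r2[a, b] >= 0.2


def test_prune_extremes(tiny_geno):
    n = 50
    codes = np.tile(np.random.default_rng(0).integers(0, 3, (n, 1)), (1, 4)).astype(np.int8)
    geno = GenotypeMatrix(codes, tiny_geno.snps, pd.DataFrame(
        {"iid": [f"i{k}" for k in range(n)], "breed": "b", "sex": 1}))
    # all pairwise r2 = 1 -> first SNP kept per chromosome
    assert prune_independent(geno) == ["s1", "s3"]


def test_ld_decay_ordering_and_no_crossing():
    """Short-decay pools cross 0.2 before long-decay pools; zero
    recombination never crosses."""
    crossings = {}
    for rate, key in ((2e-4, "short"), (5e-6, "long")):
        vals = []
        for seed in range(10):
            cfg = small_config(
                seed=seed, n_breeds=1, n_per_breed=80, n_snps=200,
                n_chromosomes=1, ld_pool_size=4, recomb_rate=rate,
                fst_per_breed=(0.1,), snp_spacing_bp=2000,
            )
            geno, _ = simulate_genotypes(cfg)
            _, L = ld_decay(geno, bin_width_bp=2000, max_dist_bp=100_000)
            vals.append(L)
        crossings[key] = np.nanmean([v for v in vals if np.isfinite(v)])
    assert crossings["short"] < crossings["long"]

    cfg = small_config(
        seed=0, n_breeds=1, n_per_breed=60, n_snps=100, n_chromosomes=1,
        ld_pool_size=2, recomb_rate=0.0, fst_per_breed=(0.1,),
        pool_weight_alpha=None,
    )
    geno, _ = simulate_genotypes(cfg)
    curve, L = ld_decay(geno, bin_width_bp=20_000, max_dist_bp=200_000)
    assert np.isinf(L)


# ---------------------------------------------------------------------------
# kinship and PCA
# ---------------------------------------------------------------------------

def test_ibs_kinship_brute_force(tiny_geno):
    K = ibs_kinship(tiny_geno)
    codes = tiny_geno.codes
    for i in range(3):
        for j in range(3):
            expect = np.mean([(2 - abs(codes[i, s] - codes[j, s])) / 2 for s in range(4)])
            assert K[i, j] == pytest.approx(expect)
    assert np.allclose(np.diag(K), 1.0)


def test_ibs_kinship_extremes():
    codes = np.array([[0, 0, 0], [2, 2, 2]], dtype=np.int8)
    snps = pd.DataFrame(
        {"snp": ["a", "b", "c"], "chrom": "1", "pos": [1, 2, 3],
         "allele1": "A", "allele2": "G"}
    )
    samples = pd.DataFrame({"iid": ["x", "y"], "breed": "b", "sex": 1})
    K = ibs_kinship(GenotypeMatrix(codes, snps, samples))
    assert K[0, 1] == pytest.approx(0.0)
    assert K[0, 0] == pytest.approx(1.0)


def test_ibs_invariant_to_snp_order_and_allele_swap(small_dataset):
    geno, _, _ = small_dataset
    sub = geno.take_snps(np.arange(100))
    K1 = ibs_kinship(sub)
    perm = np.random.default_rng(0).permutation(100)
    K2 = ibs_kinship(sub.take_snps(perm))
    np.testing.assert_allclose(K1, K2, atol=1e-12)
    flipped = sub.codes.copy()
    flipped[flipped >= 0] = 2 - flipped[flipped >= 0]
    K3 = ibs_kinship(GenotypeMatrix(flipped, sub.snps, sub.samples))
    np.testing.assert_allclose(K1, K3, atol=1e-12)


def test_pca_two_block_matrix_separates():
    n = 40
    K = np.full((n, n), 0.1)
    K[:20, :20] = 0.9
    K[20:, 20:] = 0.9
    np.fill_diagonal(K, 1.0)
    coords, vals = pca_structure(K, 2)
    assert (coords[:20, 0] > 0).all() != (coords[20:, 0] > 0).all()
    assert np.sign(coords[:20, 0]).std() == 0 and np.sign(coords[20:, 0]).std() == 0


def test_pca_breed_clusters_silhouette(small_dataset):
    from sklearn.metrics import silhouette_score

    geno, _, _ = small_dataset
    coords, _ = pca_structure(ibs_kinship(geno), 3)
    score = silhouette_score(coords, geno.samples["breed"])
    assert score > 0.5


def test_pca_rejects_nonfinite():
    K = np.eye(3)
    K[0, 1] = np.nan
    with pytest.raises(ValueError):
        pca_structure(K)


# ---------------------------------------------------------------------------
# summary table
# ---------------------------------------------------------------------------

def test_diversity_summary_shapes(small_dataset):
    geno, _, _ = small_dataset
    rows = diversity_summary(geno.take_snps(np.arange(150)))
    assert len(rows) == 4
    for r in rows:
        assert 0 <= r.p_poly <= 1
        assert 0 <= r.p_hw <= 1
        assert 0 <= r.mean_he <= 0.5
        assert r.n_independent >= 1
        assert (r.ld_curve["mean_r2"].dropna() >= 0).all()
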