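"""Genome scan, permutation thresholds, conditioning, QTL naming, Var%."""

import numpy as np
import pandas as pd
import pytest

from grammarqtl.data import build_design
from grammarqtl.mixedmodel import PolygenicModel
from grammarqtl.popgen import ibs_kinship, ld_r2
from grammarqtl.scan import (
    cluster_and_name,
    conditional_independence,
    permutation_thresholds,
    scan_trait,
    variance_explained,
)
from grammarqtl.simulate import QTLSpec, SimConfig, simulate_dataset

from conftest import small_config


@pytest.fixture(scope="module")
def planted():
    cfg = small_config(seed=21, n_per_breed=100, n_snps=800)
    geno, _, _ = simulate_dataset(cfg)
    maf = geno.codes.mean(axis=0) / 2
    ok = (maf > 0.25) & (maf < 0.45) & (geno.snps["chrom"] != "Z").to_numpy()
    j = int(np.flatnonzero(ok)[5])
    cfg2 = SimConfig(**{**cfg.__dict__, "qtl_spec": (QTLSpec(snp=j, effect=50.0),)})
    geno, pheno, _ = simulate_dataset(cfg2)
    K = ibs_kinship(geno)
    design = build_design(geno.samples, birth_weight=pheno.trait("BW0"))
    fit = PolygenicModel().fit(pheno.trait("BW8"), design, K)
    return geno, pheno, design, K, fit, j


def test_planted_qtl_is_top_hit(planted):
    geno, _, _, _, fit, j = planted
    hits = 0
    for seed in range(21, 31):
        cfg = small_config(seed=seed, n_per_breed=100, n_snps=800)
        geno, _, _ = simulate_dataset(cfg)
        maf = geno.codes.mean(axis=0) / 2
        ok = (maf > 0.25) & (maf < 0.45) & (geno.snps["chrom"] != "Z").to_numpy()
        jj = int(np.flatnonzero(ok)[5])
        cfg2 = SimConfig(**{**cfg.__dict__, "qtl_spec": (QTLSpec(snp=jj, effect=50.0),)})
        geno, pheno, _ = simulate_dataset(cfg2)
        K = ibs_kinship(geno)
        design = build_design(geno.samples, birth_weight=pheno.trait("BW0"))
        fit = PolygenicModel().fit(pheno.trait("BW8"), design, K)
        res = scan_trait(geno, fit, "BW8")
        best = int(np.nanargmin(res.table["p_raw"].to_numpy(dtype=float)))
        r2 = ld_r2(geno.codes[:, best], geno.codes[:, jj])
        hits += int(best == jj or (np.isfinite(r2) and r2 > 0.8))
    assert hits >= 9


def test_scan_invariant_to_snp_order(planted):
    geno, _, _, _, fit, _ = planted
    res = scan_trait(geno, fit, "BW8")
    perm = np.random.default_rng(0).permutation(geno.n_snps)
    res2 = scan_trait(geno.take_snps(perm), fit, "BW8")
    merged = res.table.set_index("snp").loc[res2.table["snp"]]
    np.testing.assert_allclose(
        merged["stat"].to_numpy(), res2.table["stat"].to_numpy(), rtol=1e-10
    )


def test_threshold_order_and_determinism(planted):
    geno, _, _, _, fit, _ = planted
    thr1 = permutation_thresholds(geno, fit, n_perm=150, seed=5)
    thr2 = permutation_thresholds(geno, fit, n_perm=150, seed=5)
    assert thr1 == thr2
    assert thr1[0.01] >= thr1[0.05]


def test_threshold_warns_below_100_perms(planted):
    geno, _, _, _, fit, _ = planted
    with pytest.warns(UserWarning, match="permutations"):
        permutation_thresholds(geno, fit, n_perm=50, seed=1)


def test_shuffled_phenotype_behaves_like_null(planted):
    """Destroying the genotype-phenotype link removes the planted signal."""
    geno, pheno, design, K, _, j = planted
    rng = np.random.default_rng(3)
    y = pheno.trait("BW8").copy()
    rng.shuffle(y)
    fit = PolygenicModel().fit(y, design, K)
    res = scan_trait(geno, fit, "BW8")
    thr = permutation_thresholds(geno, fit, n_perm=150, seed=2)
    logp = -np.log10(res.table["p_gc"].to_numpy(dtype=float))
    assert np.nanmax(logp) < thr[0.01] + 1.0


# ---------------------------------------------------------------------------
# conditional independence
# ---------------------------------------------------------------------------

def test_perfect_ld_pair_collapses_to_one_core(planted):
    geno, pheno, design, K, fit, j = planted
    # duplicate the planted SNP as a perfect proxy on the same chromosome
    dup = geno.codes.copy()
    k = j + 1
    dup[:, k] = dup[:, j]
    geno2 = type(geno)(dup, geno.snps, geno.samples)
    ids = [geno.snps["snp"].iloc[j], geno.snps["snp"].iloc[k]]
    core = conditional_independence(
        geno2, pheno.trait("BW8"), design, K, ids, threshold_logp=3.0
    )
    assert len(core) == 1


def test_single_snp_returned_unchanged(planted):
    geno, pheno, design, K, _, j = planted
    ids = [geno.snps["snp"].iloc[j]]
    assert conditional_independence(
        geno, pheno.trait("BW8"), design, K, ids, threshold_logp=3.0
    ) == ids


def test_two_unlinked_causal_snps_both_retained():
    kept = []
    for seed in range(40, 48):
        cfg = small_config(seed=seed, n_per_breed=100, n_snps=600, n_chromosomes=2)
        geno, _, _ = simulate_dataset(cfg)
        maf = geno.codes.mean(axis=0) / 2
        chrom1 = (geno.snps["chrom"] == "1").to_numpy()
        ok = (maf > 0.3) & (maf < 0.5) & chrom1
        idx = np.flatnonzero(ok)
        j1, j2 = int(idx[2]), int(idx[-3])  # far apart on one chromosome
        r2 = ld_r2(geno.codes[:, j1], geno.codes[:, j2])
        if np.isfinite(r2) and r2 > 0.05:
            continue
        cfg2 = SimConfig(**{
            **cfg.__dict__,
            "qtl_spec": (QTLSpec(snp=j1, effect=50.0), QTLSpec(snp=j2, effect=50.0)),
        })
        geno, pheno, _ = simulate_dataset(cfg2)
        K = ibs_kinship(geno)
        design = build_design(geno.samples, birth_weight=pheno.trait("BW0"))
        ids = [geno.snps["snp"].iloc[j1], geno.snps["snp"].iloc[j2]]
        core = conditional_independence(
            geno, pheno.trait("BW8"), design, K, ids, threshold_logp=3.0
        )
        kept.append(len(core) == 2)
    assert np.mean(kept) >= 0.8


def test_conditional_cores_not_in_high_ld(planted):
    geno, pheno, design, K, fit, j = planted
    res = scan_trait(geno, fit, "BW8")
    chrom = geno.snps["chrom"].iloc[j]
    on_chrom = res.table[res.table["chr"] == chrom]
    sig = on_chrom.nsmallest(4, "p_raw")["snp"].tolist()
    core = conditional_independence(
        geno, pheno.trait("BW8"), design, K, sig, threshold_logp=2.0
    )
    for a in range(len(core)):
        for b in range(a + 1, len(core)):
            r2 = ld_r2(
                geno.codes[:, geno.snp_index(core[a])],
                geno.codes[:, geno.snp_index(core[b])],
            )
            assert not (np.isfinite(r2) and r2 > 0.95)


# ---------------------------------------------------------------------------
# clustering / naming / Var%
# ---------------------------------------------------------------------------

def _hits(rows):
    return pd.DataFrame(
        rows, columns=["snp", "chr", "pos", "trait", "tier", "var_percent"]
    )


def test_nearby_core_snps_merge_into_one_qtl():
    hits = _hits([
        ("a", "9", 18_601_322, "BW15", "5%", 1.3),
        ("b", "9", 18_643_628, "BW14", "5%", 1.4),
    ])
    qtls = cluster_and_name(hits)
    assert len(qtls) == 1
    assert qtls[0].name == "BW_Q9"
    assert qtls[0].core_snps == ["a", "b"]
    assert set(qtls[0].traits) == {"BW15", "BW14"}


def test_single_trait_qtl_dropped_without_external_support():
    hits = _hits([("a", "3", 1000, "BW9", "5%", 1.0)])
    assert cluster_and_name(hits) == []
    external = pd.DataFrame({"snp": ["x"], "chr": ["3"], "pos": [500_000], "p": [1e-8]})
    qtls = cluster_and_name(hits, external=external)
    assert len(qtls) == 1 and qtls[0].external_support


def test_two_qtls_one_chromosome_get_letters():
    hits = _hits([
        ("a", "2", 1_000_000, "BW4", "5%", 1.0),
        ("a", "2", 1_000_000, "BW6", "1%", 1.3),
        ("b", "2", 9_000_000, "BW8", "5%", 1.1),
        ("b", "2", 9_000_000, "BW9", "5%", 1.1),
    ])
    qtls = cluster_and_name(hits)
    assert [q.name for q in qtls] == ["BW_Q2a", "BW_Q2b"]


@pytest.mark.parametrize(
    "p,a,var_y,expected",
    [(0.5, 1.0, 50.0, 1.0), (0.3, 0.0, 50.0, 0.0)],
)
def test_variance_explained_examples(p, a, var_y, expected):
    assert variance_explained(p, 1 - p, a, var_y) == pytest.approx(expected)


def test_variance_explained_symmetric_and_errors():
    assert variance_explained(0.3, 0.7, 2.0, 10.0) == pytest.approx(
        variance_explained(0.7, 0.3, 2.0, 10.0)
    )
    with pytest.raises(ValueError):
        variance_explained(0.5, 0.5, 1.0, 0.0)
    with pytest.raises(ValueError):
        variance_explained(0.5, 0.6, 1.0, 1.0)
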