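"""Desk-scale benchmark routines: calibration, recovery, and error rates.

Each function simulates data under stated conditions, runs the relevant
pipeline stage end to end, and returns measured quantities.  They power both
the test suite and the reproduction script; problem sizes are scaled to a
single CPU (genomes of a few thousand markers, hundreds of birds) while
keeping the statistical structure of the full design.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .data import build_design
from .haplotype import EMPhaser, phase_block, substitution_test
from .mixedmodel import PolygenicModel
from .popgen import ibs_kinship, ld_r2
from .qc import genotype_qc
from .scan import permutation_thresholds, scan_trait
from .simulate import EpiSpec, QTLSpec, SimConfig, VQTLSpec, simulate_dataset
from .varepi import EpistasisScan, VarianceScan


def _study(seed: int, **overrides) -> SimConfig:
    base = dict(
        n_snps=2000,
        n_chromosomes=10,
        n_per_breed=100,
        heritability=0.3,
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


def _fit_trait(geno, pheno, trait: str, method: str = "mmscore"):
    K = ibs_kinship(geno)
    design = build_design(geno.samples, birth_weight=pheno.trait("BW0"))
    fit = PolygenicModel(method=method).fit(pheno.trait(trait), design, K)
    return fit, design, K


def _pick_snp(geno, maf_range=(0.25, 0.35), chrom_not=("Z",), rng=None):
    """An autosomal SNP with pooled MAF inside the requested range."""
    g = geno.codes.astype(float)
    g[g < 0] = np.nan
    freq = np.nanmean(g, axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    ok = (
        (maf >= maf_range[0])
        & (maf <= maf_range[1])
        & ~geno.snps["chrom"].isin(chrom_not).to_numpy()
    )
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        raise RuntimeError("no SNP in the requested MAF range")
    if rng is None:
        return int(idx[idx.size // 2])
    return int(rng.choice(idx))


# ---------------------------------------------------------------------------
# calibration of the null scan
# ---------------------------------------------------------------------------

def null_calibration(
    seed: int, n_snps: int = 5000, n_per_breed: int = 100,
    heritability: float = 0.3, trait: str = "BW8",
) -> dict:
    """Lambda and p-value uniformity of a GRAMMAR scan on null data."""
    cfg = _study(seed, n_snps=n_snps, n_per_breed=n_per_breed,
                 heritability=heritability)
    geno, pheno, _ = simulate_dataset(cfg)
    geno, _ = genotype_qc(geno)
    fit, _, _ = _fit_trait(geno, pheno, trait)
    res = scan_trait(geno, fit, trait)
    p = res.table["p_raw"].to_numpy(dtype=float)
    p = p[np.isfinite(p)]
    ks = float(stats.kstest(p, "uniform").statistic)
    return {
        "lambda": float(res.lambda_gc),
        "ks_distance": ks,
        "h2_reml": float(fit.h2_),
        "n_snps_tested": int(p.size),
        "n": geno.n_samples,
    }


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------

def qtl_recovery(seed: int, effect: float = 20.0, n_seeds: int = 10,
                 trait: str = "BW8") -> dict:
    """Plant an additive QTL (MAF ~ 0.3) and recover its effect by scanning."""
    effects, ses, top_hit = [], [], 0
    for s in range(n_seeds):
        cfg = _study(seed + s)
        geno, _, _ = simulate_dataset(cfg)
        j = _pick_snp(geno)
        cfg2 = _study(seed + s, qtl_spec=(QTLSpec(snp=j, effect=effect),))
        geno, pheno, _ = simulate_dataset(cfg2)
        fit, _, _ = _fit_trait(geno, pheno, trait)
        res = scan_trait(geno, fit, trait)
        effects.append(float(res.table["effect"].iloc[j]))
        ses.append(float(res.table["se"].iloc[j]))
        best = int(np.nanargmin(res.table["p_raw"].to_numpy(dtype=float)))
        r2 = ld_r2(geno.codes[:, best], geno.codes[:, j])
        top_hit += int(best == j or (np.isfinite(r2) and r2 > 0.8))
    effects_arr, ses_arr = np.asarray(effects), np.asarray(ses)
    return {
        "effect_true": effect,
        "effect_mean": float(np.mean(effects)),
        "se_mean": float(np.mean(ses)),
        "z_of_mean": float(
            abs(np.mean(effects) - effect) / (np.mean(ses) / np.sqrt(n_seeds))
        ),
        "within_2se_rate": float(
            np.mean(np.abs(effects_arr - effect) <= 2 * ses_arr)
        ),
        "top_hit_rate": top_hit / n_seeds,
        "n_seeds": n_seeds,
    }


def h2_recovery(seed: int, n_seeds: int = 10, heritability: float = 0.3,
                trait: str = "BW8") -> dict:
    """REML heritability estimates against the simulator's realized values."""
    est, real = [], []
    for s in range(n_seeds):
        cfg = _study(seed + s, heritability=heritability)
        geno, pheno, truth = simulate_dataset(cfg)
        fit, _, _ = _fit_trait(geno, pheno, trait)
        est.append(fit.h2_)
        real.append(truth.realized_h2[trait])
    return {
        "h2_target": heritability,
        "h2_realized_mean": float(np.mean(real)),
        "h2_reml_mean": float(np.mean(est)),
        "abs_error": float(abs(np.mean(est) - np.mean(real))),
        "n_seeds": n_seeds,
    }


def em_phasing_recovery(seed: int, n: int = 1000, n_seeds: int = 10) -> dict:
    """EM frequency recovery on 3-SNP blocks drawn from a 4-haplotype pool."""
    haps = np.array([[0, 0, 1], [1, 1, 0], [0, 1, 1], [1, 0, 0]])
    freq = np.array([0.4, 0.4, 0.1, 0.1])
    errs = []
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + s)
        pick = rng.choice(4, size=(n, 2), p=freq)
        codes = haps[pick[:, 0]] + haps[pick[:, 1]]
        ph = EMPhaser(seed=seed + s).fit(codes)
        est = np.zeros(4)
        for i, h in enumerate(haps):
            code = int(sum(b << j for j, b in enumerate(h)))
            est[i] = ph.frequencies_[code]
        errs.append(np.abs(est - freq).max())
    return {
        "max_abs_error_mean": float(np.mean(errs)),
        "max_abs_error_worst": float(np.max(errs)),
        "n": n,
        "n_seeds": n_seeds,
    }


def haplotype_recovery(seed: int, effect: float = 10.0, n_seeds: int = 10,
                       trait: str = "BW1") -> dict:
    """Plant an additive effect on a core SNP carried by a single pool
    haplotype and recover it as a haplotype-substitution effect."""
    effects, ses = [], []
    s = 0
    tried = 0
    while len(effects) < n_seeds and tried < 4 * n_seeds:
        tried += 1
        cfg = _study(
            seed + s, n_breeds=1, n_per_breed=400, n_snps=400, n_chromosomes=2,
            ld_pool_size=4, recomb_rate=2e-6, fst_per_breed=(0.1,),
        )
        s += 1
        geno, _, truth = simulate_dataset(cfg)
        pool = truth.pools["breed1"]
        # a core SNP whose alternate allele rides on exactly one founder
        # haplotype, segregating at intermediate frequency
        g = geno.codes.astype(float)
        freq = np.nanmean(np.where(g < 0, np.nan, g), axis=0) / 2
        cand = np.flatnonzero(
            (pool.sum(axis=0) == 1) & (freq > 0.15) & (freq < 0.5)
            & (geno.snps["chrom"] != "Z").to_numpy()
        )
        if cand.size == 0:
            continue
        j = int(cand[cand.size // 2])
        cfg2 = SimConfig(**{**cfg.__dict__, "qtl_spec": (QTLSpec(snp=j, effect=effect),)})
        geno, pheno, _ = simulate_dataset(cfg2)
        fit, _, _ = _fit_trait(geno, pheno, trait)
        block = phase_block(geno, geno.snps["snp"].iloc[j], seed=seed + s)
        core_pos = block.member_snps.index(block.core_snp)
        carriers = [
            h for h in block.tested_haplotypes if (h >> core_pos) & 1
        ]
        if len(carriers) != 1:
            continue
        res = substitution_test(block, carriers[0], fit, trait, 1)
        if not res.testable:
            continue
        effects.append(res.effect)
        ses.append(res.se)
    effects_arr, ses_arr = np.asarray(effects), np.asarray(ses)
    return {
        "effect_true": effect,
        "effect_mean": float(np.mean(effects)),
        "se_mean": float(np.mean(ses)),
        "z_of_mean": float(
            abs(np.mean(effects) - effect)
            / (np.mean(ses) / np.sqrt(len(effects)))
        ),
        "within_2se_rate": float(
            np.mean(np.abs(effects_arr - effect) <= 2 * ses_arr)
        ),
        "n_runs": len(effects),
    }


# ---------------------------------------------------------------------------
# family-wise error of the permutation threshold
# ---------------------------------------------------------------------------

def fwer_calibration(
    seed: int,
    n_replicates: int = 200,
    n_perm: int = 200,
    n_snps: int = 2000,
    level: float = 0.05,
    trait: str = "BW8",
) -> dict:
    """Fraction of null scans with any marker past their own 5% threshold."""
    hits = 0
    for rep in range(n_replicates):
        cfg = _study(seed + 100_000 + rep, n_snps=n_snps)
        geno, pheno, _ = simulate_dataset(cfg)
        fit, _, _ = _fit_trait(geno, pheno, trait)
        thr = permutation_thresholds(
            geno, fit, n_perm=n_perm, levels=(level,), seed=seed + rep
        )
        res = scan_trait(geno, fit, trait)
        logp = -np.log10(res.table["p_gc"].to_numpy(dtype=float))
        hits += int(np.nanmax(logp) >= thr[level])
    return {
        "fwer": hits / n_replicates,
        "nominal": level,
        "n_replicates": n_replicates,
        "n_perm": n_perm,
        "n_snps": n_snps,
    }


# ---------------------------------------------------------------------------
# vGWAS power and specificity
# ---------------------------------------------------------------------------

def vgwas_power(seed: int, n_seeds: int = 10, sd_mult: float = 1.5,
                trait: str = "BW8") -> dict:
    """A planted variance-QTL should top the vGWAS; an additive QTL should not
    cross the 1% threshold of the squared-transform scan."""
    top = 0
    for s in range(n_seeds):
        cfg = _study(seed + s)
        geno, _, _ = simulate_dataset(cfg)
        j = _pick_snp(geno, maf_range=(0.3, 0.5))
        cfg2 = _study(
            seed + s,
            vqtl_spec=VQTLSpec(snp=j, sd_multipliers=(1.0, sd_mult, sd_mult ** 2)),
        )
        geno, pheno, _ = simulate_dataset(cfg2)
        K = ibs_kinship(geno)
        design = build_design(geno.samples, birth_weight=pheno.trait("BW0"))
        vs = VarianceScan().fit(geno, pheno.trait(trait), design, K, trait=trait)
        p = vs.result_.table["p_raw"].to_numpy(dtype=float)
        best = int(np.nanargmin(p))
        r2 = ld_r2(geno.codes[:, best], geno.codes[:, j])
        top += int(best == j or (np.isfinite(r2) and r2 > 0.8))

    flagged = 0
    for s in range(n_seeds):
        cfg = _study(seed + 50_000 + s)
        geno, _, _ = simulate_dataset(cfg)
        j = _pick_snp(geno)
        cfg2 = _study(seed + 50_000 + s, qtl_spec=(QTLSpec(snp=j, effect=20.0),))
        geno, pheno, _ = simulate_dataset(cfg2)
        K = ibs_kinship(geno)
        design = build_design(geno.samples, birth_weight=pheno.trait("BW0"))
        vs = VarianceScan().fit(geno, pheno.trait(trait), design, K, trait=trait)
        thr = permutation_thresholds(
            geno, vs.model_, n_perm=200, levels=(0.01,), seed=seed + s
        )
        logp = -np.log10(vs.result_.table["p_gc"].to_numpy(dtype=float))
        flagged += int(np.nanmax(logp) >= thr[0.01])
    return {
        "vqtl_top_rate": top / n_seeds,
        "additive_flag_rate": flagged / n_seeds,
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# epistasis recovery
# ---------------------------------------------------------------------------

def epistasis_recovery(seed: int, effect: float = 15.0, n_seeds: int = 10,
                       n_perm: int = 200, trait: str = "BW1") -> dict:
    """A planted interaction pair should reach the 5% tier of the per-target
    permutation null when scanning from one of its members."""
    found = 0
    for s in range(n_seeds):
        cfg = _study(seed + s)
        geno, _, _ = simulate_dataset(cfg)
        rng = np.random.default_rng(seed + s)
        j1 = _pick_snp(geno, maf_range=(0.4, 0.5), rng=rng)
        c1 = geno.snps["chrom"].iloc[j1]
        g = geno.codes.astype(float)
        freq = np.nanmean(np.where(g < 0, np.nan, g), axis=0) / 2
        maf = np.minimum(freq, 1 - freq)
        other = np.flatnonzero(
            (maf >= 0.4) & (geno.snps["chrom"] != c1).to_numpy()
            & (geno.snps["chrom"] != "Z").to_numpy()
        )
        j2 = int(other[other.size // 2])
        cfg2 = _study(seed + s, epi_spec=EpiSpec(snp1=j1, snp2=j2, effect=effect))
        geno, pheno, _ = simulate_dataset(cfg2)
        fit, _, _ = _fit_trait(geno, pheno, trait)
        es = EpistasisScan(n_perm=n_perm, seed=seed + s).fit(
            geno, fit, [geno.snps["snp"].iloc[j1]], trait=trait
        )
        target_id = geno.snps["snp"].iloc[j2]
        hit = es.table_[
            (es.table_["partner"] == target_id)
            & (es.table_["tier"] == "5% significant")
        ]
        found += int(len(hit) > 0)
    return {"recovery_rate": found / n_seeds, "n_seeds": n_seeds,
            "effect": effect, "n_perm": n_perm}


# ---------------------------------------------------------------------------
# real-data reproduction (requires the study's own genotype/phenotype tables)
# ---------------------------------------------------------------------------

def study_data_reproduction(prefix, pheno_csv, n_perm: int = 1000, seed: int = 0):
    """Rerun diversity and scan stages on the study's own data files.

    Expects a PLINK ped/map fileset and the phenotype CSV (id, breed, sex,
    BW0..BW15).  Returns per-breed diversity summaries (polymorphic fraction,
    LD-decay scale) and the per-trait scan tables needed to rebuild the QTL
    and haplotype-effect tables.  The study's datasets ship only as journal
    supplementary sheets with no public accession, so this can run only when
    the caller has downloaded them.
    """
    from pathlib import Path

    from . import io as gio
    from .qc import genotype_qc, phenotype_outlier_screen

    prefix = Path(prefix)
    if not prefix.with_suffix(".ped").exists():
        raise FileNotFoundError(
            f"study genotype fileset not found at {prefix} (journal "
            "supplementary data; no public accession)"
        )
    geno = gio.read_plink(prefix, dialect="ped_map")
    pheno, _ = gio.read_phenotypes(pheno_csv)
    pheno, _ = phenotype_outlier_screen(pheno, geno.samples["breed"])
    keep = geno.samples["iid"].isin(pheno.ids).to_numpy()
    geno, _ = genotype_qc(geno.take_samples(np.flatnonzero(keep)))
    from .popgen import diversity_summary

    diversity = diversity_summary(geno)
    K = ibs_kinship(geno)
    design = build_design(geno.samples, birth_weight=pheno.trait("BW0"))
    scans = {}
    for lab in pheno.week_labels:
        fit = PolygenicModel().fit(pheno.trait(lab), design, K)
        res = scan_trait(geno, fit, lab)
        res.thresholds = permutation_thresholds(
            geno, fit, n_perm=n_perm, seed=seed
        )
        scans[lab] = res
    return diversity, scans
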