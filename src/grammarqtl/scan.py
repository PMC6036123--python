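"""Genome-wide single-marker scans with permutation thresholds, conditional
QTL resolution, QTL clustering/naming, and per-SNP variance explained.

The scan regresses GRAMMAR residuals on every QC'd marker, applies the
genomic-control correction per trait, and screens significance against
empirical genome-wide thresholds from the maximum -log10(p) distribution of
within-breed residual permutations.  Significant markers sharing a
chromosome are resolved into conditionally independent core SNPs by forward
covariate conditioning; core SNPs within a merge window collapse into named
QTLs (BW_Q + chromosome, letters when several share a chromosome).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import FixedEffectDesign, GenotypeMatrix
from .mixedmodel import (
    PolygenicModel,
    genomic_lambda,
    grammar_scan_matrix,
    _prepare_marker,
)


@dataclass
class ScanResult:
    trait: str
    table: pd.DataFrame              # snp, chr, pos, trait, effect, se, stat, p_raw, p_gc
    lambda_gc: float
    thresholds: dict[float, float] = field(default_factory=dict)  # level -> -log10 p

    def significant(self, level: float = 0.05) -> pd.DataFrame:
        thr = self.thresholds[level]
        logp = -np.log10(self.table["p_gc"].to_numpy(dtype=float))
        return self.table[logp >= thr]


@dataclass
class QTL:
    name: str
    chrom: str
    core_snps: list[str]
    traits: dict[str, str]           # trait -> tier ("1%" or "5%")
    var_percent: dict[str, float] = field(default_factory=dict)
    external_support: bool = False


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def scan_trait(
    geno: GenotypeMatrix, fit: PolygenicModel, trait: str = ""
) -> ScanResult:
    """GRAMMAR scan of one trait across all markers, with lambda correction."""
    X = geno.codes[fit.complete_cases_].astype(float)
    res = grammar_scan_matrix(fit, X)
    adj = genomic_lambda(res["stat"][res["testable"]])
    p_gc = np.full(geno.n_snps, np.nan)
    stat_gc = res["stat"] / (adj.lambda_gc if adj.lambda_gc > 1 else 1.0)
    from scipy import stats as sps

    p_gc[res["testable"]] = sps.chi2.sf(stat_gc[res["testable"]], df=1)
    table = pd.DataFrame(
        {
            "snp": geno.snps["snp"],
            "chr": geno.snps["chrom"],
            "pos": geno.snps["pos"],
            "trait": trait,
            "effect": res["effect"],
            "se": res["se"],
            "stat": stat_gc,
            "p_raw": res["p"],
            "p_gc": p_gc,
        }
    )
    return ScanResult(trait=trait, table=table, lambda_gc=adj.lambda_gc)


def _permute_within_breed(
    rng: np.random.Generator, residuals: np.ndarray, breeds: np.ndarray, n_perm: int
) -> np.ndarray:
    """(n_perm x n) matrix of residuals shuffled within breed strata."""
    n = len(residuals)
    out = np.empty((n_perm, n))
    groups = [np.flatnonzero(breeds == b) for b in np.unique(breeds)]
    for p in range(n_perm):
        perm = np.arange(n)
        for idx in groups:
            perm[idx] = rng.permutation(idx)
        out[p] = residuals[perm]
    return out


def permutation_thresholds(
    geno: GenotypeMatrix,
    fit: PolygenicModel,
    n_perm: int = 1000,
    levels: tuple[float, ...] = (0.01, 0.05),
    seed: int = 0,
    within_breed: bool = True,
    batch: int = 200,
) -> dict[float, float]:
    """Genome-wide -log10(p) thresholds from the max-statistic permutation null.

    Residuals are shuffled across individuals (within breed by default, to
    preserve stratification), the genome-wide maximum -log10 p is recorded
    per permutation, and the thresholds are the upper quantiles of that
    distribution.
    """
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives unstable thresholds")
    rng = np.random.default_rng(seed)
    breeds = geno.samples["breed"].to_numpy()[fit.complete_cases_]
    if not within_breed:
        breeds = np.zeros_like(breeds, dtype=int)
    mmscore = fit.method == "mmscore"
    r = fit.fixed_residuals_ if mmscore else fit.residuals_
    n = len(r)

    G = geno.codes[fit.complete_cases_].astype(float)
    G[G == -1] = np.nan
    G = np.where(np.isnan(G), np.nanmean(G, axis=0), G)
    Gc = G - G.mean(axis=0)
    sxx = (Gc ** 2).sum(axis=0)
    keep = sxx > 0
    Gc = Gc[:, keep]
    if mmscore:
        Gc = fit.whitened_marker_residual(Gc)
        sxx = (Gc ** 2).sum(axis=0)
    else:
        sxx = sxx[keep]

    max_stat = np.empty(n_perm)
    done = 0
    while done < n_perm:
        k = min(batch, n_perm - done)
        R = _permute_within_breed(rng, r, breeds, k)
        if mmscore:
            Rw = fit.whiten(R.T).T
            sxy = Rw @ Gc
            with np.errstate(divide="ignore", invalid="ignore"):
                stat = sxy ** 2 / sxx[None, :]
        else:
            Rc = R - R.mean(axis=1, keepdims=True)
            syy = (Rc ** 2).sum(axis=1)
            sxy = Rc @ Gc                             # (k x m)
            with np.errstate(divide="ignore", invalid="ignore"):
                t2 = sxy ** 2 / sxx[None, :]
                stat = (n - 2) * t2 / np.maximum(syy[:, None] - t2, 1e-300)
        max_stat[done : done + k] = stat.max(axis=1)
        done += k

    from scipy import stats as sps

    max_logp = -np.log10(np.maximum(sps.chi2.sf(max_stat, df=1), 1e-300))
    return {lev: float(np.quantile(max_logp, 1.0 - lev)) for lev in levels}


# ---------------------------------------------------------------------------
# conditional independence
# ---------------------------------------------------------------------------

def conditional_independence(
    geno: GenotypeMatrix,
    y: np.ndarray,
    design: FixedEffectDesign,
    K: np.ndarray,
    sig_snps: list[str],
    threshold_logp: float,
    method: str = "mmscore",
) -> list[str]:
    """Forward conditioning on one chromosome's significant SNPs.

    The most significant SNP joins the fixed-effect design as a covariate,
    the polygenic model is refit, and the remaining SNPs are retested;
    iteration stops when no SNP passes ``threshold_logp``.  Returns the
    conditionally independent core SNPs.
    """
    if len(sig_snps) == 1:
        return list(sig_snps)
    idx = {s: geno.snp_index(s) for s in sig_snps}
    remaining = list(sig_snps)
    core: list[str] = []
    cur = design

    # initial ranking from the unconditioned fit
    while remaining:
        fit = PolygenicModel(method=method).fit(y, cur, K)
        mask = fit.complete_cases_
        X = geno.codes[mask][:, [idx[s] for s in remaining]].astype(float)
        res = grammar_scan_matrix(fit, X)
        logp = -np.log10(np.maximum(res["p"], 1e-300))
        logp[~res["testable"]] = -np.inf
        best = int(np.nanargmax(logp))
        if not np.isfinite(logp[best]) or logp[best] < threshold_logp:
            break
        snp = remaining.pop(best)
        col = _prepare_marker(geno.codes[:, idx[snp]].astype(float))
        trial = cur.with_covariate(col, f"snp[{snp}]")
        try:
            trial.check_rank()
        except ValueError:
            warnings.warn(f"covariate {snp} collinear with design; dropped")
            continue
        core.append(snp)
        cur = trial
    return core


# ---------------------------------------------------------------------------
# clustering and naming
# ---------------------------------------------------------------------------

def cluster_and_name(
    core_hits: pd.DataFrame,
    min_traits: int = 2,
    merge_bp: int = 1_000_000,
    external: pd.DataFrame | None = None,
    external_window_bp: int = 1_000_000,
    prefix: str = "BW_Q",
) -> list[QTL]:
    """Merge core SNPs into named QTLs and apply the retention rule.

    ``core_hits`` needs columns snp, chr, pos, trait, tier (and optionally
    var_percent).  QTLs associated with fewer than ``min_traits`` traits are
    kept only when co-localized (within ``external_window_bp``) with a
    significant entry of an imported external association table.
    """
    qtls: list[QTL] = []
    for chrom, grp in core_hits.groupby("chr", sort=False):
        grp = grp.sort_values("pos", kind="stable")
        clusters: list[pd.DataFrame] = []
        for _, row in grp.iterrows():
            if clusters and row["pos"] - clusters[-1]["pos"].max() <= merge_bp:
                clusters[-1] = pd.concat([clusters[-1], row.to_frame().T])
            else:
                clusters.append(row.to_frame().T)
        for cl in clusters:
            traits = {}
            varp = {}
            for _, r in cl.iterrows():
                t = str(r["trait"])
                tier = str(r["tier"])
                if t not in traits or tier == "1%":
                    traits[t] = tier
                if "var_percent" in cl.columns and pd.notna(r.get("var_percent")):
                    varp[t] = float(r["var_percent"])
            ext = False
            if external is not None and len(external):
                same = external[external["chr"].astype(str) == str(chrom)]
                if len(same):
                    dmin = np.abs(
                        same["pos"].to_numpy(dtype=float)[:, None]
                        - cl["pos"].to_numpy(dtype=float)[None, :]
                    ).min()
                    ext = dmin <= external_window_bp
            qtls.append(
                QTL(
                    name="",
                    chrom=str(chrom),
                    core_snps=list(dict.fromkeys(cl["snp"])),
                    traits=traits,
                    var_percent=varp,
                    external_support=bool(ext),
                )
            )
    qtls = [q for q in qtls if len(q.traits) >= min_traits or q.external_support]

    # names: BW_Q<chrom>, letters a, b, ... in map order when several share one
    by_chrom: dict[str, list[QTL]] = {}
    for q in qtls:
        by_chrom.setdefault(q.chrom, []).append(q)
    for chrom, qs in by_chrom.items():
        qs.sort(key=lambda q: min(core_hits.loc[core_hits["snp"].isin(q.core_snps), "pos"]))
        if len(qs) == 1:
            qs[0].name = f"{prefix}{chrom}"
        else:
            for letter, q in zip("abcdefghij", qs):
                q.name = f"{prefix}{chrom}{letter}"
    return qtls


def variance_explained(p: float, q: float, a: float, var_y: float) -> float:
    """Var% = 2 p q a^2 / Var_y * 100 for an allele-substitution effect a."""
    if var_y <= 0:
        raise ValueError("phenotypic variance must be positive")
    if not np.isclose(p + q, 1.0):
        raise ValueError("allele frequencies must sum to 1")
    return float(2.0 * p * q * a * a / var_y * 100.0)
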