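"""Subpopulation diversity statistics, LD structure, kinship, and PCA.

Per breed this module produces the ingredients of a diversity summary table:
the fraction of polymorphic SNPs (MAF > 0.05), an independent-marker set
(greedy pruning at r^2 < 0.2), the fraction of independent markers in
Hardy-Weinberg equilibrium (exact test p > 0.05), mean expected
heterozygosity, and the LD-decay curve with the distance at which mean r^2
first drops through 0.2.  Pooled across breeds it provides the genome-wide
IBS kinship matrix and its PCA for population-structure assessment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .data import MISSING, GenotypeMatrix


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def allele_freq_and_maf(geno_or_codes) -> pd.DataFrame:
    """Per-SNP allele2 frequency and MAF over non-missing calls.

    All-missing SNPs get NaN frequency and are flagged ``all_missing``.
    """
    codes = geno_or_codes.codes if isinstance(geno_or_codes, GenotypeMatrix) else geno_or_codes
    g = np.asarray(codes, dtype=float)
    g[np.asarray(codes) == MISSING] = np.nan
    n_called = np.sum(~np.isnan(g), axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.nansum(g, axis=0) / (2.0 * n_called)
    freq = np.where(n_called == 0, np.nan, freq)
    maf = np.minimum(freq, 1.0 - freq)
    return pd.DataFrame(
        {"freq_allele2": freq, "maf": maf, "n_called": n_called,
         "all_missing": n_called == 0}
    )


def expected_het(freqs: np.ndarray) -> float:
    """Mean expected heterozygosity 2p(1-p) over the supplied SNP set."""
    freqs = np.asarray(freqs, dtype=float)
    freqs = freqs[~np.isnan(freqs)]
    if freqs.size == 0:
        raise ValueError("expected_het needs a non-empty frequency set")
    return float(np.mean(2.0 * freqs * (1.0 - freqs)))


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact conditional HWE test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts (of the same parity) whose conditional
    probability does not exceed the observed one.  Monomorphic samples
    return 1.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n < 1:
        raise ValueError("need at least one genotype")
    n_a = 2 * n_hom1 + n_het  # copies of the rarer-or-either allele
    n_b = 2 * n_hom2 + n_het
    if n_a == 0 or n_b == 0:
        return 1.0
    rare, common = min(n_a, n_b), max(n_a, n_b)
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = (common - hets) // 2
    # conditional log-probability of each het count given the allele totals
    logp = (
        gammaln(n + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
        + hets * np.log(2.0)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = np.flatnonzero(hets == n_het)
    if obs.size != 1:
        raise ValueError("observed het count inconsistent with allele totals")
    p_obs = probs[obs[0]]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of genotype codes on joint non-missing calls.

    Returns NaN when either SNP is monomorphic on the joint set or fewer than
    two joint calls exist.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = (g1 != MISSING) & (g2 != MISSING) & ~np.isnan(g1) & ~np.isnan(g2)
    if ok.sum() < 2:
        return float("nan")
    a, b = g1[ok], g2[ok]
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _r2_matrix(codes: np.ndarray) -> np.ndarray:
    """Pairwise r^2 with mean imputation of missing calls (small SNP sets)."""
    g = codes.astype(float)
    g[codes == MISSING] = np.nan
    mean = np.nanmean(g, axis=0)
    g = np.where(np.isnan(g), mean, g)
    sd = g.std(axis=0)
    keep = sd > 0
    r2 = np.full((codes.shape[1], codes.shape[1]), np.nan)
    if keep.any():
        c = np.corrcoef(g[:, keep], rowvar=False)
        c = np.atleast_2d(c)
        r2[np.ix_(keep, keep)] = c * c
    return r2


def prune_independent(
    geno: GenotypeMatrix, r2_max: float = 0.2, window_bp: int = 1_000_000
) -> list[str]:
    """Greedy left-to-right pruning: keep a SNP iff r^2 < ``r2_max`` against
    every already-kept SNP within ``window_bp`` on the same chromosome."""
    kept_ids: list[str] = []
    chroms = geno.snps["chrom"].to_numpy()
    pos = geno.snps["pos"].to_numpy()
    ids = geno.snps["snp"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        idx = idx[np.argsort(pos[idx], kind="stable")]
        kept: list[int] = []
        for j in idx:
            ok = True
            for k in reversed(kept):
                if pos[j] - pos[k] > window_bp:
                    break
                r2 = ld_r2(geno.codes[:, k], geno.codes[:, j])
                if not np.isnan(r2) and r2 >= r2_max:
                    ok = False
                    break
            if ok:
                kept.append(j)
        kept_ids.extend(ids[kept])
    return kept_ids


def ld_decay(
    geno: GenotypeMatrix,
    bin_width_bp: int = 1_000,
    max_dist_bp: int = 500_000,
    r2_cross: float = 0.2,
) -> tuple[pd.DataFrame, float]:
    """Mean r^2 per intra-chromosomal distance bin, and the bp distance where
    the binned curve first crosses ``r2_cross`` downward (linear
    interpolation between bin centres; inf if it never crosses)."""
    chroms = geno.snps["chrom"].to_numpy()
    pos = geno.snps["pos"].to_numpy()
    n_bins = max_dist_bp // bin_width_bp
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)

    g = geno.codes.astype(float)
    g[geno.codes == MISSING] = np.nan
    mean = np.nanmean(g, axis=0)
    gi = np.where(np.isnan(g), mean, g)
    sd = gi.std(axis=0)

    for chrom in pd.unique(chroms):
        idx = np.flatnonzero((chroms == chrom) & (sd > 0))
        idx = idx[np.argsort(pos[idx], kind="stable")]
        p = pos[idx]
        x = gi[:, idx]
        xc = x - x.mean(axis=0)
        norm = np.sqrt((xc ** 2).sum(axis=0))
        for a in range(len(idx)):
            far = np.searchsorted(p, p[a] + max_dist_bp, side="right")
            if far <= a + 1:
                continue
            d = p[a + 1 : far] - p[a]
            r = (xc[:, a] @ xc[:, a + 1 : far]) / (norm[a] * norm[a + 1 : far])
            b = np.minimum(d // bin_width_bp, n_bins - 1).astype(int)
            np.add.at(sums, b, r * r)
            np.add.at(counts, b, 1)

    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centre = (np.arange(n_bins) + 0.5) * bin_width_bp
    curve = pd.DataFrame({"dist_bp": centre, "mean_r2": mean_r2, "n_pairs": counts})

    crossing = float("inf")
    valid = np.flatnonzero(~np.isnan(mean_r2))
    for i in range(len(valid) - 1):
        a, b = valid[i], valid[i + 1]
        if mean_r2[a] >= r2_cross > mean_r2[b]:
            frac = (mean_r2[a] - r2_cross) / (mean_r2[a] - mean_r2[b])
            crossing = float(centre[a] + frac * (centre[b] - centre[a]))
            break
    return curve, crossing


# ---------------------------------------------------------------------------
# kinship and PCA
# ---------------------------------------------------------------------------

def ibs_kinship(geno: GenotypeMatrix) -> np.ndarray:
    """Mean allele-sharing kinship: phi_ij = mean over shared non-missing loci
    of (2 - |g_i - g_j|) / 2.  Diagonal is exactly 1."""
    codes = geno.codes
    ind = [(codes == k).astype(np.float32) for k in (0, 1, 2)]
    valid = (codes != MISSING).astype(np.float32)
    denom = valid @ valid.T
    if (denom == 0).any():
        raise ValueError("a sample pair shares no genotyped locus")
    # sum over loci of |gi - gj| via indicator cross-products
    absdiff = np.zeros_like(denom)
    for a in range(3):
        for b in range(3):
            w = abs(a - b)
            if w:
                absdiff += w * (ind[a] @ ind[b].T)
    phi = (2.0 * denom - absdiff) / (2.0 * denom)
    phi = (phi + phi.T) / 2.0
    np.fill_diagonal(phi, 1.0)
    return phi.astype(float)


def pca_structure(K: np.ndarray, n_components: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """PCA of a double-centred kinship matrix.

    Returns (coordinates, eigenvalues); components ordered by decreasing
    eigenvalue; each component's sign is fixed so its largest-magnitude
    loading is positive.
    """
    K = np.asarray(K, dtype=float)
    if not np.isfinite(K).all():
        raise ValueError("kinship matrix contains non-finite entries")
    n = K.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    Kc = J @ K @ J
    Kc = (Kc + Kc.T) / 2.0
    vals, vecs = np.linalg.eigh(Kc)
    order = np.argsort(vals)[::-1][:n_components]
    vals = vals[order]
    vecs = vecs[:, order]
    coords = vecs * np.sqrt(np.maximum(vals, 0.0))
    for j in range(coords.shape[1]):
        k = np.argmax(np.abs(coords[:, j]))
        if coords[k, j] < 0:
            coords[:, j] = -coords[:, j]
    return coords, vals


# ---------------------------------------------------------------------------
# summary table
# ---------------------------------------------------------------------------

@dataclass
class DiversitySummary:
    breed: str
    n_samples: int
    p_poly: float
    n_independent: int
    p_hw: float
    mean_he: float
    ld_curve: pd.DataFrame = field(repr=False)
    l_r2_02_bp: float = float("inf")


def diversity_summary(
    geno: GenotypeMatrix,
    maf_poly: float = 0.05,
    hw_alpha: float = 0.05,
    hw_on_independent: bool = True,
    bin_width_bp: int = 1_000,
    max_dist_bp: int = 500_000,
) -> list[DiversitySummary]:
    """Per-breed diversity summary over the shared marker panel."""
    out = []
    for breed in pd.unique(geno.samples["breed"]):
        sub = geno.take_samples(geno.breed_index(breed))
        af = allele_freq_and_maf(sub)
        called = ~af["all_missing"]
        p_poly = float((af["maf"][called] > maf_poly).mean())

        indep = prune_independent(sub)
        ipos = sub.snps["snp"].isin(indep).to_numpy()
        freqs = af["freq_allele2"].to_numpy()[ipos]
        mean_he = expected_het(freqs)

        hw_idx = np.flatnonzero(ipos) if hw_on_independent else np.flatnonzero(called)
        pvals = []
        for j in hw_idx:
            col = sub.codes[:, j]
            counts = [(col == c).sum() for c in (0, 1, 2)]
            pvals.append(hwe_exact(*counts))
        p_hw = float(np.mean(np.asarray(pvals) > hw_alpha)) if pvals else float("nan")

        curve, crossing = ld_decay(sub, bin_width_bp, max_dist_bp)
        out.append(
            DiversitySummary(
                breed=str(breed),
                n_samples=sub.n_samples,
                p_poly=p_poly,
                n_independent=len(indep),
                p_hw=p_hw,
                mean_he=mean_he,
                ld_curve=curve,
                l_r2_02_bp=crossing,
            )
        )
    return out
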