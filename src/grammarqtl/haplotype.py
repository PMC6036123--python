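"""Haplotype blocks around core SNPs: definition, EM phasing, and effect tests.

Blocks grow outward from a core SNP while adjacent markers stay in LD
(r^2 > 0.2), capped at six members.  Within a block, haplotype frequencies
and per-individual diplotypes are estimated by a multi-restart EM over the
enumerable haplotype space (<= 64 haplotypes at 6 SNPs).  Haplotypes at
>= 5% frequency in at least one subpopulation are tested on GRAMMAR
residuals at two levels: the allele-substitution effect of the haplotype
count (0/1/2) and the homozygous-diplotype contrast, with Bonferroni
corrections over, respectively, the total tested haplotypes and the number
of loci.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeMatrix
from .mixedmodel import PolygenicModel, grammar_scan_matrix, grammar_test
from .popgen import ld_r2


# ---------------------------------------------------------------------------
# block definition
# ---------------------------------------------------------------------------

def define_block(
    geno: GenotypeMatrix,
    core_snp: str,
    r2_min: float = 0.2,
    max_snps: int = 6,
) -> list[str]:
    """Grow a block of adjacent SNPs in LD around the core SNP.

    Expansion alternates left/right along the map while each newly added
    adjacent pair has r^2 > ``r2_min`` in the supplied genotype subset
    (evaluate per breed by passing a breed subset), capped at ``max_snps``
    members centred on the core.
    """
    j = geno.snp_index(core_snp)
    chrom = geno.snps["chrom"].iloc[j]
    on_chrom = np.flatnonzero((geno.snps["chrom"] == chrom).to_numpy())
    order = on_chrom[np.argsort(geno.snps["pos"].iloc[on_chrom].to_numpy(), kind="stable")]
    k = int(np.flatnonzero(order == j)[0])

    left, right = k, k
    grow_left = grow_right = True
    while (right - left + 1) < max_snps and (grow_left or grow_right):
        if grow_left and left > 0:
            r2 = ld_r2(geno.codes[:, order[left - 1]], geno.codes[:, order[left]])
            if not np.isnan(r2) and r2 > r2_min:
                left -= 1
            else:
                grow_left = False
        else:
            grow_left = False
        if (right - left + 1) >= max_snps:
            break
        if grow_right and right < len(order) - 1:
            r2 = ld_r2(geno.codes[:, order[right]], geno.codes[:, order[right + 1]])
            if not np.isnan(r2) and r2 > r2_min:
                right += 1
            else:
                grow_right = False
        else:
            grow_right = False
    members = [geno.snps["snp"].iloc[i] for i in order[left : right + 1]]
    if len(members) == 1:
        warnings.warn(
            f"core SNP {core_snp} is isolated; single-SNP block (alleles as haplotypes)"
        )
    return members


# ---------------------------------------------------------------------------
# EM phasing
# ---------------------------------------------------------------------------

def _compatible_pairs(pattern: tuple[int, ...], n_hap: int, k: int):
    """Unordered haplotype pairs consistent with a genotype pattern."""
    pairs = []
    for a in range(n_hap):
        for b in range(a, n_hap):
            ok = True
            for j in range(k):
                g = pattern[j]
                if g == MISSING:
                    continue
                if ((a >> j) & 1) + ((b >> j) & 1) != g:
                    ok = False
                    break
            if ok:
                pairs.append((a, b))
    return pairs


class EMPhaser:
    """Maximum-likelihood haplotype frequencies by EM (sklearn-style).

    Parameters
    ----------
    max_iter, tol : EM stopping rule on the log-likelihood increase.
    n_restarts : random restarts beyond the uniform initialisation; the best
        log-likelihood wins; ties with distinct frequency vectors are kept in
        ``alternative_frequencies_`` (symmetric phase ambiguities).
    seed : RNG seed for the restarts.

    Fitted attributes: ``haplotypes_`` (bit-encoded ints), ``frequencies_``,
    ``diplotypes_`` (n x 2 haplotype indices, max posterior),
    ``posterior_`` (n,), ``loglik_``, ``alternative_frequencies_``.
    """

    def __init__(self, max_iter: int = 1000, tol: float = 1e-8,
                 n_restarts: int = 10, seed: int = 0):
        self.max_iter = max_iter
        self.tol = tol
        self.n_restarts = n_restarts
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {"max_iter": self.max_iter, "tol": self.tol,
                "n_restarts": self.n_restarts, "seed": self.seed}

    def set_params(self, **params) -> "EMPhaser":
        for key, val in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, val)
        return self

    def fit(self, codes: np.ndarray) -> "EMPhaser":
        codes = np.asarray(codes)
        n, k = codes.shape
        if k > 6:
            raise ValueError("blocks are limited to 6 SNPs (64 haplotypes)")
        n_hap = 1 << k
        patterns = [tuple(int(c) for c in row) for row in codes]
        unique: dict[tuple, list[tuple[int, int]]] = {}
        for pat in patterns:
            if pat not in unique:
                pairs = _compatible_pairs(pat, n_hap, k)
                if not pairs:
                    raise ValueError(f"genotype pattern {pat} admits no diplotype")
                unique[pat] = pairs

        rng = np.random.default_rng(self.seed)
        inits = [np.full(n_hap, 1.0 / n_hap)]
        inits += [rng.dirichlet(np.ones(n_hap)) for _ in range(self.n_restarts)]

        solutions = []
        for f0 in inits:
            f, ll = self._run_em(f0, patterns, unique, n, n_hap)
            solutions.append((ll, f))
        best_ll = max(ll for ll, _ in solutions)
        keep: list[np.ndarray] = []
        for ll, f in solutions:
            if ll >= best_ll - 1e-6 and not any(
                np.allclose(f, g, atol=1e-4) for g in keep
            ):
                keep.append(f)

        self.haplotypes_ = np.arange(n_hap)
        self.frequencies_ = keep[0]
        self.alternative_frequencies_ = keep[1:]
        self.loglik_ = best_ll
        self.n_snps_ = k

        # max-posterior diplotype per individual
        f = self.frequencies_
        dip = np.empty((n, 2), dtype=int)
        post = np.empty(n)
        for i, pat in enumerate(patterns):
            pairs = unique[pat]
            probs = np.array(
                [(2.0 if a != b else 1.0) * f[a] * f[b] for a, b in pairs]
            )
            tot = probs.sum()
            if tot <= 0:  # all compatible haplotypes at zero frequency
                probs = np.ones(len(pairs))
                tot = probs.sum()
            best = int(np.argmax(probs))
            dip[i] = pairs[best]
            post[i] = probs[best] / tot
        self.diplotypes_ = dip
        self.posterior_ = post
        return self

    def _run_em(self, f, patterns, unique, n, n_hap):
        f = f.copy()
        prev_ll = -np.inf
        for _ in range(self.max_iter):
            counts = np.zeros(n_hap)
            ll = 0.0
            for pat in patterns:
                pairs = unique[pat]
                probs = np.array(
                    [(2.0 if a != b else 1.0) * f[a] * f[b] for a, b in pairs]
                )
                tot = probs.sum()
                if tot <= 0:
                    probs = np.ones(len(pairs)) / len(pairs)
                    tot = 1.0
                    ll += -700.0  # impossible under current f; heavy penalty
                else:
                    ll += np.log(tot)
                w = probs / tot
                for (a, b), wi in zip(pairs, w):
                    counts[a] += wi
                    counts[b] += wi
            f = counts / (2.0 * n)
            if ll < prev_ll - 1e-9:
                raise AssertionError("EM log-likelihood decreased")
            if ll - prev_ll < self.tol:
                prev_ll = ll
                break
            prev_ll = ll
        return f, prev_ll

    def haplotype_string(self, h: int, allele1: list[str], allele2: list[str]) -> str:
        """Decode a bit-encoded haplotype into its allele letters."""
        return "".join(
            allele2[j] if (h >> j) & 1 else allele1[j] for j in range(self.n_snps_)
        )


# ---------------------------------------------------------------------------
# block container and frequency tables
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeBlock:
    locus: str
    member_snps: list[str]
    core_snp: str
    hap_strings: list[str]                 # indexed by haplotype code
    frequencies: pd.DataFrame              # subpop x haplotype code
    diplotypes: np.ndarray                 # (n, 2) haplotype codes
    posterior: np.ndarray
    tested_haplotypes: list[int] = field(default_factory=list)


def phase_block(
    geno: GenotypeMatrix,
    core_snp: str,
    locus: str = "",
    r2_min: float = 0.2,
    min_freq: float = 0.05,
    seed: int = 0,
) -> HaplotypeBlock:
    """Define, phase, and summarise the block around one core SNP."""
    members = define_block(geno, core_snp, r2_min=r2_min)
    cols = [geno.snp_index(s) for s in members]
    codes = geno.codes[:, cols]
    phaser = EMPhaser(seed=seed).fit(codes)
    a1 = [geno.snps["allele1"].iloc[c] for c in cols]
    a2 = [geno.snps["allele2"].iloc[c] for c in cols]
    strings = [
        phaser.haplotype_string(h, a1, a2) for h in range(1 << len(members))
    ]
    freqs = haplotype_frequency_table(
        phaser.diplotypes_, geno.samples["breed"].to_numpy(), 1 << len(members)
    )
    tested = retained_haplotypes(freqs, min_freq)
    return HaplotypeBlock(
        locus=locus or core_snp,
        member_snps=members,
        core_snp=core_snp,
        hap_strings=strings,
        frequencies=freqs,
        diplotypes=phaser.diplotypes_,
        posterior=phaser.posterior_,
        tested_haplotypes=tested,
    )


def haplotype_frequency_table(
    diplotypes: np.ndarray, subpops: np.ndarray, n_hap: int
) -> pd.DataFrame:
    """Per-subpopulation haplotype frequencies from hard diplotype calls."""
    rows = {}
    for pop in pd.unique(subpops):
        sel = subpops == pop
        flat = diplotypes[sel].ravel()
        counts = np.bincount(flat, minlength=n_hap)
        rows[pop] = counts / flat.size
    return pd.DataFrame(rows).T


def retained_haplotypes(freqs: pd.DataFrame, min_freq: float = 0.05) -> list[int]:
    """Haplotypes reaching ``min_freq`` in at least one subpopulation."""
    keep = (freqs >= min_freq).any(axis=0)
    return [int(h) for h in freqs.columns[keep]]


def haplotype_counts(diplotypes: np.ndarray, hap: int) -> np.ndarray:
    """Per-individual 0/1/2 count of the target haplotype."""
    return (diplotypes == hap).sum(axis=1)


# ---------------------------------------------------------------------------
# effect tests
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeEffect:
    locus: str
    haplotype: str
    trait: str
    kind: str                     # "substitution" or "diplotype"
    effect: float
    se: float
    stat: float
    p: float
    n_tests: int
    bonferroni_alpha: float = 0.05
    testable: bool = True

    @property
    def significant(self) -> bool:
        return self.testable and self.p < self.bonferroni_alpha / self.n_tests


def _effect_regression(fit_or_residuals, x: np.ndarray):
    """One-column marker-style test honouring the fitted engine's method."""
    if isinstance(fit_or_residuals, PolygenicModel):
        res = grammar_scan_matrix(fit_or_residuals, x[:, None])
        return (
            float(res["effect"][0]),
            float(res["se"][0]),
            float(res["stat"][0]),
            float(res["p"][0]),
        )
    return grammar_test(np.asarray(fit_or_residuals, float), x)


def substitution_test(
    block: HaplotypeBlock,
    hap: int,
    fit,
    trait: str,
    n_tests: int,
    mask: np.ndarray | None = None,
) -> HaplotypeEffect:
    """Allele-substitution effect of one haplotype.

    The 0/1/2 count of the target haplotype (all other haplotypes pooled as
    the alternative allele) is tested against the polygenic null fit; pass a
    fitted :class:`PolygenicModel` for the calibrated engine test, or a raw
    GRAMMAR-residual vector (with ``mask``) for the plain regression.
    """
    if isinstance(fit, PolygenicModel):
        mask = fit.complete_cases_
    counts = haplotype_counts(block.diplotypes, hap)[mask].astype(float)
    name = block.hap_strings[hap]
    if counts.std() == 0:
        return HaplotypeEffect(
            block.locus, name, trait, "substitution",
            np.nan, np.nan, np.nan, np.nan, n_tests, testable=False,
        )
    eff, se, stat, p = _effect_regression(fit, counts)
    return HaplotypeEffect(
        block.locus, name, trait, "substitution", eff, se, stat, p, n_tests
    )


def diplotype_test(
    block: HaplotypeBlock,
    hap: int,
    fit,
    trait: str,
    n_tests: int,
    mask: np.ndarray | None = None,
    min_homozygotes: int = 3,
) -> HaplotypeEffect:
    """Homozygous-diplotype contrast: target homozygotes vs all other
    diplotype classes, effect in grams relative to the non-homozygote mean."""
    if isinstance(fit, PolygenicModel):
        mask = fit.complete_cases_
    counts = haplotype_counts(block.diplotypes, hap)[mask]
    hom = (counts == 2).astype(float)
    name = block.hap_strings[hap]
    if hom.sum() < min_homozygotes:
        return HaplotypeEffect(
            block.locus, name, trait, "diplotype",
            np.nan, np.nan, np.nan, np.nan, n_tests, testable=False,
        )
    eff, se, stat, p = _effect_regression(fit, hom)
    return HaplotypeEffect(
        block.locus, name, trait, "diplotype", eff, se, stat, p, n_tests
    )
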