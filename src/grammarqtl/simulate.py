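"""Synthetic multi-breed genotype/phenotype generator with full ground truth.

The generator emulates a panel of divergent chicken breeds genotyped on a
dense SNP chip and weighed weekly through the growth phase:

* **Breed divergence** — per-SNP ancestral frequencies are perturbed per breed
  by a Balding–Nichols Beta draw governed by that breed's F\\ :sub:`ST`.
* **Linkage disequilibrium** — each breed carries a finite pool of founder
  haplotypes; individuals' chromosomes are mosaics of pool haplotypes with
  crossovers at ``recomb_rate`` per bp, so r² decays with distance on a scale
  set by the pool size and crossover rate.
* **Phenotypes** — weekly body weight is a per-breed logistic growth curve
  plus sex and birth-weight fixed effects, planted additive QTLs, an optional
  variance-QTL and epistatic pair, a polygenic term built from the simulated
  genome-wide genotypes, and Gaussian noise scaled to a target narrow-sense
  heritability.

Every component is recorded in :class:`SimTruth`; the emitted phenotype is
exactly the sum of its recorded components.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, PhenotypeTable


class SimConfigError(ValueError):
    pass


@dataclass
class QTLSpec:
    """A planted additive QTL: allele-count effect in grams.

    ``effect`` is either a scalar (same effect at every post-hatch week;
    hatch weight is left to egg/maternal variation) or an explicit per-week
    sequence including week 0; ``breeds`` restricts the effect to the named
    breeds (None = all breeds).
    """

    snp: int
    effect: float | Sequence[float]
    breeds: tuple[str, ...] | None = None


@dataclass
class VQTLSpec:
    """A variance-QTL: per-genotype multipliers of the residual SD."""

    snp: int
    sd_multipliers: tuple[float, float, float] = (1.0, 1.5, 2.25)


@dataclass
class EpiSpec:
    """An epistatic pair: grams per unit product of centred codes."""

    snp1: int
    snp2: int
    effect: float


@dataclass
class SimConfig:
    """Study-scale defaults: 4 breeds x 100 birds, dense autosomal+Z panel,
    weekly weights from hatch to week 15."""

    n_breeds: int = 4
    n_per_breed: int = 100
    n_snps: int = 46211
    n_chromosomes: int = 29          # last chromosome is Z
    fst_per_breed: tuple[float, ...] = (0.05, 0.05, 0.05, 0.15)
    ld_pool_size: int = 16
    pool_weight_alpha: float | None = 0.5   # Dirichlet skew of founder
    # contributions (None = equal); unequal contributions mimic the few
    # dominant families of a conserved flock and give the within-breed
    # kinship the spread a variance-component fit needs
    recomb_rate: float = 1e-5        # per-bp crossover probability
    snp_spacing_bp: int = 20_000
    n_weeks: int = 16                # BW0 .. BW15
    heritability: float = 0.3
    qtl_spec: tuple[QTLSpec, ...] = ()
    vqtl_spec: VQTLSpec | None = None
    epi_spec: EpiSpec | None = None
    sex_effect: float = 30.0         # grams at the final week; scales with growth
    birthweight_slope: float = 1.0   # grams per gram of birth weight
    # per-breed logistic curves: (asymptote g, rate per week, inflection week)
    growth_curve_params: tuple[tuple[float, float, float], ...] = (
        (1000.0, 0.33, 8.5),
        (1100.0, 0.33, 8.5),
        (1800.0, 0.35, 9.0),
        (1600.0, 0.35, 9.0),
    )
    residual_cv: float = 0.12        # residual SD as fraction of the curve mean
    residual_sd_floor: float = 5.0   # grams; keeps hatch-weight noise sane
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_breeds, self.n_per_breed, self.n_snps,
               self.n_chromosomes, self.n_weeks, self.ld_pool_size) < 1:
            raise SimConfigError("all counts must be >= 1")
        if not 0.0 <= self.heritability <= 1.0:
            raise SimConfigError("heritability must lie in [0, 1]")
        if len(self.fst_per_breed) != self.n_breeds:
            if len(set(self.fst_per_breed)) == 1:
                self.fst_per_breed = self.fst_per_breed[:1] * self.n_breeds
            else:
                raise SimConfigError("fst_per_breed length must equal n_breeds")
        if any(not 0.0 <= f <= 1.0 for f in self.fst_per_breed):
            raise SimConfigError("fst values must lie in [0, 1]")
        if self.n_snps < 2 * self.n_chromosomes:
            raise SimConfigError("need at least 2 SNPs per chromosome")
        for q in self.qtl_spec:
            if not 0 <= q.snp < self.n_snps:
                raise SimConfigError("QTL snp index out of range")
        if self.vqtl_spec and not 0 <= self.vqtl_spec.snp < self.n_snps:
            raise SimConfigError("vQTL snp index out of range")
        if self.epi_spec and not (
            0 <= self.epi_spec.snp1 < self.n_snps
            and 0 <= self.epi_spec.snp2 < self.n_snps
        ):
            raise SimConfigError("epistatic snp index out of range")
        if len(self.growth_curve_params) < self.n_breeds:
            reps = -(-self.n_breeds // len(self.growth_curve_params))
            self.growth_curve_params = (self.growth_curve_params * reps)[: self.n_breeds]

    @property
    def breed_names(self) -> list[str]:
        return [f"breed{b + 1}" for b in range(self.n_breeds)]

    @property
    def week_labels(self) -> list[str]:
        return [f"BW{w}" for w in range(self.n_weeks)]


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset.

    ``components`` maps component name -> (n_individuals, n_weeks) array; the
    emitted body weight is exactly their sum.
    """

    pools: dict[str, np.ndarray]
    components: dict[str, np.ndarray]
    polygenic_std: np.ndarray
    realized_h2: dict[str, float]
    qtl_records: list[dict]
    vqtl_record: dict | None
    epi_record: dict | None
    warnings: list[str] = field(default_factory=list)

    def phenotype_sum(self) -> np.ndarray:
        return sum(self.components.values())

    def to_json(self, path) -> None:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            raise TypeError(type(x))

        payload = {
            "realized_h2": self.realized_h2,
            "qtl_records": self.qtl_records,
            "vqtl_record": self.vqtl_record,
            "epi_record": self.epi_record,
            "warnings": self.warnings,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=conv)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _chromosome_layout(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Spread SNPs across chromosomes as evenly as possible."""
    base, extra = divmod(cfg.n_snps, cfg.n_chromosomes)
    sizes = np.full(cfg.n_chromosomes, base, dtype=int)
    sizes[:extra] += 1
    if sizes.min() < 2:
        raise SimConfigError("need at least 2 SNPs per chromosome")
    labels = [str(c + 1) for c in range(cfg.n_chromosomes)]
    labels[-1] = "Z"
    chrom = np.repeat(labels, sizes)
    pos = np.concatenate(
        [cfg.snp_spacing_bp * (np.arange(k) + 1) for k in sizes]
    )
    return chrom, pos


def _mosaic_haplotypes(
    rng: np.random.Generator,
    pool: np.ndarray,
    pos_by_chrom: list[np.ndarray],
    snp_slices: list[slice],
    n_haps: int,
    recomb_rate: float,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Sample ``n_haps`` mosaic haplotypes from a founder pool."""
    H, m = pool.shape
    out = np.empty((n_haps, m), dtype=np.int8)
    for sl, pos in zip(snp_slices, pos_by_chrom):
        k = len(pos)
        fresh = rng.choice(H, size=(n_haps, k), p=weights)
        if recomb_rate > 0 and k > 1:
            gaps = np.diff(pos).astype(float)
            p_x = 1.0 - np.exp(-recomb_rate * gaps)
            new = np.empty((n_haps, k), dtype=bool)
            new[:, 0] = True
            new[:, 1:] = rng.random((n_haps, k - 1)) < p_x
        else:
            new = np.zeros((n_haps, k), dtype=bool)
            new[:, 0] = True
        # forward-fill the pool index chosen at each renewal point
        cols = np.arange(k)
        last = np.maximum.accumulate(np.where(new, cols, 0), axis=1)
        idx = np.take_along_axis(fresh, last, axis=1)
        out[:, sl] = pool[idx, np.arange(sl.start, sl.stop)[None, :]]
    return out


def simulate_genotypes(config: SimConfig) -> tuple[GenotypeMatrix, dict[str, np.ndarray]]:
    """Draw the multi-breed genotype panel; returns (genotypes, founder pools).

    Z-chromosome females are hemizygous: their Z genotype is twice a single
    haplotype's allele, so they are never heterozygous on Z.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    chrom, pos = _chromosome_layout(config)
    m = config.n_snps
    n_b = config.n_per_breed

    # chromosome bookkeeping
    snp_slices, pos_by_chrom = [], []
    start = 0
    for lab in pd.unique(chrom):
        k = int((chrom == lab).sum())
        snp_slices.append(slice(start, start + k))
        pos_by_chrom.append(pos[start : start + k])
        start += k
    z_mask = chrom == "Z"

    p_anc = rng.uniform(0.05, 0.95, size=m)
    # ancestral founder pool shared by undiverged (fst = 0) breeds, so zero
    # divergence really means one founder population
    anc_pool = (rng.random((config.ld_pool_size, m)) < p_anc).astype(np.int8)
    if config.pool_weight_alpha is None:
        anc_weights = None
    else:
        anc_weights = rng.dirichlet(
            np.full(config.ld_pool_size, config.pool_weight_alpha)
        )
    pools: dict[str, np.ndarray] = {}
    codes = np.empty((config.n_breeds * n_b, m), dtype=np.int8)
    sexes = np.empty(config.n_breeds * n_b, dtype=int)

    for b, name in enumerate(config.breed_names):
        fst = config.fst_per_breed[b]
        if fst <= 0:
            pool = anc_pool.copy()
        else:
            a = p_anc * (1 - fst) / fst
            bb = (1 - p_anc) * (1 - fst) / fst
            p_b = rng.beta(a, bb)
            pool = (rng.random((config.ld_pool_size, m)) < p_b).astype(np.int8)
        pools[name] = pool
        if config.pool_weight_alpha is None:
            weights = None
        elif fst <= 0:
            weights = anc_weights  # undiverged breeds share the founder mix
        else:
            weights = rng.dirichlet(
                np.full(config.ld_pool_size, config.pool_weight_alpha)
            )
        haps = _mosaic_haplotypes(
            rng, pool, pos_by_chrom, snp_slices, 2 * n_b, config.recomb_rate,
            weights=weights,
        )
        h1, h2 = haps[:n_b], haps[n_b:]
        g = (h1 + h2).astype(np.int8)
        sex = (rng.random(n_b) < 0.5).astype(int)  # 1 male, 0 female
        # hemizygous female Z: duplicate haplotype 1's allele
        g[np.ix_(sex == 0, z_mask)] = 2 * h1[np.ix_(sex == 0, z_mask)]
        rows = slice(b * n_b, (b + 1) * n_b)
        codes[rows] = g
        sexes[rows] = sex

    snps = pd.DataFrame(
        {
            "snp": [f"snp{j}" for j in range(m)],
            "chrom": chrom,
            "pos": pos,
            "allele1": "A",
            "allele2": "G",
        }
    )
    samples = pd.DataFrame(
        {
            "iid": [
                f"{name}_{i:04d}"
                for name in config.breed_names
                for i in range(n_b)
            ],
            "breed": np.repeat(config.breed_names, n_b),
            "sex": sexes,
        }
    )
    return GenotypeMatrix(codes, snps, samples), pools


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _logistic(asym: float, rate: float, infl: float, week: np.ndarray) -> np.ndarray:
    return asym / (1.0 + np.exp(-rate * (week - infl)))


def simulate_phenotypes(
    geno: GenotypeMatrix, config: SimConfig, pools: dict[str, np.ndarray] | None = None
) -> tuple[PhenotypeTable, SimTruth]:
    """Emit weekly body weights decomposed into recorded components.

    The polygenic value is a weighted sum of the individual's own (centred)
    genotypes with i.i.d. normal SNP weights, standardised to unit pooled
    within-breed variance and rescaled each week so that the within-breed
    genetic fraction of the genetic+residual variance equals the target
    heritability.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    n = geno.n_samples
    weeks = np.arange(config.n_weeks, dtype=float)
    breed_of = geno.samples["breed"].to_numpy()
    breed_idx = np.searchsorted(np.array(config.breed_names), breed_of)
    sex = geno.samples["sex"].to_numpy(dtype=float)
    truth_warnings: list[str] = []

    # growth curve per individual per week
    curves = np.stack(
        [_logistic(a, r, t0, weeks) for (a, r, t0) in config.growth_curve_params]
    )  # (n_breeds, n_weeks)
    curve_comp = curves[breed_idx]

    # sex effect grows with the curve, reaching config.sex_effect at the last week
    ratio = curve_comp / curve_comp[:, -1:]
    sex_comp = config.sex_effect * sex[:, None] * ratio

    # polygenic term drawn from the genome's own centred IBS kinship, so the
    # generative covariance has exactly the structure the null model assumes;
    # standardised to unit pooled within-breed SD so the heritability target
    # refers to within-breed variance
    from .mixedmodel import gower_center
    from .popgen import ibs_kinship

    K = gower_center(ibs_kinship(geno), ridge_scale=1e-6)
    d, U = np.linalg.eigh(K)
    d = np.maximum(d, 0.0)
    raw = U @ (np.sqrt(d) * rng.normal(size=n))
    dev = raw.copy()
    for name in config.breed_names:
        sel = breed_of == name
        dev[sel] -= raw[sel].mean()
    pooled_sd = dev.std()
    if pooled_sd == 0:
        g_std = np.zeros(n)
        truth_warnings.append("polygenic term degenerate (no within-breed variance)")
    else:
        g_std = raw / pooled_sd

    # per-week phenotypic scale (shared across breeds, so the variance
    # components the null model assumes are homoscedastic) and h2 split
    week_scale = np.maximum(
        config.residual_cv * curves.mean(axis=0), config.residual_sd_floor
    )
    sd_total = np.broadcast_to(week_scale, (n, config.n_weeks)).copy()
    h2 = config.heritability
    poly_comp = np.sqrt(h2) * sd_total * g_std[:, None]
    # hatch weight reflects egg provisioning, not the bird's own growth
    # genetics: no polygenic share at week 0 (it would otherwise leak into
    # the birth-weight covariate and be absorbed by the fixed effects)
    poly_comp[:, 0] = 0.0

    # planted additive QTLs
    qtl_comp = np.zeros((n, config.n_weeks))
    qtl_records = []
    for q in config.qtl_spec:
        x = geno.codes[:, q.snp].astype(float)
        x[geno.codes[:, q.snp] < 0] = np.nan
        x = np.where(np.isnan(x), np.nanmean(x), x)
        if np.ndim(q.effect):
            eff = np.broadcast_to(
                np.asarray(q.effect, dtype=float), (config.n_weeks,)
            ).copy()
        else:
            eff = np.full(config.n_weeks, float(q.effect))
            eff[0] = 0.0  # scalar effects act post-hatch only
        mask = np.ones(n)
        if q.breeds is not None:
            mask = np.isin(breed_of, q.breeds).astype(float)
        mono = True
        for name in config.breed_names:
            sel = breed_of == name
            if np.nanstd(geno.codes[sel, q.snp].astype(float)) > 0:
                mono = False
        if mono:
            truth_warnings.append(f"planted QTL at snp {q.snp} is monomorphic in all breeds")
        qtl_comp += (mask * x)[:, None] * eff[None, :]
        qtl_records.append(
            {
                "snp": int(q.snp),
                "snp_id": str(geno.snps["snp"].iloc[q.snp]),
                "effect": eff.tolist(),
                "breeds": list(q.breeds) if q.breeds else None,
            }
        )

    # epistatic product term on centred codes
    epi_comp = np.zeros((n, config.n_weeks))
    epi_record = None
    if config.epi_spec is not None:
        e = config.epi_spec
        x1 = geno.codes[:, e.snp1].astype(float)
        x2 = geno.codes[:, e.snp2].astype(float)
        x1 = np.where(x1 < 0, np.nanmean(np.where(x1 < 0, np.nan, x1)), x1)
        x2 = np.where(x2 < 0, np.nanmean(np.where(x2 < 0, np.nan, x2)), x2)
        prod = (x1 - x1.mean()) * (x2 - x2.mean())
        week_on = np.ones(config.n_weeks)
        week_on[0] = 0.0  # post-hatch, like scalar QTL effects
        epi_comp = e.effect * prod[:, None] * week_on[None, :]
        epi_record = {
            "snp1": int(e.snp1),
            "snp2": int(e.snp2),
            "snp1_id": str(geno.snps["snp"].iloc[e.snp1]),
            "snp2_id": str(geno.snps["snp"].iloc[e.snp2]),
            "effect": float(e.effect),
        }

    # residual noise, optionally scaled by a variance-QTL; week 0 carries the
    # full phenotypic scale since it has no polygenic share
    sd_e = np.sqrt(1.0 - h2) * sd_total
    sd_e[:, 0] = sd_total[:, 0]
    vqtl_record = None
    if config.vqtl_spec is not None:
        v = config.vqtl_spec
        xv = geno.codes[:, v.snp].astype(float)
        xv = np.where(xv < 0, 1.0, xv).astype(int)
        mult = np.asarray(v.sd_multipliers, dtype=float)[np.clip(xv, 0, 2)]
        sd_e = sd_e * mult[:, None]
        vqtl_record = {
            "snp": int(v.snp),
            "snp_id": str(geno.snps["snp"].iloc[v.snp]),
            "sd_multipliers": list(v.sd_multipliers),
        }
    noise_comp = rng.normal(size=(n, config.n_weeks)) * sd_e

    # birth-weight carry-over: BW0 is itself the birth weight
    partial = curve_comp + sex_comp + poly_comp + qtl_comp + epi_comp + noise_comp
    bw0 = partial[:, 0]
    bw_comp = np.zeros((n, config.n_weeks))
    bw_comp[:, 1:] = config.birthweight_slope * (bw0 - bw0.mean())[:, None]

    components = {
        "growth_curve": curve_comp,
        "sex": sex_comp,
        "birth_weight": bw_comp,
        "qtl": qtl_comp,
        "polygenic": poly_comp,
        "epistasis": epi_comp,
        "noise": noise_comp,
    }
    total = sum(components.values())
    # floor at zero by absorbing the (never observed in practice) deficit
    # into the noise component so the decomposition identity holds exactly
    neg = total < 0
    if neg.any():
        noise_comp[neg] -= total[neg]
        total = sum(components.values())

    # realized within-breed h2 per trait
    realized = {}
    for w, lab in enumerate(config.week_labels):
        num = den = cnt = 0.0
        for name in config.breed_names:
            sel = breed_of == name
            num += poly_comp[sel, w].var() * sel.sum()
            den += total[sel, w].var() * sel.sum()
            cnt += sel.sum()
        realized[lab] = float(num / den) if den > 0 else float("nan")

    pheno = PhenotypeTable(
        geno.samples["iid"],
        pd.DataFrame(total, columns=config.week_labels),
    )
    truth = SimTruth(
        pools=pools or {},
        components=components,
        polygenic_std=g_std,
        realized_h2=realized,
        qtl_records=qtl_records,
        vqtl_record=vqtl_record,
        epi_record=epi_record,
        warnings=truth_warnings,
    )
    for msg in truth_warnings:
        warnings.warn(msg, stacklevel=2)
    return pheno, truth


def simulate_dataset(config: SimConfig):
    """Convenience wrapper: genotypes + phenotypes + truth in one call."""
    geno, pools = simulate_genotypes(config)
    pheno, truth = simulate_phenotypes(geno, config, pools)
    return geno, pheno, truth


def config_to_dict(config: SimConfig) -> dict:
    return asdict(config)
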