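"""Variance-heterogeneity GWAS and the exhaustive two-locus epistasis scan.

vGWAS: the trait is rank inverse-normal transformed, squared, and pushed
through the full GRAMMAR pipeline (fixed effects, polygenic fit, per-marker
regression, lambda correction); a locus whose genotypes shift the residual
variance shifts the mean of the squared transform.

Epistasis: for each target SNP, every other marker is tested with a nested
pair of regressions on the GRAMMAR residuals — additive-only (two loci)
versus additive plus a product interaction term — compared by an F test.
Genome-wide empirical significance per target comes from the distribution of
the maximum F over within-breed residual permutations, with tiers at the 5%
(significant) and 10% (suggestive) quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import GenotypeMatrix
from .mixedmodel import PolygenicModel, _prepare_marker
from .scan import ScanResult, _permute_within_breed, scan_trait


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def inverse_normal_transform(y: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal (Blom) transform with average ranks for ties.

    z_i = Phi^{-1}((r_i - 0.375) / (n + 0.25)) over the non-missing values;
    missing entries stay NaN.
    """
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y)
    vals = y[ok]
    if vals.size < 10:
        raise ValueError("need at least 10 non-missing values")
    if np.ptp(vals) == 0:
        raise ValueError("all values identical; transform undefined")
    ranks = stats.rankdata(vals, method="average")
    z = stats.norm.ppf((ranks - 0.375) / (vals.size + 0.25))
    out = np.full_like(y, np.nan)
    out[ok] = z
    return out


# ---------------------------------------------------------------------------
# vGWAS
# ---------------------------------------------------------------------------

class VarianceScan:
    """Variance-heterogeneity scan (sklearn-style estimator).

    ``fit`` transforms the trait (inverse-normal then squared), refits the
    polygenic model on the transformed values, and scans all markers; use
    ``refit_polygenic=False`` for the direct-regression variant without the
    polygenic refit.

    Fitted attributes: ``result_`` (ScanResult), ``model_`` (PolygenicModel),
    ``z2_`` (transformed trait).
    """

    def __init__(self, refit_polygenic: bool = True, method: str = "mmscore",
                 adjust_fixed: bool = True):
        self.refit_polygenic = refit_polygenic
        self.method = method
        self.adjust_fixed = adjust_fixed

    def get_params(self, deep: bool = True) -> dict:
        return {"refit_polygenic": self.refit_polygenic, "method": self.method,
                "adjust_fixed": self.adjust_fixed}

    def set_params(self, **params) -> "VarianceScan":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(
        self,
        geno: GenotypeMatrix,
        y: np.ndarray,
        design,
        K: np.ndarray,
        trait: str = "",
        square: bool = True,
    ) -> "VarianceScan":
        y = np.asarray(y, dtype=float)
        if self.adjust_fixed:
            # rank-transforming the raw trait would order individuals mostly
            # by breed; adjusting for the fixed effects first keeps the
            # within-group dispersion signal the scan is after
            Fm = design.matrix if hasattr(design, "matrix") else np.asarray(design, float)
            ok = np.isfinite(y)
            beta, *_ = np.linalg.lstsq(Fm[ok], y[ok], rcond=None)
            adj = np.full_like(y, np.nan)
            adj[ok] = y[ok] - Fm[ok] @ beta
        else:
            adj = y
        z = inverse_normal_transform(adj)
        z2 = z ** 2 if square else z
        self.z2_ = z2
        model = PolygenicModel(method=self.method)
        if self.refit_polygenic:
            model.fit(z2, design, K)
        else:
            model.fit(z2, design, np.eye(len(z2)))
        self.model_ = model
        self.result_ = scan_trait(geno, model, trait=trait or "vGWAS")
        return self


def vgwas_scan(geno, y, design, K, trait: str = "vGWAS") -> ScanResult:
    """Functional wrapper over :class:`VarianceScan`."""
    return VarianceScan().fit(geno, y, design, K, trait=trait).result_


# ---------------------------------------------------------------------------
# two-locus F test
# ---------------------------------------------------------------------------

@dataclass
class EpistasisResult:
    target: str
    partner: str
    trait: str
    a1: float
    a2: float
    a12: float
    f_stat: float
    df_num: int
    df_den: int
    p_nominal: float
    p_empirical: float = float("nan")
    tier: str = ""                    # "", "10% suggestive", "5% significant"
    testable: bool = True


def two_locus_ftest(
    residuals: np.ndarray, x1: np.ndarray, x2: np.ndarray
) -> EpistasisResult:
    """F test of the interaction term between two loci on model residuals.

    Null model: residuals ~ x1 + x2 (additive).  Full model adds the product
    of centred codes.  F = ((RSS0 - RSS1)/1) / (RSS1/(n-4)).  Collinear or
    monomorphic inputs are flagged not testable.
    """
    r = np.asarray(residuals, dtype=float)
    x1 = _prepare_marker(np.asarray(x1, dtype=float))
    x2 = _prepare_marker(np.asarray(x2, dtype=float))
    n = len(r)
    blank = EpistasisResult(
        "", "", "", np.nan, np.nan, np.nan, np.nan, 1, n - 4, np.nan, testable=False
    )
    if n <= 14 or x1.std() == 0 or x2.std() == 0:
        return blank
    one = np.ones(n)
    w = (x1 - x1.mean()) * (x2 - x2.mean())
    Z0 = np.column_stack([one, x1, x2])
    Z1 = np.column_stack([one, x1, x2, w])
    if np.linalg.matrix_rank(Z1) < 4:
        return blank
    beta0, rss0 = _ols_rss(Z0, r)
    beta1, rss1 = _ols_rss(Z1, r)
    df_den = n - 4
    if rss1 <= 0:
        return blank
    f = (rss0 - rss1) / (rss1 / df_den)
    p = float(stats.f.sf(f, 1, df_den))
    return EpistasisResult(
        "", "", "", float(beta1[1]), float(beta1[2]), float(beta1[3]),
        float(f), 1, df_den, p,
    )


def _ols_rss(Z: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, res, rank, _ = np.linalg.lstsq(Z, y, rcond=None)
    fitted = Z @ beta
    rss = float(((y - fitted) ** 2).sum())
    return beta, rss


# ---------------------------------------------------------------------------
# exhaustive per-target scan with permutation nulls
# ---------------------------------------------------------------------------

class EpistasisScan:
    """Per-target exhaustive two-locus scan (sklearn-style estimator).

    For each target SNP, F statistics against every other marker are computed
    with a shared-basis vectorisation; partners within ``exclude_bp`` of the
    target (same chromosome) are skipped, as are pairs with any occupied
    two-locus genotype cell under ``min_cell`` individuals.  The empirical
    null per target is the genome-wide maximum F over ``n_perm`` within-breed
    residual permutations.

    Fitted attributes: ``results_`` (list of EpistasisResult for partners
    passing the suggestive tier), ``table_`` (full per-pair DataFrame),
    ``null_max_f_`` (per-target permutation maxima).
    """

    def __init__(
        self,
        n_perm: int = 1000,
        exclude_bp: int = 1_000_000,
        min_cell: int = 5,
        seed: int = 0,
        levels: tuple[float, float] = (0.05, 0.10),
    ):
        self.n_perm = n_perm
        self.exclude_bp = exclude_bp
        self.min_cell = min_cell
        self.seed = seed
        self.levels = levels

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_perm": self.n_perm,
            "exclude_bp": self.exclude_bp,
            "min_cell": self.min_cell,
            "seed": self.seed,
            "levels": self.levels,
        }

    def set_params(self, **params) -> "EpistasisScan":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- internals ----------------------------------------------------------
    @staticmethod
    def _orthonormalise(v: np.ndarray, basis: list[np.ndarray]) -> np.ndarray:
        for b in basis:
            v = v - (b @ v) * b
        norm = np.linalg.norm(v)
        return v / norm if norm > 1e-10 else np.zeros_like(v)

    def _target_scan(self, r, x1, G, testable) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """F statistics for one target against partner matrix G (n x m)."""
        n, m = G.shape
        q0 = np.ones(n) / np.sqrt(n)
        q1 = self._orthonormalise(x1.copy(), [q0])
        # partner columns orthonormalised against (1, x1)
        Q2 = G - np.outer(q0, q0 @ G) - np.outer(q1, q1 @ G)
        norms = np.linalg.norm(Q2, axis=0)
        ok = testable & (norms > 1e-8)
        Q2 = np.where(ok[None, :], Q2 / np.maximum(norms, 1e-300), 0.0)
        # interaction columns orthonormalised against (1, x1, x2_j)
        W = (x1 - x1.mean())[:, None] * (G - G.mean(axis=0))
        W = W - np.outer(q0, q0 @ W) - np.outer(q1, q1 @ W)
        W = W - Q2 * np.einsum("ij,ij->j", Q2, W)[None, :]
        wn = np.linalg.norm(W, axis=0)
        ok = ok & (wn > 1e-8)
        W = np.where(ok[None, :], W / np.maximum(wn, 1e-300), 0.0)

        yy = float(r @ r)
        a = float(q0 @ r)
        b = float(q1 @ r)
        c = r @ Q2
        dterm = r @ W
        rss1 = np.maximum(yy - a * a - b * b - c ** 2 - dterm ** 2, 1e-300)
        f = dterm ** 2 / (rss1 / (n - 4))
        f = np.where(ok, f, np.nan)
        return f, Q2, W

    def _perm_max_f(self, R, x1, Q2, W, batch: int = 100) -> np.ndarray:
        n = R.shape[1]
        q0 = np.ones(n) / np.sqrt(n)
        q1 = self._orthonormalise(x1.copy(), [q0])
        live = (np.abs(W) > 0).any(axis=0)
        out = np.empty(R.shape[0])
        if not live.any():
            out.fill(np.nan)
            return out
        for s in range(0, R.shape[0], batch):
            Rb = R[s : s + batch]
            yy = (Rb ** 2).sum(axis=1)
            a = Rb @ q0
            b = Rb @ q1
            C = Rb @ Q2
            D = Rb @ W
            rss1 = np.maximum(
                yy[:, None] - a[:, None] ** 2 - b[:, None] ** 2 - C ** 2 - D ** 2,
                1e-300,
            )
            f = D ** 2 / (rss1 / (n - 4))
            f[:, ~live] = np.nan
            out[s : s + batch] = np.nanmax(f, axis=1)
        return out

    def fit(
        self,
        geno: GenotypeMatrix,
        fit_model: PolygenicModel,
        targets: list[str],
        trait: str = "",
    ) -> "EpistasisScan":
        if not targets:
            raise ValueError("empty target list")
        mask = fit_model.complete_cases_
        r = fit_model.residuals_
        breeds = geno.samples["breed"].to_numpy()[mask]
        G = geno.codes[mask].astype(float)
        G[G == -1] = np.nan
        G = np.where(np.isnan(G), np.nanmean(G, axis=0), G)
        hard = np.rint(G).astype(int)
        pos = geno.snps["pos"].to_numpy()
        chrom = geno.snps["chrom"].to_numpy()
        ids = geno.snps["snp"].to_numpy()
        n = len(r)

        rng = np.random.default_rng(self.seed)
        rows = []
        self.null_max_f_ = {}
        sig_lv, sug_lv = self.levels
        for t in targets:
            j = geno.snp_index(t)
            x1 = G[:, j]
            near = (chrom == chrom[j]) & (np.abs(pos - pos[j]) <= self.exclude_bp)
            testable = ~near & (G.std(axis=0) > 0)
            # two-locus cell occupancy filter on hard calls
            cell_ok = np.ones(geno.n_snps, dtype=bool)
            for g1 in (0, 1, 2):
                sel = hard[:, j] == g1
                if not sel.any():
                    continue
                counts = np.stack(
                    [(hard[sel] == g2).sum(axis=0) for g2 in (0, 1, 2)]
                )
                cell_ok &= ~((counts > 0) & (counts < self.min_cell)).any(axis=0)
            testable &= cell_ok

            f, Q2, W = self._target_scan(r, x1, G, testable)
            R = _permute_within_breed(rng, r, breeds, self.n_perm)
            max_f = self._perm_max_f(R, x1, Q2, W)
            self.null_max_f_[t] = max_f
            thr_sig = float(np.quantile(max_f, 1 - sig_lv))
            thr_sug = float(np.quantile(max_f, 1 - sug_lv))

            for jj in np.flatnonzero(testable & np.isfinite(f)):
                fj = f[jj]
                p_emp = float((1 + (max_f >= fj).sum()) / (self.n_perm + 1))
                tier = ""
                if fj >= thr_sig:
                    tier = "5% significant"
                elif fj >= thr_sug:
                    tier = "10% suggestive"
                res = two_locus_ftest(r, x1, G[:, jj])
                res.target = ids[j]
                res.partner = ids[jj]
                res.trait = trait
                res.p_empirical = p_emp
                res.tier = tier
                rows.append(res)

        self.results_ = [x for x in rows if x.tier]
        columns = ["target", "partner", "trait", "a1", "a2", "a12",
                   "f_stat", "p_nominal", "p_empirical", "tier"]
        self.table_ = pd.DataFrame(
            [{c: getattr(x, c) for c in columns} for x in rows], columns=columns
        )
        return self


def epistasis_scan(
    geno, fit_model, targets, n_perm: int = 1000, seed: int = 0, trait: str = ""
) -> "EpistasisScan":
    """Functional wrapper over :class:`EpistasisScan`."""
    return EpistasisScan(n_perm=n_perm, seed=seed).fit(geno, fit_model, targets, trait)


def genotype_class_means(
    y: np.ndarray, x1: np.ndarray, x2: np.ndarray
) -> pd.DataFrame:
    """Two-locus genotype-class phenotype means (boxplot-ready export)."""
    rows = []
    x1 = np.asarray(x1)
    x2 = np.asarray(x2)
    for g1 in (0, 1, 2):
        for g2 in (0, 1, 2):
            sel = (x1 == g1) & (x2 == g2) & np.isfinite(y)
            if sel.any():
                rows.append((g1, g2, int(sel.sum()), float(np.mean(y[sel]))))
    return pd.DataFrame(rows, columns=["g1", "g2", "n", "mean"])
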