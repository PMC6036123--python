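"""Polygenic mixed-model engine: REML fit, GRAMMAR residuals, genomic control.

The null model per trait is ``y = F beta + G + e`` with ``cov(G)`` proportional
to the genome-wide IBS kinship and i.i.d. residuals.  The raw allele-sharing
matrix carries a large constant baseline that is confounded with the
intercept, so the fit uses the Gower-centred, trace-normalised kinship; it is
eigen-decomposed once and the REML log-likelihood is profiled over the
heritability ratio with a bounded 1-D optimiser.

Two per-marker second steps are provided:

* ``mmscore`` (default) — the variance-weighted score test
  ``(x_c' V^-1 e)^2 / (x_c' V^-1 x_c)`` on the fixed-effect residuals
  ``e = y - F beta``, which stays calibrated (lambda ~ 1) under strong
  structure;
* ``residual`` — plain OLS of the GRAMMAR residuals ``y - F beta - G_hat`` on
  the genotype, the simple-regression reading of the two-step procedure
  (conservative under strong relatedness).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import optimize, stats

from .data import MISSING, FixedEffectDesign

_CHI2_MEDIAN = float(stats.chi2.ppf(0.5, df=1))  # 0.4549...


def gower_center(K: np.ndarray, ridge_scale: float = 0.0) -> np.ndarray:
    """Double-centre a kinship matrix and normalise its mean diagonal to 1."""
    K = np.asarray(K, dtype=float)
    n = K.shape[0]
    rm = K.mean(axis=0)
    Kc = K - rm[None, :] - rm[:, None] + rm.mean()
    scale = np.trace(Kc) / n
    if scale <= 0:
        raise ValueError("degenerate kinship: non-positive centred trace")
    Kc = Kc / scale
    if ridge_scale > 0:
        Kc = Kc + ridge_scale * np.eye(n)
    return (Kc + Kc.T) / 2.0


class GCAdjustment:
    """Genomic-control result: inflation factor and corrected statistics."""

    def __init__(self, lambda_gc: float, corrected_stat: np.ndarray,
                 corrected_p: np.ndarray):
        if not lambda_gc > 0:
            raise ValueError("lambda must be positive")
        self.lambda_gc = lambda_gc
        self.corrected_stat = corrected_stat
        self.corrected_p = corrected_p


class PolygenicModel:
    """REML fit of the polygenic null model (sklearn-style estimator).

    Parameters
    ----------
    ridge_scale : float
        Ridge added to the centred kinship (times its mean diagonal) to
        guarantee positive semi-definiteness.
    method : {"mmscore", "residual"}
        Per-marker second-step flavour used by downstream scans.

    Fitted attributes: ``sigma2_g_``, ``sigma2_e_``, ``h2_``, ``beta_``,
    ``blup_``, ``residuals_`` (GRAMMAR), ``fixed_residuals_``, ``loglik_``,
    ``complete_cases_``.
    """

    def __init__(self, ridge_scale: float = 1e-6, method: str = "mmscore"):
        self.ridge_scale = ridge_scale
        self.method = method

    def get_params(self, deep: bool = True) -> dict:
        return {"ridge_scale": self.ridge_scale, "method": self.method}

    def set_params(self, **params) -> "PolygenicModel":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- fitting ------------------------------------------------------------
    def fit(self, y: np.ndarray, F, K: np.ndarray) -> "PolygenicModel":
        y = np.asarray(y, dtype=float)
        Fm = F.matrix if isinstance(F, FixedEffectDesign) else np.asarray(F, float)
        mask = np.isfinite(y)
        self.complete_cases_ = mask
        y = y[mask]
        X = Fm[mask]
        n, p = X.shape
        if np.std(y) == 0:
            raise ValueError("constant trait vector")

        Kt = gower_center(np.asarray(K, float)[np.ix_(mask, mask)],
                          ridge_scale=self.ridge_scale)
        d, U = np.linalg.eigh(Kt)
        # allele-sharing similarity is not guaranteed PSD; small negative
        # eigenvalues are clipped, badly indefinite input is an error
        if d.min() < -0.05 * max(1.0, d.max()):
            raise ValueError("kinship not PSD beyond ridge tolerance")
        d = np.maximum(d, 0.0)

        yt = U.T @ y
        Xt = U.T @ X

        def negremll(h2: float) -> float:
            return -self._remll(h2, yt, Xt, d, n, p)[0]

        res = optimize.minimize_scalar(
            negremll, bounds=(1e-6, 1 - 1e-6), method="bounded",
            options={"xatol": 1e-8},
        )
        h2_opt = float(res.x)
        at_zero = negremll(1e-12)
        if at_zero <= res.fun + 1e-9:
            h2_opt = 0.0
            if abs(at_zero - negremll(0.5)) < 1e-6:
                warnings.warn(
                    "variance components unidentifiable (kinship ~ identity);"
                    " returning boundary fit sigma2_g = 0"
                )

        ll, beta, s2g, s2e = self._remll(max(h2_opt, 1e-12), yt, Xt, d, n, p)
        if h2_opt == 0.0:
            s2g, s2e = 0.0, s2g + s2e
        self.h2_ = float(s2g / (s2g + s2e)) if (s2g + s2e) > 0 else 0.0
        self.sigma2_g_ = float(s2g)
        self.sigma2_e_ = float(s2e)
        self.beta_ = beta
        self.loglik_ = float(ll)
        self.design_ = X
        self.eigvals_ = d
        self._U = U
        self._v = h2_opt * d + (1.0 - h2_opt)   # V / sigma2_total shape
        self._s2 = s2g + s2e

        e = y - X @ beta
        self.fixed_residuals_ = e
        if s2g > 0:
            w = (s2g * d) / (s2g * d + s2e)
            ghat = U @ (w * (U.T @ e))
        else:
            ghat = np.zeros(n)
        self.blup_ = ghat
        self.residuals_ = e - ghat
        self.y_ = y
        return self

    @staticmethod
    def _remll(h2, yt, Xt, d, n, p):
        """Profiled REML log-likelihood at heritability ratio ``h2``."""
        v = h2 * d + (1.0 - h2)
        iv = 1.0 / v
        XtW = Xt * iv[:, None]
        XX = Xt.T @ XtW
        Xy = XtW.T @ yt
        beta = np.linalg.solve(XX, Xy)
        r = yt - Xt @ beta
        quad = float(r @ (iv * r))
        s2 = quad / (n - p)
        _, logdet_xx = np.linalg.slogdet(XX)
        ll = -0.5 * ((n - p) * np.log(s2) + np.log(v).sum() + logdet_xx + (n - p))
        return ll, beta, h2 * s2, (1.0 - h2) * s2

    # -- whitening (for the score test) -------------------------------------
    def whiten(self, M: np.ndarray) -> np.ndarray:
        """Multiply by V^{-1/2} (columns of M live on analysed samples)."""
        Mt = self._U.T @ M
        Mt = Mt * (1.0 / np.sqrt(self._v * self._s2)).reshape(
            -1, *([1] * (M.ndim - 1))
        )
        return self._U @ Mt

    def whitened_marker_residual(self, M: np.ndarray) -> np.ndarray:
        """Whiten marker columns and project off the whitened fixed design."""
        Mw = self.whiten(M)
        if not hasattr(self, "_design_q"):
            Xw = self.whiten(self.design_)
            self._design_q, _ = np.linalg.qr(Xw)
        Q = self._design_q
        return Mw - Q @ (Q.T @ Mw)


def _prepare_marker(x: np.ndarray) -> np.ndarray:
    """Mean-impute missing codes and return a float vector."""
    x = np.asarray(x, dtype=float).copy()
    x[x == MISSING] = np.nan
    if np.isnan(x).any():
        x = np.where(np.isnan(x), np.nanmean(x), x)
    return x


def _impute_matrix(X: np.ndarray) -> np.ndarray:
    G = np.asarray(X, dtype=float).copy()
    G[G == MISSING] = np.nan
    if np.isnan(G).any():
        mean = np.nanmean(G, axis=0)
        G = np.where(np.isnan(G), mean, G)
    return G


def residual_scan_matrix(residuals: np.ndarray, X: np.ndarray) -> dict:
    """OLS of GRAMMAR residuals on each column of an (n x m) code matrix."""
    r = np.asarray(residuals, dtype=float)
    G = _impute_matrix(X)
    n = len(r)
    Gc = G - G.mean(axis=0)
    sxx = (Gc ** 2).sum(axis=0)
    rc = r - r.mean()
    syy = float(rc @ rc)
    sxy = Gc.T @ rc
    testable = sxx > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / np.maximum(sxx, 1e-300)
        rss = np.maximum(syy - slope * sxy, 0.0)
        se = np.sqrt((rss / (n - 2)) / np.maximum(sxx, 1e-300))
        stat = (slope / np.maximum(se, 1e-300)) ** 2
    slope = np.where(testable, slope, np.nan)
    se = np.where(testable, se, np.nan)
    stat = np.where(testable, stat, np.nan)
    p = np.where(testable, stats.chi2.sf(stat, df=1), np.nan)
    return {"effect": slope, "se": se, "stat": stat, "p": p, "testable": testable}


def mmscore_scan_matrix(fit: PolygenicModel, X: np.ndarray) -> dict:
    """Variance-weighted score test of each marker against the null fit.

    The denominator projects the whitened marker off the whitened design
    (x' P x with P the GLS projection), so markers sharing structure with
    the fixed effects keep a calibrated null.
    """
    G = _impute_matrix(X)
    Gc = G - G.mean(axis=0)
    testable = (Gc ** 2).sum(axis=0) > 0
    Xw = fit.whitened_marker_residual(Gc)
    ew = fit.whiten(fit.fixed_residuals_)
    sxx = (Xw ** 2).sum(axis=0)
    sxy = Xw.T @ ew
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / np.maximum(sxx, 1e-300)
        se = 1.0 / np.sqrt(np.maximum(sxx, 1e-300))
        stat = sxy ** 2 / np.maximum(sxx, 1e-300)
    slope = np.where(testable, slope, np.nan)
    se = np.where(testable, se, np.nan)
    stat = np.where(testable, stat, np.nan)
    p = np.where(testable, stats.chi2.sf(stat, df=1), np.nan)
    return {"effect": slope, "se": se, "stat": stat, "p": p, "testable": testable}


def grammar_scan_matrix(fit_or_residuals, X: np.ndarray, method: str = "residual") -> dict:
    """Dispatch the per-marker second step over a genotype matrix.

    Accepts either a fitted :class:`PolygenicModel` (honouring its method)
    or a raw residual vector (residual regression only).
    """
    if isinstance(fit_or_residuals, PolygenicModel):
        fit = fit_or_residuals
        if fit.method == "mmscore":
            return mmscore_scan_matrix(fit, X)
        return residual_scan_matrix(fit.residuals_, X)
    if method == "mmscore":
        raise TypeError("mmscore needs the fitted PolygenicModel, not residuals")
    return residual_scan_matrix(np.asarray(fit_or_residuals, float), X)


def grammar_test(
    residuals: np.ndarray, x: np.ndarray, method: str = "residual"
) -> tuple[float, float, float, float]:
    """Single-marker GRAMMAR step: regression of residuals on the genotype.

    Returns (effect in grams per allele copy, SE, Wald chi-square, p);
    monomorphic markers return NaNs.  ``method='score'`` uses the null
    residual variance in the denominator instead of the OLS one.
    """
    r = np.asarray(residuals, dtype=float)
    x = _prepare_marker(x)
    n = len(r)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx <= 0:
        return (float("nan"),) * 4
    rc = r - r.mean()
    sxy = float(xc @ rc)
    syy = float(rc @ rc)
    slope = sxy / sxx
    if method == "score":
        se = np.sqrt((syy / n) / sxx)
    else:
        rss = max(syy - slope * sxy, 0.0)
        se = np.sqrt((rss / (n - 2)) / sxx)
    if se == 0:
        return slope, 0.0, float("inf"), 0.0
    stat = (slope / se) ** 2
    p = float(stats.chi2.sf(stat, df=1))
    return slope, float(se), float(stat), p


def genomic_lambda(statistics: np.ndarray, min_count: int = 100) -> GCAdjustment:
    """Median-based genomic-control lambda with divide-by-lambda correction.

    Lambda is the median chi-square statistic over its theoretical null
    median (0.4549); statistics are divided by lambda only when lambda > 1
    (the correction never deflates).  NaN entries (untestable markers) are
    ignored; infinite entries are an error.
    """
    stats_arr = np.asarray(statistics, dtype=float)
    finite = stats_arr[np.isfinite(stats_arr)]
    if finite.size == 0:
        raise ValueError("no finite statistics")
    if np.isinf(stats_arr).any():
        raise ValueError("non-finite statistics present")
    if finite.size < min_count:
        warnings.warn(f"lambda estimated from only {finite.size} statistics")
    lam = float(np.median(finite) / _CHI2_MEDIAN)
    factor = lam if lam > 1.0 else 1.0
    corrected = stats_arr / factor
    corrected_p = stats.chi2.sf(corrected, df=1)
    return GCAdjustment(lam, corrected, corrected_p)
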