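"""Phenotype-outlier screening and genotype quality control.

Phenotype screen: within each breed and week, records beyond 1.5 x IQR from
the quartiles are marked; marked-high records survive only when the bird is
consistently high through the rest of the growth phase, and birds losing more
than one third of their weekly records are dropped entirely.

Genotype QC order: (1) samples by call rate, (2) SNPs by call rate / MAF /
missing map position (marker statistics computed on the surviving samples),
(3) Z markers heterozygous in any female (a physically impossible call for
the hemizygous sex).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeMatrix, PhenotypeTable

REMOVAL_REASONS = {
    "sample_call_rate",
    "snp_call_rate",
    "maf",
    "no_position",
    "z_female_het",
    "phenotype_outlier_individual",
}


@dataclass
class QCReport:
    removed_samples: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["iid", "reason"])
    )
    removed_snps: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp", "reason"])
    )
    outlier_cells: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["iid", "trait", "action"])
    )
    counts: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "n_samples_removed": len(self.removed_samples),
            "n_snps_removed": len(self.removed_snps),
            "n_outlier_cells": len(self.outlier_cells),
            **self.counts,
        }


# ---------------------------------------------------------------------------
# phenotype screen
# ---------------------------------------------------------------------------

def phenotype_outlier_screen(
    pheno: PhenotypeTable,
    breeds: pd.Series | np.ndarray,
    consistent_high_frac: float = 0.5,
    drop_frac: float = 1 / 3,
) -> tuple[PhenotypeTable, QCReport]:
    """Apply the boxplot-style 1.5 x IQR outlier rule per breed and week.

    A marked-high record is retained only when the bird is marked-high in at
    least ``consistent_high_frac`` of the weeks from its first marked week
    onward ("consistently high through the growth phase"); low outliers are
    always blanked.  Birds with more than ``drop_frac`` of their week records
    blanked are removed outright.
    """
    breeds = np.asarray(breeds)
    w = pheno.weights.to_numpy(dtype=float).copy()
    n, n_weeks = w.shape
    high = np.zeros_like(w, dtype=bool)
    low = np.zeros_like(w, dtype=bool)

    for breed in np.unique(breeds):
        sel = breeds == breed
        for j in range(n_weeks):
            col = w[sel, j]
            ok = ~np.isnan(col)
            if ok.sum() < 4:
                warnings.warn(
                    f"breed {breed}, week {j}: <4 records, outlier screen skipped"
                )
                continue
            q1, q3 = np.percentile(col[ok], [25, 75])
            iqr = q3 - q1
            lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            rows = np.flatnonzero(sel)
            low[rows, j] = col < lo    # strict: exactly-at-fence is retained
            high[rows, j] = col > hi

    # consistently-high exemption
    keep_high = np.zeros(n, dtype=bool)
    for i in range(n):
        marked = np.flatnonzero(high[i])
        if marked.size == 0:
            continue
        first = marked[0]
        span = n_weeks - first
        keep_high[i] = marked.size / span >= consistent_high_frac

    cells = []
    removed = (low | high) & ~(high & keep_high[:, None])
    for i, j in zip(*np.nonzero(low | high)):
        action = "removed" if removed[i, j] else "retained_consistent_high"
        cells.append((pheno.ids.iloc[i], pheno.week_labels[j], action))
    w[removed] = np.nan

    # one-third rule on the number of blanked week records
    frac_removed = removed.sum(axis=1) / n_weeks
    drop = frac_removed > drop_frac
    report = QCReport(
        removed_samples=pd.DataFrame(
            {
                "iid": pheno.ids[drop].to_numpy(),
                "reason": "phenotype_outlier_individual",
            }
        ),
        outlier_cells=pd.DataFrame(cells, columns=["iid", "trait", "action"]),
        counts={
            "pheno_in": n,
            "pheno_kept": int((~drop).sum()),
            "pheno_dropped": int(drop.sum()),
        },
    )
    out = PhenotypeTable(
        pheno.ids[~drop],
        pd.DataFrame(w[~drop], columns=pheno.week_labels),
    )
    return out, report


# ---------------------------------------------------------------------------
# genotype QC
# ---------------------------------------------------------------------------

def _maf(codes: np.ndarray, female_z_mask: np.ndarray | None = None) -> np.ndarray:
    """Per-SNP MAF on non-missing calls; optionally excluding female Z calls."""
    g = codes.astype(float)
    g[codes == MISSING] = np.nan
    if female_z_mask is not None:
        g[female_z_mask] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        freq = np.nanmean(g, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    return np.where(np.isnan(maf), 0.0, maf)


def genotype_qc(
    geno: GenotypeMatrix,
    sample_cr: float = 0.9,
    snp_cr: float = 0.9,
    maf_min: float = 0.05,
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop low-call-rate samples, then failing SNPs, then female-het Z markers."""
    miss = geno.missing_mask()
    n, m = geno.codes.shape

    # (1) sample call rate
    cr_sample = 1.0 - miss.mean(axis=1)
    bad_sample = cr_sample < sample_cr
    if bad_sample.all():
        raise ValueError("genotype QC removed every sample")
    removed_samples = pd.DataFrame(
        {"iid": geno.samples["iid"][bad_sample].to_numpy(), "reason": "sample_call_rate"}
    )
    kept = geno.take_samples(np.flatnonzero(~bad_sample))

    # (2) SNP filters on surviving samples
    miss2 = kept.missing_mask()
    cr_snp = 1.0 - miss2.mean(axis=0)
    is_z = (kept.snps["chrom"] == "Z").to_numpy()
    female = (kept.samples["sex"] == 0).to_numpy()
    fz_mask = np.outer(female, is_z)
    maf = _maf(kept.codes, female_z_mask=fz_mask)
    pos = kept.snps["pos"].to_numpy()
    no_pos = ~np.isfinite(pos.astype(float)) | (pos.astype(float) <= 0)

    reason = np.full(kept.n_snps, "", dtype=object)
    reason[maf < maf_min] = "maf"
    reason[cr_snp < snp_cr] = "snp_call_rate"
    reason[no_pos] = "no_position"

    # (3) Z markers heterozygous in any female
    if female.any() and is_z.any():
        het_female = (kept.codes[female][:, is_z] == 1).any(axis=0)
        z_idx = np.flatnonzero(is_z)[het_female]
        for j in z_idx:
            if reason[j] == "":
                reason[j] = "z_female_het"

    bad_snp = reason != ""
    removed_snps = pd.DataFrame(
        {"snp": kept.snps["snp"][bad_snp].to_numpy(), "reason": reason[bad_snp]}
    )
    out = kept.take_snps(np.flatnonzero(~bad_snp))
    report = QCReport(
        removed_samples=removed_samples,
        removed_snps=removed_snps,
        counts={
            "samples_in": n,
            "samples_kept": out.n_samples,
            "snps_in": m,
            "snps_kept": out.n_snps,
        },
    )
    return out, report
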