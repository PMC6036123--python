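"""Core in-memory containers shared across the pipeline.

Genotypes are held as an individuals x SNPs matrix of allele-count codes
{0, 1, 2} with ``MISSING`` (-1) for no-calls; the code counts copies of
``allele2`` (the second-listed allele, PLINK convention).  Marker metadata and
sample metadata travel with the matrix as pandas DataFrames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: sentinel for a missing genotype call (never 0, which is a valid code)
MISSING: int = -1

SNP_COLUMNS = ["snp", "chrom", "pos", "allele1", "allele2"]
SAMPLE_COLUMNS = ["iid", "breed", "sex"]


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs genotype codes plus marker map and sample table.

    Parameters
    ----------
    codes : int8 ndarray, shape (n_samples, n_snps)
        Allele2 copy counts in {0, 1, 2}; ``MISSING`` marks no-calls.
    snps : DataFrame with columns snp, chrom, pos, allele1, allele2
        Marker map; ``pos`` is 1-based bp.  ``chrom`` is a string label
        ("1".."28", "Z", ...).
    samples : DataFrame with columns iid, breed, sex
        ``sex`` coded 0 = female, 1 = male (may be -1 if unknown).
    """

    codes: np.ndarray
    snps: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D (individuals x SNPs)")
        self.snps = self.snps.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        if self.codes.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} snps"
            )
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be in {0, 1, 2, MISSING}")
        if self.samples["iid"].duplicated().any():
            raise ValueError("duplicate individual ids")

    # -- basic properties ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.codes == MISSING

    def validate_map(self) -> None:
        """Check positions strictly increase within each chromosome."""
        for _, grp in self.snps.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions must strictly increase within chromosome")

    # -- subsetting ---------------------------------------------------------
    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.codes[idx], self.snps.copy(), self.samples.iloc[idx].copy()
        )

    def take_snps(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.codes[:, idx], self.snps.iloc[idx].copy(), self.samples.copy()
        )

    def breed_index(self, breed: str) -> np.ndarray:
        return np.flatnonzero((self.samples["breed"] == breed).to_numpy())

    def snp_index(self, snp_id: str) -> int:
        hits = np.flatnonzero((self.snps["snp"] == snp_id).to_numpy())
        if len(hits) != 1:
            raise KeyError(f"snp id {snp_id!r} not found (or duplicated)")
        return int(hits[0])


@dataclass
class PhenotypeTable:
    """Per-individual weekly body weights (grams) plus covariates.

    ``weights`` is a DataFrame indexed like ``ids`` with one column per week
    label (``BW0`` .. ``BW15`` by default); NaN marks a missing record.
    Birth weight (``BW0``) doubles as the birth-weight covariate.
    """

    ids: pd.Series
    weights: pd.DataFrame

    def __post_init__(self) -> None:
        self.ids = pd.Series(self.ids).reset_index(drop=True)
        self.weights = self.weights.reset_index(drop=True)
        if len(self.ids) != len(self.weights):
            raise ValueError("ids and weights row counts differ")
        w = self.weights.to_numpy(dtype=float)
        if np.nanmin(w, initial=0.0) < -1e-9:
            raise ValueError("body weights must be >= 0 or missing")
        if (w < 0).any():  # clip float-epsilon negatives from clamping
            self.weights = self.weights.clip(lower=0.0)

    @property
    def week_labels(self) -> list[str]:
        return list(self.weights.columns)

    def trait(self, label: str) -> np.ndarray:
        return self.weights[label].to_numpy(dtype=float)

    def copy(self) -> "PhenotypeTable":
        return PhenotypeTable(self.ids.copy(), self.weights.copy())


@dataclass
class FixedEffectDesign:
    """Design matrix for the fixed part of the polygenic model.

    Columns: intercept, breed one-hot (first level dropped), sex, birth
    weight, then any SNP covariates appended during conditional testing.
    """

    matrix: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("design matrix must be 2-D")
        if not self.names:
            self.names = [f"x{j}" for j in range(self.matrix.shape[1])]
        if len(self.names) != self.matrix.shape[1]:
            raise ValueError("names length must equal column count")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def with_covariate(self, column: np.ndarray, name: str) -> "FixedEffectDesign":
        column = np.asarray(column, dtype=float).reshape(-1, 1)
        return FixedEffectDesign(np.hstack([self.matrix, column]), self.names + [name])

    def check_rank(self) -> None:
        rank = np.linalg.matrix_rank(self.matrix)
        if rank < self.matrix.shape[1]:
            raise ValueError("fixed-effect design is rank deficient")


def build_design(
    samples: pd.DataFrame,
    birth_weight: np.ndarray | None = None,
) -> FixedEffectDesign:
    """Assemble mean + breed + sex (+ birth weight) design from a sample table.

    The first breed level (alphabetical) is the reference and is dropped so
    the design keeps full column rank alongside the intercept.
    """
    n = len(samples)
    cols = [np.ones(n)]
    names = ["intercept"]
    breeds = sorted(samples["breed"].unique())
    for b in breeds[1:]:
        cols.append((samples["breed"] == b).to_numpy(dtype=float))
        names.append(f"breed[{b}]")
    sex = samples["sex"].to_numpy(dtype=float)
    if np.unique(sex[sex >= 0]).size > 1:
        cols.append(sex)
        names.append("sex")
    if birth_weight is not None:
        bw = np.asarray(birth_weight, dtype=float)
        cols.append(bw - np.nanmean(bw))
        names.append("birth_weight")
    return FixedEffectDesign(np.column_stack(cols), names)
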