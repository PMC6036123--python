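"""Readers and writers for the formats the pipeline touches.

Supports PLINK text (.ped/.map) and binary (.bed/.bim/.fam) genotype layouts,
the phenotype CSV (id, breed, sex, BW0..BW15), results TSVs with a fixed
column order, a flat key=value config format, and import of external
association tables for cross-method co-localization.

Genotype codes count copies of allele2.  In the text dialect the map file
carries no allele listing, so alleles are normalised lexicographically
(allele1 < allele2) on load; the binary dialect keeps the bim's A1/A2 order.
A ped/map marker at which only one allele is observed is inherently
ambiguous and loads as code 0 with a collapsed allele pair; round trips are
exact for markers with both alleles observed (the bed dialect is always
exact).
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeMatrix, PhenotypeTable

RESULT_COLUMNS = ["snp", "chr", "pos", "trait", "effect", "se", "stat", "p_raw", "p_gc"]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit codes in SNP-major .bed files: 00 hom A1, 01 missing, 10 het, 11 hom A2
_BED_DECODE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_BED_ENCODE = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}


class PlinkFormatError(ValueError):
    """Raised when PLINK companion files disagree or are malformed."""


# ---------------------------------------------------------------------------
# ped/map
# ---------------------------------------------------------------------------

def _read_map(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            chrom, snp, _cm, pos = parts[:4]
            rows.append((snp, chrom, int(pos)))
    df = pd.DataFrame(rows, columns=["snp", "chrom", "pos"])
    if df["snp"].duplicated().any():
        raise PlinkFormatError("duplicated marker id in map file")
    return df


def _read_ped_map(prefix: Path) -> GenotypeMatrix:
    snps = _read_map(prefix.with_suffix(".map"))
    m = len(snps)
    iids, breeds, sexes, rows = [], [], [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise PlinkFormatError(
                    f"ped row has {len(parts)} fields, expected {6 + 2 * m}"
                )
            fid, iid, _pat, _mat, sex, _phe = parts[:6]
            iids.append(iid)
            breeds.append(fid)
            # ped sex: 1 male, 2 female, 0 unknown -> internal 1/0/-1
            sexes.append({"1": 1, "2": 0}.get(sex, -1))
            rows.append(parts[6:])
    alleles = np.array(rows, dtype="U1").reshape(len(rows), m, 2)

    codes = np.empty((len(rows), m), dtype=np.int8)
    a1s, a2s = [], []
    for j in range(m):
        col = alleles[:, j, :]
        obs = np.unique(col[col != "0"])
        if len(obs) > 2:
            raise PlinkFormatError(f"marker {snps['snp'][j]} has >2 alleles")
        if len(obs) == 0:
            a1, a2 = "0", "0"
        elif len(obs) == 1:
            a1, a2 = obs[0], obs[0]
        else:
            a1, a2 = sorted(obs)  # lexicographic normalisation
        a1s.append(a1)
        a2s.append(a2)
        miss = (col == "0").any(axis=1)
        codes[:, j] = (col == a2).sum(axis=1).astype(np.int8)
        if a1 == a2:  # monomorphic: count of the single allele is 2 -> code 0
            codes[:, j] = 0
        codes[miss, j] = MISSING

    snps = snps.assign(allele1=a1s, allele2=a2s)
    samples = pd.DataFrame({"iid": iids, "breed": breeds, "sex": sexes})
    return GenotypeMatrix(codes, snps[["snp", "chrom", "pos", "allele1", "allele2"]], samples)


def _write_ped_map(geno: GenotypeMatrix, prefix: Path) -> None:
    snps = geno.snps
    with open(prefix.with_suffix(".map"), "w") as fh:
        for _, r in snps.iterrows():
            fh.write(f"{r.chrom}\t{r.snp}\t0\t{r.pos}\n")
    a1 = snps["allele1"].to_numpy()
    a2 = snps["allele2"].to_numpy()
    pair = {0: (a1, a1), 1: (a1, a2), 2: (a2, a2)}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i in range(geno.n_samples):
            s = geno.samples.iloc[i]
            sex = {1: "1", 0: "2"}.get(int(s.sex), "0")
            fields = [str(s.breed), str(s.iid), "0", "0", sex, "-9"]
            row = geno.codes[i]
            for j in range(geno.n_snps):
                c = int(row[j])
                if c == MISSING:
                    fields += ["0", "0"]
                else:
                    x, y = pair[c]
                    fields += [x[j], y[j]]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# bed/bim/fam
# ---------------------------------------------------------------------------

def _read_bed(prefix: Path) -> GenotypeMatrix:
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "allele1", "allele2"],
        dtype={"chrom": str, "snp": str, "allele1": str, "allele2": str},
    )
    if bim["snp"].duplicated().any():
        raise PlinkFormatError("duplicated marker id in bim file")
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "phe"],
        dtype={"fid": str, "iid": str},
    )
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise PlinkFormatError("bad bed magic bytes (need SNP-major v1 layout)")
    bps = (n + 3) // 4  # bytes per SNP block
    body = raw[3:]
    if body.size != bps * m:
        raise PlinkFormatError("bed payload size disagrees with bim/fam counts")
    blocks = body.reshape(m, bps)
    # unpack 2-bit fields, little-endian within each byte
    shifts = np.arange(4, dtype=np.uint8) * 2
    two_bit = (blocks[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = _BED_DECODE[two_bit.reshape(m, -1)[:, :n]].T.copy()

    snps = bim[["snp", "chrom", "pos", "allele1", "allele2"]]
    sex = fam["sex"].map({1: 1, 2: 0}).fillna(-1).astype(int)
    samples = pd.DataFrame({"iid": fam["iid"], "breed": fam["fid"], "sex": sex})
    return GenotypeMatrix(codes, snps, samples)


def _write_bed(geno: GenotypeMatrix, prefix: Path) -> None:
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for _, r in geno.snps.iterrows():
            fh.write(f"{r.chrom}\t{r.snp}\t0\t{r.pos}\t{r.allele1}\t{r.allele2}\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for _, s in geno.samples.iterrows():
            sex = {1: "1", 0: "2"}.get(int(s.sex), "0")
            fh.write(f"{s.breed}\t{s.iid}\t0\t0\t{sex}\t-9\n")
    n, m = geno.n_samples, geno.n_snps
    bps = (n + 3) // 4
    lut = np.zeros(256, dtype=np.uint8)
    for code, bits in _BED_ENCODE.items():
        lut[code & 0xFF] = bits  # MISSING (-1) wraps to 255
    padded = np.zeros((m, bps * 4), dtype=np.uint8)
    padded[:, :n] = lut[geno.codes.T.astype(np.uint8)]
    shifts = np.arange(4, dtype=np.uint8) * 2
    blocks = (padded.reshape(m, bps, 4) << shifts[None, None, :]).sum(axis=2)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(blocks.astype(np.uint8).tobytes())


# ---------------------------------------------------------------------------
# public surface
# ---------------------------------------------------------------------------

def read_plink(prefix, dialect: str = "ped_map") -> GenotypeMatrix:
    """Load a PLINK fileset; ``dialect`` is ``ped_map`` or ``bed``."""
    prefix = Path(prefix)
    if dialect == "ped_map":
        return _read_ped_map(prefix)
    if dialect == "bed":
        return _read_bed(prefix)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_plink(geno: GenotypeMatrix, prefix, dialect: str = "ped_map") -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "ped_map":
        _write_ped_map(geno, prefix)
    elif dialect == "bed":
        _write_bed(geno, prefix)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_phenotypes(path) -> tuple[PhenotypeTable, pd.DataFrame]:
    """Load the phenotype CSV: id, breed, sex, then week columns BW0..BWk.

    Returns the PhenotypeTable plus the id/breed/sex sample frame.
    """
    df = pd.read_csv(path, dtype={"id": str, "breed": str})
    week_cols = [c for c in df.columns if c.upper().startswith("BW")]
    meta = pd.DataFrame(
        {"iid": df["id"], "breed": df["breed"], "sex": df["sex"].astype(int)}
    )
    return PhenotypeTable(df["id"], df[week_cols].astype(float)), meta


def write_phenotypes(pheno: PhenotypeTable, meta: pd.DataFrame, path) -> None:
    out = pd.DataFrame({"id": pheno.ids})
    out["breed"] = meta["breed"].to_numpy()
    out["sex"] = meta["sex"].to_numpy()
    for c in pheno.week_labels:
        out[c] = pheno.weights[c].to_numpy()
    out.to_csv(path, index=False, float_format="%.6g")


def write_results(table: pd.DataFrame, path) -> None:
    """Write a results TSV with the fixed column order and %.6g floats."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [c for c in RESULT_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    table[cols + extra].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_external_table(path) -> pd.DataFrame:
    """Import an external association table (columns snp, chr, pos, p).

    Used for cross-method co-localization: QTLs supported by an external
    scan within the merge window are retained even when single-trait.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype={"snp": str, "chr": str})
    required = {"snp", "chr", "pos", "p"}
    if not required.issubset(df.columns):
        raise ValueError(f"external table needs columns {sorted(required)}")
    return df


def read_config(path) -> dict:
    """Parse a flat ``key = value`` config file; '#' starts a comment."""
    out: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"bad config line: {line!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            out[key] = _coerce(val)
    return out


def _coerce(val: str):
    for cast in (int, float):
        try:
            return cast(val)
        except ValueError:
            pass
    if val.lower() in {"true", "false"}:
        return val.lower() == "true"
    if "," in val:
        return [_coerce(v.strip()) for v in val.split(",")]
    return val


def file_digest(path) -> str:
    """Short sha256 digest of a file, for run logs."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]
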