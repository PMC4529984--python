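"""Genotype, GRM, and tabular file formats plus the shared domain types.

The formats handled here are the de-facto standards of SNP-array genetics:

* PLINK 1 binary genotypes (``.bed``/``.bim``/``.fam``, SNP-major v1.00),
  decoded bit-exactly from the 2-bit encoding;
* GCTA binary genetic relationship matrices (``.grm.bin`` float32 lower
  triangle, ``.grm.id``, optional ``.grm.N.bin``);
* delimited phenotype/covariate/summary-statistic tables aligned to the
  genotype sample order, which is canonical throughout the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1  # sentinel for a missing genotype in GenotypeMatrix.counts

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "PhenotypeVector",
    "CovariateMatrix",
    "SummaryStats",
    "read_plink",
    "write_plink",
    "read_gcta_grm",
    "write_gcta_grm",
    "read_phenotype_table",
    "read_covariate_table",
    "read_summary_stats",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Minor-allele counts for ``N_total`` samples at ``P`` biallelic SNPs.

    ``counts`` holds values in {0, 1, 2} with :data:`MISSING` (-1) marking a
    missing call. ``allele_freqs`` is optional and, when present, holds the
    *true* per-SNP allele frequency (known in simulations, strictly inside
    (0, 1)) used by the true-frequency standardization convention.
    """

    counts: np.ndarray
    sample_ids: list[str]
    snp_ids: list[str]
    allele_freqs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n, p = self.counts.shape
        if len(self.sample_ids) != n or len(self.snp_ids) != p:
            raise ValueError("id lists do not match counts shape")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids are not unique")
        if len(set(self.snp_ids)) != p:
            raise ValueError("snp_ids are not unique")
        valid = np.isin(self.counts, (0, 1, 2, MISSING))
        if not valid.all():
            bad = self.counts[~valid].ravel()[0]
            raise ValueError(f"genotype count {bad!r} outside {{0,1,2,missing}}")
        if self.allele_freqs is not None:
            self.allele_freqs = np.asarray(self.allele_freqs, dtype=float)
            if self.allele_freqs.shape != (p,):
                raise ValueError("allele_freqs length must equal SNP count")
            if not ((self.allele_freqs > 0) & (self.allele_freqs < 1)).all():
                raise ValueError("allele_freqs must lie strictly inside (0, 1)")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_snps(self) -> int:
        return self.counts.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.counts == MISSING

    def imputed(self) -> np.ndarray:
        """Counts as float with missing entries replaced by the SNP mean.

        Per-SNP mean imputation of the non-missing counts keeps the linear
        algebra dense; the missingness mask stays available for reporting.
        """
        out = self.counts.astype(float)
        miss = self.missing_mask
        if miss.any():
            masked = np.ma.masked_array(out, mask=miss)
            col_means = masked.mean(axis=0).filled(np.nan)
            if np.isnan(col_means).any():
                j = int(np.flatnonzero(np.isnan(col_means))[0])
                raise ValueError(f"SNP {self.snp_ids[j]!r} has no observed genotypes")
            out[miss] = np.broadcast_to(col_means, out.shape)[miss]
        return out


@dataclass
class PhenotypeVector:
    """A quantitative outcome aligned to a genotype sample set."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.sample_ids) != self.values.size:
            raise ValueError("sample_ids length must match values")
        if not np.isfinite(self.values).all():
            raise ValueError("phenotype values must be finite")


@dataclass
class CovariateMatrix:
    """Confounders Z (N×K) with an explicit intercept column by construction."""

    values: np.ndarray
    sample_ids: list[str]
    column_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        n, k = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length must match rows")
        if not self.column_names:
            self.column_names = [f"covar{j}" for j in range(k)]
        if len(self.column_names) != k:
            raise ValueError("column_names length must match columns")
        if np.linalg.matrix_rank(self.values) < k:
            raise ValueError("covariate matrix is rank deficient "
                             f"(rank < K={k}); drop a redundant column")

    @classmethod
    def intercept_only(cls, sample_ids: list[str]) -> "CovariateMatrix":
        n = len(sample_ids)
        return cls(np.ones((n, 1)), list(sample_ids), ["intercept"])


@dataclass
class SummaryStats:
    """Per-SNP t statistics from an external association study."""

    snp_ids: list[str]
    t_stats: np.ndarray

    def __post_init__(self) -> None:
        self.t_stats = np.asarray(self.t_stats, dtype=float).ravel()
        if len(self.snp_ids) != self.t_stats.size:
            raise ValueError("snp_ids length must match t_stats")
        if not np.isfinite(self.t_stats).all():
            raise ValueError("t statistics must be finite")

    def aligned_to(self, snp_ids: list[str]) -> np.ndarray:
        """t statistics reordered to a genotype SNP order."""
        index = {s: i for i, s in enumerate(self.snp_ids)}
        try:
            rows = [index[s] for s in snp_ids]
        except KeyError as exc:
            raise KeyError(f"SNP {exc.args[0]!r} missing from summary stats") from None
        return self.t_stats[list(rows)]


# ---------------------------------------------------------------------------
# PLINK 1 binary (.bed/.bim/.fam)
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes((0x6C, 0x1B))
# 2-bit codes in a SNP-major v1.00 .bed, per pair of bits (little-endian
# within the byte): 0b00 hom A1, 0b01 missing, 0b10 het, 0b11 hom A2.
# Counts below are copies of the .bim allele-2 (the counted allele).
_CODE_TO_COUNT = np.array([0, MISSING, 1, 2], dtype=np.int8)
_COUNT_TO_CODE = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}


def read_plink(bed_path, bim_path=None, fam_path=None) -> GenotypeMatrix:
    """Decode a PLINK 1 binary fileset into a :class:`GenotypeMatrix`.

    Only the SNP-major (mode byte 0x01) v1.00 layout is supported; the
    individual-major dialect raises a format error.
    """
    bed_path = Path(bed_path)
    bim_path = Path(bim_path) if bim_path else bed_path.with_suffix(".bim")
    fam_path = Path(fam_path) if fam_path else bed_path.with_suffix(".fam")

    bim = pd.read_csv(bim_path, sep=r"\s+", header=None,
                      names=["chrom", "snp", "cm", "pos", "a1", "a2"],
                      dtype={"snp": str})
    fam = pd.read_csv(fam_path, sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"],
                      dtype={"fid": str, "iid": str})
    n, p = len(fam), len(bim)

    raw = bed_path.read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise ValueError(f"{bed_path}: not a PLINK .bed file (bad magic bytes)")
    if len(raw) < 3 or raw[2] != 0x01:
        raise ValueError(f"{bed_path}: only SNP-major .bed (mode byte 0x01) is supported")
    bytes_per_snp = (n + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != bytes_per_snp * p:
        raise ValueError(f"{bed_path}: payload has {payload.size} bytes, "
                         f"expected {bytes_per_snp * p} for N={n}, P={p}")

    blocks = payload.reshape(p, bytes_per_snp)
    # expand each byte into its four 2-bit genotype codes, sample-fastest
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (blocks[:, :, None] >> shifts) & 0x03
    codes = codes.reshape(p, bytes_per_snp * 4)[:, :n]
    counts = _CODE_TO_COUNT[codes].T.copy()

    return GenotypeMatrix(counts, list(fam["iid"]), list(bim["snp"]))


def write_plink(gm: GenotypeMatrix, prefix) -> None:
    """Write a GenotypeMatrix as a PLINK 1 SNP-major fileset (test/export aid)."""
    prefix = Path(prefix)
    n, p = gm.counts.shape
    bytes_per_snp = (n + 3) // 4
    codes = np.zeros((p, bytes_per_snp * 4), dtype=np.uint8)
    counts_t = gm.counts.T
    for value, code in _COUNT_TO_CODE.items():
        codes[:, :n][counts_t == value] = code
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (codes.reshape(p, bytes_per_snp, 4) << shifts).sum(axis=2).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + b"\x01")
        fh.write(packed.tobytes())
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for snp in gm.snp_ids:
            fh.write(f"1\t{snp}\t0\t0\tA\tB\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for iid in gm.sample_ids:
            fh.write(f"{iid}\t{iid}\t0\t0\t0\t-9\n")


# ---------------------------------------------------------------------------
# GCTA binary GRM
# ---------------------------------------------------------------------------

def read_gcta_grm(prefix) -> tuple[np.ndarray, list[str]]:
    """Read a GCTA binary GRM triplet; returns the symmetric matrix and ids.

    ``.grm.bin`` stores the lower triangle (including the diagonal) row by
    row as float32; ``.grm.id`` is a two-column FID/IID text file. Any
    ``.grm.N.bin`` companion is ignored on read.
    """
    prefix = Path(prefix)
    ids_df = pd.read_csv(prefix.with_suffix(".grm.id"), sep=r"\s+", header=None,
                         names=["fid", "iid"], dtype=str)
    n = len(ids_df)
    stream = np.fromfile(prefix.with_suffix(".grm.bin"), dtype=np.float32)
    expected = n * (n + 1) // 2
    if stream.size != expected:
        raise ValueError(f"{prefix}.grm.bin holds {stream.size} float32 values, "
                         f"expected N(N+1)/2 = {expected} for N={n}")
    mat = np.zeros((n, n), dtype=np.float32)
    tril = np.tril_indices(n)
    mat[tril] = stream
    mat = mat + np.tril(mat, -1).T
    return mat.astype(np.float64), list(ids_df["iid"])


def write_gcta_grm(prefix, matrix: np.ndarray, ids: list[str],
                   n_snps: int | None = None) -> None:
    """Write a symmetric matrix in GCTA binary GRM format.

    ``.grm.N.bin`` (per-pair SNP counts) is written as the constant ``n_snps``
    when given, matching how GCTA records complete-data GRMs.
    """
    prefix = Path(prefix)
    matrix = np.asarray(matrix)
    n = len(ids)
    if matrix.shape != (n, n):
        raise ValueError("matrix shape does not match id count")
    tril = np.tril_indices(n)
    matrix[tril].astype(np.float32).tofile(prefix.with_suffix(".grm.bin"))
    with open(prefix.with_suffix(".grm.id"), "w") as fh:
        for iid in ids:
            fh.write(f"{iid}\t{iid}\n")
    if n_snps is not None:
        np.full(n * (n + 1) // 2, n_snps, dtype=np.float32).tofile(
            prefix.with_suffix(".grm.N.bin"))


# ---------------------------------------------------------------------------
# delimited tables
# ---------------------------------------------------------------------------

def _read_aligned(path, id_column, value_columns, sample_ids) -> tuple[np.ndarray, int]:
    df = pd.read_csv(path, sep=None, engine="python", dtype={id_column: str})
    if df[id_column].duplicated().any():
        dup = df.loc[df[id_column].duplicated(), id_column].iloc[0]
        raise ValueError(f"{path}: duplicate id {dup!r}")
    if value_columns is None:
        value_columns = [c for c in df.columns if c != id_column]
    for col in value_columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"{path}: non-numeric value in column {col!r}, row {row}")
    df = df.set_index(id_column)
    extra = df.index.difference(sample_ids)
    if len(extra):
        warnings.warn(f"{path}: dropped {len(extra)} row(s) with ids absent "
                      "from the genotype data", stacklevel=3)
    missing = [s for s in sample_ids if s not in df.index]
    if missing:
        raise KeyError(f"{path}: no row for genotype sample {missing[0]!r} "
                       f"({len(missing)} missing in total)")
    values = df.loc[list(sample_ids), value_columns].to_numpy(dtype=float)
    return values, list(value_columns)


def read_phenotype_table(path, sample_ids, id_column="IID",
                         value_column=None) -> PhenotypeVector:
    """Read a one-trait phenotype table, reordered to the genotype sample order."""
    cols = [value_column] if value_column else None
    values, _cols = _read_aligned(path, id_column, cols, sample_ids)
    if values.shape[1] != 1:
        raise ValueError(f"{path}: expected exactly one phenotype column, "
                         f"got {values.shape[1]}; pass value_column")
    return PhenotypeVector(values[:, 0], list(sample_ids))


def read_covariate_table(path, sample_ids, id_column="IID",
                         value_columns=None) -> CovariateMatrix:
    """Read covariates, append an intercept, and align to the genotype order."""
    values, used_cols = _read_aligned(path, id_column, value_columns, sample_ids)
    with_intercept = np.column_stack([np.ones(len(sample_ids)), values])
    return CovariateMatrix(with_intercept, list(sample_ids),
                           ["intercept"] + used_cols)


def read_summary_stats(path, id_column="SNP", t_column="T") -> SummaryStats:
    """Read external GWAS t statistics, one row per SNP."""
    df = pd.read_csv(path, sep=None, engine="python", dtype={id_column: str})
    if df[id_column].duplicated().any():
        raise ValueError(f"{path}: duplicate SNP ids")
    return SummaryStats(list(df[id_column]), df[t_column].to_numpy(dtype=float))
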