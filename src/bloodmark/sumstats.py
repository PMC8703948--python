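"""GWAS / QTL summary statistics: containers, I/O, harmonization, LD.

Summary statistics are held as a pandas DataFrame with a fixed schema
(one row per variant association); an :class:`LDMatrix` carries the SNP x SNP
dosage correlation for a locus. Harmonization aligns a molecule's QTL table
and a disease GWAS table onto shared variants with consistent effect alleles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import ridge_invert

log = logging.getLogger(__name__)

#: canonical column order of a summary-statistics table
SUMSTAT_COLUMNS = ["snp", "chrom", "pos", "a1", "a2", "freq", "beta", "se", "p", "n"]

#: header names used by the tab-separated on-disk format
FILE_HEADER = ["SNP", "CHR", "BP", "A1", "A2", "FREQ", "BETA", "SE", "P", "N"]

_VALID_ALLELES = {"A", "C", "G", "T"}
_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class SumStats:
    """One association record set: a GWAS, or one molecule's QTLs.

    ``kind`` is "molecule" or "disease"; ``omic`` tags molecules by layer
    (RNA / methylation / protein / cytokine / metabolite / none).
    """

    table: pd.DataFrame
    trait: str = ""
    kind: str = "molecule"
    omic: str = "none"

    def __post_init__(self):
        missing = [c for c in SUMSTAT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"summary statistics missing columns: {missing}")
        if self.table["snp"].duplicated().any():
            raise ValueError("snp ids must be unique within a SumStats table")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class LDMatrix:
    """Symmetric SNP x SNP dosage correlation with unit diagonal."""

    snps: list[str]
    r: np.ndarray
    ridge_repaired: bool = False
    flagged_constant: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.snps)
        if self.r.shape != (k, k):
            raise ValueError("LD matrix shape does not match SNP list")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        if np.nanmax(np.abs(self.r)) > 1.0 + 1e-8:
            raise ValueError("LD correlations must lie in [-1, 1]")

    def subset(self, snps: list[str]) -> "LDMatrix":
        idx = [self.snps.index(s) for s in snps]
        return LDMatrix(list(snps), self.r[np.ix_(idx, idx)],
                        ridge_repaired=self.ridge_repaired)

    def r2(self, a: str, b: str) -> float:
        i, j = self.snps.index(a), self.snps.index(b)
        return float(self.r[i, j] ** 2)


def read_sumstats(path, column_map: dict[str, str] | None = None, *,
                  trait: str = "", kind: str = "molecule",
                  omic: str = "none", sep: str = "\t") -> SumStats:
    """Read a tab-separated summary-statistics file into a :class:`SumStats`.

    ``column_map`` maps canonical names (see :data:`SUMSTAT_COLUMNS`) to file
    headers; the default expects the package's own SNP/CHR/BP/... header.
    Malformed rows (non-numeric beta/se/p, se <= 0, p outside (0, 1]) are
    dropped with a logged count. Duplicate snp ids keep the smallest-p record.
    """
    mapping = dict(zip(SUMSTAT_COLUMNS, FILE_HEADER))
    if column_map:
        mapping.update(column_map)
    raw = pd.read_csv(path, sep=sep, dtype=str)
    missing = [v for v in mapping.values() if v not in raw.columns]
    if missing:
        raise ValueError(f"mandatory column(s) missing from {path}: {missing}")
    df = raw.rename(columns={v: k for k, v in mapping.items()})[SUMSTAT_COLUMNS].copy()
    n_in = len(df)
    for col in ("pos", "freq", "beta", "se", "p", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("a1", "a2"):
        df[col] = df[col].astype(str).str.upper()
    ok = (
        df["snp"].notna()
        & df["beta"].notna()
        & (df["se"] > 0)
        & (df["p"] > 0)
        & (df["p"] <= 1)
        & df["a1"].isin(_VALID_ALLELES)
        & df["a2"].isin(_VALID_ALLELES)
    )
    df = df[ok]
    dropped = n_in - len(df)
    if dropped:
        log.warning("read_sumstats(%s): dropped %d malformed row(s)", path, dropped)
    if df["snp"].duplicated().any():
        n_dup = int(df["snp"].duplicated().sum())
        log.warning("read_sumstats(%s): %d duplicate snp id(s); keeping smallest p",
                    path, n_dup)
        df = df.sort_values(["snp", "p"], kind="mergesort").drop_duplicates("snp")
    if df.empty:
        raise ValueError(f"no valid rows in {path}")
    # z/p consistency is advisory: GWAS files often store truncated p
    from scipy import stats as _st
    z = np.abs(df["beta"] / df["se"])
    p_from_z = 2.0 * _st.norm.sf(z)
    bad = (df["p"] > np.minimum(1.0, p_from_z * 10)) | (df["p"] * 10 < p_from_z)
    if bad.any():
        log.warning("read_sumstats(%s): %d row(s) with p inconsistent with beta/se",
                    path, int(bad.sum()))
    return SumStats(df.reset_index(drop=True), trait=trait, kind=kind, omic=omic)


def write_sumstats(ss: SumStats, path, sep: str = "\t") -> None:
    out = ss.table[SUMSTAT_COLUMNS].copy()
    out.columns = FILE_HEADER
    out.to_csv(path, sep=sep, index=False)


def _is_palindromic(a1: str, a2: str) -> bool:
    return (a1, a2) in _PALINDROMIC


def harmonize(molecule: SumStats, disease: SumStats) -> pd.DataFrame:
    """Pair molecule-QTL and disease-GWAS records on shared, allele-aligned SNPs.

    Returns a DataFrame with one row per retained SNP and columns
    ``snp, chrom, pos, a1, a2, beta_qtl, se_qtl, p_qtl, beta_gwas, se_gwas,
    p_gwas, n_qtl, n_gwas``. When the disease record's effect allele equals the
    molecule's other allele, the disease beta sign is flipped (alleles swapped);
    strand-ambiguous (A/T, C/G) SNPs and irreconcilable allele pairs are
    dropped and counted in the log.
    """
    if len(molecule) == 0 or len(disease) == 0:
        raise ValueError("harmonize requires two nonempty tables")
    m = molecule.table.set_index("snp")
    d = disease.table.set_index("snp")
    shared = m.index.intersection(d.index)
    if shared.empty:
        raise ValueError("no shared SNPs between molecule and disease tables")
    rows = []
    n_pal = n_mismatch = 0
    for snp in shared:
        mr, dr = m.loc[snp], d.loc[snp]
        if _is_palindromic(mr["a1"], mr["a2"]):
            n_pal += 1
            continue
        beta_d = dr["beta"]
        if (dr["a1"], dr["a2"]) == (mr["a1"], mr["a2"]):
            pass
        elif (dr["a1"], dr["a2"]) == (mr["a2"], mr["a1"]):
            beta_d = -beta_d
        else:
            n_mismatch += 1
            continue
        rows.append({
            "snp": snp, "chrom": mr["chrom"], "pos": int(mr["pos"]),
            "a1": mr["a1"], "a2": mr["a2"],
            "beta_qtl": float(mr["beta"]), "se_qtl": float(mr["se"]),
            "p_qtl": float(mr["p"]),
            "beta_gwas": float(beta_d), "se_gwas": float(dr["se"]),
            "p_gwas": float(dr["p"]),
            "n_qtl": float(mr["n"]), "n_gwas": float(dr["n"]),
        })
    if n_pal or n_mismatch:
        log.info("harmonize: dropped %d palindromic and %d allele-mismatched SNP(s)",
                 n_pal, n_mismatch)
    if not rows:
        raise ValueError("harmonization left no usable SNPs")
    return pd.DataFrame(rows).sort_values("pos", kind="mergesort").reset_index(drop=True)


def ld_from_genotypes(genotypes: np.ndarray,
                      snps: list[str] | None = None) -> LDMatrix:
    """Pearson dosage correlation for a locus (individuals x SNPs).

    Constant columns get self-correlation 1, cross terms 0, and are flagged.
    Near-singular matrices are repaired by minimal ridge inflation.
    """
    g = np.asarray(genotypes, dtype=float)
    if g.ndim != 2 or g.shape[0] < 2 or g.shape[1] < 1:
        raise ValueError("need >= 2 individuals and >= 1 SNP")
    n, k = g.shape
    if snps is None:
        snps = [f"snp{i}" for i in range(k)]
    sd = g.std(axis=0)
    constant = sd == 0
    flagged = [snps[i] for i in np.flatnonzero(constant)]
    if flagged:
        log.warning("ld_from_genotypes: constant SNP column(s) flagged: %s", flagged)
    gz = np.zeros_like(g)
    nz = ~constant
    gz[:, nz] = (g[:, nz] - g[:, nz].mean(axis=0)) / sd[nz]
    r = gz.T @ gz / n
    r[np.diag_indices(k)] = 1.0
    r = np.clip(r, -1.0, 1.0)
    repaired = False
    if k > 1:
        w = np.linalg.eigvalsh(0.5 * (r + r.T))
        if w.min() < -1e-8:
            _, ridge = ridge_invert(r)
            r = (r + ridge * np.eye(k)) / (1 + ridge)
            repaired = True
            log.info("ld_from_genotypes: ridge repair applied (%.2e)", ridge)
    return LDMatrix(list(snps), 0.5 * (r + r.T), ridge_repaired=repaired,
                    flagged_constant=flagged)
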