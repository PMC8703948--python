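import numpy as np
import pandas as pd
import pytest

from bloodmark import DiseaseModel, QtlArchitecture
from bloodmark.sumstats import SumStats, LDMatrix


@pytest.fixture
def small_arch() -> QtlArchitecture:
    return QtlArchitecture(n_snps=12, maf=0.3, causal_idx=(0,),
                           beta_im=(0.5,), ld_rho=0.9)


@pytest.fixture
def balanced_disease() -> DiseaseModel:
    return DiseaseModel(beta_md_true=0.3, prevalence=0.5,
                        n_cases=2_500, n_controls=2_500)


def make_sumstats(rows, trait="t", kind="molecule", omic="RNA") -> SumStats:
    """Build a SumStats from (snp, a1, a2, beta, se, p) tuples."""
    recs = []
    for i, (snp, a1, a2, beta, se, p) in enumerate(rows):
        recs.append({"snp": snp, "chrom": "1", "pos": (i + 1) * 1000,
                     "a1": a1, "a2": a2, "freq": 0.3,
                     "beta": beta, "se": se, "p": p, "n": 1000})
    return SumStats(pd.DataFrame(recs), trait=trait, kind=kind, omic=omic)


def make_pairs(beta_qtl, beta_gwas, se_qtl=None, se_gwas=None,
               p_qtl=None) -> pd.DataFrame:
    """Hand-built harmonized pair table for MR unit tests."""
    k = len(beta_qtl)
    se_qtl = se_qtl if se_qtl is not None else [0.01] * k
    se_gwas = se_gwas if se_gwas is not None else [0.01] * k
    p_qtl = p_qtl if p_qtl is not None else [1e-10] * k
    return pd.DataFrame({
        "snp": [f"rs{i}" for i in range(k)],
        "chrom": "1", "pos": np.arange(1, k + 1) * 1000,
        "a1": "A", "a2": "G",
        "beta_qtl": np.asarray(beta_qtl, float),
        "se_qtl": np.asarray(se_qtl, float),
        "p_qtl": np.asarray(p_qtl, float),
        "beta_gwas": np.asarray(beta_gwas, float),
        "se_gwas": np.asarray(se_gwas, float),
        "p_gwas": 0.01, "n_qtl": 1000.0, "n_gwas": 1000.0,
    })


def identity_ld(k: int) -> LDMatrix:
    return LDMatrix([f"rs{i}" for i in range(k)], np.eye(k))
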