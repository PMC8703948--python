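"""Summary-based Mendelian randomization, HEIDI, and sensitivity analyses.

The molecule-disease effect is estimated from two sets of summary statistics:
for each instrument i, the Wald ratio beta_md(i) = beta_id / beta_im with
first-order delta-method SE_md(i) = SE_id / |beta_im|. Multiple cis
instruments are combined by LD-aware inverse-variance weighting of the Wald
z-scores; the HEIDI test probes whether the per-instrument ratios are
homogeneous (one shared causal variant) or heterogeneous (distinct causal
variants in linkage). Classic two-sample MR tools (fixed-effect IVW,
Cochran's Q, stepwise outlier removal, MR-Egger) cover genome-wide
instruments, and per-omic Bonferroni thresholds plus the QQ inflation factor
lambda provide the multiple-testing layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import nearest_psd, ridge_invert, satterthwaite_quadform_p
from .sumstats import LDMatrix

log = logging.getLogger(__name__)

CIS_P_THRESHOLD = 5e-8       # cis-QTL instrument significance
CIS_WINDOW_BP = 1_000_000    # +/- window around the molecule's site
GENOMEWIDE_P_THRESHOLD = 1e-5
PRUNE_R2 = 0.9
HEIDI_R2_MIN, HEIDI_R2_MAX = 0.05, 0.9
HEIDI_MAX_SNPS = 20
HEIDI_ALPHA = 0.05


@dataclass
class MarkerAssociation:
    """One molecule-disease MR result."""

    molecule: str
    disease: str
    omic: str
    beta_md: float
    se_md: float
    p_smr: float
    n_instruments: int
    method: str  # smr_multi | ivw | egger
    p_heidi: float | None = None
    heidi_flag: str = "untested"  # "+" | "-" | "untested"

    def set_heidi(self, p_heidi: float | None) -> "MarkerAssociation":
        self.p_heidi = p_heidi
        if p_heidi is None or not np.isfinite(p_heidi):
            self.p_heidi, self.heidi_flag = None, "untested"
        else:
            # p <= 0.05 marks colocalization-driven ("-"); > 0.05 a shared variant
            self.heidi_flag = "-" if p_heidi <= HEIDI_ALPHA else "+"
        return self


@dataclass
class InflationReport:
    lam: float
    n_tests: int
    qq: pd.DataFrame  # columns: expected_p, observed_p
    low_confidence: bool = False


# ---------------------------------------------------------------- Wald layer

def wald_ratio(beta_id: float, beta_im: float) -> float:
    """Single-instrument MR estimate beta_id / beta_im."""
    if beta_im == 0:
        raise ZeroDivisionError("instrument with beta_im = 0 is rejected")
    return beta_id / beta_im


def delta_se(se_id: float, beta_im: float) -> float:
    """First-order delta-method SE of the Wald ratio, treating beta_im fixed."""
    if beta_im == 0:
        raise ZeroDivisionError("instrument with beta_im = 0 is rejected")
    if se_id <= 0:
        raise ValueError("se_id must be positive")
    return se_id / abs(beta_im)


def wald_estimates(pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-instrument Wald ratios/SEs/z from a harmonized pair table."""
    usable = pairs[pairs["beta_qtl"] != 0].copy()
    if len(usable) < len(pairs):
        log.info("wald_estimates: rejected %d instrument(s) with beta_qtl = 0",
                 len(pairs) - len(usable))
    usable["beta_md"] = usable["beta_gwas"] / usable["beta_qtl"]
    usable["se_md"] = usable["se_gwas"] / usable["beta_qtl"].abs()
    usable["z"] = usable["beta_md"] / usable["se_md"]
    return usable


# -------------------------------------------------------- instrument selection

def select_cis_instruments(pairs: pd.DataFrame, site_pos: int, ld: LDMatrix,
                           p_threshold: float = CIS_P_THRESHOLD,
                           window_bp: int = CIS_WINDOW_BP,
                           r2_max: float = PRUNE_R2) -> list[str]:
    """Significant cis SNPs pruned to pairwise r2 <= ``r2_max``.

    Candidates: QTL p below threshold and within the cis window of the
    molecule's site. Greedy pruning keeps the smaller-p SNP (position breaks
    ties). An empty list is the explicit "untestable" outcome.
    """
    cand = pairs[(pairs["p_qtl"] < p_threshold)
                 & ((pairs["pos"] - site_pos).abs() <= window_bp)]
    if cand.empty:
        return []
    cand = cand.sort_values(["p_qtl", "pos"], kind="mergesort")
    kept: list[str] = []
    for snp in cand["snp"]:
        if all(ld.r2(snp, k) <= r2_max for k in kept):
            kept.append(snp)
    return kept


def select_genomewide_instruments(qtl_table: pd.DataFrame,
                                  p_threshold: float = GENOMEWIDE_P_THRESHOLD,
                                  clump_bp: int = 1_000_000) -> list[str]:
    """Distance-clumped genome-wide instruments (p ascending, 1 Mb spacing)."""
    cand = qtl_table[qtl_table["p"] < p_threshold] if "p" in qtl_table.columns \
        else qtl_table[qtl_table["p_qtl"] < p_threshold]
    if cand.empty:
        return []
    pcol = "p" if "p" in cand.columns else "p_qtl"
    cand = cand.sort_values([pcol, "pos"], kind="mergesort")
    kept_pos: dict[str, list[int]] = {}
    kept: list[str] = []
    for _, row in cand.iterrows():
        chrom, pos = str(row["chrom"]), int(row["pos"])
        if all(abs(pos - q) > clump_bp for q in kept_pos.get(chrom, [])):
            kept.append(row["snp"])
            kept_pos.setdefault(chrom, []).append(pos)
    return kept


# ------------------------------------------------------------------ SMR core

def smr_multi(pairs: pd.DataFrame, ld: LDMatrix,
              instruments: list[str] | None = None, *,
              molecule: str = "", disease: str = "",
              omic: str = "none") -> MarkerAssociation:
    """Multi-SNP SMR: LD-aware inverse-variance combination of Wald z-scores.

    With z the vector of per-instrument Wald z-statistics and R the signed
    instrument correlation from the LD matrix, the combined statistic is
    z_comb = (1' R^-1 z) / sqrt(1' R^-1 1); beta_md is the same-weights mean
    of the Wald ratios and the SE follows from the weighted covariance.
    Reduces exactly to the single-instrument Wald test for one instrument.
    """
    w = wald_estimates(pairs)
    if instruments is not None:
        w = w[w["snp"].isin(instruments)]
    if w.empty:
        raise ValueError("smr_multi needs at least one usable instrument")
    snps = list(w["snp"])
    r = ld.subset(snps).r
    rinv, ridge = ridge_invert(r)
    if ridge:
        log.info("smr_multi: singular instrument correlation, ridge %.1e", ridge)
    ones = np.ones(len(snps))
    z = w["z"].to_numpy()
    denom = float(ones @ rinv @ ones)
    z_comb = float(ones @ rinv @ z) / np.sqrt(denom)
    weights = rinv @ ones / denom          # same weights for the point estimate
    beta = float(weights @ w["beta_md"].to_numpy())
    se_vec = w["se_md"].to_numpy()
    cov = r * np.outer(se_vec, se_vec)
    se = float(np.sqrt(weights @ cov @ weights))
    p = float(np.clip(2.0 * stats.norm.sf(abs(z_comb)), np.finfo(float).tiny, 1.0))
    return MarkerAssociation(molecule=molecule, disease=disease, omic=omic,
                             beta_md=beta, se_md=se, p_smr=p,
                             n_instruments=len(snps), method="smr_multi")


def heidi_test(pairs: pd.DataFrame, ld: LDMatrix,
               r2_min: float = HEIDI_R2_MIN, r2_max: float = HEIDI_R2_MAX,
               max_snps: int = HEIDI_MAX_SNPS,
               min_test_snps: int = 3) -> float | None:
    """Heterogeneity-in-dependent-instruments p-value (None if untestable).

    The top SNP is the smallest-QTL-p instrument; test SNPs are those with
    r2_min < r2(., top) < r2_max, capped at the ``max_snps`` strongest QTL
    signals. d_i = beta_md(i) - beta_md(top) with a full first-order
    delta-method covariance (GWAS- and QTL-side terms, LD-correlated);
    T = sum d_i^2 / Var(d_i) against the moment-matched scaled chi-square of
    the correlated quadratic form.
    """
    w = wald_estimates(pairs).reset_index(drop=True)
    if w.empty:
        return None
    top_i = int(w["p_qtl"].idxmin())
    top_snp = w.loc[top_i, "snp"]
    r2_top = np.array([ld.r2(s, top_snp) for s in w["snp"]])
    testable = w[(r2_top > r2_min) & (r2_top < r2_max)]
    testable = testable.sort_values("p_qtl", kind="mergesort").head(max_snps)
    if len(testable) < min_test_snps:
        return None
    sel = pd.concat([w.loc[[top_i]], testable])
    snps = list(sel["snp"])
    r = ld.subset(snps).r
    b_im = sel["beta_qtl"].to_numpy()
    se_im = sel["se_qtl"].to_numpy()
    b_id = sel["beta_gwas"].to_numpy()
    se_id = sel["se_gwas"].to_numpy()
    # cov(beta_md_i, beta_md_j), both sampling layers, LD-correlated
    gwas_term = r * np.outer(se_id, se_id) / np.outer(b_im, b_im)
    qtl_term = (r * np.outer(b_id, b_id) * np.outer(se_im, se_im)
                / np.outer(b_im ** 2, b_im ** 2))
    cov_b = gwas_term + qtl_term
    k = len(snps)
    # difference operator d_i = beta_md(i) - beta_md(top); top is row 0
    dmat = np.hstack([-np.ones((k - 1, 1)), np.eye(k - 1)])
    cov_d = dmat @ cov_b @ dmat.T
    cov_d, repaired = nearest_psd(cov_d)
    if repaired:
        log.info("heidi_test: covariance repaired to PSD")
    var_d = np.diag(cov_d)
    beta_md = sel["beta_md"].to_numpy()
    d = beta_md[1:] - beta_md[0]
    t_stat = float(np.sum(d * d / var_d))
    sd = np.sqrt(var_d)
    corr = cov_d / np.outer(sd, sd)
    return satterthwaite_quadform_p(t_stat, corr)


# ----------------------------------------------------------- 2SMR sensitivity

def ivw_estimate(wald: pd.DataFrame, *, molecule: str = "", disease: str = "",
                 omic: str = "none") -> MarkerAssociation:
    """Fixed-effect inverse-variance-weighted mean of independent Wald ratios."""
    if wald.empty:
        raise ValueError("ivw_estimate needs at least one instrument")
    wts = 1.0 / wald["se_md"].to_numpy() ** 2
    beta = float(np.sum(wts * wald["beta_md"]) / wts.sum())
    se = float(1.0 / np.sqrt(wts.sum()))
    z = beta / se
    p = float(np.clip(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny, 1.0))
    return MarkerAssociation(molecule=molecule, disease=disease, omic=omic,
                             beta_md=beta, se_md=se, p_smr=p,
                             n_instruments=len(wald), method="ivw")


def cochran_q(wald: pd.DataFrame) -> tuple[float, int, float]:
    """Cochran's heterogeneity Q, its df, and the chi-square p-value."""
    if len(wald) < 2:
        raise ValueError("Cochran's Q needs >= 2 instruments")
    wts = 1.0 / wald["se_md"].to_numpy() ** 2
    b = wald["beta_md"].to_numpy()
    pooled = np.sum(wts * b) / wts.sum()
    q = float(np.sum(wts * (b - pooled) ** 2))
    df = len(wald) - 1
    return q, df, float(stats.chi2.sf(q, df))


def stepwise_outlier_removal(wald: pd.DataFrame, alpha: float = 0.05,
                             min_keep: int = 3) -> tuple[pd.DataFrame, list[dict]]:
    """Iteratively drop the largest-Q-contribution instrument while Q p < alpha.

    Stops at ``min_keep`` instruments regardless of residual heterogeneity;
    the audit trail records each removal with the Q state that triggered it.
    """
    if len(wald) < min_keep:
        raise ValueError(f"need >= {min_keep} instruments")
    current = wald.copy()
    audit: list[dict] = []
    while len(current) > min_keep:
        q, df, p = cochran_q(current)
        if p >= alpha:
            break
        wts = 1.0 / current["se_md"].to_numpy() ** 2
        b = current["beta_md"].to_numpy()
        pooled = np.sum(wts * b) / wts.sum()
        contrib = wts * (b - pooled) ** 2
        worst = int(np.argmax(contrib))
        audit.append({"removed": current.iloc[worst]["snp"], "q": q, "df": df,
                      "p": p, "contribution": float(contrib[worst])})
        current = current.drop(current.index[worst])
    return current, audit


def mr_egger(wald_ready: pd.DataFrame) -> tuple[float, float, float]:
    """MR-Egger: weighted regression of beta_id on beta_im with free intercept.

    Instruments are oriented so beta_im > 0; weights are se_id^-2. Returns
    (slope, intercept, intercept p); the intercept tests directional
    pleiotropy.
    """
    if len(wald_ready) < 3:
        raise ValueError("MR-Egger needs >= 3 instruments")
    import statsmodels.api as sm
    sign = np.sign(wald_ready["beta_qtl"].to_numpy())
    sign[sign == 0] = 1.0
    x = wald_ready["beta_qtl"].to_numpy() * sign
    y = wald_ready["beta_gwas"].to_numpy() * sign
    wts = 1.0 / wald_ready["se_gwas"].to_numpy() ** 2
    fit = sm.WLS(y, sm.add_constant(x), weights=wts).fit()
    return float(fit.params[1]), float(fit.params[0]), float(fit.pvalues[0])


# ------------------------------------------------- multiple testing, diagnostics

def bonferroni_threshold(alpha: float, n_molecules: int) -> float:
    """Per-omic-disease Bonferroni significance threshold alpha / n."""
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    return alpha / n_molecules


def inflation_lambda(p_values) -> InflationReport:
    """QQ inflation factor: no-intercept slope of observed on expected chi2.

    Observed p-values are mapped to 1-df chi-square quantiles and regressed
    (through the origin) on the quantiles of the uniform order statistics
    i/(n+1). lambda ~ 1 indicates calibration.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p) & (p > 0) & (p <= 1)]
    n = p.size
    if n == 0:
        raise ValueError("no valid p-values")
    low_conf = n < 10
    if low_conf:
        log.warning("inflation_lambda: only %d test(s); low-confidence report", n)
    obs_sorted = np.sort(p)
    expected = np.arange(1, n + 1) / (n + 1.0)
    chi_obs = stats.chi2.isf(obs_sorted, 1)
    chi_exp = stats.chi2.isf(expected, 1)
    lam = float(np.sum(chi_exp * chi_obs) / np.sum(chi_exp ** 2))
    qq = pd.DataFrame({"expected_p": expected, "observed_p": obs_sorted})
    return InflationReport(lam=lam, n_tests=n, qq=qq, low_confidence=low_conf)


def characterize_enrichment(marker_pos, annotation_intervals,
                            background_pos) -> tuple[float, float]:
    """Fisher's exact enrichment of markers in annotation intervals.

    Intervals are half-open [start, end); the 2x2 table crosses
    marker set vs background set (background must contain the markers)
    against inside vs outside. Returns (sample odds ratio, two-sided p).
    """
    bg = np.asarray(background_pos)
    mk = np.asarray(marker_pos)
    if bg.size == 0:
        raise ValueError("background set is empty")
    iv = [(int(s), int(e)) for s, e in annotation_intervals]

    def inside(x) -> np.ndarray:
        hit = np.zeros(x.size, dtype=bool)
        for s, e in iv:
            hit |= (x >= s) & (x < e)
        return hit

    a = int(inside(mk).sum())
    b = mk.size - a
    c = int(inside(bg).sum())
    d = bg.size - c
    table = np.array([[a, b], [c, d]])
    if (a + b == 0) or (c + d == 0):
        raise ValueError("degenerate enrichment table")
    if b == 0 or c == 0:
        odds = np.inf if (a > 0 and d > 0) else np.nan
    else:
        odds = (a * d) / (b * c)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if np.array_equal(table[0], table[1]):
        odds = 1.0
    return float(odds), float(p)


def associations_to_frame(assocs: list[MarkerAssociation]) -> pd.DataFrame:
    """MarkerAssociation records as the canonical output table."""
    return pd.DataFrame([{
        "molecule": a.molecule, "disease": a.disease, "omic": a.omic,
        "beta": a.beta_md, "se": a.se_md, "p_smr": a.p_smr,
        "p_heidi": a.p_heidi, "flag": a.heidi_flag,
        "n_instruments": a.n_instruments, "method": a.method,
    } for a in assocs])
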