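"""Synthetic-data generators with known ground truth.

Everything the analysis consumes can be generated here: cis-QTL loci with
AR(1)-style linkage disequilibrium, liability-threshold case/control GWAS
cohorts (shared-causal, linkage/colocalization, or null scenarios),
case/control marker matrices with planted mean shifts, and exponential-hazard
conversion cohorts. Each generator is a pure function of (parameters, seed)
and carries a :class:`CohortTruth` record that estimation code never reads.

Genotypes come from two latent Gaussian AR(1) haplotypes thresholded at the
allele frequency, which gives Hardy-Weinberg dosages and a tunable LD decay
without an external reference panel. Thresholding attenuates the latent
correlation, so the dosage-scale LD is calibrated empirically where a target
r2 matters (the colocalization scenario picks its direct-effect SNP by
realized r2, not by the latent parameter).

Disease liability is standardized to (near) unit variance and case/control
GWAS marginal effects are returned on the liability scale via the classic
observed-to-liability conversion K(1-K) / (phi(t) * P(1-P)), so that the
Wald ratio of GWAS over QTL effects recovers ``beta_md_true`` directly.
A logit-scale output (score-test approximation beta_lin / (pbar(1-pbar)))
is available via ``scale="logit"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import spawn_rng
from .sumstats import SumStats, LDMatrix, ld_from_genotypes

__all__ = [
    "QtlArchitecture", "DiseaseModel", "CohortTruth",
    "QtlLocus", "GwasCohort", "CaseControlCohort", "ConversionCohort",
    "gen_genotypes", "gen_qtl_sumstats", "gen_gwas_sumstats",
    "gen_case_control_matrix", "gen_conversion_cohort", "marginal_ols",
]


@dataclass
class QtlArchitecture:
    """Genetic architecture of one cis locus.

    ``beta_im`` is the per-allele effect of each causal SNP on the raw
    molecule value (SD units of the noise scale); ``ld_rho`` is the latent
    AR(1) adjacent-SNP correlation in [0, 1); ``window_bp`` the locus span.
    """

    n_snps: int
    maf: float = 0.3
    causal_idx: tuple[int, ...] = (0,)
    beta_im: tuple[float, ...] = (0.5,)
    ld_rho: float = 0.9
    window_bp: int = 2_000_000

    def __post_init__(self):
        if self.n_snps < 1:
            raise ValueError("n_snps must be positive")
        if not (0.01 < self.maf < 0.5) and self.maf != 0.5:
            if not (0.01 < self.maf <= 0.5):
                raise ValueError("maf must lie in (0.01, 0.5]")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must lie in [0, 1)")
        self.causal_idx = tuple(int(i) for i in np.atleast_1d(self.causal_idx))
        self.beta_im = tuple(float(b) for b in np.atleast_1d(self.beta_im))
        if len(self.causal_idx) != len(self.beta_im):
            raise ValueError("causal_idx and beta_im must have equal length")
        if any(i < 0 or i >= self.n_snps for i in self.causal_idx):
            raise ValueError("causal_idx out of range")
        if not all(np.isfinite(self.beta_im)):
            raise ValueError("beta_im must be finite")


@dataclass
class DiseaseModel:
    """Liability-scale disease model for the GWAS cohort.

    ``beta_md_true``: effect of the standardized molecule on standardized
    disease liability (equals log-odds per molecule SD up to the usual
    liability/logit scale factor); ``prevalence`` in (0, 1).
    """

    beta_md_true: float = 0.0
    prevalence: float = 0.5
    n_cases: int = 10_000
    n_controls: int = 10_000

    def __post_init__(self):
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie in (0,1)")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("n_cases and n_controls must be positive")


@dataclass
class CohortTruth:
    """Planted ground truth; for parameter-recovery tests only."""

    beta_md_true: float | None = None
    mediation: str | None = None
    direct_snp: str | None = None
    direct_effect: float | None = None
    direct_r2_with_top: float | None = None
    marker_shift: np.ndarray | None = None
    conversion_log_hr: float | None = None
    beta_im_std: np.ndarray | None = None


@dataclass
class QtlLocus:
    sumstats: SumStats
    ld: LDMatrix
    truth: CohortTruth
    genotype_sd: np.ndarray = field(default=None, repr=False)


@dataclass
class GwasCohort:
    sumstats: SumStats
    truth: CohortTruth


@dataclass
class CaseControlCohort:
    matrix: np.ndarray
    labels: np.ndarray
    marker_ids: list[str]
    truth: CohortTruth


@dataclass
class ConversionCohort:
    matrix: np.ndarray
    time: np.ndarray
    event: np.ndarray
    score: np.ndarray
    marker_ids: list[str]
    truth: CohortTruth


def _haplotypes(rng: np.random.Generator, n: int, arch: QtlArchitecture) -> np.ndarray:
    """One latent AR(1) Gaussian haplotype matrix thresholded to alleles."""
    k = arch.n_snps
    latent = np.empty((n, k))
    latent[:, 0] = rng.standard_normal(n)
    if k > 1:
        innov = rng.standard_normal((n, k - 1)) * np.sqrt(1.0 - arch.ld_rho ** 2)
        for j in range(1, k):
            latent[:, j] = arch.ld_rho * latent[:, j - 1] + innov[:, j - 1]
    thresh = stats.norm.ppf(1.0 - arch.maf)
    return (latent > thresh)


def gen_genotypes(n_individuals: int, arch: QtlArchitecture, seed) -> np.ndarray:
    """0/1/2 dosages, n_individuals x n_snps, Hardy-Weinberg at ``arch.maf``."""
    if n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    rng = seed if isinstance(seed, np.random.Generator) else spawn_rng(seed, 0)
    h1 = _haplotypes(rng, n_individuals, arch)
    h2 = _haplotypes(rng, n_individuals, arch)
    return (h1.astype(np.int8) + h2.astype(np.int8))


def marginal_ols(genotypes: np.ndarray, y: np.ndarray):
    """Per-SNP simple linear regression, vectorized.

    Returns (beta, se, p) arrays; p is the two-sided normal tail of beta/se.
    Monomorphic SNPs get beta 0, huge se, p 1.
    """
    g = np.asarray(genotypes, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", gc, gc)
    sxy = gc.T @ yc
    syy = float(yc @ yc)
    mono = sxx <= 0
    sxx_safe = np.where(mono, 1.0, sxx)
    beta = sxy / sxx_safe
    rss = np.maximum(syy - beta * sxy, 0.0)
    dof = max(n - 2, 1)
    se = np.sqrt(rss / dof / sxx_safe)
    se = np.where(se <= 0, np.finfo(float).tiny ** 0.25, se)
    beta = np.where(mono, 0.0, beta)
    se = np.where(mono, 1e6, se)
    z = beta / se
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    return beta, se, p


def _locus_table(arch: QtlArchitecture, beta, se, p, freq, n, prefix="rs") -> pd.DataFrame:
    k = arch.n_snps
    pos = np.unique(np.round(np.linspace(1, arch.window_bp, k)).astype(int))
    if pos.size < k:  # tiny windows: fall back to consecutive coordinates
        pos = np.arange(1, k + 1)
    return pd.DataFrame({
        "snp": [f"{prefix}{i}" for i in range(k)],
        "chrom": "1", "pos": pos,
        "a1": "A", "a2": "G",
        "freq": freq, "beta": beta, "se": se, "p": p, "n": n,
    })


def _molecule(g: np.ndarray, arch: QtlArchitecture, noise_sd: float,
              rng: np.random.Generator) -> np.ndarray:
    raw = g[:, list(arch.causal_idx)].astype(float) @ np.asarray(arch.beta_im)
    raw = raw + rng.normal(0.0, noise_sd, size=g.shape[0])
    sd = raw.std()
    if sd == 0:
        raise ValueError("degenerate (constant) molecule vector")
    return (raw - raw.mean()) / sd


def gen_qtl_sumstats(arch: QtlArchitecture, n: int, noise_sd: float = 1.0,
                     seed=0, trait: str = "molecule", omic: str = "RNA") -> QtlLocus:
    """Simulate a QTL cohort and return per-SNP marginal statistics + LD.

    The molecule is the causal-dosage burden plus Gaussian noise, standardized
    to unit variance; summary statistics are the per-SNP marginal regressions
    and the LD matrix is the empirical dosage correlation of this cohort.
    """
    if n < 100:
        raise ValueError("QTL cohort must have n >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else spawn_rng(seed, 1)
    g = gen_genotypes(n, arch, rng)
    m = _molecule(g, arch, noise_sd, rng)
    beta, se, p = marginal_ols(g, m)
    freq = g.mean(axis=0) / 2.0
    table = _locus_table(arch, beta, se, p, freq, n)
    ss = SumStats(table, trait=trait, kind="molecule", omic=omic)
    ld = ld_from_genotypes(g, list(table["snp"]))
    beta_im_std = np.zeros(arch.n_snps)
    gsd = g.std(axis=0)
    # standardized per-allele effect implied by the architecture (population-level)
    raw_sd_proxy = np.sqrt(
        float(np.asarray(arch.beta_im) @
              np.cov(g[:, list(arch.causal_idx)].astype(float), rowvar=False).reshape(
                  len(arch.causal_idx), len(arch.causal_idx)) @
              np.asarray(arch.beta_im)) + noise_sd ** 2)
    for i, b in zip(arch.causal_idx, arch.beta_im):
        beta_im_std[i] = b / raw_sd_proxy
    truth = CohortTruth(beta_im_std=beta_im_std)
    return QtlLocus(sumstats=ss, ld=ld, truth=truth, genotype_sd=gsd)


_MEDIATIONS = ("shared_causal", "distinct_causal_in_ld", "null")


def gen_gwas_sumstats(arch: QtlArchitecture, disease: DiseaseModel,
                      mediation: str = "shared_causal", seed=0,
                      noise_sd: float = 1.0, direct_effect: float = 0.15,
                      target_r2: float = 0.6, scale: str = "liability",
                      exact_logistic: bool = False,
                      trait: str = "disease") -> GwasCohort:
    """Simulate an independent case/control GWAS cohort for the same locus.

    Liability = molecule * beta_md_true (shared_causal), or a direct effect of
    a non-causal SNP in LD with the QTL top SNP (distinct_causal_in_ld, with
    beta_md_true forced to 0), or pure noise (null); residual variance is
    shrunk so total liability variance is ~1. Cases are liability above the
    (1 - prevalence) quantile; ``n_cases``/``n_controls`` are sampled and
    per-SNP marginal statistics returned on the requested scale.
    """
    if mediation not in _MEDIATIONS:
        raise ValueError(f"mediation must be one of {_MEDIATIONS}")
    if disease.n_cases + disease.n_controls < 1000:
        raise ValueError("GWAS cohort must total >= 1000 samples")
    rng = seed if isinstance(seed, np.random.Generator) else spawn_rng(seed, 2)
    kprev = disease.prevalence
    n_pop = int(np.ceil(max(disease.n_cases / kprev,
                            disease.n_controls / (1 - kprev)) * 1.15)) + 100
    g = gen_genotypes(n_pop, arch, rng)

    beta_md = disease.beta_md_true
    truth = CohortTruth(mediation=mediation)
    if mediation == "shared_causal":
        m = _molecule(g, arch, noise_sd, rng)
        signal = beta_md * m
        sig_var = beta_md ** 2
        truth.beta_md_true = beta_md
    elif mediation == "distinct_causal_in_ld":
        top = arch.causal_idx[int(np.argmax(np.abs(arch.beta_im)))]
        r = np.corrcoef(g.astype(float), rowvar=False)[top]
        candidates = np.array([j for j in range(arch.n_snps)
                               if j not in arch.causal_idx])
        if candidates.size == 0:
            raise ValueError("no non-causal SNP available for a direct effect")
        j_direct = int(candidates[np.argmin(np.abs(r[candidates] ** 2 - target_r2))])
        gd = g[:, j_direct].astype(float)
        gd = (gd - gd.mean()) / gd.std()
        signal = direct_effect * gd
        sig_var = direct_effect ** 2
        truth.beta_md_true = 0.0
        truth.direct_snp = f"rs{j_direct}"
        truth.direct_effect = direct_effect
        truth.direct_r2_with_top = float(r[j_direct] ** 2)
    else:
        signal = 0.0
        sig_var = 0.0
        truth.beta_md_true = 0.0
    resid_sd = np.sqrt(max(1.0 - sig_var, 0.05))
    liability = signal + rng.normal(0.0, resid_sd, size=n_pop)

    thresh = np.quantile(liability, 1.0 - kprev)
    case_idx = np.flatnonzero(liability > thresh)
    ctrl_idx = np.flatnonzero(liability <= thresh)
    if case_idx.size < disease.n_cases or ctrl_idx.size < disease.n_controls:
        raise ValueError("empty or insufficient case/control stratum after ascertainment")
    take_cases = rng.choice(case_idx, size=disease.n_cases, replace=False)
    take_ctrls = rng.choice(ctrl_idx, size=disease.n_controls, replace=False)
    keep = np.concatenate([take_cases, take_ctrls])
    y = np.zeros(keep.size)
    y[:disease.n_cases] = 1.0
    gs = g[keep]

    n_tot = keep.size
    if exact_logistic:
        import statsmodels.api as sm
        beta = np.empty(arch.n_snps)
        se = np.empty(arch.n_snps)
        for j in range(arch.n_snps):
            x = sm.add_constant(gs[:, j].astype(float))
            fit = sm.Logit(y, x).fit(disp=0)
            beta[j], se[j] = fit.params[1], fit.bse[1]
        p = np.clip(2.0 * stats.norm.sf(np.abs(beta / se)), np.finfo(float).tiny, 1.0)
    else:
        beta, se, p = marginal_ols(gs, y)
        pbar = y.mean()
        if scale == "logit":
            factor = 1.0 / (pbar * (1 - pbar))
        else:  # observed 0/1 slope -> standardized-liability slope
            t = stats.norm.ppf(1.0 - kprev)
            factor = kprev * (1 - kprev) / (stats.norm.pdf(t) * pbar * (1 - pbar))
        beta = beta * factor
        se = se * factor
    freq = gs.mean(axis=0) / 2.0
    table = _locus_table(arch, beta, se, p, freq, n_tot)
    ss = SumStats(table, trait=trait, kind="disease", omic="none")
    return GwasCohort(sumstats=ss, truth=truth)


def gen_case_control_matrix(n_cases: int, n_controls: int, n_markers: int,
                            effect_vector, seed=0, noise_sd: float = 1.0,
                            shuffle: bool = True) -> CaseControlCohort:
    """Marker matrix with planted case/control mean shifts.

    Marker j is N(shift_j * label, noise_sd^2); a zero entry in
    ``effect_vector`` is a null marker.
    """
    if n_markers < 1:
        raise ValueError("need at least one marker")
    shift = np.broadcast_to(np.asarray(effect_vector, dtype=float),
                            (n_markers,)).copy()
    rng = seed if isinstance(seed, np.random.Generator) else spawn_rng(seed, 3)
    n = n_cases + n_controls
    labels = np.concatenate([np.ones(n_cases, dtype=int),
                             np.zeros(n_controls, dtype=int)])
    x = rng.normal(0.0, noise_sd, size=(n, n_markers))
    x += labels[:, None] * shift[None, :]
    if shuffle:
        order = rng.permutation(n)
        x, labels = x[order], labels[order]
    ids = [f"m{j}" for j in range(n_markers)]
    return CaseControlCohort(matrix=x, labels=labels, marker_ids=ids,
                             truth=CohortTruth(marker_shift=shift))


def gen_conversion_cohort(n: int, score_effect: float, censor_rate: float = 0.2,
                          max_followup_days: float = 1000.0, seed=0,
                          score=None, n_markers: int = 0, n_informative: int = 0,
                          marker_loading: float = 0.7,
                          baseline_hazard: float = 1.0 / 200.0,
                          require_events: bool = False) -> ConversionCohort:
    """Baseline markers plus exponential conversion times.

    The risk score defaults to N(0, 1) (pass ``score`` for e.g. a binary
    score); event times are exponential with hazard
    ``baseline_hazard * exp(score_effect * score)``. Random censoring uses an
    exponential with rate ``baseline_hazard * censor_rate / (1 - censor_rate)``
    (so roughly ``censor_rate`` of null subjects censor before converting),
    plus administrative censoring at ``max_followup_days``. The first
    ``n_informative`` markers load on the score with ``marker_loading``.
    """
    if n < 20:
        raise ValueError("conversion cohort needs n >= 20")
    rng = seed if isinstance(seed, np.random.Generator) else spawn_rng(seed, 4)
    score = rng.standard_normal(n) if score is None else np.asarray(score, float)
    if score.size != n:
        raise ValueError("score length must equal n")
    if n_markers:
        x = rng.standard_normal((n, n_markers))
        k = min(n_informative, n_markers)
        if k:
            lam = float(marker_loading)
            x[:, :k] = lam * score[:, None] + np.sqrt(max(1 - lam ** 2, 0.0)) \
                * rng.standard_normal((n, k))
    else:
        x = np.empty((n, 0))
    hazard = baseline_hazard * np.exp(score_effect * score)
    t_event = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        rate_c = baseline_hazard * censor_rate / (1.0 - censor_rate)
        t_cens = rng.exponential(1.0 / rate_c, size=n)
    else:
        t_cens = np.full(n, np.inf)
    t_cens = np.minimum(t_cens, max_followup_days)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-6)
    if require_events and event.sum() == 0:
        raise ValueError("all samples censored but events were required")
    ids = [f"m{j}" for j in range(n_markers)]
    return ConversionCohort(matrix=x, time=time, event=event, score=score,
                            marker_ids=ids,
                            truth=CohortTruth(conversion_log_hr=float(score_effect)))
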