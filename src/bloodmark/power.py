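"""Simulation framework for marker-panel classification power.

Given SMR effect estimates (beta_md, SE_md) for a set of markers, each
replicate (i) redraws the effect of every marker from N(beta_md, SE_md) to
propagate estimation uncertainty, (ii) simulates a standard-normal expression
matrix with N(0, 0.01)-variance environmental noise, (iii) assigns case
labels by the logistic probability of the linear score (zero intercept, so
cases and controls are balanced in expectation), and (iv) fits a logistic
panel, recording AUC, Nagelkerke R2 and AIC. Medians across replicates
summarize a panel; the cross-omics optimizer ranks pooled markers by |beta|,
evaluates nested top-k panels on the same per-replicate dataset, and picks
the panel size with the lowest median AIC. HEIDI(+) and HEIDI(-) strata are
processed separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import aic, fit_logistic, nagelkerke_r2, rank_auc, spawn_rng

DEFAULT_N_SAMPLES = 10_000
DEFAULT_N_REPS = 1_000
DEFAULT_NOISE_SD = 0.1  # noise of variance 0.01


@dataclass
class EffectVector:
    """Marker effect estimates feeding the simulation."""

    ids: list[str]
    beta: np.ndarray
    se: np.ndarray
    omic: list[str] | None = None
    p_smr: np.ndarray | None = None

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if len(self.ids) == 0:
            raise ValueError("EffectVector must contain at least one marker")
        if not (len(self.ids) == self.beta.size == self.se.size):
            raise ValueError("ids/beta/se length mismatch")
        if not np.all(np.isfinite(self.beta)) or not np.all(np.isfinite(self.se)):
            raise ValueError("effects must be finite")
        if np.any(self.se < 0):
            raise ValueError("se must be nonnegative")
        if self.omic is None:
            self.omic = ["none"] * len(self.ids)
        if self.p_smr is None:
            self.p_smr = np.ones(len(self.ids))
        else:
            self.p_smr = np.asarray(self.p_smr, dtype=float)


@dataclass
class ModelFitSummary:
    auc: float
    r2_nagelkerke: float
    aic: float
    n_markers: int
    ridge_fallback: bool = False


@dataclass
class SimulationReport:
    median_auc: float
    median_r2: float
    optimal_size: int
    optimal_markers: list[str]
    optimal_omics: list[str]
    optimal_median_aic: float
    optimal_median_auc: float
    optimal_median_r2: float
    per_size: pd.DataFrame = field(repr=False, default=None)
    heidi_stratum: str = "all"


def draw_effects(effects: EffectVector, seed) -> np.ndarray:
    """One realized effect per marker: independent N(beta_md, SE_md) draws."""
    rng = seed if isinstance(seed, np.random.Generator) else spawn_rng(seed, 10)
    return rng.normal(effects.beta, effects.se)


def simulate_dataset(realized_beta, n_samples: int = DEFAULT_N_SAMPLES,
                     noise_sd: float = DEFAULT_NOISE_SD, seed=0):
    """Expression matrix and Bernoulli case labels for realized effects.

    Columns are N(0,1) plus N(0, noise_sd^2) noise; the linear score
    s = E @ B is the log-odds of being a case (zero intercept), so
    P(case) = 1 / (1 + exp(-s)) and the expected case fraction is 1/2.
    """
    b = np.asarray(realized_beta, dtype=float).ravel()
    if b.size == 0:
        raise ValueError("empty effect vector")
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else spawn_rng(seed, 11)
    e = rng.standard_normal((n_samples, b.size))
    e += rng.normal(0.0, noise_sd, size=e.shape)
    score = e @ b
    prob = 1.0 / (1.0 + np.exp(-score))
    labels = (rng.random(n_samples) < prob).astype(int)
    return e, labels


def fit_panel(matrix: np.ndarray, labels: np.ndarray) -> ModelFitSummary:
    """Logistic panel fit: rank AUC, Nagelkerke R2, AIC = -2 ll + 2(k+1)."""
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise ValueError("single-class dataset")
    fit = fit_logistic(matrix, labels, tol=1e-6, max_iter=200)
    n = labels.size
    return ModelFitSummary(
        auc=rank_auc(fit.scores, labels),
        r2_nagelkerke=nagelkerke_r2(fit.ll_model, fit.ll_null, n),
        aic=aic(fit.ll_model, fit.n_params),
        n_markers=np.atleast_2d(matrix).shape[1] if np.ndim(matrix) > 1 else 1,
        ridge_fallback=fit.ridge_fallback,
    )


def median_power(effects: EffectVector, n_reps: int = DEFAULT_N_REPS,
                 n_samples: int = DEFAULT_N_SAMPLES,
                 noise_sd: float = DEFAULT_NOISE_SD, seed=0):
    """Median AUC and Nagelkerke R2 of the full panel across replicates."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    aucs, r2s = [], []
    for rep in range(n_reps):
        rng = spawn_rng(seed, 20, rep)
        b = draw_effects(effects, rng)
        e, y = simulate_dataset(b, n_samples, noise_sd, rng)
        if y.min() == y.max():  # pathological replicate; count as uninformative
            aucs.append(0.5)
            r2s.append(0.0)
            continue
        summary = fit_panel(e, y)
        aucs.append(summary.auc)
        r2s.append(summary.r2_nagelkerke)
    return float(np.median(aucs)), float(np.median(r2s))


def _ranked_order(effects: EffectVector) -> np.ndarray:
    """|beta| descending; ties by smaller p_smr, then lexicographic id."""
    keys = list(zip(-np.abs(effects.beta), effects.p_smr, effects.ids))
    return np.array(sorted(range(len(keys)), key=lambda i: keys[i]))


def optimal_cross_omics(effects: EffectVector, n_reps: int = DEFAULT_N_REPS,
                        n_samples: int = DEFAULT_N_SAMPLES,
                        noise_sd: float = DEFAULT_NOISE_SD, seed=0,
                        heidi_stratum: str = "all") -> SimulationReport:
    """Lowest-median-AIC nested panel over |beta|-ranked pooled markers.

    Within each replicate the nested top-1..top-n panels are fit on the same
    simulated dataset so AIC comparisons are paired; medians are taken across
    replicates per panel size.
    """
    order = _ranked_order(effects)
    n = len(order)
    aic_mat = np.empty((n_reps, n))
    auc_mat = np.empty((n_reps, n))
    r2_mat = np.empty((n_reps, n))
    for rep in range(n_reps):
        rng = spawn_rng(seed, 30, rep)
        b = draw_effects(effects, rng)
        e, y = simulate_dataset(b[order], n_samples, noise_sd, rng)
        if y.min() == y.max():
            aic_mat[rep] = np.nan
            auc_mat[rep] = 0.5
            r2_mat[rep] = 0.0
            continue
        for k in range(1, n + 1):
            s = fit_panel(e[:, :k], y)
            aic_mat[rep, k - 1] = s.aic
            auc_mat[rep, k - 1] = s.auc
            r2_mat[rep, k - 1] = s.r2_nagelkerke
    med_aic = np.nanmedian(aic_mat, axis=0)
    med_auc = np.nanmedian(auc_mat, axis=0)
    med_r2 = np.nanmedian(r2_mat, axis=0)
    best = int(np.argmin(med_aic))
    chosen = order[: best + 1]
    per_size = pd.DataFrame({
        "size": np.arange(1, n + 1),
        "median_aic": med_aic, "median_auc": med_auc, "median_r2": med_r2,
    })
    return SimulationReport(
        median_auc=float(med_auc[-1]), median_r2=float(med_r2[-1]),
        optimal_size=best + 1,
        optimal_markers=[effects.ids[i] for i in chosen],
        optimal_omics=[effects.omic[i] for i in chosen],
        optimal_median_aic=float(med_aic[best]),
        optimal_median_auc=float(med_auc[best]),
        optimal_median_r2=float(med_r2[best]),
        per_size=per_size, heidi_stratum=heidi_stratum,
    )


def stratified_reports(effects: EffectVector, heidi_flags,
                       **kwargs) -> dict[str, SimulationReport]:
    """Run the cross-omics optimizer separately for HEIDI(+) and HEIDI(-)."""
    flags = np.asarray(list(heidi_flags))
    out: dict[str, SimulationReport] = {}
    for stratum in ("+", "-"):
        idx = np.flatnonzero(flags == stratum)
        if idx.size == 0:
            continue
        sub = EffectVector(
            ids=[effects.ids[i] for i in idx],
            beta=effects.beta[idx], se=effects.se[idx],
            omic=[effects.omic[i] for i in idx],
            p_smr=effects.p_smr[idx],
        )
        out[stratum] = optimal_cross_omics(sub, heidi_stratum=stratum, **kwargs)
    return out
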