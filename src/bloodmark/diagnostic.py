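"""Sparse diagnostic marker panels from case/control matrices.

The pipeline order is frozen: (1) Spearman concordance filter against the
SMR effect direction on the feature-selection set, (2) Bayesian-lasso style
spike-and-slab screen keeping markers with posterior inclusion > 1/2,
(3) L1-penalized logistic regression on the training set with the penalty
chosen by cross-validated deviance, (4) Youden-index cut point on the
training scores, (5) frozen-coefficient validation (AUC with DeLong CI,
accuracy, sensitivity, specificity at the frozen cut point). A matched
HEIDI(+)/HEIDI(-) comparison fits equal-sized panels from both strata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from ._stats import delong_auc_ci, fit_logistic, rank_auc, spawn_rng

log = logging.getLogger(__name__)


class EmptyPanelError(RuntimeError):
    """The chosen penalty zeroed every coefficient (distinct from fit failure)."""


@dataclass
class CandidateFilterResult:
    retained: list[str]
    rho: pd.Series           # per-marker Spearman rho vs the 0/1 label
    concordant: pd.Series    # per-marker direction-agreement flag


@dataclass
class PanelModel:
    """Fitted sparse linear panel with a frozen operating cut point."""

    marker_ids: list[str]
    coef: np.ndarray
    intercept: float
    cut_point: float | None = None
    penalty: float | None = None
    metrics: dict = field(default_factory=dict)
    notes: dict = field(default_factory=dict)

    def score(self, matrix: np.ndarray, marker_ids: list[str]) -> np.ndarray:
        cols = []
        missing = [m for m in self.marker_ids if m not in marker_ids]
        if missing:
            raise KeyError(f"matrix is missing model marker column(s): {missing}")
        for m in self.marker_ids:
            cols.append(marker_ids.index(m))
        x = np.asarray(matrix, dtype=float)[:, cols]
        return x @ self.coef + self.intercept


def spearman_concordance_filter(matrix: np.ndarray, labels: np.ndarray,
                                smr_betas: dict[str, float] | pd.Series,
                                marker_ids: list[str],
                                rho_min: float = 0.05) -> CandidateFilterResult:
    """Keep markers whose Spearman rho with diagnosis matches the SMR sign
    and exceeds ``rho_min`` in magnitude."""
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    x = np.asarray(matrix, dtype=float)
    betas = pd.Series(smr_betas)
    rho_vals, keep, conc = {}, [], {}
    for j, mid in enumerate(marker_ids):
        col = x[:, j]
        if np.all(col == col[0]):
            log.warning("spearman filter: constant marker %s dropped", mid)
            rho_vals[mid] = np.nan
            conc[mid] = False
            continue
        rho = stats.spearmanr(col, labels).statistic
        rho_vals[mid] = rho
        same_sign = np.sign(rho) == np.sign(betas.get(mid, 0.0))
        conc[mid] = bool(same_sign)
        if same_sign and abs(rho) > rho_min:
            keep.append(mid)
    return CandidateFilterResult(retained=keep,
                                 rho=pd.Series(rho_vals),
                                 concordant=pd.Series(conc))


def bayesian_lasso_screen(matrix: np.ndarray, labels: np.ndarray,
                          marker_ids: list[str], n_mcmc: int = 2000,
                          burn_in: int = 500, seed=0,
                          slab_scale: float = 1.0) -> tuple[list[str], dict]:
    """Spike-and-slab Gibbs screen on the 0/1 outcome (Gaussian likelihood).

    Each coefficient has a point mass at zero and a N(0, sigma^2 tau^2) slab;
    the inclusion probability and sigma^2 are sampled by conjugate updates
    and the inclusion prior follows a Beta(1, 1). A marker is retained iff
    its posterior inclusion frequency exceeds 1/2 (the posterior median of
    the coefficient is then nonzero). Returns (retained ids, diagnostics);
    a split-chain ratio > 1.2 on sigma^2 only warns.
    """
    x = np.asarray(matrix, dtype=float)
    y = np.asarray(labels, dtype=float).ravel()
    n, p = x.shape if x.ndim == 2 else (x.shape[0], 0)
    if p == 0:
        return [], {"inclusion": pd.Series(dtype=float), "converged": True}
    if n_mcmc < 1000:
        raise ValueError("need >= 1000 post-burn-in samples")
    rng = seed if isinstance(seed, np.random.Generator) else spawn_rng(seed, 40)
    xc = x - x.mean(axis=0)
    sd = xc.std(axis=0)
    sd[sd == 0] = 1.0
    xc = xc / sd
    yc = y - y.mean()
    ss_x = np.einsum("ij,ij->j", xc, xc)  # = n per column after scaling
    beta = np.zeros(p)
    gamma = np.zeros(p, dtype=bool)
    sigma2 = max(float(np.var(yc)), 1e-6)
    pi_incl = 0.5
    tau2 = slab_scale ** 2
    resid = yc.copy()
    total = burn_in + n_mcmc
    incl_count = np.zeros(p)
    sigma2_trace = np.empty(n_mcmc)
    for it in range(total):
        for j in range(p):
            if gamma[j]:
                resid += xc[:, j] * beta[j]
            prec = ss_x[j] + 1.0 / tau2
            mu = (xc[:, j] @ resid) / prec
            var = sigma2 / prec
            # marginal inclusion odds, integrating the coefficient out
            log_odds = (np.log(pi_incl / (1 - pi_incl))
                        + 0.5 * np.log(1.0 / (tau2 * prec))
                        + 0.5 * mu * mu / var)
            incl = rng.random() < 1.0 / (1.0 + np.exp(-log_odds))
            gamma[j] = incl
            if incl:
                beta[j] = mu + np.sqrt(var) * rng.standard_normal()
                resid -= xc[:, j] * beta[j]
            else:
                beta[j] = 0.0
        k = int(gamma.sum())
        pi_incl = rng.beta(1.0 + k, 1.0 + p - k)
        pi_incl = min(max(pi_incl, 1e-4), 1 - 1e-4)
        shape = 0.5 * (n + k) + 1.0
        scale_ = 0.5 * (resid @ resid + (beta[gamma] ** 2).sum() / tau2) + 1.0
        sigma2 = scale_ / rng.gamma(shape)
        if it >= burn_in:
            incl_count += gamma
            sigma2_trace[it - burn_in] = sigma2
    inclusion = incl_count / n_mcmc
    half = n_mcmc // 2
    m1, m2 = sigma2_trace[:half].mean(), sigma2_trace[half:].mean()
    split_ratio = max(m1, m2) / max(min(m1, m2), 1e-12)
    converged = split_ratio <= 1.2
    if not converged:
        log.warning("bayesian_lasso_screen: split-chain ratio %.2f > 1.2; "
                    "screen may not have converged", split_ratio)
    retained = [marker_ids[j] for j in range(p) if inclusion[j] > 0.5]
    diag = {"inclusion": pd.Series(inclusion, index=marker_ids),
            "split_ratio": float(split_ratio), "converged": bool(converged)}
    return retained, diag


def _lambda_max(x: np.ndarray, y: np.ndarray) -> float:
    # KKT bound for mean-log-loss objective: the all-zero solution is optimal
    # iff max |x' (y - ybar)| / n <= lambda
    n = y.size
    return float(np.abs(x.T @ (y - y.mean())).max() / n)


def lasso_logistic(matrix: np.ndarray, labels: np.ndarray,
                   marker_ids: list[str], cv_folds: int = 10, seed=0,
                   n_lambdas: int = 40, lambda_min_ratio: float = 1e-3,
                   penalty: float | None = None) -> PanelModel:
    """L1-penalized logistic panel; penalty by minimum cross-validated deviance.

    The objective is mean log-loss + lambda * ||beta||_1 (intercept
    unpenalized); the path is log-spaced below the all-zero KKT bound. Pass
    ``penalty`` to skip cross-validation. Markers with zero coefficients are
    excluded from the returned model; an all-zero solution raises
    :class:`EmptyPanelError`.
    """
    x = np.asarray(matrix, dtype=float)
    y = np.asarray(labels).astype(int)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    n = y.size
    lam_max = _lambda_max(x, y)
    if penalty is None:
        lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambdas)
        rs = int(seed) % (2 ** 31) if not isinstance(seed, np.random.Generator) else 0
        folds = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=rs)
        dev = np.zeros(n_lambdas)
        for tr, te in folds.split(x, y):
            for i, lam in enumerate(lambdas):
                model = _l1_fit(x[tr], y[tr], lam)
                eta = x[te] @ model[0] + model[1]
                dev[i] += -np.sum(y[te] * eta - np.logaddexp(0.0, eta))
        penalty = float(lambdas[int(np.argmin(dev))])
    coef, intercept = _l1_fit(x, y, penalty)
    nz = np.flatnonzero(coef != 0.0)
    if nz.size == 0:
        raise EmptyPanelError("chosen penalty removed every marker")
    return PanelModel(marker_ids=[marker_ids[j] for j in nz],
                      coef=coef[nz], intercept=intercept, penalty=penalty,
                      notes={"n_input_markers": len(marker_ids),
                             "lambda_max": lam_max})


def _l1_fit(x: np.ndarray, y: np.ndarray, lam: float):
    """liblinear L1 logistic solve for objective mean-log-loss + lam*||b||_1."""
    n = y.size
    if lam >= _lambda_max(x, y):
        return np.zeros(x.shape[1]), float(np.log(y.mean() / (1 - y.mean())))
    c = 1.0 / (n * lam)
    # liblinear L1-penalizes the intercept; a large intercept_scaling makes
    # the effective intercept penalty negligible
    model = LogisticRegression(l1_ratio=1.0, C=c, solver="liblinear",
                               tol=1e-8, max_iter=5000, random_state=0,
                               intercept_scaling=1e3)
    import warnings as _w
    with _w.catch_warnings():
        # liblinear's stopping rule can flag near-converged solves at this
        # tolerance; the KKT check in the test suite guards actual optimality
        from sklearn.exceptions import ConvergenceWarning
        _w.simplefilter("ignore", ConvergenceWarning)
        model.fit(x, y)
    return model.coef_.ravel(), float(model.intercept_[0])


def lasso_kkt_violation(x: np.ndarray, y: np.ndarray, coef: np.ndarray,
                        intercept: float, lam: float) -> float:
    """Largest KKT violation of the L1 logistic solution (0 = exact optimum)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    eta = x @ coef + intercept
    mu = 1.0 / (1.0 + np.exp(-eta))
    grad = x.T @ (mu - y) / y.size
    viol = np.where(coef == 0.0,
                    np.maximum(np.abs(grad) - lam, 0.0),
                    np.abs(grad + lam * np.sign(coef)))
    return float(max(viol.max(initial=0.0), abs(np.mean(mu - y))))


def youden_cutpoint(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximizing sensitivity + specificity - 1.

    Candidate thresholds are midpoints between adjacent sorted unique scores
    (classification: score > threshold = case); ties take the smallest.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    uniq = np.unique(scores)
    if uniq.size < 2:
        raise ValueError("all scores identical; no usable threshold")
    mids = 0.5 * (uniq[:-1] + uniq[1:])
    n1 = labels.sum()
    n0 = labels.size - n1
    best_j, best_t = -np.inf, mids[0]
    for t in mids:
        pred = scores > t
        sens = np.sum(pred & (labels == 1)) / n1
        spec = np.sum(~pred & (labels == 0)) / n0
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return float(best_t)


def panel_metrics(scores: np.ndarray, labels: np.ndarray,
                  cut_point: float) -> dict:
    labels = np.asarray(labels).astype(int)
    auc_val, lo, hi = delong_auc_ci(scores, labels)
    pred = (np.asarray(scores) > cut_point).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    n1 = int(labels.sum())
    n0 = labels.size - n1
    return {"auc": auc_val, "auc_ci": (lo, hi),
            "accuracy": (tp + tn) / labels.size,
            "sensitivity": tp / n1 if n1 else np.nan,
            "specificity": tn / n0 if n0 else np.nan}


def validate_panel(model: PanelModel, matrix: np.ndarray, labels: np.ndarray,
                   marker_ids: list[str]) -> dict:
    """Frozen-model validation: no coefficient or cut point is refit."""
    if model.cut_point is None:
        raise ValueError("model has no cut point; finish training first")
    scores = model.score(matrix, marker_ids)
    return panel_metrics(scores, labels, model.cut_point)


def build_diagnostic_panel(feature_matrix, feature_labels,
                           train_matrix, train_labels, marker_ids,
                           smr_betas, *, rho_min: float = 0.05,
                           n_mcmc: int = 2000, burn_in: int = 500,
                           cv_folds: int = 10, seed=0,
                           skip_blasso: bool = False) -> PanelModel:
    """Frozen three-set pipeline: filter + screen on the feature-selection set,
    LASSO + Youden cut point on the training set."""
    filt = spearman_concordance_filter(feature_matrix, feature_labels,
                                       smr_betas, marker_ids, rho_min)
    if not filt.retained:
        raise EmptyPanelError("concordance filter removed every marker")
    idx = [marker_ids.index(m) for m in filt.retained]
    if skip_blasso:
        screened = filt.retained
        screen_diag = {"skipped": True}
    else:
        screened, screen_diag = bayesian_lasso_screen(
            np.asarray(feature_matrix, float)[:, idx], feature_labels,
            filt.retained, n_mcmc=n_mcmc, burn_in=burn_in, seed=seed)
    if not screened:
        raise EmptyPanelError("Bayesian-lasso screen removed every marker")
    tr_idx = [marker_ids.index(m) for m in screened]
    x_tr = np.asarray(train_matrix, float)[:, tr_idx]
    model = lasso_logistic(x_tr, train_labels, screened,
                           cv_folds=cv_folds, seed=seed)
    scores = model.score(train_matrix, list(marker_ids))
    model.cut_point = youden_cutpoint(scores, train_labels)
    model.metrics = panel_metrics(scores, train_labels, model.cut_point)
    model.notes.update({"n_after_filter": len(filt.retained),
                        "n_after_screen": len(screened),
                        "screen": {k: v for k, v in screen_diag.items()
                                   if k != "inclusion"}})
    return model


def heidi_matched_comparison(plus_ids: list[str], minus_ids: list[str],
                             minus_p_smr, matrix: np.ndarray,
                             labels: np.ndarray,
                             marker_ids: list[str]) -> dict:
    """Equal-sized HEIDI(+) vs top-HEIDI(-) logistic panels on the same data.

    The HEIDI(-) set is ranked by ascending SMR p and truncated to the size
    of the HEIDI(+) set; if too few are available, all are used and flagged.
    Reports AUC and log-likelihood for both strata.
    """
    if not plus_ids or not minus_ids:
        raise ValueError("both marker strata must be nonempty")
    k = len(plus_ids)
    order = np.argsort(np.asarray(minus_p_smr), kind="stable")
    chosen_minus = [minus_ids[i] for i in order[:k]]
    short = len(chosen_minus) < k
    if short:
        log.warning("heidi_matched_comparison: only %d HEIDI(-) markers for "
                    "k=%d", len(chosen_minus), k)

    def _fit(ids):
        cols = [marker_ids.index(m) for m in ids]
        fit = fit_logistic(np.asarray(matrix, float)[:, cols], labels)
        return {"auc": rank_auc(fit.scores, labels),
                "log_likelihood": fit.ll_model, "n_markers": len(ids)}

    return {"plus": _fit(plus_ids), "minus": _fit(chosen_minus),
            "matched": not short}
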