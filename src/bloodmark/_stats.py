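"""Shared statistical primitives used across the package.

Small, dependency-light routines that several modules need: unpenalized
logistic fits with explicit log-likelihoods, rank-based AUC with DeLong
confidence intervals, Nagelkerke pseudo-R2, and the moment-matched
(Satterthwaite) p-value for a correlated quadratic form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney concordance of `scores` for binary `labels` (1 = case)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(scores)
    return (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong_auc_ci(scores, labels, alpha: float = 0.05) -> tuple[float, float, float]:
    """AUC with a DeLong (1988) asymptotic confidence interval.

    Returns (auc, lower, upper). The variance uses the structural-component
    (midrank) formulation; the interval is clipped to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("DeLong CI needs both classes present")
    tx = _midranks(pos)
    ty = _midranks(neg)
    tz = _midranks(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n  # structural components of the cases
    v10 = 1.0 - (tz[m:] - ty) / m  # ... and of the controls
    var = np.var(v01, ddof=1) / m + np.var(v10, ddof=1) / n
    half = stats.norm.ppf(1 - alpha / 2) * np.sqrt(max(var, 0.0))
    return float(auc), float(max(0.0, auc - half)), float(min(1.0, auc + half))


def satterthwaite_quadform_p(t_stat: float, corr: np.ndarray) -> float:
    """P-value for T = sum of squared correlated standard normals.

    Under the null, T = z'z with z ~ N(0, C) is a mixture sum(lambda_k chi2_1)
    over the eigenvalues of C. The two-moment (Satterthwaite) match approximates
    T ~ a * chi2_nu with a = tr(C^2)/tr(C), nu = tr(C)^2/tr(C^2).
    """
    corr = np.asarray(corr, dtype=float)
    tr1 = np.trace(corr)
    tr2 = float(np.sum(corr * corr))  # tr(C^2) for symmetric C
    if tr1 <= 0 or tr2 <= 0:
        return 1.0
    scale = tr2 / tr1
    df = tr1 * tr1 / tr2
    return float(stats.chi2.sf(t_stat / scale, df))


def nearest_psd(mat: np.ndarray, eps: float = 1e-10) -> tuple[np.ndarray, bool]:
    """Clip negative eigenvalues; returns (repaired matrix, whether repaired)."""
    mat = np.asarray(mat, dtype=float)
    sym = 0.5 * (mat + mat.T)
    w, v = np.linalg.eigh(sym)
    if w.min() >= eps:
        return sym, False
    w_clipped = np.clip(w, eps, None)
    return (v * w_clipped) @ v.T, True


def ridge_invert(mat: np.ndarray, max_tries: int = 12):
    """Invert a symmetric matrix, inflating the diagonal minimally if singular.

    Returns (inverse, ridge_used). Ridge grows geometrically from 1e-8 of the
    mean diagonal until the solve succeeds and is well conditioned.
    """
    mat = np.asarray(mat, dtype=float)
    base = float(np.mean(np.diag(mat))) or 1.0
    ridge = 0.0
    for k in range(max_tries):
        try:
            m = mat + ridge * np.eye(mat.shape[0])
            if np.linalg.cond(m) < 1e10:
                return np.linalg.inv(m), ridge
        except np.linalg.LinAlgError:
            pass
        ridge = base * 1e-8 * (10.0 ** k) if ridge == 0.0 else ridge * 10.0
    raise np.linalg.LinAlgError("matrix not invertible even after ridge repair")


@dataclass
class LogisticFit:
    """Unpenalized (or ridge-fallback) logistic fit with log-likelihoods."""

    coef: np.ndarray
    intercept: float
    ll_model: float
    ll_null: float
    scores: np.ndarray  # linear predictor per sample
    ridge_fallback: bool = False

    @property
    def n_params(self) -> int:
        return self.coef.size + 1

    def predict_score(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float) @ self.coef + self.intercept


def _bernoulli_ll(y: np.ndarray, eta: np.ndarray) -> float:
    # log L = sum y*eta - log(1+exp(eta)), stable via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(x: np.ndarray, y: np.ndarray, *, tol: float = 1e-8,
                 max_iter: int = 500) -> LogisticFit:
    """Maximum-likelihood logistic regression of binary y on columns of x.

    Falls back to a mild ridge (L2, C=1e3) when the unpenalized problem is
    separable / fails to converge; the fallback is flagged on the result.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 1 and x.shape[1] > 1 and np.asarray(y).size == x.shape[1]:
        x = x.T
    y = np.asarray(y).astype(int).ravel()
    if y.min() == y.max():
        raise ValueError("logistic fit needs both classes present")
    ybar = y.mean()
    ll0 = float(y.size * (ybar * np.log(ybar) + (1 - ybar) * np.log1p(-ybar)))
    ridge = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = LogisticRegression(C=np.inf, solver="lbfgs", tol=tol,
                                   max_iter=max_iter)
        model.fit(x, y)
    coef = model.coef_.ravel()
    # heuristically detect separation: runaway coefficients
    if not np.all(np.isfinite(coef)) or np.abs(coef).max(initial=0.0) > 50.0:
        ridge = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = LogisticRegression(C=1e3, solver="lbfgs",
                                       tol=tol, max_iter=max_iter)
            model.fit(x, y)
        coef = model.coef_.ravel()
    intercept = float(model.intercept_[0])
    eta = x @ coef + intercept
    return LogisticFit(coef=coef, intercept=intercept,
                       ll_model=_bernoulli_ll(y, eta), ll_null=ll0,
                       scores=eta, ridge_fallback=ridge)


def nagelkerke_r2(ll_model: float, ll_null: float, n: int) -> float:
    """Nagelkerke's rescaled likelihood-ratio pseudo-R2."""
    cox_snell = 1.0 - np.exp((2.0 / n) * (ll_null - ll_model))
    max_r2 = 1.0 - np.exp((2.0 / n) * ll_null)
    if max_r2 <= 0:
        return 0.0
    return float(np.clip(cox_snell / max_r2, 0.0, 1.0))


def aic(ll_model: float, n_params: int) -> float:
    return -2.0 * ll_model + 2.0 * n_params


def spawn_rng(seed, *path: int) -> np.random.Generator:
    """Counter-based seed fan-out: independent stream per (seed, path).

    A Generator passed as ``seed`` yields a child stream spawned from it
    (deterministic given the parent's state; the parent advances).
    """
    if isinstance(seed, np.random.Generator):
        return seed.spawn(1)[0]
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, path)]))
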