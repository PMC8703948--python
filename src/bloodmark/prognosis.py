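"""Conversion-risk prognosis: risk panels, Cox regression, Kaplan-Meier.

Baseline marker matrices from at-risk subjects (the motivating case is MCI
elders followed for conversion to Alzheimer's disease) are reduced to a
sparse risk panel by the same filter/LASSO/Youden machinery as the
diagnostic module, with converter status as the outcome. The frozen panel
splits a validation cohort into high- and low-risk groups whose conversion
hazard is compared by univariate Cox regression (Efron ties) and summarized
by per-group Kaplan-Meier curves and median non-conversion times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter

from .diagnostic import (PanelModel, lasso_logistic, panel_metrics,
                         spearman_concordance_filter, youden_cutpoint)

log = logging.getLogger(__name__)


@dataclass
class PrognosisResult:
    hazard_ratio: float
    hr_p: float
    hr_ci: tuple[float, float]
    km_curves: dict[str, pd.DataFrame]  # group -> (time, at_risk, events, survival)
    median_survival: dict[str, float | None]  # None = never reached
    n_events: int = 0


def label_converters(followup: pd.DataFrame) -> pd.Series:
    """Converter (1) / non-converter (0) labels from follow-up records.

    ``followup`` needs columns sample, time, event; an optional boolean
    ``recovered`` column excludes subjects who recovered from dementia status.
    Samples with missing time or event are dropped with a warning.
    """
    if followup.empty:
        raise ValueError("empty follow-up record set")
    df = followup.copy()
    if "recovered" in df.columns:
        n_rec = int(df["recovered"].fillna(False).astype(bool).sum())
        if n_rec:
            log.info("label_converters: excluding %d recovered subject(s)", n_rec)
        df = df[~df["recovered"].fillna(False).astype(bool)]
    ok = df["time"].notna() & df["event"].notna()
    if (~ok).any():
        log.warning("label_converters: dropping %d subject(s) with missing "
                    "follow-up", int((~ok).sum()))
    df = df[ok]
    if df.empty:
        raise ValueError("no usable follow-up records")
    return pd.Series(df["event"].astype(int).to_numpy(),
                     index=df["sample"].to_numpy(), name="converter")


def build_risk_model(matrix: np.ndarray, converter_labels: np.ndarray,
                     marker_ids: list[str], smr_betas=None, *,
                     rho_min: float = 0.05, cv_folds: int = 10,
                     seed=0) -> PanelModel:
    """Sparse conversion-risk panel on converter status.

    Reuses the diagnostic stages: optional Spearman concordance filter
    (applied when SMR betas are supplied), LASSO with cross-validated
    penalty, and a Youden cut point on the training scores.
    """
    y = np.asarray(converter_labels).astype(int)
    ids = list(marker_ids)
    x = np.asarray(matrix, dtype=float)
    if smr_betas is not None:
        filt = spearman_concordance_filter(x, y, smr_betas, ids, rho_min)
        if not filt.retained:
            raise ValueError("concordance filter removed every marker")
        cols = [ids.index(m) for m in filt.retained]
        x, ids = x[:, cols], filt.retained
    model = lasso_logistic(x, y, ids, cv_folds=cv_folds, seed=seed)
    scores = model.score(matrix, list(marker_ids))
    model.cut_point = youden_cutpoint(scores, y)
    model.metrics = panel_metrics(scores, y, model.cut_point)
    model.notes["risk_group_rule"] = "high iff score > cut_point (boundary -> low)"
    return model


def assign_risk_groups(model: PanelModel, matrix: np.ndarray,
                       marker_ids: list[str]) -> np.ndarray:
    """High/low conversion-risk groups from the frozen panel.

    Returns a boolean array (True = high risk); a score exactly at the cut
    point classifies as low risk (strict inequality).
    """
    if model.cut_point is None:
        raise ValueError("model has no cut point")
    return model.score(matrix, marker_ids) > model.cut_point


def _km_table(kmf: KaplanMeierFitter) -> pd.DataFrame:
    ev = kmf.event_table
    surv = kmf.survival_function_.iloc[:, 0]
    return pd.DataFrame({"time": ev.index.to_numpy(),
                         "at_risk": ev["at_risk"].to_numpy(),
                         "events": ev["observed"].to_numpy(),
                         "survival": surv.reindex(ev.index).to_numpy()})


def _km_median(kmf: KaplanMeierFitter) -> float | None:
    med = kmf.median_survival_time_
    return None if np.isinf(med) else float(med)


def cox_univariate(groups: np.ndarray, time: np.ndarray,
                   event: np.ndarray) -> PrognosisResult:
    """Univariate Cox PH fit of the high/low risk indicator (Efron ties).

    HR = exp(coefficient) for high vs low risk, with the Wald p-value, plus
    Kaplan-Meier curves and median non-conversion times per group.
    """
    groups = np.asarray(groups).astype(bool)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    if event.sum() == 0:
        raise ValueError("Cox regression needs at least one event")
    df = pd.DataFrame({"time": time, "event": event,
                       "high_risk": groups.astype(int)})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    hr = float(np.exp(cph.params_["high_risk"]))
    p = float(cph.summary.loc["high_risk", "p"])
    lo = float(np.exp(cph.confidence_intervals_.iloc[0, 0]))
    hi = float(np.exp(cph.confidence_intervals_.iloc[0, 1]))
    curves, medians = {}, {}
    for name, mask in (("high", groups), ("low", ~groups)):
        if mask.sum() == 0:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask], label=name)
        curves[name] = _km_table(kmf)
        medians[name] = _km_median(kmf)
    return PrognosisResult(hazard_ratio=hr, hr_p=p, hr_ci=(lo, hi),
                           km_curves=curves, median_survival=medians,
                           n_events=int(event.sum()))


def nonconversion_summary(groups: np.ndarray, time: np.ndarray,
                          event: np.ndarray, horizon_days: float) -> pd.DataFrame:
    """Per-group Kaplan-Meier survival at a horizon plus median survival.

    The median is the earliest time where S(t) <= 0.5 ("not reached" = NaN).
    """
    if horizon_days <= 0:
        raise ValueError("horizon must be positive")
    groups = np.asarray(groups).astype(bool)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    rows = []
    for name, mask in (("high", groups), ("low", ~groups)):
        if mask.sum() == 0:
            raise ValueError(f"empty {name}-risk group")
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask])
        surv_at = float(kmf.predict(horizon_days))
        med = _km_median(kmf)
        rows.append({"group": name, "n": int(mask.sum()),
                     "events": int(event[mask].sum()),
                     "survival_at_horizon": surv_at,
                     "median_survival_days": np.nan if med is None else med})
    return pd.DataFrame(rows)
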