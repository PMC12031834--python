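"""Survival analysis of ICANS risk from EEG covariates.

Two Cox proportional-hazards formulations are used, matching how the EEGs
were scheduled: a *fixed*-covariate model where the pre-infusion (baseline)
EEG value is a constant predictor of time-to-ICANS from infusion (day 0), and
a *time-dependent* model in counting-process format where the covariate is
updated at each post-infusion EEG day (last observation carried forward) —
EEGs recorded on or after clinical ICANS onset never contribute, since the
question is prediction, not description, of neurotoxicity.

Estimation is by partial likelihood with Efron tie handling; results are
reported as hazard ratios with Wald 95% confidence intervals. Multivariable
models are selected by a forward-backward stepwise procedure on the
likelihood-ratio test. No multiplicity correction is applied across the
feature family; reports should flag this.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, CoxTimeVaryingFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from .exceptions import (ConfigError, DataError, DegenerateError, FitError,
                         SizeError)
from .records import PatientTimeline

#: Tiny interval used when the event falls on day 0 (an immediate event must
#: still occupy a positive-length at-risk interval).
_IMMEDIATE_EVENT_STOP = 1e-3


@dataclass
class CoxResult:
    """One fitted covariate: hazard ratio, Wald 95% CI, p-value."""

    covariate: str
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    coef: float
    se: float
    n_events: int
    model_type: str          # "fixed" or "time_dependent"
    adjusted: bool = False
    log_likelihood: float = float("nan")


def _covariate_series(tl: PatientTimeline, feature: str) -> list[float]:
    """Per-EEG covariate values for one timeline."""
    if feature == "grade":
        return [float(g) for g in tl.grades]
    cov = tl.covariates.get(feature)
    if cov is not None:
        if np.isscalar(cov):
            return [float(cov)] * len(tl.eeg_days)
        return [float(v) for v in cov]
    return [float(f.as_dict()[feature]) for f in tl.features]


def expand_counting_process(timelines: Sequence[PatientTimeline],
                            feature: str) -> pd.DataFrame:
    """Long-format (start, stop] survival rows with a time-varying covariate.

    The covariate is carried forward from the most recent EEG: the baseline
    (pre-infusion) value applies from day 0 until the first post-infusion EEG
    day, then each pre-onset EEG updates it. Rows partition (0, event-or-censor
    day] per patient; the event flag sits on the final row. EEGs flagged as
    recorded during ICANS are skipped.
    """
    rows = []
    for tl in timelines:
        end = tl.end_day
        if end < 0:
            raise DataError(f"{tl.patient_id}: negative follow-up time")
        values = _covariate_series(tl, feature)
        excluded = tl.excluded
        usable = [(d, v) for d, v, ex in zip(tl.eeg_days, values, excluded) if not ex]
        if not usable:
            raise DataError(f"{tl.patient_id}: no usable EEG measurement")
        pre = [v for d, v in usable if d <= 0]
        if not pre:
            pre = [usable[0][1]]
        current = pre[-1]
        update_days = [(d, v) for d, v in usable if 0 < d < end]

        if end == 0:  # immediate event on infusion day
            rows.append((tl.patient_id, 0.0, _IMMEDIATE_EVENT_STOP, tl.event, current))
            continue
        start = 0.0
        for d, v in update_days:
            if d > start:
                rows.append((tl.patient_id, start, d, False, current))
                start = d
            current = v
        rows.append((tl.patient_id, start, end, tl.event, current))
    df = pd.DataFrame(rows, columns=["patient_id", "start", "stop", "event", feature])
    validate_counting_process(df)
    return df


def validate_counting_process(df: pd.DataFrame) -> None:
    """Check the counting-process invariants (raises :class:`DataError`)."""
    if (df["start"] >= df["stop"]).any():
        raise DataError("rows with start >= stop")
    for pid, sub in df.groupby("patient_id"):
        sub = sub.sort_values("start")
        if int(sub["event"].sum()) > 1:
            raise DataError(f"{pid}: more than one event row")
        starts, stops = sub["start"].to_numpy(), sub["stop"].to_numpy()
        if not np.allclose(starts[1:], stops[:-1]):
            raise DataError(f"{pid}: rows not contiguous")


def baseline_table(timelines: Sequence[PatientTimeline],
                   feature: str) -> pd.DataFrame:
    """Fixed-covariate table: baseline EEG value, follow-up time, event flag."""
    rows = []
    for tl in timelines:
        values = _covariate_series(tl, feature)
        pre = [v for d, v in zip(tl.eeg_days, values) if d <= 0]
        if not pre:
            raise DataError(f"{tl.patient_id}: no baseline EEG")
        rows.append((tl.patient_id, max(tl.end_day, _IMMEDIATE_EVENT_STOP),
                     tl.event, pre[-1]))
    return pd.DataFrame(rows, columns=["patient_id", "duration", "event", feature])


def _check_fit_inputs(df: pd.DataFrame, covariates: Sequence[str]) -> int:
    n_events = int(df["event"].sum())
    if n_events == 0:
        raise DegenerateError("no events: Cox model is undefined")
    if n_events < 5:
        warnings.warn(f"only {n_events} events; estimates will be unstable",
                      RuntimeWarning)
    for cov in covariates:
        if df[cov].nunique() < 2:
            raise DegenerateError(f"covariate {cov!r} is constant across rows")
    return n_events


def fit_cox(df: pd.DataFrame, covariates: Sequence[str],
            model: str = "fixed", adjusted: Optional[bool] = None
            ) -> list[CoxResult]:
    """Fit a Cox model and return one :class:`CoxResult` per covariate.

    ``model='fixed'`` expects columns (duration, event, covariates...);
    ``model='time_dependent'`` expects counting-process columns
    (patient_id, start, stop, event, covariates...). Efron tie handling,
    Wald 95% confidence intervals.
    """
    covariates = list(covariates)
    if not covariates:
        raise ConfigError("need at least one covariate")
    n_events = _check_fit_inputs(df, covariates)
    ll, summary = _fit_lifelines(df, covariates, model)
    out = []
    for cov in covariates:
        row = summary.loc[cov]
        out.append(CoxResult(
            covariate=cov, hr=float(row["exp(coef)"]),
            ci_low=float(np.exp(row["coef"] - 1.959963984540054 * row["se(coef)"])),
            ci_high=float(np.exp(row["coef"] + 1.959963984540054 * row["se(coef)"])),
            p_value=float(row["p"]), coef=float(row["coef"]),
            se=float(row["se(coef)"]), n_events=n_events, model_type=model,
            adjusted=(len(covariates) > 1 if adjusted is None else adjusted),
            log_likelihood=ll,
        ))
    return out


def _fit_lifelines(df: pd.DataFrame, covariates: list[str], model: str):
    opts = {"fit_options": {"precision": 1e-12}}
    try:
        if model == "fixed":
            fitter = CoxPHFitter()
            fitter.fit(df[["duration", "event"] + covariates],
                       duration_col="duration", event_col="event", **opts)
        elif model == "time_dependent":
            fitter = CoxTimeVaryingFitter()
            fitter.fit(df[["patient_id", "start", "stop", "event"] + covariates],
                       id_col="patient_id", start_col="start", stop_col="stop",
                       event_col="event", **opts)
        else:
            raise ConfigError(f"unknown model type {model!r}")
    except ConvergenceError as exc:
        raise FitError(f"Cox fit did not converge: {exc}",
                       diagnostics=str(exc)) from exc
    return float(fitter.log_likelihood_), fitter.summary


def _null_log_likelihood(df: pd.DataFrame, model: str) -> float:
    # Null partial log-likelihood recovered from any single-covariate fit:
    # ll_null = ll_fit - LR/2, with LR the model's likelihood-ratio statistic.
    probe = [c for c in df.columns
             if c not in ("patient_id", "start", "stop", "event", "duration")
             and df[c].nunique() > 1][0]
    if model == "fixed":
        fitter = CoxPHFitter()
        fitter.fit(df[["duration", "event", probe]], "duration", "event")
    else:
        fitter = CoxTimeVaryingFitter()
        fitter.fit(df[["patient_id", "start", "stop", "event", probe]],
                   id_col="patient_id", start_col="start", stop_col="stop",
                   event_col="event")
    lr = float(fitter.log_likelihood_ratio_test().test_statistic)
    return float(fitter.log_likelihood_) - lr / 2.0


def stepwise_select(df: pd.DataFrame, candidates: Sequence[str],
                    alpha: float = 0.05, model: str = "fixed"
                    ) -> tuple[list[str], list[CoxResult]]:
    """Forward-backward covariate selection on the likelihood-ratio test.

    At each forward step the candidate with the smallest LRT p-value enters if
    p < alpha (lexicographic tie-break for determinism); after each entry,
    covariates whose removal is not rejected at alpha are dropped. Returns the
    selected covariates and the final multivariable fit (empty list and no
    results if nothing enters).
    """
    candidates = sorted(candidates)
    selected: list[str] = []
    ll_current = _null_log_likelihood(df, model)

    improved = True
    while improved:
        improved = False
        best = None
        for cand in candidates:
            if cand in selected:
                continue
            try:
                ll_new = _fit_lifelines(df, selected + [cand], model)[0]
            except (FitError, DegenerateError):
                continue
            p = stats.chi2.sf(2.0 * (ll_new - ll_current), df=1)
            if p < alpha and (best is None or p < best[0] - 1e-15):
                best = (p, cand, ll_new)
        if best is not None:
            selected.append(best[1])
            ll_current = best[2]
            improved = True
            # backward pass
            for cov in list(selected[:-1]):
                reduced = [c for c in selected if c != cov]
                ll_reduced = (_fit_lifelines(df, reduced, model)[0]
                              if reduced else _null_log_likelihood(df, model))
                p_drop = stats.chi2.sf(2.0 * (ll_current - ll_reduced), df=1)
                if p_drop >= alpha:
                    selected.remove(cov)
                    ll_current = ll_reduced
    if not selected:
        return [], []
    return selected, fit_cox(df, selected, model=model, adjusted=len(selected) > 1)


def tertile_cutoffs(values: Sequence[float]) -> tuple[float, float]:
    """Empirical 33.3/66.7 percentile cut-offs (linear interpolation)."""
    values = np.asarray(values, dtype=float)
    if values.size < 9:
        raise SizeError("tertile analysis needs at least 9 values")
    lo, hi = np.percentile(values, [100.0 / 3.0, 200.0 / 3.0])
    if lo == hi:
        warnings.warn("degenerate tertile cut-offs (heavy ties)", RuntimeWarning)
    return float(lo), float(hi)


def tertile_analysis(df: pd.DataFrame, feature: str, model: str = "fixed",
                     values: Optional[Sequence[float]] = None
                     ) -> tuple[tuple[float, float], CoxResult]:
    """Dichotomize a feature at its upper-tertile cut-off and fit the risk.

    Cut-offs come from ``values`` when given (e.g. one value per record)
    or from the feature column itself; the fitted covariate is the indicator
    "feature above the second/third-tertile cut-off".
    """
    cuts = tertile_cutoffs(df[feature] if values is None else values)
    work = df.copy()
    indicator = f"{feature}_above_t3"
    work[indicator] = (work[feature] > cuts[1]).astype(float)
    result = fit_cox(work, [indicator], model=model)[0]
    return cuts, result


def group_compare(values: Sequence[float], labels: Sequence,
                  kind: str = "continuous") -> tuple[float, float]:
    """Two-group comparison: Mann-Whitney U (continuous) or chi-square.

    Returns (statistic, two-sided p). The chi-square is Pearson's without
    continuity correction; a warning is issued when any expected cell count
    is below 5.
    """
    values = np.asarray(values)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise SizeError("values and labels must have equal length")
    groups = np.unique(labels)
    if len(groups) != 2:
        raise DataError(f"need exactly two groups, got {len(groups)}")
    if kind == "continuous":
        a = values[labels == groups[0]].astype(float)
        b = values[labels == groups[1]].astype(float)
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        return float(stat), float(p)
    if kind == "categorical":
        table = pd.crosstab(pd.Series(values), pd.Series(labels)).to_numpy()
        stat, p, _dof, expected = stats.chi2_contingency(table, correction=False)
        if (expected < 5).any():
            warnings.warn("chi-square expected counts below 5", RuntimeWarning)
        return float(stat), float(p)
    raise ConfigError(f"unknown kind {kind!r}")
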