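"""Stage 6: prognostic screening of selected lncRNAs.

Candidates are first screened univariately: tumor samples are split at the
median of each lncRNA's expression and compared with the Kaplan-Meier
estimator and the log-rank test.  Survivors of that screen enter a
multivariate Cox proportional-hazards model (Breslow tie handling, via
lifelines) together with the clinical covariates; a lncRNA whose Cox term
stays significant is flagged an independent prognostic factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from lifelines.statistics import logrank_test

__all__ = ["CoxResult", "km_logrank", "cox_fit", "prognostic_screen"]


@dataclass
class CoxResult:
    """Multivariate Cox fit: per-covariate estimates plus convergence state."""

    summary: pd.DataFrame  # index: covariate; columns: beta, hr, ci_lower, ci_upper, se, p
    converged: bool
    n: int
    n_events: int


def km_logrank(
    time, event, groups
) -> tuple[dict[str, pd.DataFrame], float, float]:
    """Kaplan-Meier curves and the two-group log-rank test.

    ``groups`` assigns each observation to one of exactly two groups.
    Returns ``(curves, chi2, p)`` where ``curves`` maps group label to a
    frame of product-limit survival estimates, and the chi-square statistic
    (1 df) accumulates observed-minus-expected event counts with
    hypergeometric variances over the event times.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups).tolist())
    if len(labels) != 2:
        raise ValueError("log-rank screen requires exactly two groups")
    masks = {lab: groups == lab for lab in labels}
    for lab, m in masks.items():
        if m.sum() == 0:
            raise ValueError(f"group {lab!r} has no subjects")
        if event[m].sum() == 0:
            raise ValueError(f"group {lab!r} has no events")
    curves = {}
    for lab, m in masks.items():
        kmf = KaplanMeierFitter()
        kmf.fit(time[m], event[m], label=str(lab))
        sf = kmf.survival_function_
        curves[str(lab)] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    a, b = labels
    res = logrank_test(
        time[masks[a]], time[masks[b]],
        event_observed_A=event[masks[a]], event_observed_B=event[masks[b]],
    )
    return curves, float(res.test_statistic), float(res.p_value)


def cox_fit(
    records: pd.DataFrame,
    duration_col: str = "time",
    event_col: str = "event",
    covariates: list[str] | None = None,
) -> CoxResult:
    """Multivariate Cox proportional hazards via the partial likelihood.

    Categorical covariates are dummy-coded against a first-level reference;
    numeric covariates enter as-is.  Ties are handled with Breslow's
    approximation.  Monotone likelihood (separation) or non-convergence is
    flagged rather than reported as an estimate.
    """
    if covariates is None:
        covariates = [c for c in records.columns if c not in (duration_col, event_col)]
    df = records[[duration_col, event_col]].copy()
    df[event_col] = df[event_col].astype(int)
    for c in covariates:
        col = records[c]
        if pd.api.types.is_numeric_dtype(col):
            if col.nunique() <= 1:
                raise ValueError(f"constant covariate {c!r}")
            df[c] = col.astype(float)
        else:
            dummies = pd.get_dummies(col.astype(str), prefix=c, drop_first=True, dtype=float)
            if dummies.shape[1] == 0:
                raise ValueError(f"constant covariate {c!r}")
            df = pd.concat([df, dummies], axis=1)
    n_events = int(df[event_col].sum())
    if n_events < 10:
        warnings.warn(f"only {n_events} events; Cox estimates may be unstable")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=ConvergenceWarning)
            cph.fit(df, duration_col=duration_col, event_col=event_col)
        converged = True
    except (ConvergenceError, ConvergenceWarning):
        # retry tolerantly to recover estimates where possible, but flag
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col=duration_col, event_col=event_col)
            converged = False
        except ConvergenceError:
            empty = pd.DataFrame(
                columns=["beta", "hr", "ci_lower", "ci_upper", "se", "p"], dtype=float
            )
            return CoxResult(summary=empty, converged=False, n=len(df), n_events=n_events)
    s = cph.summary
    summary = pd.DataFrame(
        {
            "beta": s["coef"],
            "hr": s["exp(coef)"],
            "ci_lower": np.exp(s["coef lower 95%"]),
            "ci_upper": np.exp(s["coef upper 95%"]),
            "se": s["se(coef)"],
            "p": s["p"],
        }
    )
    return CoxResult(summary=summary, converged=converged, n=len(df), n_events=n_events)


def median_split(expr: pd.Series) -> pd.Series:
    """Rank-based median split: lower half 'low', upper half 'high'.

    Ordering ties are broken by sample id so even sample counts always
    split exactly in half.
    """
    order = sorted(expr.index, key=lambda s: (expr[s], str(s)))
    half = len(order) // 2
    lab = pd.Series("low", index=order)
    lab.iloc[:] = ["low"] * half + ["high"] * (len(order) - half)
    return lab.reindex(expr.index)


def prognostic_screen(
    lnc_expr: pd.DataFrame,
    selected: list[str],
    records: pd.DataFrame,
    covariate_cols: list[str] | None = None,
    alpha: float = 0.05,
    duration_col: str = "time",
    event_col: str = "event",
) -> pd.DataFrame:
    """KM/log-rank screen then multivariate Cox per surviving lncRNA.

    For each selected lncRNA: split samples at the median expression and
    keep the lncRNA when the log-rank p < ``alpha``; then fit a Cox model
    of standardized expression plus the clinical covariates and flag the
    lncRNA independent iff its own term's p < ``alpha``.  All-tied
    expression is skipped with a warning.
    """
    if covariate_cols is None:
        covariate_cols = [c for c in records.columns if c not in (duration_col, event_col)]
    samples = [s for s in records.index if s in set(lnc_expr.columns)]
    if len(samples) < 10:
        raise ValueError("too few samples shared between expression and survival records")
    rec = records.loc[samples]
    rows = []
    for lnc in sorted(set(selected) & set(lnc_expr.index)):
        expr = lnc_expr.loc[lnc, samples].astype(float)
        if expr.nunique() <= 1:
            warnings.warn(f"{lnc}: all-tied expression; skipped from prognostic screen")
            continue
        groups = median_split(expr)
        try:
            _, chi2, logrank_p = km_logrank(
                rec[duration_col], rec[event_col], groups.loc[samples]
            )
        except ValueError as exc:
            warnings.warn(f"{lnc}: log-rank not applicable ({exc}); skipped")
            continue
        row = {
            "lncrna_id": lnc,
            "logrank_chi2": chi2,
            "logrank_p": logrank_p,
            "cox_beta": np.nan,
            "cox_hr": np.nan,
            "cox_p": np.nan,
            "independent": False,
        }
        if logrank_p < alpha:
            df = rec[[duration_col, event_col] + list(covariate_cols)].copy()
            df["lnc_expr"] = (expr - expr.mean()) / expr.std(ddof=0)
            fit = cox_fit(df, duration_col, event_col)
            if fit.converged and "lnc_expr" in fit.summary.index:
                row["cox_beta"] = fit.summary.loc["lnc_expr", "beta"]
                row["cox_hr"] = fit.summary.loc["lnc_expr", "hr"]
                row["cox_p"] = fit.summary.loc["lnc_expr", "p"]
                row["independent"] = bool(row["cox_p"] < alpha)
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["lncrna_id", "logrank_chi2", "logrank_p", "cox_beta", "cox_hr", "cox_p", "independent"],
    )
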