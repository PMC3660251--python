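"""Relapse-free survival analysis.

Kaplan-Meier estimation, log-rank comparison of subtype survival curves,
Cox proportional-hazards regression (Efron tie handling) with Wald
confidence intervals, and bidirectional (backward-forward) covariate
selection by AIC.  Times are in months; records are censored at a 5-year
(60-month) horizon before analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

logger = logging.getLogger(__name__)

HORIZON_MONTHS = 60.0
HIGH_RISK_SUBTYPES = frozenset({"C4", "C6"})


def censor_at_horizon(records: pd.DataFrame, horizon: float = HORIZON_MONTHS
                      ) -> pd.DataFrame:
    """Truncate follow-up beyond ``horizon`` months: later times become the
    horizon with the event flag cleared; records at or before it are kept."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    out = records.copy()
    late = out["time_months"] > horizon
    out.loc[late, "time_months"] = horizon
    out.loc[late, "event"] = 0
    return out


def km_curve(records: pd.DataFrame) -> KaplanMeierFitter:
    """Product-limit survival estimate; ``survival_at`` gives the
    right-continuous step value."""
    if len(records) == 0:
        raise ValueError("no survival records")
    kmf = KaplanMeierFitter()
    kmf.fit(records["time_months"], records["event"])
    return kmf


def survival_at(kmf: KaplanMeierFitter, t: float) -> float:
    return float(kmf.predict(t))


def logrank_test(records: pd.DataFrame, groups: pd.Series
                 ) -> tuple[float, int, float]:
    """Log-rank chi-squared test across groups; df = groups − 1."""
    groups = pd.Series(groups).reindex(records.index)
    levels = pd.unique(groups.dropna())
    if len(levels) < 2:
        raise ValueError("log-rank test needs at least two groups")
    res = multivariate_logrank_test(records["time_months"], groups,
                                    records["event"])
    return float(res.test_statistic), len(levels) - 1, float(res.p_value)


@dataclass
class CoxResult:
    """Hazard ratios with 95% Wald CIs plus model-level statistics."""

    summary: pd.DataFrame  # index covariate; hr, ci_lower, ci_upper, p
    model_p: float
    n: int
    n_events: int
    log_likelihood: float
    aic: float
    covariates: tuple = ()
    fitter: CoxPHFitter | None = field(default=None, repr=False)


def _encode_covariates(records: pd.DataFrame, covariates) -> pd.DataFrame:
    """Dummy-encode categorical covariates against their first (sorted)
    level as the reference, e.g. stage II as 'tnm_stage=III (ref=II)'."""
    cols = {}
    for c in covariates:
        v = records[c]
        if v.dtype.kind in "ifb" and v.nunique() > 2:
            cols[c] = v.astype(float)
        elif v.dtype.kind in "ifb":
            cols[c] = v.astype(float)
        else:
            levels = sorted(v.dropna().unique())
            ref = levels[0]
            for lev in levels[1:]:
                cols[f"{c}={lev} (ref={ref})"] = (v == lev).astype(float)
    enc = pd.DataFrame(cols, index=records.index)
    const = [c for c in enc.columns if enc[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariate(s): {const}")
    return enc


def null_log_partial_likelihood(records: pd.DataFrame) -> float:
    """Efron log partial likelihood of the covariate-free model (all risk
    scores equal): for a tie group of size d at an event time with risk-set
    size r, the contribution is -sum_{j=0..d-1} log(r - j)."""
    t = records["time_months"].to_numpy(dtype=float)
    e = records["event"].to_numpy(dtype=int)
    ll = 0.0
    for u in np.unique(t[e == 1]):
        d = int(((t == u) & (e == 1)).sum())
        r = int((t >= u).sum())
        ll -= sum(np.log(r - j) for j in range(d))
    return float(ll)


def cox_fit(records: pd.DataFrame, covariates,
            alpha: float = 0.05) -> CoxResult:
    """Cox proportional-hazards fit (Efron ties) on complete cases.

    ``records`` must hold time_months and event plus the covariate columns;
    categorical covariates are dummy-encoded against their first sorted
    level.  The model p-value is the likelihood-ratio test against the null
    model.
    """
    covariates = list(covariates)
    if not covariates:
        raise ValueError("no covariates supplied")
    data = records[["time_months", "event"] + covariates].dropna()
    enc = _encode_covariates(data, covariates)
    df = pd.concat([data[["time_months", "event"]], enc], axis=1)
    cph = CoxPHFitter(alpha=alpha)
    try:
        cph.fit(df, duration_col="time_months", event_col="event")
    except Exception as exc:  # lifelines ConvergenceError and warnings
        raise RuntimeError(
            f"Cox model did not converge for {covariates}: {exc}") from exc
    s = cph.summary
    summary = pd.DataFrame({
        "hr": s["exp(coef)"],
        "ci_lower": s["exp(coef) lower 95%"],
        "ci_upper": s["exp(coef) upper 95%"],
        "p": s["p"],
    })
    lrt = cph.log_likelihood_ratio_test()
    k = enc.shape[1]
    ll = float(cph.log_likelihood_)
    return CoxResult(summary=summary, model_p=float(lrt.p_value),
                     n=len(df), n_events=int(df["event"].sum()),
                     log_likelihood=ll, aic=2 * k - 2 * ll,
                     covariates=tuple(covariates), fitter=cph)


def _null_result(records: pd.DataFrame) -> CoxResult:
    ll0 = null_log_partial_likelihood(records)
    return CoxResult(summary=pd.DataFrame(
        columns=["hr", "ci_lower", "ci_upper", "p"]),
        model_p=1.0, n=len(records),
        n_events=int(records["event"].sum()),
        log_likelihood=ll0, aic=-2 * ll0, covariates=())


def stepwise_cox(records: pd.DataFrame, candidates,
                 verbose: bool = False) -> tuple[CoxResult, tuple]:
    """Bidirectional AIC-guided covariate selection, starting from the full
    model, on the subset of records with every candidate observed.

    At each step the single addition or removal giving the largest AIC
    decrease is taken; selection stops when no move improves the AIC.
    Deterministic given the data.  Returns (result, selected covariates).
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate covariates")
    data = records[["time_months", "event"] + candidates].dropna()

    def fit_or_none(covs):
        if not covs:
            return _null_result(data)
        try:
            return cox_fit(data, covs)
        except RuntimeError:
            return None

    current = tuple(candidates)
    best = fit_or_none(current)
    if best is None:
        # full model inadmissible; fall back to null and step forward
        current, best = (), _null_result(data)
    while True:
        moves = []
        for c in current:
            cand = tuple(x for x in current if x != c)
            moves.append((cand, fit_or_none(cand)))
        for c in candidates:
            if c not in current:
                moves.append((current + (c,), fit_or_none(current + (c,))))
        moves = [(covs, r) for covs, r in moves if r is not None]
        if not moves:
            break
        covs, res = min(moves, key=lambda m: m[1].aic)
        if res.aic < best.aic - 1e-9:
            current, best = covs, res
            if verbose:
                logger.info("step: %s (AIC %.2f)", covs, res.aic)
        else:
            break
    if not current:
        warnings.warn("stepwise selection retained no covariate; "
                      "returning the null model")
    return best, current


def recode_high_risk(labels: pd.Series,
                     high=HIGH_RISK_SUBTYPES) -> pd.Series:
    """Binary high-risk indicator combining the poor-prognosis subtypes
    (default C4 and C6) against all others."""
    return labels.isin(high).astype(int).rename("high_risk")
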