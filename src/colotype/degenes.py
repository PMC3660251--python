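"""One-vs-rest moderated t-statistics and discriminant-gene selection.

For each subtype, every gene is tested subtype-vs-all-others with an
empirical-Bayes moderated t-statistic: gene-wise pooled variances are
shrunk toward a common prior variance s0² with prior degrees of freedom d0,
both estimated by moment-matching the distribution of log sample variances
across genes.  The moderated statistic

    t_g = logFC_g / (s̃_g · sqrt(1/n1 + 1/n2)),
    s̃_g² = (d0·s0² + d_g·s_g²) / (d0 + d_g),

is referred to a t distribution on d0 + d_g degrees of freedom.  Subtype
signatures are the genes passing an adjusted-p and log-fold-change filter
(defaults 1e-5 and 0.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

P_THRESHOLD = 1e-5
LFC_THRESHOLD = 0.5


@dataclass(frozen=True)
class DiscriminantSet:
    """Genes discriminating one subtype from the rest, split by direction
    and ordered by decreasing |moderated t|."""

    subtype: str
    up_genes: tuple
    down_genes: tuple
    p_threshold: float = P_THRESHOLD
    lfc_threshold: float = LFC_THRESHOLD


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration on the
    better-conditioned reciprocal scale."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: float
                            ) -> tuple[float, float]:
    """Moment-match log sample variances to estimate the prior degrees of
    freedom d0 and prior variance s0².

    Returns (d0, s0²); d0 = inf when the observed spread of log variances
    is no larger than expected from chi-squared sampling alone.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 2:
        raise ValueError("need at least two positive gene variances")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var > 0:
        d0 = 2.0 * trigamma_inverse(e_var)
        s0_2 = np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_2 = np.exp(e_mean)
    return d0, float(s0_2)


def adjust_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, order-preserving,
    capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def moderated_t(expr: pd.DataFrame, labels: pd.Series, subtype: str,
                prior_df: float | None = None,
                prior_var: float | None = None) -> pd.DataFrame:
    """Gene-wise moderated t-test of ``subtype`` vs all other samples.

    Parameters
    ----------
    expr : DataFrame, genes x samples
    labels : Series mapping sample to subtype
    subtype : the group of interest
    prior_df, prior_var : optional overrides of the estimated (d0, s0²);
        ``prior_df=0`` recovers the ordinary pooled two-sample t-test and
        ``prior_df=inf`` gives every gene the common variance s0².

    Returns
    -------
    DataFrame indexed by gene with columns log_fc, t_mod, df_total, p,
    p_adj.
    """
    labels = labels.reindex(expr.columns)
    in_grp = (labels == subtype).to_numpy()
    n1, n2 = int(in_grp.sum()), int((~in_grp).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"both groups need >= 2 samples (subtype {subtype}: {n1} vs rest "
            f"{n2})")
    X = expr.to_numpy(dtype=float)
    x1, x2 = X[:, in_grp], X[:, ~in_grp]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    df_resid = n1 + n2 - 2
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df_resid

    zero = s2 <= 0
    if zero.any():
        floor = max(np.median(s2[~zero]) if (~zero).any() else 1.0, 1e-12)
        floor *= 1e-8
        logger.warning("%d all-constant gene(s); variance floor %.3g applied",
                       int(zero.sum()), floor)
        s2 = np.where(zero, floor, s2)

    if prior_df is None or prior_var is None:
        d0_est, s0_2_est = estimate_variance_prior(s2, df_resid)
        d0 = d0_est if prior_df is None else prior_df
        s0_2 = s0_2_est if prior_var is None else prior_var
    else:
        d0, s0_2 = prior_df, prior_var

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    log_fc = m1 - m2
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    t_mod = log_fc / se
    p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    return pd.DataFrame(
        {"log_fc": log_fc, "t_mod": t_mod,
         "df_total": np.full(len(s2), df_total), "p": p,
         "p_adj": adjust_bh(p)},
        index=expr.index)


def moderated_t_all(expr: pd.DataFrame, labels: pd.Series,
                    **kwargs) -> dict[str, pd.DataFrame]:
    """One-vs-rest moderated t tables for every subtype present."""
    return {s: moderated_t(expr, labels, s, **kwargs)
            for s in sorted(pd.unique(labels.dropna()))}


def discriminant_genes(stats_by_subtype: dict[str, pd.DataFrame],
                       p_threshold: float = P_THRESHOLD,
                       lfc_threshold: float = LFC_THRESHOLD
                       ) -> dict[str, DiscriminantSet]:
    """Apply the adjusted-p and |logFC| filters per subtype; up and down
    lists ordered by |t_mod| descending."""
    out = {}
    for s, tab in stats_by_subtype.items():
        keep = tab[(tab["p_adj"] < p_threshold)
                   & (tab["log_fc"].abs() > lfc_threshold)]
        keep = keep.reindex(keep["t_mod"].abs()
                            .sort_values(ascending=False).index)
        out[s] = DiscriminantSet(
            subtype=s,
            up_genes=tuple(keep.index[keep["log_fc"] > lfc_threshold]),
            down_genes=tuple(keep.index[keep["log_fc"] < -lfc_threshold]),
            p_threshold=p_threshold, lfc_threshold=lfc_threshold)
    return out


def stats_table(stats_by_subtype: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Wide per-gene table with logFC and adjusted p per contrast
    (columns logFC_<s>vsRest, adjp_<s>vsRest)."""
    cols = {}
    for s, tab in stats_by_subtype.items():
        cols[f"logFC_{s}vsRest"] = tab["log_fc"]
        cols[f"adjp_{s}vsRest"] = tab["p_adj"]
    return pd.DataFrame(cols)
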