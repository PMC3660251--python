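"""Subtype characterization.

Associations between subtypes and clinical/molecular annotations
(chi-squared contingency tests), hypergeometric gene-set enrichment of
subtype signatures, generic up/down signature scoring, chromosomal
instability (CIN) calling from copy-number profiles (CIN+ when at least
20% of the genome is gained or lost), and per-region comparison of
alteration frequencies across subtypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .degenes import adjust_bh
from .features import center_genes
from .sim import CGHCohort, CGHProfile

logger = logging.getLogger(__name__)

CIN_THRESHOLD = 0.20
REGION_ALPHA = 0.01
ENRICHMENT_TOP_N = 1000


def chi_squared_test(table, correction: str = "auto"
                     ) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence on a contingency table.

    ``correction`` is ``auto`` (Yates continuity correction iff the table
    is 2x2), ``none`` or ``yates``.  Returns (statistic, df, p).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(t < 0):
        raise ValueError("contingency table counts must be non-negative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero row or column margin; test undefined")
    if correction == "auto":
        corr = t.shape == (2, 2)
    elif correction == "yates":
        corr = True
    elif correction == "none":
        corr = False
    else:
        raise ValueError(f"unknown correction {correction!r}")
    res = stats.chi2_contingency(t, correction=corr)
    return float(res.statistic), int(res.dof), float(res.pvalue)


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric over-representation of one gene set in a signature."""

    set_name: str
    direction: str
    overlap: int
    set_size: int
    signature_size: int
    universe_size: int
    p: float
    p_adj: float = np.nan


def hypergeometric_enrichment(signature, gene_sets: dict, universe,
                              direction: str = "up"
                              ) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric P(X >= overlap) for each gene set against
    a signature, BH-adjusted across sets.

    Gene sets are intersected with the universe; the signature must be a
    subset of the universe.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    signature = set(signature)
    if not signature <= universe:
        raise ValueError("signature must be a subset of the universe")
    M, n_sig = len(universe), len(signature)
    raw = []
    for name, genes in gene_sets.items():
        gs = set(genes) & universe
        ov = len(gs & signature)
        # P(X >= ov) with X ~ Hypergeom(M, |set|, |signature|)
        p = float(stats.hypergeom.sf(ov - 1, M, len(gs), n_sig))
        raw.append((name, ov, len(gs), p))
    p_adj = adjust_bh([r[3] for r in raw]) if raw else []
    return [EnrichmentResult(set_name=name, direction=direction, overlap=ov,
                             set_size=k, signature_size=n_sig,
                             universe_size=M, p=p, p_adj=float(pa))
            for (name, ov, k, p), pa in zip(raw, p_adj)]


def top_signature(stats_table: pd.DataFrame, n: int = ENRICHMENT_TOP_N,
                  direction: str = "up") -> list:
    """The n most up- (or down-) regulated genes of a subtype by moderated
    t-statistic."""
    ranked = stats_table["t_mod"].sort_values(ascending=(direction == "down"))
    return list(ranked.index[:n])


def score_signature(expr: pd.DataFrame, up_genes=(), down_genes=(),
                    center_statistic: str = "median"
                    ) -> pd.DataFrame:
    """Mean centered expression over up genes minus mean over down genes,
    per sample; binary class = score > 0."""
    up = [g for g in up_genes if g in expr.index]
    down = [g for g in down_genes if g in expr.index]
    if not up and not down:
        raise ValueError("no signature genes present in the matrix")
    centered = center_genes(expr, statistic=center_statistic)
    score = pd.Series(0.0, index=expr.columns)
    if up:
        score = score + centered.loc[up].mean(axis=0)
    if down:
        score = score - centered.loc[down].mean(axis=0)
    return pd.DataFrame({"score": score, "positive": score > 0})


def cin_call(profile: CGHProfile, threshold: float = CIN_THRESHOLD
             ) -> tuple[float, bool]:
    """Fraction of genome length in a non-neutral state, and the CIN+ flag
    (inclusive at the threshold: 'at least 20% gain or loss')."""
    lengths = profile.bins["length"].to_numpy(dtype=float)
    total = lengths.sum()
    if total <= 0:
        raise ValueError("profile has zero total genome length")
    altered = lengths[np.asarray(profile.states) != 0].sum()
    frac = float(altered / total)
    return frac, frac >= threshold


def cin_calls(cohort: CGHCohort, threshold: float = CIN_THRESHOLD
              ) -> pd.DataFrame:
    """CIN fraction and flag for every sample of a cohort."""
    rows = {}
    for sid in cohort.sample_ids:
        frac, flag = cin_call(cohort.profile(sid), threshold)
        rows[sid] = {"altered_fraction": frac, "cin_positive": flag}
    return pd.DataFrame.from_dict(rows, orient="index")


def region_frequency_test(cohort: CGHCohort, labels: pd.Series,
                          alpha: float = REGION_ALPHA) -> pd.DataFrame:
    """Per bin and alteration sign, chi-squared comparison of alteration
    proportions across subtypes, BH-adjusted over all testable rows.

    Returns one row per (bin, sign) with per-subtype frequencies, p, p_adj
    and a significance flag at ``alpha``.
    """
    labels = labels.reindex(cohort.states.columns)
    subtypes = sorted(pd.unique(labels.dropna()))
    if len(subtypes) < 2:
        raise ValueError("need at least two subtypes")
    rows = []
    for b in cohort.bins.index:
        states = cohort.states.loc[b]
        for sign, name in ((1, "gain"), (-1, "loss")):
            hit = (states == sign)
            tab = np.array([[int(hit[labels == s].sum()),
                             int((~hit)[labels == s].sum())]
                            for s in subtypes])
            if tab[:, 0].sum() == 0 or tab[:, 1].sum() == 0:
                logger.debug("bin %s %s skipped (zero margin)", b, name)
                continue
            _, _, p = chi_squared_test(tab, correction="none")
            freqs = {f"freq_{s}": tab[i, 0] / tab[i].sum()
                     for i, s in enumerate(subtypes)}
            rows.append({"bin": b, "alteration": name, **freqs, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = adjust_bh(out["p"].to_numpy())
        out["significant"] = out["p_adj"] < alpha
    return out


def subtype_marker_table(annotations: pd.DataFrame, marker: str,
                         by: str = "subtype") -> pd.DataFrame:
    """Subtype x marker-status contingency table for a binary annotation."""
    return pd.crosstab(annotations[by], annotations[marker])
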