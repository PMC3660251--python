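"""Distance-to-centroid subtype classifier.

The predictor keeps, for each subtype, its top up- and down-regulated
marker genes (ranked by |moderated t|, subject to the discriminant
thresholds) and the mean centered expression of the union of markers per
subtype (the centroids).  A new sample is centered against its own cohort's
gene medians and assigned to the subtype whose centroid is nearest in
1 − Pearson correlation distance; a sample nearly equidistant to its two
closest centroids is additionally flagged with the mixed pair.

The number of gene pairs per subtype is chosen by stratified 10-fold
cross-validation of the whole build (statistics re-estimated within each
training fold).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from . import degenes
from .features import center_genes

logger = logging.getLogger(__name__)

MIXED_DELTA = 0.05
_TINY = 1e-12


@dataclass
class CentroidModel:
    """Serializable nearest-centroid predictor."""

    subtypes: tuple
    genes: tuple
    centroids: pd.DataFrame  # genes x subtypes
    d_pairs: int
    distance: str = "one_minus_pearson"
    mixed_delta: float = MIXED_DELTA
    markers: dict = field(default_factory=dict)  # subtype -> {up, down}

    def to_json(self) -> str:
        return json.dumps({
            "subtypes": list(self.subtypes),
            "genes": list(self.genes),
            "centroids": {s: self.centroids[s].tolist()
                          for s in self.subtypes},
            "d_pairs": self.d_pairs,
            "distance": self.distance,
            "mixed_delta": self.mixed_delta,
            "markers": {s: {d: list(g) for d, g in m.items()}
                        for s, m in self.markers.items()},
        })

    @classmethod
    def from_json(cls, text: str) -> "CentroidModel":
        obj = json.loads(text)
        genes = tuple(obj["genes"])
        centroids = pd.DataFrame(
            {s: obj["centroids"][s] for s in obj["subtypes"]},
            index=list(genes))
        return cls(subtypes=tuple(obj["subtypes"]), genes=genes,
                   centroids=centroids, d_pairs=obj["d_pairs"],
                   distance=obj["distance"], mixed_delta=obj["mixed_delta"],
                   markers={s: {d: tuple(g) for d, g in m.items()}
                            for s, m in obj.get("markers", {}).items()})


@dataclass(frozen=True)
class SubtypeCall:
    """Assignment of one sample: nearest subtype, the full distance vector,
    and the mixed pair when the two best distances are nearly tied."""

    sample_id: str
    label: str | None
    distances: dict
    mixed: frozenset | None = None


def _ranked_markers(stats: pd.DataFrame, p_threshold: float,
                    lfc_threshold: float) -> tuple[pd.Index, pd.Index]:
    """Qualifying up/down genes ordered by decreasing |t_mod|."""
    ok = stats[(stats["p_adj"] < p_threshold)
               & (stats["log_fc"].abs() > lfc_threshold)]
    ok = ok.reindex(ok["t_mod"].abs().sort_values(ascending=False).index)
    return (ok.index[ok["log_fc"] > 0], ok.index[ok["log_fc"] < 0])


def build_centroid_model(expr: pd.DataFrame, labels: pd.Series,
                         stats: dict[str, pd.DataFrame] | None = None,
                         d_pairs: int = 5,
                         p_threshold: float = degenes.P_THRESHOLD,
                         lfc_threshold: float = degenes.LFC_THRESHOLD,
                         mixed_delta: float = MIXED_DELTA,
                         center_statistic: str = "median") -> CentroidModel:
    """Build the predictor from a genes x samples training matrix.

    Per subtype the ``d_pairs`` strongest qualifying up- and down-regulated
    genes are kept; the model genes are their union and the centroids the
    per-subtype means of gene-centered training expression over those genes.
    """
    labels = labels.reindex(expr.columns)
    subtypes = tuple(sorted(pd.unique(labels.dropna())))
    if len(subtypes) < 2:
        raise ValueError("need at least two subtypes to build centroids")
    if stats is None:
        stats = degenes.moderated_t_all(expr, labels)

    markers: dict[str, dict[str, tuple]] = {}
    deficits = []
    for s in subtypes:
        up, down = _ranked_markers(stats[s], p_threshold, lfc_threshold)
        if len(up) < d_pairs or len(down) < d_pairs:
            deficits.append(f"{s}: {len(up)} up / {len(down)} down "
                            f"qualifying (need {d_pairs})")
            continue
        markers[s] = {"up": tuple(up[:d_pairs]),
                      "down": tuple(down[:d_pairs])}
    if deficits:
        raise ValueError("insufficient discriminant genes — "
                         + "; ".join(deficits))

    genes: list[str] = []
    for s in subtypes:
        for g in (*markers[s]["up"], *markers[s]["down"]):
            if g not in genes:
                genes.append(g)
    centered = center_genes(expr.loc[genes], statistic=center_statistic)
    centroids = pd.DataFrame(
        {s: centered.loc[:, (labels == s).to_numpy()].mean(axis=1)
         for s in subtypes})
    return CentroidModel(subtypes=subtypes, genes=tuple(genes),
                         centroids=centroids, d_pairs=d_pairs,
                         mixed_delta=mixed_delta, markers=markers)


def _call_sample(sid: str, x: np.ndarray, centroids: np.ndarray,
                 subtypes: Sequence[str], mixed_delta: float
                 ) -> SubtypeCall:
    if np.std(x) == 0:
        warnings.warn(f"sample {sid} has zero variance over model genes; "
                      "left unclassified")
        return SubtypeCall(sid, None, {s: np.nan for s in subtypes})
    xc = x - x.mean()
    cc = centroids - centroids.mean(axis=0, keepdims=True)
    denom = np.linalg.norm(xc) * np.linalg.norm(cc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ cc) / np.where(denom > 0, denom, np.nan)
    d = 1.0 - r
    order = np.argsort(d)
    d1, d2 = d[order[0]], d[order[1]]
    if d1 <= _TINY:
        mixed = (frozenset({subtypes[order[0]], subtypes[order[1]]})
                 if d2 <= _TINY else None)
    elif (d2 - d1) / d1 < mixed_delta:
        mixed = frozenset({subtypes[order[0]], subtypes[order[1]]})
    else:
        mixed = None
    return SubtypeCall(sid, subtypes[order[0]],
                       dict(zip(subtypes, d)), mixed)


def classify(model: CentroidModel, expr: pd.DataFrame,
             center_statistic: str = "median") -> list[SubtypeCall]:
    """Assign every sample of a genes x samples cohort to its nearest
    centroid.  The cohort is centered with its own gene medians; model
    genes absent from the cohort are dropped pairwise (at least 50% must be
    present)."""
    present = [g for g in model.genes if g in expr.index]
    if len(present) < 0.5 * len(model.genes):
        raise ValueError(
            f"only {len(present)}/{len(model.genes)} model genes present; "
            "need at least 50%")
    if len(present) < len(model.genes):
        logger.warning("%d of %d model genes missing from cohort; dropped",
                       len(model.genes) - len(present), len(model.genes))
    if expr.shape[1] > 1:
        centered = center_genes(expr.loc[present],
                                statistic=center_statistic)
    else:
        # a one-sample cohort is its own median; centering would zero it
        logger.warning("single-sample cohort; per-cohort centering skipped")
        centered = expr.loc[present]
    C = model.centroids.loc[present, list(model.subtypes)].to_numpy()
    return [_call_sample(str(sid), centered[sid].to_numpy(), C,
                        list(model.subtypes), model.mixed_delta)
            for sid in centered.columns]


def calls_to_frame(calls: list[SubtypeCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append({
            "sample_id": c.sample_id, "label": c.label,
            "mixed": "/".join(sorted(c.mixed)) if c.mixed else "",
            **{f"d_{s}": v for s, v in c.distances.items()}})
    return pd.DataFrame(rows).set_index("sample_id")


class NearestCentroidSubtyper(BaseEstimator, ClassifierMixin):
    """Nearest-centroid subtype classifier, scikit-learn style.

    ``fit`` takes samples x genes expression (DataFrame with gene-named
    columns) and subtype labels, runs the one-vs-rest moderated t-tests and
    keeps ``d_pairs`` up- and down-regulated marker genes per subtype;
    ``predict`` centers the query cohort by its own gene medians and
    assigns each sample to the nearest centroid in correlation distance.

    Attributes
    ----------
    model_ : CentroidModel
    classes_ : ndarray of subtype labels
    """

    def __init__(self, d_pairs: int = 5,
                 p_threshold: float = degenes.P_THRESHOLD,
                 lfc_threshold: float = degenes.LFC_THRESHOLD,
                 mixed_delta: float = MIXED_DELTA,
                 center_statistic: str = "median"):
        self.d_pairs = d_pairs
        self.p_threshold = p_threshold
        self.lfc_threshold = lfc_threshold
        self.mixed_delta = mixed_delta
        self.center_statistic = center_statistic

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = pd.Series(np.asarray(y), index=X.index)
        self.model_ = build_centroid_model(
            X.T, y, d_pairs=self.d_pairs, p_threshold=self.p_threshold,
            lfc_threshold=self.lfc_threshold, mixed_delta=self.mixed_delta,
            center_statistic=self.center_statistic)
        self.classes_ = np.asarray(self.model_.subtypes)
        return self

    def assign(self, X) -> list[SubtypeCall]:
        check_is_fitted(self, "model_")
        return classify(self.model_, pd.DataFrame(X).T,
                        center_statistic=self.center_statistic)

    def predict(self, X):
        return np.asarray([c.label for c in self.assign(X)], dtype=object)


def cv_scan_pairs(expr: pd.DataFrame, labels: pd.Series,
                  d_range: Sequence[int] = range(1, 26), folds: int = 10,
                  seed: int = 0,
                  p_threshold: float = degenes.P_THRESHOLD,
                  lfc_threshold: float = degenes.LFC_THRESHOLD
                  ) -> tuple[pd.Series, int]:
    """Cross-validated misclassification curve over gene-pair counts.

    Stratified ``folds``-fold CV; within each training fold the moderated-t
    statistics and centroids are rebuilt from scratch, and the held-out
    samples are classified for every d in ``d_range``.  Returns the pooled
    misclassification percentage per d and the smallest d attaining the
    minimum.
    """
    labels = labels.reindex(expr.columns)
    counts = labels.value_counts()
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if (counts < folds).any():
        small = counts[counts < folds]
        raise ValueError(
            f"subtype(s) smaller than {folds} samples: "
            f"{dict(small)}; use fewer folds")
    d_range = list(d_range)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    wrong = {d: 0 for d in d_range}
    total = 0
    sample_idx = np.arange(expr.shape[1])
    for train, test in skf.split(sample_idx, labels.to_numpy()):
        tr_expr = expr.iloc[:, train]
        tr_labels = labels.iloc[train]
        te_expr = expr.iloc[:, test]
        te_labels = labels.iloc[test]
        stats = degenes.moderated_t_all(tr_expr, tr_labels)
        total += len(test)
        for d in d_range:
            model = build_centroid_model(
                tr_expr, tr_labels, stats=stats, d_pairs=d,
                p_threshold=p_threshold, lfc_threshold=lfc_threshold)
            calls = classify(model, te_expr)
            pred = pd.Series({c.sample_id: c.label for c in calls})
            wrong[d] += int((pred.reindex(te_labels.index.astype(str)).values
                             != te_labels.values).sum())
    curve = pd.Series({d: 100.0 * wrong[d] / total for d in d_range},
                      name="misclassification_pct")
    d_selected = min(d for d in d_range
                     if curve[d] == curve.min())
    return curve, d_selected
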