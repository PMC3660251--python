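"""Synthetic colon-cancer cohort generator.

Emulates a bulk expression cohort with six molecular subtypes (C1..C6) at
realistic prevalences, subtype-conditional mutation/epigenotype marker
frequencies, subtype-specific arm-level copy-number patterns, and
subtype-dependent relapse-free survival.  Every downstream stage of the
pipeline (feature selection, consensus clustering, differential expression,
centroid classification, characterization, survival) is exercisable on its
output without any external data.

All randomness flows from a single ``seed``; each component (expression,
annotations, survival, CGH) draws from an independent generator derived
from it, so adding one component never perturbs the others.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default subtype labels, ordered.
SUBTYPES = ("C1", "C2", "C3", "C4", "C5", "C6")

#: Subtype prevalences of the discovery cohort (C1..C6).
DEFAULT_PREVALENCES = (0.21, 0.19, 0.13, 0.10, 0.27, 0.10)

#: 5-year relapse-free survival proportion per subtype (stage II-III).
DEFAULT_RFS_5Y = {
    "C1": 0.70, "C2": 0.77, "C3": 0.65, "C4": 0.52, "C5": 0.70, "C6": 0.61,
}

#: Subtype-conditional binary marker probabilities.  C2 is the
#: mismatch-repair-deficient, BRAF-mutant, CpG-island-methylator subtype;
#: C3 is the KRAS-mutant subtype; C1/C5/C6 are the chromosomally unstable,
#: TP53-mutant, distal subtypes.
DEFAULT_MARKER_FREQS = {
    "C1": {"dMMR": 0.05, "BRAF": 0.05, "KRAS": 0.30, "CIMP": 0.03,
           "TP53": 0.70, "distal": 0.75},
    "C2": {"dMMR": 0.68, "BRAF": 0.40, "KRAS": 0.30, "CIMP": 0.59,
           "TP53": 0.35, "distal": 0.30},
    "C3": {"dMMR": 0.05, "BRAF": 0.05, "KRAS": 0.87, "CIMP": 0.18,
           "TP53": 0.35, "distal": 0.30},
    "C4": {"dMMR": 0.10, "BRAF": 0.15, "KRAS": 0.30, "CIMP": 0.34,
           "TP53": 0.35, "distal": 0.30},
    "C5": {"dMMR": 0.05, "BRAF": 0.05, "KRAS": 0.30, "CIMP": 0.03,
           "TP53": 0.70, "distal": 0.75},
    "C6": {"dMMR": 0.05, "BRAF": 0.05, "KRAS": 0.30, "CIMP": 0.03,
           "TP53": 0.70, "distal": 0.75},
}

#: Pathological TNM stage distribution (I, II, III, IV), shared by all
#: subtypes (no stage/subtype association).
DEFAULT_STAGE_PROBS = {"I": 0.06, "II": 0.45, "III": 0.37, "IV": 0.12}

# Approximate GRCh37 autosome arm lengths in Mb (p, q).  Acrocentric short
# arms are given their small nominal sizes.
_ARM_MB = {
    1: (125, 124), 2: (93, 150), 3: (91, 107), 4: (50, 141), 5: (48, 133),
    6: (61, 110), 7: (60, 99), 8: (45, 101), 9: (49, 92), 10: (40, 96),
    11: (53, 82), 12: (36, 98), 13: (18, 97), 14: (17, 90), 15: (19, 84),
    16: (37, 53), 17: (24, 57), 18: (17, 61), 19: (26, 33), 20: (28, 35),
    21: (13, 35), 22: (15, 36),
}

#: Recurrent arm-level copy-number pattern shared by the chromosomally
#: unstable (CIN+) subtypes: +7, -8p, +8q, +13q, -17p, -18, +20q.
CIN_PATTERN = (
    ("7p", 1, 0.9), ("7q", 1, 0.9), ("8p", -1, 0.9), ("8q", 1, 0.9),
    ("13q", 1, 0.9), ("17p", -1, 0.9), ("18p", -1, 0.9), ("18q", -1, 0.9),
    ("20q", 1, 0.9),
)

DEFAULT_CGH_PATTERNS = {
    "C1": CIN_PATTERN, "C2": (), "C3": (), "C4": (),
    "C5": CIN_PATTERN, "C6": CIN_PATTERN,
}

#: Per-arm probability of a private (random-sign) alteration, on top of the
#: recurrent pattern.  CIN+ tumors carry substantial private aneuploidy.
DEFAULT_CGH_BACKGROUND = {
    "C1": 0.20, "C2": 0.02, "C3": 0.05, "C4": 0.08, "C5": 0.20, "C6": 0.20,
}


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults encode the published cohort: subtype prevalences
    (21/19/13/10/27/10 %), C2 enriched for dMMR (68%) and BRAF mutation
    (40%), C3 for KRAS mutation (87%), 5-year RFS of
    (70, 77, 65, 52, 70, 61) % for C1..C6, and the recurrent CIN copy-number
    pattern in C1/C5/C6.
    """

    n_samples: int = 300
    subtypes: Sequence[str] = SUBTYPES
    prevalences: Sequence[float] = DEFAULT_PREVALENCES
    n_genes: int = 2000
    n_markers_per_subtype: int = 180
    effect_size: float = 1.5
    noise_sd: float = 1.0
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    marker_freqs: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_MARKER_FREQS)
    stage_probs: Mapping[str, float] = field(
        default_factory=lambda: DEFAULT_STAGE_PROBS)
    rfs_5y: Mapping[str, float] = field(
        default_factory=lambda: DEFAULT_RFS_5Y)
    censor_rate: float = 0.0135  # per month; ln(2)/51.5-month median follow-up
    cgh_patterns: Mapping[str, Sequence[tuple]] = field(
        default_factory=lambda: DEFAULT_CGH_PATTERNS)
    cgh_background: Mapping[str, float] = field(
        default_factory=lambda: DEFAULT_CGH_BACKGROUND)
    seed: int = 0

    def validate(self) -> None:
        prev = np.asarray(self.prevalences, dtype=float)
        if len(prev) != len(self.subtypes):
            raise ConfigurationError(
                f"{len(self.subtypes)} subtypes but {len(prev)} prevalences")
        if np.any(prev < 0) or np.any(prev > 1):
            raise ConfigurationError("prevalences must lie in [0, 1]")
        if abs(prev.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"prevalences sum to {prev.sum():.12f}, expected 1")
        if self.n_samples < len(self.subtypes):
            raise ConfigurationError(
                "n_samples must be at least the number of subtypes")
        if self.n_markers_per_subtype * len(self.subtypes) > self.n_genes:
            raise ConfigurationError(
                "marker blocks exceed n_genes; reduce n_markers_per_subtype")
        for s, p in self.rfs_5y.items():
            if not (0.0 < p <= 1.0):
                raise ConfigurationError(
                    f"rfs_5y[{s}]={p} outside (0, 1]")
        for s, freqs in self.marker_freqs.items():
            for m, p in freqs.items():
                if not (0.0 <= p <= 1.0):
                    raise ConfigurationError(
                        f"marker_freqs[{s}][{m}]={p} outside [0, 1]")
        if self.noise_sd < 0 or self.censor_rate < 0:
            raise ConfigurationError("noise_sd and censor_rate must be >= 0")

    def rng(self, component: int) -> np.random.Generator:
        """Independent generator for one component (0=labels/expression,
        1=annotations, 2=survival, 3=cgh)."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(component,)))


@dataclass(frozen=True)
class CGHProfile:
    """Arm-level copy-number profile of one sample.

    ``bins`` holds genome-ordered, non-overlapping intervals (chrom, arm,
    start, end, length in bp; 1-based inclusive coordinates); ``states`` is
    one of {-1 loss, 0 neutral, +1 gain} per bin.
    """

    sample_id: str
    bins: pd.DataFrame
    states: np.ndarray

    def __post_init__(self):
        if len(self.states) != len(self.bins):
            raise ValueError("states length must equal number of bins")


@dataclass
class CGHCohort:
    """Copy-number states for a cohort on a shared bin grid.

    ``states`` is bins x samples with values in {-1, 0, +1}.
    """

    bins: pd.DataFrame
    states: pd.DataFrame

    def profile(self, sample_id: str) -> CGHProfile:
        return CGHProfile(sample_id, self.bins,
                          self.states[sample_id].to_numpy())

    @property
    def sample_ids(self):
        return list(self.states.columns)


def default_genome_bins() -> pd.DataFrame:
    """One bin per autosome arm, approximate GRCh37 lengths, 1-based
    inclusive coordinates concatenated per chromosome."""
    rows = []
    for chrom, (p_mb, q_mb) in _ARM_MB.items():
        p_len = int(p_mb * 1e6)
        q_len = int(q_mb * 1e6)
        rows.append((str(chrom), "p", 1, p_len, p_len))
        rows.append((str(chrom), "q", p_len + 1, p_len + q_len, q_len))
    bins = pd.DataFrame(rows, columns=["chrom", "arm", "start", "end",
                                       "length"])
    bins.index = bins["chrom"] + bins["arm"]
    bins.index.name = "bin"
    return bins


def _draw_labels(config: SimConfig, rng: np.random.Generator) -> pd.Series:
    labels = rng.choice(list(config.subtypes), size=config.n_samples,
                        p=np.asarray(config.prevalences, dtype=float))
    sample_ids = [f"S{i:04d}" for i in range(config.n_samples)]
    return pd.Series(labels, index=sample_ids, name="subtype")


def marker_blocks(config: SimConfig) -> dict[str, dict[str, list[str]]]:
    """Disjoint, contiguous marker gene blocks per subtype.

    Each subtype owns ``n_markers_per_subtype`` consecutive genes, the first
    half shifted up and the second half shifted down in that subtype.
    """
    m = config.n_markers_per_subtype
    blocks: dict[str, dict[str, list[str]]] = {}
    for i, s in enumerate(config.subtypes):
        ids = [f"G{j:05d}" for j in range(i * m, (i + 1) * m)]
        blocks[s] = {"up": ids[: m // 2], "down": ids[m // 2:]}
    return blocks


def simulate_expression(config: SimConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Draw a log2 expression matrix (genes x samples) plus subtype labels.

    Each sample is its subtype's mean vector plus i.i.d. Gaussian noise of
    sd ``noise_sd``.  The subtype mean equals a shared gene-level baseline,
    shifted by ±``effect_size`` on the subtype's own marker block.
    """
    config.validate()
    rng = config.rng(0)
    labels = _draw_labels(config, rng)
    gene_ids = [f"G{j:05d}" for j in range(config.n_genes)]
    baseline = config.baseline_mean + config.baseline_sd * rng.standard_normal(
        config.n_genes)

    means = pd.DataFrame(
        np.tile(baseline[:, None], (1, len(config.subtypes))),
        index=gene_ids, columns=list(config.subtypes))
    for s, block in marker_blocks(config).items():
        means.loc[block["up"], s] += config.effect_size
        means.loc[block["down"], s] -= config.effect_size

    noise = config.noise_sd * rng.standard_normal(
        (config.n_genes, config.n_samples))
    values = means[labels].to_numpy() + noise
    expr = pd.DataFrame(values, index=gene_ids, columns=labels.index)
    return expr, labels


def simulate_annotations(labels: pd.Series, config: SimConfig) -> pd.DataFrame:
    """Draw per-sample binary markers and TNM stage conditional on subtype."""
    config.validate()
    unknown = set(labels.unique()) - set(config.subtypes)
    if unknown:
        raise ConfigurationError(f"unknown subtype labels: {sorted(unknown)}")
    rng = config.rng(1)
    marker_names = sorted({m for f in config.marker_freqs.values() for m in f})
    out = pd.DataFrame(index=labels.index)
    out["subtype"] = labels
    for m in marker_names:
        p = labels.map(lambda s: config.marker_freqs.get(s, {}).get(m, 0.0))
        out[m] = (rng.random(len(labels)) < p.to_numpy()).astype(int)
    stages = list(config.stage_probs)
    probs = np.asarray([config.stage_probs[s] for s in stages], dtype=float)
    probs = probs / probs.sum()
    out["tnm_stage"] = rng.choice(stages, size=len(labels), p=probs)
    return out


def hazard_rate(rfs_5y: float) -> float:
    """Constant monthly hazard implied by a 5-year relapse-free proportion:
    lambda = -ln(rfs_5y) / 60."""
    if not (0.0 < rfs_5y <= 1.0):
        raise ConfigurationError(f"rfs_5y={rfs_5y} outside (0, 1]")
    return -np.log(rfs_5y) / 60.0


#: Administrative follow-up cap in months (longest follow-up ~200 months).
FOLLOWUP_CAP = 240.0


def simulate_survival(labels: pd.Series, config: SimConfig) -> pd.DataFrame:
    """Draw relapse-free survival records (time in months, event flag).

    Event times are exponential with the subtype's hazard; censoring is an
    independent exponential clock plus an administrative cap; the record is
    the earlier of the two with ``event`` marking a relapse.
    """
    config.validate()
    for s in labels.unique():
        if s not in config.rfs_5y:
            raise ConfigurationError(f"rfs_5y undefined for subtype {s}")
    rng = config.rng(2)
    rates = labels.map(lambda s: hazard_rate(config.rfs_5y[s])).to_numpy()
    with np.errstate(divide="ignore"):
        event_t = np.where(rates > 0,
                           rng.exponential(1.0, len(labels)) /
                           np.where(rates > 0, rates, 1.0),
                           np.inf)
    if config.censor_rate > 0:
        censor_t = rng.exponential(1.0 / config.censor_rate, len(labels))
    else:
        censor_t = np.full(len(labels), np.inf)
    censor_t = np.minimum(censor_t, FOLLOWUP_CAP)
    time = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)
    return pd.DataFrame({"time_months": time, "event": event},
                        index=labels.index)


def _resolve_pattern(pattern, bins: pd.DataFrame, subtype: str) -> np.ndarray:
    """Expand (region, state, penetrance) triples to per-bin arrays; region
    names are arm labels ('8p') or whole chromosomes ('18')."""
    state = np.zeros(len(bins), dtype=int)
    pen = np.zeros(len(bins), dtype=float)
    for region, st, p in pattern:
        region = str(region)
        if region[-1] in "pq":
            mask = bins.index == region
        else:
            mask = (bins["chrom"] == region).to_numpy()
        if not mask.any():
            raise ConfigurationError(
                f"cgh pattern region {region!r} not on the bin grid")
        conflict = mask & (state != 0) & (state != st)
        if conflict.any():
            raise ConfigurationError(
                f"conflicting states for subtype {subtype} on bins "
                f"{list(bins.index[conflict])}")
        state[mask] = st
        pen[mask] = p
    return state, pen


def simulate_cgh(labels: pd.Series, config: SimConfig,
                 bins: pd.DataFrame | None = None) -> CGHCohort:
    """Draw arm-level copy-number profiles.

    Each sample receives its subtype's recurrent alterations with the
    configured penetrance, plus random-sign private alterations on the
    remaining arms at the subtype's background rate.
    """
    config.validate()
    for s in labels.unique():
        if s not in config.cgh_patterns:
            raise ConfigurationError(f"cgh_patterns undefined for subtype {s}")
    if bins is None:
        bins = default_genome_bins()
    rng = config.rng(3)
    resolved = {s: _resolve_pattern(config.cgh_patterns[s], bins, s)
                for s in labels.unique()}
    states = np.zeros((len(bins), len(labels)), dtype=int)
    for j, (sid, s) in enumerate(labels.items()):
        pat_state, pat_pen = resolved[s]
        hit = rng.random(len(bins)) < pat_pen
        col = np.where(hit, pat_state, 0)
        bg = config.cgh_background.get(s, 0.0)
        free = pat_state == 0
        bg_hit = free & (rng.random(len(bins)) < bg)
        col = np.where(bg_hit, rng.choice([-1, 1], size=len(bins)), col)
        states[:, j] = col
    return CGHCohort(bins=bins,
                     states=pd.DataFrame(states, index=bins.index,
                                         columns=labels.index))


def simulate_cohort(config: SimConfig):
    """Full synthetic cohort: (expression, labels, annotations, survival,
    cgh)."""
    expr, labels = simulate_expression(config)
    annot = simulate_annotations(labels, config)
    surv = simulate_survival(labels, config)
    cgh = simulate_cgh(labels, config)
    return expr, labels, annot, surv, cgh
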