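"""End-to-end subtyping pipeline.

Chains the analysis stages — simulate or ingest a cohort, select variant
genes, discover subtypes by consensus clustering, compute subtype
signatures, train and apply the centroid classifier, characterize the
subtypes, and analyze relapse-free survival — writing every artifact plus
a manifest of seeds and parameters to a report directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, centroid, charact, consensus, degenes, io, sim, surv
from .features import DEFAULT_N_FEATURES, select_most_variant

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, thresholds and seeds for one pipeline run.

    When ``expression_path`` is unset, a synthetic cohort is generated from
    ``sim`` settings instead.
    """

    expression_path: str | None = None
    annotations_path: str | None = None
    cgh_path: str | None = None
    gene_sets_path: str | None = None
    n_features: int = DEFAULT_N_FEATURES
    k_min: int = 2
    k_max: int = 10
    n_iter: int = 1000
    sample_frac: float = 0.9
    feature_frac: float = 0.9
    delta_area_threshold: float = consensus.DELTA_AREA_THRESHOLD
    p_threshold: float = degenes.P_THRESHOLD
    lfc_threshold: float = degenes.LFC_THRESHOLD
    d_max: int = 25
    cv_folds: int = 10
    mixed_delta: float = centroid.MIXED_DELTA
    cin_threshold: float = charact.CIN_THRESHOLD
    enrichment_top_n: int = charact.ENRICHMENT_TOP_N
    region_alpha: float = charact.REGION_ALPHA
    survival_horizon: float = surv.HORIZON_MONTHS
    seed: int = 0
    sim: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _load_or_simulate(config: PipelineConfig):
    if config.expression_path:
        expr = io.read_expression(config.expression_path)
        annot = (io.read_annotations(config.annotations_path)
                 if config.annotations_path else None)
        cgh = io.read_seg(config.cgh_path) if config.cgh_path else None
        survdf = None
        if annot is not None and {"time_months", "event"} <= set(annot.columns):
            survdf = annot[["time_months", "event"]].dropna()
        return expr, annot, survdf, cgh
    cfg = sim.SimConfig(**{**config.sim, "seed": config.seed})
    expr, labels, annot, survdf, cgh = sim.simulate_cohort(cfg)
    annot = annot.join(survdf)
    return expr, annot, survdf, cgh


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute every stage and write a report directory; returns its path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "parameters": dataclasses.asdict(config), "stages": []}

    def stage(name):
        manifest["stages"].append(name)
        logger.info("stage: %s", name)

    try:
        stage("ingest")
        expr, annot, survdf, cgh = _load_or_simulate(config)
        io.write_expression(expr, out / "expression.tsv")
        if annot is not None:
            io.write_annotations(annot, out / "annotations.csv")

        stage("features")
        selection = select_most_variant(expr, config.n_features)
        (out / "selected_genes.txt").write_text(
            "\n".join(selection.selected_gene_ids) + "\n")
        expr_sel = expr.loc[list(selection.selected_gene_ids)]

        stage("consensus")
        ccfg = consensus.ConsensusConfig(
            k_range=(config.k_min, config.k_max), n_iter=config.n_iter,
            sample_frac=config.sample_frac, feature_frac=config.feature_frac,
            seed=config.seed)
        runs = consensus.run_consensus_scan(expr_sel, ccfg)
        ksel = consensus.select_k(runs, config.delta_area_threshold)
        k = ksel.k_selected
        labels = runs[k].labels.map(lambda c: f"C{c}")
        io.write_table(runs[k].M, out / f"consensus_k{k}.tsv")
        labels.rename("subtype").to_frame().to_csv(out / "subtypes.csv")
        manifest["k_selected"] = int(k)
        manifest["delta_areas"] = {str(kk): float(v)
                                   for kk, v in ksel.deltas.items()}

        stage("degenes")
        stats = degenes.moderated_t_all(expr, labels)
        io.write_table(degenes.stats_table(stats), out / "gene_stats.tsv")

        stage("centroid")
        curve, d_sel = centroid.cv_scan_pairs(
            expr, labels, d_range=range(1, config.d_max + 1),
            folds=config.cv_folds, seed=config.seed,
            p_threshold=config.p_threshold,
            lfc_threshold=config.lfc_threshold)
        model = centroid.build_centroid_model(
            expr, labels, stats=stats, d_pairs=d_sel,
            p_threshold=config.p_threshold,
            lfc_threshold=config.lfc_threshold,
            mixed_delta=config.mixed_delta)
        (out / "centroid_model.json").write_text(model.to_json())
        io.write_table(curve.to_frame(), out / "cv_curve.tsv")
        calls = centroid.classify(model, expr)
        io.write_table(centroid.calls_to_frame(calls), out / "calls.tsv")
        manifest["d_selected"] = int(d_sel)
        manifest["cv_misclassification_pct"] = float(curve[d_sel])

        stage("characterize")
        if annot is not None:
            rows = []
            for col in annot.columns:
                if col in ("subtype", "time_months", "event"):
                    continue
                tab = pd.crosstab(labels, annot[col])
                if tab.shape[0] < 2 or tab.shape[1] < 2:
                    continue
                try:
                    stat, df_, p = charact.chi_squared_test(tab)
                except ValueError:
                    continue
                rows.append({"annotation": col, "statistic": stat,
                             "df": df_, "p": p})
            io.write_table(pd.DataFrame(rows), out / "associations.tsv",
                           index=False)
        if config.gene_sets_path:
            gene_sets = io.read_gmt(config.gene_sets_path)
            universe = list(expr.index)
            enr_rows = []
            for s in model.subtypes:
                for direction in ("up", "down"):
                    signature = charact.top_signature(
                        stats[s], config.enrichment_top_n, direction)
                    for r in charact.hypergeometric_enrichment(
                            signature, gene_sets, universe, direction):
                        enr_rows.append({"subtype": s,
                                         **dataclasses.asdict(r)})
            io.write_table(pd.DataFrame(enr_rows), out / "enrichment.tsv",
                           index=False)
        if cgh is not None:
            cin = charact.cin_calls(cgh, config.cin_threshold)
            io.write_table(cin, out / "cin.tsv")
            regions = charact.region_frequency_test(
                cgh, labels, config.region_alpha)
            io.write_table(regions, out / "cgh_regions.tsv", index=False)
        else:
            logger.info("no CGH input; CIN and region stages skipped")

        stage("survival")
        if survdf is not None:
            rec = surv.censor_at_horizon(survdf, config.survival_horizon)
            _, _, p_lr = surv.logrank_test(rec, labels.reindex(rec.index))
            rec2 = rec.copy()
            rec2["high_risk"] = surv.recode_high_risk(
                labels.reindex(rec.index))
            manifest["logrank_p"] = float(p_lr)
            if rec2["high_risk"].nunique() > 1:
                cox = surv.cox_fit(rec2, ["high_risk"])
                io.write_table(cox.summary, out / "cox.tsv")
                manifest["high_risk_hr"] = float(cox.summary["hr"].iloc[0])
            else:
                logger.info("high-risk recoding is constant; Cox skipped")
        else:
            logger.info("no survival input; survival stage skipped")
    except Exception as exc:
        failed = manifest["stages"][-1] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline failed in stage {failed!r}: {exc}"
                           ) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return out
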