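"""End-to-end orchestration: simulate -> normalize -> cna -> score -> associate
-> train -> permute -> survival, driven by a structured config.

Every stage writes plain-text outputs (TSV/JSON) into the output directory,
tagged with a hash of the config so reruns are attributable; stages can be
toggled independently and never mutate another stage's inputs on disk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import association, prediction, preprocess, signatures, simulate, survival as surv
from .errors import ValidationError
from .io import write_matrix

logger = logging.getLogger(__name__)

STAGES = ("simulate", "normalize", "cna", "score", "associate", "train", "permute", "survival")


@dataclasses.dataclass
class PipelineConfig:
    """Validated pipeline configuration (YAML-backed)."""

    output_dir: str = "cnascape_out"
    seed: int = simulate.REFERENCE_SEED
    stages: tuple[str, ...] = STAGES
    simulation: dict[str, Any] = dataclasses.field(default_factory=dict)
    association: dict[str, Any] = dataclasses.field(default_factory=dict)
    training: dict[str, Any] = dataclasses.field(default_factory=dict)
    n_permutations: int = 0
    strata_vars: tuple[str, ...] = ("gender", "er_status", "os_months", "os_event")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown pipeline config key(s): {sorted(unknown)}")
        if "stages" in raw:
            bad = set(raw["stages"]) - set(STAGES)
            if bad:
                raise ValidationError(f"unknown stage(s): {sorted(bad)}")
            raw["stages"] = tuple(raw["stages"])
        if "strata_vars" in raw:
            raw["strata_vars"] = tuple(raw["strata_vars"])
        return cls(**raw)

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run the toggled stages; returns a report dict (also written to disk)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    report: dict[str, Any] = {"config_hash": cfg_hash, "seed": config.seed, "stages": {}}
    t_all = time.time()

    def stage_done(name: str, t0: float, **info):
        report["stages"][name] = {"seconds": round(time.time() - t0, 3), **info}
        logger.info("stage %s done in %.2fs", name, time.time() - t0)

    cohort = None
    scores = None
    seg_features = None
    model = None
    clf = None
    split = None
    labels = None

    sim_cfg = simulate.SimulationConfig(seed=config.seed, **config.simulation)
    if "simulate" in config.stages:
        t0 = time.time()
        cohort = simulate.simulate_cohort(sim_cfg)
        simulate.write_cohort(cohort, outdir / "data")
        stage_done("simulate", t0, n_samples=sim_cfg.n_samples, n_genes=sim_cfg.n_genes)
    else:
        raise ValidationError("pipeline currently requires the simulate stage as data source")

    expr = cohort.expression
    if "normalize" in config.stages:
        t0 = time.time()
        x = preprocess.filter_expressed(expr, fraction=0.0, expressed="nonmissing")
        x = preprocess.median_center_genes(x)
        x = preprocess.standardize_samples(x)
        expr = x.values
        write_matrix(expr, outdir / "expression_normalized.tsv")
        stage_done("normalize", t0, n_genes=expr.shape[0])

    gene_cna = cohort.gene_cna
    if "cna" in config.stages:
        t0 = time.time()
        gene_cna = preprocess.gene_cna_extreme(cohort.seg, cohort.coords)
        seg_features = preprocess.segment_scores(gene_cna, cohort.segment_defs)
        write_matrix(seg_features, outdir / "segment_cna.tsv")
        stage_done("cna", t0, n_segments=seg_features.shape[0])
    else:
        seg_features = preprocess.segment_scores(gene_cna, cohort.segment_defs)

    if "score" in config.stages:
        t0 = time.time()
        score_table = signatures.score_archive(expr, cohort.signatures)
        write_matrix(score_table, outdir / "signature_scores.tsv")
        scores = score_table.loc["sig_main"]
        stage_done("score", t0, n_signatures=score_table.shape[0])

    if "associate" in config.stages:
        if scores is None:
            raise ValidationError("associate stage requires the score stage")
        t0 = time.time()
        land = association.landscape(scores, gene_cna, **config.association)
        land.to_csv(outdir / "association_landscape.tsv", sep="\t")
        stage_done(
            "associate", t0,
            n_called=int((land["call"] != "none").sum()),
        )

    if "train" in config.stages:
        if scores is None:
            raise ValidationError("train stage requires the score stage")
        t0 = time.time()
        labels = signatures.dichotomize(scores, rule="top_third")
        split = prediction.stratified_split(
            cohort.clinical, config.strata_vars, train_frac=0.7, seed=config.seed
        )
        X = seg_features.T  # samples x segments
        clf = prediction.ElasticNetPhenotypeClassifier(
            random_state=config.seed, **config.training
        )
        clf.fit(X.loc[split.train], labels.labels.loc[split.train])
        model = clf.model_
        ev_train = prediction.evaluate(model, X.loc[split.train], labels.labels.loc[split.train])
        ev_test = prediction.evaluate(model, X.loc[split.test], labels.labels.loc[split.test])
        ev_test.roc.to_csv(outdir / "roc_test.tsv", sep="\t", index=False)
        remap = prediction.remap_coefficients(model, cohort.segment_defs, cohort.coords)
        remap.to_csv(outdir / "gene_coefficients.tsv", sep="\t")
        model_report = model.to_report()
        model_report["config_hash"] = cfg_hash
        model_report["split"] = {
            "train": len(split.train),
            "test": len(split.test),
            "strata_vars": list(split.strata_vars),
            "seed": split.seed,
        }
        model_report["auc"] = {"train": ev_train.auc, "test": ev_test.auc}
        model_report["highly_predictable"] = prediction.highly_predictable([ev_test])
        (outdir / "model_report.json").write_text(json.dumps(model_report, indent=1))
        stage_done("train", t0, auc_test=round(ev_test.auc, 4))

    if "permute" in config.stages and config.n_permutations > 0:
        if labels is None:
            raise ValidationError("permute stage requires the train stage")
        t0 = time.time()
        perm = prediction.permutation_null(
            seg_features.T,
            labels.labels,
            cohort.clinical,
            strata_vars=config.strata_vars,
            n_perm=config.n_permutations,
            seed=config.seed,
            **config.training,
        )
        perm_report = {
            "config_hash": cfg_hash,
            "n_permutations": perm.n_permutations,
            "max_auc": perm.max_auc,
            "median_auc": perm.median_auc,
            "aucs": [round(float(a), 4) for a in perm.aucs],
        }
        (outdir / "permutation_null.json").write_text(json.dumps(perm_report, indent=1))
        stage_done("permute", t0, max_auc=round(perm.max_auc, 4))

    if "survival" in config.stages:
        if scores is None or model is None:
            raise ValidationError("survival stage requires score and train stages")
        t0 = time.time()
        records = surv.censor_10yr_cause_specific(cohort.survival)
        results = {}
        prob = pd.Series(model.predict_proba(seg_features.T), index=seg_features.columns)
        for name, values in (("observed_score", scores), ("predicted_probability", prob)):
            rg = surv.risk_groups(values, records)
            chi2, p = surv.logrank(records, rg.groups)
            curves = surv.km_curve(records, rg.groups)
            for g, curve in curves.items():
                curve.to_csv(outdir / f"km_{name}_{g}.tsv", sep="\t", index=False)
            results[name] = {
                "chi_square": chi2,
                "logrank_p": p,
                "events": {g: list(v) for g, v in rg.events.items()},
            }
        (outdir / "survival_report.json").write_text(
            json.dumps({"config_hash": cfg_hash, **results}, indent=1)
        )
        stage_done("survival", t0)

    report["total_seconds"] = round(time.time() - t_all, 3)
    (outdir / "run_report.json").write_text(json.dumps(report, indent=1))
    return report
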