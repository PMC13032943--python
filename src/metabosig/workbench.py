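"""End-to-end orchestration: simulate -> preprocess -> split -> train
(+ control) -> rank -> signature -> holdout rank -> enrich, with a JSON
manifest recording parameters, seeds and per-stage output checksums."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, enrich, preprocess, rank, signature, simcohort, splits

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("metabosig")

STAGES = ("simulate", "preprocess", "split", "train", "rank", "signature",
          "holdout_rank", "enrich")


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic-cohort pipeline run."""

    out_dir: str = "metabosig_out"
    label: str = "class_label"
    secondary: str | None = "treatment"
    ml_fraction: float = 0.80
    n_folds: int = 5
    n_trees: int = 500
    step: int = 50
    max_k: int | None = None
    n_boot: int = 10_000
    tolerance_ppm: float = 5.0
    smoothing_span: float = 0.75
    seed: int = 0
    cohort: dict = field(default_factory=dict)       # CohortSpec overrides
    association: dict = field(default_factory=dict)  # generate_association_table kwargs

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on a synthetic cohort; returns the manifest dict.

    Outputs land under ``config.out_dir``; failures abort with the stage
    name while earlier outputs are preserved on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "config": asdict(config), "results": {}}
    stage = "start"
    try:
        # --- simulate -------------------------------------------------
        stage = "simulate"
        spec = simcohort.CohortSpec(**{"seed": config.seed, **config.cohort})
        meta = simcohort.generate_cohort(spec)
        table, planted = simcohort.generate_peak_table(meta, spec)
        planted_compounds = simcohort.planted_compound_annotations(spec)
        assoc_kwargs = {"n_taxa": 30, "n_compounds": 120, "frac_significant": 0.6,
                        "seed": config.seed + 101, **config.association}
        if len(planted_compounds):
            assoc_kwargs.setdefault("planted_taxon_compounds",
                                    planted_compounds["compound_id"].tolist())
        assoc = simcohort.generate_association_table(**assoc_kwargs)
        meta.to_csv(out / "metadata.csv", index=False)
        simcohort.write_peak_table(table, out / "peaks.tsv")
        assoc.drop(columns=["significant"]).to_csv(out / "associations.csv", index=False)
        (out / "planted_features.txt").write_text(
            "\n".join(str(table.columns[i]) for i in planted) + "\n")
        _finish(manifest, stage, out, ["metadata.csv", "peaks.tsv", "associations.csv",
                                       "planted_features.txt"])

        # --- preprocess -----------------------------------------------
        stage = "preprocess"
        norm, fc = preprocess.run_default_pipeline(table, meta)
        norm.data.to_csv(out / "matrix.tsv", sep="\t")
        fc.to_csv(out / "matrix_fc.tsv", sep="\t")
        _finish(manifest, stage, out, ["matrix.tsv", "matrix_fc.tsv"],
                extra={"steps": norm.steps,
                       "n_features_kept": int(norm.data.shape[1]),
                       "n_features_removed": int(len(norm.removed_features))})

        # --- split ----------------------------------------------------
        stage = "split"
        plan = splits.make_plan(meta, config.label, secondary=config.secondary,
                                ml_fraction=config.ml_fraction,
                                n_folds=config.n_folds, seed=config.seed + 11)
        plan.to_csv(out / "plan.csv")
        folds = plan.fold_of()
        splits.assert_no_subject_leakage(folds, meta)
        _finish(manifest, stage, out, ["plan.csv"],
                extra={"n_folds": plan.n_folds,
                       "n_ml": len(plan.ml_samples()),
                       "n_holdout": len(plan.holdout_samples())})

        # --- train ----------------------------------------------------
        stage = "train"
        per_sample = meta.drop_duplicates("sample_id").set_index("sample_id")
        labels = per_sample[config.label]
        subjects = per_sample["subject_id"]
        model = classify.RandomForestCV(norm.data, labels, folds,
                                        n_trees=config.n_trees, seed=config.seed + 21)
        ev = model.fit(label_name=config.label)
        ev.control = classify.permuted_label_control(
            norm.data, labels, folds, subjects,
            n_trees=config.n_trees, seed=config.seed + 22)
        comparison = ev.compare_to_control()
        ev.scores.to_csv(out / "pooled_scores.csv")
        train_summary = {
            "auroc": ev.auroc, "auprc": ev.auprc,
            "control_auroc": ev.control.auroc, "control_auprc": ev.control.auprc,
            "delong_z": comparison.statistic, "delong_p": comparison.p_value,
            "stars": classify.star_code(comparison.p_value),
        }
        (out / "evaluation.json").write_text(json.dumps(train_summary, indent=2))
        manifest["results"]["train"] = train_summary
        _finish(manifest, stage, out, ["pooled_scores.csv", "evaluation.json"])

        # --- rank -----------------------------------------------------
        stage = "rank"
        ml_ids = folds.index
        ranked_ml = rank.rank_by_v(fc.loc[ml_ids], norm.data.loc[ml_ids], labels)
        ranked_ml.to_tsv(out / "ranked_ml.tsv")
        ranked_sex = rank.rank_by_v(fc.loc[ml_ids], norm.data.loc[ml_ids],
                                    per_sample["sex"])
        agreement = rank.spearman_rank_agreement(ranked_ml.criterion(),
                                                 ranked_sex.criterion())
        manifest["results"]["rank"] = {"spearman_rho_vs_sex": agreement.rho,
                                       "spearman_p": agreement.p_value}
        _finish(manifest, stage, out, ["ranked_ml.tsv"])

        # --- signature ------------------------------------------------
        stage = "signature"
        ana = signature.SignatureAnalysis(
            norm.data.loc[ml_ids], fc.loc[ml_ids], labels, folds, subjects,
            step=config.step, n_trees=config.n_trees, seed=config.seed + 31,
            smoothing_span=config.smoothing_span, max_k=config.max_k)
        thr = ana.fit()
        thr.curve.to_tsv(out / "elimination_curve.tsv")
        sig_summary = {"n_signature": thr.n_signature, "no_signal": thr.no_signal,
                       "derivative_at_elbow": thr.derivative_at_elbow}
        (out / "signature.json").write_text(json.dumps(sig_summary, indent=2))
        manifest["results"]["signature"] = sig_summary
        _finish(manifest, stage, out, ["elimination_curve.tsv", "signature.json"])

        # --- holdout rank --------------------------------------------
        stage = "holdout_rank"
        hold_ids = plan.holdout_samples()
        ranked_hold = rank.rank_by_v(fc.loc[hold_ids], norm.data.loc[hold_ids], labels)
        ranked_hold.to_tsv(out / "ranked_holdout.tsv")
        _finish(manifest, stage, out, ["ranked_holdout.tsv"])

        # --- enrich ---------------------------------------------------
        stage = "enrich"
        db = enrich.build_microbe_db(assoc)
        db.write(out / "microbe_sets.gmt", out / "microbe_compounds.csv")
        n_sig = thr.n_signature if thr.n_signature > 0 else min(200, len(ranked_hold.table))
        enrich_files = ["microbe_sets.gmt", "microbe_compounds.csv"]
        enrich_summary = {}
        for direction in ("all", "pos", "neg"):
            res = enrich.run_enrichment(ranked_hold, n_sig, db,
                                        tolerance_ppm=config.tolerance_ppm,
                                        direction=direction)
            fname = f"enrichment_{direction}.tsv"
            res.table.to_csv(out / fname, sep="\t", index=False)
            enrich_files.append(fname)
            enrich_summary[direction] = {"n_sets": int(len(res.table)),
                                         "n_significant": int(len(res.significant_sets()))}
        manifest["results"]["enrich"] = enrich_summary
        _finish(manifest, stage, out, enrich_files)

    except Exception:
        log.exception("pipeline failed at stage %r", stage)
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    log.info("pipeline complete: %d stages", len(manifest["stages"]))
    return manifest


def _finish(manifest: dict, stage: str, out: Path, files: list[str],
            extra: dict | None = None) -> None:
    entry = {"outputs": {f: _sha256(out / f) for f in files}}
    if extra:
        entry.update(extra)
    manifest["stages"][stage] = entry
    log.info("stage %s complete (%d outputs)", stage, len(files))
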