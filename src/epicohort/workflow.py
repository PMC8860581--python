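"""End-to-end pipeline: bundle -> annotation -> DE -> stratification ->
profiles -> VAE -> cohorts -> enrichment.

Each stage is a pure function of its inputs, the configuration and the root
seed; the run manifest records per-stage status, derived seeds and output
checksums so identical configurations reproduce identical results. A stage
failure is recorded and downstream stages are skipped.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation, cohorts as cohorts_mod, enrichment, expression, \
    profiles as profiles_mod, stratification, synthetic, vae as vae_mod

logger = logging.getLogger(__name__)

STAGE_ORDER = ["bundle", "annotate", "expression", "stratify", "profile",
               "embed", "cohorts"]


@dataclass
class PipelineConfig:
    output_dir: str | Path
    input_dir: str | Path | None = None     # exported bundle; None = simulate
    synthetic: synthetic.SyntheticConfig | None = None
    vae: vae_mod.VAEConfig | None = None
    tail_sd: float = cohorts_mod.DEFAULT_TAIL_SD
    jaccard_threshold: float = cohorts_mod.DEFAULT_JACCARD
    stratification_set: str = "tissue+anterior"
    seed: int = 0


@dataclass
class PipelineResult:
    manifest: dict
    outputs: dict = field(default_factory=dict)


def _checksum(df: pd.DataFrame) -> str:
    return hashlib.md5(
        df.to_csv().encode()).hexdigest()  # stable across runs


def _derive_seeds(root: int) -> dict[str, int]:
    rng = np.random.default_rng(root)
    return {name: int(rng.integers(0, 2**31 - 1))
            for name in ("synthetic", "vae")}


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = _derive_seeds(config.seed)
    manifest: dict = {"seed": config.seed, "derived_seeds": seeds,
                      "stages": {}}
    outputs: dict = {}

    def stage(name):
        def deco(fn):
            if any(s.get("status") == "error"
                   for s in manifest["stages"].values()):
                manifest["stages"][name] = {"status": "skipped"}
                return None
            t0 = time.perf_counter()
            try:
                info = fn() or {}
                info["status"] = "completed"
            except Exception as exc:
                logger.exception("stage %s failed", name)
                info = {"status": "error", "error": str(exc)}
            info["seconds"] = round(time.perf_counter() - t0, 3)
            manifest["stages"][name] = info
            return None
        return deco

    @stage("bundle")
    def _bundle():
        if config.input_dir is not None:
            bundle = synthetic.load_bundle(config.input_dir)
            src = str(config.input_dir)
        else:
            from dataclasses import replace
            cfg = config.synthetic or synthetic.SyntheticConfig()
            cfg = replace(cfg, seed=seeds["synthetic"])
            bundle = synthetic.generate_dataset(cfg)
            src = "synthetic"
        outputs["bundle"] = bundle
        return {"source": src, "genes": bundle.counts.shape[0],
                "samples": bundle.counts.shape[1],
                "counts_md5": _checksum(bundle.counts)}

    @stage("annotate")
    def _annotate():
        bundle = outputs["bundle"]
        tables = {
            key: annotation.assign_peaks_to_genes(df, bundle.gene_models,
                                                  mark=key[0])
            for key, df in bundle.peaks.items()}
        outputs["mark_signals"] = profiles_mod.mark_signal_wide(tables)
        ref = {}
        for tissue in stratification.MARK_REFERENCE_TISSUES:
            key = (synthetic.MARK, tissue, stratification.MARK_REFERENCE_STAGE)
            ref[tissue] = annotation.assign_peaks_to_genes(
                bundle.peaks[key], bundle.gene_models, mark=synthetic.MARK,
                window_preset="tss_symmetric")["signal"]
        outputs["mark_reference"] = pd.DataFrame(ref)
        outputs["states"] = annotation.assign_chromatin_states(
            bundle.chromhmm, bundle.gene_models)
        return {"chip_cells": len(tables),
                "marked_genes": int((outputs["mark_reference"] > 0)
                                    .any(axis=1).sum())}

    @stage("expression")
    def _expression():
        bundle = outputs["bundle"]
        filtered = expression.filter_low_counts(bundle.counts)
        factors = expression.tmm_factors(filtered)
        outputs["factors"] = factors
        outputs["norm"] = expression.normalize(filtered, factors)
        outputs["cpm"] = expression.tmm_cpm(filtered, factors)
        contrasts = expression.plan_contrasts(
            bundle.metadata, stratification_set=config.stratification_set)
        outputs["contrasts"] = contrasts
        outputs["de"] = expression.run_all_contrasts(
            filtered, bundle.metadata, contrasts, factors)
        return {"genes_after_filter": filtered.shape[0],
                "contrasts": len(contrasts)}

    @stage("stratify")
    def _stratify():
        bundle = outputs["bundle"]
        strat_names = [c.name for c in stratification
                       .stratification_contrasts(outputs["contrasts"])]
        response = stratification.label_expression_response(
            {n: outputs["de"][n] for n in strat_names}, outputs["cpm"],
            bundle.metadata)
        marked = stratification.label_marked(
            outputs["mark_reference"].reindex(response.index).fillna(0.0))
        labels = stratification.stratify(response, marked)
        outputs["labels"] = labels
        outputs["ectopic"] = stratification.survey_ectopic(
            outputs["cpm"], bundle.metadata)
        labels.to_csv(out_dir / "labels.tsv", sep="\t")
        counts = labels["category"].value_counts().to_dict()
        return {"category_counts": counts,
                "ectopic_genes": int(len(outputs["ectopic"]))}

    @stage("profile")
    def _profile():
        labels = outputs["labels"]
        subset = labels.index[labels["response"] == "consistently_affected"]
        unscaled = profiles_mod.assemble_profiles(
            outputs["norm"], outputs["bundle"].metadata,
            outputs["mark_signals"].reindex(outputs["norm"].index)
            .fillna(0.0),
            outputs["de"], subset)
        outputs["profiles"] = profiles_mod.scale_features(unscaled)
        blocks = {k: len(v) for k, v in unscaled.blocks.items()}
        return {"genes": len(subset), "features": unscaled.data.shape[1],
                "blocks": blocks}

    @stage("embed")
    def _embed():
        from dataclasses import replace
        cfg = config.vae or vae_mod.VAEConfig()
        cfg = replace(cfg, seed=seeds["vae"])
        model = vae_mod.train_vae(outputs["profiles"], cfg)
        outputs["model"] = model
        emb = vae_mod.encode(model, outputs["profiles"])
        outputs["embedding"] = emb
        emb.codes.to_csv(out_dir / "latent.tsv", sep="\t")
        hist = model.history
        return {"latent_dim": cfg.latent_dim,
                "final_train_mse": float(hist["train_mse"].iloc[-1]),
                "final_val_mse": float(hist.get(
                    "val_mse", pd.Series([np.nan])).iloc[-1]),
                "embedding_md5": _checksum(emb.codes)}

    @stage("cohorts")
    def _cohorts():
        emb = outputs["embedding"]
        all_cohorts = cohorts_mod.extract_cohorts(emb, config.tail_sd)
        kept, omitted, report = cohorts_mod.prune_overlapping(
            all_cohorts, config.jaccard_threshold)
        outputs["cohorts"] = all_cohorts
        outputs["cohorts_kept"] = kept
        outputs["cohort_overlap"] = report
        from . import io as io_mod
        io_mod.write_gmt({c.id: c.genes for c in all_cohorts},
                         out_dir / "cohorts.gmt")
        bundle = outputs["bundle"]
        info = {"n_cohorts": len(all_cohorts), "n_kept": len(kept),
                "sizes": {c.id: c.size for c in all_cohorts}}
        if "archetype" in bundle.truth.columns:
            truth_sets = {
                a: set(bundle.truth.index[bundle.truth["archetype"] == a])
                for a in bundle.truth["archetype"].unique()
                if a != "background"}
            match = cohorts_mod.best_match_jaccard(all_cohorts, truth_sets)
            outputs["archetype_match"] = match
            info["mean_best_match_jaccard"] = float(
                match["jaccard"].mean())
            universe = set(emb.codes.index)
            ora_top = {}
            for c in kept:
                table = enrichment.ora(
                    set(c.genes), universe,
                    {a: s & universe for a, s in truth_sets.items()
                     if s & universe})
                if len(table):
                    ora_top[c.id] = table.iloc[0]["set"]
            info["top_enriched_archetype"] = ora_top
        return info

    manifest["completed"] = sum(
        1 for s in manifest["stages"].values()
        if s.get("status") == "completed")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return PipelineResult(manifest, outputs)
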