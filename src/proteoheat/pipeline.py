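"""End-to-end orchestration: simulate -> preprocess -> differential ->
detection classification -> enrichment -> climate/physiology.

One YAML configuration drives the whole run; every stage logs its
input/output record counts and the thresholds it used into a
:class:`RunManifest` that is written alongside the stage outputs, so a run
is auditable and exactly reproducible from its manifest.  All analysis
tables are written deterministically (no timestamps inside them); the
manifest is the only file carrying wall-clock information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .containers import IntensityMatrix, SampleDesign
from .detection import annotate_tracks, find_on_off, find_switch_like, profiles_from_matrix
from .differential import DifferentialAbundanceModel
from .enrichment import enrich
from .climate import anova_two_way, window_summary
from .io import (write_config, write_gmt, write_intensity_matrix, write_mask,
                 write_sample_design)
from .preprocess import (filter_missing, impute_minimal, log2_normalize, plot_qc,
                         qc_summary)
from .simulate import (SimConfig, generate_annotations, generate_dataset,
                       generate_microclimate, generate_traits)

logger = logging.getLogger("proteoheat")

STAGES = ("simulate", "preprocess", "differential", "classify", "enrichment", "climate")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the diagnostic."""


@dataclass
class RunManifest:
    """Auditable record of a pipeline run."""

    config: dict
    seed: int
    version: str = __version__
    started: str = ""
    finished: str = ""
    stages: dict = field(default_factory=dict)  # stage -> {counts, params, outputs}

    def record(self, stage: str, counts: dict, params: dict, outputs: list) -> None:
        self.stages[stage] = {
            "counts": {k: int(v) for k, v in counts.items()},
            "params": params,
            "outputs": outputs,
        }

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "started": self.started,
            "finished": self.finished,
            "config": self.config,
            "stages": self.stages,
        }


DEFAULT_CONFIG = {
    "seed": 0,
    "simulate": {},
    "preprocess": {"max_missing": 0.75, "impute": "global_min", "normalize": "median"},
    "differential": {
        "model": "class_day", "alpha": 0.05, "lfc_min": 1.0, "interaction_fdr": 0.05,
        "contrasts": ["baseline_class", "sensitive_day", "tolerant_day"],
    },
    "classify": {"level": "class", "freq_delta_min": 0.5,
                 "high_min": 2.0 / 3.0, "low_max": 1.0 / 3.0},
    "enrichment": {"min_size": 3},
    "climate": {"days": 7, "ck_temp_mean": 30.0, "ehs_delta": 4.9, "rh": 60.0},
}


def _merged(config: dict) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for key, val in (config or {}).items():
        if key not in cfg and key not in ("outdir",):
            raise PipelineError(f"pre-flight: unknown config section {key!r}")
        if isinstance(val, dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def run_pipeline(config: dict | None = None, outdir=None) -> RunManifest:
    """Run every stage in dependency order and return the manifest.

    ``config`` follows the schema of :data:`DEFAULT_CONFIG` (any subset;
    missing keys take defaults).  If ``outdir`` is given, all stage outputs
    plus ``manifest.yaml`` are written there.
    """
    cfg = _merged(config or {})
    seed = int(cfg["seed"])
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, seed=seed,
                           started=datetime.now(timezone.utc).isoformat())

    stage = "simulate"
    try:
        sim_cfg = SimConfig(seed=seed, **cfg["simulate"])
        matrix, design, registry = generate_dataset(sim_cfg)
        annotations = generate_annotations(matrix.protein_ids, registry, seed=seed)
        outputs = []
        if out is not None:
            write_intensity_matrix(matrix, out / "matrix.tsv")
            write_mask(matrix, out / "mask.tsv")
            write_sample_design(design, out / "design.csv")
            registry.table.to_csv(out / "registry.tsv", sep="\t", index=False)
            write_gmt(annotations, out / "pathways.gmt")
            outputs = ["matrix.tsv", "mask.tsv", "design.csv", "registry.tsv",
                       "pathways.gmt"]
        manifest.record(stage, {
            "proteins": matrix.n_proteins, "samples": matrix.n_samples,
            "planted": len(registry.table), "pathways": len(annotations),
        }, {"n_proteins": sim_cfg.n_proteins,
            "missing_target": sim_cfg.missing_target}, outputs)

        stage = "preprocess"
        pp = cfg["preprocess"]
        normalized = log2_normalize(matrix, method=pp["normalize"])
        filtered = filter_missing(normalized, max_missing_fraction=pp["max_missing"])
        imputed = impute_minimal(filtered, strategy=pp["impute"])
        qc = qc_summary(imputed, design)
        outputs = []
        if out is not None:
            write_intensity_matrix(imputed, out / "imputed.tsv")
            qc.sample_missing.rename("missing_fraction").to_csv(
                out / "qc_sample_missing.tsv", sep="\t")
            qc.correlation.to_csv(out / "qc_correlation.tsv", sep="\t")
            qc.variance_decomposition.to_csv(out / "qc_variance.tsv", sep="\t")
            plot_qc(qc, design, out / "qc")
            outputs = ["imputed.tsv", "qc_sample_missing.tsv", "qc_correlation.tsv",
                       "qc_variance.tsv", "qc_correlation.png", "qc_pca.png"]
        manifest.record(stage, {
            "proteins_in": matrix.n_proteins, "proteins_retained": imputed.n_proteins,
            "cells_imputed": int((~filtered.mask).sum().sum()),
        }, dict(pp), outputs)

        stage = "differential"
        dd = cfg["differential"]
        model = DifferentialAbundanceModel(imputed, design, model=dd["model"])
        results = model.fit()
        dap_tables = {}
        for name in dd["contrasts"]:
            dap_tables[name] = results.call_daps(
                name, alpha=dd["alpha"], lfc_min=dd["lfc_min"])
        inter = results.interaction_daps(fdr=dd["interaction_fdr"])
        counts = {f"daps_{n}": int(t["significant"].sum()) for n, t in dap_tables.items()}
        counts["interaction_daps"] = int(inter["significant"].sum())
        counts["proteins_tested"] = imputed.n_proteins
        manifest.record(stage, counts, {
            "model": dd["model"], "alpha": dd["alpha"], "lfc_min": dd["lfc_min"],
            "interaction_fdr": dd["interaction_fdr"],
            "d0": float(results.moderation.d0),
            "s0_sq": float(results.moderation.s0_sq)}, [])

        stage = "classify"
        cc = cfg["classify"]
        for name in list(dap_tables):
            dap_tables[name] = annotate_tracks(
                dap_tables[name], imputed.mask, design, name, level=cc["level"],
                freq_delta_min=cc["freq_delta_min"])
        inter = annotate_tracks(inter, imputed.mask, design, "interaction",
                                level=cc["level"], freq_delta_min=cc["freq_delta_min"])
        profiles = profiles_from_matrix(imputed, design, level="class")
        on_off = find_on_off(profiles, design)
        switch = find_switch_like(profiles, design,
                                  high_min=cc["high_min"], low_max=cc["low_max"])
        outputs = []
        if out is not None:
            for name, tab in dap_tables.items():
                tab.to_csv(out / f"daps_{name}.tsv", sep="\t")
                outputs.append(f"daps_{name}.tsv")
            inter.to_csv(out / "daps_interaction.tsv", sep="\t")
            on_off.to_csv(out / "on_off.tsv", sep="\t")
            switch.to_csv(out / "switch_like.tsv", sep="\t")
            outputs += ["daps_interaction.tsv", "on_off.tsv", "switch_like.tsv"]
        manifest.record(stage, {
            "on_off": len(on_off), "switch_like": len(switch),
        }, dict(cc), outputs)

        stage = "enrichment"
        ee = cfg["enrichment"]
        background = list(imputed.protein_ids)
        enrich_tables = {}
        for name, tab in dap_tables.items():
            sig = tab[tab["significant"] & (tab["track"] == "intensity_driven")]
            for direction in ("up", "down"):
                dap_ids = sig.index[sig["direction"] == direction]
                if len(dap_ids) == 0:
                    continue
                enrich_tables[f"{name}_{direction}"] = enrich(
                    dap_ids, annotations, background, min_size=ee["min_size"])
        outputs = []
        if out is not None:
            for key, tab in enrich_tables.items():
                tab.to_csv(out / f"enrichment_{key}.tsv", sep="\t")
                outputs.append(f"enrichment_{key}.tsv")
        manifest.record(stage, {
            key: int((tab["q"] < 0.05).sum()) for key, tab in enrich_tables.items()
        }, dict(ee), outputs)

        stage = "climate"
        cl = cfg["climate"]
        records = generate_microclimate(
            days=cl["days"], ck_temp_mean=cl["ck_temp_mean"],
            ehs_delta=cl["ehs_delta"], rh_profile=cl["rh"], seed=seed)
        summary = window_summary(records)
        traits = generate_traits(seed=seed)
        anovas = {t: anova_two_way(traits, t) for t in traits["trait"].unique()}
        outputs = []
        if out is not None:
            records.to_csv(out / "microclimate.csv", index=False)
            summary.table.to_csv(out / "climate_summary.tsv", sep="\t")
            traits.to_csv(out / "traits.csv", index=False)
            for t, res in anovas.items():
                res.anova_table.to_csv(out / f"anova_{t}.tsv", sep="\t")
                outputs.append(f"anova_{t}.tsv")
            outputs = ["microclimate.csv", "climate_summary.tsv", "traits.csv"] + outputs
        manifest.record(stage, {
            "climate_records": len(records), "trait_rows": len(traits),
        }, {k: float(v) if isinstance(v, (int, float)) else v for k, v in cl.items()},
            outputs)
    except PipelineError:
        raise
    except Exception as exc:
        if out is not None:
            (out / f"FAILED_{stage}").write_text(f"{type(exc).__name__}: {exc}\n")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest.finished = datetime.now(timezone.utc).isoformat()
    if out is not None:
        write_config(manifest.to_dict(), out / "manifest.yaml")
    logger.info("pipeline complete: %d stages", len(manifest.stages))
    return manifest
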