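"""End-to-end orchestration: preprocess → discover → differential → producers → panel.

A single :class:`RunConfig` drives every stage; one global seed
deterministically derives per-stage seeds by stable hashing of the stage
name, so any stage can be re-run in isolation and reproduce its output
bit-for-bit.  Each run writes a manifest with per-stage counts, parameters
and output checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import conjugates, differential, panel, preprocess, simulate
from .io import (FeatureTable, SampleSheet, align, read_feature_table,
                 read_sample_sheet, write_feature_table)

logger = logging.getLogger(__name__)


def derive_seed(global_seed: int, stage: str) -> int:
    """Stage seed from the global seed via stable name hashing (< 2**31)."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    out_dir: str = "phenolomics_run"
    feature_table: str | None = None      # None -> simulate
    sample_sheet: str | None = None
    seed: int = 0
    cohort: dict = field(default_factory=dict)       # simulate.CohortConfig overrides
    assay: dict = field(default_factory=dict)        # simulate.AssayConfig overrides
    filter: dict = field(default_factory=dict)       # preprocess.FilterSpec overrides
    skip_serrf: bool = False
    serrf: dict = field(default_factory=dict)        # qc_drift_correct kwargs
    ppm_tol: float = 5.0
    conj_max_ratio: float = 0.5
    agly_min_ratio: float = 2.0
    alpha: float = 0.05
    transform: str = "log"
    producer_up: float = 1.5
    producer_down: float = 0.67
    n_candidates: int = 26
    max_panel_size: int = 6
    auc_threshold: float = 0.75
    cv_folds: int = 10
    stages: list[str] = field(default_factory=lambda: [
        "preprocess", "conjugates", "differential", "producers", "panel"])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(config: RunConfig) -> dict:
    """Execute the configured stages and return (and write) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {}}

    def record(stage: str, info: dict, files: dict[str, Path] = {}) -> None:
        manifest["stages"][stage] = info
        for name, p in files.items():
            manifest["outputs"][name] = {"path": str(p), "sha256": _checksum(p)}
        _write_manifest()

    def _write_manifest() -> None:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    try:
        # ------------------------------------------------------------ inputs
        if config.feature_table and config.sample_sheet:
            table = read_feature_table(config.feature_table)
            sheet = read_sample_sheet(config.sample_sheet)
            truth = None
        else:
            cfg = simulate.config_from_dict(
                {"seed": derive_seed(config.seed, "simulate"), **config.cohort}, "cohort")
            table, sheet, truth = simulate.generate_cohort(cfg)
            write_feature_table(table, out / "cohort_features.csv")
            from .io import write_sample_sheet
            write_sample_sheet(sheet, out / "cohort_samples.csv")
        record("inputs", {"n_features": table.n_features,
                          "n_samples": len(table.sample_ids),
                          "simulated": truth is not None})

        # -------------------------------------------------------- preprocess
        if "preprocess" in config.stages:
            spec = preprocess.FilterSpec(**config.filter)
            table = preprocess.filter_features(table, spec)
            n_after_filter = table.n_features
            if not config.skip_serrf:
                table = preprocess.qc_drift_correct(
                    table, sheet, seed=derive_seed(config.seed, "serrf"),
                    **config.serrf)
            table = preprocess.creatinine_normalize(table, sheet)
            table = preprocess.impute_missing(table)
            path = out / "processed_features.csv"
            write_feature_table(table, path)
            record("preprocess", {"n_features": table.n_features,
                                  "n_after_filter": n_after_filter,
                                  "serrf": not config.skip_serrf},
                   {"processed_features": path})

        cohort = align(table, sheet)

        # -------------------------------------------------------- conjugates
        if "conjugates" in config.stages:
            assay_cfg = simulate.config_from_dict(
                {"seed": derive_seed(config.seed, "assay"), **config.assay}, "assay")
            arms, assay_truth = simulate.generate_enzyme_assay(assay_cfg)
            all_hits = []
            for arm_name, assay in arms.items():
                shift = conjugates.ShiftClass.by_name(
                    {"sulfatase": "sulfate", "glucuronidase": "glucuronide"}[arm_name])
                pairs = conjugates.find_mass_shift_pairs(assay.table, shift,
                                                         ppm_tol=config.ppm_tol)
                hits = conjugates.score_enzyme_response(
                    pairs, assay, conjugate_max_ratio=config.conj_max_ratio,
                    aglycon_min_ratio=config.agly_min_ratio)
                all_hits.append(conjugates.hits_to_frame(hits))
            hits_df = pd.concat(all_hits, ignore_index=True) if all_hits else pd.DataFrame()
            path = out / "conjugate_hits.csv"
            hits_df.to_csv(path, index=False)
            record("conjugates",
                   {"n_candidate_pairs": int(len(hits_df)),
                    "n_hits": int(hits_df["passes"].sum()) if len(hits_df) else 0},
                   {"conjugate_hits": path})

        # ------------------------------------------------------ differential
        if "differential" in config.stages:
            results = differential.paired_t_test(cohort, alpha=config.alpha,
                                                 transform=config.transform)
            path = out / "differential.csv"
            results.to_csv(path, index=False)
            record("differential",
                   {"n_features": int(len(results)),
                    "n_significant": int(results["significant"].sum())},
                   {"differential": path})

        # --------------------------------------------------------- producers
        if "producers" in config.stages:
            profiles = differential.classify_producers(
                cohort, up=config.producer_up, down=config.producer_down)
            path = out / "producers.csv"
            profiles.to_csv(path, index=False)
            record("producers", {"n_subjects": int(len(profiles))},
                   {"producers": path})

        # ------------------------------------------------------------- panel
        if "panel" in config.stages:
            if "differential" not in config.stages:
                results = differential.paired_t_test(cohort, alpha=config.alpha)
            cand_ids = results.nsmallest(
                min(config.n_candidates, len(results)), "p_value")["feature_id"].tolist()
            cands = panel.PanelCandidateSet(cand_ids, max_size=config.max_panel_size,
                                            auc_threshold=config.auc_threshold)
            search = panel.search_best_panel(cohort, cands)
            mean_auc, sd_auc = panel.cross_validate_panel(
                cohort, list(search.best.feature_subset), k=config.cv_folds,
                seed=derive_seed(config.seed, "cv"))
            search.best.cv_mean_auc, search.best.cv_sd_auc = mean_auc, sd_auc
            search.best.n_folds = config.cv_folds
            path = out / "panels.csv"
            search.retained.to_csv(path, index=False)
            best_path = out / "best_panel.json"
            with open(best_path, "w") as fh:
                json.dump({"features": list(search.best.feature_subset),
                           "in_sample_auc": search.best.in_sample_auc,
                           "cv_mean_auc": mean_auc, "cv_sd_auc": sd_auc,
                           "n_folds": config.cv_folds,
                           "n_evaluated": search.n_evaluated}, fh, indent=2)
            record("panel", {"n_evaluated": search.n_evaluated,
                             "n_retained": int(len(search.retained)),
                             "best_auc": search.best.in_sample_auc,
                             "cv_mean_auc": mean_auc, "cv_sd_auc": sd_auc},
                   {"panels": path, "best_panel": best_path})
    except Exception as exc:
        manifest["error"] = {"stage": _next_stage(manifest, config), "message": str(exc)}
        _write_manifest()
        raise

    return manifest


def _next_stage(manifest: dict, config: RunConfig) -> str:
    done = set(manifest["stages"])
    for s in ["inputs"] + list(config.stages):
        if s not in done:
            return s
    return "unknown"
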