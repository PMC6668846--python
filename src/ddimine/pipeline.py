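"""Orchestration of the two-step workflow.

Step one (dataset pipeline): disproportionality screen -> propensity-
adjusted LASSO interaction calls -> ADE-level pair datasets -> inference-
score validation.  Step two (model pipeline): pair descriptors -> under-
sampled forest ensemble -> compound-out cross-validation -> optional
library screen.

A single global seed fans out to per-stage seeds through a counter scheme
(SHA-256 of "seed:stage-name", reduced mod 2^31), so stages are
individually reproducible without seed collisions.  Every run writes a
manifest with the configuration hash, effective seeds and record counts;
two runs with identical configuration and inputs produce identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .ade_classifier import (
    CVReport,
    EnsembleModel,
    ScreenSummary,
    compound_out_cv,
    fit_undersampled_forest,
    screen_pair_library,
)
from .dataset_builder import (
    PairDataset,
    ValidationReport,
    build_pair_dataset,
    score_dataset,
    validate_dataset,
)
from .interaction_inference import LassoConfig, calls_to_frame, infer_interactions
from .pair_descriptors import TargetProfileMatrix
from .signal_screen import ScreenConfig, enumerate_candidate_pairs, screen_database
from .sr_model import (
    AdeOntology,
    DrugAdeLabels,
    InferenceScoreTable,
    load_sr_database,
)

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Validated configuration of a full run."""

    sr_path: str
    ontology_path: str
    labels_path: str
    profiles_path: str | None = None
    inference_scores_path: str | None = None
    outdir: str = "ddimine_out"
    seed: int = 0

    screen: ScreenConfig = field(default_factory=ScreenConfig)
    lasso: LassoConfig = field(default_factory=LassoConfig)

    # classifier settings
    M: int = 10
    n_trees: int = 500
    cv_folds: int = 5
    ad_coverage: float = 0.95
    thresholds: tuple[float, ...] = (0.5, 0.8)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        for req in ("sr_path", "ontology_path", "labels_path"):
            if req not in raw:
                raise ValueError(f"missing required configuration key {req!r}")
        kwargs = dict(raw)
        if isinstance(kwargs.get("screen"), dict):
            kwargs["screen"] = ScreenConfig(**kwargs["screen"])
        if isinstance(kwargs.get("lasso"), dict):
            kwargs["lasso"] = LassoConfig(**kwargs["lasso"])
        if "thresholds" in kwargs:
            kwargs["thresholds"] = tuple(kwargs["thresholds"])
        return cls(**kwargs)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["thresholds"] = list(self.thresholds)
        return d

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    def validate_inputs(self, need_profiles: bool = False) -> None:
        required = {
            "sr_path": self.sr_path,
            "ontology_path": self.ontology_path,
            "labels_path": self.labels_path,
        }
        if need_profiles:
            required["profiles_path"] = self.profiles_path
        for name, p in required.items():
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"required input {name} missing: {p}")


def _write_manifest(outdir: Path, cfg: PipelineConfig, stages: dict[str, Any]) -> None:
    manifest = {
        "version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "global_seed": cfg.seed,
        "stage_seeds": {s: stage_seed(cfg.seed, s) for s in stages},
        "stages": stages,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run_dataset_pipeline(
    cfg: PipelineConfig,
) -> tuple[dict[str, PairDataset], dict[str, ValidationReport]]:
    """Screen -> interaction inference -> dataset build -> validation."""
    cfg.validate_inputs()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: dict[str, Any] = {}

    t0 = time.time()
    db = load_sr_database(cfg.sr_path)
    ontology = AdeOntology.from_yaml(cfg.ontology_path)
    labels = DrugAdeLabels.from_tsv(cfg.labels_path)
    stages["load"] = {"n_reports": db.n, "n_labeled_drugs": len(labels.drugs),
                      "elapsed_s": round(time.time() - t0, 2)}
    logger.info("loaded %d reports, %d labeled drugs", db.n, len(labels.drugs))

    t0 = time.time()
    pairs = enumerate_candidate_pairs(db, labels.drugs, cfg.screen)
    pts = sorted(ontology.all_pts())
    signals = screen_database(db, pairs, pts, cfg.screen)
    signals.to_csv(outdir / "signals.tsv", sep="\t", index=False)
    stages["screen"] = {
        "n_candidate_pairs": len(pairs),
        "n_signals": int(signals["passed"].sum()),
        "elapsed_s": round(time.time() - t0, 2),
    }
    logger.info("screen: %d pairs, %d passing signals", len(pairs),
                int(signals["passed"].sum()))

    t0 = time.time()
    pt_to_ade = {pt: ade for ade in ontology.ades for pt in ontology.pts_for(ade)}
    lasso = LassoConfig(
        n_lambdas=cfg.lasso.n_lambdas,
        lambda_min_ratio=cfg.lasso.lambda_min_ratio,
        cv_folds=cfg.lasso.cv_folds,
        subsample=cfg.lasso.subsample,
        seed=stage_seed(cfg.seed, "lasso"),
    )
    calls = infer_interactions(db, signals, labels, pt_to_ade, cfg.screen, lasso)
    calls_to_frame(calls).to_csv(outdir / "calls.tsv", sep="\t", index=False)
    stages["infer"] = {
        "n_calls": len(calls),
        "n_synergistic": sum(c.verdict == "synergistic" for c in calls),
        "elapsed_s": round(time.time() - t0, 2),
    }

    t0 = time.time()
    datasets: dict[str, PairDataset] = {}
    reports: dict[str, ValidationReport] = {}
    is_table = (
        InferenceScoreTable.from_tsv(cfg.inference_scores_path)
        if cfg.inference_scores_path and Path(cfg.inference_scores_path).exists()
        else None
    )
    for ade in ontology.ades:
        ds = build_pair_dataset(calls, ontology, ade, labels)
        if len(ds) == 0:
            logger.warning("ADE %s: empty dataset, skipped", ade)
            continue
        datasets[ade] = ds
        ds.to_tsv(outdir / f"dataset_{ade}.tsv")
        if is_table is not None and 0 < ds.n_positive < len(ds):
            rep = validate_dataset(ds, score_dataset(ds, is_table, labels))
            reports[ade] = rep
            (outdir / f"validation_{ade}.json").write_text(
                json.dumps(rep.to_dict(), indent=2)
            )
    stages["build"] = {
        "datasets": {a: len(d) for a, d in datasets.items()},
        "elapsed_s": round(time.time() - t0, 2),
    }
    _write_manifest(outdir, cfg, stages)
    return datasets, reports


def run_model_pipeline(
    cfg: PipelineConfig,
    dataset: PairDataset,
    library_pairs: list[tuple[str, str]] | None = None,
) -> tuple[EnsembleModel, CVReport, ScreenSummary | None]:
    """Featurize -> train -> compound-out CV -> optional library screen."""
    cfg.validate_inputs(need_profiles=True)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: dict[str, Any] = {}

    t0 = time.time()
    profiles = TargetProfileMatrix.from_long_tsv(cfg.profiles_path)
    X = profiles.descriptor_matrix(dataset.pairs)
    stages["featurize"] = {
        "n_pairs": len(dataset),
        "n_descriptors": X.shape[1],
        "target_order_hash": profiles.target_order_hash,
        "elapsed_s": round(time.time() - t0, 2),
    }

    t0 = time.time()
    model = fit_undersampled_forest(
        X,
        dataset.labels,
        M=cfg.M,
        n_trees=cfg.n_trees,
        seed=stage_seed(cfg.seed, "train"),
        ad_coverage=cfg.ad_coverage,
        ade=dataset.ade,
        target_order_hash=profiles.target_order_hash,
    )
    model.save(outdir / f"model_{dataset.ade}")
    stages["train"] = {"M": model.M, "tau": model.tau,
                       "elapsed_s": round(time.time() - t0, 2)}

    t0 = time.time()
    cv = compound_out_cv(
        dataset,
        X,
        k=cfg.cv_folds,
        seed=stage_seed(cfg.seed, "cv"),
        M=cfg.M,
        n_trees=cfg.n_trees,
        ad_coverage=cfg.ad_coverage,
        target_order_hash=profiles.target_order_hash,
    )
    (outdir / f"cv_{dataset.ade}.json").write_text(json.dumps(cv.to_dict(), indent=2))
    cv.predictions.to_csv(outdir / f"cv_predictions_{dataset.ade}.tsv", sep="\t", index=False)
    stages["cv"] = {"auc": cv.auc, "balanced_accuracy": cv.balanced_accuracy,
                    "elapsed_s": round(time.time() - t0, 2)}

    summary = None
    if library_pairs:
        t0 = time.time()
        XL = profiles.descriptor_matrix(library_pairs)
        summary, table, hist = screen_pair_library(
            model, library_pairs, XL, cfg.thresholds, profiles.target_order_hash
        )
        table.to_csv(outdir / f"library_{dataset.ade}.tsv", sep="\t", index=False)
        counts, edges = hist
        pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}).to_csv(
            outdir / f"library_hist_{dataset.ade}.tsv", sep="\t", index=False
        )
        stages["library"] = {
            "total": summary.total,
            "in_ad": summary.in_ad,
            "counts": {str(k): v for k, v in summary.counts.items()},
            "elapsed_s": round(time.time() - t0, 2),
        }
    _write_manifest(outdir, cfg, stages)
    return model, cv, summary
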