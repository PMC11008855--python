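"""End-to-end orchestration: phantoms → denoise → segment → features →
selection → CVAE classification → metrics.

A single global seed fans out to per-stage seeds through
``numpy.random.SeedSequence([seed, stage_index])`` (stages indexed in
pipeline order), so any stage can be re-run in isolation and the whole
report is a pure function of (config, seed).  Configuration is a strictly
validated YAML document; unknown keys are rejected with every offending key
named.  While a run is in progress the report carries a ``.partial`` marker
file, removed on success.
"""

from __future__ import annotations

import json
import os
import time
from typing import Callable

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from hybridpath import cvae as cvae_mod
from hybridpath import fixtures, metrics
from hybridpath.denoise import asmdbutmf
from hybridpath.feature_selection import FSConfig, select_features
from hybridpath.features import FEATURE_NAMES, extract_features
from hybridpath.optimize import OptConfig
from hybridpath.segmentation import LevelSetParams, SegmentConfig, segment

STAGE_ORDER = ("simulate", "augment", "denoise", "segment", "extract",
               "select", "classify")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Strict):
    n_per_class: int = 20
    image_size: int = 128
    n_nuclei_benign: int = 5
    n_nuclei_malignant: int = 5
    noise_density: float = 0.3


class StageToggles(_Strict):
    augment: bool = False
    denoise: bool = True
    segment: bool = True
    select: bool = True
    classify: bool = True


class SelectStage(_Strict):
    alpha_w: float = 0.99
    knn_k: int = 5
    cv_folds: int = 3
    pop_size: int = 12
    t_max: int = 20


class CVAEStage(_Strict):
    h1: int = 64
    h2: int = 32
    z_dim: int = 8
    learning_rate: float = 0.01
    epochs: int = 120
    batch_size: int = 32
    folds: int = 5


class SegmentStage(_Strict):
    threshold_epochs: int = 3
    mu_penalty: float = 0.2
    lambda_edge: float = 5.0
    sigma: float = 1.5
    dt: float = 0.1
    iters: int = 40
    eps: float = 1.5


class PipelineConfig(_Strict):
    seed: int = 0
    outdir: str = "hybridpath_run"
    simulate: SimulateConfig = SimulateConfig()
    stages: StageToggles = StageToggles()
    segment: SegmentStage = SegmentStage()
    select: SelectStage = SelectStage()
    cvae: CVAEStage = CVAEStage()


class ConfigError(ValueError):
    pass


def load_config(path: str | os.PathLike) -> PipelineConfig:
    """Load and validate a pipeline YAML; empty files mean all defaults."""
    if not os.path.exists(path):
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def validate_config(raw: dict) -> PipelineConfig:
    try:
        return PipelineConfig(**raw)
    except ValidationError as exc:
        lines = []
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"]) or "<root>"
            lines.append(f"{loc}: {err['msg']}")
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(lines)) from exc


def dump_config(config: PipelineConfig, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh)


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage 31-bit seed from the global seed."""
    idx = STAGE_ORDER.index(stage)
    ss = np.random.SeedSequence([int(global_seed), idx])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_pipeline(config: PipelineConfig,
                 log: Callable[[str], None] | None = None) -> dict:
    """Run the enabled stages in order and return the serializable report."""
    t0 = time.time()
    log = log or (lambda msg: None)
    os.makedirs(config.outdir, exist_ok=True)
    report_path = os.path.join(config.outdir, "report.json")
    partial_marker = report_path + ".partial"
    with open(partial_marker, "w") as fh:
        fh.write("run in progress\n")

    report: dict = {"seed": config.seed, "config": config.model_dump(),
                    "timings": {}, "artifacts": {}}
    try:
        result = _run_stages(config, report, log)
    except Exception:
        raise
    else:
        os.remove(partial_marker)
    report["timings"]["total_s"] = round(time.time() - t0, 3)
    with open(report_path, "w") as fh:
        json.dump(result, fh, indent=2, sort_keys=True)
    # deterministic companion: everything except wall-clock timings, so two
    # runs with the same (config, seed) produce byte-identical files
    deterministic = {k: v for k, v in result.items() if k != "timings"}
    metrics_path = os.path.join(config.outdir, "metrics.json")
    with open(metrics_path, "w") as fh:
        json.dump(deterministic, fh, indent=2, sort_keys=True)
    report["artifacts"]["report"] = report_path
    report["artifacts"]["metrics"] = metrics_path
    return result


def _timed(report: dict, name: str, fn):
    start = time.time()
    out = fn()
    report["timings"][f"{name}_s"] = round(time.time() - start, 3)
    return out


def _run_stages(config: PipelineConfig, report: dict,
                log: Callable[[str], None]) -> dict:
    sim = config.simulate

    # --- simulate -----------------------------------------------------------
    log(f"[simulate] {2 * sim.n_per_class} phantoms, seed {config.seed}")
    seed0 = stage_seed(config.seed, "simulate")

    def simulate():
        images, masks, labels = [], [], []
        for i in range(2 * sim.n_per_class):
            label = "benign" if i < sim.n_per_class else "malignant"
            spec = fixtures.PhantomSpec(
                size=(sim.image_size, sim.image_size),
                n_nuclei=(sim.n_nuclei_benign if label == "benign"
                          else sim.n_nuclei_malignant),
                class_label=label, seed=seed0 + i,
            )
            img, msk, _ = fixtures.make_phantom(spec)
            if sim.noise_density > 0:
                _, img = fixtures.make_saltpepper_pair(
                    img, fixtures.NoiseSpec(density=sim.noise_density,
                                            seed=seed0 + 100000 + i))
            images.append(img)
            masks.append(msk)
            labels.append(0 if label == "benign" else 1)
        return images, masks, np.array(labels)

    images, true_masks, y = _timed(report, "simulate", simulate)
    report["n_images"] = len(images)

    # --- denoise ------------------------------------------------------------
    if config.stages.denoise:
        log("[denoise] ASMDBUTMF")
        images = _timed(report, "denoise", lambda: [asmdbutmf(im) for im in images])

    # --- segment ------------------------------------------------------------
    if config.stages.segment:
        log("[segment] thresholding-based level set")
        seg_cfg = SegmentConfig(
            threshold_epochs=config.segment.threshold_epochs,
            levelset=LevelSetParams(
                mu_penalty=config.segment.mu_penalty,
                lambda_edge=config.segment.lambda_edge,
                sigma=config.segment.sigma, dt=config.segment.dt,
                iters=config.segment.iters, eps=config.segment.eps,
            ),
        )
        masks = _timed(report, "segment",
                       lambda: [segment(im, seg_cfg) for im in images])
        dices = [metrics.dice(m, t) for m, t in zip(masks, true_masks)]
        report["segmentation_mean_dice"] = float(np.mean(dices))
    else:
        masks = [m for m in true_masks]

    # --- extract ------------------------------------------------------------
    log("[extract] 33-feature morphometry")

    def extract():
        return np.stack([
            extract_features(im, mk).values for im, mk in zip(images, masks)
        ])

    X = _timed(report, "extract", extract)
    feats_path = os.path.join(config.outdir, "features.csv")
    fixtures.write_features(X, feats_path, FEATURE_NAMES)
    np.savetxt(os.path.join(config.outdir, "labels.csv"), y, fmt="%d",
               header="label", comments="")
    report["artifacts"]["features"] = feats_path

    # --- select -------------------------------------------------------------
    selected = np.ones(X.shape[1], dtype=bool)
    if config.stages.select:
        log("[select] hybrid CSCO-ROA wrapper selection")
        fs_cfg = FSConfig(
            alpha_w=config.select.alpha_w, knn_k=config.select.knn_k,
            cv_folds=config.select.cv_folds,
            optimizer=OptConfig(pop_size=config.select.pop_size, dim=33,
                                bounds=(-4.0, 4.0), t_max=config.select.t_max,
                                seed=stage_seed(config.seed, "select"),
                                mode="hybrid"),
        )
        mask_sel, opt_res = _timed(report, "select",
                                   lambda: select_features(X, y, fs_cfg))
        selected = mask_sel.bits.astype(bool)
        report["selected_features"] = {
            "bits": mask_sel.bits.tolist(),
            "n_selected": mask_sel.n_selected,
            "family_counts": mask_sel.family_counts(),
            "best_fitness": opt_res.best_fitness,
        }

    # --- classify + evaluate ------------------------------------------------
    result = dict(report)
    if config.stages.classify:
        log(f"[classify] CVAE, {config.cvae.folds}-fold cross-validation")
        cvae_cfg = cvae_mod.CVAEConfig(
            h1=config.cvae.h1, h2=config.cvae.h2, z_dim=config.cvae.z_dim,
            learning_rate=config.cvae.learning_rate,
            batch_size=config.cvae.batch_size, epochs=config.cvae.epochs,
        )
        cls_seed = stage_seed(config.seed, "classify")
        Xsel = X[:, selected]
        pad = np.zeros((X.shape[0], 33 - Xsel.shape[1]))

        def pipeline_fn(X_train, y_train, X_test):
            # unselected columns enter as constant 0 so the net keeps width 33
            x_min, x_max = cvae_mod.fit_minmax(X_train)
            tr = cvae_mod.apply_minmax(X_train, x_min, x_max)
            te = cvae_mod.apply_minmax(X_test, x_min, x_max)
            tr = np.hstack([tr, pad[: tr.shape[0]]])
            te = np.hstack([te, pad[: te.shape[0]]])
            params, _ = cvae_mod.train(tr, y_train, cvae_cfg, seed=cls_seed)
            return cvae_mod.classify_batch(te, params)

        cv = _timed(report, "classify", lambda: metrics.kfold_evaluate(
            Xsel, y, config.cvae.folds, pipeline_fn, seed=cls_seed))
        result["metrics"] = cv["average"]
        result["fold_table"] = [r.as_dict() for r in cv["folds"]]
        result["n_defined"] = cv["n_defined"]
    result["timings"] = report["timings"]
    return result
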