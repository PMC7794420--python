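"""End-to-end run: phantom → PRM/deformation → network inputs → CV → report → CAM.

Phantom generation and preprocessing are deterministic and cheap at demo
scale, so they are recomputed in memory on every run; the expensive stages
(cross-validated training, evaluation) cache their artifacts in the run
directory keyed by a content hash of the relevant config subsections, and a
rerun with an unchanged config reloads them instead of retraining.  Every
run directory carries the full config copy, seeds and package version needed
to reproduce it bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cnn import TrainConfig, cross_validate
from .config import RunConfig
from .evaluation import evaluate_predictions
from .gradcam import export_overlay, grad_cam
from .phantom import PhantomParams, generate_cohort
from .preprocess import assemble, subject_maps
from .prm import PRMThresholds

logger = logging.getLogger("prm3d")


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    (out / "run_meta.json").write_text(json.dumps({
        "package_version": __version__,
        "seeds": {"phantom": config.phantom.seed, "train": config.train.seed},
    }, indent=2))

    stage_key = _hash({
        "phantom": config.phantom.model_dump(mode="json"),
        "prm": config.prm.model_dump(mode="json"),
        "train": config.train.model_dump(mode="json"),
    })
    pred_csv = out / "predictions.csv"
    report_json = out / "metrics.json"
    done = out / "train.done.json"
    cached = (
        done.exists()
        and json.loads(done.read_text()).get("key") == stage_key
        and pred_csv.exists()
    )

    params = PhantomParams(shape=config.phantom.shape,
                           upper_lobe_bias=config.phantom.upper_lobe_bias)
    logger.info("stage phantom: %d COPD + %d non-COPD subjects, seed %d",
                config.phantom.n_copd, config.phantom.n_noncopd,
                config.phantom.seed)
    try:
        cohort = generate_cohort(config.phantom.n_copd, config.phantom.n_noncopd,
                                 params, config.phantom.seed)
    except Exception as exc:
        raise RuntimeError(f"stage phantom failed: {exc}") from exc
    cohort.manifest.to_csv(out / "manifest.csv", index=False)

    th = PRMThresholds(config.prm.insp_cut, config.prm.exp_cut)
    kind = config.train.input_kind
    logger.info("stage prep: assembling %r inputs", kind)
    try:
        inputs = [
            assemble(subject_maps(s, kinds=(kind,)), kind, s.subject_id,
                     label=1 if s.truth.group == "COPD" else 0)
            for s in cohort.subjects
        ]
    except Exception as exc:
        raise RuntimeError(f"stage prep failed: {exc}") from exc

    if cached:
        logger.info("stage train: cache hit (%s), skipping", stage_key)
        results = None
        df = pd.read_csv(pred_csv)
        report = evaluate_predictions(df["p_copd"].to_numpy(),
                                      df["label"].to_numpy())
    else:
        cfg = TrainConfig(config.train.iterations, config.train.batch_size,
                          config.train.learning_rate, config.train.seed)
        logger.info("stage train: %d-fold CV, %d iterations, batch %d",
                    config.train.folds, cfg.iterations, cfg.batch_size)
        try:
            results, report = cross_validate(inputs, k=config.train.folds, cfg=cfg)
        except Exception as exc:
            raise RuntimeError(f"stage train failed: {exc}") from exc
        rows = []
        for r in results:
            r.model.save(out / f"model_fold{r.fold}.pkl")
            pd.DataFrame({"loss": r.loss_history, "accuracy": r.acc_history}
                         ).to_csv(out / f"history_fold{r.fold}.csv", index=False)
            rows += [
                {"subject_id": sid, "fold": r.fold, "label": int(lab),
                 "p_copd": float(p)}
                for sid, lab, p in zip(r.test_ids, r.test_labels, r.test_probs)
            ]
        pd.DataFrame(rows).to_csv(pred_csv, index=False)
        done.write_text(json.dumps({"key": stage_key}))

    report_json.write_text(json.dumps(report.as_dict(), indent=2))
    pd.DataFrame(report.roc, columns=["fpr", "tpr"]).to_csv(
        out / "roc.csv", index=False)
    from .evaluation import per_fold_table

    df = pd.read_csv(pred_csv)
    per_fold_table(df["p_copd"].to_numpy(), df["label"].to_numpy(),
                   df["fold"].to_numpy()).to_csv(out / "metrics_per_fold.csv",
                                                 index=False)

    if config.cam.n_examples > 0 and results is not None:
        logger.info("stage cam: %d example overlays", config.cam.n_examples)
        by_id = {s.subject_id: s for s in cohort.subjects}
        model = results[0].model
        shown = 0
        for sid, p, lab in zip(results[0].test_ids, results[0].test_probs,
                               results[0].test_labels):
            if lab == 1 and p >= 0.5:  # true positives
                inp = next(i for i in inputs if i.subject_id == sid)
                heat = grad_cam(model, inp, config.cam.target_class)
                export_overlay(heat, by_id[sid].pair.insp, out / "cam",
                               prefix=sid)
                shown += 1
                if shown >= config.cam.n_examples:
                    break

    logger.info("pipeline complete in %.1f s → %s", time.time() - t0, out)
    return out
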