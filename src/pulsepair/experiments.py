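"""Experiment orchestration: split, train all arms, tabulate, map features.

Reproduces the study design on a synthetic cohort: a patient-level
label-stratified test split is set aside; contrastive pretraining runs on
the remaining patients (optionally plus an unlabelled cohort); horseshoe
probes and end-to-end classifiers are evaluated on the held-out patients,
one row per arm with Precision / Sensitivity / Specificity / AUC.

Pretraining never sees test patients, even though it uses no labels — a
stricter protocol than leaving unlabelled test signals in, chosen to rule
out representation leakage into the evaluation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from .bayes import HorseshoeConfig
from .contrastive import ContrastiveConfig, train_ssl
from .downstream import (build_feature_table, evaluate_classifier,
                         fit_horseshoe_logistic, youden_threshold)
from .encoder import Encoder, count_parameters
from .end_to_end import FinetuneConfig, predict_patients, train_end_to_end
from .nn import state_hash
from .signals import (Recording, apply_norm, fit_norm_stats,
                      segment_recording)

logger = logging.getLogger(__name__)

__all__ = ["ExperimentPlan", "split_cohort", "run_table",
           "export_embedding_map"]


def split_cohort(labels_by_patient: dict[str, int], fraction: float,
                 seed: int) -> dict[str, str]:
    """Patient-level stratified train/test assignment.

    Within each label class a ``fraction`` share (rounded) goes to 'test'.
    Raises if a class has fewer than two patients.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 41]))
    assignment: dict[str, str] = {}
    for label in sorted({v for v in labels_by_patient.values()}):
        pids = sorted(p for p, l in labels_by_patient.items() if l == label)
        if len(pids) < 2:
            raise ValueError(
                f"label {label}: {len(pids)} patient(s), cannot stratify")
        n_test = max(1, int(round(fraction * len(pids))))
        order = rng.permutation(len(pids))
        test = {pids[i] for i in order[:n_test]}
        for p in pids:
            assignment[p] = "test" if p in test else "train"
    return assignment


@dataclass
class ExperimentPlan:
    """All arms of the comparison grid at a chosen (desk) scale."""

    labelled: list[Recording]
    unlabelled: list[Recording] | None = None
    test_fraction: float = 0.20
    encoder_preset: str = "small"
    contrastive: ContrastiveConfig = field(default_factory=ContrastiveConfig)
    finetune: FinetuneConfig = field(default_factory=FinetuneConfig)
    horseshoe: HorseshoeConfig = field(default_factory=HorseshoeConfig)
    probe_feature_sets: tuple[str, ...] = ("ssl", "clinical", "clinical+ssl")
    end_to_end_inits: tuple[str, ...] = ("random", "ssl")
    seed: int = 0


def _ssl_arms(plan: ExperimentPlan) -> list[str]:
    arms = ["labelled"]
    if plan.unlabelled:
        arms.append("labelled+unlabelled")
    return arms


def run_table(plan: ExperimentPlan) -> tuple[pd.DataFrame, dict, dict]:
    """Run every arm; returns (results table, provenance record, artifacts).

    ``artifacts`` holds the per-arm SSL models and patient feature tables so
    callers can export embedding maps without re-training.

    Arms that fail are recorded with an ``error`` column and the run
    continues.  All arms share one test split; thresholds come from
    non-test scores (Youden's J).
    """
    labels = {r.patient_id: r.label for r in plan.labelled}
    split = split_cohort(labels, plan.test_fraction, plan.seed)
    train_recs = [r for r in plan.labelled if split[r.patient_id] == "train"]
    test_recs = [r for r in plan.labelled if split[r.patient_id] == "test"]

    stats = fit_norm_stats(train_recs)
    norm_lab = [apply_norm(r, stats) for r in plan.labelled]
    norm_train = [r for r in norm_lab if split[r.patient_id] == "train"]
    norm_unlab = [apply_norm(r, stats) for r in (plan.unlabelled or [])]

    provenance: dict = {
        "seed": plan.seed, "test_patients": sorted(
            p for p, s in split.items() if s == "test"),
        "norm_stats": stats.__dict__, "arms": {},
    }
    rows: list[dict] = []

    ssl_models: dict[str, Encoder] = {}
    tables: dict[str, pd.DataFrame] = {}
    for arm in _ssl_arms(plan):
        segs = [s for r in norm_train for s in segment_recording(r)]
        if arm == "labelled+unlabelled":
            segs += [s for r in norm_unlab for s in segment_recording(r)]
        try:
            model, hist = train_ssl(segs, plan.encoder_preset, plan.contrastive)
            ssl_models[arm] = model
            tables[arm] = build_feature_table(model, norm_lab, splits=split)
            provenance["arms"][f"ssl({arm})"] = {
                "n_segments": len(segs),
                "weights_hash": state_hash(model.state()),
                "final_loss": float(hist["loss"].iloc[-1]) if len(hist) else None,
            }
        except Exception as exc:  # an arm failure must not kill the run
            logger.exception("SSL arm %s failed", arm)
            rows.append({"model": f"SSL({arm})", "features": "-", "error": str(exc)})

    def eval_probe(table: pd.DataFrame, feature_set: str, label: str):
        try:
            fit = fit_horseshoe_logistic(table, feature_set, plan.horseshoe)
            is_test = table["split"].to_numpy() == "test"
            y = table["hospitalized"].to_numpy(dtype=float)
            s = fit.scores.to_numpy()
            thr = youden_threshold(s[~is_test], y[~is_test])
            m = evaluate_classifier(s[is_test], y[is_test], threshold=thr)
            rows.append({"model": "Logistic regression", "features": label,
                         **{k: m[k] for k in
                            ("precision", "sensitivity", "specificity", "auc")}})
        except Exception as exc:
            logger.exception("probe %s failed", label)
            rows.append({"model": "Logistic regression", "features": label,
                         "error": str(exc)})

    for arm, table in tables.items():
        for fs in plan.probe_feature_sets:
            if "ssl" in fs:
                eval_probe(table, fs, f"{fs}[{arm}]")
        # clinical-only sets do not depend on the SSL arm: evaluate once
        if arm == _ssl_arms(plan)[0]:
            for fs in plan.probe_feature_sets:
                if "ssl" not in fs:
                    eval_probe(table, fs, fs)

    # end-to-end arms: carve a validation fifth of the training patients
    tr_pids = sorted({r.patient_id for r in norm_train})
    val_split = split_cohort({p: labels[p] for p in tr_pids}, 0.2,
                             plan.seed + 1)
    e2e_train = [r for r in norm_train if val_split[r.patient_id] == "train"]
    e2e_val = [r for r in norm_train if val_split[r.patient_id] == "test"]
    norm_test = [r for r in norm_lab if split[r.patient_id] == "test"]
    for init in plan.end_to_end_inits:
        arms = _ssl_arms(plan) if init == "ssl" else [None]
        for arm in arms:
            name = "Random" if init == "random" else f"SSL({arm})"
            try:
                cfg = FinetuneConfig(**{**plan.finetune.__dict__, "init": init})
                model, hist = train_end_to_end(
                    e2e_train, cfg, plan.encoder_preset,
                    ssl_model=ssl_models.get(arm), val_recordings=e2e_val)
                val_scores = predict_patients(model, e2e_val)
                val_y = pd.Series({r.patient_id: r.label for r in e2e_val})
                thr = youden_threshold(val_scores[val_y.index].to_numpy(),
                                       val_y.to_numpy())
                test_scores = predict_patients(model, norm_test)
                test_y = pd.Series({r.patient_id: r.label for r in norm_test})
                m = evaluate_classifier(test_scores[test_y.index].to_numpy(),
                                        test_y.to_numpy(), threshold=thr)
                rows.append({"model": "Deep learning", "features": name,
                             **{k: m[k] for k in
                                ("precision", "sensitivity", "specificity", "auc")}})
                provenance["arms"][f"e2e({name})"] = {
                    "weights_hash": state_hash(model.state()),
                    "n_parameters": count_parameters(model),
                }
            except Exception as exc:
                logger.exception("end-to-end arm %s failed", name)
                rows.append({"model": "Deep learning", "features": name,
                             "error": str(exc)})

    results = pd.DataFrame(rows)
    artifacts = {"ssl_models": ssl_models, "feature_tables": tables,
                 "split": split}
    return results, provenance, artifacts


def export_embedding_map(features: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """2-D t-SNE coordinates of patient-level SSL features.

    ``features`` is a feature table with ``ssl_*`` columns and the three
    vital-sign columns; the output has one row per patient with map
    coordinates plus heart_rate, resp_rate and spo2 for external plotting.
    """
    ssl_cols = [c for c in features.columns if c.startswith("ssl_")]
    x = features[ssl_cols].to_numpy(dtype=np.float64)
    if x.shape[0] < 10:
        raise ValueError("need at least 10 patients for an embedding map")
    if np.allclose(x.var(axis=0), 0):
        raise ValueError("degenerate (constant) features")
    perplexity = min(30.0, (x.shape[0] - 1) / 3)
    coords = TSNE(n_components=2, random_state=seed, init="pca",
                  perplexity=perplexity).fit_transform(x)
    out = pd.DataFrame({
        "patient_id": features["patient_id"].to_numpy(),
        "tsne_1": coords[:, 0], "tsne_2": coords[:, 1],
    })
    for col in ("heart_rate", "resp_rate", "spo2"):
        if col in features.columns:
            out[col] = features[col].to_numpy()
    return out
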