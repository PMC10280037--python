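"""Patient-level features and Bayesian probes of the learned representation.

Each patient's feature vector is the arithmetic mean of the 32-dimensional
representation-stage embeddings of their segments, optionally concatenated
with eight clinical covariates.  Horseshoe-prior probes (logistic for
hospitalization, linear for heart rate / respiratory rate / SpO2) are fitted
on the training split with features standardized by training-split
statistics, and scored on every row.

Classification is summarized by AUC (rank / Mann–Whitney formulation, ties
counted one half), plus sensitivity, specificity and precision at the
threshold maximizing Youden's J on the training split; regression by RMSE
and R².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .bayes import HorseshoeConfig, HorseshoePosterior, fit_horseshoe
from .encoder import Encoder, embed, EMBED_DIM
from .signals import Recording, Segment, segment_recording, segments_to_array, \
    CLINICAL_FIELDS

__all__ = [
    "FitResult", "aggregate_patient_features", "build_feature_table",
    "feature_set_columns", "fit_horseshoe_logistic", "fit_horseshoe_linear",
    "evaluate_classifier", "evaluate_regressor", "youden_threshold",
    "FEATURE_SETS", "REGRESSION_TARGETS",
]

SSL_COLS = [f"ssl_{i:02d}" for i in range(EMBED_DIM)]
CLIN_COLS = [f"clin_{name}" for name in CLINICAL_FIELDS]
REGRESSION_TARGETS = ("heart_rate", "resp_rate", "spo2")
FEATURE_SETS = ("ssl", "clinical", "clinical+ssl", "spo2_hr", "spo2_hr+ssl")


def feature_set_columns(name: str) -> list[str]:
    """Column lists for the named probe feature sets."""
    sets = {
        "ssl": SSL_COLS,
        "clinical": CLIN_COLS,
        "clinical+ssl": CLIN_COLS + SSL_COLS,
        "spo2_hr": ["clin_spo2", "clin_heart_rate"],
        "spo2_hr+ssl": ["clin_spo2", "clin_heart_rate"] + SSL_COLS,
    }
    if name not in sets:
        raise ValueError(f"unknown feature set {name!r}; have {sorted(sets)}")
    return sets[name]


def aggregate_patient_features(embeddings: np.ndarray,
                               patient_ids: list[str]) -> pd.DataFrame:
    """Mean embedding per patient (rows indexed by patient_id).

    ``embeddings`` is (n_segments, 32); ``patient_ids`` maps each row to its
    patient.  Order of segments within a patient does not matter.
    """
    if len(patient_ids) != embeddings.shape[0]:
        raise ValueError("one patient id per embedding row required")
    df = pd.DataFrame(embeddings, columns=SSL_COLS)
    df["patient_id"] = patient_ids
    return df.groupby("patient_id").mean()


def build_feature_table(model: Encoder, recordings: list[Recording],
                        splits: dict[str, str] | None = None) -> pd.DataFrame:
    """One row per patient: SSL features, clinical covariates, targets, split.

    Recordings are expected normalized already; they are segmented, embedded
    at the representation stage, and averaged per patient.  Patients whose
    recordings are all shorter than one window are excluded with a warning.
    """
    embeddings, seg_pids = [], []
    meta_by_pid: dict[str, dict] = {}
    for rec in recordings:
        segs = segment_recording(rec)
        if segs:
            z = embed(model, segments_to_array(segs), stage="representation")
            embeddings.append(z)
            seg_pids.extend([rec.patient_id] * len(segs))
        meta_by_pid.setdefault(rec.patient_id, {
            "hospitalized": rec.label,
            "heart_rate": rec.meta.get("heart_rate"),
            "resp_rate": rec.meta.get("resp_rate"),
            "spo2": rec.meta.get("spo2"),
            **{f"clin_{k}": v
               for k, v in rec.meta.get("clinical", {}).items()},
        })
    if not embeddings:
        raise ValueError("no recording long enough to produce a segment")
    feats = aggregate_patient_features(np.concatenate(embeddings), seg_pids)
    dropped = set(meta_by_pid) - set(feats.index)
    if dropped:
        warnings.warn(f"{len(dropped)} patient(s) without segments excluded")
    meta = pd.DataFrame.from_dict(
        {pid: meta_by_pid[pid] for pid in feats.index}, orient="index")
    table = pd.concat([feats, meta], axis=1).reset_index(names="patient_id")
    if splits is not None:
        table["split"] = table["patient_id"].map(splits)
    return table


@dataclass
class FitResult:
    """Posterior summaries and per-patient predictive scores of one probe."""

    feature_set: str
    target: str
    coef: pd.DataFrame            # index: feature name; mean / ci_low / ci_high
    scores: pd.Series             # indexed by patient_id, all rows scored
    posterior: HorseshoePosterior
    train_ids: list[str]


def _standardize(train: np.ndarray, full: np.ndarray):
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (train - mean) / sd, (full - mean) / sd, mean, sd


def _fit_probe(table: pd.DataFrame, feature_set, target: str,
               config: HorseshoeConfig, linear: bool) -> FitResult:
    cols = (feature_set_columns(feature_set) if isinstance(feature_set, str)
            else list(feature_set))
    name = feature_set if isinstance(feature_set, str) else "+".join(cols)
    if target not in table.columns:
        raise ValueError(f"target {target!r} not in table")
    train = table[table["split"] == "train"] if "split" in table.columns else table
    if train.empty:
        raise ValueError("no training rows in table")
    x_train = train[cols].to_numpy(dtype=np.float64)
    x_full = table[cols].to_numpy(dtype=np.float64)
    y_train = train[target].to_numpy(dtype=np.float64)

    xs_train, xs_full, _, sd_x = _standardize(x_train, x_full)
    if linear:
        mu_y, sd_y = y_train.mean(), y_train.std()
        if sd_y == 0:
            raise ValueError(f"constant target {target!r}")
        post = fit_horseshoe(xs_train, (y_train - mu_y) / sd_y, config, linear=True)
        raw = post.predict(xs_full) * sd_y + mu_y
        beta_scale = sd_y / sd_x
    else:
        post = fit_horseshoe(xs_train, y_train, config, linear=False)
        raw = post.predict(xs_full)
        beta_scale = 1.0 / sd_x

    summ = post.coef_summary()
    coef = pd.DataFrame(
        {k: v * beta_scale for k, v in summ.items()}, index=cols)
    scores = pd.Series(raw, index=table["patient_id"].to_numpy(), name="score")
    return FitResult(name, target, coef, scores, post,
                     train_ids=list(train["patient_id"]))


def fit_horseshoe_logistic(table: pd.DataFrame, feature_set,
                           config: HorseshoeConfig | None = None,
                           target: str = "hospitalized") -> FitResult:
    """Horseshoe logistic probe; scores are posterior-mean probabilities."""
    return _fit_probe(table, feature_set, target, config or HorseshoeConfig(),
                      linear=False)


def fit_horseshoe_linear(table: pd.DataFrame, feature_set, target: str,
                         config: HorseshoeConfig | None = None) -> FitResult:
    """Horseshoe linear probe for heart_rate / resp_rate / spo2."""
    return _fit_probe(table, feature_set, target, config or HorseshoeConfig(),
                      linear=True)


# ---------------------------------------------------------------------------
# metrics

def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the rank (Mann–Whitney) formulation; ties count one half."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Score cut maximizing Youden's J = sensitivity + specificity − 1.

    Candidate thresholds are the observed scores; prediction is
    score >= threshold.  The smallest maximizer is returned.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    cands = np.unique(scores)
    best_j, best_t = -np.inf, cands[0]
    for t in cands:
        pred = scores >= t
        sens = np.mean(pred[labels == 1]) if np.any(labels == 1) else 0.0
        spec = np.mean(~pred[labels == 0]) if np.any(labels == 0) else 0.0
        j = sens + spec - 1
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return float(best_t)


def evaluate_classifier(scores: np.ndarray, labels: np.ndarray,
                        threshold: float | None = None) -> dict[str, float]:
    """AUC plus sensitivity/specificity/precision at a threshold.

    The threshold should be chosen on non-test data (Youden's J via
    :func:`youden_threshold`) and applied here unchanged; when omitted it is
    derived from the supplied scores themselves.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    auc = auc_score(scores, labels)
    if threshold is None:
        threshold = youden_threshold(scores, labels)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    return {
        "auc": auc,
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "precision": tp / (tp + fp) if tp + fp else np.nan,
        "threshold": float(threshold),
    }


def evaluate_regressor(predictions: np.ndarray, truth: np.ndarray
                       ) -> dict[str, float]:
    """RMSE and R² (R² about the truth's mean; NaN for zero-variance truth)."""
    predictions = np.asarray(predictions, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if truth.size < 2:
        raise ValueError("need at least 2 observations")
    rmse = float(np.sqrt(np.mean((predictions - truth) ** 2)))
    sst = float(np.sum((truth - truth.mean()) ** 2))
    if sst == 0:
        warnings.warn("zero-variance truth: R2 undefined")
        return {"rmse": rmse, "r2": float("nan")}
    sse = float(np.sum((predictions - truth) ** 2))
    return {"rmse": rmse, "r2": 1.0 - sse / sst}
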