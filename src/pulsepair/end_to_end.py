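"""End-to-end hospitalization classifier.

The network is the contrastive encoder with its last 32-unit head layer
replaced by a single output.  It can be initialized randomly or from
pretrained contrastive weights (trunk + first head layer copied; the new
single-output layer is always freshly initialized).  Training is segment
level — every segment inherits its patient's label — with binary
cross-entropy on label-smoothed targets; the minority class is oversampled
at the patient level before segmentation so that a replicated patient
contributes all of their segments again.  Evaluation is patient level: a
patient's score is the mean sigmoid output over their segments.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .augment import AugmentPolicy, apply_policy
from .contrastive import Encoder
from .downstream import auc_score
from .encoder import EncoderConfig, build_encoder, PRESETS
from .signals import Recording, segment_recording, segments_to_array

logger = logging.getLogger(__name__)

__all__ = [
    "FinetuneConfig", "build_classifier", "smooth_labels",
    "oversample_minority", "train_end_to_end", "predict_patients",
    "bce_with_logits",
]


@dataclass(frozen=True)
class FinetuneConfig:
    """End-to-end training settings."""

    init: str = "random"            # 'random' or 'ssl'
    label_smoothing: float = 0.1    # ε; targets become y(1−ε) + ε/2
    oversample: bool = True
    epochs: int = 5
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    dropout: float = 0.0
    batch_size: int = 32
    augment: AugmentPolicy | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.label_smoothing < 0.5:
            raise ValueError("label_smoothing must be in [0, 0.5)")
        if self.init not in ("random", "ssl"):
            raise ValueError("init must be 'random' or 'ssl'")


def build_classifier(config: EncoderConfig | str, init: str = "random",
                     ssl_model: Encoder | None = None, seed: int = 0) -> Encoder:
    """Single-output classifier; optionally warm-started from SSL weights.

    With ``init='ssl'`` the trunk and first 32-unit head layer are copied
    bit-for-bit from ``ssl_model`` (whose architecture must match); the
    replaced single-output layer is always freshly initialized.
    """
    model = build_encoder(config, head="classifier", seed=seed)
    if init == "ssl":
        if ssl_model is None:
            raise ValueError("init='ssl' requires ssl_model")
        if ssl_model.config != model.config:
            raise ValueError(
                "SSL weights were trained with a different architecture: "
                f"{ssl_model.config} vs {model.config}")
        kept = ssl_model.trunk_and_fc1_state()
        own = nn.collect_state(model._as_layer())
        for k, v in kept.items():
            own[k][...] = v
    elif init != "random":
        raise ValueError(f"unknown init mode {init!r}")
    return model


def smooth_labels(y: np.ndarray, eps: float) -> np.ndarray:
    """y' = y(1−ε) + ε/2; hard 0/1 targets become ε/2 and 1−ε/2."""
    if not 0.0 <= eps < 0.5:
        raise ValueError(f"label smoothing must be in [0, 0.5), got {eps}")
    y = np.asarray(y, dtype=np.float64)
    return y * (1.0 - eps) + eps / 2.0


def oversample_minority(items: list, labels: np.ndarray,
                        rng: np.random.Generator) -> tuple[list, np.ndarray]:
    """Resample minority-class items with replacement until classes balance.

    Majority items pass through untouched; balanced input is returned
    unchanged.  Deterministic under a fixed rng.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    n0, n1 = int(np.sum(labels == classes[0])), int(np.sum(labels == classes[1]))
    if n0 == n1:
        return list(items), labels
    minority = classes[1] if n1 < n0 else classes[0]
    deficit = abs(n0 - n1)
    pool = [i for i, lab in enumerate(labels) if lab == minority]
    extra = rng.choice(pool, size=deficit, replace=True)
    out_items = list(items) + [items[i] for i in extra]
    out_labels = np.concatenate([labels, labels[extra]])
    return out_items, out_labels


def bce_with_logits(logits: np.ndarray, targets: np.ndarray
                    ) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dlogits)."""
    z = np.asarray(logits, dtype=np.float64).ravel()
    y = np.asarray(targets, dtype=np.float64).ravel()
    # stable: log(1+e^z) - y z
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
    p = 1.0 / (1.0 + np.exp(-z))
    return loss, (p - y) / z.size


def train_end_to_end(train_recordings: list[Recording],
                     config: FinetuneConfig,
                     encoder_config: EncoderConfig | str = "small",
                     ssl_model: Encoder | None = None,
                     val_recordings: list[Recording] | None = None
                     ) -> tuple[Encoder, pd.DataFrame]:
    """Fine-tune the classifier on labelled recordings; returns (model, history).

    Requires patient-disjoint train/validation recordings, each with a 0/1
    label.  History has per-epoch mean training loss and, when validation
    recordings are given, patient-level validation AUC.
    """
    if any(r.label is None for r in train_recordings):
        raise ValueError("all training recordings need labels")
    if val_recordings:
        overlap = ({r.patient_id for r in train_recordings}
                   & {r.patient_id for r in val_recordings})
        if overlap:
            raise ValueError(
                f"train/validation splits share patients: {sorted(overlap)[:3]}")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 31]))
    model = build_classifier(encoder_config, init=config.init,
                             ssl_model=ssl_model, seed=config.seed)
    if config.dropout > 0:
        model.dropout.p = config.dropout
        model.set_dropout_rng(rng)
    opt = nn.Adam(model, lr=config.learning_rate,
                  weight_decay=config.weight_decay)

    recs = list(train_recordings)
    labels = np.array([r.label for r in recs])
    if config.oversample:
        recs, labels = oversample_minority(recs, labels, rng)

    # expand each (possibly replicated) recording into its segments
    segs, seg_labels = [], []
    for rec, lab in zip(recs, labels):
        ss = segment_recording(rec)
        segs.extend(ss)
        seg_labels.extend([lab] * len(ss))
    seg_labels = smooth_labels(np.array(seg_labels, dtype=np.float64),
                               config.label_smoothing)

    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(segs))
        losses = []
        for start in range(0, len(segs), config.batch_size):
            idx = order[start: start + config.batch_size]
            batch = [segs[i] for i in idx]
            if config.augment is not None:
                batch = [apply_policy(s, config.augment, rng) for s in batch]
            x = segments_to_array(batch)
            z = model.forward(x, train=True)
            loss, dz = bce_with_logits(z, seg_labels[idx])
            if not np.isfinite(loss):
                raise RuntimeError(f"training loss diverged at epoch {epoch}")
            model.zero_grad()
            model.backward(dz.reshape(z.shape))
            opt.step()
            losses.append(loss)
        row = {"epoch": epoch, "loss": float(np.mean(losses))}
        if val_recordings:
            scores = predict_patients(model, val_recordings)
            val_labels = pd.Series(
                {r.patient_id: r.label for r in val_recordings})
            row["val_auc"] = auc_score(scores[val_labels.index].to_numpy(),
                                       val_labels.to_numpy())
        history.append(row)
        logger.info("end-to-end epoch %d: %s", epoch, row)
    return model, pd.DataFrame(history)


def predict_patients(model: Encoder, recordings: list[Recording]) -> pd.Series:
    """Patient score = mean sigmoid segment output over the patient's segments."""
    by_pid: dict[str, list] = {}
    for rec in recordings:
        by_pid.setdefault(rec.patient_id, []).extend(segment_recording(rec))
    scores = {}
    for pid, segs in by_pid.items():
        if not segs:
            warnings.warn(f"patient {pid} has no full-length segment; excluded")
            continue
        z = model.forward(segments_to_array(segs), train=False).ravel()
        scores[pid] = float(np.mean(1.0 / (1.0 + np.exp(-z))))
    return pd.Series(scores, name="score")
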