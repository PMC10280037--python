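"""Patient-instance contrastive pretext task.

Mini-batches hold N pairs of segments (2N segments); the two members of a
pair come from the same pseudo-patient, and for each query segment the other
2(N−1) segments in the batch act as negatives.  Admission and discharge
recordings of the same child count as *different* pseudo-patients, because a
hospital stay separates them and the underlying physiology has changed.

The loss for query ``q`` with positive partner ``k₊`` is noise-contrastive
estimation with dot-product similarity and temperature τ:

    l = −log [ exp(q·k₊/τ) / Σ_i exp(q·k_i/τ) ]

where the sum runs over the positive and the 2(N−1) negatives.  The reported
batch loss is the mean of l over all 2N queries (both pair members serve as
queries).  Chance level is ln(2N−1); top-1 retrieval chance is 1/(2N−1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import nn
from .augment import AugmentPolicy, apply_policy
from .encoder import Encoder, EncoderConfig, build_encoder
from .signals import Segment, segments_to_array

logger = logging.getLogger(__name__)

__all__ = [
    "PairBatch", "ContrastiveConfig", "make_pair_batches", "nce_loss",
    "nce_loss_and_grad", "train_ssl", "pair_accuracy", "chance_loss",
    "chance_accuracy",
]


@dataclass
class PairBatch:
    """2N segments ordered as N pairs: slots (2j, 2j+1) share a pseudo-patient."""

    segments: list[Segment]
    pseudo_patient_ids: list[str]

    def __post_init__(self):
        if len(self.segments) != 2 * len(self.pseudo_patient_ids):
            raise ValueError("batch must hold exactly 2 segments per pseudo-patient")
        for j, pid in enumerate(self.pseudo_patient_ids):
            a, b = self.segments[2 * j], self.segments[2 * j + 1]
            if not (a.pseudo_patient_id == b.pseudo_patient_id == pid):
                raise ValueError(f"pair {j} does not share pseudo-patient {pid!r}")
        if len(set(self.pseudo_patient_ids)) != len(self.pseudo_patient_ids):
            raise ValueError("pseudo-patients within a batch must be distinct")

    @property
    def n_pairs(self) -> int:
        return len(self.pseudo_patient_ids)

    def to_array(self) -> np.ndarray:
        return segments_to_array(self.segments)


@dataclass(frozen=True)
class ContrastiveConfig:
    """Pretext-task training settings."""

    batch_pairs: int = 8         # N
    temperature: float = 0.5     # τ of the NCE loss
    epochs: int = 5
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    dropout: float = 0.0
    augment: AugmentPolicy = field(default_factory=AugmentPolicy)
    seed: int = 0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.batch_pairs < 2:
            raise ValueError("training needs at least 2 pairs per batch")


def group_by_pseudo_patient(segments: Sequence[Segment]) -> dict[str, list[Segment]]:
    groups: dict[str, list[Segment]] = {}
    for s in segments:
        groups.setdefault(s.pseudo_patient_id, []).append(s)
    return groups


def make_pair_batches(segments: Sequence[Segment], n_pairs: int,
                      rng: np.random.Generator,
                      policy: AugmentPolicy | None = None
                      ) -> list[PairBatch]:
    """One epoch of pair batches.

    Pseudo-patients are shuffled and consumed in groups of ``n_pairs``
    (a trailing incomplete group is dropped); each contributes two distinct
    segments drawn without replacement.  Pseudo-patients with fewer than two
    segments are skipped with a warning.  The augmentation policy, if given,
    is applied independently to every emitted segment.
    """
    groups = group_by_pseudo_patient(segments)
    thin = [pid for pid, segs in groups.items() if len(segs) < 2]
    if thin:
        warnings.warn(f"skipping {len(thin)} pseudo-patient(s) with a single segment")
        for pid in thin:
            del groups[pid]
    if len(groups) < n_pairs:
        raise ValueError(
            f"need at least {n_pairs} pseudo-patients with >=2 segments, "
            f"have {len(groups)}")
    pids = sorted(groups)
    order = rng.permutation(len(pids))
    batches = []
    for start in range(0, len(pids) - n_pairs + 1, n_pairs):
        chosen = [pids[i] for i in order[start: start + n_pairs]]
        segs: list[Segment] = []
        for pid in chosen:
            pool = groups[pid]
            i, j = rng.choice(len(pool), size=2, replace=False)
            for s in (pool[i], pool[j]):
                segs.append(apply_policy(s, policy, rng) if policy else s)
        batches.append(PairBatch(segs, chosen))
    return batches


def _pairwise_logits(z: np.ndarray, tau: float) -> np.ndarray:
    if tau <= 0:
        raise ValueError("temperature must be > 0")
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite embeddings")
    s = z @ z.T / tau
    np.fill_diagonal(s, -np.inf)  # a query never scores against itself
    return s


def _partners(n: int) -> np.ndarray:
    return np.arange(n) ^ 1  # (0,1), (2,3), ... swap within pairs


def nce_loss(embeddings: np.ndarray, tau: float) -> float:
    """Mean NCE loss over all 2N queries of a pair batch.

    ``embeddings`` is (2N, d), rows ordered as consecutive pairs.  For N=1
    the softmax has only the positive candidate and the loss is 0.
    """
    z = np.asarray(embeddings, dtype=np.float64)
    s = _pairwise_logits(z, tau)
    idx = np.arange(z.shape[0])
    pos = s[idx, _partners(z.shape[0])]
    return float(np.mean(logsumexp(s, axis=1) - pos))


def nce_loss_and_grad(embeddings: np.ndarray, tau: float
                      ) -> tuple[float, np.ndarray]:
    """Loss plus its gradient with respect to the embeddings."""
    z = np.asarray(embeddings, dtype=np.float64)
    n = z.shape[0]
    s = _pairwise_logits(z, tau)
    lse = logsumexp(s, axis=1)
    p = np.exp(s - lse[:, None])         # row-softmax over the 2N−1 candidates
    idx = np.arange(n)
    part = _partners(n)
    loss = float(np.mean(lse - s[idx, part]))
    g = p
    g[idx, part] -= 1.0
    g /= n
    dz = (g + g.T) @ z / tau             # s = z zᵀ/τ is symmetric in z
    return loss, dz


def chance_loss(n_pairs: int) -> float:
    """Uniform-softmax baseline ln(2N−1)."""
    return float(np.log(2 * n_pairs - 1))


def chance_accuracy(n_pairs: int) -> float:
    """Top-1 retrieval chance 1/(2N−1)."""
    return 1.0 / (2 * n_pairs - 1)


def pair_accuracy(model: Encoder, batches: Iterable[PairBatch],
                  stage: str = "projection") -> float:
    """Fraction of queries whose positive partner is the top-1 dot-product
    neighbour among the 2N−1 in-batch candidates (argmax takes the first
    index on exact ties)."""
    hits = total = 0
    for batch in batches:
        z = model.forward(batch.to_array(), train=False,
                          stage=None if stage == "projection" else stage)
        s = z @ z.T
        np.fill_diagonal(s, -np.inf)
        pred = np.argmax(s, axis=1)
        hits += int(np.sum(pred == _partners(z.shape[0])))
        total += z.shape[0]
    if total == 0:
        raise ValueError("no batches supplied to pair_accuracy")
    return hits / total


def train_ssl(segments: Sequence[Segment],
              encoder_config: EncoderConfig | str,
              config: ContrastiveConfig,
              val_segments: Sequence[Segment] | None = None
              ) -> tuple[Encoder, pd.DataFrame]:
    """Train the encoder on the pretext task; returns (model, history).

    History has one row per epoch with the mean training loss and, when
    validation segments are given, the top-1 pair-retrieval accuracy on
    freshly drawn validation batches.  Deterministic for a fixed seed on a
    single thread.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    model = build_encoder(encoder_config, head="projection", seed=config.seed)
    if config.dropout > 0:
        model.dropout.p = config.dropout
        model.set_dropout_rng(rng)
    opt = nn.Adam(model, lr=config.learning_rate,
                  weight_decay=config.weight_decay)
    history = []
    for epoch in range(config.epochs):
        losses = []
        for batch in make_pair_batches(segments, config.batch_pairs, rng,
                                       policy=config.augment):
            x = batch.to_array()
            z = model.forward(x, train=True)
            loss, dz = nce_loss_and_grad(z, config.temperature)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"contrastive loss diverged at epoch {epoch}: {loss}")
            model.zero_grad()
            model.backward(dz)
            opt.step()
            losses.append(loss)
        row = {"epoch": epoch, "loss": float(np.mean(losses))}
        if val_segments is not None:
            val_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13, epoch]))
            val_batches = make_pair_batches(val_segments, config.batch_pairs, val_rng)
            row["pair_accuracy"] = pair_accuracy(model, val_batches)
        history.append(row)
        logger.info("ssl epoch %d: %s", epoch, row)
    return model, pd.DataFrame(history)
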