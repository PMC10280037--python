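"""1-D ResNet-style encoder for two-channel PPG segments.

The encoder maps a batch of 10 s segments, shaped ``(batch, 2, 800)``, through
a convolutional trunk (stem + four residual stages, max-pooling after every
stage) and a two-layer fully connected head of 32 units each.  After
contrastive training the last head layer is discarded: the 32-dimensional
output of the *first* head layer is the representation used downstream, while
the full head output (the "projection") is what the contrastive loss sees.

Two presets are provided:

``full``
    A ResNet50-like bottleneck trunk whose widths and kernel size are
    calibrated so that the single-output end-to-end classifier variant has
    exactly 9,218,369 trainable parameters (see
    ``scripts/calibrate_full_preset.py`` for the search).

``small``
    A four-stage basic-block trunk of ~50k parameters for desk-scale
    training and testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn

__all__ = [
    "EncoderConfig", "Encoder", "build_encoder", "embed", "count_parameters",
    "count_parameters_formula", "save_weights", "load_weights", "PRESETS",
]

EMBED_DIM = 32  # both head layers have 32 units
SEGMENT_LEN = 800  # 10 s at 80 Hz
IN_CHANNELS = 2  # red + infrared


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture hyper-parameters of the trunk and head.

    ``stage_widths`` are the per-stage mid widths; bottleneck stages output
    four times their mid width.  ``head`` selects ``projection`` (two 32-unit
    layers), ``representation`` (first 32-unit layer only) or ``classifier``
    (first 32-unit layer + single output).
    """

    stage_blocks: tuple[int, int, int, int] = (1, 1, 1, 1)
    stage_widths: tuple[int, int, int, int] = (8, 16, 32, 64)
    kernel_size: int = 7
    use_bottleneck: bool = False
    stem_width: int = 8
    stem_kernel: int = 7
    dropout: float = 0.0
    preset: str = "custom"

    def __post_init__(self):
        if self.kernel_size % 2 == 0 or self.stem_kernel % 2 == 0:
            raise ValueError("kernel sizes must be odd")
        if len(self.stage_blocks) != 4 or len(self.stage_widths) != 4:
            raise ValueError("exactly four stages are required")
        if any(b < 1 for b in self.stage_blocks) or any(w < 1 for w in self.stage_widths):
            raise ValueError("stage blocks and widths must be positive")

    @property
    def trunk_out_channels(self) -> int:
        w4 = self.stage_widths[-1]
        return 4 * w4 if self.use_bottleneck else w4

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EncoderConfig":
        d = dict(d)
        d["stage_blocks"] = tuple(d["stage_blocks"])
        d["stage_widths"] = tuple(d["stage_widths"])
        return cls(**d)


# The full preset's widths/kernel were found by exhaustive search so that the
# classifier variant counts exactly 9,218,369 trainable parameters.
PRESETS: dict[str, EncoderConfig] = {}


def _register_presets():
    from ._full_preset import FULL_PRESET_KWARGS

    PRESETS["full"] = EncoderConfig(preset="full", **FULL_PRESET_KWARGS)
    PRESETS["small"] = EncoderConfig(
        stage_blocks=(1, 1, 1, 1), stage_widths=(8, 16, 32, 64), kernel_size=7,
        use_bottleneck=False, stem_width=8, stem_kernel=7, preset="small")


class Encoder:
    """Convolutional trunk + head, with selectable output stage."""

    def __init__(self, config: EncoderConfig, head: str = "projection",
                 seed: int = 0):
        if head not in ("projection", "representation", "classifier"):
            raise ValueError(f"unknown head mode: {head!r}")
        self.config = config
        self.head_mode = head
        rng = np.random.default_rng(seed)
        c = config

        layers: list[nn.Layer] = [
            nn.Conv1d(IN_CHANNELS, c.stem_width, c.stem_kernel, stride=2, rng=rng),
            nn.BatchNorm1d(c.stem_width), nn.ReLU(), nn.MaxPool1d(2),
        ]
        in_ch = c.stem_width
        for blocks, width in zip(c.stage_blocks, c.stage_widths):
            for _ in range(blocks):
                if c.use_bottleneck:
                    layers.append(nn.BottleneckBlock(in_ch, width, c.kernel_size, rng))
                    in_ch = width * nn.BottleneckBlock.expansion
                else:
                    layers.append(nn.ResidualBlock(in_ch, width, c.kernel_size, rng))
                    in_ch = width
            layers.append(nn.MaxPool1d(2))
        layers.append(nn.GlobalAvgPool())
        self.trunk = nn.Sequential(*layers)

        self.dropout = nn.Dropout(c.dropout)
        self.fc1 = nn.Linear(in_ch, EMBED_DIM, rng=rng)
        self.relu1 = nn.ReLU()
        out_dim = 1 if head == "classifier" else EMBED_DIM
        # small-gain head init keeps initial similarities/logits near zero,
        # so training starts at the chance-level loss
        self.fc2 = nn.Linear(EMBED_DIM, out_dim, rng=rng, gain=0.1)
        self._head_layers = [self.dropout, self.fc1, self.relu1, self.fc2]

    # -- Layer-like protocol over the whole model -------------------------
    def children(self) -> list[nn.Layer]:
        layers = [self.trunk, self.dropout, self.fc1, self.relu1]
        if self.head_mode != "representation":
            layers.append(self.fc2)
        return layers

    def _as_layer(self) -> nn.Sequential:
        return nn.Sequential(*self.children())

    def forward(self, x: np.ndarray, train: bool = False,
                stage: str | None = None) -> np.ndarray:
        """Run a ``(batch, 2, 800)`` array through trunk and head.

        ``stage='representation'`` stops after the first head layer.
        """
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 3 or x.shape[1] != IN_CHANNELS:
            raise ValueError(
                f"expected input of shape (batch, {IN_CHANNELS}, {SEGMENT_LEN}), "
                f"got {x.shape}")
        h = self.trunk.forward(x, train=train)
        h = self.dropout.forward(h, train=train)
        h = self.relu1.forward(self.fc1.forward(h, train=train), train=train)
        if stage == "representation" or self.head_mode == "representation":
            return h
        return self.fc2.forward(h, train=train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = self.fc2.backward(dy)
        dh = self.fc1.backward(self.relu1.backward(dh))
        dh = self.dropout.backward(dh)
        return self.trunk.backward(dh)

    def zero_grad(self):
        self._as_layer().zero_grad()

    def set_dropout_rng(self, rng: np.random.Generator):
        self.dropout.rng = rng

    # -- state -------------------------------------------------------------
    def state(self) -> dict[str, np.ndarray]:
        return nn.collect_state(self._as_layer())

    def load(self, state: dict[str, np.ndarray]):
        nn.load_state(self._as_layer(), state)

    def trunk_and_fc1_state(self) -> dict[str, np.ndarray]:
        """State of everything except the last head layer (the part kept
        when the head is discarded or replaced)."""
        full = self.state()
        n_kept = len(self.children()) - (0 if self.head_mode == "representation" else 1)
        keep_prefixes = tuple(f"{i}." for i in range(n_kept))
        return {k: v for k, v in full.items() if k.startswith(keep_prefixes)}


def build_encoder(config: EncoderConfig | str, head: str = "projection",
                  seed: int = 0) -> Encoder:
    """Construct an encoder from a config or preset name ('full'/'small')."""
    if isinstance(config, str):
        if not PRESETS:
            _register_presets()
        if config not in PRESETS:
            raise ValueError(f"unknown preset {config!r}; have {sorted(PRESETS)}")
        config = PRESETS[config]
    return Encoder(config, head=head, seed=seed)


def embed(model: Encoder, segments: np.ndarray, stage: str = "representation"
          ) -> np.ndarray:
    """Embed segments in evaluation mode (no dropout, running BN stats).

    ``stage`` selects the 32-d output before ('representation') or after
    ('projection') the final head layer; rows align with input order.
    """
    if stage not in ("representation", "projection"):
        raise ValueError(f"unknown stage {stage!r}")
    segments = np.asarray(segments, dtype=np.float64)
    if segments.ndim == 2:
        segments = segments[None]
    return model.forward(segments, train=False,
                         stage="representation" if stage == "representation" else None)


def count_parameters(model: Encoder | nn.Layer) -> int:
    """Number of trainable scalars in the model."""
    if isinstance(model, Encoder):
        return nn.count_parameters(model._as_layer())
    return nn.count_parameters(model)


def count_parameters_formula(config: EncoderConfig, head: str = "projection") -> int:
    """Closed-form trainable-parameter count; must agree with instantiation.

    Used by the preset-calibration search, where instantiating millions of
    candidate models would be wasteful.
    """
    c = config
    total = IN_CHANNELS * c.stem_width * c.stem_kernel + 2 * c.stem_width
    in_ch = c.stem_width
    for blocks, w in zip(c.stage_blocks, c.stage_widths):
        for _ in range(blocks):
            if c.use_bottleneck:
                out = 4 * w
                total += in_ch * w + 2 * w          # 1x1 reduce + BN
                total += w * w * c.kernel_size + 2 * w   # k-conv + BN
                total += w * out + 2 * out          # 1x1 expand + BN
                if in_ch != out:
                    total += in_ch * out + 2 * out  # projection shortcut + BN
                in_ch = out
            else:
                total += in_ch * w * c.kernel_size + 2 * w
                total += w * w * c.kernel_size + 2 * w
                if in_ch != w:
                    total += in_ch * w + 2 * w
                in_ch = w
    total += in_ch * EMBED_DIM + EMBED_DIM  # fc1
    if head == "projection":
        total += EMBED_DIM * EMBED_DIM + EMBED_DIM
    elif head == "classifier":
        total += EMBED_DIM + 1
    elif head != "representation":
        raise ValueError(f"unknown head mode: {head!r}")
    return total


# -- weight files -----------------------------------------------------------

def save_weights(path: str | Path, model: Encoder) -> str:
    """Persist weights (npz) + config/hash sidecar (json); returns the hash."""
    path = Path(path)
    state = model.state()
    h = nn.state_hash(state)
    np.savez(path.with_suffix(".npz"), **state)
    meta = {"config": model.config.to_dict(), "head": model.head_mode, "hash": h}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return h


def load_weights(path: str | Path, head: str | None = None) -> Encoder:
    """Rebuild an encoder from a weight file; verifies the content hash."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    config = EncoderConfig.from_dict(meta["config"])
    with np.load(path.with_suffix(".npz")) as z:
        state = {k: z[k] for k in z.files}
    if nn.state_hash(state) != meta["hash"]:
        raise ValueError(f"weight file {path} is corrupt: content hash mismatch")
    if head is not None and head != meta["head"]:
        raise ValueError(
            f"weights were saved with head={meta['head']!r}, requested {head!r}")
    model = Encoder(config, head=meta["head"])
    model.load(state)
    return model
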