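"""Recording and segment containers, windowing, normalization, cohort I/O.

A recording is a two-channel (red, infrared) PPG time series at 80 Hz.
Recordings are cut into 10 s windows with 2 s overlap between consecutive
windows, and each channel is normalized with the mean and standard deviation
pooled over a reference set of recordings (the labelled cohort).

On disk a recording is a two-column CSV (``red,ir`` header, one sample per
row) with a JSON sidecar of metadata, and a cohort is a manifest CSV listing
the recording files with patient id, split assignment and label.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FS = 80  # Hz; the acquisition pipeline downsamples to this rate
SD_FLOOR = 1e-8
CLINICAL_FIELDS = (
    "weight", "muac", "temperature", "heart_rate", "spo2",
    "restlessness", "able_to_drink", "difficulty_breathing",
)

__all__ = [
    "FS", "CLINICAL_FIELDS", "Recording", "Segment", "NormalizationStats",
    "segment_recording", "fit_norm_stats", "apply_norm", "invert_norm",
    "write_cohort", "read_cohort", "segments_to_array",
]


@dataclass
class Recording:
    """A two-channel PPG time series with identifiers and optional label.

    ``samples`` has shape (T, 2): column 0 is the red channel, column 1 the
    infrared channel.  ``meta`` carries the generating profile's reference
    values (heart_rate, resp_rate, spo2, clinical covariates) when known.
    """

    patient_id: str
    recording_id: str
    samples: np.ndarray
    phase: str = "single"
    fs: int = FS
    label: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs != FS:
            raise ValueError(f"sampling rate must be {FS} Hz, got {self.fs}")
        if self.samples.ndim != 2 or self.samples.shape[1] != 2:
            raise ValueError(
                f"samples must be (T, 2) [red, ir], got {self.samples.shape}")
        if self.phase not in ("admission", "discharge", "single"):
            raise ValueError(f"unknown phase {self.phase!r}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def pseudo_patient_id(self) -> str:
        """Identity used for contrastive pairing: admission and discharge
        recordings of one child count as different pseudo-patients."""
        if self.phase == "single":
            return self.patient_id
        return f"{self.patient_id}:{self.phase}"


@dataclass
class Segment:
    """One fixed-length window of a recording; shape (window, 2)."""

    patient_id: str
    recording_id: str
    index: int
    samples: np.ndarray
    pseudo_patient_id: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2 or self.samples.shape[1] != 2:
            raise ValueError(f"segment samples must be (L, 2), got {self.samples.shape}")
        if not self.pseudo_patient_id:
            self.pseudo_patient_id = self.patient_id


@dataclass(frozen=True)
class NormalizationStats:
    """Per-channel pooled mean/SD of a reference recording set."""

    mean_red: float
    sd_red: float
    mean_ir: float
    sd_ir: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationStats":
        return cls(**json.loads(Path(path).read_text()))

    @property
    def mean(self) -> np.ndarray:
        return np.array([self.mean_red, self.mean_ir])

    @property
    def sd(self) -> np.ndarray:
        return np.array([self.sd_red, self.sd_ir])


def segment_recording(rec: Recording, window_s: float = 10.0,
                      overlap_s: float = 2.0) -> list[Segment]:
    """Cut a recording into overlapping windows.

    Windows are ``window_s`` long with ``overlap_s`` shared between
    consecutive windows (stride = window − overlap).  A trailing remainder
    shorter than one window is dropped; a recording shorter than one window
    yields no segments.
    """
    if overlap_s < 0 or window_s <= overlap_s:
        raise ValueError(
            f"need window_s > overlap_s >= 0, got {window_s}, {overlap_s}")
    win = window_s * rec.fs
    if abs(win - round(win)) > 1e-9:
        raise ValueError(f"window_s*fs must be an integer sample count, got {win}")
    win = int(round(win))
    stride = int(round((window_s - overlap_s) * rec.fs))
    T = rec.n_samples
    if T < win:
        return []
    n = (T - win) // stride + 1
    return [
        Segment(rec.patient_id, rec.recording_id, i,
                rec.samples[i * stride: i * stride + win],
                pseudo_patient_id=rec.pseudo_patient_id)
        for i in range(n)
    ]


def fit_norm_stats(reference: Sequence[Recording]) -> NormalizationStats:
    """Per-channel mean and SD pooled over all samples of all recordings.

    SD uses the population convention (divide by n).  A zero-variance channel
    gets its SD clamped to a small floor, with a warning.
    """
    if not reference:
        raise ValueError("reference recording set is empty")
    stacked = np.concatenate([r.samples for r in reference], axis=0)
    if stacked.shape[0] < 2:
        raise ValueError("need at least 2 samples to estimate normalization stats")
    mean = stacked.mean(axis=0)
    sd = stacked.std(axis=0)  # population (ddof=0)
    for ch, name in enumerate(("red", "ir")):
        if sd[ch] < SD_FLOOR:
            warnings.warn(f"{name} channel has (near-)zero variance; "
                          f"SD clamped to {SD_FLOOR}")
            sd[ch] = SD_FLOOR
    return NormalizationStats(mean[0], sd[0], mean[1], sd[1])


def _affine(x, mean, sd, forward: bool):
    if forward:
        return (x - mean) / sd
    return x * sd + mean


def apply_norm(x: Recording | Segment, stats: NormalizationStats):
    """Map each channel to (value − mean)/sd; returns a new object."""
    y = _affine(x.samples, stats.mean, stats.sd, forward=True)
    return replace(x, samples=y)


def invert_norm(x: Recording | Segment, stats: NormalizationStats):
    """Inverse of :func:`apply_norm`."""
    y = _affine(x.samples, stats.mean, stats.sd, forward=False)
    return replace(x, samples=y)


def segments_to_array(segments: Sequence[Segment]) -> np.ndarray:
    """Stack segments into a (batch, 2, L) channel-first array for the encoder."""
    return np.stack([s.samples.T for s in segments])


# ---------------------------------------------------------------------------
# cohort files

def write_cohort(out_dir: str | Path, recordings: Sequence[Recording],
                 splits: dict[str, str] | None = None) -> Path:
    """Write recordings as CSV+JSON pairs plus a manifest; returns manifest path.

    ``splits`` optionally maps patient_id -> 'train'/'test'.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        base = out_dir / rec.recording_id
        np.savetxt(base.with_suffix(".csv"), rec.samples, delimiter=",",
                   header="red,ir", comments="", fmt="%.6f")
        sidecar = {
            "patient_id": rec.patient_id, "recording_id": rec.recording_id,
            "phase": rec.phase, "fs": rec.fs, "duration_s": rec.duration_s,
            "label": rec.label, **{k: rec.meta[k] for k in
                                   ("heart_rate", "resp_rate", "spo2", "clinical")
                                   if k in rec.meta},
        }
        base.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
        rows.append({
            "recording": base.with_suffix(".csv").name,
            "patient_id": rec.patient_id,
            "split": (splits or {}).get(rec.patient_id, ""),
            "label": "" if rec.label is None else rec.label,
        })
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path: str | Path) -> list[Recording]:
    """Load a cohort written by :func:`write_cohort`.

    Labels come from the manifest (missing = unlabelled); split assignments
    are attached to ``Recording.meta['split']``.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    df = pd.read_csv(manifest_path, dtype={"label": "Int64", "split": "string"})
    recs = []
    for row in df.itertuples():
        csv_path = manifest_path.parent / row.recording
        if not csv_path.exists():
            raise FileNotFoundError(f"recording file missing: {csv_path}")
        sidecar_path = csv_path.with_suffix(".json")
        if not sidecar_path.exists():
            raise FileNotFoundError(f"sidecar missing: {sidecar_path}")
        meta = json.loads(sidecar_path.read_text())
        if meta.get("fs") != FS:
            raise ValueError(
                f"{csv_path.name}: sampling rate {meta.get('fs')} Hz is not "
                f"supported; recordings must be {FS} Hz")
        data = pd.read_csv(csv_path)
        if list(data.columns) != ["red", "ir"]:
            raise ValueError(f"{csv_path.name}: expected 'red,ir' columns, "
                             f"got {list(data.columns)}")
        label = None if pd.isna(row.label) else int(row.label)
        rec_meta = {k: meta[k] for k in ("heart_rate", "resp_rate", "spo2", "clinical")
                    if k in meta}
        split = "" if pd.isna(row.split) else str(row.split)
        if split:
            rec_meta["split"] = split
        recs.append(Recording(
            patient_id=str(row.patient_id), recording_id=meta["recording_id"],
            samples=data.to_numpy(dtype=np.float64), phase=meta["phase"],
            fs=int(meta["fs"]), label=label, meta=rec_meta))
    return recs
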