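"""Synthetic paediatric PPG cohort simulator.

Emulates the data structure the pipeline assumes: a cohort of young children
where a latent illness-severity variable drives heart rate and respiratory
rate up, oxygen saturation (SpO2) down, hospitalization risk up, and shifts
eight clinical covariates; each child contributes ~60 s two-channel (red,
infrared) PPG recordings at 80 Hz whose waveform encodes those vitals.

The waveform model per beat is a two-lobe pulse (systolic peak + dicrotic
bump, each a Gaussian), with three respiratory modulations at the breathing
frequency: baseline wander, pulse-amplitude modulation, and beat-interval
modulation (respiratory sinus arrhythmia).  The red/infrared amplitudes are
set so that the ratio-of-ratios R = (AC_red/DC_red)/(AC_ir/DC_ir) satisfies
the common empirical pulse-oximeter calibration ``spo2 = 110 − 25·R``, which
makes SpO2 recoverable from the generated channels by construction.

An "unlabelled" cohort mode emits two admission and two discharge recordings
per child with no labels; discharge recordings are generated from a copy of
the profile with severity shrunk toward zero (the child has partly
recovered), which is why admission and discharge are treated as different
pseudo-patients by the pretext task.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.signal import periodogram

from .signals import FS, Recording, CLINICAL_FIELDS

__all__ = [
    "PatientProfile", "SimConfig", "physio_link", "sample_cohort",
    "synth_recording", "shrink_severity", "generate_cohort",
    "ratio_of_ratios", "estimate_spo2", "spectral_heart_rate",
    "spectral_resp_rate",
    "SPO2_CAL_INTERCEPT", "SPO2_CAL_SLOPE",
]

# empirical linear pulse-oximeter calibration: spo2 = 110 - 25 R
SPO2_CAL_INTERCEPT = 110.0
SPO2_CAL_SLOPE = -25.0

# latent-severity links (units per SD of severity)
HR_BASE, HR_SLOPE, HR_NOISE = 130.0, 22.0, 6.0       # beats/min
RR_BASE, RR_SLOPE, RR_NOISE = 36.0, 11.0, 3.0        # breaths/min
SPO2_BASE, SPO2_SLOPE, SPO2_NOISE = 97.0, -3.0, 0.8  # percent
HOSP_SLOPE = 2.0                                     # logit units per severity SD


@dataclass
class PatientProfile:
    """Latent severity plus true vitals, covariates and outcome for one child."""

    patient_id: str
    severity: float
    heart_rate: float   # beats/min, in [60, 220]
    resp_rate: float    # breaths/min, in [15, 90]
    spo2: float         # percent, in [70, 100]
    hospitalized: int
    clinical: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 60 <= self.heart_rate <= 220:
            raise ValueError(f"heart_rate out of range: {self.heart_rate}")
        if not 15 <= self.resp_rate <= 90:
            raise ValueError(f"resp_rate out of range: {self.resp_rate}")
        if not 70 <= self.spo2 <= 100:
            raise ValueError(f"spo2 out of range: {self.spo2}")
        if self.hospitalized not in (0, 1):
            raise ValueError("hospitalized must be 0 or 1")
        missing = set(CLINICAL_FIELDS) - set(self.clinical)
        if missing:
            raise ValueError(f"missing clinical covariates: {sorted(missing)}")


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings; defaults are the cohort conditions emulated."""

    n_patients: int = 100
    duration_s: float = 60.0
    fs: int = FS
    prevalence_target: float = 0.12
    noise_sd: float = 0.02          # additive sensor noise, signal units
    motion_artifact_rate: float = 0.0  # bursts per minute
    seed: int = 0
    unlabelled: bool = False

    def __post_init__(self):
        if self.fs != FS:
            raise ValueError(f"fs is fixed at {FS} Hz")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0 < self.prevalence_target < 1:
            raise ValueError("prevalence_target must be in (0, 1)")
        n = self.duration_s * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration_s * fs must be an integer sample count")
        if self.noise_sd < 0 or self.motion_artifact_rate < 0:
            raise ValueError("noise_sd and motion_artifact_rate must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


def physio_link(severity: float | np.ndarray):
    """Noise-free monotone links from severity to (HR, RR, SpO2), pre-clipping."""
    hr = HR_BASE + HR_SLOPE * np.asarray(severity)
    rr = RR_BASE + RR_SLOPE * np.asarray(severity)
    spo2 = SPO2_BASE + SPO2_SLOPE * np.asarray(severity)
    return hr, rr, spo2


def _calibrate_intercept(prevalence: float, slope: float = HOSP_SLOPE) -> float:
    """Solve E_{s~N(0,1)}[logistic(a + slope*s)] = prevalence for a."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(80)
    w = weights / weights.sum()

    def expected(a):
        return float(w @ (1.0 / (1.0 + np.exp(-(a + slope * nodes))))) - prevalence

    return brentq(expected, -30.0, 30.0, xtol=1e-10)


def _clinical_covariates(severity: float, hr: float, spo2: float,
                         rng: np.random.Generator) -> dict:
    """Eight triage covariates: continuous ones linear in severity with
    Gaussian noise, binary ones Bernoulli with logistic-in-severity
    probability.  Measured HR/SpO2 are the physiological values plus bounded
    (uniform) device noise."""
    def logistic(x):
        return 1.0 / (1.0 + np.exp(-x))

    return {
        "weight": float(max(2.5, 10.5 - 1.2 * severity + rng.normal(0, 1.5))),
        "muac": float(max(8.0, 14.0 - 1.0 * severity + rng.normal(0, 0.8))),
        "temperature": float(37.2 + 0.6 * severity + rng.normal(0, 0.4)),
        "heart_rate": float(np.clip(hr + rng.uniform(-3, 3), 60, 220)),
        "spo2": float(np.clip(spo2 + rng.uniform(-1, 1), 70, 100)),
        "restlessness": int(rng.random() < logistic(-1.5 + 1.2 * severity)),
        "able_to_drink": int(rng.random() < logistic(2.0 - 1.2 * severity)),
        "difficulty_breathing": int(rng.random() < logistic(-1.8 + 1.5 * severity)),
    }


def _profile_from_severity(pid: str, severity: float, intercept: float,
                           rng: np.random.Generator) -> PatientProfile:
    hr0, rr0, spo20 = physio_link(severity)
    hr = float(np.clip(hr0 + rng.normal(0, HR_NOISE), 60, 220))
    rr = float(np.clip(rr0 + rng.normal(0, RR_NOISE), 15, 90))
    spo2 = float(np.clip(spo20 + rng.normal(0, SPO2_NOISE), 70, 100))
    p_hosp = 1.0 / (1.0 + np.exp(-(intercept + HOSP_SLOPE * severity)))
    hosp = int(rng.random() < p_hosp)
    clinical = _clinical_covariates(severity, hr, spo2, rng)
    return PatientProfile(pid, float(severity), hr, rr, spo2, hosp, clinical)


def sample_cohort(config: SimConfig) -> list[PatientProfile]:
    """Draw a cohort of patient profiles; deterministic under a fixed seed.

    Severity is standard normal; vitals follow monotone links plus clipped
    Gaussian noise; hospitalization is Bernoulli with a logistic-in-severity
    probability whose intercept is calibrated so the expected cohort
    prevalence equals ``config.prevalence_target``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 201]))
    intercept = _calibrate_intercept(config.prevalence_target)
    width = max(4, len(str(config.n_patients)))
    profiles = []
    for i in range(config.n_patients):
        severity = rng.standard_normal()
        pid = f"p{i:0{width}d}"
        profiles.append(_profile_from_severity(pid, severity, intercept, rng))
    return profiles


def shrink_severity(profile: PatientProfile, rng: np.random.Generator,
                    factor: float = 0.3) -> PatientProfile:
    """Discharge-time copy of a profile: severity shrunk toward zero and
    vitals re-derived from the link (the child has partly recovered)."""
    s = profile.severity * factor
    hr0, rr0, spo20 = physio_link(s)
    return replace(
        profile, severity=s,
        heart_rate=float(np.clip(hr0 + rng.normal(0, HR_NOISE / 2), 60, 220)),
        resp_rate=float(np.clip(rr0 + rng.normal(0, RR_NOISE / 2), 15, 90)),
        spo2=float(np.clip(spo20 + rng.normal(0, SPO2_NOISE / 2), 70, 100)),
    )


# ---------------------------------------------------------------------------
# waveform synthesis

def _pulse_train(t: np.ndarray, heart_rate: float, resp_rate: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Zero-mean cardiac AC waveform with respiratory modulations.

    Each beat is a systolic Gaussian plus a smaller, later dicrotic Gaussian;
    beat intervals and pulse amplitudes are modulated at the respiratory
    frequency, and the respiratory phase is randomized per recording.
    """
    f_resp = resp_rate / 60.0
    phi_rsa, phi_am = rng.uniform(0, 2 * np.pi, size=2)
    duration = t[-1] + (t[1] - t[0])

    # beat onset times with respiratory sinus arrhythmia (interval modulation)
    beats = []
    tb = rng.uniform(0, 60.0 / heart_rate)  # random initial beat phase
    while tb < duration:
        beats.append(tb)
        interval = (60.0 / heart_rate) * (
            1.0 + 0.04 * np.sin(2 * np.pi * f_resp * tb + phi_rsa))
        tb += interval

    x = np.zeros_like(t)
    for tb in beats:
        ibi = 60.0 / heart_rate
        amp = 1.0 + 0.12 * np.sin(2 * np.pi * f_resp * tb + phi_am)
        # systolic peak + dicrotic bump, widths tied to the beat interval
        x += amp * np.exp(-0.5 * ((t - tb - 0.30 * ibi) / (0.10 * ibi)) ** 2)
        x += 0.35 * amp * np.exp(-0.5 * ((t - tb - 0.62 * ibi) / (0.14 * ibi)) ** 2)
    return x - x.mean()


def synth_recording(profile: PatientProfile, config: SimConfig,
                    phase: str = "single", rep: int = 0) -> Recording:
    """Generate one two-channel recording for a profile.

    Deterministic given (config.seed, patient_id, phase, rep).  Discharge
    recordings use a severity-shrunken copy of the profile.
    """
    phase_code = {"single": 0, "admission": 1, "discharge": 2}[phase]
    ident = zlib.crc32(profile.patient_id.encode())
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, ident, phase_code, rep]))

    if phase == "discharge":
        profile = shrink_severity(profile, rng)

    n = config.n_samples
    t = np.arange(n) / config.fs
    ac = _pulse_train(t, profile.heart_rate, profile.resp_rate, rng)

    # channel scaling from the SpO2 calibration: R = (110 - spo2)/25
    R = (profile.spo2 - SPO2_CAL_INTERCEPT) / SPO2_CAL_SLOPE
    dc_ir, dc_red = 2.0, 2.0
    ac_ir = 0.30                      # perfusion amplitude, infrared channel
    ac_red = R * ac_ir * dc_red / dc_ir

    f_resp = profile.resp_rate / 60.0
    phi_bw = rng.uniform(0, 2 * np.pi)
    wander = 0.05 * np.sin(2 * np.pi * f_resp * t + phi_bw)  # baseline drift

    ir = dc_ir + ac_ir * ac + wander
    red = dc_red + ac_red * ac + wander

    if config.noise_sd > 0:
        red = red + rng.normal(0, config.noise_sd, size=n)
        ir = ir + rng.normal(0, config.noise_sd, size=n)

    if config.motion_artifact_rate > 0:
        n_events = rng.poisson(config.motion_artifact_rate * config.duration_s / 60.0)
        for _ in range(n_events):
            start = rng.uniform(0, config.duration_s)
            dur = rng.uniform(0.5, 2.0)
            amp = rng.uniform(1.0, 3.0) * rng.choice([-1.0, 1.0])
            mask = (t >= start) & (t < start + dur)
            ramp = amp * (t[mask] - start) / dur  # high-amplitude ramp burst
            red[mask] += ramp
            ir[mask] += ramp

    rec_id = f"{profile.patient_id}_{phase}_{rep}"
    meta = {
        "heart_rate": profile.heart_rate, "resp_rate": profile.resp_rate,
        "spo2": profile.spo2, "clinical": profile.clinical,
        "severity": profile.severity,
    }
    label = None if config.unlabelled else profile.hospitalized
    return Recording(profile.patient_id, rec_id, np.column_stack([red, ir]),
                     phase=phase, fs=config.fs, label=label, meta=meta)


def generate_cohort(config: SimConfig
                    ) -> tuple[list[PatientProfile], list[Recording]]:
    """Profiles plus recordings: one 'single' recording per patient for a
    labelled cohort, or two admission + two discharge recordings (no labels)
    when ``config.unlabelled`` is set."""
    profiles = sample_cohort(config)
    recordings = []
    for prof in profiles:
        if config.unlabelled:
            for phase in ("admission", "discharge"):
                for rep in range(2):
                    recordings.append(synth_recording(prof, config, phase, rep))
        else:
            recordings.append(synth_recording(prof, config, "single", 0))
    return profiles, recordings


# ---------------------------------------------------------------------------
# physiological read-back (used to validate the generator)

def spectral_heart_rate(rec: Recording, channel: int = 1) -> float:
    """Heart rate (bpm) from the dominant periodogram peak in 0.8–4 Hz."""
    f, p = periodogram(rec.samples[:, channel] - rec.samples[:, channel].mean(),
                       fs=rec.fs)
    band = (f >= 0.8) & (f <= 4.0)
    return 60.0 * float(f[band][np.argmax(p[band])])


def spectral_resp_rate(rec: Recording, channel: int = 1) -> float:
    """Respiratory rate (breaths/min) from the low-frequency baseline peak,
    searched below 0.1× the cardiac frequency's band (0.15–1.5 Hz)."""
    x = rec.samples[:, channel] - rec.samples[:, channel].mean()
    f, p = periodogram(x, fs=rec.fs)
    band = (f >= 0.15) & (f <= 1.5)
    return 60.0 * float(f[band][np.argmax(p[band])])


def ratio_of_ratios(rec: Recording) -> float:
    """R = (AC_red/DC_red)/(AC_ir/DC_ir), with AC taken as the periodogram
    amplitude at the cardiac fundamental and DC as the channel mean."""
    hr_hz = spectral_heart_rate(rec) / 60.0
    f, p_red = periodogram(rec.samples[:, 0], fs=rec.fs)
    _, p_ir = periodogram(rec.samples[:, 1], fs=rec.fs)
    k = int(np.argmin(np.abs(f - hr_hz)))
    sl = slice(max(k - 1, 0), k + 2)  # tolerate spectral leakage into neighbours
    ac_red = np.sqrt(p_red[sl].sum())
    ac_ir = np.sqrt(p_ir[sl].sum())
    dc_red = rec.samples[:, 0].mean()
    dc_ir = rec.samples[:, 1].mean()
    return float((ac_red / dc_red) / (ac_ir / dc_ir))


def estimate_spo2(rec: Recording) -> float:
    """SpO2 via the inverse calibration spo2 = 110 − 25·R."""
    return SPO2_CAL_INTERCEPT + SPO2_CAL_SLOPE * ratio_of_ratios(rec)
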