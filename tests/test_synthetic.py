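"""Cohort and waveform generator behaviour."""

import dataclasses

import numpy as np
import pytest

from pulsepair.synthetic import (SimConfig, estimate_spo2, generate_cohort,
                                 physio_link, sample_cohort, shrink_severity,
                                 spectral_heart_rate, spectral_resp_rate,
                                 synth_recording, _calibrate_intercept,
                                 _profile_from_severity)


@pytest.fixture(scope="module")
def base_profile():
    icpt = _calibrate_intercept(0.12)
    return _profile_from_severity("px", 0.0, icpt, np.random.default_rng(5))


def clean_config(**kw):
    return SimConfig(n_patients=1, seed=3, noise_sd=0.0,
                     motion_artifact_rate=0.0, **kw)


class TestCohortSampling:
    def test_seeded_determinism_field_by_field(self):
        cfg = SimConfig(n_patients=25, seed=9)
        a, b = sample_cohort(cfg), sample_cohort(cfg)
        assert a == b

    def test_monotone_severity_links(self):
        hr_lo, rr_lo, spo2_lo = physio_link(-3.0)
        hr_hi, rr_hi, spo2_hi = physio_link(3.0)
        assert hr_hi > hr_lo and rr_hi > rr_lo and spo2_hi < spo2_lo

    def test_profiles_respect_physiological_bounds(self):
        for p in sample_cohort(SimConfig(n_patients=300, seed=2)):
            assert 60 <= p.heart_rate <= 220
            assert 15 <= p.resp_rate <= 90
            assert 70 <= p.spo2 <= 100
            assert p.hospitalized in (0, 1)
            assert len(p.clinical) == 8

    def test_clinical_vitals_track_physiological_values(self):
        for p in sample_cohort(SimConfig(n_patients=100, seed=4)):
            assert abs(p.clinical["heart_rate"] - p.heart_rate) <= 3 + 1e-9
            assert abs(p.clinical["spo2"] - p.spo2) <= 1 + 1e-9

    def test_prevalence_calibration_other_targets(self):
        # intercept calibration must hold for targets other than the default
        for target in (0.05, 0.30):
            cfg = SimConfig(n_patients=4000, prevalence_target=target, seed=8)
            frac = np.mean([p.hospitalized for p in sample_cohort(cfg)])
            assert abs(frac - target) < 0.025

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_patients=0)
        with pytest.raises(ValueError):
            SimConfig(n_patients=5, prevalence_target=1.2)
        with pytest.raises(ValueError):
            SimConfig(n_patients=5, fs=100)


class TestWaveform:
    def test_shape_and_determinism(self, base_profile):
        cfg = clean_config()
        a = synth_recording(base_profile, cfg)
        b = synth_recording(base_profile, cfg)
        assert a.samples.shape == (4800, 2)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_spectral_peak_tracks_heart_rate(self, base_profile):
        for hr in (80, 120, 160, 200):
            p = dataclasses.replace(base_profile, heart_rate=float(hr),
                                    resp_rate=40.0, spo2=95.0)
            rec = synth_recording(p, clean_config())
            assert abs(spectral_heart_rate(rec) - hr) <= 2.0

    def test_baseline_tracks_resp_rate(self, base_profile):
        for rr in (20, 40, 60):
            p = dataclasses.replace(base_profile, heart_rate=130.0,
                                    resp_rate=float(rr), spo2=96.0)
            rec = synth_recording(p, clean_config())
            assert abs(spectral_resp_rate(rec) - rr) <= 3.0

    def test_ratio_of_ratios_recovers_spo2(self, base_profile):
        for spo2 in (80.0, 90.0, 95.0, 99.0):
            p = dataclasses.replace(base_profile, heart_rate=120.0,
                                    resp_rate=35.0, spo2=spo2)
            rec = synth_recording(p, SimConfig(n_patients=1, seed=3,
                                               noise_sd=0.005))
            assert abs(estimate_spo2(rec) - spo2) <= 1.0

    def test_same_profile_recordings_differ_samplewise(self, base_profile):
        cfg = clean_config()
        a = synth_recording(base_profile, cfg, rep=0)
        b = synth_recording(base_profile, cfg, rep=1)
        assert not np.array_equal(a.samples, b.samples)  # phase-randomized
        assert a.meta["heart_rate"] == b.meta["heart_rate"]

    def test_motion_artifacts_add_bursts(self, base_profile):
        quiet = synth_recording(base_profile, clean_config())
        noisy = synth_recording(
            base_profile, SimConfig(n_patients=1, seed=3, noise_sd=0.0,
                                    motion_artifact_rate=10.0))
        assert np.abs(noisy.samples - quiet.samples).max() > 0.5

    def test_discharge_has_milder_physiology(self):
        icpt = _calibrate_intercept(0.12)
        sick = _profile_from_severity("ps", 2.5, icpt, np.random.default_rng(1))
        rng = np.random.default_rng(2)
        recovered = shrink_severity(sick, rng)
        assert abs(recovered.severity) < abs(sick.severity)
        assert recovered.heart_rate < sick.heart_rate


class TestCohortModes:
    def test_labelled_mode_one_recording_with_label(self):
        profiles, recs = generate_cohort(SimConfig(n_patients=5, seed=1))
        assert len(recs) == 5
        assert all(r.phase == "single" and r.label in (0, 1) for r in recs)

    def test_unlabelled_mode_admission_discharge_pairs(self):
        profiles, recs = generate_cohort(
            SimConfig(n_patients=3, seed=1, unlabelled=True))
        assert len(recs) == 12  # 2 admission + 2 discharge each
        assert all(r.label is None for r in recs)
        phases = {r.patient_id: sorted(x.phase for x in recs
                                       if x.patient_id == r.patient_id)
                  for r in recs}
        for ph in phases.values():
            assert ph == ["admission", "admission", "discharge", "discharge"]

    def test_admission_discharge_distinct_pseudo_patients(self):
        _, recs = generate_cohort(SimConfig(n_patients=2, seed=1, unlabelled=True))
        pseudo = {r.pseudo_patient_id for r in recs}
        assert len(pseudo) == 4  # 2 patients x 2 phases
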