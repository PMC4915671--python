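"""Forward EEG model: planted responses, noise, artifacts, study assembly."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

import flowssvep as fs
from flowssvep import preprocess as pp
from flowssvep.spectral import fit_harmonics
from flowssvep.synth import (
    HARMONICS,
    ResponseTopography,
    StudyDesign,
    forward_signal,
    generate_study,
    harmonic_frequencies,
    inject_artifacts,
    load_recording,
    pink_noise,
    save_recording,
    simulate_subject_components,
)


def _single_component_topo(re, im, harmonic="1F1", channel=1, **kw):
    rows = [
        dict(channel=channel, harmonic=harmonic, pattern=p, speed=s,
             re=re, im=im)
        for p in ("radial", "rotation", "translation")
        for s in (2.0, 4.0, 8.0)
    ]
    kw.setdefault("pink_sd", 0.0)
    kw.setdefault("white_sd", 0.0)
    kw.setdefault("artifact_rate", 0.0)
    return ResponseTopography(responses=pd.DataFrame(rows), **kw)


def test_harmonic_frequencies(default_spec):
    assert harmonic_frequencies(default_spec) == {
        "1F1": pytest.approx(1.2),
        "2F1": pytest.approx(2.4),
        "3F1": pytest.approx(3.6),
        "1F2": pytest.approx(24.0),
    }


class TestForwardSignal:
    def test_noiseless_round_trip_single_component(self, default_spec):
        topo = _single_component_topo(2.0, 0.0)
        rec = forward_signal(
            topo, default_spec, None, "radial", 8.0, seed=0,
            n_channels=2, noise=False,
        )
        freqs = list(harmonic_frequencies(default_spec).values())
        re, im = fit_harmonics(rec.samples, rec.sampling_rate, freqs)
        assert re[0, 0] == pytest.approx(2.0, abs=1e-9)
        assert im[0, 0] == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(rec.samples[1], 0)  # unplanted channel silent

    def test_ground_truth_stored(self, default_spec):
        topo = _single_component_topo(1.0, -0.5, harmonic="3F1")
        rec = forward_signal(
            topo, default_spec, None, "rotation", 4.0, seed=0,
            n_channels=1, noise=False,
        )
        assert rec.ground_truth["3F1"][0] == pytest.approx(1.0 - 0.5j)
        assert rec.ground_truth["1F1"][0] == 0

    def test_duration_must_be_integer_cycles(self, default_spec):
        topo = _single_component_topo(1.0, 0.0)
        with pytest.raises(ValueError, match="integer number"):
            forward_signal(
                topo, default_spec, None, "radial", 8.0, seed=0,
                duration=1.0, n_channels=1,
            )

    def test_noise_only_coefficients_zero_mean(self, default_spec):
        topo = _single_component_topo(0.0, 0.0, pink_sd=3.0, white_sd=2.0)
        freqs = list(harmonic_frequencies(default_spec).values())
        coefs = []
        for seed in range(40):
            rec = forward_signal(
                topo, default_spec, None, "radial", 8.0, seed=seed,
                n_channels=1,
            )
            re, im = fit_harmonics(rec.samples, rec.sampling_rate, freqs)
            coefs.append(re[0] + 1j * im[0])
        coefs = np.array(coefs)
        sem = coefs.std(axis=0).max() / np.sqrt(len(coefs))
        assert np.all(np.abs(coefs.mean(axis=0)) < 4 * sem + 1e-12)

    def test_subject_offset_added(self, default_spec):
        topo = _single_component_topo(1.0, 0.0)
        off = np.zeros((1, len(HARMONICS)), dtype=complex)
        off[0, 0] = 0.5 + 0.25j
        rec = forward_signal(
            topo, default_spec, off, "radial", 8.0, seed=0,
            n_channels=1, noise=False,
        )
        assert rec.ground_truth["1F1"][0] == pytest.approx(1.5 + 0.25j)


def test_pink_noise_spectral_slope(rng):
    x = pink_noise(2 ** 16, rng, exponent=1.0, sd=1.0, sampling_rate=432.43)
    f, psd = sps.welch(x, fs=432.43, nperseg=4096)
    band = (f >= 1) & (f <= 50)
    slope = np.polyfit(np.log10(f[band]), np.log10(psd[band]), 1)[0]
    assert slope == pytest.approx(-1.0, abs=0.3)
    assert x.std() == pytest.approx(1.0, abs=1e-9)


class TestInjectArtifacts:
    def test_rate_zero_is_identity(self, default_spec):
        topo = _single_component_topo(1.0, 0.0)
        rec = forward_signal(topo, default_spec, None, "radial", 8.0, 0,
                             n_channels=2, noise=False)
        out, flags = inject_artifacts(rec, default_spec, 0.0, 120.0, seed=1)
        assert not flags.any()
        np.testing.assert_array_equal(out.samples, rec.samples)

    def test_rate_one_flags_every_cycle_via_detector(self, default_spec):
        # background noise means a 120 uV transient always pushes the cycle
        # peak-to-peak strictly beyond the 120 uV rejection bound
        topo = _single_component_topo(1.0, 0.0, pink_sd=6.0, white_sd=3.0)
        rec = forward_signal(topo, default_spec, None, "radial", 8.0, 0,
                             n_channels=4)
        out, flags = inject_artifacts(rec, default_spec, 1.0, 120.0, seed=2)
        assert flags.all()
        epoch = pp.segment_cycles(out, default_spec)
        detected = pp.flag_artifacts(epoch)
        assert detected.all()

    def test_binomial_expectation(self, default_spec):
        topo = _single_component_topo(0.0, 0.0)
        rec = forward_signal(topo, default_spec, None, "radial", 8.0, 0,
                             n_channels=1, noise=False)
        total = sum(
            inject_artifacts(rec, default_spec, 0.2, 120.0, seed=s)[1].sum()
            for s in range(200)
        )
        # 200 trials x 10 cycles x 0.2: mean 400, sd ~18
        assert 300 < total < 500

    def test_invalid_rate(self, default_spec):
        topo = _single_component_topo(0.0, 0.0)
        rec = forward_signal(topo, default_spec, None, "radial", 8.0, 0,
                             n_channels=1, noise=False)
        with pytest.raises(ValueError):
            inject_artifacts(rec, default_spec, 1.5, 120.0, seed=0)


class TestGenerateStudy:
    def test_recording_count(self, default_spec, null_topography):
        design = StudyDesign(n_subjects=2, trials_per_condition=2)
        study = generate_study(
            design, null_topography, default_spec, seed=0, n_channels=2
        )
        assert len(study) == 2 * 9 * 2

    def test_same_seed_identical(self, default_spec, null_topography):
        design = StudyDesign(n_subjects=1, trials_per_condition=1)
        a = generate_study(design, null_topography, default_spec, 3, n_channels=2)
        b = generate_study(design, null_topography, default_spec, 3, n_channels=2)
        for (ra, fa), (rb, fb) in zip(a, b):
            np.testing.assert_array_equal(ra.samples, rb.samples)
            np.testing.assert_array_equal(fa, fb)

    def test_subject_intercept_shared_within_subject(self, default_spec):
        topo = _single_component_topo(1.0, 0.0, subject_intercept_sd=1.0)
        design = StudyDesign(n_subjects=2, trials_per_condition=2,
                             patterns=("radial",), speeds=(8.0,))
        study = generate_study(design, topo, default_spec, 4, n_channels=1)
        truths = {}
        for rec, _ in study:
            truths.setdefault(rec.subject, []).append(rec.ground_truth["1F1"][0])
        for subj, vals in truths.items():
            assert all(v == vals[0] for v in vals)
        # different subjects drew different intercepts
        s1, s2 = (truths[s][0] for s in sorted(truths))
        assert s1 != s2

    def test_zero_intercept_sd_all_subjects_identical(self, default_spec):
        topo = _single_component_topo(1.0, 0.5, subject_intercept_sd=0.0)
        design = StudyDesign(n_subjects=3, trials_per_condition=1,
                             patterns=("radial",), speeds=(8.0,))
        study = generate_study(design, topo, default_spec, 5, n_channels=1)
        for rec, _ in study:
            assert rec.ground_truth["1F1"][0] == pytest.approx(1.0 + 0.5j)

    def test_trials_per_condition_bounds(self):
        with pytest.raises(ValueError):
            StudyDesign(trials_per_condition=11)
        with pytest.raises(ValueError):
            StudyDesign(trials_per_condition=0)


def test_simulate_subject_components_structure(default_spec, demo_topo):
    design = StudyDesign(n_subjects=4)
    comp = simulate_subject_components(
        design, demo_topo, default_spec, seed=6, n_channels=8,
        harmonics=("1F1", "3F1"),
    )
    assert len(comp) == 4 * 9 * 8 * 2
    assert set(comp.harmonic) == {"1F1", "3F1"}
    # same seed reproduces exactly
    comp2 = simulate_subject_components(
        design, demo_topo, default_spec, seed=6, n_channels=8,
        harmonics=("1F1", "3F1"),
    )
    pd.testing.assert_frame_equal(comp, comp2)


def test_recording_io_round_trip(tmp_path, default_spec):
    topo = _single_component_topo(1.0, -1.0)
    rec = forward_signal(topo, default_spec, None, "radial", 8.0, 0,
                         n_channels=2, noise=False, subject="s01", trial=3)
    save_recording(tmp_path, rec, name="trial")
    back = load_recording(tmp_path, "trial")
    np.testing.assert_array_equal(back.samples, rec.samples)
    assert back.subject == "s01" and back.trial == 3
    assert back.ground_truth["1F1"][0] == pytest.approx(1.0 - 1.0j)
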