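"""Signal-cleaning properties: notch, heartbeat template, CAR, envelopes."""

import numpy as np
import pytest
from scipy import signal

from bistableflow.containers import Recording
from bistableflow.preprocess import (
    common_average_reference,
    detect_heartbeats,
    detrend_notch,
    extract_high_gamma,
    heartbeat_template,
    lowpass_downsample,
    remove_heartbeat_artifact,
)
from bistableflow.synthetic import ArtifactParams, inject_artifacts


def band_power(x, fs, f0, bw=2.0):
    f, p = signal.welch(x, fs=fs, nperseg=min(len(x), 4096))
    sel = (f >= f0 - bw) & (f <= f0 + bw)
    return p[sel].mean()


def test_notch_attenuates_line_harmonics_only():
    fs = 512.0
    t = np.arange(int(20 * fs)) / fs
    rng = np.random.default_rng(0)
    x = (np.sin(2 * np.pi * 60 * t) + np.sin(2 * np.pi * 120 * t)
         + np.sin(2 * np.pi * 37 * t) + 0.1 * rng.normal(size=len(t)))
    rec = Recording(data=x[None, :], fs=fs)
    out = detrend_notch(rec)
    for f0 in (60.0, 120.0):
        assert band_power(out.data[0], fs, f0) < 0.01 * band_power(x, fs, f0)
    keep = band_power(out.data[0], fs, 37.0)
    assert keep > 0.8 * band_power(x, fs, 37.0)


def test_notch_rejects_line_at_nyquist():
    rec = Recording(data=np.zeros((1, 1000)), fs=100.0)
    with pytest.raises(ValueError, match="Nyquist"):
        detrend_notch(rec, line_freq=60.0)


def test_detrend_is_per_block():
    fs = 500.0
    n = 400
    x = np.concatenate([np.linspace(0, 5, 200), np.linspace(10, 2, 200)])
    rec = Recording(data=x[None, :], fs=fs)
    out = detrend_notch(rec, block_boundaries=np.array([0, 200]))
    # each block's linear trend removed independently
    assert np.abs(out.data[0, :200]).max() < 1e-8
    assert np.abs(out.data[0, 200:]).max() < 1e-8
    assert out.data.shape == (1, n)


def test_detect_heartbeats_refractory_and_flat_signal():
    fs = 500.0
    ecg = np.zeros(int(10 * fs))
    true_beats = np.arange(0.5, 9.5, 0.8)
    for b in true_beats:
        c = int(b * fs)
        ecg[c:c + 3] = 1.0
        ecg[c + 10:c + 13] = 0.9  # echo inside refractory window: ignored
    beats = detect_heartbeats(ecg, fs)
    assert len(beats) == len(true_beats)
    with pytest.warns(UserWarning, match="flat"):
        out = detect_heartbeats(np.zeros(1000), fs)
    assert out.size == 0


def test_heartbeat_template_recovers_injected_waveform():
    fs = 512.0
    rng = np.random.default_rng(1)
    rec = Recording(data=0.3 * rng.normal(size=(1, int(90 * fs))), fs=fs)
    inj = inject_artifacts(rec, ArtifactParams(artifact_scale=2.0, seed=1))
    tpl = heartbeat_template(inj.recording.data[0], fs, inj.beat_times)
    wave = inj.artifact_waveform
    half = min(len(tpl), len(wave)) // 2
    ct, cw = len(tpl) // 2, len(wave) // 2
    a = tpl[ct - half:ct + half]
    b = wave[cw - half:cw + half]
    # correlated and of matching amplitude near the beat center
    assert np.corrcoef(a, b)[0, 1] > 0.9
    assert abs(a.max() - b.max()) < 0.3 * b.max()


def test_remove_heartbeat_artifact_policies():
    rec = Recording(data=np.random.default_rng(0).normal(size=(1, 5000)), fs=500.0)
    with pytest.warns(UserWarning, match="passed through"):
        out = remove_heartbeat_artifact(rec, np.array([]))
    np.testing.assert_array_equal(out.data, rec.data)
    with pytest.raises(ValueError, match="10 beats"):
        remove_heartbeat_artifact(rec, np.arange(1, 6, 1.0))


def test_common_average_reference_zero_mean():
    rng = np.random.default_rng(2)
    rec = Recording(data=rng.normal(size=(4, 100)) + 5.0, fs=100.0)
    out = common_average_reference(rec)
    np.testing.assert_allclose(out.data.mean(axis=0), 0.0, atol=1e-12)
    with pytest.raises(ValueError):
        common_average_reference(Recording(data=np.zeros((1, 10)), fs=10.0))


def test_high_gamma_envelope_tracks_band_amplitude():
    fs = 512.0
    n = int(30 * fs)
    rng = np.random.default_rng(3)
    sos = signal.butter(3, (50, 120), btype="bandpass", fs=fs, output="sos")
    hg = signal.sosfiltfilt(sos, rng.normal(size=n))
    amp = np.where(np.arange(n) < n // 2, 1.0, 3.0)
    x = amp * hg + 0.1 * rng.normal(size=n)
    env = extract_high_gamma(Recording(data=x[None, :], fs=fs))
    first = env.log_amplitude[0, :n // 2].mean()
    second = env.log_amplitude[0, n // 2:].mean()
    # log10 amplitude ratio of 3 ~ 0.477
    assert second - first == pytest.approx(np.log10(3.0), abs=0.1)
    # per-block demeaning makes each block zero mean
    env2 = extract_high_gamma(Recording(data=x[None, :], fs=fs),
                              block_boundaries=np.array([0, n // 2]))
    assert abs(env2.log_amplitude[0, :n // 2].mean()) < 1e-10
    assert abs(env2.log_amplitude[0, n // 2:].mean()) < 1e-10


def test_lowpass_downsample_rate_and_content():
    fs = 512.0
    t = np.arange(int(10 * fs)) / fs
    x = np.sin(2 * np.pi * 10 * t) + np.sin(2 * np.pi * 100 * t)
    rec = Recording(data=x[None, :], fs=fs)
    out = lowpass_downsample(rec, cutoff=50.0, fs_new=256.0)
    assert out.fs == 256.0
    assert out.n_samples == rec.n_samples // 2
    assert band_power(out.data[0], out.fs, 10.0) > 100 * band_power(out.data[0], out.fs, 100.0)
    with pytest.raises(ValueError):
        lowpass_downsample(rec, cutoff=200.0, fs_new=256.0)
    with pytest.raises(ValueError):
        lowpass_downsample(rec, cutoff=50.0, fs_new=1024.0)
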