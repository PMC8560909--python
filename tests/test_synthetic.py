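"""Synthetic-data generator properties: schedules, VARs, gamma, artifacts."""

import numpy as np
import pytest

from bistableflow.containers import Recording
from bistableflow.synthetic import (
    ArtifactParams,
    CouplingSpec,
    PerceptScheduleParams,
    build_coefficients,
    companion_spectral_radius,
    gen_event_locked_gamma,
    gen_percept_schedule,
    gen_var_recording,
    inject_artifacts,
    simulate_var_trials,
)
from bistableflow.varfit import gc_time


# ---------------------------------------------------------------------------
# percept schedules
# ---------------------------------------------------------------------------

def test_schedule_presses_monotone_within_presentation():
    ev = gen_percept_schedule(PerceptScheduleParams(
        n_presentations=4, reaction_time_jitter=0.2, seed=1))
    for pid in ev.presentation_ids:
        t = ev.presses(pid)["time_s"].to_numpy()
        assert np.all(np.diff(t) > 0)
        assert t.min() >= 0 and t.max() < ev.presentation_length


def test_schedule_alternates_between_percepts():
    ev = gen_percept_schedule(PerceptScheduleParams(n_presentations=6, seed=2))
    for pid in ev.presentation_ids:
        codes = ev.presses(pid)["percept_code"].tolist()
        for a, b in zip(codes, codes[1:]):
            assert a != b


def test_schedule_mean_durations_near_configured():
    params = PerceptScheduleParams(
        presentation_length=400.0, n_presentations=8,
        mean_duration_preferred=8.0, mean_duration_nonpreferred=4.0, seed=3)
    ev = gen_percept_schedule(params)
    durs = {"A": [], "B": []}
    for pid in ev.presentation_ids:
        g = ev.presses(pid)
        t = g["time_s"].to_numpy()
        c = g["percept_code"].to_numpy()
        for i in range(len(t) - 1):
            durs[c[i]].append(t[i + 1] - t[i])
    assert np.mean(durs["A"]) == pytest.approx(8.0, rel=0.15)
    assert np.mean(durs["B"]) == pytest.approx(4.0, rel=0.15)


def test_schedule_unsure_fraction():
    ev = gen_percept_schedule(PerceptScheduleParams(
        presentation_length=300.0, n_presentations=10, p_unsure=0.2, seed=4))
    frac = (ev.events["percept_code"] == "unsure").mean()
    assert 0.1 < frac < 0.3


def test_schedule_rejects_bad_params():
    with pytest.raises(ValueError):
        gen_percept_schedule(PerceptScheduleParams(mean_duration_preferred=-1))
    with pytest.raises(ValueError):
        gen_percept_schedule(PerceptScheduleParams(p_unsure=1.0))


# ---------------------------------------------------------------------------
# condition-switching VAR recordings
# ---------------------------------------------------------------------------

def two_group_spec(gain_a, gain_b, seed=0, **kw):
    return CouplingSpec(
        n_channels=2,
        channel_groups=["occipital", "temporal"],
        directed_gains={
            "baseline": {},
            "A": {("occipital", "temporal"): gain_a},
            "B": {("occipital", "temporal"): gain_b},
        },
        seed=seed,
        **kw,
    )


def test_coefficients_stable_and_baseline_present():
    coeffs = build_coefficients(two_group_spec(0.4, 0.0))
    assert set(coeffs) == {"baseline", "A", "B"}
    for A in coeffs.values():
        assert companion_spectral_radius(A) < 1.0


def test_unstable_var_raises_with_radius():
    # bidirectional strong coupling destabilizes (one-way coupling is
    # triangular and inherits the stable diagonal spectrum)
    spec = CouplingSpec(
        n_channels=2,
        channel_groups=["occipital", "temporal"],
        directed_gains={"baseline": {
            ("occipital", "temporal"): 3.0,
            ("temporal", "occipital"): 3.0,
        }},
    )
    ev = gen_percept_schedule(PerceptScheduleParams(n_presentations=1, seed=0))
    with pytest.raises(ValueError, match="spectral radius"):
        gen_var_recording(spec, events=ev)


def test_condition_switching_changes_directed_coupling():
    """GC from the driven direction is higher in the strongly coupled percept."""
    spec = two_group_spec(0.5, 0.0, seed=7)
    ev = gen_percept_schedule(PerceptScheduleParams(
        presentation_length=120.0, n_presentations=2,
        mean_duration_preferred=10.0, mean_duration_nonpreferred=10.0, seed=7))
    rec = gen_var_recording(spec, events=ev)
    assert rec.n_samples == int(240 * spec.fs)
    # carve per-percept segments (1 s clear of presses) and compare GC
    from bistableflow.granger import extract_trials
    segs = {"A": [], "B": []}
    for pid in ev.presentation_ids:
        g = ev.presses(pid)
        t = g["time_s"].to_numpy() + ev.presentation_onsets[pid]
        c = g["percept_code"].to_numpy()
        for i in range(len(t) - 1):
            if t[i + 1] - t[i] > 3.0:
                segs[c[i]].append((t[i] + 1.0, t[i + 1] - 1.0, c[i]))
    gc = {}
    for code in ("A", "B"):
        tr = extract_trials(rec, segs[code], trial_len_s=0.5)
        gc[code] = gc_time(tr.data, order=3)
    assert gc["A"][0] > gc["B"][0] + 0.01  # occipital -> temporal stronger in A


def test_simulate_var_trials_matches_ground_truth_coupling():
    A = np.zeros((2, 2, 1))
    A[0, 0, 0] = 0.5
    A[1, 1, 0] = 0.5
    A[1, 0, 0] = 0.6
    x = simulate_var_trials(A, 200, 80, np.random.default_rng(0))
    gc_xy, gc_yx = gc_time(x - x.mean(-1, keepdims=True), 1)
    assert gc_xy > 0.1
    assert gc_yx < 0.02


# ---------------------------------------------------------------------------
# event-locked high gamma
# ---------------------------------------------------------------------------

def test_event_locked_gamma_boosts_envelope_near_presses():
    ev = gen_percept_schedule(PerceptScheduleParams(
        presentation_length=120.0, n_presentations=1, seed=5))
    fs = 512.0
    rec = gen_event_locked_gamma(ev, fs, 2, boost_channels=[0],
                                 boost_factor=3.0, seed=5)
    from bistableflow.preprocess import extract_high_gamma
    env = extract_high_gamma(rec)
    presses = ev.absolute_press_times()
    near = np.zeros(rec.n_samples, bool)
    for p in presses:
        c = int(p * fs)
        near[max(0, c - int(0.3 * fs)):c + int(0.3 * fs)] = True
    boosted = env.log_amplitude[0]
    flat = env.log_amplitude[1]
    assert boosted[near].mean() - boosted[~near].mean() > 0.2
    assert abs(flat[near].mean() - flat[~near].mean()) < 0.05


def test_event_locked_gamma_validates_inputs():
    ev = gen_percept_schedule(PerceptScheduleParams(n_presentations=1, seed=0))
    with pytest.raises(ValueError, match="boost_sign"):
        gen_event_locked_gamma(ev, 512.0, 1, boost_sign="bad")
    with pytest.raises(ValueError, match="sampling rate"):
        gen_event_locked_gamma(ev, 200.0, 1)


# ---------------------------------------------------------------------------
# artifacts
# ---------------------------------------------------------------------------

def test_injected_artifact_is_beat_locked_and_ecg_detectable():
    rng = np.random.default_rng(8)
    rec = Recording(data=rng.normal(size=(2, 512 * 60)), fs=512.0)
    inj = inject_artifacts(rec, ArtifactParams(artifact_scale=3.0, seed=8))
    assert inj.recording.data.shape == rec.data.shape
    assert len(inj.beat_times) > 40  # ~70 bpm over a minute
    # contaminated minus clean equals the same waveform at every beat
    diff = inj.recording.data[0] - inj.clean.data[0]
    half = len(inj.artifact_waveform) // 2
    for b in inj.beat_times[5:10]:
        c = int(round(b * rec.fs))
        seg = diff[c - half:c - half + len(inj.artifact_waveform)]
        np.testing.assert_allclose(seg, inj.artifact_waveform, atol=1e-9)
    # R-waves dominate the ECG at the true beats
    from bistableflow.preprocess import detect_heartbeats
    detected = detect_heartbeats(inj.ecg, rec.fs)
    assert len(detected) == len(inj.beat_times)
    assert np.max(np.abs(detected - inj.beat_times)) < 0.05


def test_line_noise_amplitude():
    rec = Recording(data=np.zeros((1, 512 * 4)), fs=512.0)
    inj = inject_artifacts(rec, ArtifactParams(
        artifact_scale=0.0, line_amplitude=2.0, seed=0))
    t = np.arange(rec.n_samples) / rec.fs
    np.testing.assert_allclose(
        inj.recording.data[0], 2.0 * np.sin(2 * np.pi * 60.0 * t), atol=1e-9)
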